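"""Classifier feature gene lists: loading, platform restriction, DE derivation.

Classifiers built on small gene lists transfer better across platforms (no
platform measures every gene of the large historical signatures, and fewer
features mean less over-fitting). This module manages those lists and can
derive a fresh reduced list by intersecting differentially expressed genes
from two independently labelled cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix

logger = logging.getLogger("bdc")

__all__ = ["GeneSet", "DEConfig", "load_gene_list", "restrict_to_platforms", "derive_de_gene_list"]


@dataclass(frozen=True)
class GeneSet:
    """An ordered, duplicate-free list of approved gene symbols."""

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


def load_gene_list(path, name: str) -> GeneSet:
    """Load a one-symbol-per-line gene list; ``#`` comments and blanks skipped,
    whitespace trimmed, duplicates dropped keeping first occurrence."""
    symbols: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym and sym not in seen:
                seen.add(sym)
                symbols.append(sym)
    if not symbols:
        raise ValueError(f"gene list {path} is empty after parsing")
    return GeneSet(name=name, symbols=tuple(symbols))


def restrict_to_platforms(
    genes: GeneSet, matrices: Sequence[ExpressionMatrix]
) -> GeneSet:
    """Subset ``genes`` to those measured on every platform, preserving order.

    Dropped genes are logged per matrix; an empty result raises with the
    per-platform losses.
    """
    if not matrices:
        raise ValueError("at least one matrix required")
    kept = list(genes.symbols)
    losses: dict[str, list[str]] = {}
    for m in matrices:
        available = set(m.gene_ids)
        lost = [g for g in kept if g not in available]
        if lost:
            losses[m.dataset_tag] = lost
            logger.info(
                "restrict_to_platforms: %s lacks %d gene(s): %s",
                m.dataset_tag,
                len(lost),
                lost[:10],
            )
        kept = [g for g in kept if g in available]
    if not kept:
        raise ValueError(f"no gene of {genes.name!r} measured on all platforms; losses: {losses}")
    return GeneSet(name=f"{genes.name}|restricted", symbols=tuple(kept))


@dataclass
class DEConfig:
    """Settings for the cross-dataset differential-expression gene list.

    ``alpha`` is the Benjamini–Hochberg FDR level per dataset; ``max_genes``
    truncates the final ranked list.
    """

    alpha: float = 0.05
    max_genes: int = 60


def _de_single(matrix: ExpressionMatrix, labels: Sequence[str], alpha: float):
    """Per-gene two-sided rank-sum BL vs DLBCL with BH correction.

    Returns (significant mask, effect sign, |Cohen's d|) arrays over genes.
    """
    y = np.asarray(labels)
    for cls in ("BL", "DLBCL"):
        if (y == cls).sum() < 3:
            raise ValueError(
                f"{matrix.dataset_tag}: need >=3 samples of class {cls}, "
                f"got {(y == cls).sum()}"
            )
    x = matrix.values
    bl = x[:, y == "BL"]
    dl = x[:, y == "DLBCL"]
    # vectorized Mann-Whitney across genes
    res = mannwhitneyu(bl, dl, axis=1, alternative="two-sided")
    reject, _, _, _ = multipletests(res.pvalue, alpha=alpha, method="fdr_bh")
    diff = bl.mean(axis=1) - dl.mean(axis=1)
    n1, n2 = bl.shape[1], dl.shape[1]
    pooled_var = (
        (n1 - 1) * bl.var(axis=1, ddof=1) + (n2 - 1) * dl.var(axis=1, ddof=1)
    ) / (n1 + n2 - 2)
    d = np.abs(diff) / np.sqrt(np.maximum(pooled_var, 1e-12))
    return reject, np.sign(diff), d


def derive_de_gene_list(
    a: ExpressionMatrix,
    labels_a: Sequence[str],
    b: ExpressionMatrix,
    labels_b: Sequence[str],
    config: DEConfig | None = None,
) -> GeneSet:
    """Derive a reduced classifier gene list from two labelled cohorts.

    Per cohort, each gene gets a two-sided rank-sum test (BL vs DLBCL) with
    BH FDR control at ``config.alpha``. Genes significant in *both* cohorts
    with a concordant direction of change are ranked by mean absolute effect
    size (Cohen's d averaged over cohorts) and truncated to
    ``config.max_genes``.
    """
    config = config or DEConfig()
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise ValueError("datasets share no genes")
    a_sub = a.subset_genes(shared)
    b_sub = b.subset_genes(shared)
    sig_a, sign_a, d_a = _de_single(a_sub, labels_a, config.alpha)
    sig_b, sign_b, d_b = _de_single(b_sub, labels_b, config.alpha)
    keep = sig_a & sig_b & (sign_a == sign_b) & (sign_a != 0)
    if not keep.any():
        raise ValueError("no gene significant and concordant in both datasets")
    genes = np.asarray(shared)[keep]
    score = ((d_a + d_b) / 2.0)[keep]
    # stable rank: effect size descending, symbol as deterministic tie-break
    order = np.lexsort((genes, -score))
    selected = genes[order][: config.max_genes]
    return GeneSet(name=f"de_alpha{config.alpha}", symbols=tuple(selected))
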