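"""Per-gene cross-platform normalization.

Two platform-agnostic transforms make expression values comparable across
measurement technologies:

* **Z-score** — per gene, ``z = (x - m) / s`` where ``m`` and ``s`` are the
  mean and standard deviation of the gene over all samples (sample sd,
  ``n-1`` denominator).
* **Rank** — per gene, samples are ranked ascending (ties averaged) and
  ``r = R/N - 0.5`` where ``R`` is the sample's rank among the ``N`` samples.

Both operate per dataset independently, matching the transfer-experiment
design (train-set and test-set statistics never mix). A frozen-stats mode
lets single new samples be projected onto stored training statistics.

More sophisticated methods (XPN, DWD, ...) plug in through
:func:`apply_external_normalizer`; they are intentionally not re-implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression_io import ExpressionMatrix

__all__ = [
    "ZScoreStats",
    "ZeroVarianceError",
    "zscore_normalize",
    "rank_normalize",
    "apply_external_normalizer",
]


class ZeroVarianceError(ValueError):
    """A gene row is constant, so z-scoring is undefined."""


@dataclass
class ZScoreStats:
    """Frozen per-gene mean/sd (log-expression units) for projecting new samples."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("mean and sd must cover the same genes")
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0].tolist()
            raise ZeroVarianceError(f"non-positive sd for gene(s): {bad[:10]}")

    def to_dict(self) -> dict:
        return {
            "genes": list(self.mean.index),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZScoreStats":
        idx = pd.Index(d["genes"])
        return cls(mean=pd.Series(d["mean"], index=idx), sd=pd.Series(d["sd"], index=idx))


def zscore_normalize(
    matrix: ExpressionMatrix,
    frozen: Optional[ZScoreStats] = None,
    zero_variance: str = "error",
) -> tuple[ExpressionMatrix, ZScoreStats]:
    """Z-score each gene row; returns the normalized matrix and the stats used.

    By default mean/sd are computed from ``matrix`` itself (``n-1``
    denominator). Supplying ``frozen`` stats instead projects the samples onto
    training statistics — the deployment path for single clinical samples.

    ``zero_variance``: ``"error"`` (default) raises on constant rows;
    ``"zero-fill"`` maps them to z = 0 with a warning.
    """
    if matrix.normalization_state != "raw":
        raise ValueError(
            f"expected raw matrix, got normalization_state={matrix.normalization_state!r}"
        )
    if zero_variance not in ("error", "zero-fill"):
        raise ValueError(f"unknown zero-variance policy {zero_variance!r}")

    if frozen is None:
        mean = matrix.data.mean(axis=1)
        sd = matrix.data.std(axis=1, ddof=1)
        constant = sd.index[(sd == 0) | sd.isna()].tolist()
        if constant:
            if zero_variance == "error":
                raise ZeroVarianceError(
                    f"zero-variance gene(s) in {matrix.dataset_tag}: {constant}"
                )
            import warnings

            warnings.warn(
                f"{len(constant)} zero-variance gene(s) z-scored to 0 "
                f"in {matrix.dataset_tag}",
                stacklevel=2,
            )
            sd = sd.mask((sd == 0) | sd.isna(), 1.0)
            stats = ZScoreStats(mean=mean, sd=sd)
        else:
            stats = ZScoreStats(mean=mean, sd=sd)
    else:
        missing = [g for g in matrix.gene_ids if g not in frozen.mean.index]
        if missing:
            raise ValueError(f"frozen stats missing gene(s): {missing[:10]}")
        stats = ZScoreStats(
            mean=frozen.mean.loc[matrix.gene_ids],
            sd=frozen.sd.loc[matrix.gene_ids],
        )

    z = matrix.data.sub(stats.mean, axis=0).div(stats.sd, axis=0)
    out = replace(matrix, data=z, normalization_state="zscore")
    return out, stats


def rank_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rank each gene row across samples and map to ``r = R/N - 0.5``.

    Ties receive average ranks. Invariant to any strictly increasing
    per-gene transform of the input, which is what makes the transform
    platform-agnostic.
    """
    if matrix.normalization_state != "raw":
        raise ValueError(
            f"expected raw matrix, got normalization_state={matrix.normalization_state!r}"
        )
    n = matrix.n_samples
    if n < 2:
        raise ValueError("rank normalization undefined for a single sample")
    ranks = rankdata(matrix.values, method="average", axis=1)
    r = ranks / n - 0.5
    return replace(
        matrix,
        data=pd.DataFrame(r, index=matrix.data.index, columns=matrix.data.columns),
        normalization_state="rank",
    )


def apply_external_normalizer(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    method_hook: Callable[[pd.DataFrame, pd.DataFrame], tuple[pd.DataFrame, pd.DataFrame]],
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Run a plug-in cross-platform normalizer over a gene-aligned matrix pair.

    The hook receives the two gene x sample DataFrames and must return two
    frames of identical shape, index and columns. Outputs are tagged
    ``normalization_state="external"``.
    """
    if list(a.gene_ids) != list(b.gene_ids):
        raise ValueError("matrices must be gene-aligned before external normalization")
    out_a, out_b = method_hook(a.data.copy(), b.data.copy())
    for src, out in ((a, out_a), (b, out_b)):
        if out.shape != src.data.shape:
            raise ValueError(
                f"hook output shape {out.shape} != input shape {src.data.shape} "
                f"for {src.dataset_tag}"
            )
        if list(out.index) != src.gene_ids or list(out.columns) != src.sample_ids:
            raise ValueError(f"hook permuted genes/samples for {src.dataset_tag}")
    return (
        replace(a, data=out_a, normalization_state="external"),
        replace(b, data=out_b, normalization_state="external"),
    )
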