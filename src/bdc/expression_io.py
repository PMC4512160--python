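"""Reading, validation and harmonization of expression matrices and sample annotations.

The common data model is a gene x sample matrix of log-scale, expression-summarized
values (``ExpressionMatrix``) plus per-sample metadata (``SampleAnnotation``).
Matrices are assumed already preprocessed (e.g. rma/vst + quantile normalization
upstream); no intensity-level transform is applied here.

File formats
------------
Expression TSV
    First column header ``gene_id``, remaining headers are sample ids; UTF-8,
    decimal point, numeric body.
Annotation TSV
    Columns ``sample_id, class_label, class_probability, patient_id,
    platform_version, dissection, array_date``; blank fields mean absent.
Alias map TSV
    Columns ``old_symbol, approved_symbol``.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bdc")

NORMALIZATION_STATES = ("raw", "zscore", "rank", "external")
CLASS_LABELS = ("BL", "DLBCL", "intermediate", "unknown")
DISSECTION_STATES = ("micro", "normal", "unknown")


class ExpressionIOError(ValueError):
    """Malformed expression/annotation input."""


@dataclass
class ExpressionMatrix:
    """A gene x sample table of log-scale expression values.

    ``data`` is a pandas DataFrame with gene symbols (or probe ids, before
    collapse) as the index and sample ids as columns. ``dataset_tag``
    identifies the cohort/platform; ``normalization_state`` records which
    per-gene transform, if any, has been applied.
    """

    data: pd.DataFrame
    dataset_tag: str
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        if self.normalization_state not in NORMALIZATION_STATES:
            raise ExpressionIOError(
                f"unknown normalization_state {self.normalization_state!r}"
            )
        idx = self.data.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate gene id(s): {dups[:10]}")
        cols = self.data.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate sample id(s): {dups[:10]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ExpressionIOError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order; all must be present."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ExpressionIOError(
                f"gene(s) missing from {self.dataset_tag}: {missing}"
            )
        return replace(self, data=self.data.loc[list(genes)].copy())


@dataclass
class SampleAnnotation:
    """Per-sample metadata used for training labels and replicate analysis."""

    sample_id: str
    class_label: str = "unknown"
    class_probability: Optional[float] = None
    patient_id: str = ""
    platform_version: str = ""
    dissection: str = "unknown"
    array_date: Optional[datetime.date] = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ExpressionIOError(
                f"sample {self.sample_id}: unknown class label {self.class_label!r}"
            )
        if self.dissection not in DISSECTION_STATES:
            raise ExpressionIOError(
                f"sample {self.sample_id}: unknown dissection state {self.dissection!r}"
            )
        if self.class_probability is not None and not (
            0.0 <= self.class_probability <= 1.0
        ):
            raise ExpressionIOError(
                f"sample {self.sample_id}: class_probability "
                f"{self.class_probability} outside [0,1]"
            )


@dataclass
class AliasMap:
    """Many-to-one mapping from outdated gene symbols to approved symbols.

    Acyclic by construction: an approved symbol either maps to itself or is
    absent from the map, so resolution never loops.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for old, new in self.mapping.items():
            target = self.mapping.get(new)
            if target is not None and target != new:
                raise ExpressionIOError(
                    f"alias map not acyclic: {old} -> {new} -> {target}"
                )

    def resolve(self, symbol: str) -> str:
        return self.mapping.get(symbol, symbol)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path, dataset_tag: str) -> ExpressionMatrix:
    """Read an expression TSV into a raw ``ExpressionMatrix``.

    The file must have a ``gene_id`` first column and one column per sample.
    Non-numeric cells and duplicated sample ids are rejected with an error
    naming the offending row/column.
    """
    # check the header before pandas mangles duplicate column names (s1, s1.1)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ExpressionIOError(f"{path}: expected gene_id column plus samples")
    if header[0] != "gene_id":
        raise ExpressionIOError(
            f"{path}: first header must be 'gene_id', got {header[0]!r}"
        )
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ExpressionIOError(f"{path}: duplicate sample id {sid!r}")
        seen.add(sid)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    genes = df.iloc[:, 0].tolist()
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    mask = numeric.isna().to_numpy()
    if mask.any():
        r, c = np.argwhere(mask)[0]
        raise ExpressionIOError(
            f"{path}: non-numeric cell {body.iat[r, c]!r} at gene "
            f"{genes[r]!r}, sample {sample_ids[c]!r}"
        )
    numeric.index = pd.Index(genes, name="gene_id")
    return ExpressionMatrix(
        data=numeric.astype(float), dataset_tag=dataset_tag, normalization_state="raw"
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_annotations(path) -> list[SampleAnnotation]:
    """Read the annotation TSV; blank fields become absent/unknown."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id"}
    if not required <= set(df.columns):
        raise ExpressionIOError(f"{path}: missing column(s) {required - set(df.columns)}")
    annotations = []
    for _, row in df.iterrows():
        prob = row.get("class_probability", "")
        date = row.get("array_date", "")
        annotations.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                class_label=row.get("class_label", "") or "unknown",
                class_probability=float(prob) if prob != "" else None,
                patient_id=row.get("patient_id", ""),
                platform_version=row.get("platform_version", ""),
                dissection=row.get("dissection", "") or "unknown",
                array_date=datetime.date.fromisoformat(date) if date else None,
            )
        )
    return annotations


def write_annotations(annotations: Iterable[SampleAnnotation], path) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "sample_id": a.sample_id,
                "class_label": a.class_label,
                "class_probability": "" if a.class_probability is None else a.class_probability,
                "patient_id": a.patient_id,
                "platform_version": a.platform_version,
                "dissection": a.dissection,
                "array_date": "" if a.array_date is None else a.array_date.isoformat(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alias_map(path) -> AliasMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["old_symbol", "approved_symbol"]:
        raise ExpressionIOError(
            f"{path}: expected columns old_symbol, approved_symbol"
        )
    return AliasMap(dict(zip(df["old_symbol"], df["approved_symbol"])))


# ---------------------------------------------------------------------------
# harmonization operations


def _mean_collapse(df: pd.DataFrame, groups: Sequence[str]) -> pd.DataFrame:
    """Average rows sharing a group key, preserving first-appearance order."""
    grouped = df.groupby(pd.Index(groups, name="gene_id"), sort=False).mean()
    return grouped


def collapse_probes(
    matrix: ExpressionMatrix, probe_gene_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene by arithmetic mean.

    Probes absent from ``probe_gene_map`` are dropped (count logged): keeping
    unmapped probes under their probe id would leave a mixed probe/gene index
    downstream.
    """
    mapped = [p for p in matrix.gene_ids if p in probe_gene_map]
    dropped = matrix.n_genes - len(mapped)
    if dropped:
        logger.info(
            "collapse_probes[%s]: dropped %d unmapped probe(s)",
            matrix.dataset_tag,
            dropped,
        )
    if not mapped:
        raise ExpressionIOError(
            f"{matrix.dataset_tag}: no probe maps to any gene; empty output"
        )
    sub = matrix.data.loc[mapped]
    genes = [probe_gene_map[p] for p in mapped]
    collapsed = _mean_collapse(sub, genes)
    return replace(matrix, data=collapsed)


def harmonize_symbols(matrix: ExpressionMatrix, aliases: AliasMap) -> ExpressionMatrix:
    """Replace gene symbols by their approved aliases; merge collisions by mean.

    Symbols not present in the alias map pass through unchanged. Two rows that
    map onto the same approved symbol are averaged, mirroring the probe
    collapse rule.
    """
    renamed = [aliases.resolve(g) for g in matrix.gene_ids]
    n_changed = sum(1 for old, new in zip(matrix.gene_ids, renamed) if old != new)
    if n_changed:
        logger.info(
            "harmonize_symbols[%s]: updated %d symbol(s)",
            matrix.dataset_tag,
            n_changed,
        )
    collapsed = _mean_collapse(matrix.data, renamed)
    return replace(matrix, data=collapsed)


def align_datasets(
    a: ExpressionMatrix, b: ExpressionMatrix, genes: "GeneSetLike"
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the classifier genes both platforms measure.

    Output row order is the gene-set order, identical in both matrices. An
    empty intersection raises, listing what each dataset is missing.
    """
    symbols = list(getattr(genes, "symbols", genes))
    if not symbols:
        raise ExpressionIOError("gene set is empty")
    a_genes = set(a.gene_ids)
    b_genes = set(b.gene_ids)
    shared = [g for g in symbols if g in a_genes and g in b_genes]
    if not shared:
        raise ExpressionIOError(
            "no classifier gene measured on both platforms; "
            f"missing from {a.dataset_tag}: {[g for g in symbols if g not in a_genes]}; "
            f"missing from {b.dataset_tag}: {[g for g in symbols if g not in b_genes]}"
        )
    return a.subset_genes(shared), b.subset_genes(shared)


# typing helper: anything with .symbols or an iterable of strings
GeneSetLike = Sequence
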