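"""Core data containers: expression matrices and genomic (CNV/methylation) matrices.

Expression data are stored probes x samples in a pandas DataFrame, with
explicit flags for the scale (linear MAS5-like intensities vs log2) and
whether quantile normalization has been applied.  Sample annotations
(batch, class label, subtype, replicate group, GAPDH QC probes) live in a
separate DataFrame indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: annotation column names recognised throughout the package
ANN_CLASS = "class_label"
ANN_BATCH = "batch"
ANN_SUBTYPE = "subtype"
ANN_REPLICATE = "replicate_group"
ANN_GAPDH3 = "gapdh_3prime"
ANN_GAPDH5 = "gapdh_5prime"


class MatrixParseError(ValueError):
    """Raised when an expression table on disk is malformed."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = sorted(index[index.duplicated()].unique().tolist())
        raise ValueError(f"duplicated {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Probes x samples expression values plus normalization state.

    Parameters
    ----------
    data:
        DataFrame with probe ids as index and sample ids as columns.
    scale:
        ``"linear"`` or ``"log2"``.
    quantile_normalized:
        True once every column shares the same sorted value multiset.
    annotations:
        Optional per-sample annotations indexed by sample id; must cover
        every sample in ``data``.
    """

    data: pd.DataFrame
    scale: str = "linear"
    quantile_normalized: bool = False
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite (no missing cells)")
        if self.annotations is not None:
            missing = self.data.columns.difference(self.annotations.index)
            if len(missing):
                raise ValueError(f"samples missing from annotations: {list(missing)}")

    # -- convenience accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def annotation(self, name: str) -> pd.Series:
        """Return one annotation column aligned to this matrix's samples."""
        if self.annotations is None or name not in self.annotations.columns:
            raise KeyError(f"annotation {name!r} not available")
        return self.annotations.loc[self.sample_ids, name]

    def subset(self, probes=None, samples=None) -> "ExpressionMatrix":
        """Row/column subset preserving the requested order."""
        data = self.data
        if probes is not None:
            data = data.loc[list(probes)]
        if samples is not None:
            data = data[list(samples)]
        ann = self.annotations
        if ann is not None and samples is not None:
            ann = ann.loc[list(samples)]
        return replace(self, data=data, annotations=ann)

    def with_data(self, data: pd.DataFrame, **changes) -> "ExpressionMatrix":
        return replace(self, data=data, **changes)


def read_expression_table(path, dialect: str = "plain-tsv",
                          scale: str = "linear",
                          annotations: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a tab-delimited expression table.

    ``plain-tsv``: header row of sample ids, first column of probe ids.
    ``gct-like``: two leading metadata lines (version, dimensions) and a
    Description column after the probe-id column, as in GCT files.
    """
    path = Path(path)
    if dialect == "plain-tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif dialect == "gct-like":
        raw = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, dtype=str)
        if len(raw.columns) and str(raw.columns[0]).lower() in ("description", "desc"):
            raw = raw.drop(columns=raw.columns[0])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if raw.index.isna().any() or raw.columns.isna().any():
        raise MatrixParseError(f"{path}: malformed header or probe-id column")
    try:
        _check_unique(raw.index, "probe ids")
        _check_unique(raw.columns, "sample ids")
    except ValueError as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[row]][0]
        raise MatrixParseError(
            f"{path}: non-numeric or missing value at probe {row!r}, sample {col!r}")
    return ExpressionMatrix(numeric.astype(float), scale=scale, annotations=annotations)


def write_expression_table(m: ExpressionMatrix, path) -> None:
    """Write a plain TSV round-trippable by :func:`read_expression_table`."""
    m.data.to_csv(path, sep="\t", index_label=m.data.index.name or "probe_id")


def read_annotations(path) -> pd.DataFrame:
    """Read a sample-annotation TSV keyed by sample id (first column)."""
    ann = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(ann.index, "sample ids")
    return ann


@dataclass
class GenomicMatrix:
    """Gene/probe x sample matrix of copy-number log2 ratios or methylation.

    When ``coords`` is given (columns ``chrom``, ``pos``), features are
    stored sorted by genomic position so that sliding windows over adjacent
    probes are well defined.
    """

    data: pd.DataFrame
    kind: str  # "copy_number" | "methylation"
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("copy_number", "methylation"):
            raise ValueError(f"kind must be 'copy_number' or 'methylation', got {self.kind!r}")
        _check_unique(self.data.index, "feature ids")
        _check_unique(self.data.columns, "sample ids")
        if self.coords is not None:
            missing = self.data.index.difference(self.coords.index)
            if len(missing):
                raise ValueError(f"features missing coordinates: {list(missing)[:5]}")
            order = self.coords.loc[self.data.index].sort_values(
                ["chrom", "pos"], kind="mergesort").index
            self.data = self.data.loc[order]
            self.coords = self.coords.loc[order]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def read_genomic_matrix(path, kind: str, coords_path=None) -> GenomicMatrix:
    """Read a feature x sample TSV, optionally with a (chrom, pos) coordinate TSV."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    coords = None
    if coords_path is not None:
        coords = pd.read_csv(coords_path, sep="\t", index_col=0)
        if not {"chrom", "pos"}.issubset(coords.columns):
            raise MatrixParseError(f"{coords_path}: needs 'chrom' and 'pos' columns")
    return GenomicMatrix(data, kind=kind, coords=coords)


def collapse_segments_to_genes(segments: pd.DataFrame,
                               gene_coords: pd.DataFrame) -> GenomicMatrix:
    """Collapse SEG-like copy-number calls to gene level.

    ``segments`` columns: sample, chrom, start, end, log2.
    ``gene_coords``: indexed by gene id with columns chrom, start, end.
    A gene's value per sample is the mean log2 ratio of overlapping
    segments; genes with no overlapping segment in any sample are dropped.
    """
    required = {"sample", "chrom", "start", "end", "log2"}
    if not required.issubset(segments.columns):
        raise MatrixParseError(f"segment table needs columns {sorted(required)}")
    samples = sorted(segments["sample"].unique())
    rows = {}
    for gene, g in gene_coords.iterrows():
        hit = segments[(segments["chrom"] == g["chrom"])
                       & (segments["end"] >= g["start"])
                       & (segments["start"] <= g["end"])]
        if hit.empty:
            continue
        rows[gene] = hit.groupby("sample")["log2"].mean().reindex(samples)
    data = pd.DataFrame(rows).T
    data = data.dropna(axis=0, how="any")
    coords = gene_coords.loc[data.index, ["chrom", "start"]].rename(columns={"start": "pos"})
    return GenomicMatrix(data, kind="copy_number", coords=coords)
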