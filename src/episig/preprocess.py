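"""QC filtering, normalization, batch adjustment and replicate averaging.

The target state for signature training and projection is: linear
intensities log2-transformed, quantile-normalized, low-signal and
low-variance probes removed, degraded samples (GAPDH 3'/5' ratio > 3)
dropped, and batches mean-aligned per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (ANN_BATCH, ANN_GAPDH3, ANN_GAPDH5, ExpressionMatrix)


def log2_transform(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """log2 with a positive floor applied first (MAS5-like intensities)."""
    if m.scale == "log2":
        raise ValueError("matrix is already log2-scale; refusing to double-transform")
    if floor <= 0:
        raise ValueError("floor must be positive")
    data = np.log2(m.data.clip(lower=floor))
    return m.with_data(data, scale="log2")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map every column onto the mean-of-order-statistics reference.

    Ties within a column receive the mean of the reference values their
    order-statistic positions span (the common convention, which makes the
    transform idempotent).
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = m.values
    n_probes, n_samples = vals.shape
    reference = np.sort(vals, axis=0).mean(axis=1)
    ref_csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(vals)
    for j in range(n_samples):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        boundary = np.flatnonzero(np.diff(sorted_col) != 0)
        starts = np.concatenate([[0], boundary + 1])
        ends = np.concatenate([boundary + 1, [n_probes]])
        group_means = (ref_csum[ends] - ref_csum[starts]) / (ends - starts)
        assigned = np.repeat(group_means, ends - starts)
        out[order, j] = assigned
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return m.with_data(data, quantile_normalized=True)


@dataclass
class ProbeFilterResult:
    matrix: ExpressionMatrix
    removed_low_signal: list = field(default_factory=list)
    removed_low_variance: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_removed_low_signal": len(self.removed_low_signal),
            "n_removed_low_variance": len(self.removed_low_variance),
            "removed_low_signal": list(self.removed_low_signal),
            "removed_low_variance": list(self.removed_low_variance),
        }


def filter_probes(m: ExpressionMatrix,
                  low_signal_quantile: float = 0.25,
                  min_present_fraction: float = 0.25,
                  variance_quantile: float = 0.25) -> ProbeFilterResult:
    """Drop low-signal probes, then low-variance probes.

    A probe is "present" in a sample when its value exceeds the dataset-wide
    ``low_signal_quantile`` quantile; probes present in fewer than
    ``min_present_fraction`` of samples are removed.  Of the survivors,
    probes whose across-sample variance falls strictly below the
    ``variance_quantile`` quantile of the variance distribution are removed.
    Surviving probes keep their original order.
    """
    if m.scale != "log2":
        raise ValueError("filter_probes expects log2-scale values")
    vals = m.values
    signal_threshold = np.quantile(vals, low_signal_quantile)
    present_fraction = (vals > signal_threshold).mean(axis=1)
    keep_signal = present_fraction >= min_present_fraction
    removed_low_signal = [p for p, k in zip(m.probe_ids, keep_signal) if not k]
    if not keep_signal.any():
        raise ValueError("all probes removed by the low-signal filter; "
                         "relax low_signal_quantile / min_present_fraction")
    surviving = m.data.loc[keep_signal]
    variances = surviving.to_numpy().var(axis=1, ddof=1)
    var_threshold = np.quantile(variances, variance_quantile)
    keep_var = variances >= var_threshold
    removed_low_variance = [p for p, k in zip(surviving.index, keep_var) if not k]
    if not keep_var.any():
        raise ValueError("all probes removed by the variance filter; "
                         "relax variance_quantile")
    out = m.with_data(surviving.loc[keep_var])
    return ProbeFilterResult(out, removed_low_signal, removed_low_variance)


@dataclass
class SampleFilterResult:
    matrix: ExpressionMatrix
    removed: list = field(default_factory=list)
    ratios: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"n_removed": len(self.removed), "removed": list(self.removed),
                "ratios": {k: float(v) for k, v in self.ratios.items()}}


def filter_degraded_samples(m: ExpressionMatrix, max_ratio: float = 3.0) -> SampleFilterResult:
    """Drop samples whose GAPDH 3'/5' intensity ratio is strictly above ``max_ratio``.

    A ratio of exactly ``max_ratio`` keeps the sample.  Samples without
    control intensities are retained with a warning.
    """
    if m.annotations is None or not {ANN_GAPDH3, ANN_GAPDH5}.issubset(m.annotations.columns):
        warnings.warn("GAPDH control intensities missing; no samples removed")
        return SampleFilterResult(m, [], {})
    g3 = m.annotation(ANN_GAPDH3).astype(float)
    g5 = m.annotation(ANN_GAPDH5).astype(float)
    ratios = g3 / g5
    removed, kept = [], []
    for sid in m.sample_ids:
        r = ratios[sid]
        if np.isnan(r):
            warnings.warn(f"sample {sid!r}: missing GAPDH controls; retained")
            kept.append(sid)
        elif r > max_ratio:
            removed.append(sid)
        else:
            kept.append(sid)
    return SampleFilterResult(m.subset(samples=kept), removed,
                              {s: ratios[s] for s in removed})


def adjust_batches(m: ExpressionMatrix, strategy: str = "center",
                   batch_key: str = ANN_BATCH) -> ExpressionMatrix:
    """Per-gene within-batch location(/scale) adjustment.

    For each gene, each batch is centered on zero (and scaled to unit SD
    under ``center-scale``), then the gene's global mean is restored, so
    batches become mean-aligned without disturbing the overall level.  This
    is a documented, pluggable stand-in for heavier batch-correction
    schemes such as distance-weighted discrimination.
    """
    if strategy not in ("center", "center-scale"):
        raise ValueError(f"unknown strategy {strategy!r}")
    batches = m.annotation(batch_key)
    if batches.isna().any():
        raise ValueError("every sample needs a batch label")
    global_mean = m.data.mean(axis=1)
    out = m.data.copy()
    for batch, cols in batches.groupby(batches).groups.items():
        cols = list(cols)
        block = m.data[cols]
        centered = block.sub(block.mean(axis=1), axis=0)
        if strategy == "center-scale":
            if len(cols) < 2:
                raise ValueError(f"batch {batch!r} has a single sample; "
                                 "center-scale needs >= 2 per batch")
            sd = block.std(axis=1, ddof=1).replace(0.0, 1.0)
            centered = centered.div(sd, axis=0)
        out[cols] = centered.add(global_mean, axis=0)
    return m.with_data(out)


def average_replicates(obj, replicate_key):
    """Average replicate columns (ExpressionMatrix) or rows (ActivityTable).

    ``replicate_key`` is an annotation column name (ExpressionMatrix only)
    or an explicit sample->group mapping / Series.  One output column/row
    per group, in order of first appearance; groups of size 1 pass through.
    """
    from .projection import ActivityTable  # local import to avoid a cycle

    if isinstance(obj, ExpressionMatrix):
        if isinstance(replicate_key, str):
            groups = obj.annotation(replicate_key)
        else:
            groups = pd.Series(dict(replicate_key)).loc[obj.sample_ids]
        _check_groups(groups)
        order = list(dict.fromkeys(groups))
        data = obj.data.T.groupby(groups, sort=False).mean().T[order]
        ann = None
        if obj.annotations is not None:
            first = {g: groups[groups == g].index[0] for g in order}
            ann = obj.annotations.loc[[first[g] for g in order]]
            ann.index = order
        return ExpressionMatrix(data, scale=obj.scale,
                                quantile_normalized=obj.quantile_normalized,
                                annotations=ann)
    if isinstance(obj, ActivityTable):
        groups = pd.Series(dict(replicate_key)) if not isinstance(replicate_key, pd.Series) \
            else replicate_key
        groups = groups.loc[obj.raw.index]
        _check_groups(groups)
        order = list(dict.fromkeys(groups))
        raw = obj.raw.groupby(groups, sort=False).mean().loc[order]
        # rescaling is recomputed after averaging, per the fixed pipeline order
        return ActivityTable(raw=raw, rescaled=None, dataset_id=obj.dataset_id,
                             meta=dict(obj.meta, replicate_averaged=True))
    raise TypeError(f"cannot average replicates of {type(obj).__name__}")


def _check_groups(groups: pd.Series) -> None:
    if groups.isna().any() or any(str(g) == "" for g in groups):
        raise ValueError("empty or missing replicate-group key")
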