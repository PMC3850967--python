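"""Copy-number and methylation correlates of activity-defined subgroups.

Extreme groups are tumors at opposite corners of a pathway pair (e.g.
EZH2-high / HDAC4-low vs EZH2-low / HDAC4-high).  Copy-number genes are
labeled subgroup-specifically altered when the log2 tumor/normal ratio
exceeds +-0.5 in at least 20% of one subgroup and not the other; genes
altered in both subgroups are removed.  Differential methylation uses a
two-sample Welch t-test on sliding-window probe means (p < 0.1 kept), with
the false-positive rate calibrated by shuffling sample labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import GenomicMatrix
from .projection import ActivityTable


def define_extreme_groups(a, pathway_a: str, pathway_b: str, cutoff: float,
                          symmetric: bool = True) -> tuple[list, list]:
    """Opposite-corner sample groups on a pathway pair.

    Under the default symmetric rule, "high" means score > max(cutoff,
    1 - cutoff) and "low" means score < min(cutoff, 1 - cutoff), so a
    cutoff of 0.2 selects >0.8 / <0.2 corners while 0.5 splits at the
    midpoint.  With ``symmetric=False`` both conditions use the cutoff
    itself (high > cutoff, low < cutoff).
    Group 1 = A high & B low; group 2 = A low & B high.
    """
    scores = a.scores() if isinstance(a, ActivityTable) else pd.DataFrame(a)
    sa, sb = scores[pathway_a], scores[pathway_b]
    if symmetric:
        hi, lo = max(cutoff, 1 - cutoff), min(cutoff, 1 - cutoff)
    else:
        hi = lo = cutoff
    group1 = list(scores.index[(sa > hi) & (sb < lo)])
    group2 = list(scores.index[(sa < lo) & (sb > hi)])
    if not group1 or not group2:
        raise ValueError(f"empty extreme group at cutoff {cutoff}: "
                         f"|group1|={len(group1)}, |group2|={len(group2)}")
    return group1, group2


def cnv_subgroup_filter(g: GenomicMatrix, group1, group2,
                        amp_threshold: float = 0.5,
                        del_threshold: float = -0.5,
                        min_fraction: float = 0.2) -> pd.DataFrame:
    """Classify genes by subgroup-specific copy-number alteration.

    A gene is altered within a subgroup when the fraction of that
    subgroup's samples with log2 ratio > ``amp_threshold`` (gain) or
    < ``del_threshold`` (loss) reaches ``min_fraction``.  Genes altered in
    both subgroups (any direction) are removed; a gene gained in one group
    and lost in the other also counts as altered in both.  Every gene gets
    exactly one status.
    """
    if g.kind != "copy_number":
        raise ValueError("expected a copy_number matrix")
    group1, group2 = list(group1), list(group2)
    if set(group1) & set(group2):
        raise ValueError("extreme groups must be disjoint")
    if not group1 or not group2:
        raise ValueError("both groups must be non-empty")
    out = {}
    for label, members in (("g1", group1), ("g2", group2)):
        block = g.data[members].to_numpy()
        out[f"frac_gain_{label}"] = (block > amp_threshold).mean(axis=1)
        out[f"frac_loss_{label}"] = (block < del_threshold).mean(axis=1)
    df = pd.DataFrame(out, index=g.data.index)
    g1_alt = (df["frac_gain_g1"] >= min_fraction) | (df["frac_loss_g1"] >= min_fraction)
    g2_alt = (df["frac_gain_g2"] >= min_fraction) | (df["frac_loss_g2"] >= min_fraction)
    status = pd.Series("none", index=df.index, dtype=object)
    status[g1_alt & g2_alt] = "removed"
    only1 = g1_alt & ~g2_alt
    only2 = g2_alt & ~g1_alt
    gain1 = df["frac_gain_g1"] >= df["frac_loss_g1"]
    gain2 = df["frac_gain_g2"] >= df["frac_loss_g2"]
    status[only1 & gain1] = "group1_specific_gain"
    status[only1 & ~gain1] = "group1_specific_loss"
    status[only2 & gain2] = "group2_specific_gain"
    status[only2 & ~gain2] = "group2_specific_loss"
    df["status"] = status
    return df


def _window_means(g: GenomicMatrix, window_size: int) -> pd.DataFrame:
    """Centered rolling mean over adjacent same-chromosome probes."""
    if g.coords is None:
        raise ValueError("genomic coordinates required for window construction")
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError("window_size must be an odd positive count")
    pieces = []
    for _, idx in g.coords.groupby("chrom", sort=False).groups.items():
        block = g.data.loc[idx]
        if window_size > len(block):
            warnings.warn(f"window of {window_size} exceeds chromosome probe "
                          f"count {len(block)}; truncating")
        pieces.append(block.rolling(window_size, center=True, min_periods=1).mean())
    return pd.concat(pieces).loc[g.data.index]


def sliding_window_meth_test(g: GenomicMatrix, group1, group2,
                             window_size: int = 5,
                             alpha: float = 0.1) -> pd.DataFrame:
    """Welch t-test of window-averaged methylation between two subgroups.

    With ``window_size=1`` this reduces exactly to a per-probe Welch test.
    Features with identical, variance-free values in both groups get
    t = 0, p = 1.  ``kept`` flags features with p < alpha.
    """
    group1, group2 = list(group1), list(group2)
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs >= 2 samples")
    win = _window_means(g, window_size)
    w1 = win[group1].to_numpy()
    w2 = win[group2].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(w1, w2, axis=1, equal_var=False)
    # zero variance in both groups: equal means -> no evidence, else infinite t
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        equal_means = np.isclose(w1.mean(axis=1), w2.mean(axis=1))
        t = np.where(degenerate & equal_means, 0.0, t)
        p = np.where(degenerate & equal_means, 1.0, p)
        t = np.where(degenerate & ~equal_means, np.inf, t)
        p = np.where(degenerate & ~equal_means, 0.0, p)
    result = pd.DataFrame({"t": t, "p": p, "kept": p < alpha}, index=win.index)
    # optional BH-adjusted column for convenience (not part of the original
    # procedure, which controls error via the permutation estimate only)
    order = np.argsort(p, kind="mergesort")
    m = len(p)
    bh = np.empty(m)
    ranked = p[order] * m / (np.arange(m) + 1)
    bh[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    result["p_bh"] = np.clip(bh, 0, 1)
    return result


@dataclass
class PermutationFPR:
    mean_fraction: float
    sd_fraction: float
    se_binomial: float
    fractions: np.ndarray

    def to_dict(self) -> dict:
        return {"mean_fraction": self.mean_fraction,
                "sd_fraction": self.sd_fraction,
                "se_binomial": self.se_binomial,
                "fractions": self.fractions.tolist()}


def permutation_false_positive_rate(g: GenomicMatrix, group1, group2,
                                    window_size: int = 5, alpha: float = 0.1,
                                    n_perm: int = 100, seed=None) -> PermutationFPR:
    """Estimate the kept-fraction under label shuffling.

    Sample labels are shuffled ``n_perm`` times preserving group sizes; the
    fraction of features with p < alpha is recorded per shuffle.  Reports
    the mean fraction, its spread across shuffles, and a binomial standard
    error; invariant to which group is called "1".
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    group1, group2 = list(group1), list(group2)
    # pooled order is canonical so the estimate ignores which group is "1"
    pooled = np.array(sorted(group1 + group2, key=str), dtype=object)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = len(group1)
    fractions = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(pooled))
        p1 = list(pooled[perm[:n1]])
        p2 = list(pooled[perm[n1:]])
        res = sliding_window_meth_test(g, p1, p2, window_size=window_size, alpha=alpha)
        fractions[i] = res["kept"].mean()
    mean = float(fractions.mean())
    sd = float(fractions.std(ddof=1)) if n_perm > 1 else 0.0
    n_features = g.data.shape[0]
    se = float(np.sqrt(max(mean * (1 - mean), 0.0) / (n_features * n_perm)))
    return PermutationFPR(mean_fraction=mean, sd_fraction=sd, se_binomial=se,
                          fractions=fractions)
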