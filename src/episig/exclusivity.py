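"""Relationships among pathway activities across a tumor compendium.

Covers the Spearman correlation matrix over pathways, 2x2 quadrant
classification of a pathway pair at an activation threshold, the
co-activation deficit test (observed joint activation below the
independence expectation), and subtype association by one-way ANOVA with
enrichment fractions among highly activated samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .projection import ActivityTable


def _scores_frame(a) -> pd.DataFrame:
    if isinstance(a, ActivityTable):
        return a.scores()
    return pd.DataFrame(a)


def pairwise_correlations(a, method: str = "spearman") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric Spearman correlation (and p-value) matrix over pathways.

    Ranks use average ties; p-values use the standard large-sample
    t approximation.  A constant pathway column yields NaN with a warning.
    """
    if method != "spearman":
        raise ValueError("only spearman correlations are supported")
    scores = _scores_frame(a)
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 samples for correlations")
    cols = list(scores.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            xi, xj = scores[ci].to_numpy(), scores[cj].to_numpy()
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                warnings.warn(f"constant pathway column in pair ({ci}, {cj}); "
                              "correlation undefined")
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.spearmanr(xi, xj)
            r.loc[ci, cj] = r.loc[cj, ci] = rij
            p.loc[ci, cj] = p.loc[cj, ci] = pij
    return r, p


@dataclass
class QuadrantSummary:
    """2x2 activation counts for a pathway pair at one activation rule.

    ``threshold`` is either the numeric cutoff applied to both rescaled
    scores, or a dict describing the model-decision-boundary rule (raw
    probability > 1/2) with its rescaled-scale equivalents per pathway.
    """

    threshold: float | dict
    both_active: int
    a_only: int
    b_only: int
    neither: int
    pathway_a: str = "A"
    pathway_b: str = "B"
    p_value: float | None = None

    @property
    def n(self) -> int:
        return self.both_active + self.a_only + self.b_only + self.neither

    @property
    def observed_coactivation(self) -> float:
        return self.both_active / self.n

    @property
    def marginal_a(self) -> float:
        return (self.both_active + self.a_only) / self.n

    @property
    def marginal_b(self) -> float:
        return (self.both_active + self.b_only) / self.n

    @property
    def expected_coactivation(self) -> float:
        # independence expectation: exactly the product of the marginals
        return self.marginal_a * self.marginal_b

    def to_dict(self) -> dict:
        return {
            "pathway_a": self.pathway_a, "pathway_b": self.pathway_b,
            "threshold": self.threshold, "n": self.n,
            "counts": {"both_active": self.both_active, "a_only": self.a_only,
                       "b_only": self.b_only, "neither": self.neither},
            "observed_coactivation": self.observed_coactivation,
            "marginal_a": self.marginal_a, "marginal_b": self.marginal_b,
            "expected_coactivation": self.expected_coactivation,
            "p_value": self.p_value,
        }


def _activation_mask(a, pathway: str, threshold) -> pd.Series:
    """Boolean activation per sample; strict inequality at the boundary.

    ``threshold=None`` uses the probit model's own decision boundary (raw
    activation probability > 1/2, the same rule LOOCV accuracy uses),
    which is robust to the top-compression of the log/min-max rescaled
    scale; a numeric threshold is applied to the rescaled score.
    """
    if threshold is None:
        if not isinstance(a, ActivityTable):
            raise ValueError("probability-boundary activation needs an "
                             "ActivityTable with raw probabilities; pass an "
                             "explicit rescaled-score threshold instead")
        return a.raw[pathway] > 0.5
    return _scores_frame(a)[pathway] > threshold


def rescaled_equivalent_threshold(a: ActivityTable, pathway: str,
                                  p_star: float = 0.5) -> float:
    """Rescaled-score value corresponding to raw probability ``p_star``."""
    y = np.log(a.raw[pathway].to_numpy(dtype=float))
    span = y.max() - y.min()
    if span == 0:
        return 0.5
    return float((np.log(p_star) - y.min()) / span)


def classify_quadrants(a, pathway_a: str, pathway_b: str,
                       threshold: float | None = None
                       ) -> tuple[pd.Series, QuadrantSummary]:
    """Label every sample as both / A_only / B_only / neither.

    By default a sample is "active" on a pathway when its raw activation
    probability exceeds 1/2 (the model's decision boundary); passing a
    numeric ``threshold`` instead applies ``rescaled score > threshold``
    to both pathways.  Either way the boundary itself is not active
    (strict inequality).
    """
    scores = _scores_frame(a)
    for pw in (pathway_a, pathway_b):
        if pw not in scores.columns:
            raise KeyError(f"pathway {pw!r} not present in activity table")
    active_a = _activation_mask(a, pathway_a, threshold)
    active_b = _activation_mask(a, pathway_b, threshold)
    if threshold is None:
        threshold_used = {"rule": "raw_probability>0.5",
                          "rescaled_equivalent": {
                              pathway_a: rescaled_equivalent_threshold(a, pathway_a),
                              pathway_b: rescaled_equivalent_threshold(a, pathway_b)}}
    else:
        threshold_used = threshold
    labels = pd.Series("neither", index=scores.index, dtype=object)
    labels[active_a & active_b] = "both"
    labels[active_a & ~active_b] = "A_only"
    labels[~active_a & active_b] = "B_only"
    summary = QuadrantSummary(
        threshold=threshold_used,
        both_active=int((active_a & active_b).sum()),
        a_only=int((active_a & ~active_b).sum()),
        b_only=int((~active_a & active_b).sum()),
        neither=int((~active_a & ~active_b).sum()),
        pathway_a=pathway_a, pathway_b=pathway_b)
    summary.p_value = coactivation_deficit_test(summary)
    return labels, summary


def coactivation_deficit_test(q: QuadrantSummary, method: str = "binomial") -> float:
    """One-sided probability of so little co-activation under independence.

    ``binomial`` (default): ``P(X <= both_active)`` for
    ``X ~ Binomial(n, marginal_A * marginal_B)``.  Because the marginals
    are estimated from the same samples and co-vary with the observed
    count, this plug-in test is strongly conservative (measured type-I
    error well below nominal); it is kept as the headline deficit measure
    because conservatism only strengthens a rejection.

    ``fisher`` / ``fisher-midp``: the classical calibrated alternatives
    that condition on the observed margins — one-sided hypergeometric
    probability of the 2x2 table, without or with the mid-p correction
    for discreteness.  Use these when the type-I error itself matters.
    """
    if q.n < 1:
        raise ValueError("empty quadrant summary")
    if method == "binomial":
        expected = q.expected_coactivation
        if expected == 0:
            return 1.0 if q.both_active == 0 else 0.0
        return float(stats.binom.cdf(q.both_active, q.n, expected))
    if method in ("fisher", "fisher-midp"):
        row_a = q.both_active + q.a_only
        col_b = q.both_active + q.b_only
        p = stats.hypergeom.cdf(q.both_active, q.n, row_a, col_b)
        if method == "fisher-midp":
            p -= 0.5 * stats.hypergeom.pmf(q.both_active, q.n, row_a, col_b)
        return float(p)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SubtypeAssociation:
    f_statistic: dict            # pathway -> F
    p_value: dict                # pathway -> p
    subtype_means: pd.DataFrame  # subtype x pathway
    enrichment: pd.Series        # fraction of jointly "activated" samples per subtype
    n_activated: int
    conditions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"f_statistic": {k: float(v) for k, v in self.f_statistic.items()},
                "p_value": {k: float(v) for k, v in self.p_value.items()},
                "subtype_means": self.subtype_means.to_dict(),
                "enrichment": self.enrichment.to_dict(),
                "n_activated": self.n_activated,
                "conditions": self.conditions}


def subtype_association(a, subtype_labels, pathways,
                        threshold: float | None = None) -> SubtypeAssociation:
    """One-way ANOVA of activity across subtypes, plus enrichment fractions.

    ``pathways`` may be a single name, a list of names (all required
    "high"), or a mapping name -> "high"/"low".  Enrichment is the subtype
    composition of the samples satisfying every condition jointly.  Under
    the default activation rule (``threshold=None``) "high" means raw
    probability > 1/2 and "low" means raw probability < 1/2; with a
    numeric threshold, "high" means score > threshold and "low" means
    score < 1 - threshold.  Subtypes with fewer than 2 samples are
    dropped with a warning.
    """
    scores = _scores_frame(a)
    if isinstance(pathways, str):
        conditions = {pathways: "high"}
    elif isinstance(pathways, dict):
        conditions = dict(pathways)
    else:
        conditions = {p: "high" for p in pathways}
    for pw, direction in conditions.items():
        if pw not in scores.columns:
            raise KeyError(f"pathway {pw!r} not present")
        if direction not in ("high", "low"):
            raise ValueError(f"condition for {pw!r} must be 'high' or 'low'")
    subtypes = pd.Series(subtype_labels)
    subtypes = subtypes.loc[scores.index]
    sizes = subtypes.value_counts()
    small = sizes[sizes < 2].index
    if len(small):
        warnings.warn(f"dropping subtype(s) with < 2 samples: {list(small)}")
        keep = ~subtypes.isin(small)
        scores_anova = scores[keep]
        subtypes_anova = subtypes[keep]
    else:
        scores_anova, subtypes_anova = scores, subtypes
    if subtypes_anova.nunique() < 2:
        raise ValueError("need at least 2 subtypes with >= 2 samples each")
    f_stat, p_val = {}, {}
    for pw in conditions:
        groups = [scores_anova.loc[subtypes_anova == s, pw].to_numpy()
                  for s in subtypes_anova.unique()]
        f, p = stats.f_oneway(*groups)
        f_stat[pw], p_val[pw] = float(f), float(p)
    subtype_means = scores_anova.groupby(subtypes_anova).mean()[list(conditions)]
    mask = pd.Series(True, index=scores.index)
    for pw, direction in conditions.items():
        if threshold is None:
            high = _activation_mask(a, pw, None)
            mask &= high if direction == "high" else ~high
        elif direction == "high":
            mask &= scores[pw] > threshold
        else:
            mask &= scores[pw] < 1 - threshold
    activated = subtypes[mask]
    if len(activated):
        enrichment = activated.value_counts(normalize=True)
    else:
        enrichment = pd.Series(dtype=float)
    return SubtypeAssociation(f_statistic=f_stat, p_value=p_val,
                              subtype_means=subtype_means, enrichment=enrichment,
                              n_activated=int(mask.sum()),
                              conditions={k: v for k, v in conditions.items()})
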