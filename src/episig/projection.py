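"""Project trained signatures onto independent expression datasets.

The fixed pipeline order for cross-dataset comparison is:
predict raw probabilities -> average replicates -> rescale within dataset.
Rescaling takes the log of the raw probabilities and linearly maps them to
span [0, 1] within each dataset; any log base gives the identical result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .signature_model import SignatureModel


@dataclass
class ActivityTable:
    """Samples x pathways activation probabilities and rescaled scores."""

    raw: pd.DataFrame
    rescaled: pd.DataFrame | None = None
    dataset_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.raw.to_numpy(dtype=float)
        if ((vals <= 0) | (vals >= 1)).any():
            raise ValueError("raw probabilities must lie strictly in (0, 1)")
        if self.rescaled is not None:
            r = self.rescaled.to_numpy(dtype=float)
            if ((r < 0) | (r > 1)).any():
                raise ValueError("rescaled scores must lie in [0, 1]")
            if not (self.rescaled.index.equals(self.raw.index)
                    and self.rescaled.columns.equals(self.raw.columns)):
                raise ValueError("rescaled table must match raw table shape/labels")

    @property
    def sample_ids(self) -> list:
        return list(self.raw.index)

    @property
    def pathway_names(self) -> list:
        return list(self.raw.columns)

    def scores(self) -> pd.DataFrame:
        """Rescaled scores, computing them on the fly if absent."""
        if self.rescaled is None:
            return rescale_table(self).rescaled
        return self.rescaled


@dataclass
class MatchedLoadings:
    gene_ids: list
    u: np.ndarray      # restricted to matched genes, re-normalized to unit length
    coverage: float


def match_genes(model: SignatureModel, m: ExpressionMatrix,
                min_coverage: float = 0.5) -> MatchedLoadings:
    """Map signature genes into the target matrix and restrict the loadings."""
    present_mask = np.array([g in m.data.index for g in model.gene_ids])
    coverage = float(present_mask.mean())
    if coverage < min_coverage:
        raise ValueError(f"only {coverage:.0%} of signature genes found in target "
                         f"(floor {min_coverage:.0%}); missing {1 - coverage:.0%}")
    genes = [g for g, ok in zip(model.gene_ids, present_mask) if ok]
    u = model.u[present_mask]
    u = u / np.linalg.norm(u)
    return MatchedLoadings(gene_ids=genes, u=u, coverage=coverage)


def predict_activity(model: SignatureModel, m: ExpressionMatrix,
                     standardization: str = "target",
                     min_coverage: float = 0.5) -> tuple[pd.Series, dict]:
    """Raw activation probability per target sample.

    Target rows are standardized per gene within the target dataset by
    default (``standardization="target"``), which is scale-robust across
    platforms; ``"training"`` reuses the training-set parameters instead.
    Zero-variance signature genes in the target are dropped with a warning
    and the loadings re-normalized.
    """
    if m.scale != "log2":
        warnings.warn("target matrix is not log2-scale; projections assume "
                      "log2 + quantile-normalized input")
    if standardization not in ("target", "training"):
        raise ValueError(f"unknown standardization {standardization!r}")
    matched = match_genes(model, m, min_coverage=min_coverage)
    x = m.data.loc[matched.gene_ids].to_numpy(dtype=float)
    u = matched.u
    if standardization == "target":
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        ok = sd > 0
        if not ok.all():
            dropped = [g for g, o in zip(matched.gene_ids, ok) if not o]
            warnings.warn(f"dropping {len(dropped)} zero-variance signature "
                          f"gene(s) in target: {dropped[:5]}")
            x, mu, sd, u = x[ok], mu[ok], sd[ok], u[ok]
            u = u / np.linalg.norm(u)
    else:
        idx = [model.gene_ids.index(g) for g in matched.gene_ids]
        mu = model.gene_means[idx]
        sd = model.gene_sds[idx]
    xs = (x - mu[:, None]) / sd[:, None]
    scores = u @ xs
    probs = model.predict(scores)
    info = {"coverage": matched.coverage, "n_genes_used": len(u),
            "standardization": standardization}
    return pd.Series(probs, index=m.sample_ids, name=model.pathway or "activity"), info


def rescale_activity(raw) -> np.ndarray:
    """Within-dataset log + min-max rescale of one pathway's probabilities.

    ``score = (log(p) - min log(p)) / (max log(p) - min log(p))``; a
    degenerate (constant) input maps every sample to 0.5.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one probability")
    if ((raw <= 0) | (raw >= 1)).any():
        raise ValueError("raw probabilities must lie strictly in (0, 1)")
    y = np.log(raw)
    span = y.max() - y.min()
    if span == 0:
        return np.full_like(y, 0.5)
    return (y - y.min()) / span


def build_activity_table(models: dict, m: ExpressionMatrix, dataset_id: str = "",
                         standardization: str = "target",
                         min_coverage: float = 0.5) -> ActivityTable:
    """Apply several trained signatures to one dataset (raw probabilities)."""
    cols, coverage = {}, {}
    for name, model in models.items():
        probs, info = predict_activity(model, m, standardization=standardization,
                                       min_coverage=min_coverage)
        cols[name] = probs
        coverage[name] = info["coverage"]
    raw = pd.DataFrame(cols)
    return ActivityTable(raw=raw, dataset_id=dataset_id,
                         meta={"coverage": coverage,
                               "standardization": standardization})


def rescale_table(table: ActivityTable) -> ActivityTable:
    """Rescale every pathway column within the dataset; flags degenerate ones."""
    rescaled = {}
    degenerate = []
    for name in table.pathway_names:
        vals = table.raw[name].to_numpy()
        scores = rescale_activity(vals)
        if np.all(scores == 0.5) and len(scores) > 1:
            degenerate.append(name)
        rescaled[name] = pd.Series(scores, index=table.raw.index)
    meta = dict(table.meta)
    if degenerate:
        meta["degenerate_pathways"] = degenerate
    return ActivityTable(raw=table.raw, rescaled=pd.DataFrame(rescaled),
                         dataset_id=table.dataset_id, meta=meta)
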