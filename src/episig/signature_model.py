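"""Train pathway signatures from two-class expression data.

A signature is built in three steps:

1. **Gene selection** — rank probes by a regularized signal-to-noise
   statistic between the pathway-activated and control classes,
   ``(mean1 - mean0) / (s_pooled + s0)`` with stabilizer ``s0`` set to the
   median pooled SD, and keep the top ``n_genes``.
2. **Metagene** — standardize each selected gene to mean 0 / SD 1 across
   training samples and take the first singular triplet of the genes x
   samples matrix.  The loading vector ``u`` (first left singular vector)
   defines the metagene; a sample's score is ``m_j = u^T x_j`` (equal to
   the first right singular vector entry times the singular value ``d``).
   The sign is oriented so that the activated class has the higher mean
   score.
3. **Bayesian probit regression** — ``P(activated | m) = Phi(alpha + beta*m)``
   with a normal prior on ``(alpha, beta)``, sampled by the classic
   data-augmentation Gibbs scheme: truncated-normal latent variables given
   coefficients, conjugate bivariate-normal update given latents.

Predicted activation probability is the *posterior mean* of
``Phi(alpha + beta*m)`` over the retained draws (not Phi at the posterior
mean coefficients; the two differ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .matrix import ANN_CLASS, ExpressionMatrix

_TINY = 1e-300


@dataclass
class TrainingDesign:
    """Binary class labels (0 = control, 1 = pathway-activated) per sample."""

    sample_ids: list
    class_labels: np.ndarray

    def __post_init__(self) -> None:
        self.class_labels = np.asarray(self.class_labels, dtype=int)
        if len(self.sample_ids) != len(self.class_labels):
            raise ValueError("sample_ids and class_labels differ in length")
        if not set(np.unique(self.class_labels)) <= {0, 1}:
            raise ValueError("class labels must be 0/1")
        if len(np.unique(self.class_labels)) < 2:
            raise ValueError("both classes must be present")

    @classmethod
    def from_annotations(cls, m: ExpressionMatrix, column: str = ANN_CLASS) -> "TrainingDesign":
        labels = m.annotation(column).astype(int)
        return cls(sample_ids=m.sample_ids, class_labels=labels.to_numpy())

    def subset(self, keep_idx) -> "TrainingDesign":
        ids = [self.sample_ids[i] for i in keep_idx]
        return TrainingDesign(ids, self.class_labels[list(keep_idx)])


@dataclass
class SignatureConfig:
    """Tunable parameters for one signature.

    ``n_metagenes`` is reserved: the general framework allows several
    metagenes but only the first principal component is used here.
    """

    n_genes: int = 200
    prior_mean: tuple = (0.0, 0.0)
    prior_var: float = 100.0
    n_draws: int = 5000
    burn_in: int = 1000
    thin: int = 10
    seed: int | None = None
    s0: float | None = None  # None -> median pooled SD
    n_metagenes: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prior_mean"] = list(self.prior_mean)
        return d


def two_class_statistic(m: ExpressionMatrix, design: TrainingDesign,
                        s0: float | None = None) -> pd.Series:
    """Regularized signal-to-noise statistic per probe (signed)."""
    data = m.subset(samples=design.sample_ids)
    labels = design.class_labels
    for cls in (0, 1):
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
    x = data.values
    x1, x0 = x[:, labels == 1], x[:, labels == 0]
    n1, n0 = x1.shape[1], x0.shape[1]
    v1 = x1.var(axis=1, ddof=1)
    v0 = x0.var(axis=1, ddof=1)
    pooled_sd = np.sqrt(((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2))
    if s0 is None:
        s0 = float(np.median(pooled_sd))
    stat = (x1.mean(axis=1) - x0.mean(axis=1)) / (pooled_sd + s0)
    return pd.Series(stat, index=data.data.index)


def select_signature_genes(m: ExpressionMatrix, design: TrainingDesign,
                           n_genes: int, s0: float | None = None) -> list:
    """Top ``n_genes`` probes by |regularized two-class statistic|.

    Ranked descending; exact ties broken lexicographically by probe id for
    determinism.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > m.n_probes:
        raise ValueError(f"n_genes={n_genes} exceeds probe count {m.n_probes}")
    stat = two_class_statistic(m, design, s0=s0)
    ranked = (pd.DataFrame({"absstat": stat.abs()})
              .assign(probe=stat.index.astype(str))
              .sort_values(["absstat", "probe"], ascending=[False, True],
                           kind="mergesort"))
    return list(ranked.index[:n_genes])


@dataclass
class MetageneResult:
    u: np.ndarray            # unit loading vector over genes (orientation applied)
    d: float                 # first singular value
    scores: np.ndarray       # per training sample, orientation applied
    sign_orientation: int
    gene_means: np.ndarray
    gene_sds: np.ndarray


def compute_metagene(m: ExpressionMatrix, design: TrainingDesign) -> MetageneResult:
    """First-singular-vector metagene of the standardized signature submatrix.

    Standardization uses per-gene mean and SD (ddof=1) across the training
    samples; a zero-variance gene is an error.  The orientation is flipped
    if necessary so the class-1 mean score is >= the class-0 mean score.
    """
    data = m.subset(samples=design.sample_ids)
    x = data.values
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(f"zero-variance gene(s) cannot be standardized: "
                         f"{[data.probe_ids[i] for i in zero[:5]]}")
    xs = (x - mu[:, None]) / sd[:, None]
    u_all, s, vt = np.linalg.svd(xs, full_matrices=False)
    u, d = u_all[:, 0], float(s[0])
    scores = d * vt[0]
    labels = design.class_labels
    sign = 1
    if scores[labels == 1].mean() < scores[labels == 0].mean():
        sign = -1
    return MetageneResult(u=sign * u, d=d, scores=sign * scores,
                          sign_orientation=sign, gene_means=mu, gene_sds=sd)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed (or Generator) is required")
    return np.random.default_rng(seed)


def fit_probit_bayes(scores, labels, prior_mean=(0.0, 0.0), prior_cov=None,
                     n_draws: int = 5000, burn_in: int = 1000, seed=None,
                     thin: int = 1) -> np.ndarray:
    """Albert–Chib data-augmentation Gibbs sampler for binary probit.

    Model: ``y_i ~ Bernoulli(Phi(alpha + beta * m_i))`` with
    ``(alpha, beta) ~ N(prior_mean, prior_cov)`` (default ``100 * I``,
    weakly informative).  Latent ``z_i ~ N(alpha + beta*m_i, 1)`` truncated
    to the positive (y=1) or non-positive (y=0) half-line; coefficients are
    then conjugate bivariate normal.  Truncated normals are drawn by
    inverse CDF on the numerically safe tail, so the sampler stays stable
    even when the classes are perfectly separated and coefficients drift
    large.

    Returns an ``(n_draws, 2)`` array of post-burn-in ``(alpha, beta)``
    draws; identical inputs and seed give identical draws.  ``thin`` keeps
    every thin-th post-burn-in draw: under complete class separation the
    posterior is prior-dominated and wide while the data-augmentation chain
    moves in small conditional steps, so thinning is needed for the stored
    draws to represent it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite metagene scores")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in shape")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    n = len(scores)
    rng = _as_rng(seed)
    if prior_cov is None:
        prior_cov = 100.0 * np.eye(2)
    prior_cov = np.asarray(prior_cov, dtype=float)
    # conjugate pieces are data-independent; precompute once
    b0 = np.asarray(prior_mean, dtype=float)
    b0_inv = np.linalg.inv(prior_cov)
    x = np.column_stack([np.ones(n), scores])
    post_cov = np.linalg.inv(b0_inv + x.T @ x)
    chol = np.linalg.cholesky(post_cov)
    prior_term = b0_inv @ b0
    if thin < 1:
        raise ValueError("thin must be >= 1")
    pos = labels == 1
    neg = ~pos
    beta = b0.copy()
    draws = np.empty((n_draws, 2))
    z = np.empty(n)
    kept = 0
    for it in range(burn_in + n_draws * thin):
        mu = x @ beta
        u = rng.random(n)
        # z | beta, y: N(mu, 1) truncated to z>0 (y=1) or z<=0 (y=0)
        q_pos = np.maximum(ndtr(mu[pos]), _TINY)
        z[pos] = mu[pos] - ndtri(np.maximum(u[pos] * q_pos, _TINY))
        q_neg = np.maximum(ndtr(-mu[neg]), _TINY)
        z[neg] = mu[neg] + ndtri(np.maximum(u[neg] * q_neg, _TINY))
        mean = post_cov @ (prior_term + x.T @ z)
        beta = mean + chol @ rng.standard_normal(2)
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            draws[kept] = beta
            kept += 1
    return draws


def predict_probability(draws: np.ndarray, scores) -> np.ndarray:
    """Posterior-mean activation probability ``E[Phi(alpha + beta*m)]``."""
    scores = np.atleast_1d(np.asarray(scores, dtype=float))
    alpha = draws[:, 0][:, None]
    beta = draws[:, 1][:, None]
    return ndtr(alpha + beta * scores[None, :]).mean(axis=0)


@dataclass
class SignatureModel:
    """Everything needed to project a trained signature onto new data.

    The probit regression operates on metagene scores divided by
    ``score_scale`` (the training-score SD), so the weakly informative
    coefficient prior lives on a unit scale regardless of signature size;
    raw scores are stored untouched.
    """

    gene_ids: list
    gene_means: np.ndarray
    gene_sds: np.ndarray
    u: np.ndarray
    d: float
    sign_orientation: int
    draws: np.ndarray
    train_scores: np.ndarray
    train_probabilities: np.ndarray
    score_scale: float = 1.0
    config: dict = field(default_factory=dict)
    pathway: str = ""

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.draws = np.asarray(self.draws, dtype=float)
        self.gene_means = np.asarray(self.gene_means, dtype=float)
        self.gene_sds = np.asarray(self.gene_sds, dtype=float)
        if not np.isclose(np.linalg.norm(self.u), 1.0, atol=1e-8):
            raise ValueError("loading vector must have unit norm")
        if self.d <= 0:
            raise ValueError("singular value must be positive")
        if (self.gene_sds <= 0).any():
            raise ValueError("gene SDs must be positive")
        if self.draws.size == 0:
            raise ValueError("posterior draws must be non-empty")
        if self.score_scale <= 0:
            raise ValueError("score_scale must be positive")

    def predict(self, scores) -> np.ndarray:
        """Activation probability for raw metagene scores."""
        return predict_probability(self.draws,
                                   np.asarray(scores, dtype=float) / self.score_scale)

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway,
            "gene_ids": [str(g) for g in self.gene_ids],
            "gene_means": self.gene_means.tolist(),
            "gene_sds": self.gene_sds.tolist(),
            "u": self.u.tolist(),
            "d": self.d,
            "sign_orientation": self.sign_orientation,
            "draws": self.draws.tolist(),
            "score_scale": self.score_scale,
            "train_scores": np.asarray(self.train_scores).tolist(),
            "train_probabilities": np.asarray(self.train_probabilities).tolist(),
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(gene_ids=d["gene_ids"],
                   gene_means=np.array(d["gene_means"]),
                   gene_sds=np.array(d["gene_sds"]),
                   u=np.array(d["u"]), d=float(d["d"]),
                   sign_orientation=int(d["sign_orientation"]),
                   draws=np.array(d["draws"]),
                   score_scale=float(d.get("score_scale", 1.0)),
                   train_scores=np.array(d["train_scores"]),
                   train_probabilities=np.array(d["train_probabilities"]),
                   config=d.get("config", {}), pathway=d.get("pathway", ""))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "SignatureModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_signature(m: ExpressionMatrix, design: TrainingDesign,
                    config: SignatureConfig, pathway: str = "") -> SignatureModel:
    """Gene selection + metagene + probit posterior, composed."""
    if config.seed is None:
        raise ValueError("SignatureConfig.seed is required for training")
    if config.n_metagenes != 1:
        raise NotImplementedError("only the first metagene is supported")
    genes = select_signature_genes(m, design, config.n_genes, s0=config.s0)
    sub = m.subset(probes=genes, samples=design.sample_ids)
    meta = compute_metagene(sub, design)
    # the probit sees unit-SD scores so the prior scale is size-independent
    score_scale = float(np.std(meta.scores, ddof=1))
    draws = fit_probit_bayes(meta.scores / score_scale, design.class_labels,
                             prior_mean=config.prior_mean,
                             prior_cov=config.prior_var * np.eye(2),
                             n_draws=config.n_draws, burn_in=config.burn_in,
                             seed=config.seed, thin=config.thin)
    train_probs = predict_probability(draws, meta.scores / score_scale)
    return SignatureModel(gene_ids=genes, gene_means=meta.gene_means,
                          gene_sds=meta.gene_sds, u=meta.u, d=meta.d,
                          sign_orientation=meta.sign_orientation, draws=draws,
                          train_scores=meta.scores,
                          train_probabilities=train_probs,
                          score_scale=score_scale,
                          config=config.to_dict(), pathway=pathway)


def predict_held_out(model: SignatureModel, m: ExpressionMatrix, sample_id) -> float:
    """Probability for one sample standardized with the *training* parameters."""
    x = m.data.loc[model.gene_ids, sample_id].to_numpy(dtype=float)
    xs = (x - model.gene_means) / model.gene_sds
    return float(model.predict(model.u @ xs)[0])


@dataclass
class LoocvResult:
    sample_ids: list
    probabilities: np.ndarray
    labels: np.ndarray
    accuracy: float
    confusion: dict  # tp, fp, tn, fn at threshold 0.5

    def to_dict(self) -> dict:
        return {"sample_ids": [str(s) for s in self.sample_ids],
                "probabilities": self.probabilities.tolist(),
                "labels": self.labels.tolist(),
                "accuracy": self.accuracy, "confusion": self.confusion}


def run_loocv(m: ExpressionMatrix, design: TrainingDesign,
              config: SignatureConfig) -> LoocvResult:
    """Leave-one-out cross-validation of the whole training procedure.

    For every sample the full pipeline — gene selection, metagene, probit
    fit — is re-run on the remaining samples and the held-out sample is
    predicted with the refit model (training-parameter standardization).
    """
    labels = design.class_labels
    for cls in (0, 1):
        if (labels == cls).sum() < 3:
            raise ValueError(f"LOOCV needs >= 3 samples per class (class {cls})")
    rng = _as_rng(config.seed)
    n = len(design.sample_ids)
    fold_seeds = rng.integers(0, 2**31 - 1, size=n)
    probs = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub_design = design.subset(keep)
        sub_m = m.subset(samples=sub_design.sample_ids)
        fold_cfg = replace(config, seed=int(fold_seeds[i]))
        model = train_signature(sub_m, sub_design, fold_cfg)
        probs[i] = predict_held_out(model, m, design.sample_ids[i])
    pred = (probs > 0.5).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return LoocvResult(sample_ids=list(design.sample_ids), probabilities=probs,
                       labels=labels, accuracy=(tp + tn) / n,
                       confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn})
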