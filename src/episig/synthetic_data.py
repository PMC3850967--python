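"""Ground-truth generators for every input the pipeline consumes.

Emulated structure:

* **Training sets** — two-class (control vs pathway-activated) log2
  expression with additive effects on a known signature gene set, optional
  batch offsets, Gaussian noise.
* **Tumor compendia** — latent pathway activities drawn from a Gaussian
  copula hitting a target Spearman correlation matrix (Pearson parameter
  ``2 sin(pi * rho_s / 6)``), mapped to [0, 1] by the normal CDF and added
  linearly to signature-gene expression.  The default correlation targets
  encode the strong negative EZH2-HDAC4 dependence observed across
  cancers, mild positive coupling among the deacetylase pathways, and an
  embryonal-type EZH2-DNMT2 association.  Subtypes are assigned by
  thresholding designated latent activities (basal-like = HDAC4-high,
  luminal-like = EZH2-high).
* **Genomic correlates** — copy-number log2 ratios with planted
  group-specific gains/losses, and beta-like methylation values with
  planted window shifts, on two synthetic chromosomes.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .matrix import (ANN_BATCH, ANN_CLASS, ANN_SUBTYPE, ExpressionMatrix,
                     GenomicMatrix)
from .signature_model import TrainingDesign

PATHWAYS = ["EZH2", "HDAC4", "HDAC1", "SIRT1", "DNMT2"]

#: default target Spearman correlations among latent pathway activities
DEFAULT_SPEARMAN = pd.DataFrame(
    [[1.0, -0.7, -0.2, -0.3, 0.3],
     [-0.7, 1.0, 0.4, 0.4, -0.2],
     [-0.2, 0.4, 1.0, 0.4, 0.0],
     [-0.3, 0.4, 0.4, 1.0, 0.0],
     [0.3, -0.2, 0.0, 0.0, 1.0]],
    index=PATHWAYS, columns=PATHWAYS)

BASELINE_MEAN = 7.0   # log2 units, MAS5-like intensities after log transform
BASELINE_SD = 1.0


@dataclass
class SyntheticTruth:
    """Everything the generators know that the pipeline must recover."""

    latent_activity: pd.DataFrame | None = None      # samples x pathways in [0,1]
    pathway_correlation_target: pd.DataFrame | None = None
    signature_gene_sets: dict = field(default_factory=dict)
    effect_size: float = 0.0
    subtype_labels: pd.Series | None = None
    batch_labels: pd.Series | None = None
    planted_cnv: list = field(default_factory=list)
    planted_meth: list = field(default_factory=list)


def spearman_to_pearson(rho_s):
    """Pearson copula parameter reproducing a target Spearman correlation."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def _check_correlation(r: np.ndarray) -> None:
    if not np.allclose(r, r.T):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(r), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    eigvals = np.linalg.eigvalsh(r)
    if eigvals.min() < -1e-10:
        raise ValueError(f"correlation matrix is not positive semi-definite: "
                         f"smallest eigenvalue {eigvals.min():.4g}")


def _probe_ids(n_probes: int) -> list:
    width = max(4, len(str(n_probes - 1)))
    return [f"probe_{i:0{width}d}" for i in range(n_probes)]


def simulate_training_set(n_per_class: int = 10, n_probes: int = 1000,
                          n_signature_genes: int = 200, effect_size: float = 2.0,
                          batch_spec: dict | None = None, noise_sd: float = 1.0,
                          seed: int = 0, signature_genes: list | None = None,
                          probe_ids: list | None = None, pathway: str = "pathway"
                          ) -> tuple[ExpressionMatrix, TrainingDesign, SyntheticTruth]:
    """Two-class training set with additive signature effects.

    Baseline log2 expression per probe is Normal(7, 1); activated-class
    samples receive ``+ effect_size * noise_sd`` on the signature genes;
    Gaussian noise with SD ``noise_sd`` is added everywhere.  Optional
    ``batch_spec`` maps batch name -> additive offset; samples are assigned
    to batches round-robin.
    """
    if n_per_class < 1 or n_probes < 1:
        raise ValueError("n_per_class and n_probes must be positive")
    if probe_ids is None:
        probe_ids = _probe_ids(n_probes)
    if len(probe_ids) != n_probes:
        raise ValueError("probe_ids length must equal n_probes")
    if signature_genes is None:
        if n_signature_genes > n_probes:
            raise ValueError("n_signature_genes exceeds n_probes")
        signature_genes = probe_ids[:n_signature_genes]
    sig_idx = [probe_ids.index(g) for g in signature_genes]
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_probes)
    x = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_probes, n))
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    x[np.ix_(sig_idx, np.flatnonzero(labels == 1))] += effect_size * noise_sd
    sample_ids = ([f"ctrl_{i:02d}" for i in range(n_per_class)]
                  + [f"act_{i:02d}" for i in range(n_per_class)])
    ann = pd.DataFrame({ANN_CLASS: labels}, index=sample_ids)
    batch_labels = None
    if batch_spec:
        names = list(batch_spec)
        assign = [names[i % len(names)] for i in range(n)]
        offsets = np.array([batch_spec[b] for b in assign])
        x = x + offsets[None, :]
        ann[ANN_BATCH] = assign
        batch_labels = pd.Series(assign, index=sample_ids)
    data = pd.DataFrame(x, index=probe_ids, columns=sample_ids)
    m = ExpressionMatrix(data, scale="log2", annotations=ann)
    design = TrainingDesign(sample_ids=sample_ids, class_labels=labels)
    truth = SyntheticTruth(signature_gene_sets={pathway: list(signature_genes)},
                           effect_size=effect_size, batch_labels=batch_labels)
    return m, design, truth


def default_pathway_spec(n_probes: int, genes_per_pathway: int = 200,
                         pathways: list | None = None) -> dict:
    """Disjoint signature gene sets taken from the front of the probe list."""
    pathways = pathways or PATHWAYS
    if genes_per_pathway * len(pathways) > n_probes:
        raise ValueError("not enough probes for disjoint pathway gene sets")
    ids = _probe_ids(n_probes)
    return {pw: ids[k * genes_per_pathway:(k + 1) * genes_per_pathway]
            for k, pw in enumerate(pathways)}


def _default_subtype_rule(activity: pd.DataFrame) -> pd.Series:
    """Threshold designated latent activities into intrinsic-like subtypes."""
    labels = pd.Series("other", index=activity.index, dtype=object)
    if "HDAC4" in activity:
        labels[activity["HDAC4"] > 0.6] = "basal-like"
    if "EZH2" in activity:
        labels[(activity["EZH2"] > 0.6) & (labels == "other")] = "luminal-like"
    return labels


def simulate_tumor_compendium(n_samples: int = 2000,
                              pathway_spec: dict | None = None,
                              target_rank_correlation: pd.DataFrame | None = None,
                              subtype_rule=None, n_probes: int = 2500,
                              noise_sd: float = 1.0, effect_size: float = 2.0,
                              seed: int = 0
                              ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Tumor compendium with correlated latent pathway activities.

    Latent activities come from a Gaussian copula whose Pearson parameter
    is adjusted so that the *rank* correlations match
    ``target_rank_correlation`` (default: the mutually exclusive
    EZH2/HDAC4 structure).  Expression is baseline + activity-scaled
    signature-gene effects + noise, so a latent activity of 1 looks like a
    fully activated training sample and 0 like a control.
    """
    if target_rank_correlation is None:
        target_rank_correlation = DEFAULT_SPEARMAN
    if pathway_spec is None:
        pathway_spec = default_pathway_spec(
            n_probes, pathways=list(target_rank_correlation.index))
    pathways = list(target_rank_correlation.index)
    rho_s = target_rank_correlation.to_numpy(dtype=float)
    r = spearman_to_pearson(rho_s)
    np.fill_diagonal(r, 1.0)
    _check_correlation(r)
    rng = np.random.default_rng(seed)
    # eigen square root is robust to semi-definite targets
    w, v = np.linalg.eigh(r)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal(size=(n_samples, len(pathways))) @ root.T
    activity = pd.DataFrame(ndtr(z), columns=pathways,
                            index=[f"tumor_{i:04d}" for i in range(n_samples)])
    probe_ids = _probe_ids(n_probes)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_probes)
    x = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_probes, n_samples))
    index_of = {p: i for i, p in enumerate(probe_ids)}
    for pw in pathways:
        genes = pathway_spec[pw]
        idx = [index_of[g] for g in genes]
        x[idx, :] += effect_size * noise_sd * activity[pw].to_numpy()[None, :]
    subtype_rule = subtype_rule or _default_subtype_rule
    subtypes = subtype_rule(activity)
    ann = pd.DataFrame({ANN_SUBTYPE: subtypes})
    data = pd.DataFrame(x, index=probe_ids, columns=activity.index)
    m = ExpressionMatrix(data, scale="log2", annotations=ann)
    truth = SyntheticTruth(latent_activity=activity,
                           pathway_correlation_target=target_rank_correlation,
                           signature_gene_sets={p: list(g) for p, g in pathway_spec.items()},
                           effect_size=effect_size, subtype_labels=subtypes)
    return m, truth


def simulate_quadrant_counts(n: int, p_a: float, p_b: float, seed=None,
                             p_both: float | None = None) -> tuple[int, int, int, int]:
    """Exact-count quadrant generator: (both, A_only, B_only, neither).

    By default A and B activate independently (``p_both = p_a * p_b``); an
    explicit joint probability can impose exclusivity or co-activation.
    """
    if p_both is None:
        p_both = p_a * p_b
    probs = [p_both, p_a - p_both, p_b - p_both, 1 - p_a - p_b + p_both]
    if min(probs) < -1e-12:
        raise ValueError(f"inconsistent quadrant probabilities {probs}")
    probs = np.clip(probs, 0.0, 1.0)
    probs = probs / probs.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    return tuple(int(c) for c in counts)


def simulate_genomic_correlates(group1, group2, n_genes: int = 500,
                                n_probes: int = 500,
                                planted_cnv: list | None = None,
                                planted_meth: list | None = None,
                                cnv_noise_sd: float = 0.15,
                                cnv_effect: float = 0.8,
                                meth_noise_sd: float = 0.05,
                                seed: int = 0
                                ) -> tuple[GenomicMatrix, GenomicMatrix]:
    """Copy-number and methylation matrices with planted group effects.

    ``planted_cnv``: list of (gene_index, group (1|2), direction (+1|-1),
    carrier_fraction); carriers are drawn from the group and shifted by
    ``direction * cnv_effect``.  ``planted_meth``: list of
    (start_probe_index, width, group, shift) applied to every sample of
    the group over a contiguous probe window.  Coordinates span two
    synthetic chromosomes.
    """
    group1, group2 = list(group1), list(group2)
    samples = group1 + group2
    groups = {1: group1, 2: group2}
    rng = np.random.default_rng(seed)
    for spec in (planted_cnv or []):
        if spec[3] > 1:
            raise ValueError(f"planted carrier fraction {spec[3]} exceeds 1")
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    cnv = rng.normal(0.0, cnv_noise_sd, size=(n_genes, len(samples)))
    cnv_df = pd.DataFrame(cnv, index=gene_ids, columns=samples)
    for gene_idx, group, direction, fraction in (planted_cnv or []):
        members = groups[group]
        n_carriers = int(np.ceil(fraction * len(members)))
        carriers = rng.choice(members, size=n_carriers, replace=False)
        cnv_df.loc[gene_ids[gene_idx], carriers] += direction * cnv_effect
    gene_coords = _two_chromosome_coords(gene_ids)
    cnv_matrix = GenomicMatrix(cnv_df, kind="copy_number", coords=gene_coords)

    probe_ids = [f"cg_{i:05d}" for i in range(n_probes)]
    base = rng.uniform(0.2, 0.8, size=n_probes)
    meth = base[:, None] + rng.normal(0.0, meth_noise_sd, size=(n_probes, len(samples)))
    meth_df = pd.DataFrame(meth, index=probe_ids, columns=samples)
    for start, width, group, shift in (planted_meth or []):
        members = groups[group]
        meth_df.iloc[start:start + width, meth_df.columns.get_indexer(members)] += shift
    meth_df = meth_df.clip(0.01, 0.99)
    probe_coords = _two_chromosome_coords(probe_ids)
    meth_matrix = GenomicMatrix(meth_df, kind="methylation", coords=probe_coords)
    return cnv_matrix, meth_matrix


def _two_chromosome_coords(feature_ids: list) -> pd.DataFrame:
    n = len(feature_ids)
    half = (n + 1) // 2
    chrom = ["chr1"] * half + ["chr2"] * (n - half)
    pos = list(range(1000, 1000 * (half + 1), 1000))
    pos += list(range(1000, 1000 * (n - half + 1), 1000))
    return pd.DataFrame({"chrom": chrom, "pos": pos}, index=feature_ids)
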