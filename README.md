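# episig

Pathway-activity signatures for epigenetic regulators, end to end: train
Bayesian probit regression signatures on SVD metagenes from two-class
expression experiments, project them onto tumor compendia, and analyse
mutual exclusivity, subtype association, and copy-number / methylation
correlates of the inferred activities.

## The problem

Many epigenetic pathways (histone methylation by EZH2, deacetylation by
class 1/2/3 HDACs, RNA methylation by DNMT2) have no direct activity
assay in tumor profiling data. A workaround with a strong track record is
the *expression signature*: activate the pathway experimentally in
quiescent epithelial cells, profile mRNA against matched controls, and
learn a classifier whose probability output serves as a per-sample
activity estimate in any expression dataset. With activities in hand for
a compendium of tumors, one can ask which pathways co-occur, which are
mutually exclusive, how activity maps onto intrinsic subtypes, and which
genomic alterations travel with each activity state.

## The model

For a two-class training set (control vs activated):

* select the `k` genes with the largest regularized signal-to-noise
  statistic `(x̄₁ − x̄₀)/(s_pooled + s₀)`;
* summarize them per sample as a **metagene score** `m_j = uᵀx_j`, where
  `u` is the first left singular vector of the standardized genes ×
  samples matrix;
* fit a Bayesian binary probit `P(activated | m) = Φ(α + β·m)` by
  truncated-normal data augmentation (Gibbs), prior `N(0, 100·I)`;
* report for any new sample the posterior mean of `Φ(α + β·m)`.

Projected probabilities are log-transformed and min–max rescaled within
each dataset to span [0, 1] for cross-dataset comparison. A pathway pair
is analysed by 2×2 quadrant counts of activation calls; the independence
expectation for co-activation is the product of the marginal activation
fractions, and a one-sided exact test quantifies the deficit. Subgroup
genomics use a ±0.5 log2-ratio / ≥20% copy-number filter with removal of
alterations shared by both subgroups, and a sliding-window Welch test
(p < 0.1 kept) with label-shuffling false-positive calibration for
methylation.

All inputs are plain TSV (expression and genomic matrices, sample
annotations, probe coordinates); no downloads are required — the
`episig.synthetic_data` module generates training sets, compendia with a
specified latent rank-correlation structure (Gaussian copula), and
genomic matrices with planted effects, all with known ground truth.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study
(five pathways, 600-tumor compendium, master seed 17) and write their
tables under `results/study/`:

```bash
cd analysis
python 01_simulate.py
python 02_train_signatures.py
python 03_project_activity.py
python 04_exclusivity.py
python 05_genomic_correlates.py
```

or equivalently `episig all --outdir results/study --seed 17`. The
exclusivity step prints:

```
Spearman correlations between predicted activities:
         EZH2  HDAC4  HDAC1  SIRT1  DNMT2
pathway
EZH2     1.00  -0.77  -0.39  -0.53   0.26
HDAC4   -0.77   1.00   0.22   0.34  -0.42
...
EZH2/HDAC4 quadrants (n=600): both 80, EZH2-only 252, HDAC4-only 226, neither 42
observed co-activation 13.3% vs expected 28.2% (deficit p = 2.4e-18)
HDAC4 subtype ANOVA F = 296.1 (p = 4.72e-90); enrichment among activated: basal-like 81%, ...
```

Reading: the compendium was generated with a latent EZH2–HDAC4 rank
correlation of −0.7, and the trained signatures recover it (−0.77);
tumors with both pathways called active are less than half as frequent as
independence predicts (13.3% vs 28.2%), the planted mutual-exclusivity
structure; and HDAC4 activity separates the simulated subtypes, with 81%
of HDAC4-activated tumors carrying the basal-like label. The correlates
step then recovers exactly the planted group-specific copy-number
alterations and a ~10% methylation false-positive rate at α = 0.1,
matching its nominal level.

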