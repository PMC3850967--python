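"""Stage orchestration: simulate -> preprocess -> train -> loocv -> predict
-> exclusivity -> correlates, with TSV/JSON artifacts on disk.

Every stochastic stage derives its generator deterministically from the
single master seed, so rerunning a fixed config reproduces all numeric
artifacts bitwise.  The config hash is stamped into the JSON artifacts for
provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from .exclusivity import classify_quadrants, pairwise_correlations, subtype_association
from .genomic_correlates import (cnv_subgroup_filter, define_extreme_groups,
                                 permutation_false_positive_rate,
                                 sliding_window_meth_test)
from .matrix import (ANN_SUBTYPE, ExpressionMatrix, read_annotations,
                     read_expression_table, read_genomic_matrix,
                     write_expression_table)
from .projection import ActivityTable, build_activity_table, rescale_table
from .signature_model import (LoocvResult, SignatureConfig, SignatureModel,
                              TrainingDesign, run_loocv, train_signature)
from .synthetic_data import (DEFAULT_SPEARMAN, default_pathway_spec,
                             simulate_genomic_correlates,
                             simulate_training_set, simulate_tumor_compendium)

log = logging.getLogger("episig")

STAGES = ["simulate", "preprocess", "train", "loocv", "predict",
          "exclusivity", "correlates"]
_STAGE_SEED = {name: i + 1 for i, name in enumerate(STAGES)}

_STOCHASTIC_STAGES = {"simulate", "train", "loocv", "correlates"}


def default_config(**overrides) -> dict:
    cfg = {
        "seed": 17,
        "outdir": "runs/demo",
        "dataset_id": "synthetic_compendium",
        "pathways": ["EZH2", "HDAC4", "HDAC1", "SIRT1", "DNMT2"],
        "simulate": {
            "n_per_class": 10,
            "n_probes": 2000,
            "genes_per_pathway": 200,
            "effect_size": 2.0,
            "noise_sd": 1.0,
            "n_samples": 600,
            "n_cnv_genes": 300,
            "n_meth_probes": 300,
        },
        "preprocess": {"quantile_normalize": True, "filter_probes": False,
                       "low_signal_quantile": 0.25, "min_present_fraction": 0.25,
                       "variance_quantile": 0.25},
        "train": {"n_genes": 200, "n_draws": 2000, "burn_in": 500,
                  "thin": 10, "prior_var": 100.0},
        "loocv": {"n_draws": 800, "burn_in": 200, "thin": 1},
        # threshold None = activation at the probit decision boundary
        "exclusivity": {"pathway_a": "EZH2", "pathway_b": "HDAC4",
                        "threshold": None},
        "correlates": {"cutoff": 0.5, "window_size": 5, "alpha": 0.1,
                       "n_perm": 20, "amp_threshold": 0.5,
                       "del_threshold": -0.5, "min_fraction": 0.2},
    }
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return default_config(**user)


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg.get("seed"), int):
        raise ValueError("config must provide an integer master 'seed' "
                         "before any stochastic stage runs")
    unknown = [s for s in cfg if s not in
               {"seed", "outdir", "dataset_id", "pathways"} | set(STAGES)]
    if unknown:
        raise ValueError(f"unknown config section(s): {unknown}")


def config_hash(cfg: dict) -> str:
    """Hash of the scientific parameters (output location excluded)."""
    stripped = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(stripped, sort_keys=True).encode()).hexdigest()[:16]


def _stage_rng(cfg: dict, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg["seed"], _STAGE_SEED[stage]])


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# stages

def stage_simulate(cfg: dict, out: Path) -> None:
    s = cfg["simulate"]
    rng = _stage_rng(cfg, "simulate")
    pathways = cfg["pathways"]
    spec = default_pathway_spec(s["n_probes"], s["genes_per_pathway"], pathways)
    data_dir = out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    for pw in pathways:
        m, design, _ = simulate_training_set(
            n_per_class=s["n_per_class"], n_probes=s["n_probes"],
            effect_size=s["effect_size"], noise_sd=s["noise_sd"],
            seed=int(rng.integers(2**31)), signature_genes=spec[pw], pathway=pw)
        write_expression_table(m, data_dir / f"training_{pw}.tsv")
        m.annotations.to_csv(data_dir / f"training_{pw}.annotations.tsv",
                             sep="\t", index_label="sample_id")
    target = cfg.get("target_spearman")
    target = (pd.DataFrame(target, index=pathways, columns=pathways)
              if target is not None else DEFAULT_SPEARMAN.loc[pathways, pathways])
    comp, truth = simulate_tumor_compendium(
        n_samples=s["n_samples"], pathway_spec=spec,
        target_rank_correlation=target, n_probes=s["n_probes"],
        noise_sd=s["noise_sd"], effect_size=s["effect_size"],
        seed=int(rng.integers(2**31)))
    write_expression_table(comp, data_dir / "compendium.tsv")
    comp.annotations.to_csv(data_dir / "compendium.annotations.tsv",
                            sep="\t", index_label="sample_id")
    truth.latent_activity.to_csv(data_dir / "latent_activity.tsv", sep="\t",
                                 index_label="sample_id")
    # genomic correlates follow the latent extreme groups of the headline pair
    exc = cfg["exclusivity"]
    g1, g2 = define_extreme_groups(truth.latent_activity,
                                   exc["pathway_a"], exc["pathway_b"],
                                   cutoff=cfg["correlates"]["cutoff"])
    planted_cnv = [(0, 1, +1, 0.4), (1, 2, -1, 0.4), (2, 1, +1, 0.4)]
    planted_meth = [(0, 5, 1, 0.15), (20, 5, 2, -0.15)]
    cnv, meth = simulate_genomic_correlates(
        g1, g2, n_genes=s["n_cnv_genes"], n_probes=s["n_meth_probes"],
        planted_cnv=planted_cnv, planted_meth=planted_meth,
        seed=int(rng.integers(2**31)))
    cnv.data.to_csv(data_dir / "copy_number.tsv", sep="\t", index_label="gene_id")
    cnv.coords.to_csv(data_dir / "copy_number.coords.tsv", sep="\t",
                      index_label="gene_id")
    meth.data.to_csv(data_dir / "methylation.tsv", sep="\t", index_label="probe_id")
    meth.coords.to_csv(data_dir / "methylation.coords.tsv", sep="\t",
                       index_label="probe_id")
    _write_json(data_dir / "groups.json",
                {"group1": [str(x) for x in g1], "group2": [str(x) for x in g2],
                 "config_hash": config_hash(cfg)})
    log.info("simulate: %d training sets, compendium %d samples, "
             "extreme groups %d/%d", len(pathways), s["n_samples"],
             len(g1), len(g2))


def _load_training(out: Path, pw: str) -> tuple[ExpressionMatrix, TrainingDesign]:
    data_dir = out / "data"
    ann = read_annotations(data_dir / f"training_{pw}.annotations.tsv")
    m = read_expression_table(data_dir / f"training_{pw}.tsv", scale="log2",
                              annotations=ann)
    return m, TrainingDesign.from_annotations(m)


def _apply_preprocess(cfg: dict, m: ExpressionMatrix) -> ExpressionMatrix:
    p = cfg["preprocess"]
    if p.get("filter_probes"):
        m = pp.filter_probes(m, p["low_signal_quantile"],
                             p["min_present_fraction"],
                             p["variance_quantile"]).matrix
    if p.get("quantile_normalize", True):
        m = pp.quantile_normalize(m)
    return m


def stage_preprocess(cfg: dict, out: Path) -> None:
    data_dir = out / "data"
    norm_dir = out / "normalized"
    norm_dir.mkdir(parents=True, exist_ok=True)
    report = {}
    for pw in cfg["pathways"]:
        m, _ = _load_training(out, pw)
        mp = _apply_preprocess(cfg, m)
        write_expression_table(mp, norm_dir / f"training_{pw}.tsv")
        report[f"training_{pw}"] = {"n_probes": mp.n_probes,
                                    "n_samples": mp.n_samples}
    ann = read_annotations(data_dir / "compendium.annotations.tsv")
    comp = read_expression_table(data_dir / "compendium.tsv", scale="log2",
                                 annotations=ann)
    comp_p = _apply_preprocess(cfg, comp)
    write_expression_table(comp_p, norm_dir / "compendium.tsv")
    report["compendium"] = {"n_probes": comp_p.n_probes,
                            "n_samples": comp_p.n_samples}
    report["config_hash"] = config_hash(cfg)
    _write_json(norm_dir / "qc_report.json", report)
    log.info("preprocess: wrote normalized matrices")


def _signature_config(cfg: dict, section: str, seed: int) -> SignatureConfig:
    t = cfg["train"]
    over = cfg.get(section, {})
    return SignatureConfig(n_genes=t["n_genes"],
                           prior_var=t["prior_var"],
                           n_draws=over.get("n_draws", t["n_draws"]),
                           burn_in=over.get("burn_in", t["burn_in"]),
                           thin=over.get("thin", t.get("thin", 10)),
                           seed=seed)


def stage_train(cfg: dict, out: Path) -> None:
    rng = _stage_rng(cfg, "train")
    model_dir = out / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    for pw in cfg["pathways"]:
        ann = read_annotations(out / "data" / f"training_{pw}.annotations.tsv")
        m = read_expression_table(out / "normalized" / f"training_{pw}.tsv",
                                  scale="log2", annotations=ann)
        design = TrainingDesign.from_annotations(m)
        sc = _signature_config(cfg, "train", int(rng.integers(2**31)))
        model = train_signature(m, design, sc, pathway=pw)
        model.save(model_dir / f"{pw}.json")
        log.info("train %s: %d genes, d=%.2f", pw, len(model.gene_ids), model.d)


def stage_loocv(cfg: dict, out: Path) -> None:
    rng = _stage_rng(cfg, "loocv")
    model_dir = out / "models"
    results = {}
    for pw in cfg["pathways"]:
        ann = read_annotations(out / "data" / f"training_{pw}.annotations.tsv")
        m = read_expression_table(out / "normalized" / f"training_{pw}.tsv",
                                  scale="log2", annotations=ann)
        design = TrainingDesign.from_annotations(m)
        sc = _signature_config(cfg, "loocv", int(rng.integers(2**31)))
        res = run_loocv(m, design, sc)
        results[pw] = res.to_dict()
        log.info("loocv %s: accuracy %.2f", pw, res.accuracy)
    results["config_hash"] = config_hash(cfg)
    _write_json(model_dir / "loocv.json", results)


def stage_predict(cfg: dict, out: Path) -> None:
    models = {pw: SignatureModel.load(out / "models" / f"{pw}.json")
              for pw in cfg["pathways"]}
    ann = read_annotations(out / "data" / "compendium.annotations.tsv")
    comp = read_expression_table(out / "normalized" / "compendium.tsv",
                                 scale="log2", annotations=ann)
    table = build_activity_table(models, comp, dataset_id=cfg["dataset_id"])
    table = rescale_table(table)
    act_dir = out / "activity"
    act_dir.mkdir(parents=True, exist_ok=True)
    table.raw.to_csv(act_dir / "activity_raw.tsv", sep="\t",
                     index_label="sample_id")
    table.rescaled.to_csv(act_dir / "activity_rescaled.tsv", sep="\t",
                          index_label="sample_id")
    _write_json(act_dir / "activity.meta.json",
                dict(table.meta, dataset_id=table.dataset_id,
                     config_hash=config_hash(cfg)))
    log.info("predict: %d samples x %d pathways", *table.raw.shape)


def _load_activity(out: Path) -> ActivityTable:
    raw = pd.read_csv(out / "activity" / "activity_raw.tsv", sep="\t", index_col=0)
    rescaled = pd.read_csv(out / "activity" / "activity_rescaled.tsv", sep="\t",
                           index_col=0)
    return ActivityTable(raw=raw, rescaled=rescaled)


def stage_exclusivity(cfg: dict, out: Path) -> None:
    table = _load_activity(out)
    exc = cfg["exclusivity"]
    exc_dir = out / "exclusivity"
    exc_dir.mkdir(parents=True, exist_ok=True)
    r, p = pairwise_correlations(table)
    r.to_csv(exc_dir / "spearman_r.tsv", sep="\t", index_label="pathway")
    p.to_csv(exc_dir / "spearman_p.tsv", sep="\t", index_label="pathway")
    labels, summary = classify_quadrants(table, exc["pathway_a"],
                                         exc["pathway_b"],
                                         threshold=exc["threshold"])
    labels.rename("quadrant").to_csv(exc_dir / "quadrant_labels.tsv", sep="\t",
                                     index_label="sample_id")
    _write_json(exc_dir / "quadrant_summary.json",
                dict(summary.to_dict(), config_hash=config_hash(cfg)))
    ann = read_annotations(out / "data" / "compendium.annotations.tsv")
    assoc = subtype_association(table, ann[ANN_SUBTYPE],
                                {exc["pathway_b"]: "high"},
                                threshold=exc["threshold"])
    _write_json(exc_dir / "subtype_association.json",
                dict(assoc.to_dict(), config_hash=config_hash(cfg)))
    log.info("exclusivity: r_s(%s,%s)=%.2f, deficit p=%.3g",
             exc["pathway_a"], exc["pathway_b"],
             r.loc[exc["pathway_a"], exc["pathway_b"]], summary.p_value)


def stage_correlates(cfg: dict, out: Path) -> None:
    table = _load_activity(out)
    exc, cor = cfg["exclusivity"], cfg["correlates"]
    g1, g2 = define_extreme_groups(table, exc["pathway_a"], exc["pathway_b"],
                                   cutoff=cor["cutoff"])
    cnv = read_genomic_matrix(out / "data" / "copy_number.tsv", "copy_number",
                              out / "data" / "copy_number.coords.tsv")
    meth = read_genomic_matrix(out / "data" / "methylation.tsv", "methylation",
                               out / "data" / "methylation.coords.tsv")
    # genomic matrices cover only the simulated extreme-group samples
    g1 = [s for s in g1 if s in cnv.data.columns]
    g2 = [s for s in g2 if s in cnv.data.columns]
    cor_dir = out / "correlates"
    cor_dir.mkdir(parents=True, exist_ok=True)
    _write_json(cor_dir / "extreme_groups.json",
                {"group1": [str(x) for x in g1], "group2": [str(x) for x in g2],
                 "cutoff": cor["cutoff"], "config_hash": config_hash(cfg)})
    status = cnv_subgroup_filter(cnv, g1, g2, cor["amp_threshold"],
                                 cor["del_threshold"], cor["min_fraction"])
    status.to_csv(cor_dir / "cnv_status.tsv", sep="\t", index_label="gene_id")
    meth_res = sliding_window_meth_test(meth, g1, g2,
                                        window_size=cor["window_size"],
                                        alpha=cor["alpha"])
    meth_res.to_csv(cor_dir / "meth_windows.tsv", sep="\t",
                    index_label="probe_id")
    rng = _stage_rng(cfg, "correlates")
    fpr = permutation_false_positive_rate(meth, g1, g2,
                                          window_size=cor["window_size"],
                                          alpha=cor["alpha"],
                                          n_perm=cor["n_perm"], seed=rng)
    _write_json(cor_dir / "meth_fpr.json",
                dict(fpr.to_dict(), config_hash=config_hash(cfg)))
    log.info("correlates: %d specific CNV genes, %d kept methylation probes, "
             "FPR %.3f", int((status["status"].str.contains("specific")).sum()),
             int(meth_res["kept"].sum()), fpr.mean_fraction)


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "loocv": stage_loocv,
    "predict": stage_predict,
    "exclusivity": stage_exclusivity,
    "correlates": stage_correlates,
}


def run_pipeline(config: dict, stages=None) -> Path:
    """Execute the requested stages in canonical order; returns the outdir."""
    cfg = copy.deepcopy(config)
    validate_config(cfg)
    if stages is None or stages == ["all"]:
        stages = STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.used.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        for stage in [s for s in STAGES if s in stages]:
            log.info("stage %s starting (config %s)", stage, config_hash(cfg))
            try:
                _STAGE_FN[stage](cfg, out)
            except Exception as exc:
                log.error("stage %s failed: %s", stage, exc)
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
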