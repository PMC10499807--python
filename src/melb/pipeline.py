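"""End-to-end diagnostic and prognostic workflows over a simulated cohort.

Each workflow runs the full construction-validation loop on a synthetic
cohort: split -> signature/classifier construction on the discovery samples
-> prediction on held-out validation samples -> evaluation.  The prognostic
workflow additionally clusters serum methylomes, stratifies survival by
predicted risk and compares deconvolved immune fractions across risk arms.

A run manifest (full configuration + seeds) is produced with every report so
reruns are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import classifiers, clustering, deconvolution, metrics, survival
from .errors import MelbError
from .io_core import BetaMatrix, SampleSheet
from .synthetic_data import SimulationConfig, simulate_cohort, config_to_dict


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_iterations: int = 1000
    n_trees: int = 1000
    cv_folds: int = 10
    split_fractions: tuple = (0.64, 0.16)   # train / model-select; rest validates
    prognostic_train_fraction: float = 0.7
    top_variance: int = 1000
    k_range: tuple = (2, 8)
    n_resamples: int = 1000
    subsample_frac: float = 0.8
    survival_horizon: float = 60.0
    seed: int = 0
    fast_mode: bool = False

    def effective(self) -> "PipelineConfig":
        """Fast mode scales the iteration/resampling counts for test runs."""
        if not self.fast_mode:
            return self
        cfg = PipelineConfig(**{**asdict(self), "simulation": self.simulation})
        cfg.n_iterations = min(self.n_iterations, 50)
        cfg.n_resamples = min(self.n_resamples, 100)
        cfg.n_trees = min(self.n_trees, 300)
        cfg.cv_folds = min(self.cv_folds, 5)
        return cfg


def manifest_of(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["simulation"] = config_to_dict(cfg.simulation)
    return d


def _split_serum(sheet: SampleSheet, cfg: PipelineConfig) -> SampleSheet:
    serum = sheet.rows(specimen={"serum", "plasma"})["sample_id"].tolist()
    return classifiers.split_cohort(sheet, cfg.split_fractions, "group",
                                    seed=cfg.seed, subset=serum)


def run_diagnostic_workflow(cfg: PipelineConfig,
                            cohort=None) -> dict:
    """Simulate (or accept) a cohort, build d-MeLB, evaluate on validation serum."""
    eff = cfg.effective()
    beta, sheet, gt = cohort if cohort is not None else simulate_cohort(eff.simulation)
    sheet.covers(beta)
    sheet = _split_serum(sheet, eff)

    serum_ids = sheet.rows(specimen={"serum", "plasma"})["sample_id"].tolist()
    tissue_ids = sheet.rows(specimen="tissue")["sample_id"].tolist()
    serum = beta.subset_samples(serum_ids)
    tissue = beta.subset_samples(tissue_ids)

    bundle = classifiers.build_dmelb(serum, tissue, sheet,
                                     n_iterations=eff.n_iterations,
                                     master_seed=eff.seed,
                                     n_trees=eff.n_trees, cv_folds=eff.cv_folds)
    val = sheet.rows(split="validation", specimen={"serum", "plasma"})
    preds = classifiers.predict(bundle, serum, val["sample_id"].tolist())
    truth = val.set_index("sample_id")["group"].eq("MNG")
    pred_pos = pd.Series({p.sample_id: p.label == "positive" for p in preds})
    scores = pd.Series({p.sample_id: p.score for p in preds})
    report = metrics.metric_report(
        truth.loc[pred_pos.index].to_numpy(), pred_pos.to_numpy(),
        scores[truth.loc[pred_pos.index]].to_numpy(),
        scores[~truth.loc[pred_pos.index]].to_numpy())
    return {
        "manifest": manifest_of(cfg),
        "cutoff": bundle.cutoff,
        "signature_size": len(bundle.signature),
        "signature": list(bundle.signature.probe_ids),
        "training_metrics": bundle.training_metrics,
        "provenance": _jsonable(bundle.provenance),
        "validation": report,
        "ground_truth_overlap": len(set(bundle.signature.probe_ids)
                                    & set(gt.diagnostic_probes)),
    }


def run_prognostic_workflow(cfg: PipelineConfig, cohort=None) -> dict:
    """Cluster serum, build p-MeLB, stratify survival and immune fractions."""
    eff = cfg.effective()
    beta, sheet, gt = cohort if cohort is not None else simulate_cohort(eff.simulation)
    sheet.covers(beta)

    mng_serum = sheet.samples(specimen="serum", group="MNG")
    serum = beta.subset_samples(mng_serum)
    sig = clustering.top_variance_probes(serum, min(eff.top_variance,
                                                    len(serum.probe_ids)))
    clus = clustering.consensus_kmeans(
        serum, sig, k_range=range(eff.k_range[0], eff.k_range[1] + 1),
        n_resamples=eff.n_resamples, subsample_frac=eff.subsample_frac,
        seed=eff.seed)
    cluster_labels = clus.assignments[clus.selected_k]

    labeled = sheet.rows(specimen="tissue", group="MNG",
                         outcome={"CR", "CNR"})["sample_id"].tolist()
    sheet = classifiers.split_cohort(sheet, (eff.prognostic_train_fraction, 0.0),
                                     ["outcome"], seed=eff.seed, subset=labeled)
    tissue = beta.subset_samples(sheet.samples(specimen="tissue"))
    try:
        bundle = classifiers.build_pmelb(tissue, serum, sheet, cluster_labels,
                                         n_iterations=eff.n_iterations,
                                         master_seed=eff.seed,
                                         n_trees=eff.n_trees,
                                         cv_folds=eff.cv_folds)
    except MelbError as exc:
        # every draw degenerate: tissue outcomes carry no methylation signal,
        # so there is no prognostic signature and no risk stratification
        return {
            "manifest": manifest_of(cfg),
            "selected_k": clus.selected_k,
            "signature_size": 0,
            "degenerate": True,
            "note": str(exc),
            "validation": None,
            "survival": {"logrank": {"chi_square": 0.0, "p": 1.0,
                                     "note": "no prognostic signature"}},
            "deconvolution": {},
        }

    val = sheet.rows(specimen="tissue", split="validation",
                     outcome={"CR", "CNR"})
    preds_val = classifiers.predict(bundle, tissue, val["sample_id"].tolist())
    truth = val.set_index("sample_id")["outcome"].eq("CR")
    pred_pos = pd.Series({p.sample_id: p.label == "positive" for p in preds_val})
    report = metrics.metric_report(truth.loc[pred_pos.index].to_numpy(),
                                   pred_pos.to_numpy())

    # risk stratification of the serum cohort
    serum_preds = classifiers.predict(bundle, serum, mng_serum)
    risk = pd.Series({p.sample_id: "high" if p.label == "positive" else "low"
                      for p in serum_preds})
    st = sheet.table.set_index("sample_id").loc[risk.index]
    times = st["person_time"].to_numpy(dtype=float)
    events = (st["outcome"] == "CR").to_numpy()
    surv_report = {}
    if len(risk.unique()) == 2:
        lr = survival.logrank_test(times, events, risk.to_numpy())
        surv_report["logrank"] = lr
        for arm in ("high", "low"):
            mask = (risk == arm).to_numpy()
            if mask.sum() and times[mask].min() > 0:
                km = survival.km_estimate(times[mask], events[mask])
                surv_report[f"rfs_{eff.survival_horizon:.0f}mo_{arm}"] = \
                    survival.survival_at(km, eff.survival_horizon)
    else:
        surv_report["logrank"] = {"chi_square": 0.0, "p": 1.0,
                                  "note": "single predicted arm"}

    # immune deconvolution by predicted risk arm
    atlas = deconvolution.ReferenceAtlas.from_beta_matrix(gt.atlas)
    dres = deconvolution.deconvolve(serum, atlas)
    dtab = deconvolution.deconv_table(dres)
    deconv_report = {}
    hi = dtab.loc[risk[risk == "high"].index.intersection(dtab.index)]
    lo = dtab.loc[risk[risk == "low"].index.intersection(dtab.index)]
    if len(hi) >= 2 and len(lo) >= 2:
        wt = metrics.welch_t(hi["neutrophil"], lo["neutrophil"])
        deconv_report["neutrophil_welch"] = {
            "mean_diff": wt["mean_diff"], "p": wt["p"]}
        finite = dtab["nlr"].replace([np.inf], np.nan).dropna()
        hi_n = finite.loc[finite.index.intersection(hi.index)]
        lo_n = finite.loc[finite.index.intersection(lo.index)]
        if len(hi_n) >= 2 and len(lo_n) >= 2:
            wn = metrics.welch_t(hi_n, lo_n)
            deconv_report["nlr_welch"] = {"mean_diff": wn["mean_diff"],
                                          "p": wn["p"]}
        cr = st["outcome"].eq("CR")
        table = [[int((cr & (risk == "high")).sum()),
                  int((~cr & (risk == "high")).sum())],
                 [int((cr & (risk == "low")).sum()),
                  int((~cr & (risk == "low")).sum())]]
        deconv_report["recurrence_odds"] = _jsonable(
            metrics.fisher_odds_ratio(table))

    return {
        "manifest": manifest_of(cfg),
        "selected_k": clus.selected_k,
        "cutoff": bundle.cutoff,
        "signature_size": len(bundle.signature),
        "signature": list(bundle.signature.probe_ids),
        "oob_error": bundle.training_metrics["oob_error"],
        "provenance": _jsonable(bundle.provenance),
        "validation": report,
        "survival": surv_report,
        "deconvolution": deconv_report,
        "ground_truth_overlap": len(set(bundle.signature.probe_ids)
                                    & set(gt.prognostic_probes)),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def report_to_json(report: dict, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
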