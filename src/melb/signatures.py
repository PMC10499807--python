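"""Signature derivation for the liquid-biopsy classifiers.

Four nested stages:

1. tumor-specific DMPs — probes separating meningioma tissue from nontumor
   brain controls at a (randomized) rank-sum significance level;
2. similarly methylated probes (SMPs) — tumor-specific probes whose mean
   absolute serum-tissue difference over patient pairs is small, i.e.
   tumor methylation that survives into circulating DNA;
3. the diagnostic (d-MeLB) signature — the 20-30 SMPs best separating
   untreated meningioma serum from non-meningioma serum (glioblastoma
   excluded), ranked by FDR-adjusted rank-sum p;
4. the prognostic (p-MeLB) signature — probes differential both between
   confirmed-recurrence / confirmed-non-recurrence tissue and between
   adverse- and favorable-outcome serum clusters, ranked by combined p.

Every derivation records the exact thresholds drawn for it, so iteration
loops can replay a draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffmeth import adjust_fdr, wilcoxon_dmp
from .errors import DegenerateDrawError, ValidationError
from .io_core import BetaMatrix, SampleSheet

#: d-MeLB signature size bounds
DMELB_SIZE_RANGE = (20, 30)
#: randomization range of the tumor-specific significance draw
P_THRESHOLD_RANGE = (1e-4, 0.05)
#: randomization range of the serum/tissue similarity bound (beta units)
SMP_DELTA_RANGE = (0.1, 0.2)


@dataclass
class SignatureSet:
    probe_ids: list
    stage: str                      # tumor_specific | smp | d_melb | p_melb
    params: dict = field(default_factory=dict)
    iteration_seed: int | None = None

    def __post_init__(self):
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probes in signature")
        if self.stage == "d_melb" and not (
                DMELB_SIZE_RANGE[0] <= len(self.probe_ids) <= DMELB_SIZE_RANGE[1]):
            raise ValidationError(
                f"d-MeLB signature size {len(self.probe_ids)} outside "
                f"{DMELB_SIZE_RANGE}")

    def __len__(self):
        return len(self.probe_ids)

    def __contains__(self, probe):
        return probe in set(self.probe_ids)


def select_tumor_specific_dmps(tissue: BetaMatrix, sheet: SampleSheet,
                               p_threshold: float,
                               adjust: bool = False) -> SignatureSet:
    """Probes separating MNG tissue from nontumor controls at p <= threshold.

    Unadjusted rank-sum p by default (the randomization range 1e-4..0.05
    implies raw p); ``adjust=True`` switches to FDR-adjusted p.
    """
    if not (P_THRESHOLD_RANGE[0] <= p_threshold <= P_THRESHOLD_RANGE[1]
            or p_threshold == 0.0):
        raise ValidationError(
            f"p_threshold outside randomization range {P_THRESHOLD_RANGE}")
    mng = [s for s in sheet.samples(specimen="tissue", group="MNG")
           if s in set(tissue.sample_ids)]
    ctl = [s for s in sheet.samples(specimen="tissue", group="control")
           if s in set(tissue.sample_ids)]
    if len(mng) < 2 or len(ctl) < 2:
        raise ValidationError("tissue matrix needs MNG and control groups")
    t = wilcoxon_dmp(tissue, mng, ctl)
    col = "p_fdr" if adjust else "p_value"
    keep = t.index[t[col] <= p_threshold].tolist()
    return SignatureSet(keep, stage="tumor_specific",
                        params={"p_threshold": p_threshold, "adjusted": adjust})


def serum_tissue_pairs(sheet: SampleSheet) -> list[tuple[str, str]]:
    """(serum_id, tissue_id) pairs sharing a patient, MNG only."""
    t = sheet.table
    mng = t[t.group == "MNG"]
    pairs = []
    for pid, sub in mng.groupby("patient_id"):
        serum = sub[sub.specimen.isin(["serum", "plasma"])]["sample_id"].tolist()
        tis = sub[sub.specimen == "tissue"]["sample_id"].tolist()
        if serum and tis:
            pairs.append((serum[0], tis[0]))
    return pairs


def select_smps(candidates: SignatureSet, serum: BetaMatrix, tissue: BetaMatrix,
                pairs: list[tuple[str, str]], delta: float) -> SignatureSet:
    """Keep candidates whose mean |beta_serum - beta_tissue| over pairs <= delta."""
    if not pairs:
        raise ValidationError("no serum/tissue pairs")
    if delta <= 0:
        raise ValidationError("delta must be positive")
    pairs = [(s, t) for (s, t) in pairs
             if s in set(serum.sample_ids) and t in set(tissue.sample_ids)]
    if not pairs:
        raise ValidationError("no pairs present in the matrices")
    s_cols = [p[0] for p in pairs]
    t_cols = [p[1] for p in pairs]
    S = serum.subset_probes(candidates.probe_ids).values[s_cols].to_numpy()
    T = tissue.subset_probes(candidates.probe_ids).values[t_cols].to_numpy()
    mean_abs = np.abs(S - T).mean(axis=1)
    keep = [p for p, m in zip(candidates.probe_ids, mean_abs) if m <= delta]
    return SignatureSet(keep, stage="smp",
                        params={**candidates.params, "smp_delta": delta,
                                "n_pairs": len(pairs)})


def _top_by_fdr(t: pd.DataFrame, target_size: int) -> list:
    """target_size probes with smallest FDR p; ties by larger |diff_mean|,
    then lexical probe id."""
    order = t.assign(_absd=-t["diff_mean"].abs(), _id=t.index)
    order = order.sort_values(["p_fdr", "_absd", "_id"], kind="mergesort")
    return order.index[:target_size].tolist()


def derive_dmelb_signature(smps: SignatureSet, serum: BetaMatrix,
                           sheet: SampleSheet, target_size: int = 25) -> SignatureSet:
    """Final diagnostic signature: untreated MNG vs non-MNG serum over SMPs."""
    if not (DMELB_SIZE_RANGE[0] <= target_size <= DMELB_SIZE_RANGE[1]):
        raise ValidationError(f"target_size outside {DMELB_SIZE_RANGE}")
    if len(smps) < target_size:
        raise ValidationError(
            f"only {len(smps)} SMPs available for target_size={target_size}")
    present = set(serum.sample_ids)
    mng = [s for s in sheet.samples(specimen={"serum", "plasma"}, group="MNG",
                                    treated_presurgery=False) if s in present]
    non = [s for s in sheet.rows(specimen={"serum", "plasma"})
           .query("group != 'MNG' and group != 'glioblastoma'")["sample_id"]
           if s in present]
    if len(mng) < 3 or len(non) < 3:
        raise ValidationError("too few eligible samples (<3/group)")
    t = wilcoxon_dmp(serum.subset_probes(smps.probe_ids), mng, non)
    chosen = _top_by_fdr(t, target_size)
    return SignatureSet(chosen, stage="d_melb",
                        params={**smps.params, "target_size": target_size,
                                "n_untreated_mng": len(mng), "n_non_mng": len(non)})


def adverse_clusters(clusters: pd.Series, sheet: SampleSheet) -> list:
    """Serum clusters enriched for confirmed recurrence (above-average CR rate)."""
    t = sheet.table.set_index("sample_id")
    cr = (t.loc[clusters.index, "outcome"] == "CR").astype(float)
    overall = cr.mean()
    by_cluster = cr.groupby(clusters).mean()
    adv = by_cluster.index[by_cluster > overall].tolist()
    if not adv:  # degenerate: no enrichment signal, take the single worst
        adv = [by_cluster.idxmax()]
    return sorted(adv)


def derive_pmelb_signature(tissue: BetaMatrix, serum: BetaMatrix,
                           sheet: SampleSheet, clusters: pd.Series,
                           params: dict) -> SignatureSet:
    """Prognostic signature: CR-vs-CNR tissue DMPs intersected with
    adverse-vs-favorable serum-cluster DMPs, ranked by combined p.

    ``params`` carries the drawn thresholds: p_max_tissue, diff_min_tissue,
    p_max_serum, diff_min_serum.  An empty intersection raises
    :class:`DegenerateDrawError` so the iteration loop can resample.
    """
    present_t = set(tissue.sample_ids)
    cr = [s for s in sheet.samples(specimen="tissue", group="MNG", outcome="CR")
          if s in present_t]
    cnr = [s for s in sheet.samples(specimen="tissue", group="MNG", outcome="CNR")
           if s in present_t]
    if len(cr) < 2 or len(cnr) < 2:
        raise ValidationError("need CR and CNR tissue training samples")
    t_tis = wilcoxon_dmp(tissue, cr, cnr)
    keep_t = (t_tis["p_fdr"] <= params["p_max_tissue"]) & \
             (t_tis["diff_mean"].abs() >= params["diff_min_tissue"])

    adv = adverse_clusters(clusters, sheet)
    present_s = set(serum.sample_ids)
    s_adv = [s for s in clusters.index if clusters[s] in adv and s in present_s]
    s_fav = [s for s in clusters.index if clusters[s] not in adv and s in present_s]
    if len(s_adv) < 2 or len(s_fav) < 2:
        raise DegenerateDrawError("cluster split leaves a side with <2 samples")
    t_ser = wilcoxon_dmp(serum, s_adv, s_fav)
    keep_s = (t_ser["p_fdr"] <= params["p_max_serum"]) & \
             (t_ser["diff_mean"].abs() >= params["diff_min_serum"])

    common = t_tis.index[keep_t].intersection(t_ser.index[keep_s])
    if len(common) == 0:
        raise DegenerateDrawError("empty tissue/serum intersection")
    combined = (np.log(np.clip(t_tis.loc[common, "p_value"], 1e-300, None))
                + np.log(np.clip(t_ser.loc[common, "p_value"], 1e-300, None)))
    order = pd.DataFrame({"c": combined,
                          "_absd": -t_tis.loc[common, "diff_mean"].abs()},
                         index=common).sort_values(["c", "_absd"], kind="mergesort")
    return SignatureSet(order.index.tolist(), stage="p_melb",
                        params={**params, "adverse_clusters": adv})


def check_nesting(d_melb: SignatureSet, smps: SignatureSet,
                  tumor_specific: SignatureSet) -> None:
    """Assert the pipeline nesting d-MeLB subset-of SMP subset-of tumor-specific."""
    if not set(d_melb.probe_ids) <= set(smps.probe_ids):
        raise ValidationError("d-MeLB signature not contained in SMPs")
    if not set(smps.probe_ids) <= set(tumor_specific.probe_ids):
        raise ValidationError("SMPs not contained in tumor-specific DMPs")
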