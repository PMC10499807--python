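"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a paired serum/tissue methylation study of meningioma
(MNG) versus other central-nervous-system entities:

* per-probe baseline betas drawn from a bimodal Beta mixture (array-like);
* planted MNG-specific diagnostic probes (mean shift ``delta_diag`` in the
  tumor profile), risk-specific prognostic probes (shift ``delta_prog`` in
  high-risk tumors) and serum-cluster-specific probes;
* serum as a mixture ``tf * tumor + (1 - tf) * blood`` so paired serum and
  tissue are highly correlated, with the blood component carrying an
  immune-cell mixture (Dirichlet fractions over a reference atlas, with a
  neutrophil shift in high-risk patients);
* recurrence outcomes derived from simulated event times: exponential
  hazards per latent risk arm, uniform follow-up, and the five-year rule for
  confirmed non-recurrence (CNR).

Every sampled value passes through a Beta(mu*c, (1-mu)*c) observation model,
so all betas respect [0,1] with array-like heteroscedasticity.  All
randomness flows from one seed through named child streams, so a fixed
config is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_core import BetaMatrix, ExpressionMatrix, ProbeAnnotation, SampleSheet

CELL_TYPES = ("neutrophil", "B", "CD4T", "CD8T", "NK", "monocyte")

#: Dirichlet concentration of blood immune fractions (blood-like mixture,
#: neutrophils ~1/3 of cfDNA); high-risk patients get the neutrophil entry
#: doubled, producing the outcome-linked neutrophil/NLR shift.
_ALPHA_BASE = {"neutrophil": 8.0, "B": 3.0, "CD4T": 5.0, "CD8T": 4.0,
               "NK": 2.0, "monocyte": 3.0}
_ALPHA_HIGHRISK_NEUTROPHIL = 16.0

_CGI_CLASSES = np.array(["island", "shore", "shelf", "open_sea"])
_CGI_PROPS = np.array([0.30, 0.25, 0.15, 0.30])


@dataclass
class SimulationConfig:
    """Study-design knobs for :func:`simulate_cohort`.

    Defaults describe the reference scenario used throughout the test suite:
    50 meningioma and 50 non-meningioma serum samples, paired tumor tissue,
    a second tissue-only meningioma series, planted diagnostic effect 0.3.
    """

    n_probes: int = 4000
    # cohort cells: (specimen, group, latent risk)
    n_serum_mng: int = 50          # paired with tissue, half high / half low risk
    n_serum_nonmng: dict = field(default_factory=lambda: {
        "glioma": 20, "glioblastoma": 10, "pituitary": 10, "control": 10})
    n_tissue_mng_extra: int = 50   # tissue-only MNG patients (prognostic series)
    n_tissue_control: int = 20     # nontumor brain tissue
    # planted signatures
    n_signature_diag: int = 120
    n_signature_prog: int = 80
    delta_diag: float = 0.3
    delta_prog: float = 0.3
    n_clusters: int = 4
    n_cluster_probes: int = 50     # per serum cluster
    delta_cluster: float = 0.3
    n_gbm_probes: int = 60         # glioblastoma-specific (the 'distinct' subtype)
    delta_gbm: float = 0.3
    n_immune_probes: int = 300     # cell-type discriminating block in blood
    # observation model
    tumor_fraction_serum: float = 0.8
    beta_concentration: float = 60.0
    # survival model (months)
    baseline_hazard: float = 0.001   # low-risk arm
    hazard_ratio: float = 30.0
    follow_up_min: float = 6.0
    follow_up_max: float = 120.0
    treated_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_serum_mng, self.n_tissue_control) < 2:
            raise ValidationError("infeasible group sizes")
        if any(v < 0 for v in self.n_serum_nonmng.values()):
            raise ValidationError("negative non-MNG group size")
        planted = (self.n_signature_diag + self.n_signature_prog
                   + self.n_clusters * self.n_cluster_probes
                   + self.n_gbm_probes + self.n_immune_probes)
        if planted > self.n_probes:
            raise ValidationError(
                f"planted probe blocks ({planted}) exceed n_probes ({self.n_probes})")
        for name in ("delta_diag", "delta_prog", "delta_cluster", "delta_gbm"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValidationError(f"{name} must lie in [0,1)")
        if not (0 < self.tumor_fraction_serum <= 1):
            raise ValidationError("tumor_fraction_serum must lie in (0,1]")
        if self.hazard_ratio <= 0 or self.baseline_hazard < 0:
            raise ValidationError("hazard parameters must be positive")


@dataclass
class GroundTruth:
    """Latent state of a simulated cohort, for recovery checks."""

    diagnostic_probes: list
    prognostic_probes: list
    cluster_probes: dict          # cluster label -> probe list
    gbm_probes: list
    immune_probes: list
    risk: pd.Series               # sample_id -> {'high','low'} (MNG only)
    clusters: pd.Series           # MNG serum sample_id -> 1..k
    cell_fractions: pd.DataFrame  # serum samples x cell types
    atlas: BetaMatrix             # immune probes x cell types (noise-free means)
    annotation: ProbeAnnotation
    beta: BetaMatrix | None = None     # full simulated matrix (for integration)
    pgp_probes: list | None = None     # set by simulate_expression

    def probe_gene(self, probe: str):
        g = self.annotation.table.loc[probe, "gene_symbol"]
        return None if pd.isna(g) else g


def _beta_noise(rng: np.random.Generator, mean: np.ndarray, c: float) -> np.ndarray:
    mu = np.clip(mean, 0.02, 0.98)
    if not np.isfinite(c):  # degenerate noise-free limit
        return mu
    return rng.beta(mu * c, (1.0 - mu) * c)


def _bimodal_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    lo = rng.beta(2.0, 8.0, size=n)
    hi = rng.beta(8.0, 2.0, size=n)
    return np.where(rng.random(n) < 0.5, lo, hi)


def _shiftable_baseline(rng: np.random.Generator, delta: float, sign: np.ndarray) -> np.ndarray:
    """Baselines leaving room for a +/- delta shift without boundary clipping."""
    lo = np.where(sign > 0, 0.10, 0.05 + delta)
    hi = np.where(sign > 0, 0.95 - delta, 0.90)
    return rng.uniform(lo, hi)


def _atlas_means(rng: np.random.Generator, probe_ids, cell_types,
                 frac_discriminating: float = 0.5) -> pd.DataFrame:
    """Noise-free reference means: discriminating probes are unmethylated in
    their own cell type and methylated elsewhere."""
    n = len(probe_ids)
    k = len(cell_types)
    base = _bimodal_baseline(rng, n)
    M = np.tile(base[:, None], (1, k))
    n_disc = max(int(round(frac_discriminating * n)), k)
    disc_idx = rng.choice(n, size=min(n_disc, n), replace=False)
    owner = np.arange(disc_idx.size) % k
    rng.shuffle(owner)
    M[disc_idx, :] = 0.90
    M[disc_idx, owner] = 0.05
    return pd.DataFrame(M, index=list(probe_ids), columns=list(cell_types))


def simulate_reference_atlas(cell_types=CELL_TYPES, n_probes: int = 500,
                             seed: int = 0) -> BetaMatrix:
    """Reference methylation atlas: one column per cell type.

    At least 10% of probes discriminate a single cell type (beta near 0 in
    that type, near 1 in the others), which is what reference-based
    deconvolution needs.
    """
    cell_types = list(cell_types)
    if len(cell_types) < 2:
        raise ValidationError("need >= 2 cell types")
    if n_probes < len(cell_types):
        raise ValidationError("n_probes must be >= number of cell types")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    ids = [f"imm{i:06d}" for i in range(n_probes)]
    return BetaMatrix(_atlas_means(rng, ids, cell_types))


def simulate_cohort(cfg: SimulationConfig) -> tuple[BetaMatrix, SampleSheet, GroundTruth]:
    """Simulate a paired serum/tissue methylation cohort.

    Returns the beta matrix (probes x all samples), the sample sheet and a
    :class:`GroundTruth` carrying every latent quantity (planted probe sets,
    risk/cluster labels, immune fractions, the probe annotation and the
    matrix itself).
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rngs = {name: np.random.default_rng(child) for name, child in zip(
        ["layout", "baseline", "survival", "immune", "noise", "annotation"],
        ss.spawn(6))}

    probes = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    r = rngs["layout"]
    perm = r.permutation(cfg.n_probes)
    cursor = 0

    def take(n):
        nonlocal cursor
        out = perm[cursor:cursor + n]
        cursor += n
        return out

    idx_diag = take(cfg.n_signature_diag)
    idx_prog = take(cfg.n_signature_prog)
    idx_clus = {k + 1: take(cfg.n_cluster_probes) for k in range(cfg.n_clusters)}
    idx_gbm = take(cfg.n_gbm_probes)
    idx_imm = take(cfg.n_immune_probes)

    rb = rngs["baseline"]
    baseline = _bimodal_baseline(rb, cfg.n_probes)
    sign_diag = np.where(rb.random(cfg.n_signature_diag) < 0.5, 1.0, -1.0)
    baseline[idx_diag] = _shiftable_baseline(rb, cfg.delta_diag, sign_diag)
    sign_prog = np.where(rb.random(cfg.n_signature_prog) < 0.5, 1.0, -1.0)
    baseline[idx_prog] = _shiftable_baseline(rb, cfg.delta_prog, sign_prog)
    sign_clus = {}
    for k, idx in idx_clus.items():
        sign_clus[k] = np.where(rb.random(idx.size) < 0.5, 1.0, -1.0)
        baseline[idx] = _shiftable_baseline(rb, cfg.delta_cluster, sign_clus[k])
    sign_gbm = np.where(rb.random(cfg.n_gbm_probes) < 0.5, 1.0, -1.0)
    baseline[idx_gbm] = _shiftable_baseline(rb, cfg.delta_gbm, sign_gbm)

    atlas_means = _atlas_means(rngs["immune"], [probes[i] for i in idx_imm],
                               list(CELL_TYPES))

    # ----- sample layout -------------------------------------------------
    rows = []  # (sample_id, patient_id, specimen, group, risk)
    n_high = cfg.n_serum_mng // 2
    for i in range(cfg.n_serum_mng):
        pid = f"P{i:04d}"
        risk = "high" if i < n_high else "low"
        rows.append((f"S_MNG_{i:03d}", pid, "serum", "MNG", risk))
        rows.append((f"T_MNG_{i:03d}", pid, "tissue", "MNG", risk))
    pcount = cfg.n_serum_mng
    n_high_x = cfg.n_tissue_mng_extra // 2
    for i in range(cfg.n_tissue_mng_extra):
        pid = f"P{pcount + i:04d}"
        risk = "high" if i < n_high_x else "low"
        rows.append((f"T_MNGX_{i:03d}", pid, "tissue", "MNG", risk))
    pcount += cfg.n_tissue_mng_extra
    for grp, n in cfg.n_serum_nonmng.items():
        tag = grp.upper().replace(" ", "_")
        for i in range(n):
            pid = f"P{pcount:04d}"
            pcount += 1
            rows.append((f"S_{tag}_{i:03d}", pid, "serum", grp, "none"))
    for i in range(cfg.n_tissue_control):
        pid = f"P{pcount:04d}"
        pcount += 1
        rows.append((f"T_CTL_{i:03d}", pid, "tissue", "control", "none"))

    layout = pd.DataFrame(rows, columns=["sample_id", "patient_id", "specimen",
                                         "group", "risk"])

    # serum clusters: risk-aligned (adverse clusters carry the high-risk arm)
    adverse = [k for k in idx_clus if k > cfg.n_clusters // 2] or [cfg.n_clusters]
    favorable = [k for k in idx_clus if k not in adverse]
    clus_labels = {}
    mng_serum = layout[(layout.specimen == "serum") & (layout.group == "MNG")]
    for _, row in mng_serum.iterrows():
        pool = adverse if row.risk == "high" else (favorable or adverse)
        clus_labels[row.sample_id] = pool[r.integers(len(pool))]
    clusters = pd.Series(clus_labels, name="cluster")

    # immune fractions per serum sample
    ri = rngs["immune"]
    fr_rows, fr_idx = [], []
    for _, row in layout[layout.specimen == "serum"].iterrows():
        alpha = [_ALPHA_HIGHRISK_NEUTROPHIL if (ct == "neutrophil" and row.risk == "high")
                 else _ALPHA_BASE[ct] for ct in CELL_TYPES]
        fr_rows.append(ri.dirichlet(alpha))
        fr_idx.append(row.sample_id)
    fractions = pd.DataFrame(fr_rows, index=fr_idx, columns=list(CELL_TYPES))

    # ----- per-sample mean profiles -------------------------------------
    tf = cfg.tumor_fraction_serum
    A = atlas_means.to_numpy()
    mean_cols = {}
    for _, row in layout.iterrows():
        tumor = baseline.copy()
        if row.group == "MNG":
            tumor[idx_diag] = baseline[idx_diag] + sign_diag * cfg.delta_diag
            if row.risk == "high":
                tumor[idx_prog] = baseline[idx_prog] + sign_prog * cfg.delta_prog
        elif row.group == "glioblastoma":
            tumor[idx_gbm] = baseline[idx_gbm] + sign_gbm * cfg.delta_gbm
        if row.specimen == "tissue":
            mean_cols[row.sample_id] = tumor
            continue
        blood = baseline.copy()
        blood[idx_imm] = A @ fractions.loc[row.sample_id].to_numpy()
        w = 0.0 if row.group == "control" else tf
        serum = w * tumor + (1.0 - w) * blood
        if row.sample_id in clus_labels:
            k = clus_labels[row.sample_id]
            serum[idx_clus[k]] = np.clip(
                serum[idx_clus[k]] + sign_clus[k] * cfg.delta_cluster, 0.02, 0.98)
        mean_cols[row.sample_id] = serum

    M = np.column_stack([mean_cols[s] for s in layout.sample_id])
    values = _beta_noise(rngs["noise"], M, cfg.beta_concentration)
    beta = BetaMatrix(pd.DataFrame(values, index=probes,
                                   columns=list(layout.sample_id)))

    # ----- survival and outcome labels ----------------------------------
    rs = rngs["survival"]
    person_time, outcome, treated, collection = {}, {}, {}, {}
    for pid, sub in layout.groupby("patient_id", sort=True):
        risk = sub.risk.iloc[0]
        grp = sub.group.iloc[0]
        F = rs.uniform(cfg.follow_up_min, cfg.follow_up_max)
        if grp == "MNG" and cfg.baseline_hazard > 0:
            h = cfg.baseline_hazard * (cfg.hazard_ratio if risk == "high" else 1.0)
            T = rs.exponential(1.0 / h)
            if T <= F:
                person_time[pid], outcome[pid] = T, "CR"
            else:
                person_time[pid] = F
                outcome[pid] = "CNR" if F >= 60.0 else "unknown"
        else:
            person_time[pid], outcome[pid] = F, "unknown"
        treated[pid] = bool(rs.random() < cfg.treated_fraction) if grp == "MNG" else False
        collection[pid] = "recurrent" if rs.random() < 0.2 else "primary"

    sheet = pd.DataFrame({
        "sample_id": layout.sample_id,
        "patient_id": layout.patient_id,
        "specimen": layout.specimen,
        "group": layout.group,
        "treated_presurgery": [treated[p] for p in layout.patient_id],
        "collection": [collection[p] for p in layout.patient_id],
        "outcome": [outcome[p] for p in layout.patient_id],
        "person_time": [round(person_time[p], 4) for p in layout.patient_id],
        "split": "unassigned",
    })

    annotation = _simulate_annotation(rngs["annotation"], probes, idx_diag,
                                      idx_prog, idx_imm)
    gt = GroundTruth(
        diagnostic_probes=[probes[i] for i in idx_diag],
        prognostic_probes=[probes[i] for i in idx_prog],
        cluster_probes={k: [probes[i] for i in idx] for k, idx in idx_clus.items()},
        gbm_probes=[probes[i] for i in idx_gbm],
        immune_probes=[probes[i] for i in idx_imm],
        risk=pd.Series(layout.risk.to_numpy(), index=layout.sample_id, name="risk"),
        clusters=clusters,
        cell_fractions=fractions,
        atlas=BetaMatrix(atlas_means),
        annotation=annotation,
        beta=beta,
    )
    return beta, SampleSheet(sheet), gt


def _simulate_annotation(rng, probes, idx_diag, idx_prog, idx_imm) -> ProbeAnnotation:
    n = len(probes)
    special = set(np.concatenate([idx_diag, idx_prog, idx_imm]).tolist())
    on_450k = np.ones(n, dtype=bool)
    on_epic = np.ones(n, dtype=bool)
    masked = np.zeros(n, dtype=bool)
    for i in range(n):
        if i in special:
            continue
        u = rng.random()
        if u < 0.03:
            masked[i] = True
        elif u < 0.08:
            on_450k[i] = False  # EPIC-only designs

    genes = np.array([None] * n, dtype=object)
    promoter = np.zeros(n, dtype=bool)
    enhancer = np.zeros(n, dtype=bool)
    for j, i in enumerate(idx_prog):
        genes[i] = f"GENE_P{j:04d}"
        if j % 2 == 0:
            promoter[i] = True
        else:
            enhancer[i] = True
    for j, i in enumerate(idx_diag):
        genes[i] = f"GENE_D{j:04d}"
        promoter[i] = bool(rng.random() < 0.5)
    rest = [i for i in range(n) if genes[i] is None]
    for i in rest:
        if rng.random() < 0.5:
            genes[i] = f"GENE_B{i:05d}"
            promoter[i] = bool(rng.random() < 0.2)
            enhancer[i] = bool((not promoter[i]) and rng.random() < 0.2)

    chroms = [f"chr{(i % 22) + 1}" for i in range(n)]
    pos = (np.arange(n) // 22 + 1) * 1000 + rng.integers(0, 500, size=n)
    t = pd.DataFrame({
        "probe_id": probes, "chrom": chroms, "pos": pos,
        "on_450k": on_450k, "on_epic": on_epic, "masked": masked,
        "cgi_context": rng.choice(_CGI_CLASSES, size=n, p=_CGI_PROPS),
        "gene_symbol": genes, "promoter": promoter, "enhancer": enhancer,
    })
    return ProbeAnnotation(t)


def simulate_expression(gt: GroundTruth, pgp_fraction: float = 0.5,
                        seed: int = 0, noise_sd: float = 0.1,
                        slope: float = 2.0) -> ExpressionMatrix:
    """Paired tissue transcriptome with planted methylation-coupled genes.

    A ``pgp_fraction`` of the prognostic probes get their target gene's
    expression negatively coupled to the probe's beta (expr = a - slope*beta
    + noise); the remaining annotated genes are independent Gaussian noise.
    The coupled probe ids are recorded on ``gt.pgp_probes``.
    """
    if not (0.0 <= pgp_fraction <= 1.0):
        raise ValidationError("pgp_fraction must lie in [0,1]")
    if gt.beta is None:
        raise ValidationError("ground truth lacks the beta matrix")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7002]))
    tissue = [s for s in gt.beta.sample_ids if s.startswith("T_MNG")]
    prog = [p for p in gt.prognostic_probes if gt.probe_gene(p)]
    if not prog:
        raise ValidationError("no prognostic probes with gene assignments")
    n_coupled = int(round(pgp_fraction * len(prog)))
    coupled = list(rng.choice(prog, size=n_coupled, replace=False))
    gt.pgp_probes = coupled

    B = gt.beta.values.loc[prog, tissue].to_numpy()
    expr = {}
    for i, probe in enumerate(prog):
        gene = gt.probe_gene(probe)
        if probe in coupled:
            e = 8.0 - slope * B[i] + (rng.normal(0.0, noise_sd, len(tissue))
                                      if noise_sd > 0 else 0.0)
        else:
            e = rng.normal(6.0, 1.0, len(tissue))
        expr[gene] = e
    # background genes unrelated to any probe of interest
    ann = gt.annotation.table
    bg_genes = [g for g in ann["gene_symbol"].dropna().unique()
                if str(g).startswith("GENE_B")][:200]
    for gene in bg_genes:
        expr[gene] = rng.normal(6.0, 1.0, len(tissue))
    df = pd.DataFrame(expr, index=tissue).T
    return ExpressionMatrix(df)


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
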