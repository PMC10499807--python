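"""Supervised differential methylation.

Per-probe two-group Wilcoxon rank-sum tests over beta values, Benjamini-
Hochberg FDR adjustment, volcano-style threshold selection (asymmetric
effect windows supported) and genomic annotation of the retained probes
(CGI context, gene, promoter/enhancer membership).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_core import BetaMatrix, ProbeAnnotation

#: largest group size for which the exact rank-sum null is enumerated
EXACT_MAX_N = 10


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone and capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p: exact for small tie-free rows, else
    normal approximation with continuity correction and tie correction."""
    n1, n2 = x.shape[1], y.shape[1]
    p_asym = stats.mannwhitneyu(x, y, axis=1, method="asymptotic",
                                use_continuity=True).pvalue
    if min(n1, n2) > EXACT_MAX_N:
        return p_asym
    combined = np.concatenate([x, y], axis=1)
    has_ties = np.array([
        len(np.unique(row)) < row.size for row in combined
    ])
    p = p_asym.copy()
    if np.any(~has_ties):
        p_exact = stats.mannwhitneyu(x[~has_ties], y[~has_ties], axis=1,
                                     method="exact").pvalue
        p[~has_ties] = p_exact
    return p


def wilcoxon_dmp(m: BetaMatrix, g1, g2) -> pd.DataFrame:
    """Per-probe Wilcoxon rank-sum DMP table for two disjoint sample groups.

    Returns a DataFrame indexed by probe_id with columns mean_g1, mean_g2,
    diff_mean (= mean_g1 - mean_g2), p_value, p_fdr and direction
    ('hyper' when diff_mean >= 0 in group 1, else 'hypo').
    """
    g1, g2 = list(g1), list(g2)
    if set(g1) & set(g2):
        raise ValidationError(f"overlapping groups: {sorted(set(g1) & set(g2))[:5]}")
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each group needs >= 2 samples")
    x = m.subset_samples(g1).values.to_numpy(dtype=float)
    y = m.subset_samples(g2).values.to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("matrix contains missing values; impute first")
    mean1 = x.mean(axis=1)
    mean2 = y.mean(axis=1)
    p = _rank_sum_pvalues(x, y)
    diff = mean1 - mean2
    return pd.DataFrame({
        "mean_g1": mean1, "mean_g2": mean2, "diff_mean": diff,
        "p_value": p, "p_fdr": adjust_fdr(p),
        "direction": np.where(diff >= 0, "hyper", "hypo"),
    }, index=pd.Index(m.probe_ids, name="probe_id"))


def select_dmps(t: pd.DataFrame, p_fdr_max: float,
                diff_lo: float, diff_hi: float) -> pd.DataFrame:
    """Volcano-guided DMP selection.

    Keeps probes with p_fdr <= p_fdr_max and diff_mean >= diff_hi or
    <= diff_lo.  With diff_lo = -diff_hi this is the symmetric
    |diff_mean| >= diff_hi filter; asymmetric windows are allowed.
    """
    if diff_lo > 0 or diff_hi < 0:
        raise ValidationError("expected diff_lo <= 0 <= diff_hi")
    keep = (t["p_fdr"] <= p_fdr_max) & (
        (t["diff_mean"] >= diff_hi) | (t["diff_mean"] <= diff_lo)
    )
    return t[keep]


#: promoter window half-width around a TSS, in bp (0-based arithmetic)
PROMOTER_WINDOW = 200


def mark_promoter_probes(ann: ProbeAnnotation, tss: pd.DataFrame,
                         window: int = PROMOTER_WINDOW) -> ProbeAnnotation:
    """Recompute promoter flags: probe within ``window`` bp of a TSS.

    ``tss`` needs columns chrom, pos (0-based) and gene_symbol; a probe in
    the closed window [tss - window, tss + window] on the same chromosome is
    flagged as promoter and inherits the gene symbol.
    """
    t = ann.table.copy()
    t["promoter"] = False
    for _, row in tss.iterrows():
        hit = (t["chrom"] == row["chrom"]) & \
              (t["pos"] >= row["pos"] - window) & \
              (t["pos"] <= row["pos"] + window)
        t.loc[hit, "promoter"] = True
        t.loc[hit, "gene_symbol"] = row["gene_symbol"]
    return ProbeAnnotation(t.reset_index())


def annotate_dmps(t: pd.DataFrame, ann: ProbeAnnotation) -> pd.DataFrame:
    """Attach CGI context, gene symbol and promoter/enhancer flags to a DMP table."""
    a = ann.require(list(t.index))
    out = t.copy()
    for col in ("cgi_context", "gene_symbol", "promoter", "enhancer"):
        out[col] = a[col].to_numpy()
    return out
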