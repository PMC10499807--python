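"""Methylation-expression integration: probe-gene pairs (PGPs).

A PGP is a differentially methylated probe in a regulatory element (promoter
or enhancer) whose annotated target gene is differentially expressed between
the same two groups and whose methylation correlates negatively with the
gene's expression across samples — the classical signature of epigenetic
repression.  A hypergeometric enrichment utility for gene sets is included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import adjust_fdr
from .errors import ValidationError
from .io_core import BetaMatrix, ExpressionMatrix, ProbeAnnotation, SampleSheet
from .metrics import welch_t


def find_pgps(meth: BetaMatrix, expr: ExpressionMatrix, sheet: SampleSheet,
              dmps: pd.DataFrame, ann: ProbeAnnotation,
              g1: list, g2: list, r_max: float = -0.3,
              de_p_fdr_max: float = 0.05) -> pd.DataFrame:
    """Probe-gene pairs among regulatory DMPs.

    For every DMP with an annotated target gene in a promoter or enhancer,
    the gene must be differentially expressed between groups ``g1``/``g2``
    (Welch t, BH-adjusted p <= ``de_p_fdr_max``) and the Pearson correlation
    of beta with expression across shared samples must satisfy
    r <= ``r_max`` (negative).  Zero-variance expression excludes the pair.
    """
    if r_max >= 0:
        raise ValidationError("r_max must be negative")
    shared = [s for s in meth.sample_ids if s in set(expr.sample_ids)]
    if not shared:
        raise ValidationError("no shared samples between methylation and expression")
    g1s = [s for s in g1 if s in set(expr.sample_ids)]
    g2s = [s for s in g2 if s in set(expr.sample_ids)]
    if len(g1s) < 2 or len(g2s) < 2:
        raise ValidationError("each group needs >= 2 samples with expression")

    a = ann.require(list(dmps.index))
    regulatory = a[(a["promoter"] | a["enhancer"]) & a["gene_symbol"].notna()]
    genes = [g for g in regulatory["gene_symbol"].unique()
             if g in set(expr.gene_ids)]

    # differential expression per candidate gene
    de_p = {}
    de_diff = {}
    for gene in genes:
        x = expr.values.loc[gene, g1s].to_numpy(dtype=float)
        y = expr.values.loc[gene, g2s].to_numpy(dtype=float)
        if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) != np.mean(y):
            continue  # degenerate; cannot test
        res = welch_t(x, y)
        de_p[gene] = res["p"]
        de_diff[gene] = res["mean_diff"]
    if not de_p:
        return _empty_pgp_table()
    keys = sorted(de_p)
    fdr = dict(zip(keys, adjust_fdr([de_p[k] for k in keys])))

    rows = []
    for probe, arow in regulatory.iterrows():
        gene = arow["gene_symbol"]
        if gene not in fdr or fdr[gene] > de_p_fdr_max:
            continue
        b = meth.values.loc[probe, shared].to_numpy(dtype=float)
        e = expr.values.loc[gene, shared].to_numpy(dtype=float)
        if np.var(e) == 0 or np.var(b) == 0:
            continue
        r, p_r = stats.pearsonr(b, e)
        if r <= r_max:
            rows.append({
                "probe_id": probe, "gene": gene,
                "element": "promoter" if arow["promoter"] else "enhancer",
                "diff_mean": float(dmps.loc[probe, "diff_mean"]),
                "diff_expr": float(de_diff[gene]), "de_p_fdr": float(fdr[gene]),
                "r": float(r), "p_r": float(p_r),
                "concordant_serum_tissue": False,
            })
    if not rows:
        return _empty_pgp_table()
    return pd.DataFrame(rows).set_index("probe_id")


def _empty_pgp_table() -> pd.DataFrame:
    cols = ["gene", "element", "diff_mean", "diff_expr", "de_p_fdr", "r",
            "p_r", "concordant_serum_tissue"]
    return pd.DataFrame(columns=cols, index=pd.Index([], name="probe_id"))


def concordance_serum_tissue(tissue_pgps: pd.DataFrame,
                             serum_dmps: pd.DataFrame) -> pd.DataFrame:
    """Flag tissue PGPs whose probe is differential in serum with the same
    diff_mean sign; probes absent from the serum table stay False."""
    out = tissue_pgps.copy()
    flags = []
    for probe, row in out.iterrows():
        if probe in serum_dmps.index:
            flags.append(bool(np.sign(serum_dmps.loc[probe, "diff_mean"])
                              == np.sign(row["diff_mean"])
                              and row["diff_mean"] != 0))
        else:
            flags.append(False)
    out["concordant_serum_tissue"] = flags
    return out


def hypergeometric_enrichment(hits: set, gene_set: set, universe: set) -> dict:
    """One-sided over-representation p of ``gene_set`` among ``hits``."""
    hits, gene_set, universe = set(hits), set(gene_set), set(universe)
    k = len(hits & gene_set)
    M, n, N = len(universe), len(gene_set & universe), len(hits & universe)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    return {"overlap": k, "universe": M, "set_size": n, "hits": N, "p": p}
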