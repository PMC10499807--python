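"""Reference-based immune deconvolution of beta profiles.

Each sample's beta vector over the atlas probes is decomposed as a
nonnegative mixture of cell-type reference profiles (nonnegative least
squares, fractions normalized to sum 1); the neutrophil-lymphocyte ratio
(NLR) summarizes the myeloid/lymphoid balance.  This is a deterministic
constrained-least-squares stage; its deliverable is mixture recovery, not
any particular reference implementation's internals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import ValidationError
from .io_core import BetaMatrix

#: lymphocyte compartments forming the NLR denominator
LYMPHOCYTES = ("B", "CD4T", "CD8T", "NK")
#: fractions below this are truncated to zero before normalization
FRACTION_FLOOR = 1e-4


@dataclass
class ReferenceAtlas:
    """Mean beta per probe per cell type."""

    means: pd.DataFrame  # probes x cell types

    def __post_init__(self):
        if self.means.columns.has_duplicates:
            raise ValidationError("duplicate cell types")
        v = self.means.to_numpy()
        if np.any((v < 0) | (v > 1)):
            raise ValidationError("atlas betas must lie in [0,1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.means.columns)

    @classmethod
    def from_beta_matrix(cls, m: BetaMatrix) -> "ReferenceAtlas":
        return cls(m.values.copy())


@dataclass
class DeconvResult:
    sample_id: str
    fractions: pd.Series     # per cell type, sums to 1
    residual_norm: float
    degenerate: bool = False


def deconvolve(m: BetaMatrix, atlas: ReferenceAtlas) -> list[DeconvResult]:
    """Nonnegative least-squares fractions per sample over shared probes."""
    shared = [p for p in atlas.means.index if p in set(m.probe_ids)]
    k = len(atlas.cell_types)
    if len(shared) < k:
        raise ValidationError(
            f"only {len(shared)} shared probes for {k} cell types")
    A = atlas.means.loc[shared].to_numpy()
    B = m.values.loc[shared].to_numpy()
    out = []
    for j, sample in enumerate(m.sample_ids):
        b = B[:, j]
        ok = ~np.isnan(b)
        coef, rnorm = nnls(A[ok], b[ok])
        coef[coef < FRACTION_FLOOR] = 0.0
        total = coef.sum()
        degenerate = total == 0.0
        fr = coef / total if total > 0 else np.full(k, 1.0 / k)
        out.append(DeconvResult(
            sample_id=sample,
            fractions=pd.Series(fr, index=atlas.cell_types),
            residual_norm=float(rnorm), degenerate=degenerate))
    return out


def nlr(d: DeconvResult, lymphocytes=LYMPHOCYTES) -> float:
    """Neutrophil fraction over the summed lymphocyte fractions.

    Returns ``inf`` when the lymphocyte denominator is zero but neutrophils
    are present; 0 when neutrophils are absent.
    """
    missing = [c for c in ("neutrophil", *lymphocytes) if c not in d.fractions.index]
    if missing:
        raise ValidationError(f"missing cell types for NLR: {missing}")
    neut = float(d.fractions["neutrophil"])
    lymph = float(d.fractions[list(lymphocytes)].sum())
    if neut == 0.0:
        return 0.0
    if lymph == 0.0:
        return float("inf")
    return neut / lymph


def deconv_table(results: list[DeconvResult]) -> pd.DataFrame:
    """Fractions + NLR as a tidy per-sample table."""
    rows = {r.sample_id: r.fractions for r in results}
    t = pd.DataFrame(rows).T
    t["nlr"] = [nlr(r) for r in results]
    t["residual_norm"] = [r.residual_norm for r in results]
    t.index.name = "sample_id"
    return t
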