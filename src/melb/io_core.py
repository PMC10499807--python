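"""Data model and delimited-text I/O for methylation matrices and metadata.

The universal carrier between pipeline stages is the :class:`BetaMatrix`, a
probe x sample matrix of methylation beta values (methylated signal / total
signal, in [0,1]).  Sample metadata live in a :class:`SampleSheet`; per-probe
genomic context in a :class:`ProbeAnnotation`; paired transcriptomes in an
:class:`ExpressionMatrix`.  All four round-trip losslessly through UTF-8
delimited text with ``NA`` encoding missing values.

Probe harmonization (intersection of the 450K and EPIC array designs, removal
of masked probes) and K-nearest-neighbor imputation of missing beta values
also live here, since every downstream stage assumes a dense, harmonized
matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .errors import FormatError, ValidationError

SPECIMENS = {"serum", "plasma", "tissue"}
OUTCOMES = {"CR", "CNR", "unknown"}
COLLECTIONS = {"primary", "recurrent"}
SPLITS = {"training", "model_selection", "validation", "unassigned"}
CGI_CONTEXTS = {"island", "shore", "shelf", "open_sea"}

#: minimum event-free follow-up (months) required for a confirmed
#: non-recurrence label — the five-year rule.
CNR_MIN_FOLLOWUP = 60.0

_NA = "NA"


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:10]}")


@dataclass
class BetaMatrix:
    """Probe x sample matrix of beta values in [0,1] (NaN = missing)."""

    values: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        v = self.values.to_numpy(dtype=float)
        bad = (v < 0) | (v > 1)
        if np.any(bad & ~np.isnan(v)):
            rows = self.values.index[np.nanmax(np.where(np.isnan(v), 0.5, v), axis=1) > 1]
            rows = rows.union(self.values.index[np.nanmin(np.where(np.isnan(v), 0.5, v), axis=1) < 0])
            raise ValidationError(
                f"beta values outside [0,1] for probes: {list(rows[:10])}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes) -> "BetaMatrix":
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise ValidationError(f"probes absent from matrix: {missing[:10]}")
        return BetaMatrix(self.values.loc[list(probes)])

    def subset_samples(self, samples) -> "BetaMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing[:10]}")
        return BetaMatrix(self.values[list(samples)])


@dataclass
class SampleSheet:
    """Per-sample metadata driving every supervised contrast and split.

    Columns: sample_id, patient_id, specimen, group, treated_presurgery,
    collection, outcome, person_time, split.
    """

    table: pd.DataFrame

    REQUIRED = [
        "sample_id", "patient_id", "specimen", "group", "treated_presurgery",
        "collection", "outcome", "person_time", "split",
    ]

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        _check_unique(t["sample_id"], "sample ids")
        for col, allowed in [("specimen", SPECIMENS), ("outcome", OUTCOMES),
                             ("collection", COLLECTIONS), ("split", SPLITS)]:
            bad = set(t[col]) - allowed
            if bad:
                raise FormatError(f"invalid {col} values: {sorted(bad)}")
        if (t["person_time"].astype(float) < 0).any():
            raise ValidationError("negative person_time")
        cnr = t[t["outcome"] == "CNR"]
        short = cnr[cnr["person_time"].astype(float) < CNR_MIN_FOLLOWUP]
        if len(short):
            raise ValidationError(
                "CNR requires >= 60 months follow-up; violated by: "
                f"{short['sample_id'].tolist()[:10]}"
            )
        self.table = t.reset_index(drop=True)

    def covers(self, m: BetaMatrix) -> None:
        """Every sample of *m* must appear in the sheet."""
        known = set(self.table["sample_id"])
        orphans = [s for s in m.sample_ids if s not in known]
        if orphans:
            raise ValidationError(f"samples absent from sheet: {orphans[:10]}")

    def rows(self, **conditions) -> pd.DataFrame:
        """Rows matching equality/membership conditions, e.g. group='MNG'."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        for col, val in conditions.items():
            if isinstance(val, (list, set, tuple, frozenset)):
                mask &= t[col].isin(list(val))
            else:
                mask &= t[col] == val
        return t[mask]

    def samples(self, **conditions) -> list[str]:
        return self.rows(**conditions)["sample_id"].tolist()


@dataclass
class ProbeAnnotation:
    """Per-probe array membership, genomic coordinates and regulatory context.

    Coordinates are 0-based internally; files may declare 1-based input via a
    ``#coords=1-based`` header line and are shifted on read.
    """

    table: pd.DataFrame  # indexed by probe_id

    REQUIRED = ["chrom", "pos", "on_450k", "on_epic", "masked",
                "cgi_context", "gene_symbol", "promoter", "enhancer"]

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "probe_id":
            if "probe_id" in t.columns:
                t = t.set_index("probe_id")
            else:
                raise FormatError("probe annotation needs a probe_id column")
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"probe annotation missing columns: {missing}")
        _check_unique(t.index, "probe ids")
        bad = set(t["cgi_context"]) - CGI_CONTEXTS
        if bad:
            raise FormatError(f"invalid cgi_context values: {sorted(bad)}")
        self.table = t

    def require(self, probes) -> pd.DataFrame:
        missing = [p for p in probes if p not in self.table.index]
        if missing:
            raise ValidationError(f"unannotated probes: {missing[:10]}")
        return self.table.loc[list(probes)]


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log-scale expression."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# delimited-text readers/writers


def _sniff_delimiter(path: str, explicit: str | None) -> str:
    if explicit:
        return explicit
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_beta_matrix(path: str, delimiter: str | None = None) -> BetaMatrix:
    """Read a probe x sample beta matrix from delimited text.

    First column holds probe ids, the header row sample ids; missing values
    are encoded ``NA``.  Values outside [0,1] raise :class:`ValidationError`
    naming the offending probes; duplicate ids raise :class:`FormatError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=[_NA], comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df.astype(float))


def write_beta_matrix(m: BetaMatrix, path: str, delimiter: str = "\t") -> None:
    df = m.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep=delimiter, na_rep=_NA, float_format="%.10g")


def read_sample_sheet(path: str, delimiter: str | None = None) -> SampleSheet:
    sep = _sniff_delimiter(path, delimiter)
    t = pd.read_csv(path, sep=sep, na_values=[_NA], comment="#")
    if "treated_presurgery" in t.columns:
        t["treated_presurgery"] = t["treated_presurgery"].astype(bool)
    t["sample_id"] = t["sample_id"].astype(str)
    t["patient_id"] = t["patient_id"].astype(str)
    return SampleSheet(t)


def write_sample_sheet(s: SampleSheet, path: str, delimiter: str = "\t") -> None:
    s.table.to_csv(path, sep=delimiter, na_rep=_NA, index=False)


def read_probe_annotation(path: str, delimiter: str | None = None) -> ProbeAnnotation:
    """Read probe annotation; a ``#coords=1-based`` header shifts pos to 0-based."""
    one_based = False
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#coords=1-based"):
            one_based = True
    sep = _sniff_delimiter(path, delimiter)
    t = pd.read_csv(path, sep=sep, na_values=[_NA], comment="#")
    for col in ("on_450k", "on_epic", "masked", "promoter", "enhancer"):
        if col in t.columns:
            t[col] = t[col].astype(bool)
    if "gene_symbol" in t.columns:
        t["gene_symbol"] = t["gene_symbol"].astype(object).where(t["gene_symbol"].notna(), None)
    if one_based:
        t["pos"] = t["pos"].astype(int) - 1
    return ProbeAnnotation(t)


def write_probe_annotation(a: ProbeAnnotation, path: str, delimiter: str = "\t") -> None:
    t = a.table.reset_index()
    t.to_csv(path, sep=delimiter, na_rep=_NA, index=False)


def read_expression_matrix(path: str, delimiter: str | None = None) -> ExpressionMatrix:
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=[_NA], comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(e: ExpressionMatrix, path: str, delimiter: str = "\t") -> None:
    df = e.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter, na_rep=_NA, float_format="%.10g")


# ---------------------------------------------------------------------------
# harmonization and imputation


def harmonize_probes(m: BetaMatrix, ann: ProbeAnnotation,
                     require_both_arrays: bool = True) -> BetaMatrix:
    """Restrict to unmasked probes, optionally to the 450K/EPIC intersection.

    Order-preserving and idempotent; every probe of *m* must be annotated.
    """
    t = ann.require(m.probe_ids)
    keep = ~t["masked"].to_numpy()
    if require_both_arrays:
        keep &= t["on_450k"].to_numpy() & t["on_epic"].to_numpy()
    return BetaMatrix(m.values.loc[keep])


def impute_missing_knn(m: BetaMatrix, k: int = 5,
                       min_shared: int = 3) -> BetaMatrix:
    """Impute missing betas from the mean of the k nearest probes.

    Distances are Euclidean over pairwise-complete sample columns
    (nan-Euclidean scaling); probes sharing fewer than *min_shared* observed
    columns with the target are excluded as neighbors (the requirement is
    capped at the target's own observed count, so narrow matrices stay
    imputable).  Observed entries are never altered; imputed values are
    clipped to [0,1].
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if not np.all(obs.sum(axis=1) > 0):
        dead = m.values.index[obs.sum(axis=1) == 0].tolist()
        raise ValidationError(f"probes with no observed values: {dead[:10]}")
    if np.all(obs):
        return BetaMatrix(m.values.copy())

    D = nan_euclidean_distances(X, X)
    shared = obs.astype(int) @ obs.astype(int).T
    np.fill_diagonal(D, np.inf)

    out = X.copy()
    need_rows = np.where(~obs.all(axis=1))[0]
    for i in need_rows:
        Di = D[i].copy()
        Di[shared[i] < min(min_shared, int(obs[i].sum()))] = np.inf
        order = np.argsort(Di, kind="stable")
        for j in np.where(~obs[i])[0]:
            donors = [r for r in order if np.isfinite(Di[r]) and obs[r, j]][:k]
            if not donors:
                raise ValidationError(
                    f"no usable neighbors for probe {m.probe_ids[i]}"
                )
            out[i, j] = float(np.clip(np.mean(X[donors, j]), 0.0, 1.0))
    return BetaMatrix(pd.DataFrame(out, index=m.values.index,
                                   columns=m.values.columns))
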