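"""Performance and association statistics for classifier evaluation.

Confusion-matrix summaries (accuracy, Se/Sp, PPV/NPV, Matthews correlation,
clinical utility index with its published grade bands, Cohen's kappa),
rank-based AUC, Fisher exact odds ratios, Welch t-tests and correlation
coefficients.  Exact tests delegate to scipy; the bespoke quantities (MCC
zero-marginal convention, CUI grading, concordance AUC) are computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

#: CUI grade bands, closed on the left.
CUI_GRADES = [(0.81, "excellent"), (0.64, "good"), (0.49, "satisfactory")]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("negative confusion counts")
        if self.total == 0:
            raise ValidationError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, truth, pred) -> "ConfusionCounts":
        truth = np.asarray(truth, dtype=bool)
        pred = np.asarray(pred, dtype=bool)
        return cls(tp=int(np.sum(truth & pred)), fp=int(np.sum(~truth & pred)),
                   tn=int(np.sum(~truth & ~pred)), fn=int(np.sum(truth & ~pred)))


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")


def specificity(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")


def ppv(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")


def npv(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fn) if (c.tn + c.fn) else float("nan")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, +1]; 0 when a marginal is empty."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def cui_grade(value: float) -> str:
    for lo, grade in CUI_GRADES:
        if value >= lo:
            return grade
    return "poor"


def cui(c: ConfusionCounts) -> dict:
    """Clinical utility indices: CUI+ = Se x PPV, CUI- = Sp x NPV.

    A zero PPV/NPV denominator flags the corresponding index as undefined.
    """
    out = {}
    se, sp_, pp, nn = sensitivity(c), specificity(c), ppv(c), npv(c)
    if math.isnan(pp) or math.isnan(se):
        out["cui_pos"], out["grade_pos"] = float("nan"), "undefined"
    else:
        out["cui_pos"] = se * pp
        out["grade_pos"] = cui_grade(out["cui_pos"])
    if math.isnan(nn) or math.isnan(sp_):
        out["cui_neg"], out["grade_neg"] = float("nan"), "undefined"
    else:
        out["cui_neg"] = sp_ * nn
        out["grade_neg"] = cui_grade(out["cui_neg"])
    return out


def cohens_kappa(table) -> float:
    """Unweighted kappa for a 2x2 agreement table (rows: rater A, cols: B)."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n <= 0:
        raise ValidationError("empty agreement table")
    p_o = np.trace(t) / n
    p_e = float(np.sum(t.sum(axis=0) * t.sum(axis=1))) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def roc_auc(scores_pos, scores_neg) -> float:
    """AUC as pairwise concordance: P(pos > neg) + 0.5 P(tie)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score vectors must be nonempty")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def fisher_odds_ratio(table) -> dict:
    """Sample odds ratio, logit-normal 95% CI and exact two-sided Fisher p.

    The two-sided p sums hypergeometric outcomes no more probable than the
    observed table (probability-mass rule).  A zero cell triggers the Haldane
    0.5 correction for the OR and CI, flagged in the result; the CI is always
    flagged approximate.
    """
    t = np.asarray(table, dtype=float)
    if t.sum() <= 0:
        raise ValidationError("empty table")
    a, b, c, d = t.ravel()
    corrected = (a == 0) or (b == 0) or (c == 0) or (d == 0)
    if corrected:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    or_ = (a2 * d2) / (b2 * c2)
    se = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    ci = (math.exp(math.log(or_) - 1.959963984540054 * se),
          math.exp(math.log(or_) + 1.959963984540054 * se))
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return {"odds_ratio": float(or_), "ci_95": ci, "p_two_sided": float(p),
            "haldane_corrected": corrected, "ci_approximate": True}


def welch_t(g1, g2) -> dict:
    """Welch two-sample t-test: mean difference, Satterthwaite 95% CI, p.

    Two identical constant groups yield p = 1 by convention.
    """
    x = np.asarray(g1, dtype=float)
    y = np.asarray(g2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs >= 2 observations")
    md = float(np.mean(x) - np.mean(y))
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        if md == 0:
            return {"mean_diff": 0.0, "ci_95": (0.0, 0.0), "p": 1.0, "df": float("nan")}
        raise ValidationError("both groups constant with unequal means: df degenerate")
    se2 = vx / x.size + vy / y.size
    df = se2**2 / ((vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1))
    res = stats.ttest_ind(x, y, equal_var=False)
    half = stats.t.ppf(0.975, df) * math.sqrt(se2)
    return {"mean_diff": md, "ci_95": (md - half, md + half),
            "p": float(res.pvalue), "df": float(df)}


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman (mid-rank) correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors, n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("zero-variance input: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(r), float(p)


def metric_report(truth, pred, scores_pos=None, scores_neg=None) -> dict:
    """Full evaluation summary for binary predictions (plus AUC if scores given)."""
    c = ConfusionCounts.from_labels(truth, pred)
    rep = {
        "n": c.total, "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
        "acc": accuracy(c), "se": sensitivity(c), "sp": specificity(c),
        "ppv": ppv(c), "npv": npv(c), "mcc": mcc(c),
    }
    rep.update(cui(c))
    truth_arr = np.asarray(truth, dtype=bool)
    pred_arr = np.asarray(pred, dtype=bool)
    t_pos = np.array([[np.sum(truth_arr & pred_arr), np.sum(truth_arr & ~pred_arr)],
                      [np.sum(~truth_arr & pred_arr), np.sum(~truth_arr & ~pred_arr)]])
    rep["kappa"] = cohens_kappa(t_pos)
    if scores_pos is not None and scores_neg is not None:
        rep["auc"] = roc_auc(scores_pos, scores_neg)
    return rep
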