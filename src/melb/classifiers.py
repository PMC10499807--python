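"""Cohort splitting, ensemble training and the classifier construction loops.

The diagnostic (d-MeLB) and prognostic (p-MeLB) classifiers are built by
repeating the full signature derivation with randomized thresholds and
training a bagged decision-tree ensemble (random forest) per iteration.
Model selection differs by arm: d-MeLB keeps the iteration with the best
ROC AUC on a held-out model-selection serum set (cutoff by Youden's J);
p-MeLB keeps the iteration with the smallest out-of-bag error (cutoff by a
grid search minimizing OOB misclassification).

Validation samples never participate in derivation or selection; the split
bookkeeping lives in the sample sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from . import signatures as sig_mod
from .errors import DegenerateDrawError, MelbError, ValidationError
from .io_core import BetaMatrix, SampleSheet, impute_missing_knn
from .metrics import ConfusionCounts, mcc, roc_auc
from .signatures import SignatureSet

#: p-MeLB cutoff grid searched for minimal OOB misclassification
PMELB_CUTOFF_GRID = np.round(np.arange(0.30, 0.70 + 1e-9, 0.01), 2)


@dataclass
class ClassifierBundle:
    """A trained binary scorer plus its signature, cutoff and provenance."""

    model: object
    signature: SignatureSet
    cutoff: float
    positive_label: str
    training_metrics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.cutoff < 1.0):
            raise ValidationError("cutoff must lie in (0,1)")


@dataclass(frozen=True)
class PredictionResult:
    sample_id: str
    score: float
    label: str  # 'positive' | 'negative'


# ---------------------------------------------------------------------------


def split_cohort(sheet: SampleSheet, fractions: tuple[float, float],
                 strata: str | list[str], seed: int,
                 subset: list[str] | None = None) -> SampleSheet:
    """Fill the split column by stratified random assignment.

    ``fractions = (train, model_select)``; the remainder goes to validation.
    Only rows in ``subset`` (default: all) are assigned; others keep their
    current split value.  Deterministic per seed.
    """
    f_tr, f_ms = fractions
    if f_tr < 0 or f_ms < 0 or f_tr + f_ms > 1 + 1e-12:
        raise ValidationError("fractions must be nonnegative and sum <= 1")
    strata = [strata] if isinstance(strata, str) else list(strata)
    t = sheet.table.copy()
    pool = t if subset is None else t[t.sample_id.isin(subset)]
    rng = np.random.default_rng(seed)
    assignment = {}
    for _, sub in pool.groupby(strata, sort=True, dropna=False):
        ids = sub["sample_id"].tolist()
        if len(ids) < 2:
            raise ValidationError(f"stratum too small: {ids}")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n = len(ids)
        n_tr = int(round(f_tr * n))
        n_ms = int(round(f_ms * n))
        while n_tr + n_ms > n:
            n_ms = max(n_ms - 1, 0) if n_ms > 0 else n_ms
            if n_tr + n_ms > n:
                n_tr -= 1
        for s in ids[:n_tr]:
            assignment[s] = "training"
        for s in ids[n_tr:n_tr + n_ms]:
            assignment[s] = "model_selection"
        for s in ids[n_tr + n_ms:]:
            assignment[s] = "validation"
    t["split"] = [assignment.get(s, sp) for s, sp in zip(t.sample_id, t.split)]
    return SampleSheet(t)


def _feature_frame(m: BetaMatrix, probes: list, samples: list) -> pd.DataFrame:
    """samples x probes feature matrix, KNN-imputing up to 10% absent probes."""
    missing = [p for p in probes if p not in set(m.probe_ids)]
    if missing:
        if len(missing) / len(probes) > 0.10:
            raise ValidationError(
                f"{len(missing)}/{len(probes)} signature probes absent (>10%)")
        pad = pd.DataFrame(np.nan, index=missing, columns=m.values.columns)
        full = BetaMatrix(pd.concat([m.values, pad]))
        full = impute_missing_knn(full, k=5)
        m = full
    return m.values.loc[list(probes), list(samples)].T


def train_ensemble(m: BetaMatrix, sheet: SampleSheet, sig: SignatureSet,
                   labels: pd.Series, positive_label: str,
                   n_trees: int = 1000, cv_folds: int = 10, seed: int = 0,
                   compute_cv: bool = True) -> ClassifierBundle:
    """Random forest of ``n_trees`` with OOB scoring and stratified CV accuracy.

    ``labels`` maps training sample ids to binary class labels.  The score of
    a sample is the fraction of trees voting for the positive class.
    """
    classes = labels.unique()
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 training classes, got {list(classes)}")
    if positive_label not in classes:
        raise ValidationError("positive_label absent from training labels")
    X = _feature_frame(m, sig.probe_ids, list(labels.index)).to_numpy()
    y = (labels == positive_label).astype(int).to_numpy()
    if y.min() == y.max():
        raise ValidationError("single-class training set")
    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                random_state=seed, n_jobs=1,
                                bootstrap=True)
    rf.fit(X, y)
    metrics = {"oob_error": float(1.0 - rf.oob_score_)}
    if compute_cv:
        folds = min(cv_folds, int(np.bincount(y).min()))
        if folds >= 2:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            metrics["cv_accuracy"] = float(np.mean(cross_val_score(
                RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                       n_jobs=1),
                X, y, cv=cv, scoring="accuracy")))
    return ClassifierBundle(model=rf, signature=sig, cutoff=0.5,
                            positive_label=positive_label,
                            training_metrics=metrics,
                            provenance={"seed": seed, "n_trees": n_trees})


def _vote_scores(rf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for class 1."""
    votes = np.zeros(X.shape[0])
    for est in rf.estimators_:
        votes += est.predict(X)
    return votes / len(rf.estimators_)


def score_samples(bundle: ClassifierBundle, m: BetaMatrix,
                  samples: list | None = None) -> pd.Series:
    samples = samples if samples is not None else m.sample_ids
    X = _feature_frame(m, bundle.signature.probe_ids, samples).to_numpy()
    return pd.Series(_vote_scores(bundle.model, X), index=samples, name="score")


def predict(bundle: ClassifierBundle, m: BetaMatrix,
            samples: list | None = None) -> list[PredictionResult]:
    """Score and classify; score >= cutoff is positive (boundary inclusive)."""
    scores = score_samples(bundle, m, samples)
    return [PredictionResult(s, float(v),
                             "positive" if v >= bundle.cutoff else "negative")
            for s, v in scores.items()]


def choose_cutoff_roc(scores_pos, scores_neg) -> float:
    """Cutoff maximizing Youden's J over midpoints of sorted unique scores.

    Boundary guards just below/above the extreme scores are included; ties on
    J resolve to the largest cutoff.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score vectors must be nonempty")
    uniq = np.unique(np.concatenate([pos, neg]))
    cands = [max(uniq[0] - 1e-6, 1e-9)]
    cands += [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])]
    cands += [min(uniq[-1] + 1e-6, 1 - 1e-9)]
    best_j, best_c = -np.inf, cands[0]
    for c in cands:
        se = np.mean(pos >= c)
        sp = np.mean(neg < c)
        j = se + sp - 1.0
        if j > best_j or (j == best_j and c > best_c):
            best_j, best_c = j, c
    return float(min(max(best_c, 1e-9), 1 - 1e-9))


# ---------------------------------------------------------------------------
# construction loops


def _draw_dmelb_params(rng: np.random.Generator, nonmng_groups: list) -> dict:
    lo, hi = sig_mod.P_THRESHOLD_RANGE
    dlo, dhi = sig_mod.SMP_DELTA_RANGE
    n_sub = rng.integers(max(1, len(nonmng_groups) - 1), len(nonmng_groups) + 1)
    subsample = sorted(rng.choice(nonmng_groups, size=n_sub, replace=False).tolist())
    return {
        "p_threshold": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        "smp_delta": float(rng.uniform(dlo, dhi)),
        "nonmng_subsample": subsample,
        "target_size": int(rng.integers(sig_mod.DMELB_SIZE_RANGE[0],
                                        sig_mod.DMELB_SIZE_RANGE[1] + 1)),
    }


def build_dmelb(serum: BetaMatrix, tissue: BetaMatrix, sheet: SampleSheet,
                n_iterations: int = 1000, master_seed: int = 0,
                n_trees: int = 1000, cv_folds: int = 10) -> ClassifierBundle:
    """Construct the diagnostic classifier over randomized iterations.

    Per iteration: draw (significance p, SMP delta, non-MNG subsample,
    signature size); derive tumor-specific DMPs, SMPs and the d-MeLB
    signature from *training* samples; train a forest; score the
    model-selection serum set.  The iteration with the highest
    model-selection AUC wins (ties: higher MCC at the Youden cutoff, then
    lower iteration index); its cutoff comes from the ROC of the
    model-selection scores.
    """
    t = sheet.table
    train_ids = t[(t.split == "training") & t.specimen.isin(["serum", "plasma"])]
    ms_ids = t[(t.split == "model_selection") & t.specimen.isin(["serum", "plasma"])]
    if train_ids.empty or ms_ids.empty:
        raise ValidationError("sheet lacks training/model_selection serum splits")
    nonmng_groups = sorted(set(train_ids.group) - {"MNG"})
    train_sheet = SampleSheet(pd.concat([
        train_ids, t[t.specimen == "tissue"]]).reset_index(drop=True))
    pairs = sig_mod.serum_tissue_pairs(train_sheet)
    serum_train = serum.subset_samples(
        [s for s in train_ids.sample_id if s in set(serum.sample_ids)])

    rng = np.random.default_rng(master_seed)
    best = None
    errors = []
    for it in range(n_iterations):
        it_seed = int(rng.integers(0, 2**31 - 1))
        it_rng = np.random.default_rng(it_seed)
        params = _draw_dmelb_params(it_rng, nonmng_groups)
        try:
            ts = sig_mod.select_tumor_specific_dmps(tissue, train_sheet,
                                                    params["p_threshold"])
            smps = sig_mod.select_smps(ts, serum_train, tissue, pairs,
                                       params["smp_delta"])
            eligible_groups = set(params["nonmng_subsample"]) | {"MNG"}
            sub_sheet = SampleSheet(
                train_ids[train_ids.group.isin(eligible_groups)]
                .reset_index(drop=True))
            d_sig = sig_mod.derive_dmelb_signature(
                smps, serum_train, sub_sheet, params["target_size"])
            sig_mod.check_nesting(d_sig, smps, ts)
            labels = train_ids.set_index("sample_id")["group"].eq("MNG") \
                .map({True: "MNG", False: "non-MNG"})
            labels = labels[labels.index.isin(set(serum_train.sample_ids))]
            bundle = train_ensemble(serum_train, train_sheet, d_sig, labels,
                                    positive_label="MNG", n_trees=n_trees,
                                    cv_folds=cv_folds, seed=it_seed,
                                    compute_cv=False)
        except (DegenerateDrawError, ValidationError) as exc:
            errors.append((it, str(exc)))
            continue
        ms_scores = score_samples(bundle, serum, ms_ids.sample_id.tolist())
        is_mng = ms_ids.set_index("sample_id")["group"].eq("MNG")
        pos = ms_scores[is_mng.reindex(ms_scores.index).fillna(False)]
        neg = ms_scores[~is_mng.reindex(ms_scores.index).fillna(True)]
        if pos.empty or neg.empty:
            errors.append((it, "model-selection set lacks a class"))
            continue
        auc = roc_auc(pos.to_numpy(), neg.to_numpy())
        cutoff = choose_cutoff_roc(pos.to_numpy(), neg.to_numpy())
        pred = ms_scores >= cutoff
        m = mcc(ConfusionCounts.from_labels(
            is_mng.reindex(ms_scores.index).to_numpy(),
            pred.to_numpy()))
        key = (auc, m, -it)
        if best is None or key > best[0]:
            bundle.cutoff = cutoff
            bundle.provenance.update(iteration=it, iteration_seed=it_seed,
                                     params=params, model_selection_auc=auc,
                                     model_selection_mcc=m)
            best = (key, bundle)
    if best is None:
        raise MelbError(f"no successful d-MeLB iteration; first errors: {errors[:3]}")
    bundle = best[1]
    # CV accuracy of the winning configuration, for the record
    labels = train_ids.set_index("sample_id")["group"].eq("MNG") \
        .map({True: "MNG", False: "non-MNG"})
    labels = labels[labels.index.isin(set(serum_train.sample_ids))]
    final = train_ensemble(serum_train, train_sheet, bundle.signature, labels,
                           positive_label="MNG", n_trees=n_trees,
                           cv_folds=cv_folds,
                           seed=bundle.provenance["iteration_seed"],
                           compute_cv=True)
    bundle.training_metrics = final.training_metrics
    return bundle


def _draw_pmelb_params(rng: np.random.Generator) -> dict:
    return {
        "p_max_tissue": float(np.exp(rng.uniform(np.log(1e-3), np.log(0.05)))),
        "diff_min_tissue": float(rng.uniform(0.10, 0.20)),
        "p_max_serum": float(np.exp(rng.uniform(np.log(1e-3), np.log(0.05)))),
        "diff_min_serum": float(rng.uniform(0.05, 0.15)),
    }


def build_pmelb(tissue: BetaMatrix, serum: BetaMatrix, sheet: SampleSheet,
                clusters: pd.Series, n_iterations: int = 1000,
                master_seed: int = 0, n_trees: int = 1000,
                cv_folds: int = 10) -> ClassifierBundle:
    """Construct the prognostic classifier over randomized iterations.

    Per iteration: draw thresholds, derive the p-MeLB signature (tissue
    CR/CNR x serum cluster intersection on training samples) and train a
    forest on CR/CNR tissue training labels.  The iteration with the
    smallest OOB error wins; the cutoff minimizes OOB misclassification over
    a 0.30-0.70 grid (ties resolve toward 0.50).
    """
    t = sheet.table
    train = t[(t.split == "training") & (t.specimen == "tissue")
              & t.outcome.isin(["CR", "CNR"])]
    if train.empty:
        raise ValidationError("no CR/CNR tissue training samples")
    train_sheet = SampleSheet(train.reset_index(drop=True))
    tissue_train = tissue.subset_samples(
        [s for s in train.sample_id if s in set(tissue.sample_ids)])
    labels = train.set_index("sample_id")["outcome"]
    labels = labels[labels.index.isin(set(tissue_train.sample_ids))]

    rng = np.random.default_rng(master_seed)
    best = None
    n_degenerate = 0
    for it in range(n_iterations):
        it_seed = int(rng.integers(0, 2**31 - 1))
        it_rng = np.random.default_rng(it_seed)
        params = _draw_pmelb_params(it_rng)
        try:
            # tissue restriction to training samples happens via tissue_train;
            # the full sheet supplies serum outcomes for cluster enrichment
            p_sig = sig_mod.derive_pmelb_signature(tissue_train, serum,
                                                   sheet, clusters, params)
            bundle = train_ensemble(tissue_train, train_sheet, p_sig, labels,
                                    positive_label="CR", n_trees=n_trees,
                                    cv_folds=cv_folds, seed=it_seed,
                                    compute_cv=False)
        except (DegenerateDrawError, ValidationError):
            n_degenerate += 1
            continue
        oob = bundle.training_metrics["oob_error"]
        key = (oob, it)
        if best is None or key < best[0]:
            bundle.provenance.update(iteration=it, iteration_seed=it_seed,
                                     params=params)
            best = (key, bundle)
    if best is None:
        raise MelbError(f"all {n_iterations} p-MeLB iterations degenerate")
    bundle = best[1]
    bundle.cutoff = _pmelb_cutoff(bundle, labels)
    bundle.provenance["n_degenerate"] = n_degenerate
    return bundle


def _pmelb_cutoff(bundle: ClassifierBundle, labels: pd.Series) -> float:
    """Grid-search cutoff minimizing OOB misclassification, ties -> near 0.50."""
    rf = bundle.model
    oob = rf.oob_decision_function_  # rows follow training order
    pos_col = list(rf.classes_).index(1)
    scores = oob[:, pos_col]
    y = (labels == bundle.positive_label).astype(int).to_numpy()
    best = None
    for c in PMELB_CUTOFF_GRID:
        err = float(np.mean((scores >= c).astype(int) != y))
        key = (err, abs(c - 0.50))
        if best is None or key < best[0]:
            best = (key, float(c))
    return best[1]


# ---------------------------------------------------------------------------
# tissue linear discriminant


def train_lda_tissue(tissue: BetaMatrix, sheet: SampleSheet,
                     sig: SignatureSet, labels: pd.Series,
                     positive_label: str, ridge: float = 1e-3) -> ClassifierBundle:
    """Binary linear discriminant on signature probes.

    Pooled within-class covariance with ridge regularization
    lambda = ridge * trace / p; score is the posterior probability of the
    positive class under equal-covariance Gaussians.
    """
    classes = list(pd.unique(labels))
    if len(classes) != 2:
        raise ValidationError("LDA requires exactly 2 classes")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValidationError("each class needs >= 2 samples")
    X = _feature_frame(tissue, sig.probe_ids, list(labels.index)).to_numpy()
    y = (labels == positive_label).astype(int).to_numpy()
    p = X.shape[1]
    means = {k: X[y == k].mean(axis=0) for k in (0, 1)}
    S = np.zeros((p, p))
    for k in (0, 1):
        d = X[y == k] - means[k]
        S += d.T @ d
    S /= (len(y) - 2)
    lam = ridge * np.trace(S) / p
    S_reg = S + lam * np.eye(p)
    w = np.linalg.solve(S_reg, means[1] - means[0])
    priors = {k: np.mean(y == k) for k in (0, 1)}
    b = -0.5 * (means[1] + means[0]) @ w + np.log(priors[1] / priors[0])
    model = {"w": w, "b": b, "kind": "lda"}

    class _LDA:
        def __init__(self, w, b):
            self.w, self.b = w, b

        def decision(self, X):
            return X @ self.w + self.b

        def posterior(self, X):
            from scipy.special import expit
            return expit(self.decision(X))

    return ClassifierBundle(model=_LDA(w, b), signature=sig, cutoff=0.5,
                            positive_label=positive_label,
                            training_metrics={},
                            provenance={"ridge": ridge, "kind": "lda"})


def predict_lda(bundle: ClassifierBundle, tissue: BetaMatrix,
                samples: list | None = None) -> list[PredictionResult]:
    samples = samples if samples is not None else tissue.sample_ids
    X = _feature_frame(tissue, bundle.signature.probe_ids, samples).to_numpy()
    post = bundle.model.posterior(X)
    return [PredictionResult(s, float(v),
                             "positive" if v >= bundle.cutoff else "negative")
            for s, v in zip(samples, post)]
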