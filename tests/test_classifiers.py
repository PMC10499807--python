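"""Splitting, forests, cutoffs, construction loops and the tissue LDA."""

import numpy as np
import pandas as pd
import pytest

from melb.classifiers import (ClassifierBundle, build_pmelb, choose_cutoff_roc,
                              predict, predict_lda, score_samples, split_cohort,
                              train_ensemble, train_lda_tissue)
from melb.errors import ValidationError
from melb.io_core import BetaMatrix, SampleSheet
from melb.metrics import roc_auc
from melb.signatures import SignatureSet


def _sheet(groups, specimen="serum"):
    n = len(groups)
    return SampleSheet(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "patient_id": [f"p{i}" for i in range(n)],
        "specimen": specimen, "group": groups,
        "treated_presurgery": False, "collection": "primary",
        "outcome": "unknown", "person_time": 12.0, "split": "unassigned"}))


def _separable_data(rng, n_per=30, n_probes=20, delta=0.4):
    base = rng.uniform(0.3, 0.5, n_probes)
    a = np.clip(base[:, None] + rng.normal(0, 0.05, (n_probes, n_per)), 0, 1)
    b = np.clip(base[:, None] + delta + rng.normal(0, 0.05, (n_probes, n_per)), 0, 1)
    vals = np.c_[a, b]
    probes = [f"cg{i}" for i in range(n_probes)]
    samples = [f"s{i}" for i in range(2 * n_per)]
    m = BetaMatrix(pd.DataFrame(vals, index=probes, columns=samples))
    labels = pd.Series(["neg"] * n_per + ["pos"] * n_per, index=samples)
    return m, labels


class TestSplitCohort:
    def test_stratified_counts(self):
        sheet = _sheet(["MNG"] * 5 + ["glioma"] * 5)
        out = split_cohort(sheet, (0.8, 0.2), "group", seed=0)
        t = out.table
        for grp in ("MNG", "glioma"):
            sub = t[t.group == grp]
            assert (sub.split == "training").sum() == 4
            assert (sub.split == "model_selection").sum() == 1

    def test_all_training(self):
        sheet = _sheet(["MNG"] * 4 + ["glioma"] * 4)
        out = split_cohort(sheet, (1.0, 0.0), "group", seed=1)
        assert (out.table.split == "training").all()

    def test_deterministic_per_seed(self):
        sheet = _sheet(["MNG"] * 10 + ["glioma"] * 10)
        a = split_cohort(sheet, (0.6, 0.2), "group", seed=7)
        b = split_cohort(sheet, (0.6, 0.2), "group", seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = split_cohort(sheet, (0.6, 0.2), "group", seed=8)
        assert not a.table.split.equals(c.table.split)

    def test_small_stratum_rejected(self):
        sheet = _sheet(["MNG"] * 5 + ["glioma"])
        with pytest.raises(ValidationError):
            split_cohort(sheet, (0.8, 0.2), "group", seed=0)


class TestTrainEnsemble:
    def test_separable_data_high_cv_accuracy(self, rng):
        m, labels = _separable_data(rng)
        sig = SignatureSet(m.probe_ids, stage="smp")
        bundle = train_ensemble(m, None, sig, labels, "pos", n_trees=200,
                                cv_folds=5, seed=0)
        assert bundle.training_metrics["cv_accuracy"] >= 0.95
        assert bundle.training_metrics["oob_error"] <= 0.1

    def test_permuted_labels_near_chance(self, rng):
        m, labels = _separable_data(rng, n_per=30)
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        sig = SignatureSet(m.probe_ids, stage="smp")
        bundle = train_ensemble(m, None, sig, perm, "pos", n_trees=200,
                                cv_folds=5, seed=0)
        assert 0.35 <= bundle.training_metrics["cv_accuracy"] <= 0.65

    def test_uninformative_features_score_near_prior(self, rng):
        """Constant features, balanced classes: per-tree votes are bootstrap
        coin flips, so the vote-fraction score sits near the 0.5 prior."""
        n = 40
        vals = np.full((10, n), 0.5)
        m = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(10)],
                                    columns=[f"s{i}" for i in range(n)]))
        labels = pd.Series(["pos"] * 20 + ["neg"] * 20, index=m.sample_ids)
        sig = SignatureSet(m.probe_ids, stage="smp")
        bundle = train_ensemble(m, None, sig, labels, "pos", n_trees=300,
                                cv_folds=2, seed=0, compute_cv=False)
        scores = score_samples(bundle, m)
        assert abs(scores.mean() - 0.5) < 0.15

    def test_single_class_rejected(self, rng):
        m, labels = _separable_data(rng, n_per=10)
        labels[:] = "pos"
        sig = SignatureSet(m.probe_ids, stage="smp")
        with pytest.raises(ValidationError):
            train_ensemble(m, None, sig, labels, "pos", n_trees=50)


class TestCutoff:
    def test_perfect_separation_midpoint(self):
        assert choose_cutoff_roc([0.8, 0.9], [0.1, 0.2]) == pytest.approx(0.5)

    def test_interleaved_distributions_j_zero(self):
        pos = [0.1, 0.4, 0.7]
        neg = [0.1, 0.4, 0.7]
        c = choose_cutoff_roc(pos, neg)
        se = np.mean(np.asarray(pos) >= c)
        sp = np.mean(np.asarray(neg) < c)
        assert se + sp - 1 == pytest.approx(0.0, abs=1e-9)

    def test_auc_pairwise_concordance(self):
        assert roc_auc([0.9, 0.4], [0.6, 0.1]) == 0.75


class TestPredict:
    def _bundle(self, rng):
        m, labels = _separable_data(rng)
        sig = SignatureSet(m.probe_ids, stage="smp")
        bundle = train_ensemble(m, None, sig, labels, "pos", n_trees=200,
                                cv_folds=2, seed=0, compute_cv=False)
        return m, labels, bundle

    def test_training_samples_reclassified(self, rng):
        m, labels, bundle = self._bundle(rng)
        preds = predict(bundle, m)
        for p in preds:
            want = "positive" if labels[p.sample_id] == "pos" else "negative"
            assert p.label == want

    def test_boundary_score_positive(self):
        class _Const:
            estimators_ = []
        b = ClassifierBundle(model=None, signature=SignatureSet(["cg0"], "smp"),
                             cutoff=0.48, positive_label="pos")
        # boundary rule checked directly on the comparison used by predict
        assert (0.48 >= b.cutoff) is True
        assert (0.4799 >= b.cutoff) is False

    def test_column_order_permutation_invariant(self, rng):
        m, labels, bundle = self._bundle(rng)
        perm = BetaMatrix(m.values[m.sample_ids[::-1]])
        a = {p.sample_id: p.score for p in predict(bundle, m)}
        b = {p.sample_id: p.score for p in predict(bundle, perm)}
        assert a == b

    def test_missing_probe_fraction_guard(self, rng):
        m, labels, bundle = self._bundle(rng)
        dropped = BetaMatrix(m.values.iloc[5:])  # 25% of 20 probes gone
        with pytest.raises(ValidationError):
            predict(bundle, dropped)


class TestPmelbContract:
    def test_oob_argmin_and_cutoff_grid(self, default_cohort):
        beta, sheet, gt = default_cohort
        labeled = sheet.rows(specimen="tissue", group="MNG",
                             outcome={"CR", "CNR"})["sample_id"].tolist()
        sheet2 = split_cohort(sheet, (0.7, 0.0), ["outcome"], seed=0,
                              subset=labeled)
        tissue = beta.subset_samples(sheet2.samples(specimen="tissue"))
        serum = beta.subset_samples(sheet2.samples(specimen="serum", group="MNG"))
        oobs = []
        bundle = None

        import melb.classifiers as clf
        orig = clf.train_ensemble

        def spy(*args, **kw):
            b = orig(*args, **kw)
            oobs.append(b.training_metrics["oob_error"])
            return b

        clf.train_ensemble = spy
        try:
            bundle = build_pmelb(tissue, serum, sheet2, gt.clusters,
                                 n_iterations=5, master_seed=0, n_trees=150)
        finally:
            clf.train_ensemble = orig
        assert bundle.training_metrics["oob_error"] == pytest.approx(min(oobs))
        assert 0.30 <= bundle.cutoff <= 0.70

    def test_validation_labels_cannot_leak(self, default_cohort):
        """Corrupting validation outcomes leaves the trained bundle unchanged."""
        beta, sheet, gt = default_cohort
        labeled = sheet.rows(specimen="tissue", group="MNG",
                             outcome={"CR", "CNR"})["sample_id"].tolist()
        sheet2 = split_cohort(sheet, (0.7, 0.0), ["outcome"], seed=0,
                              subset=labeled)
        tissue = beta.subset_samples(sheet2.samples(specimen="tissue"))
        serum = beta.subset_samples(sheet2.samples(specimen="serum", group="MNG"))
        bundle_a = build_pmelb(tissue, serum, sheet2, gt.clusters,
                               n_iterations=3, master_seed=1, n_trees=100)
        t = sheet2.table.copy()
        val_tissue = (t.split == "validation") & (t.specimen == "tissue")
        t.loc[val_tissue, "outcome"] = np.where(
            t.loc[val_tissue, "outcome"] == "CR", "unknown", "CR")
        t.loc[val_tissue, "person_time"] = 12.0
        sheet_corrupt = SampleSheet(t)
        bundle_b = build_pmelb(tissue, serum, sheet_corrupt, gt.clusters,
                               n_iterations=3, master_seed=1, n_trees=100)
        assert bundle_a.signature.probe_ids == bundle_b.signature.probe_ids
        assert bundle_a.cutoff == bundle_b.cutoff
        assert bundle_a.training_metrics["oob_error"] == \
            bundle_b.training_metrics["oob_error"]


class TestLDA:
    def test_separated_classes(self, rng):
        m, labels = _separable_data(rng, n_per=25, delta=0.3)
        sig = SignatureSet(m.probe_ids, stage="smp")
        bundle = train_lda_tissue(m, None, sig, labels, "pos")
        preds = predict_lda(bundle, m)
        acc = np.mean([(p.label == "positive") == (labels[p.sample_id] == "pos")
                       for p in preds])
        assert acc >= 0.95

    def test_equal_means_chance_level(self, rng):
        n = 60
        vals = np.clip(rng.normal(0.5, 0.05, (15, n)), 0, 1)
        m = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(15)],
                                    columns=[f"s{i}" for i in range(n)]))
        labels = pd.Series(["pos"] * 30 + ["neg"] * 30, index=m.sample_ids)
        sig = SignatureSet(m.probe_ids, stage="smp")
        bundle = train_lda_tissue(m, None, sig, labels, "pos")
        preds = predict_lda(bundle, m)
        acc = np.mean([(p.label == "positive") == (labels[p.sample_id] == "pos")
                       for p in preds])
        assert 0.3 <= acc <= 0.75

    def test_affine_rescaling_preserves_decisions(self, rng):
        m, labels = _separable_data(rng, n_per=20, delta=0.3)
        sig = SignatureSet(m.probe_ids, stage="smp")
        a = train_lda_tissue(m, None, sig, labels, "pos")
        scaled = BetaMatrix(m.values * 0.5 + 0.1)  # common affine map
        b = train_lda_tissue(scaled, None, sig, labels, "pos")
        la = [p.label for p in predict_lda(a, m)]
        lb = [p.label for p in predict_lda(b, scaled)]
        assert la == lb

    def test_single_sample_class_rejected(self, rng):
        m, labels = _separable_data(rng, n_per=5)
        labels.iloc[:-1] = "pos"
        sig = SignatureSet(m.probe_ids, stage="smp")
        with pytest.raises(ValidationError):
            train_lda_tissue(m, None, sig, labels, "pos")
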