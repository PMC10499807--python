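"""Signature derivation: tumor-specific DMPs, SMPs, d-MeLB, p-MeLB."""

import numpy as np
import pandas as pd
import pytest

from melb.errors import DegenerateDrawError, ValidationError
from melb.io_core import BetaMatrix, SampleSheet
from melb.signatures import (SignatureSet, adverse_clusters, check_nesting,
                             derive_dmelb_signature, derive_pmelb_signature,
                             select_smps, select_tumor_specific_dmps,
                             serum_tissue_pairs)
from melb.synthetic_data import SimulationConfig, simulate_cohort


def _tissue_sheet(cohort):
    return cohort[1]


class TestTumorSpecific:
    def test_planted_recovery(self, small_cohort):
        beta, sheet, gt = small_cohort
        tissue = beta.subset_samples(sheet.samples(specimen="tissue"))
        sig = select_tumor_specific_dmps(tissue, sheet, p_threshold=0.01)
        recovered = len(set(sig.probe_ids) & set(gt.diagnostic_probes))
        assert recovered / len(gt.diagnostic_probes) >= 0.95

    def test_zero_threshold_empty(self, small_cohort):
        beta, sheet, gt = small_cohort
        tissue = beta.subset_samples(sheet.samples(specimen="tissue"))
        sig = select_tumor_specific_dmps(tissue, sheet, p_threshold=0.0)
        assert len(sig) == 0

    def test_null_selection_rate_matches_threshold(self, rng):
        """Identical groups: selected fraction ~ p_threshold."""
        n_probes = 2000
        vals = rng.beta(2, 2, size=(n_probes, 30))
        probes = [f"cg{i}" for i in range(n_probes)]
        samples = [f"t{i}" for i in range(30)]
        m = BetaMatrix(pd.DataFrame(vals, index=probes, columns=samples))
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": samples, "patient_id": samples,
            "specimen": "tissue",
            "group": ["MNG"] * 15 + ["control"] * 15,
            "treated_presurgery": False, "collection": "primary",
            "outcome": "unknown", "person_time": 12.0, "split": "unassigned"}))
        sig = select_tumor_specific_dmps(m, sheet, p_threshold=0.05)
        frac = len(sig) / n_probes
        assert abs(frac - 0.05) < 0.025


class TestSMPs:
    def _paired(self, serum_vals, tissue_vals):
        probes = [f"cg{i}" for i in range(len(serum_vals))]
        serum = BetaMatrix(pd.DataFrame(np.asarray(serum_vals, float),
                                        index=probes,
                                        columns=["s0", "s1"]))
        tissue = BetaMatrix(pd.DataFrame(np.asarray(tissue_vals, float),
                                         index=probes,
                                         columns=["t0", "t1"]))
        cands = SignatureSet(probes, stage="tumor_specific")
        pairs = [("s0", "t0"), ("s1", "t1")]
        return cands, serum, tissue, pairs

    def test_identical_matrices_all_retained(self, rng):
        v = rng.random((5, 2))
        cands, serum, tissue, pairs = self._paired(v, v)
        out = select_smps(cands, serum, tissue, pairs, delta=0.01)
        assert out.probe_ids == cands.probe_ids

    def test_mean_absolute_difference_boundary(self):
        # per-pair |diffs| (0.05, 0.25) -> mean 0.15
        cands, serum, tissue, pairs = self._paired([[0.40, 0.60]],
                                                   [[0.45, 0.35]])
        assert len(select_smps(cands, serum, tissue, pairs, 0.15)) == 1
        assert len(select_smps(cands, serum, tissue, pairs, 0.10)) == 0

    def test_monotone_in_delta_and_subset(self, rng):
        v1 = rng.random((20, 2))
        v2 = np.clip(v1 + rng.normal(0, 0.1, v1.shape), 0, 1)
        cands, serum, tissue, pairs = self._paired(v1, v2)
        sizes = [len(select_smps(cands, serum, tissue, pairs, d))
                 for d in (0.05, 0.1, 0.2)]
        assert sizes == sorted(sizes)
        out = select_smps(cands, serum, tissue, pairs, 0.1)
        assert set(out.probe_ids) <= set(cands.probe_ids)

    def test_no_pairs_rejected(self, rng):
        cands, serum, tissue, _ = self._paired(rng.random((3, 2)),
                                               rng.random((3, 2)))
        with pytest.raises(ValidationError):
            select_smps(cands, serum, tissue, [], 0.1)


class TestDmelbSignature:
    def test_signature_is_planted(self, default_cohort):
        beta, sheet, gt = default_cohort
        serum = beta.subset_samples(sheet.samples(specimen="serum"))
        tissue = beta.subset_samples(sheet.samples(specimen="tissue"))
        ts = select_tumor_specific_dmps(tissue, sheet, 0.01)
        smps = select_smps(ts, serum, tissue, serum_tissue_pairs(sheet), 0.15)
        sig = derive_dmelb_signature(smps, serum, sheet, target_size=25)
        check_nesting(sig, smps, ts)
        planted = len(set(sig.probe_ids) & set(gt.diagnostic_probes))
        assert planted / len(sig) >= 0.9

    def test_target_size_exceeding_smps_rejected(self, rng):
        smps = SignatureSet([f"cg{i}" for i in range(10)], stage="smp")
        with pytest.raises(ValidationError):
            derive_dmelb_signature(smps, None, None, target_size=25)

    def test_sample_order_invariance(self, small_cohort):
        beta, sheet, gt = small_cohort
        serum_ids = sheet.samples(specimen="serum")
        tissue = beta.subset_samples(sheet.samples(specimen="tissue"))
        ts = select_tumor_specific_dmps(tissue, sheet, 0.01)
        serum = beta.subset_samples(serum_ids)
        smps = select_smps(ts, serum, tissue, serum_tissue_pairs(sheet), 0.15)
        a = derive_dmelb_signature(smps, serum, sheet, 20)
        serum_perm = beta.subset_samples(serum_ids[::-1])
        b = derive_dmelb_signature(smps, serum_perm, sheet, 20)
        assert a.probe_ids == b.probe_ids


class TestPmelbSignature:
    PARAMS = dict(p_max_tissue=0.05, diff_min_tissue=0.1,
                  p_max_serum=0.05, diff_min_serum=0.05)

    def test_recovery_from_planted(self, default_cohort):
        beta, sheet, gt = default_cohort
        tissue = beta.subset_samples(sheet.samples(specimen="tissue"))
        serum = beta.subset_samples(sheet.samples(specimen="serum", group="MNG"))
        sig = derive_pmelb_signature(tissue, serum, sheet, gt.clusters,
                                     dict(self.PARAMS))
        planted = set(gt.prognostic_probes)
        assert set(sig.probe_ids) <= planted
        assert len(set(sig.probe_ids)) / len(planted) >= 0.8

    def test_adverse_clusters_enriched_for_recurrence(self, default_cohort):
        beta, sheet, gt = default_cohort
        adv = adverse_clusters(gt.clusters, sheet)
        t = sheet.table.set_index("sample_id")
        cr = t.loc[gt.clusters.index, "outcome"].eq("CR")
        in_adv = gt.clusters.isin(adv)
        assert cr[in_adv].mean() > cr[~in_adv].mean()

    def test_disjoint_signals_degenerate_draw(self, default_cohort):
        beta, sheet, gt = default_cohort
        tissue = beta.subset_samples(sheet.samples(specimen="tissue"))
        serum = beta.subset_samples(sheet.samples(specimen="serum", group="MNG"))
        params = dict(self.PARAMS, diff_min_tissue=0.9, diff_min_serum=0.9)
        with pytest.raises(DegenerateDrawError):
            derive_pmelb_signature(tissue, serum, sheet, gt.clusters, params)

    def test_deterministic_under_fixed_params(self, default_cohort):
        beta, sheet, gt = default_cohort
        tissue = beta.subset_samples(sheet.samples(specimen="tissue"))
        serum = beta.subset_samples(sheet.samples(specimen="serum", group="MNG"))
        a = derive_pmelb_signature(tissue, serum, sheet, gt.clusters,
                                   dict(self.PARAMS))
        b = derive_pmelb_signature(tissue, serum, sheet, gt.clusters,
                                   dict(self.PARAMS))
        assert a.probe_ids == b.probe_ids


class TestSignatureSet:
    def test_dmelb_size_bounds_enforced(self):
        with pytest.raises(ValidationError):
            SignatureSet([f"cg{i}" for i in range(10)], stage="d_melb")

    def test_duplicates_rejected(self):
        with pytest.raises(ValidationError):
            SignatureSet(["cgA", "cgA"], stage="smp")
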