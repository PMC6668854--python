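"""QC filter cascade, HWE testing and batch merging."""

import numpy as np
import pandas as pd
import pytest

from hipgwas.io_formats import MISSING, GenotypeMatrix
from hipgwas.qc import QcThresholds, apply_qc, hwe_test, merge_batches
from hipgwas.simulate import SimConfig, simulate_cohort


def _cohort_for(gm, controls=None):
    controls = set(controls if controls is not None else gm.samples[: len(gm.samples) // 2])
    return pd.DataFrame(
        {
            "dog_id": gm.samples,
            "sex": "1",
            "batch": "1",
            "hip_left": ["A" if s in controls else "D" for s in gm.samples],
            "hip_right": ["A" if s in controls else "D" for s in gm.samples],
        }
    )


def _matrix(calls, chroms=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "allele_a": ["A"] * m,
            "allele_b": ["G"] * m,
        }
    )
    return GenotypeMatrix([f"d{i}" for i in range(n)], snps, calls)


class TestHwe:
    def test_exact_equilibrium_counts(self):
        stat, p, mono = hwe_test(25, 50, 25)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert not mono

    def test_hand_computed_statistic(self):
        # expected (25, 50, 25); (5^2/25) + (10^2/50) + (5^2/25) = 4
        stat, _p, _mono = hwe_test(30, 40, 30)
        assert stat == pytest.approx(4.0)

    def test_monomorphic_flagged(self):
        stat, p, mono = hwe_test(0, 0, 100)
        assert mono and p == 1.0

    def test_empty_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestApplyQc:
    def test_low_maf_snp_removed(self):
        rng = np.random.default_rng(0)
        n = 200
        common = rng.binomial(2, 0.3, size=(n, 3))
        rare = rng.binomial(2, 0.04, size=(n, 1))
        gm = _matrix(np.hstack([common, rare]))
        out, report = apply_qc(gm, _cohort_for(gm))
        assert "s3" in report.snps_removed_by_rule["maf"]
        assert out.n_snps == 3

    def test_low_call_rate_sample_removed(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.4, size=(50, 100)).astype(np.int8)
        calls[0, : int(100 * 0.11)] = MISSING  # call rate 0.89
        gm = _matrix(calls)
        _out, report = apply_qc(gm, _cohort_for(gm))
        assert report.samples_removed == ["d0"]

    def test_hwe_violation_in_controls_removed_cases_ignored(self):
        rng = np.random.default_rng(2)
        n = 300
        calls = rng.binomial(2, 0.4, size=(n, 4)).astype(np.int8)
        controls = [f"d{i}" for i in range(150)]
        # SNP 0: every control heterozygous (gross HWE violation in controls)
        calls[:150, 0] = 1
        # SNP 1: every case heterozygous (violation only in cases -> kept)
        calls[150:, 1] = 1
        gm = _matrix(calls)
        out, report = apply_qc(gm, _cohort_for(gm, controls=controls))
        assert "s0" in report.snps_removed_by_rule["hwe_controls"]
        assert "s1" not in report.snps_removed_by_rule["hwe_controls"]
        assert "s1" in list(out.snps["snp_id"])

    def test_non_autosomal_snps_dropped(self):
        rng = np.random.default_rng(3)
        calls = rng.binomial(2, 0.4, size=(100, 3)).astype(np.int8)
        gm = _matrix(calls, chroms=["1", "39", "5"])  # 39 = X in the dog map
        out, report = apply_qc(gm, _cohort_for(gm))
        assert report.snps_removed_by_rule["non_autosomal"] == ["s1"]
        assert out.n_snps == 2

    def test_idempotent(self, small_cohort):
        _cfg, gm, cohort, _t = small_cohort
        out1, _ = apply_qc(gm, cohort)
        out2, report2 = apply_qc(out1, cohort)
        assert out2.n_snps == out1.n_snps
        assert out2.n_samples == out1.n_samples
        assert not report2.samples_removed

    def test_tightening_maf_threshold_is_monotone(self, small_cohort):
        _cfg, gm, cohort, _t = small_cohort
        kept = [
            apply_qc(gm, cohort, QcThresholds(maf_min=m))[0].n_snps
            for m in (0.01, 0.05, 0.10, 0.20)
        ]
        assert kept == sorted(kept, reverse=True)

    def test_hwe_removal_rate_matches_relaxed_threshold(self):
        """On HWE-conformant genotypes the removal fraction tracks the p cut-off."""
        rng = np.random.default_rng(4)
        m = 4000
        p = rng.uniform(0.2, 0.8, size=m)
        calls = rng.binomial(1, p, size=(400, m)) + rng.binomial(1, p, size=(400, m))
        gm = _matrix(calls.astype(np.int8))
        cohort = _cohort_for(gm, controls=gm.samples)  # all controls
        _out, report = apply_qc(
            gm, cohort, QcThresholds(hwe_p_min=0.01, maf_min=0.05)
        )
        frac = len(report.snps_removed_by_rule["hwe_controls"]) / m
        assert frac == pytest.approx(0.01, abs=0.006)


class TestMergeBatches:
    def _single_snp_batch(self, ids, a, b, calls):
        snps = pd.DataFrame(
            {"snp_id": ["s0"], "chrom": ["1"], "pos": [100], "allele_a": [a], "allele_b": [b]}
        )
        return GenotypeMatrix(ids, snps, np.array(calls, dtype=np.int8).reshape(-1, 1))

    def test_reverse_complement_batch_merged(self):
        b1 = self._single_snp_batch(["a1", "a2"], "A", "G", [0, 2])
        b2 = self._single_snp_batch(["b1", "b2"], "T", "C", [1, 2])
        merged, log_df = merge_batches([b1, b2])
        assert merged.n_samples == 4 and merged.n_snps == 1
        assert np.array_equal(merged.calls[:, 0], [0, 2, 1, 2])
        assert log_df.loc[0, "action"] == "flipped"

    def test_swapped_allele_labels_recoded(self):
        b1 = self._single_snp_batch(["a1"], "A", "G", [2])
        b2 = self._single_snp_batch(["b1"], "G", "A", [2])
        merged, _log = merge_batches([b1, b2])
        assert np.array_equal(merged.calls[:, 0], [2, 0])

    def test_ambiguous_at_snp_with_discordant_labels_dropped(self):
        b1 = self._single_snp_batch(["a1"], "A", "T", [1])
        b2 = self._single_snp_batch(["b1"], "T", "A", [1])
        merged, log_df = merge_batches([b1, b2])
        assert merged.n_snps == 0
        assert log_df.loc[0, "action"] == "ambiguous_dropped"

    def test_disjoint_batches_preserve_genotypes(self):
        rng = np.random.default_rng(5)
        calls = rng.binomial(2, 0.4, size=(20, 6)).astype(np.int8)
        snps = pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(6)],
                "chrom": ["1"] * 6,
                "pos": np.arange(6) * 100 + 1,
                "allele_a": ["A"] * 6,
                "allele_b": ["G"] * 6,
            }
        )
        b1 = GenotypeMatrix([f"x{i}" for i in range(10)], snps, calls[:10])
        b2 = GenotypeMatrix([f"y{i}" for i in range(10)], snps.copy(), calls[10:])
        merged, _log = merge_batches([b1, b2])
        assert merged.n_samples == 20
        assert np.array_equal(merged.calls, calls)

    def test_overlapping_sample_ids_rejected(self):
        b1 = self._single_snp_batch(["a1"], "A", "G", [0])
        b2 = self._single_snp_batch(["a1"], "A", "G", [1])
        with pytest.raises(ValueError):
            merge_batches([b1, b2])
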