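"""Genotype I/O, per-SNP statistics and quality control."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from regionscan.genotype_io import (
    EmptyAfterQCError,
    GenotypeMatrix,
    PlinkFormatError,
    QCThresholds,
    allele_frequency,
    apply_qc,
    hwe_exact_test,
    read_dosage_tsv,
    read_plink,
    write_dosage_tsv,
    write_plink,
)


def _matrix(values, chrom=None):
    values = np.asarray(values, float)
    m = values.shape[1]
    variants = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chromosome": chrom if chrom is not None else [1] * m,
            "position": np.arange(1, m + 1) * 100,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    return GenotypeMatrix(values=values, variants=variants,
                          samples=[f"i{i}" for i in range(values.shape[0])])


class TestPlinkRoundTrip:
    def test_round_trip_identity(self, tmp_path, small_cohort):
        gm = small_cohort.genotypes
        write_plink(gm, tmp_path / "c")
        back = read_plink(tmp_path / "c")
        np.testing.assert_array_equal(
            np.nan_to_num(back.values, nan=-1), np.nan_to_num(gm.values, nan=-1)
        )
        assert back.samples == gm.samples
        pd.testing.assert_frame_equal(
            back.variants, gm.variants[back.variants.columns], check_dtype=False
        )

    def test_homozygote_coding(self, tmp_path):
        # AA -> 0, BB -> 1 (allele 1 of .bim is the counted B allele)
        gm = _matrix([[0.0], [1.0]])
        write_plink(gm, tmp_path / "two")
        back = read_plink(tmp_path / "two")
        np.testing.assert_array_equal(back.values, [[0.0], [1.0]])

    def test_missing_preserved(self, tmp_path):
        gm = _matrix([[0.0, np.nan], [0.5, 1.0], [1.0, 0.0], [np.nan, 0.5]])
        write_plink(gm, tmp_path / "mis")
        back = read_plink(tmp_path / "mis")
        assert np.isnan(back.values[0, 1]) and np.isnan(back.values[3, 0])
        assert back.values[1, 0] == 0.5

    def test_bad_magic_rejected(self, tmp_path):
        gm = _matrix([[0.0], [1.0]])
        write_plink(gm, tmp_path / "bad")
        raw = (tmp_path / "bad.bed").read_bytes()
        (tmp_path / "bad.bed").write_bytes(b"\x00" + raw[1:])
        with pytest.raises(PlinkFormatError, match="byte 0"):
            read_plink(tmp_path / "bad")

    def test_truncated_bed_rejected(self, tmp_path):
        gm = _matrix(np.zeros((5, 4)))
        write_plink(gm, tmp_path / "tr")
        raw = (tmp_path / "tr.bed").read_bytes()
        (tmp_path / "tr.bed").write_bytes(raw[:-1])
        with pytest.raises(PlinkFormatError, match="expected"):
            read_plink(tmp_path / "tr")

    def test_dosage_tsv_round_trip(self, tmp_path):
        gm = _matrix([[0.0, np.nan], [0.5, 1.0], [1.0, 0.0]])
        write_dosage_tsv(gm, tmp_path / "d.tsv")
        back = read_dosage_tsv(tmp_path / "d.tsv")
        np.testing.assert_array_equal(
            np.nan_to_num(back.values, nan=-1), np.nan_to_num(gm.values, nan=-1)
        )


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "column, expected",
        [([0.0, 0.5, 1.0], 0.5), ([0.0, 0.0, 0.5], 1 / 6), ([1.0, 1.0], 1.0)],
    )
    def test_known_frequencies(self, column, expected):
        gm = _matrix(np.asarray(column)[:, None])
        assert allele_frequency(gm, 0) == pytest.approx(expected)

    def test_missing_excluded(self):
        gm = _matrix(np.asarray([0.0, 1.0, np.nan])[:, None])
        assert allele_frequency(gm, 0) == pytest.approx(0.5)

    def test_all_missing_errors(self):
        gm = _matrix(np.asarray([np.nan, np.nan])[:, None])
        with pytest.raises(ValueError, match="missing"):
            allele_frequency(gm, 0)

    def test_binomial_sampling(self):
        # 1000 diploid draws at p=0.3: estimate inside the 99.9% binomial CI
        rng = np.random.default_rng(42)
        doses = rng.binomial(2, 0.3, size=1000) / 2.0
        gm = _matrix(doses[:, None])
        lo, hi = binom.ppf([5e-4, 1 - 5e-4], 2000, 0.3) / 2000
        assert lo <= allele_frequency(gm, 0) <= hi


def _hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-fraction enumeration of the conditional het distribution."""
    n = n_aa + n_ab + n_bb
    nb = 2 * n_bb + n_ab
    nb = min(nb, 2 * n - nb)
    if nb == 0:
        return 1.0
    weights = {}
    for het in range(nb % 2, nb + 1, 2):
        hom_min = (nb - het) // 2
        hom_maj = n - het - hom_min
        weights[het] = (
            2**het
            * math.factorial(n)
            // (math.factorial(het) * math.factorial(hom_min) * math.factorial(hom_maj))
        )
    total = sum(weights.values())
    obs = weights[min(n_ab, nb)]
    return sum(w for w in weights.values() if w <= obs) / total


class TestHWEExactTest:
    def test_perfect_hwe_most_probable(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    def test_extreme_het_deficit(self):
        assert hwe_exact_test(50, 0, 50) < 1e-8

    def test_monomorphic_convention(self):
        assert hwe_exact_test(0, 0, 100) == 1.0
        assert hwe_exact_test(100, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (50, 0, 50), (3, 10, 87), (12, 1, 3), (40, 20, 40), (1, 1, 1)],
    )
    def test_matches_exact_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(_hwe_oracle(*counts), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestApplyQC:
    def _toy(self):
        # 4 samples x 5 SNPs; SNP index 2 monomorphic; sample i2 60% missing
        vals = np.array(
            [
                [0.0, 0.5, 0.0, 1.0, 0.5],
                [0.5, 0.5, 0.0, 0.5, 0.0],
                [np.nan, np.nan, 0.0, np.nan, 0.5],
                [1.0, 0.0, 0.0, 0.0, 1.0],
            ]
        )
        return _matrix(vals)

    def test_toy_hand_applied_rules(self):
        # hand application: monomorphic SNP fails the MAF rule; after SNP
        # filtering sample i2 has 3/4 calls missing and fails its call rate
        thresholds = QCThresholds(maf_min=0.01, hwe_p_floor=1e-8,
                                  snp_call_rate_min=0.5, sample_call_rate_min=0.5)
        out, report = apply_qc(self._toy(), thresholds)
        assert out.m_snps == 4 and out.n_samples == 3
        assert report.removed_snps["maf"] == ["s2"]
        assert report.removed_samples["call_rate"] == ["i2"]
        assert report.n_snps_in - len(report.removed_snps["maf"]) == report.n_snps_out

    def test_no_op_thresholds(self):
        gm = self._toy()
        out, report = apply_qc(
            gm, QCThresholds(maf_min=0.0, hwe_p_floor=0.0,
                             snp_call_rate_min=0.0, sample_call_rate_min=0.0)
        )
        np.testing.assert_array_equal(
            np.nan_to_num(out.values, nan=-1), np.nan_to_num(gm.values, nan=-1)
        )

    def test_idempotent_at_fixpoint(self, small_cohort):
        # sample removal can nudge borderline SNP call rates, so idempotence
        # is guaranteed for the iterate-to-fixpoint mode
        once, _ = apply_qc(small_cohort.genotypes, iterate=True)
        twice, report = apply_qc(once, iterate=True)
        np.testing.assert_array_equal(
            np.nan_to_num(once.values, nan=-1), np.nan_to_num(twice.values, nan=-1)
        )
        assert sum(report.n_removed_per_criterion.values()) == 0

    def test_maf_strictly_below_threshold(self):
        # one heterozygote among 500 samples: MAF exactly 0.001 is retained
        col = np.zeros(500)
        col[0] = 0.5
        gm = _matrix(np.column_stack([col, np.tile([0.0, 0.5, 1.0, 0.5, 0.5], 100)]))
        out, _ = apply_qc(gm, QCThresholds(maf_min=0.001, hwe_p_floor=0.0,
                                           snp_call_rate_min=0.0,
                                           sample_call_rate_min=0.0))
        assert out.m_snps == 2

    def test_injected_hwe_violators_removed(self):
        from regionscan import synthetic_data as sd

        cfg = sd.SimulationConfig(n_samples=400, n_families=0, sibship_size=0,
                                  n_chromosomes=1, snps_per_chromosome=300,
                                  missing_rate=0.0, n_hwe_violators=10, seed=3)
        gm = sd.simulate_genotypes(cfg)
        violators = set(gm.variants.loc[gm.variants["hwe_violator"], "snp_id"])
        assert len(violators) == 10
        _, report = apply_qc(gm)
        assert len(violators & set(report.removed_snps["hwe"])) >= 9

    def test_empty_after_qc_error(self):
        gm = _matrix(np.full((4, 2), 0.5))
        gm.values[:, :] = np.nan
        gm.values[0, :] = 0.5
        with pytest.raises((EmptyAfterQCError, ValueError)):
            apply_qc(gm, QCThresholds(snp_call_rate_min=0.9))


class TestGenotypeMatrixValidation:
    def test_rejects_bad_dosage(self):
        with pytest.raises(ValueError, match="dosages"):
            _matrix([[0.3]])

    def test_rejects_mismatched_registry(self):
        variants = pd.DataFrame(
            {"snp_id": ["a"], "chromosome": [1], "position": [1],
             "allele_a": ["A"], "allele_b": ["B"]}
        )
        with pytest.raises(ValueError):
            GenotypeMatrix(values=np.zeros((2, 2)), variants=variants,
                           samples=["x", "y"])
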