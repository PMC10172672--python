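import numpy as np
import pandas as pd
import pytest

from metaomix.io_formats import VariantRecord
from metaomix.purity_decontam import (
    FullContaminationError,
    InsufficientDataError,
    copy_neutral_variants,
    decontaminate_counts,
    estimate_contamination,
    estimate_contamination_variant_ratio,
    estimate_purity_vaf,
    ssgsea_score,
)
from metaomix.synthetic_cohort import sample_vafs


def snv(vaf, sample_id="S1", pos=100, clonality="clonal"):
    return VariantRecord("1", pos, "C", "T", vaf, 200, "ACA",
                         "nonsynonymous", "SNV", sample_id, clonality)


class TestPurity:
    def test_quarter_vafs_give_half_purity(self):
        est = estimate_purity_vaf([snv(0.25, pos=i) for i in range(20)])
        assert est.purity == pytest.approx(0.5)
        assert est.n_variants == 20

    def test_half_vafs_clip_to_one(self):
        est = estimate_purity_vaf([snv(0.55, pos=i) for i in range(20)])
        assert est.purity == 1.0

    def test_too_few_variants_is_error(self):
        with pytest.raises(InsufficientDataError, match="3"):
            estimate_purity_vaf([snv(0.3, pos=i) for i in range(3)])

    def test_recovery_from_binomial_draws(self):
        # 500 copy-neutral variants, depth 200, purity 0.6
        vafs = sample_vafs(0.6, (2, 1), depth=200, n=500, seed=21)
        variants = [snv(float(v), pos=i) for i, v in enumerate(vafs)]
        est = estimate_purity_vaf(variants)
        assert abs(est.purity - 0.6) <= 0.05

    def test_neutral_region_restriction(self):
        inside = [snv(0.25, pos=i) for i in range(50, 70)]
        outside = [snv(0.45, pos=i) for i in range(5000, 5020)]
        est = estimate_purity_vaf(inside + outside, neutral_regions=[("1", 1, 1000)])
        assert est.purity == pytest.approx(0.5)
        assert est.n_variants == 20

    def test_copy_neutral_variant_filter(self, small_cohort):
        cohort, truth = small_cohort
        recs = [v for v in cohort.variants if v.sample_id == "P01_met"]
        neutral = copy_neutral_variants(recs, cohort.segments)
        assert 0 < len(neutral) <= len(recs)
        aberrant_spans = [
            (s.chrom, s.start, s.end) for s in cohort.segments
            if s.sample_id == "P01_met" and s.copy_number != 2
        ]
        for v in neutral:
            assert not any(a <= v.pos <= b and v.chrom == c
                           for c, a, b in aberrant_spans)


class TestSsgsea:
    def test_hand_computed_running_sum(self):
        # 4 features, set = top-ranked gene, alpha=0:
        # ES = 1 + 2/3 + 1/3 + 0 = 2.0
        expr = pd.Series([10.0, 5.0, 2.0, 1.0], index=["a", "b", "c", "d"])
        es = ssgsea_score(expr, {"a"}, alpha=0.0)
        assert es.score == pytest.approx(2.0)

    def test_set_spanning_all_features_scores_zero(self):
        expr = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        assert ssgsea_score(expr, {"a", "b", "c"}).score == 0.0

    def test_bottom_gene_flips_sign(self):
        expr = pd.Series([10.0, 5.0, 2.0, 1.0], index=["a", "b", "c", "d"])
        top = ssgsea_score(expr, {"a"}, alpha=0.0).score
        bottom = ssgsea_score(expr, {"d"}, alpha=0.0).score
        assert bottom == pytest.approx(-top)

    def test_empty_intersection_is_error(self):
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(InsufficientDataError):
            ssgsea_score(expr, {"zzz"})


class TestContamination:
    def _markers(self, n=25):
        return [f"L{i}" for i in range(n)]

    def test_exact_marker_ratio(self):
        markers = self._markers()
        liver = pd.Series(200.0, index=markers)
        met = pd.Series(80.0, index=markers)
        est = estimate_contamination(met, liver, liver_markers=markers)
        assert est.fraction == pytest.approx(0.4)
        assert est.diagnostics["n_markers"] == 25

    def test_met_identical_to_liver_is_full_contamination(self):
        markers = self._markers()
        liver = pd.Series(150.0, index=markers)
        est = estimate_contamination(liver.copy(), liver, liver_markers=markers)
        assert est.fraction == 1.0

    def test_too_few_markers_is_error(self):
        markers = self._markers(5)
        liver = pd.Series(200.0, index=markers)
        with pytest.raises(InsufficientDataError):
            estimate_contamination(liver * 0.5, liver, liver_markers=markers)

    def test_least_squares_matches_noise_free_mixture(self):
        genes = [f"g{i}" for i in range(100)]
        rs = np.random.default_rng(3)
        liver = pd.Series(rs.uniform(10, 300, 100), index=genes)
        colon = pd.Series(rs.uniform(10, 300, 100), index=genes)
        f = 0.35
        met = f * liver + (1 - f) * colon
        est = estimate_contamination(met, liver, colon=colon,
                                     liver_markers=None, method="least_squares")
        assert est.fraction == pytest.approx(f, abs=1e-12)

    def test_marker_ratio_monotone_in_true_f(self):
        markers = self._markers()
        liver = pd.Series(200.0, index=markers)
        tumor = pd.Series(0.0, index=markers)
        estimates = []
        for f in (0.1, 0.3, 0.5, 0.7, 0.9):
            met = f * liver + (1 - f) * tumor
            estimates.append(
                estimate_contamination(met, liver, liver_markers=markers).fraction
            )
        assert estimates == sorted(estimates)

    def test_recovery_on_synthetic_cohort(self, small_cohort):
        from metaomix.differential import scale_normalize_counts
        cohort, truth = small_cohort
        _, norm = scale_normalize_counts(cohort.mrna_counts.values)
        errors = []
        for met_id in cohort.sample_ids("metastasis"):
            liv_id = cohort.paired_liver(met_id)
            est = estimate_contamination(
                norm[met_id], norm[liv_id], liver_markers=cohort.liver_markers
            )
            errors.append(abs(est.fraction - truth.f[met_id[:3]]))
        assert np.median(errors) <= 0.05


class TestVariantRatio:
    def test_no_dilution_gives_zero(self):
        dna = np.full(30, 0.4)
        est = estimate_contamination_variant_ratio(dna, dna.copy())
        assert est.fraction == 0.0

    def test_half_dilution_closed_form(self):
        dna = np.full(30, 0.4)
        est = estimate_contamination_variant_ratio(dna, 0.5 * dna)
        assert est.fraction == pytest.approx(0.5)

    def test_zero_dna_vaf_excluded_then_error_when_too_few(self):
        dna = np.zeros(30)
        dna[:5] = 0.4
        with pytest.raises(InsufficientDataError):
            estimate_contamination_variant_ratio(dna, dna * 0.5)

    def test_recovery_under_binomial_noise(self):
        rs = np.random.default_rng(17)
        f_true, depth, n = 0.3, 100, 200
        dna = rs.uniform(0.2, 0.5, n)
        rna = rs.binomial(depth, (1 - f_true) * dna) / depth
        est = estimate_contamination_variant_ratio(dna, rna)
        assert abs(est.fraction - f_true) <= 0.07


class TestDecontaminate:
    def test_worked_arithmetic(self):
        met = pd.Series([10.0, 20.0], index=["a", "b"])
        liver = pd.Series([10.0, 0.0], index=["a", "b"])
        out = decontaminate_counts(met, liver, f=0.5)
        assert list(out) == [10.0, 40.0]

    def test_f_zero_is_identity(self):
        met = pd.Series([5.0, 7.0], index=["a", "b"])
        liver = pd.Series([100.0, 3.0], index=["a", "b"])
        pd.testing.assert_series_equal(decontaminate_counts(met, liver, 0.0), met)

    def test_exact_inversion_of_noise_free_mixture(self, rng):
        genes = [f"g{i}" for i in range(500)]
        tumor = pd.Series(rng.uniform(0, 500, 500), index=genes)
        liver = pd.Series(rng.uniform(0, 500, 500), index=genes)
        for f in (0.0, 0.2, 0.5, 0.8):
            met = f * liver + (1 - f) * tumor
            cleaned = decontaminate_counts(met, liver, f)
            err = np.abs(cleaned - tumor) / np.maximum(tumor, 1e-12)
            assert err.max() <= 1e-9

    def test_non_negative_and_clipping_reported(self, rng):
        met = pd.Series(rng.uniform(0, 10, 50))
        liver = pd.Series(rng.uniform(0, 100, 50))
        cleaned, clipped = decontaminate_counts(met, liver, 0.8, return_clipped=True)
        assert (cleaned >= 0).all()
        assert clipped.sum() > 0

    def test_full_contamination_with_rescale_is_error(self):
        s = pd.Series([1.0], index=["a"])
        with pytest.raises(FullContaminationError):
            decontaminate_counts(s, s, 1.0)
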