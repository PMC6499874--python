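"""One-sample t, 2x2 chi-squared, Pearson r, prevalence tables."""

import numpy as np
import pytest
from scipy import stats as sps

from braintorque import (CohortTable, chi2_prevalence, one_sample_t, pearson_r,
                         prevalence_table, species_comparison)
from braintorque.metrics import (Configuration, DimensionRecord, TorqueRecord,
                                 classify_configuration)


def make_record(pf=0.0, po=0.0, sf=0.0, so=0.0, bf=0.0, bo=0.0,
                dl=0.0, dh=0.0, dw=0.0, subject_id="s", species="human"):
    """A TorqueRecord built directly from metric values (no meshes)."""
    dims = DimensionRecord(
        left_length=170 + dl, left_height=116 + dh, left_width=70 + dw,
        right_length=170.0, right_height=116.0, right_width=70.0,
        whole_length=175.0, whole_height=118.0, whole_width=134.0)
    return TorqueRecord(
        subject_id=subject_id, species=species, sex=None,
        petalia_frontal=pf, petalia_occipital=po,
        shift_frontal=sf, shift_occipital=so,
        bending_frontal=bf, bending_occipital=bo,
        config_petalia=classify_configuration(pf, po, "petalia"),
        config_shift=classify_configuration(sf, so, "shift"),
        config_bending=classify_configuration(bf, bo, "bending"),
        dimensions=dims)


def cohort_with_bending_occipital(n_rightward: int, n_leftward: int,
                                  species: str) -> CohortTable:
    recs = [make_record(bo=+3.0, subject_id=f"{species}-r{i}", species=species)
            for i in range(n_rightward)]
    recs += [make_record(bo=-3.0, subject_id=f"{species}-l{i}", species=species)
             for i in range(n_leftward)]
    return CohortTable(recs)


class TestOneSampleT:
    def test_published_length_asymmetry_statistic(self):
        res = one_sample_t(0.92, 1.84, 91)
        assert res.statistic == pytest.approx(4.77, abs=0.005)
        assert res.df == 90
        assert res.p < 0.0005

    def test_zero_mean_gives_zero_t_unit_p(self):
        res = one_sample_t(0.0, 1.0, 10)
        assert res.statistic == 0
        assert res.p == 1

    def test_hand_computed_small_sample(self):
        res = one_sample_t(values=[1, 2, 3])
        assert res.statistic == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-9)
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)

    def test_raw_values_equal_summary_form(self, rng):
        v = rng.normal(0.4, 1.2, 37)
        a = one_sample_t(values=v)
        b = one_sample_t(float(v.mean()), float(v.std(ddof=1)), len(v))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_matches_scipy_on_raw_values(self, rng):
        v = rng.normal(0.2, 1.0, 25)
        ours = one_sample_t(values=v)
        ref = sps.ttest_1samp(v, 0.0)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t(1.0, 0.0, 10)
        with pytest.raises(ValueError):
            one_sample_t(values=[1.0])


class TestChi2Prevalence:
    def test_published_petalia_species_difference(self):
        res = chi2_prevalence(55, 36, 24, 54)
        assert res.statistic == pytest.approx(14.85, abs=0.005)
        assert res.df == 1
        assert res.p < 0.0005

    def test_proportional_rows_give_zero(self):
        assert chi2_prevalence(10, 20, 5, 10).statistic == pytest.approx(0)

    def test_hand_computed_table(self):
        # 60 * (400 - 100)^2 / 30^4 = 20/3
        assert chi2_prevalence(20, 10, 10, 20).statistic == pytest.approx(
            6.6667, abs=1e-4)

    @pytest.mark.parametrize("table", [(55, 36, 24, 54), (7, 3, 2, 9),
                                       (40, 1, 3, 50)])
    def test_matches_scipy_without_continuity_correction(self, table):
        a, b, c, d = table
        ours = chi2_prevalence(a, b, c, d)
        ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invariance_under_transpose_and_double_swap(self):
        base = chi2_prevalence(55, 36, 24, 54).statistic
        assert chi2_prevalence(55, 24, 36, 54).statistic == pytest.approx(base)
        assert chi2_prevalence(54, 24, 36, 55).statistic == pytest.approx(base)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_prevalence(0, 0, 5, 5)


class TestPearsonR:
    def test_perfect_linear_association(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_naive_covariance_oracle(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y).statistic == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPrevalenceTable:
    def test_one_subject_per_quadrant(self):
        cohort = CohortTable([
            make_record(pf=+1, po=-1), make_record(pf=+1, po=+1),
            make_record(pf=-1, po=-1), make_record(pf=-1, po=+1)])
        tab = prevalence_table(cohort, "petalia")
        assert np.allclose(tab.loc[["LO", "RO"], ["LF", "RF"]].to_numpy(), 25.0)
        assert tab.loc["total", "total"] == pytest.approx(100.0)

    def test_single_quadrant_cohort(self):
        cohort = CohortTable([make_record(pf=-1, po=-1) for _ in range(5)])
        tab = prevalence_table(cohort, "petalia")
        assert tab.loc["LO", "RF"] == pytest.approx(100.0)
        assert tab.loc["RO"].sum() == pytest.approx(0.0)

    def test_marginals_sum_to_hundred(self):
        cohort = CohortTable([make_record(pf=f, po=o)
                              for f in (-2, -1, 1) for o in (-1, 1, 2)])
        tab = prevalence_table(cohort, "petalia")
        assert tab.loc["total", "total"] == pytest.approx(100.0)
        assert tab.loc["total", ["LF", "RF"]].sum() == pytest.approx(100.0)


class TestSpeciesComparison:
    def test_identical_cohorts_give_zero(self):
        a = cohort_with_bending_occipital(6, 4, "human")
        b = cohort_with_bending_occipital(6, 4, "chimpanzee")
        assert species_comparison(a, b, "bending", "RO").statistic == \
            pytest.approx(0.0)

    def test_published_occipital_bending_difference(self):
        human = cohort_with_bending_occipital(71, 20, "human")
        chimp = cohort_with_bending_occipital(33, 45, "chimpanzee")
        res = species_comparison(human, chimp, "bending", "RO")
        assert res.statistic == pytest.approx(22.63, abs=0.005)
        assert res.p < 0.0005

    def test_disjoint_extremes_hand_value(self):
        a = cohort_with_bending_occipital(10, 0, "human")
        b = cohort_with_bending_occipital(0, 10, "chimpanzee")
        assert species_comparison(a, b, "bending", "RO").statistic == \
            pytest.approx(20.0)

    def test_full_quadrant_collapse(self):
        a = CohortTable([make_record(pf=-1, po=-1)] * 7 + [make_record(pf=1, po=1)] * 3)
        b = CohortTable([make_record(pf=-1, po=-1)] * 2 + [make_record(pf=1, po=1)] * 8)
        res = species_comparison(a, b, "petalia", "RF/LO")
        ref = sps.chi2_contingency([[7, 3], [2, 8]], correction=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
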