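import numpy as np
import pandas as pd
import pytest

from conftest import small_cohort, toy_table
from labmi.evaluation import (HoldoutMask, case_study_metrics,
                              compare_algorithms, complete_cases,
                              coverage_and_width, holdout_complete_cases,
                              holdout_values, nrmse, over_imputation_table,
                              uncertainty_propagation)
from labmi.procedures import ImputationSpec, ImputedSets
from oracles import brute_nrmse


def _sets_from_arrays(base_table, cells, arrays):
    """Completed sets where set k carries arrays[k] at the masked cells."""
    tables = [base_table.set_cells(cells, arr) for arr in arrays]
    return ImputedSets(tables=tables, spec=ImputationSpec(m=len(arrays)),
                       child_keys=[(0, k) for k in range(len(arrays))])


class TestHoldoutValues:
    def test_exact_count_and_disjointness(self, mnar_bundle):
        table = mnar_bundle.observed_labs
        masked, mask = holdout_values(table, 20, np.random.default_rng(0))
        per = mask.by_analyte()
        for a in table.analytes:
            assert len(per[a]) == 20
        # every held-out cell was observed before masking
        assert not np.isnan(mask.truth).any()
        assert np.isnan(masked.get_cells(mask.cells)).all()

    def test_zero_holdouts_is_identity(self, mnar_bundle):
        table = mnar_bundle.observed_labs
        masked, mask = holdout_values(table, 0, np.random.default_rng(0))
        assert mask.cells == []
        pd.testing.assert_frame_equal(masked.data, table.data)

    def test_scarce_analyte_reduced_with_warning(self):
        t = toy_table({"a": ([1.0, 2.0, np.nan], [1.0, 2.0, 3.0])})
        with pytest.warns(UserWarning, match="holding out 2"):
            _, mask = holdout_values(t, 50, np.random.default_rng(0))
        assert len(mask.cells) == 2


class TestHoldoutCompleteCases:
    def test_masked_cell_count(self, mnar_bundle):
        table = mnar_bundle.observed_labs
        n_cc = len(complete_cases(table))
        assert n_cc >= 10
        masked, mask = holdout_complete_cases(table, 10,
                                              np.random.default_rng(1))
        assert len(mask.cells) == 10 * len(table.analytes)
        assert not np.isnan(mask.truth).any()

    def test_insufficient_complete_cases_reports_count(self, mnar_bundle):
        table = mnar_bundle.observed_labs
        n_cc = len(complete_cases(table))
        with pytest.raises(ValueError, match=str(n_cc)):
            holdout_complete_cases(table, n_cc + 1, np.random.default_rng(0))


class TestNrmse:
    def test_exact_cases(self):
        assert nrmse([1, 2, 3], [1, 2, 3], 2.0) == 0.0
        assert nrmse([1, 1, 1, 1], [0, 0, 0, 0], 2.0) == 0.5
        with pytest.raises(ValueError, match="delta"):
            nrmse([1.0], [1.0], 0.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        y, yhat = rng.normal(size=30), rng.normal(size=30)
        a, b, delta = 3.7, -2.0, 1.3
        assert nrmse(a * yhat + b, a * y + b, abs(a) * delta) == \
            pytest.approx(nrmse(yhat, y, delta))

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(1, 20)
            y, yhat = rng.normal(size=n), rng.normal(size=n)
            d = float(rng.uniform(0.5, 3))
            assert nrmse(yhat, y, d) == pytest.approx(
                brute_nrmse(yhat, y, d), abs=1e-12)


class TestCoverage:
    def _base(self):
        t = toy_table({"a": ([1.0, 2.0, 3.0, 4.0], [0.0] * 4)})
        cells = [(p, "a", "pre") for p in t.patients[:3]]
        truth = t.get_cells(cells)
        masked = t.set_cells(cells, [np.nan] * 3)
        return masked, HoldoutMask("HV", cells, truth, 3)

    def test_all_draws_equal_truth(self):
        masked, mask = self._base()
        sets = _sets_from_arrays(masked, mask.cells, [mask.truth] * 5)
        out = coverage_and_width(sets, mask)
        assert out.loc[0, "cr"] == 1.0 and out.loc[0, "aw"] == 0.0

    def test_constant_offset_never_covers(self):
        masked, mask = self._base()
        sets = _sets_from_arrays(masked, mask.cells, [mask.truth + 10] * 5)
        out = coverage_and_width(sets, mask)
        assert out.loc[0, "cr"] == 0.0

    def test_single_set_rejected(self):
        masked, mask = self._base()
        sets = _sets_from_arrays(masked, mask.cells, [mask.truth])
        with pytest.raises(ValueError, match="m >= 2"):
            coverage_and_width(sets, mask)


class TestUncertaintyPropagation:
    def test_constant_sequence(self):
        out = uncertainty_propagation([0.7] * 50)
        np.testing.assert_allclose(out["mean"], 0.7)
        np.testing.assert_allclose(out["se"], 0.0, atol=1e-12)
        assert out["checkpoint"].tolist() == [5, 10, 20, 30, 40, 50]

    def test_truncation_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            out = uncertainty_propagation([0.5] * 8)
        assert out["checkpoint"].tolist() == [5]

    def test_final_checkpoint_is_overall_mean(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=50)
        out = uncertainty_propagation(x)
        assert out["mean"].iloc[-1] == pytest.approx(x.mean())


class TestCompareAlgorithms:
    def test_identical_vectors(self):
        out = compare_algorithms([0.5] * 10, [0.5] * 10, n_tests=45)
        assert out["t"] == 0.0 and out["p"] == 1.0
        assert not out["significant"]

    def test_bonferroni_threshold(self):
        # a raw p around 0.002 does not survive 45 tests (0.05/45 ~ 0.0011)
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0.5, 1, 30)
            out = compare_algorithms(a, b, n_tests=45)
            if 0.0015 < out["p"] < 0.05:
                assert not out["significant"]
                break
        else:
            pytest.skip("no draw landed in the p-value window")

    def test_huge_effect_survives_bonferroni(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 50)
        b = a + 5 * a.std(ddof=1)
        out = compare_algorithms(a, b, n_tests=45)
        assert out["significant"]

    def test_zero_variance_both_arms_flagged(self):
        out = compare_algorithms([1.0] * 5, [2.0] * 5, n_tests=1)
        assert not out["defined"] and not out["significant"]


class TestOverImputation:
    def _mask(self):
        t = toy_table({"a": (np.linspace(1, 8, 8).tolist(), [0.0] * 8)})
        cells = [(p, "a", "pre") for p in t.patients]
        truth = t.get_cells(cells)
        masked = t.set_cells(cells, [np.nan] * 8)
        return masked, HoldoutMask("HV", cells, truth, 8)

    def test_perfect_imputation(self):
        masked, mask = self._mask()
        sets = _sets_from_arrays(masked, mask.cells, [mask.truth] * 4)
        per, summary = over_imputation_table(sets, mask)
        assert summary["r"] == pytest.approx(1.0)
        assert (per["imputed_se"] == 0).all()

    def test_constant_imputation_undefined(self):
        masked, mask = self._mask()
        sets = _sets_from_arrays(masked, mask.cells,
                                 [np.full(8, 3.0)] * 4)
        _, summary = over_imputation_table(sets, mask)
        assert not summary["defined"] and np.isnan(summary["r"])

    def test_affine_invariance_of_r(self):
        masked, mask = self._mask()
        rng = np.random.default_rng(5)
        arrays = [mask.truth + rng.normal(0, 0.5, 8) for _ in range(4)]
        _, s1 = over_imputation_table(sets := _sets_from_arrays(
            masked, mask.cells, arrays), mask)
        arrays2 = [2.0 * a + 1.0 for a in arrays]
        mask2 = HoldoutMask("HV", mask.cells, 2.0 * mask.truth + 1.0, 8)
        _, s2 = over_imputation_table(_sets_from_arrays(
            masked, mask.cells, arrays2), mask2)
        assert s1["r"] == pytest.approx(s2["r"])


class TestCaseStudyMetrics:
    def _with_per_set_r(self, rs):
        """Craft sets whose per-set Pearson R with the truth is exact."""
        z1 = np.array([-3.0, -1.0, 1.0, 3.0])
        z1 /= np.linalg.norm(z1)
        z2 = np.array([1.0, -1.0, -1.0, 1.0])
        z2 /= np.linalg.norm(z2)
        t = toy_table({"a": (z1.tolist(), [0.0] * 4)})
        cells = [(p, "a", "pre") for p in t.patients]
        truth = t.get_cells(cells)
        masked = t.set_cells(cells, [np.nan] * 4)
        arrays = [r * z1 + np.sqrt(1 - r ** 2) * z2 for r in rs]
        return _sets_from_arrays(masked, cells, arrays), \
            HoldoutMask("HV", cells, truth, 4)

    def test_identical_sets_have_zero_spread(self):
        sets, mask = self._with_per_set_r([0.6, 0.6, 0.6])
        out = case_study_metrics(sets, mask)
        assert out["average_r"] == pytest.approx(0.6)
        assert out["se_r"] == 0.0 and out["cv_r"] == 0.0

    def test_forced_arithmetic(self):
        sets, mask = self._with_per_set_r([0.4, 0.5, 0.6])
        out = case_study_metrics(sets, mask)
        assert out["average_r"] == pytest.approx(0.5)
        assert out["cv_r"] == pytest.approx(0.1 / 0.5)

    def test_sign_flip_preserves_cv_magnitude(self):
        sets, mask = self._with_per_set_r([0.4, 0.5, 0.6])
        flipped, _ = self._with_per_set_r([-0.4, -0.5, -0.6])
        a = case_study_metrics(sets, mask)
        b = case_study_metrics(flipped, mask)
        assert b["average_r"] == pytest.approx(-a["average_r"])
        assert abs(b["cv_r"]) == pytest.approx(abs(a["cv_r"]))
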