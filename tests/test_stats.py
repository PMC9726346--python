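import itertools
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dtialps.cohort import cohort_to_frame, default_cohort_config, sample_cohort
from dtialps.stats import (
    UndefinedCorrelationError,
    age_correlations,
    compare_groups,
    fisher_exact_sex,
    format_p,
    mann_whitney_u,
    pearson,
    report,
)


def enumerated_mwu(x, y):
    """Independent oracle: full enumeration over rank assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(c)].sum() - n1 * (n1 + 1) / 2
            for c in itertools.combinations(range(len(pooled)), n1)
        ]
    )
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(1.0, p)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 rank assignments

    def test_identical_multisets_give_p_one(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n1, n2 = rng.integers(2, 7, size=2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            u_ref, p_ref = enumerated_mwu(x, y)
            u, p = mann_whitney_u(x, y, mode="exact")
            assert u == pytest.approx(u_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_asymptotic_within_exhaustive_bound_of_exact(self):
        """The normal approximation tracks the exact p; the worst-case gap
        over every tie-free configuration with n1,n2 ≤ 6 is 0.129."""
        worst = 0.0
        for n1, n2 in itertools.product(range(2, 7), repeat=2):
            for c in itertools.combinations(range(n1 + n2), n1):
                x = np.array(sorted(c), float)
                y = np.array(sorted(set(range(n1 + n2)) - set(c)), float)
                pe = mann_whitney_u(x, y, mode="exact")[1]
                pa = mann_whitney_u(x, y, mode="asymptotic")[1]
                worst = max(worst, abs(pe - pa))
        assert worst < 0.13

    def test_auto_switches_on_ties_and_size(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=30)
        y = rng.normal(size=25)
        # n1*n2 = 750 > 400: auto equals asymptotic
        assert mann_whitney_u(x, y)[1] == mann_whitney_u(x, y, mode="asymptotic")[1]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_table2_effect_detected(self):
        """Cohorts at the published left-index parameters separate clearly."""
        rng = np.random.default_rng(42)
        x = rng.normal(1.02, 0.12, 30)
        y = rng.normal(1.27, 0.25, 25)
        assert mann_whitney_u(x, y)[1] < 0.001


class TestPearson:
    def test_exact_linearity(self):
        r, r2, p = pearson([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_symmetric_residuals_give_zero(self):
        r, r2, p = pearson([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_independent_large_n_near_zero(self):
        rng = np.random.default_rng(19)
        r, r2, _ = pearson(rng.normal(size=5000), rng.normal(size=5000))
        assert abs(r) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 2.0], [1.0, 2.0])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-5, max_value=5),
    )
    def test_affine_invariance_and_r2_identity(self, a, b):
        rng = np.random.default_rng(20)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r0, r20, _ = pearson(x, y)
        r1, r21, _ = pearson(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert r21 == pytest.approx(r1 * r1, abs=1e-12)


class TestCompareGroups:
    @pytest.fixture()
    def study_frame(self):
        frame = cohort_to_frame(sample_cohort(default_cohort_config(), seed=42))
        return frame.rename(
            columns={"alps_true_left": "alps_left", "alps_true_right": "alps_right"}
        )

    def test_identical_groups_nothing_significant(self):
        half = pd.DataFrame(
            {
                "group": ["A"] * 10 + ["B"] * 10,
                "age_months": list(range(10)) * 2,
                "ga_weeks": [39.0] * 20,
                "alps_left": list(np.linspace(1, 1.5, 10)) * 2,
                "alps_right": list(np.linspace(1, 1.5, 10)) * 2,
                "sex": ["male", "female"] * 10,
            }
        )
        results = compare_groups(half)
        assert all(not r.significant for r in results)

    def test_study_cohort_alps_significant_age_not(self, study_frame):
        results = {r.variable: r for r in compare_groups(study_frame)}
        assert results["alps_left"].significant and results["alps_left"].p < 0.001
        assert results["alps_right"].significant and results["alps_right"].p < 0.001
        assert not results["age_months"].significant
        assert results["age_months"].threshold == pytest.approx(0.05 / 3)

    def test_threshold_strictly_honoured(self, study_frame):
        # a family of one relaxes the threshold to alpha itself
        loose = {r.variable: r for r in compare_groups(study_frame, family=("alps_left",))}
        assert loose["alps_left"].threshold == pytest.approx(0.05)
        for r in compare_groups(study_frame):
            assert r.significant == (r.p < r.threshold)

    def test_one_group_rejected(self, study_frame):
        with pytest.raises(ValueError):
            compare_groups(study_frame[study_frame["group"] == "ASD"])

    def test_sex_tests_available(self, study_frame):
        fisher = [r for r in compare_groups(study_frame) if r.variable == "sex_male"][0]
        assert fisher.test == "fisher-exact"
        mwu = [
            r
            for r in compare_groups(study_frame, sex_test="mannwhitney")
            if r.variable == "sex_male"
        ][0]
        assert mwu.test == "mann-whitney"
        odds, p = fisher_exact_sex(study_frame, ("ASD", "control"))
        assert 0 <= p <= 1


class TestAgeCorrelations:
    def test_four_strata(self):
        frame = cohort_to_frame(sample_cohort(default_cohort_config(), seed=21)).rename(
            columns={"alps_true_left": "alps_left", "alps_true_right": "alps_right"}
        )
        results, warnings = age_correlations(frame)
        assert len(results) == 4 and not warnings
        for res in results:
            assert res.r2 == pytest.approx(res.r**2, abs=1e-12)
            assert res.r > 0  # generator encodes a positive age association

    def test_small_sample_bias_matches_closed_form(self):
        """Mean sample R² over replicates ≈ ρ² + (1−ρ²)/n at ρ=0.68, n=30."""
        rho, n, reps = 0.68, 30, 200
        rng = np.random.default_rng(22)
        r2s = []
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            r2s.append(pearson(x, y)[1])
        expect = rho**2 + (1 - rho**2) / n
        assert np.mean(r2s) == pytest.approx(expect, abs=0.03)

    def test_constant_age_propagates_error(self):
        frame = pd.DataFrame(
            {
                "group": ["A"] * 5,
                "age_months": [48.0] * 5,
                "alps_left": [1.0, 1.1, 1.2, 1.3, 1.4],
                "alps_right": [1.0, 1.1, 1.2, 1.3, 1.4],
            }
        )
        with pytest.raises(UndefinedCorrelationError):
            age_correlations(frame)

    def test_undersized_stratum_skipped_with_warning(self):
        frame = pd.DataFrame(
            {
                "group": ["A", "A", "B", "B", "B"],
                "age_months": [40, 50, 45, 55, 60],
                "alps_left": [1.0, 1.2, 1.1, 1.3, 1.2],
                "alps_right": [1.0, 1.2, 1.1, 1.3, 1.2],
            }
        )
        results, warnings = age_correlations(frame)
        assert len(results) == 2  # only group B
        assert len(warnings) == 2 and "A" in warnings[0]


class TestReport:
    def test_p_rendering_conventions(self):
        assert format_p(0.0003) == "<.001"
        assert format_p(0.520) == ".520"
        assert format_p(0.0005) == ".001"  # boundary rounds up, not censored
        with pytest.raises(ValueError):
            format_p(1.5)

    def test_report_files_and_json(self, tmp_path):
        frame = cohort_to_frame(sample_cohort(default_cohort_config(), seed=23)).rename(
            columns={"alps_true_left": "alps_left", "alps_true_right": "alps_right"}
        )
        comparisons = compare_groups(frame)
        correlations, _ = age_correlations(frame)
        payload = report(comparisons, correlations, tmp_path)
        for name in ("demographics.csv", "alps_comparison.csv",
                     "age_correlations.csv", "stats.json"):
            assert (tmp_path / name).exists()
        loaded = json.loads((tmp_path / "stats.json").read_text())
        assert loaded == json.loads(json.dumps(payload))
        demo = pd.read_csv(tmp_path / "demographics.csv")
        assert set(demo["variable"]) == {"age_months", "ga_weeks", "sex_male"}

    def test_empty_results_valid_outputs(self, tmp_path):
        payload = report([], [], tmp_path)
        assert payload == {"comparisons": [], "correlations": []}
        assert json.loads((tmp_path / "stats.json").read_text()) == payload
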