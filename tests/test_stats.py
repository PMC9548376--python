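import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fuccitrack.models import NPC_MUT, NPC_WT
from fuccitrack.stats import (bonferroni, compare_cohorts, km_median,
                              mann_whitney, phase_km_median,
                              summarize_distribution, welch_t)


def _sample_model(model, n, rng):
    return model.g1_median_min * np.exp(
        model.g1_logsd * rng.standard_normal(n))


class TestMannWhitney:
    def test_small_sample_exact_enumeration(self):
        """x=[1,2] vs y=[3,4]: U=0 and the exact two-sided p is 2/6."""
        res = mann_whitney([1, 2], [3, 4])
        assert res.u == 0
        assert res.method == "exact_enumeration"
        assert res.p == pytest.approx(2 / 6)

    def test_identical_samples_give_p_one(self):
        res = mann_whitney([5, 5, 5, 5], [5, 5, 5, 5])
        assert res.p == 1.0
        assert res.method == "normal_tie_corrected"

    def test_exact_mode_matches_scipy_exact(self):
        """Exact p agrees with scipy's exact method for every n1,n2 <= 6."""
        rng = np.random.default_rng(42)
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                x = rng.normal(size=n1)
                y = rng.normal(0.5, size=n2)
                ours = mann_whitney(x, y)
                ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact")
                assert ours.method == "exact_enumeration"
                assert ours.u == pytest.approx(ref.statistic)
                assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = rng.normal(0.4, size=25)
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert ours.method == "normal_tie_corrected"
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_tie_correction_matches_scipy(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 5, size=15).astype(float)
        y = rng.integers(1, 6, size=18).astype(float)
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_approximation_agrees_with_permutation_oracle(self):
        """n=20 per group: the tie-corrected normal p is within Monte-Carlo
        error of a 1e5-permutation two-sided p."""
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 1.0, 20)
        y = rng.normal(0.7, 1.0, 20)
        ours = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        n_perm = 100_000
        mat = np.tile(pooled, (n_perm, 1))
        mat = rng.permuted(mat, axis=1)
        ranks = sps.rankdata(mat, axis=1)
        u_perm = ranks[:, :20].sum(axis=1) - 20 * 21 / 2
        mu = 20 * 20 / 2
        obs = abs(ours.u - mu)
        p_perm = (np.abs(u_perm - mu) >= obs - 1e-9).mean()
        assert ours.p == pytest.approx(p_perm, abs=5e-3)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=12),
           st.lists(st.integers(0, 1000), min_size=1, max_size=12))
    def test_u_symmetry(self, xs, ys):
        """U(x,y) + U(y,x) = n1*n2 always."""
        a = mann_whitney(xs, ys)
        b = mann_whitney(ys, xs)
        assert a.u + b.u == pytest.approx(len(xs) * len(ys))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.02, 2, 0.04), (0.9, 2, 1.0), (0.3, 1, 0.3)])
    def test_adjustment(self, p, m, expected):
        assert bonferroni([p], m) == [pytest.approx(expected)]

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.0], 1)


class TestBoxplotSummary:
    def test_quartile_convention_on_1_to_100(self):
        s = summarize_distribution(range(1, 101))
        assert s.median == 50.5
        assert s.q1 == 25.75
        assert s.q3 == 75.25
        assert s.whisker_lo == 1 and s.whisker_hi == 100
        assert s.n_outliers == 0

    def test_single_value(self):
        s = summarize_distribution([7.0])
        assert (s.median, s.q1, s.q3, s.whisker_lo, s.whisker_hi) == \
            (7.0, 7.0, 7.0, 7.0, 7.0)

    def test_far_outlier_excluded_from_whisker(self):
        data = list(range(10)) + [1000.0]
        s = summarize_distribution(data)
        assert s.whisker_hi == 9
        assert s.n_outliers == 1


class TestWelchT:
    def test_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 9.0])
        t, p = welch_t(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_ref = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
        p_ref = 2 * sps.t.sf(abs(t_ref), df)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)


class TestKaplanMeier:
    def test_no_censoring_equals_plain_median_position(self):
        data = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert km_median(data, [True] * 5) == 3.0

    def test_matches_lifelines_on_random_censored_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(12)
        for _ in range(10):
            t = rng.exponential(10, 80)
            c = rng.exponential(15, 80)
            obs = t <= c
            dur = np.minimum(t, c)
            kmf = lifelines.KaplanMeierFitter().fit(dur, obs)
            ours = km_median(dur, obs)
            assert ours == pytest.approx(kmf.median_survival_time_)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_median([], [])

    def test_phase_km_median_uses_end_censored_only(self):
        dur = pd.DataFrame({"phase": ["G1"] * 3,
                            "duration_min": [10.0, 20.0, 30.0]})
        audit = pd.DataFrame({
            "phase": ["G1", "G1"], "duration_min": [25.0, 99.0],
            "censor_type": ["end", "start"]})
        # events 10,20,30 + censored 25: S drops to 0.5 at 20
        assert phase_km_median(dur, audit, "G1") == 20.0


def _dur_table(values, phase="G1", genotype="x"):
    return pd.DataFrame({"cell_id": range(len(values)), "genotype": genotype,
                         "phase": phase, "duration_min": values,
                         "censored": False})


class TestCompareCohorts:
    def test_identical_cohorts_not_significant(self):
        vals = np.linspace(100, 500, 30)
        rep = compare_cohorts(_dur_table(vals), _dur_table(vals))
        pc = rep.phases["G1"]
        assert pc.summary_a.median == pc.summary_b.median
        assert pc.p_adjusted == 1.0

    def test_calibrated_cohorts_detect_shorter_mutant_g1(self):
        """Samples at the reported cohort sizes (23 vs 34) from the
        G1 models separate clearly: mutant median lower, adjusted p < 0.05."""
        rng = np.random.default_rng(99)
        wt = _dur_table(_sample_model(NPC_WT, 23, rng))
        mut = _dur_table(_sample_model(NPC_MUT, 34, rng))
        rep = compare_cohorts(wt, mut, m_tests=2)
        pc = rep.phases["G1"]
        assert pc.summary_b.median < pc.summary_a.median
        assert pc.p_adjusted < 0.05
        assert "SG2M" not in rep.phases  # missing phase skipped, no crash

    def test_null_model_rejection_rate_near_alpha(self):
        """Type-I behavior: identical generating model for both cohorts
        gives ~alpha rejections and ~zero median difference on average."""
        rng = np.random.default_rng(5)
        rejections = 0
        diffs = []
        n_rep = 120
        for _ in range(n_rep):
            a = _dur_table(_sample_model(NPC_WT, 20, rng))
            b = _dur_table(_sample_model(NPC_WT, 20, rng))
            rep = compare_cohorts(a, b, m_tests=2)
            pc = rep.phases["G1"]
            rejections += pc.p_adjusted < 0.05
            diffs.append(pc.summary_a.median - pc.summary_b.median)
        # Bonferroni m=2 makes the per-phase level 0.025
        assert rejections / n_rep < 0.10
        assert abs(np.median(diffs)) < 0.2 * NPC_WT.g1_median_min

    def test_relabeling_cells_changes_nothing(self):
        rng = np.random.default_rng(8)
        vals = _sample_model(NPC_WT, 25, rng)
        a = _dur_table(vals)
        b = a.copy()
        b["cell_id"] = [f"z{i}" for i in range(len(b))][::-1]
        va = compare_cohorts(a, _dur_table(vals * 0.5)).phases["G1"]
        vb = compare_cohorts(b, _dur_table(vals * 0.5)).phases["G1"]
        assert va.test.p == vb.test.p

    def test_report_serialization(self):
        vals = np.linspace(10, 50, 12)
        rep = compare_cohorts(_dur_table(vals), _dur_table(vals + 5))
        d = rep.to_dict()
        assert "G1" in d["phases"]
        assert "U=" in rep.to_text()
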