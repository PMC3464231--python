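import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from ing4nfkb import (SimulationConfig, ValidationError,
                      gen_expression_cohort, hazard_ratio, km_curve,
                      logrank_test, roc_optimal_cutoff,
                      stratify_and_compare)


def random_survival(seed, n=40, censor=0.3):
    rng = np.random.default_rng(seed)
    t = rng.exponential(5.0, n)
    c = rng.exponential(5.0 / censor, n) if censor else np.full(n, np.inf)
    return np.minimum(t, c), t <= c


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.survival.tolist() == pytest.approx([2/3, 1/3, 0.0])

    def test_censoring_removes_drop(self):
        km = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.times.tolist() == [1.0, 3.0]
        assert km.survival.tolist() == pytest.approx([2/3, 0.0])

    def test_all_censored_curve_is_flat_one(self):
        km = km_curve([1.0, 2.0], [0, 0])
        assert km.times.size == 0
        assert km.survival_at([0.5, 5.0]).tolist() == [1.0, 1.0]

    def test_monotone_non_increasing_in_unit_interval(self):
        t, e = random_survival(1, n=100)
        km = km_curve(t, e)
        assert np.all(np.diff(km.survival) <= 0)
        assert np.all((km.survival >= 0) & (km.survival <= 1))
        assert np.all(np.diff(km.at_risk) < 0)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_lifelines(self, seed):
        t, e = random_survival(seed, n=60)
        km = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = km.survival_at(km.times)
        ref = kmf.predict(km.times).to_numpy()
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_rmst_of_flat_curve(self):
        km = km_curve([5.0], [0])
        assert km.rmst(4.0) == 4.0


class TestLogrank:
    def test_identical_groups_give_zero_chi2(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a"] * 3 + ["b"] * 3
        res = logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_tabulated_example(self):
        """Group A events at 1,2; group B at 3,4. At t=1: n=4, nA=2, so
        E1 += 1/2, V += 1/4; at t=2: n=3, nA=1, so E1 += 1/3, V += 2/9;
        later times have no A at risk. O1=2, E1=5/6, V=17/36,
        chi2 = (7/6)^2 / (17/36) = 49/17."""
        res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1],
                           ["A", "A", "B", "B"])
        assert res.o1 == 2.0
        assert res.e1 == pytest.approx(5 / 6)
        assert res.variance == pytest.approx(17 / 36)
        assert res.chi2 == pytest.approx(49 / 17)

    def test_oe_bookkeeping(self):
        t, e = random_survival(5, n=80)
        g = np.r_[np.zeros(40), np.ones(40)]
        res = logrank_test(t, e, g)
        assert res.o1 + res.o2 == pytest.approx(res.e1 + res.e2)
        assert res.chi2 >= 0

    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_matches_lifelines(self, seed):
        t, e = random_survival(seed, n=70)
        rng = np.random.default_rng(seed + 100)
        g = rng.integers(0, 2, 70)
        if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
            pytest.skip("degenerate draw")
        res = logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_label_swap_invariance(self):
        t, e = random_survival(9, n=50)
        g = np.r_[np.zeros(25), np.ones(25)]
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_permutation_null_is_uniform(self):
        """Permuting group labels gives p-values whose rejection rate at
        alpha=0.05 sits inside the binomial 99% band (1000 perms)."""
        t, e = random_survival(11, n=60, censor=0.2)
        rng = np.random.default_rng(11)
        base = np.r_[np.zeros(30), np.ones(30)]
        rejections = 0
        for _ in range(1000):
            g = rng.permutation(base)
            if logrank_test(t, e, g).p < 0.05:
                rejections += 1
        # 99% binomial band around 0.05 with n=1000: ~[0.032, 0.068]
        assert 0.025 <= rejections / 1000 <= 0.075

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [0, 0], ["a", "b"])


class TestHazardRatio:
    def test_mirror_groups_give_hr_one(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 0, 1, 1, 0, 1]
        g = ["a"] * 3 + ["b"] * 3
        res = hazard_ratio(t, e, g, exposed="a")
        assert res.hr == pytest.approx(1.0)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_label_swap_inverts_hr_exactly(self):
        t, e = random_survival(12, n=60)
        g = np.r_[np.zeros(30), np.ones(30)]
        a = hazard_ratio(t, e, g, exposed=0.0)
        b = hazard_ratio(t, e, g, exposed=1.0)
        assert a.hr * b.hr == pytest.approx(1.0, rel=1e-12)
        assert a.ci_low * b.ci_high == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("seed", [13, 14])
    def test_cox_fit_matches_lifelines(self, seed):
        t, e = random_survival(seed, n=80)
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 80).astype(float)
        res = hazard_ratio(t, e, x, exposed=1.0, method="cox")
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.log(res.hr) == pytest.approx(
            cph.params_["x"], abs=1e-6)

    def test_programmed_hazard_ratio_recovered(self):
        cfg = SimulationConfig(seed=21, true_hr=3.0, n_samples=1000,
                               n_signature_genes=2, n_filler_genes=0)
        cohort, truth = gen_expression_cohort(cfg)
        g = np.where(truth["ing4_low"], "low", "high")
        res = hazard_ratio(cohort.clinical["time"].to_numpy(),
                           cohort.clinical["event"].to_numpy(), g,
                           exposed="low", method="cox")
        assert 2.4 <= res.hr <= 3.75
        assert res.ci_low <= 3.0 <= res.ci_high


class TestRocCutoff:
    def test_perfect_separation(self):
        res = roc_optimal_cutoff([1.0, 2.0, 3.0, 4.0],
                                 [True, True, False, False])
        assert res.cutoff == 2.5
        assert res.youden_j == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_null_marker_j_near_zero_on_average(self):
        rng = np.random.default_rng(15)
        js = []
        for _ in range(100):
            x = rng.normal(size=30)
            y = rng.integers(0, 2, 30).astype(bool)
            if y.all() or not y.any():
                continue
            js.append(roc_optimal_cutoff(x, y).youden_j)
        # optimal-scan J is biased up under the null but stays modest
        assert 0.0 < np.mean(js) < 0.5

    def test_single_class_and_constant_marker_rejected(self):
        with pytest.raises(ValidationError):
            roc_optimal_cutoff([1.0, 2.0], [True, True])
        with pytest.raises(ValidationError):
            roc_optimal_cutoff([1.0, 1.0], [True, False])


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(seed=17, n_samples=500, beta=2.0,
                           true_hr=3.0, n_signature_genes=10,
                           n_filler_genes=5)
    return gen_expression_cohort(cfg)


class TestStratifyAndCompare:
    def test_low_marker_group_has_worse_survival(self, sim):
        cohort, _ = sim
        res = stratify_and_compare(cohort.expression("ING4"),
                                   cohort.clinical, "roc", exposed="low")
        tau = float(cohort.clinical["time"].max())
        assert res.km_low.rmst(tau) < res.km_high.rmst(tau)
        # group 1 is "high" (sorted labels): fewer events than expected
        assert res.logrank.o1 < res.logrank.e1
        assert res.hr.hr > 1.0

    def test_median_policy_equals_explicit_median(self, sim):
        cohort, _ = sim
        marker = cohort.expression("ING4")
        a = stratify_and_compare(marker, cohort.clinical, "median")
        b = stratify_and_compare(marker, cohort.clinical,
                                 float(np.median(marker)))
        assert a.cutoff == b.cutoff
        assert a.logrank.chi2 == pytest.approx(b.logrank.chi2)
        assert (a.groups == b.groups).all()

    def test_degenerate_cutoff_rejected(self, sim):
        cohort, _ = sim
        marker = cohort.expression("ING4")
        with pytest.raises(ValidationError):
            stratify_and_compare(marker, cohort.clinical,
                                 float(marker.max()) + 1)
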