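"""Statistical core: pooling, bootstrap, ANOVA, KDE, empirical P, calls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import f as f_dist
from sklearn.base import clone

from aninull.nulldist import (PooledNull, StrainNullClassifier,
                              bootstrap_sample, classify_pair, empirical_p,
                              fit_kde, oneway_anova, pool_ani, strain_anova)


class TestPooling:
    def test_counts_and_label_round_trip(self):
        per_strain = {f"s{i}": [99.9 + 0.001 * j for j in range(25)]
                      for i in range(4)}
        pool = pool_ani(per_strain, species="sp")
        assert len(pool.values) == 100
        regrouped = {}
        for label, v in pool.values:
            regrouped.setdefault(label, []).append(v)
        assert regrouped == per_strain

    def test_single_value_pool_allowed(self):
        pool = pool_ani({"s": [99.98]})
        assert len(pool.values) == 1
        with pytest.raises(ValueError):
            strain_anova(pool)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_ani({})
        with pytest.raises(ValueError):
            pool_ani({"s": []})


class TestBootstrap:
    def test_degenerate_source(self):
        out = bootstrap_sample([99.98], B=10_000, seed=1)
        assert len(out) == 10_000
        assert np.all(out == 99.98)

    def test_mean_within_clt_bound_over_seeds(self):
        rng = np.random.default_rng(2)
        values = rng.normal(99.95, 0.02, size=40)
        bound = 4 * values.std() / np.sqrt(10_000)
        for seed in range(50):
            boot = bootstrap_sample(values, B=10_000, seed=seed)
            assert abs(boot.mean() - values.mean()) <= bound

    def test_deterministic_under_seed(self):
        v = [1.0, 2.0, 3.0]
        assert np.array_equal(bootstrap_sample(v, 100, seed=3),
                              bootstrap_sample(v, 100, seed=3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sample([], B=10)


class TestAnova:
    def test_hand_computed_fixture(self):
        res = oneway_anova([np.array([1.0, 2, 3]), np.array([2.0, 3, 4])])
        assert res.f_statistic == pytest.approx(1.5)
        assert res.p_value == pytest.approx(1 - f_dist.cdf(1.5, 1, 4), abs=1e-9)
        assert res.p_value == pytest.approx(0.288, abs=5e-3)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_grand_mean_shift_invariance(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=6) for _ in range(3)]
        shifted = [g + 42.0 for g in groups]
        assert oneway_anova(groups).f_statistic == \
            pytest.approx(oneway_anova(shifted).f_statistic)

    def test_error_conditions_named(self):
        with pytest.raises(ValueError, match="two strain groups"):
            oneway_anova([np.array([1.0, 2.0])])
        with pytest.raises(ValueError, match="variance"):
            oneway_anova([np.array([1.0, 1.0]), np.array([1.0, 1.0])])


class TestKde:
    values = np.random.default_rng(5).normal(99.95, 0.02, size=30)

    def test_density_integrates_to_one(self):
        kde = fit_kde(self.values)
        integral = np.trapezoid(kde.density, kde.support)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_peak_at_mean_beats_far_tail(self):
        kde = fit_kde(self.values)
        m, s = self.values.mean(), self.values.std()
        assert kde.evaluate(m)[0] > kde.evaluate(m + 10 * s)[0]

    def test_doubling_bandwidth_lowers_peak(self):
        narrow = fit_kde(self.values, bandwidth_rule="silverman")
        factor = narrow.bandwidth / self.values.std(ddof=1)
        wide = fit_kde(self.values, bandwidth_rule=2 * factor)
        assert wide.density.max() < narrow.density.max()

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            fit_kde([99.98, 99.98, 99.98])


class TestEmpiricalP:
    def test_boundary_conventions(self):
        null = [99.0, 99.5, 99.9]
        assert empirical_p(null, 99.9) == 1.0       # at the max
        assert empirical_p(null, 100.0) == 1.0      # above the max
        assert empirical_p(null, 98.0) == 0.0       # below the min

    def test_equally_spaced_order_statistic(self):
        null = np.linspace(1, 100, 100)
        assert empirical_p(null, null[49]) == 0.50

    @given(st.lists(st.floats(min_value=0, max_value=100, allow_nan=False),
                    min_size=1, max_size=50),
           st.floats(min_value=-10, max_value=110, allow_nan=False))
    def test_matches_brute_force_count(self, null, obs):
        expected = sum(1 for v in null if v <= obs) / len(null)
        assert empirical_p(null, obs) == expected

    def test_monotone_in_observed(self):
        rng = np.random.default_rng(6)
        null = rng.normal(99.9, 0.05, size=200)
        obs = np.sort(rng.uniform(99.6, 100.0, size=50))
        ps = [empirical_p(null, o) for o in obs]
        assert all(b >= a for a, b in zip(ps, ps[1:]))


class TestClassifyPair:
    @pytest.mark.parametrize("p,expected", [
        (0.002, "different"),   # well below the lower threshold
        (1.0, "identical"),     # indistinguishable from the null
        (0.5, "related"),       # null hypothesis not rejected
        (0.95, "identical"),    # tie at the upper threshold
        (0.05, "related"),      # tie at the lower threshold
    ])
    def test_thresholds(self, p, expected):
        assert classify_pair(p) == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(0.5, p_low=0.9, p_high=0.1)
        with pytest.raises(ValueError):
            classify_pair(1.5)


class TestStrainNullClassifier:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(7)
        values = rng.normal(99.95, 0.02, size=100)
        labels = np.repeat([f"s{i}" for i in range(4)], 25)
        clf = StrainNullClassifier(random_state=0)
        return clf.fit(values, labels), values

    def test_sklearn_protocol(self, fitted):
        clf, _ = fitted
        params = clf.get_params()
        assert params["n_bootstrap"] == 10_000
        fresh = clone(clf)
        assert fresh.get_params() == params

    def test_fitted_attributes(self, fitted):
        clf, values = fitted
        assert len(clf.bootstrap_sample_) == 10_000
        assert set(clf.bootstrap_sample_) <= set(values)
        assert clf.kde_ is not None
        assert clf.anova_ is not None

    def test_predict_p_monotone_and_predict_categories(self, fitted):
        clf, values = fitted
        obs = [values.min() - 1.0, np.median(values), 100.0]
        p = clf.predict_p(obs)
        assert p[0] < 0.05 <= p[1] and p[2] == 1.0
        assert list(clf.predict(obs)) == ["different", "related", "identical"]

    def test_bootstrap_ecdf_converges_to_pool_ecdf(self):
        rng = np.random.default_rng(8)
        values = np.minimum(rng.normal(99.95, 0.02, size=100), 100.0)
        for seed in range(5):
            clf = StrainNullClassifier(random_state=seed).fit(values)
            for obs in np.quantile(values, [0.1, 0.35, 0.6, 0.85]):
                assert abs(clf.predict_p([obs])[0]
                           - empirical_p(values, obs)) <= 0.02

    def test_kde_tail_probabilities_option(self, fitted):
        clf, values = fitted
        clf2 = StrainNullClassifier(p_from="kde", random_state=0)
        clf2.fit(values)
        p = clf2.predict_p([np.median(values)])[0]
        assert 0.3 < p < 0.7

    def test_input_validation(self):
        clf = StrainNullClassifier()
        with pytest.raises(ValueError):
            clf.fit([])
        with pytest.raises(ValueError):
            clf.fit([101.0])
        with pytest.raises(ValueError):
            StrainNullClassifier(p_low=0.9, p_high=0.1).fit([99.9, 99.8])


def test_pooled_null_json_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    values = np.minimum(rng.normal(99.95, 0.02, size=20), 100.0)
    clf = StrainNullClassifier(random_state=1).fit(
        values, np.repeat(["a", "b"], 10))
    null = clf.to_pooled_null("sp")
    path = tmp_path / "null.json"
    null.to_json(path)
    back = PooledNull.from_json(path)
    assert back.species == "sp"
    assert np.allclose(back.ani_values, null.ani_values)
    assert np.allclose(back.bootstrap_sample, null.bootstrap_sample)
    assert back.anova.f_statistic == pytest.approx(null.anova.f_statistic)
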