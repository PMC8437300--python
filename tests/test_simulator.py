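import numpy as np
import pytest
from scipy import stats

from iusmmt.core_data import standardize
from iusmmt.simulator import (SCENARIO_PROPORTIONS, apply_censoring,
                              read_study, scenario_config,
                              simulate_expression,
                              simulate_methylation_block, simulate_study,
                              simulate_survival, write_study)


class TestMethylationBlock:
    def test_k_distribution_mean(self, rng):
        ks = [simulate_methylation_block(10, rng).k for _ in range(5000)]
        assert np.mean(ks) == pytest.approx(20.0, abs=0.2)
        assert min(ks) >= 10 and max(ks) <= 30

    def test_adjacent_correlation(self, rng):
        M = simulate_methylation_block(548, rng, k=25)
        adj = [np.corrcoef(M.values[:, j], M.values[:, j + 1])[0, 1]
               for j in range(24)]
        assert np.mean(adj) == pytest.approx(0.5, abs=0.05)

    def test_columns_standardized(self, rng):
        M = simulate_methylation_block(100, rng, k=12)
        np.testing.assert_allclose(M.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(M.values.std(axis=0, ddof=0), 1,
                                   atol=1e-12)


class TestExpression:
    def test_null_residual_distribution(self, rng):
        n = 10_000
        M = simulate_methylation_block(n, rng, k=10)
        X = np.column_stack([standardize(rng.standard_normal(n)),
                             standardize(rng.integers(1, 6, n).astype(
                                 float))])
        G = simulate_expression(M.values, X, 0.0, rng)
        resid = G - 0.5 * X[:, 0] - 0.5 * X[:, 1]
        assert stats.kstest(resid, "norm").pvalue > 0.01

    def test_signal_variance_grows_with_tau2(self, rng):
        n = 400
        M = simulate_methylation_block(n, rng, k=20)
        X = np.zeros((n, 2))
        var = {}
        for tau2 in (0.01, 0.08):
            vs = [np.var(simulate_expression(M.values, X, tau2, rng))
                  for _ in range(100)]
            var[tau2] = np.mean(vs)
        # var(G) = 1 + tau2 * E[a' Sigma a]; the signal part scales ~8x
        assert (var[0.08] - 1) / (var[0.01] - 1) == pytest.approx(8.0,
                                                                  rel=0.3)

    def test_deterministic_given_seed(self):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            M = simulate_methylation_block(50, rng, k=10)
            X = np.zeros((50, 2))
            out.append(simulate_expression(M.values, X, 0.05, rng))
        np.testing.assert_array_equal(out[0], out[1])


class TestSurvival:
    def test_unit_exponential_point(self):
        class FixedRng:
            def uniform(self, size=None):
                return np.full(size, np.exp(-1.0))
            def normal(self, *a, **k):
                return np.zeros(k.get("size", 1))
        M = np.zeros((1, 1))
        t = simulate_survival(M, np.zeros(1), np.zeros((1, 2)), beta=0.0,
                              tau3=0.0, rng=FixedRng(),
                              weibull_lambda=1.0, weibull_rho=1.0)
        assert t[0] == pytest.approx(1.0, rel=1e-12)

    def test_exponential_distribution_at_rho_one(self, rng):
        n = 10_000
        t = simulate_survival(np.zeros((n, 1)), np.zeros(n),
                              np.zeros((n, 2)), beta=0.0, tau3=0.0,
                              rng=rng, weibull_lambda=1.0,
                              weibull_rho=1.0)
        assert stats.kstest(t, "expon").pvalue > 0.01

    def test_larger_eta_gives_smaller_times(self, rng):
        n = 4000
        G = rng.standard_normal(n)
        t = simulate_survival(np.zeros((n, 1)), G, np.zeros((n, 2)),
                              beta=1.0, tau3=0.0, rng=rng)
        rho, _ = stats.spearmanr(G, t)
        assert rho < -0.3


class TestCensoring:
    def test_rate_zero(self, rng):
        t = rng.exponential(size=20) + 0.1
        out = apply_censoring(t, 0.0, rng)
        assert out.status.all()
        np.testing.assert_array_equal(out.time, t)

    def test_exact_count(self, rng):
        t = rng.exponential(size=548) + 0.1
        out = apply_censoring(t, 0.5, rng)
        assert (out.status == 0).sum() == 274

    def test_censored_before_event(self, rng):
        t = rng.exponential(size=100) + 0.1
        out = apply_censoring(t, 0.3, rng)
        cens = out.status == 0
        assert np.all(out.time[cens] < t[cens])


class TestStudy:
    def test_complete_null_labels(self):
        study = simulate_study(scenario_config("complete_null", n=30,
                                               S=20, seed=1))
        assert set(study.truth_labels) == {"00"}

    def test_sparse_alternative_label_counts(self):
        study = simulate_study(scenario_config("sparse_alternative",
                                               n=20, S=4000, seed=2))
        n11 = sum(l == "11" for l in study.truth_labels)
        sd = np.sqrt(4000 * 0.1 * 0.9)
        assert abs(n11 - 400) <= 3 * sd

    def test_deterministic_given_seed(self):
        a = simulate_study(scenario_config("dense_null", n=25, S=5,
                                           seed=11))
        b = simulate_study(scenario_config("dense_null", n=25, S=5,
                                           seed=11))
        for ga, gb in zip(a.genes, b.genes):
            np.testing.assert_array_equal(ga.methylation.values,
                                          gb.methylation.values)
            np.testing.assert_array_equal(ga.outcome.time,
                                          gb.outcome.time)
        assert a.truth_labels == b.truth_labels

    def test_labels_match_active_effects(self):
        # expression is standardized; labels with tau2 active must show
        # methylation-expression correlation on average
        study = simulate_study(scenario_config(
            "dense_alternative", n=300, S=40, seed=5, tau2=0.1))
        r2 = {"on": [], "off": []}
        for gd, lab in zip(study.genes, study.truth_labels):
            M = gd.methylation.values
            fitted = M @ np.linalg.lstsq(M, gd.expression, rcond=None)[0]
            key = "on" if lab in ("10", "11") else "off"
            r2[key].append(np.var(fitted) / np.var(gd.expression))
        assert r2["on"] and r2["off"]
        assert np.mean(r2["on"]) > np.mean(r2["off"]) + 0.05

    def test_scenario_truth_table(self):
        assert SCENARIO_PROPORTIONS["dense_null"] == (0.10, 0.85, 0.05,
                                                      0.00)
        assert SCENARIO_PROPORTIONS["sparse_alternative"][3] == 0.10

    def test_roundtrip_write_read(self, tmp_path):
        study = simulate_study(scenario_config("sparse_null", n=30, S=3,
                                               seed=7))
        write_study(study, tmp_path / "sim")
        back = read_study(tmp_path / "sim")
        assert back.truth_labels == study.truth_labels
        for ga, gb in zip(study.genes, back.genes):
            np.testing.assert_allclose(gb.methylation.values,
                                       ga.methylation.values, atol=1e-12)
            np.testing.assert_allclose(gb.expression, ga.expression,
                                       atol=1e-12)
            np.testing.assert_allclose(gb.outcome.time, ga.outcome.time)
            np.testing.assert_array_equal(gb.outcome.status,
                                          ga.outcome.status)
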