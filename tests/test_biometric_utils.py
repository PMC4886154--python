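"""HPD, PSRF, DIC, posterior summaries and the joint log-posterior density."""

import math

import numpy as np
import pandas as pd
import pytest

from twingxe.biometric import (ModelSpec, Priors, dic, gelman_rubin_psrf,
                               hpd_interval, joint_model_logposterior,
                               summarize_posterior)
from twingxe.irt import gpcm_category_probs


def brute_force_hpd(x, mass):
    """All-windows search used as the independent oracle."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    m = int(np.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if best is None or w < best[0]:
            best = (w, x[i], x[i + m - 1])
    return best[1], best[2]


class TestHpd:
    def test_constant_samples(self):
        assert hpd_interval([3.3] * 20) == (3.3, 3.3)

    def test_uniform_grid_matches_brute_force(self):
        x = np.arange(1000) / 1000.0
        lo, hi = hpd_interval(x, 0.95)
        assert (lo, hi) == brute_force_hpd(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.002)

    def test_matches_brute_force_on_random_samples(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, int(rng.integers(5, 200)))
            mass = rng.uniform(0.5, 0.99)
            assert hpd_interval(x, mass) == brute_force_hpd(x, mass)

    def test_standard_normal_limit(self, rng):
        x = rng.normal(0, 1, 400_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            hpd_interval([])


class TestPsrf:
    def test_identical_chains(self):
        c = np.tile(np.arange(100.0), (3, 1))
        assert gelman_rubin_psrf(c) == pytest.approx(math.sqrt(99 / 100))

    def test_separated_chains(self):
        rngs = np.random.default_rng(0)
        c = np.stack([rngs.normal(0, 0.01, 50), rngs.normal(100, 0.01, 50)])
        assert gelman_rubin_psrf(c) > 100

    def test_matches_independent_formula_oracle(self, rng):
        for _ in range(10):
            m, n = int(rng.integers(2, 6)), int(rng.integers(10, 200))
            c = rng.normal(0, 1, (m, n)) + rng.normal(0, 0.3, (m, 1))
            # independent re-derivation from chain means and variances
            means = c.mean(axis=1)
            w = sum(((c[i] - means[i]) ** 2).sum() / (n - 1) for i in range(m)) / m
            b = n * ((means - means.mean()) ** 2).sum() / (m - 1)
            oracle = math.sqrt(((n - 1) / n * w + b / n) / w)
            assert gelman_rubin_psrf(c) == pytest.approx(oracle, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            gelman_rubin_psrf(np.zeros((1, 10)))
        with pytest.raises(ValueError):
            gelman_rubin_psrf(np.ones((3, 10)))


class TestDic:
    def test_arithmetic(self):
        d = np.full(20, 100.0)
        d[0] = 100.0
        val, pd_ = dic(d, 90.0)
        assert pd_ == pytest.approx(10.0)
        assert val == pytest.approx(110.0)

    def test_constant_shift_preserves_differences(self, rng):
        d1 = rng.normal(500, 5, 50)
        d2 = rng.normal(520, 5, 50)
        dic1, _ = dic(d1, 490.0)
        dic2, _ = dic(d2, 510.0)
        c = 37.0
        dic1s, pd1s = dic(d1 + c, 490.0 + c)
        dic2s, _ = dic(d2 + c, 510.0 + c)
        assert dic1s - dic1 == pytest.approx(c)      # pD is shift-invariant
        assert pd1s == pytest.approx(d1.mean() - 490.0)
        assert (dic2s - dic1s) == pytest.approx(dic2 - dic1)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            dic(np.arange(5.0), 1.0)


class TestSummaries:
    def test_heritability_single_draw(self):
        chains = {"sigma2_A": [[0.43]], "gamma0": [[math.log(0.29)]],
                  "beta0": [[math.log(0.07)]], "beta1": [[-2.81]],
                  "gamma1": [[0.54]]}
        s = summarize_posterior(chains)
        assert s.loc["h2", "mean"] == pytest.approx(0.43 / 0.79, abs=1e-6)

    def test_hpd_excluding_zero_flagged_significant(self, rng):
        chains = {"gamma1": rng.uniform(0.31, 0.84, (2, 500))}
        s = summarize_posterior(chains)
        assert bool(s.loc["gamma1", "significant"])
        chains = {"beta1": rng.uniform(-0.2, 0.5, (2, 500))}
        assert not bool(summarize_posterior(chains).loc["beta1", "significant"])

    def test_constant_chain_degenerate(self):
        s = summarize_posterior({"x": np.full((2, 50), 1.5)})
        assert s.loc["x", "sd"] == 0
        assert s.loc["x", "hpd_low"] == s.loc["x", "hpd_high"] == 1.5


class TestJointLogPosterior:
    def _tiny_data(self, y=None):
        rows = []
        vals = y if y is not None else [[0, 2], [1, 1], [2, 0], [0, 1]]
        for i, (fam, zyg, twin) in enumerate([(1, "MZ", 1), (1, "MZ", 2),
                                              (2, "DZ", 1), (2, "DZ", 2)]):
            rows.append({"family_id": fam, "zygosity": zyg, "twin": twin,
                         "item_1": vals[i][0], "item_2": vals[i][1]})
        return pd.DataFrame(rows)

    def _state(self):
        return {
            "theta": np.array([0.3, -0.2, 0.5, 0.1]),
            "A_mz": np.array([0.2]), "C_mz": np.array([-0.1]),
            "A1": np.array([0.1]), "A2": np.array([[0.15, 0.05]]),
            "C_dz": np.array([0.4]),
            "sigma2_A": 0.5, "beta0": -1.5, "beta1": -0.5,
            "gamma0": -1.0, "gamma1": 0.3,
            "log_alpha": np.array([0.1, 0.0]),
            "b1": np.array([-0.4, 0.2]), "b2": np.array([0.3, -0.1]),
        }

    def test_item_block_matches_multinomial_enumeration(self):
        # difference between full data and all-missing data isolates the
        # measurement block, which must equal the sum of GPCM log pmfs
        data = self._tiny_data()
        blank = self._tiny_data([[np.nan] * 2] * 4)
        state = self._state()
        spec = ModelSpec(True, True)
        diff = (joint_model_logposterior(state, data, spec, alpha_ref_index=1)
                - joint_model_logposterior(state, blank, spec, alpha_ref_index=1))
        oracle = 0.0
        yvals = [[0, 2], [1, 1], [2, 0], [0, 1]]
        for i, th in enumerate(state["theta"]):
            for k in range(2):
                p = gpcm_category_probs(
                    th, alpha=np.exp(state["log_alpha"][k]),
                    b1=state["b1"][k], b2=state["b2"][k])
                oracle += math.log(p[yvals[i][k]])
        assert diff == pytest.approx(oracle, abs=1e-10)

    def test_all_missing_individual_contributes_nothing(self):
        data = self._tiny_data()
        data.loc[0, ["item_1", "item_2"]] = np.nan
        state = self._state()
        lp_missing = joint_model_logposterior(state, data, alpha_ref_index=1)
        # removing that individual's cells changes only the item block
        assert np.isfinite(lp_missing)

    def test_out_of_support_and_nan(self):
        data = self._tiny_data()
        state = self._state()
        state["sigma2_A"] = -0.1
        assert joint_model_logposterior(state, data,
                                        alpha_ref_index=1) == -np.inf
        state["sigma2_A"] = float("nan")
        with pytest.raises(ValueError):
            joint_model_logposterior(state, data, alpha_ref_index=1)

    def test_latent_terms_match_manual_gaussians(self):
        # with items removed, the density is a sum of normal log pdfs
        from scipy.stats import norm

        blank = self._tiny_data([[np.nan] * 2] * 4)
        st = self._state()
        spec = ModelSpec(True, True)
        pr = Priors()
        lp = joint_model_logposterior(st, blank, spec, pr, alpha_ref_index=1)
        th = st["theta"]
        A, C = st["A_mz"][0], st["C_mz"][0]
        s2a, b0, b1, g0, g1 = (st["sigma2_A"], st["beta0"], st["beta1"],
                               st["gamma0"], st["gamma1"])
        manual = 0.0
        manual += norm.logpdf(A, 0, math.sqrt(s2a))
        manual += norm.logpdf(C, 0, math.sqrt(math.exp(g0 + g1 * A)))
        manual += norm.logpdf(th[:2], A + C,
                              math.sqrt(math.exp(b0 + b1 * A))).sum()
        A1, A2, Cd = st["A1"][0], st["A2"][0], st["C_dz"][0]
        manual += norm.logpdf(A1, 0, math.sqrt(s2a / 2))
        manual += norm.logpdf(A2, A1, math.sqrt(s2a / 2)).sum()
        manual += norm.logpdf(Cd, 0, 1)
        s = np.sqrt(np.exp(g0 + g1 * A2))
        manual += norm.logpdf(th[2:], A2 + Cd * s,
                              np.sqrt(np.exp(b0 + b1 * A2))).sum()
        # item-parameter priors on the blank-data path
        manual += -0.5 * st["log_alpha"][0] ** 2 / pr.log_alpha_var
        manual += -0.5 * ((st["b1"] ** 2).sum() + (st["b2"] ** 2).sum()) / pr.threshold_var
        # parameter priors (inverse gamma kernel and normals, up to constants)
        manual += (-(pr.sigma2_a_shape + 1) * math.log(s2a)
                   - pr.sigma2_a_scale / s2a)
        manual += -0.5 * (b0 - pr.intercept_mean) ** 2 / pr.intercept_var
        manual += -0.5 * (g0 - pr.intercept_mean) ** 2 / pr.intercept_var
        manual += -0.5 * (b1 ** 2 + g1 ** 2) / pr.slope_var
        assert lp == pytest.approx(manual, abs=1e-9)
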