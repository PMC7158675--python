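import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from netqap import (
    DyadicMatrix,
    PermutationEngine,
    ValidationError,
    lrqap,
    mrqap_dsp,
    node_permute,
    qap_correlation,
    significance_stars,
)
from netqap.net_model import DyadDesign, devectorize, dyad_index, vectorize

from conftest import random_hollow

TIE_EPS = 1e-12  # same tie rule as the implementation's null counts


def _design(y, predictors, n):
    return DyadDesign(
        response=y,
        predictors=predictors,
        dyad_index=dyad_index(n),
    )


class TestNodePermute:
    def test_identity_leaves_matrix_unchanged(self):
        m = DyadicMatrix(values=random_hollow(np.random.default_rng(0), 4), label="m")
        assert np.array_equal(node_permute(m, np.arange(4)).values, m.values)

    def test_inverse_recovers_original(self):
        rng = np.random.default_rng(1)
        m = DyadicMatrix(values=random_hollow(rng, 6), label="m")
        perm = rng.permutation(6)
        inverse = np.argsort(perm)
        assert np.array_equal(
            node_permute(node_permute(m, perm), inverse).values, m.values
        )

    def test_swap_moves_cells_as_hand_checked(self):
        values = np.arange(9, dtype=float).reshape(3, 3)
        np.fill_diagonal(values, 0)
        m = DyadicMatrix(values=values, label="m")
        swapped = node_permute(m, [1, 0, 2]).values
        assert swapped[1, 0] == values[0, 1]
        assert swapped[0, 1] == values[1, 0]
        assert swapped[1, 2] == values[0, 2]
        assert swapped[2, 1] == values[2, 0]

    def test_non_bijection_rejected(self):
        m = DyadicMatrix(values=np.zeros((3, 3)), label="m")
        with pytest.raises(ValidationError, match="bijection"):
            node_permute(m, [0, 0, 2])


class TestQapCorrelation:
    def test_self_correlation_is_one(self):
        m = random_hollow(np.random.default_rng(3), 6, binary=True)
        res = qap_correlation(m, m, PermutationEngine(n_permutations=50, seed=0))
        assert res.r_obs == pytest.approx(1.0)

    def test_zero_variance_flagged_degenerate(self):
        const = np.zeros((5, 5))
        other = random_hollow(np.random.default_rng(4), 5)
        res = qap_correlation(const, other, PermutationEngine(n_permutations=20, seed=0))
        assert res.degenerate and np.isnan(res.r_obs)

    @pytest.mark.parametrize("seed", range(3))
    def test_exhaustive_matches_full_enumeration(self, seed):
        """The exhaustive engine reproduces an independent 120-permutation
        enumeration of the n=5 null exactly."""
        rng = np.random.default_rng(seed)
        m1 = random_hollow(rng, 5, binary=True)
        m2 = random_hollow(rng, 5, binary=True)
        res = qap_correlation(m1, m2, PermutationEngine(mode="exhaustive"))
        v1 = vectorize(m1)
        r_obs = stats.pearsonr(v1, vectorize(m2)).statistic
        count = sum(
            abs(
                stats.pearsonr(v1, vectorize(m2[np.ix_(np.array(p), np.array(p))])).statistic
            )
            >= abs(r_obs) - TIE_EPS
            for p in itertools.permutations(range(5))
        )
        assert res.r_obs == pytest.approx(r_obs)
        assert res.p_two_sided == pytest.approx(count / 120)

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        m1, m2 = random_hollow(rng, 8), random_hollow(rng, 8)
        engine = lambda s: PermutationEngine(n_permutations=300, seed=s)
        p_a = qap_correlation(m1, m2, engine(5)).p_two_sided
        p_b = qap_correlation(m1, m2, engine(5)).p_two_sided
        assert p_a == p_b

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(10)
        m1 = random_hollow(rng, 5, binary=True)
        m2 = random_hollow(rng, 5, binary=True)
        p_ex = qap_correlation(m1, m2, PermutationEngine(mode="exhaustive")).p_two_sided
        n_mc = 4000
        p_mc = qap_correlation(
            m1, m2, PermutationEngine(n_permutations=n_mc, seed=1)
        ).p_two_sided
        se = np.sqrt(p_ex * (1 - p_ex) / n_mc)
        assert abs(p_mc - p_ex) <= 3 * se + 1 / n_mc


class TestMrqapDsp:
    def test_point_estimates_match_textbook_ols(self):
        rng = np.random.default_rng(11)
        n = 8
        x1, x2 = random_hollow(rng, n), random_hollow(rng, n, binary=True)
        y = 0.5 * x1 - 1.2 * x2 + random_hollow(rng, n)
        design = _design(
            vectorize(y), {"x1": vectorize(x1), "x2": vectorize(x2)}, n
        )
        res = mrqap_dsp(design, PermutationEngine(n_permutations=10, seed=0))
        fit = sm.OLS(
            design.response, sm.add_constant(np.column_stack([design.predictors["x1"], design.predictors["x2"]]))
        ).fit()
        assert res.coefficients["Intercept"] == pytest.approx(fit.params[0])
        assert res.coefficients["x1"] == pytest.approx(fit.params[1])
        assert res.coefficients["x2"] == pytest.approx(fit.params[2])
        assert res.fit_stat == pytest.approx(fit.rsquared)

    @pytest.mark.parametrize("seed", range(2))
    def test_exhaustive_single_predictor_matches_enumeration(self, seed):
        """DSP p for one predictor equals brute-force enumeration of all 120
        node permutations of the centred-predictor residual matrix."""
        rng = np.random.default_rng(seed)
        x = random_hollow(rng, 5)
        y = vectorize(random_hollow(rng, 5))
        xv = vectorize(x)
        design = _design(y, {"x": xv}, 5)
        res = mrqap_dsp(design, PermutationEngine(mode="exhaustive"))

        e = xv - xv.mean()
        e_mat = devectorize(e, 5)

        def t_of(u):
            return sm.OLS(y, sm.add_constant(u)).fit().tvalues[1]

        t_obs = t_of(e)
        count = sum(
            abs(t_of(vectorize(e_mat[np.ix_(np.array(p), np.array(p))])))
            >= abs(t_obs) - TIE_EPS
            for p in itertools.permutations(range(5))
        )
        assert res.p_values["x"] == pytest.approx(count / 120)

    def test_single_predictor_agrees_with_qap_correlation(self):
        """With one predictor the DSP t statistic is a monotone function of
        the correlation, so exhaustive p-values and signs coincide."""
        rng = np.random.default_rng(21)
        x = random_hollow(rng, 5, binary=True)
        y_mat = random_hollow(rng, 5, binary=True)
        design = _design(vectorize(y_mat), {"x": vectorize(x)}, 5)
        engine = PermutationEngine(mode="exhaustive")
        reg = mrqap_dsp(design, engine)
        corr = qap_correlation(y_mat, x, engine)
        assert np.sign(reg.coefficients["x"]) == np.sign(corr.r_obs)
        assert reg.p_values["x"] == pytest.approx(corr.p_two_sided)

    def test_perfect_collinearity_names_the_pair(self):
        rng = np.random.default_rng(13)
        x = random_hollow(rng, 6)
        design = _design(
            vectorize(random_hollow(rng, 6)),
            {"a": vectorize(x), "b": 2 * vectorize(x), "c": vectorize(random_hollow(rng, 6))},
            6,
        )
        with pytest.raises(ValidationError, match="'a' and 'b'"):
            mrqap_dsp(design, PermutationEngine(n_permutations=10, seed=0))


class TestLrqap:
    @staticmethod
    def _binary_design(seed, n=8, k=2):
        rng = np.random.default_rng(seed)
        preds = {f"x{i}": vectorize(random_hollow(rng, n, binary=True)) for i in range(k)}
        outcome = rng.integers(0, 2, size=n)
        y = vectorize((outcome[:, None] == outcome[None, :]).astype(float))
        return _design(y, preds, n)

    def test_coefficients_match_statsmodels_logit(self):
        design = self._binary_design(17)
        res = lrqap(design, PermutationEngine(n_permutations=10, seed=0))
        x = sm.add_constant(np.column_stack(list(design.predictors.values())))
        fit = sm.Logit(design.response, x).fit(disp=0)
        got = np.array(list(res.coefficients.values()))
        assert np.allclose(got, fit.params, atol=1e-6)
        assert res.fit_stat == pytest.approx(fit.prsquared, abs=1e-6)

    def test_odds_ratios_are_exp_of_coefficients(self):
        design = self._binary_design(19, k=3)
        res = lrqap(design, PermutationEngine(n_permutations=20, seed=1))
        for name, b in res.coefficients.items():
            assert res.odds_ratios[name] == np.exp(b)

    def test_non_binary_response_rejected(self):
        design = self._binary_design(23)
        design.response[0] = 0.5
        with pytest.raises(ValidationError, match="binary"):
            lrqap(design, PermutationEngine(n_permutations=5, seed=0))

    def test_constant_response_rejected(self):
        design = self._binary_design(23)
        design.response[:] = 1.0
        with pytest.raises(ValidationError, match="constant"):
            lrqap(design, PermutationEngine(n_permutations=5, seed=0))

    def test_dsp_scheme_reported_separately(self):
        design = self._binary_design(29)
        engine = PermutationEngine(n_permutations=50, seed=2)
        res_y = lrqap(design, engine, scheme="y_permute")
        res_d = lrqap(design, engine, scheme="dsp")
        assert res_y.scheme == "y_permute" and res_d.scheme == "dsp"
        # same ML fit regardless of permutation scheme
        assert res_y.coefficients == res_d.coefficients

    def test_seed_determinism(self):
        design = self._binary_design(31)
        engine = PermutationEngine(n_permutations=200, seed=9)
        a = lrqap(design, engine)
        b = lrqap(design, engine)
        assert a.p_values == b.p_values and a.model_p == b.model_p


class TestEngineAndStars:
    def test_exhaustive_limited_to_small_networks(self):
        with pytest.raises(ValidationError, match="exhaustive"):
            PermutationEngine(mode="exhaustive").permutations(9)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            PermutationEngine(mode="bootstrap")

    @pytest.mark.parametrize(
        "p,expected", [(0.03, "**"), (0.05, "**"), (0.07, "*"), (0.1, "*"), (0.5, "")]
    )
    def test_star_convention(self, p, expected):
        assert significance_stars(p) == expected

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_range_p_rejected(self, p):
        with pytest.raises(ValidationError):
            significance_stars(p)
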