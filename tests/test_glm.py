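"""GLM engine tests: fitting, distributions, diagnostics, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_hurdle_frame, make_nb_frame, nb_design
from whalekrill import glm
from whalekrill.glm import DesignSpec, Term


class TestDesignSpec:
    def test_polynomial_includes_lower_orders(self):
        cols = Term("depth", "quartic").design_columns()
        assert cols == ["depth", "depth^2", "depth^3", "depth^4"]

    def test_lagged_climate_column(self):
        assert Term("soi", "linear", lag=2).column == "soi_lag2"

    def test_duplicate_covariates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DesignSpec("y", [Term("x"), Term("x", "quadratic")])

    def test_offset_enters_as_log(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "x": [0.0, 1.0], "eff": [1.0, np.e]})
        _, _, off = DesignSpec("y", [Term("x")], offset="eff").build(df)
        np.testing.assert_allclose(off, [0.0, 1.0])

    def test_nonpositive_offset_rejected(self):
        df = pd.DataFrame({"y": [1.0], "x": [0.0], "eff": [0.0]})
        with pytest.raises(ValueError, match="positive"):
            DesignSpec("y", [Term("x")], offset="eff").build(df)


class TestNegbin:
    def test_parameter_recovery(self):
        df = make_nb_frame(seed=1, n=5000, beta=(1.0, 0.5), theta=2.0)
        fit = glm.fit_negbin(nb_design(), df)
        for name, truth in [("const", 1.0), ("x", 0.5)]:
            assert abs(fit.params[name] - truth) < 3 * fit.bse[name]
        assert fit.theta == pytest.approx(2.0, rel=0.20)

    def test_poisson_limit(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=4000)
        y = rng.poisson(np.exp(1.0 + 0.4 * x))
        df = pd.DataFrame({"x": x, "y": y})
        fit = glm.fit_negbin(nb_design(), df)
        assert fit.theta > 50
        from statsmodels.discrete.discrete_model import Poisson

        pois = Poisson(y, np.column_stack([np.ones(4000), x])).fit(disp=0)
        assert abs(fit.params["const"] - pois.params[0]) < 1e-2
        assert abs(fit.params["x"] - pois.params[1]) < 1e-2

    def test_all_zero_response_rejected(self):
        df = pd.DataFrame({"x": np.arange(20.0), "y": np.zeros(20, dtype=int)})
        with pytest.raises(ValueError, match="all zeros"):
            glm.fit_negbin(nb_design(), df)

    def test_bitwise_reproducible(self):
        df = make_nb_frame(seed=3, n=1000)
        a = glm.fit_negbin(nb_design(), df)
        b = glm.fit_negbin(nb_design(), df)
        assert (a.params == b.params).all()
        assert a.llf == b.llf

    def test_offset_shifts_intercept(self):
        df = make_nb_frame(seed=4, n=3000, beta=(1.0, 0.5), theta=2.0)
        df["eff"] = np.e  # constant effort e => log-offset of 1
        fit = glm.fit_negbin(DesignSpec("y", [Term("x")], offset="eff"), df)
        assert fit.params["const"] == pytest.approx(0.0, abs=0.15)


class TestInformationCriteria:
    def test_aic_bic_against_hand_loglik(self):
        # 5-point intercept-only logistic: ll = 3 log(3/5) + 2 log(2/5)
        df = pd.DataFrame({"y": [1, 0, 0, 1, 1], "z": np.zeros(5)})
        fit = glm.fit_logistic(DesignSpec("y", [], family="logistic"), df)
        ll = 3 * np.log(0.6) + 2 * np.log(0.4)
        assert fit.llf == pytest.approx(ll, abs=1e-8)
        assert fit.aic == pytest.approx(2 * 1 - 2 * ll)
        assert fit.bic == pytest.approx(np.log(5) * 1 - 2 * ll)

    def test_nb_aic_counts_dispersion(self):
        df = make_nb_frame(seed=5, n=500)
        fit = glm.fit_negbin(nb_design(), df)
        assert fit.k_params == 3  # const, x, theta
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.llf)


class TestHurdle:
    def test_parameter_recovery(self):
        df = make_hurdle_frame(seed=6, n=5000, gamma=(-0.5, 1.0),
                               beta=(2.0, 0.8), theta=1.5)
        zero = DesignSpec("y", [Term("x")], family="logistic")
        count = DesignSpec("y", [Term("x")], family="trunc-negbin")
        h = glm.fit_hurdle(zero, count, df)
        for part, truths in [(h.zero, {"const": -0.5, "x": 1.0}),
                             (h.count, {"const": 2.0, "x": 0.8})]:
            for name, val in truths.items():
                assert abs(part.params[name] - val) < 3 * part.bse[name]
        assert h.count.theta == pytest.approx(1.5, rel=0.25)

    def test_combined_information_criteria(self):
        df = make_hurdle_frame(seed=7, n=800)
        zero = DesignSpec("y", [Term("x")], family="logistic")
        count = DesignSpec("y", [Term("x")], family="trunc-negbin")
        h = glm.fit_hurdle(zero, count, df)
        assert h.llf == pytest.approx(h.zero.llf + h.count.llf)
        assert h.k_params == h.zero.k_params + h.count.k_params
        assert h.aic == pytest.approx(2 * h.k_params - 2 * h.llf)

    def test_no_zeros_degenerates_zero_part_only(self):
        df = make_hurdle_frame(seed=8, n=500)
        df = df[df.y > 0].reset_index(drop=True)
        zero = DesignSpec("y", [Term("x")], family="logistic")
        count = DesignSpec("y", [Term("x")], family="trunc-negbin")
        h = glm.fit_hurdle(zero, count, df)
        assert h.zero is None and "zero" in h.errors
        assert h.count is not None

    def test_ztnb_pmf_normalizes(self):
        y = np.arange(1, 2000)
        total = glm.ztnb_pmf(y, mu=3.0, theta=2.0).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_hurdle_mean_matches_monte_carlo(self):
        from whalekrill.synthetic import sample_ztnb

        pi, mu, theta = 0.6, 3.0, 2.0
        rng = np.random.default_rng(9)
        n = 400_000
        present = rng.uniform(size=n) < pi
        y = np.zeros(n)
        y[present] = sample_ztnb(np.full(present.sum(), mu), theta, rng)
        assert y.mean() == pytest.approx(
            float(glm.hurdle_mean(pi, mu, theta)), rel=0.01
        )

    def test_observed_zero_fraction_matches_logistic_part(self):
        df = make_hurdle_frame(seed=10, n=5000)
        p = 1.0 / (1.0 + np.exp(-(-0.5 + 1.0 * df.x)))
        assert (df.y == 0).mean() == pytest.approx(1 - p.mean(), abs=0.02)


class TestZinb:
    def test_no_excess_zeros_reduces_to_nb(self):
        df = make_nb_frame(seed=11, n=5000, beta=(1.0, 0.5), theta=2.0)
        nb = glm.fit_negbin(nb_design(), df)
        zi = glm.fit_zinb(nb_design(), df)
        pi_hat = float(glm.zinb_inflation_probs(zi))
        assert pi_hat < 0.05
        assert abs(zi.params["x"] - nb.params["x"]) < 1e-2

    def test_inflation_probability_recovery(self):
        rng = np.random.default_rng(12)
        n = 5000
        x = rng.normal(size=n)
        mu = np.exp(1.2 + 0.5 * x)
        theta = 2.0
        y = rng.negative_binomial(theta, theta / (theta + mu))
        y[rng.uniform(size=n) < 0.3] = 0
        df = pd.DataFrame({"x": x, "y": y})
        zi = glm.fit_zinb(nb_design(), df)
        assert 0.25 <= float(glm.zinb_inflation_probs(zi)) <= 0.35

    def test_all_zero_response_rejected(self):
        df = pd.DataFrame({"x": np.arange(30.0), "y": np.zeros(30, dtype=int)})
        with pytest.raises(ValueError, match="all zeros"):
            glm.fit_zinb(nb_design(), df)


class TestVuong:
    def test_self_comparison_is_null(self):
        df = make_nb_frame(seed=13, n=300)
        fit = glm.fit_negbin(nb_design(), df)
        z, p, pref = glm.vuong_test(fit, fit)
        assert (z, p, pref) == (0.0, 1.0, "neither")

    def test_mismatched_observations_rejected(self):
        a = glm.fit_negbin(nb_design(), make_nb_frame(seed=14, n=300))
        b = glm.fit_negbin(nb_design(), make_nb_frame(seed=14, n=200))
        with pytest.raises(ValueError, match="different observation"):
            glm.vuong_test(a, b)

    def test_power_against_strong_inflation(self):
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(600 + s)
            n = 3000
            x = rng.normal(size=n)
            mu = np.exp(1.0 + 0.5 * x)
            y = rng.negative_binomial(1.5, 1.5 / (1.5 + mu))
            y[rng.uniform(size=n) < 0.5] = 0
            df = pd.DataFrame({"x": x, "y": y})
            nb = glm.fit_negbin(nb_design(), df)
            zi = glm.fit_zinb(nb_design(), df)
            _, _, pref = glm.vuong_test(zi, nb)
            wins += pref == "a"
        assert wins >= 9


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        rng = np.random.default_rng(15)
        z = rng.normal(size=(100, 3))
        q, _ = np.linalg.qr(z - z.mean(axis=0))  # orthogonal, zero-mean
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        assert np.allclose(glm.vif(X), 1.0, atol=1e-8)

    def test_duplicated_column_infinite_vif(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        v = glm.vif(X)
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_known_correlation_closed_form(self):
        # construct exact sample correlation 0.9 => VIF = 1/(1-0.81)
        rng = np.random.default_rng(17)
        z = rng.normal(size=(200, 2))
        z -= z.mean(axis=0)
        q, _ = np.linalg.qr(z)
        x1 = q[:, 0]
        x2 = 0.9 * q[:, 0] + np.sqrt(1 - 0.81) * q[:, 1]
        v = glm.vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert v["x1"] == pytest.approx(1 / (1 - 0.81), rel=1e-6)

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            glm.vif(pd.DataFrame({"a": [1.0, 2.0]}))


class TestMoransI:
    def test_checkerboard_negative_autocorrelation(self):
        xs, ys = np.meshgrid(np.arange(8.0), np.arange(8.0))
        loc = np.column_stack([xs.ravel(), ys.ravel()])
        res = ((xs + ys) % 2 * 2 - 1).ravel()  # +-1 checkerboard
        m = glm.morans_i(res, loc, weights=1.0)  # rook neighbours
        assert m.I < 0 and m.p < 0.01

    def test_smooth_field_positive_autocorrelation(self):
        from whalekrill.synthetic import simulate_field

        rng = np.random.default_rng(18)
        loc = rng.uniform(0, 20, size=(200, 2))
        res = simulate_field(loc, 1.0, 8.0, seed=19)
        m = glm.morans_i(res, loc)
        assert m.I > 0 and m.p < 0.01

    def test_expected_value(self):
        rng = np.random.default_rng(20)
        m = glm.morans_i(rng.normal(size=50), rng.uniform(0, 10, (50, 2)))
        assert m.expected == pytest.approx(-1 / 49)

    def test_constant_residuals_undefined(self):
        rng = np.random.default_rng(21)
        m = glm.morans_i(np.ones(20), rng.uniform(0, 10, (20, 2)))
        assert not m.defined and np.isnan(m.I)


class TestNagelkerke:
    def test_equal_likelihoods_zero(self):
        assert glm.nagelkerke_r2(-100.0, -100.0, 50) == 0.0

    def test_hand_computed_case(self):
        val = glm.nagelkerke_r2(-100.0, -120.0, 100)
        assert val == pytest.approx((1 - np.exp(-0.4)) / (1 - np.exp(-2.4)), abs=1e-9)

    def test_saturated_limit_approaches_one(self):
        # fitted log-likelihood -> 0 (perfect fit) drives R2 -> 1
        assert glm.nagelkerke_r2(-1e-9, -120.0, 100) == pytest.approx(1.0, abs=1e-6)

    def test_worse_than_null_warns(self):
        with pytest.warns(UserWarning, match="optimizer failure"):
            val = glm.nagelkerke_r2(-130.0, -120.0, 100)
        assert val < 0


class LstsqFitter:
    """Plain least-squares fitter used to exercise the CV machinery."""

    def __init__(self, frame):
        X = np.column_stack([np.ones(len(frame)), frame.x])
        self.beta, *_ = np.linalg.lstsq(X, frame.y, rcond=None)

    def predict(self, frame):
        return self.beta[0] + self.beta[1] * frame.x


class TestKfoldCV:
    def test_noiseless_linear_zero_test_error(self):
        df = pd.DataFrame({"x": np.linspace(0, 1, 60)})
        df["y"] = 2.0 + 3.0 * df.x
        rep = glm.kfold_cv(LstsqFitter, df, "y", k=10, runs=3, seed=0)
        assert rep.rmse_test < 1e-9 and rep.mae_test < 1e-9

    def test_same_seed_identical_report(self):
        df = make_nb_frame(seed=22, n=300)
        fitter = lambda fr: glm.fit_negbin(nb_design(), fr)
        a = glm.kfold_cv(fitter, df, "y", k=5, runs=2, seed=3)
        b = glm.kfold_cv(fitter, df, "y", k=5, runs=2, seed=3)
        assert a == b

    def test_generalization_gap_on_overfit_prone_fit(self):
        # 8 spurious covariates at n=100: held-out error exceeds training
        # error in the clear majority of replicates
        wins = 0
        n_rep = 20
        for s in range(n_rep):
            rng = np.random.default_rng(700 + s)
            df = pd.DataFrame(
                {f"x{i}": rng.normal(size=100) for i in range(8)}
            )
            df["x"] = rng.normal(size=100)
            df["y"] = rng.negative_binomial(2.0, 2.0 / (2.0 + np.exp(1.0)), 100)
            spec = DesignSpec("y", [Term(f"x{i}") for i in range(8)] + [Term("x")])
            rep = glm.kfold_cv(
                lambda fr: glm.fit_negbin(spec, fr), df, "y", k=5, runs=1, seed=s
            )
            wins += rep.rmse_test >= rep.rmse_training
        assert wins > n_rep / 2

    def test_n_smaller_than_k_rejected(self):
        df = make_nb_frame(seed=23, n=5)
        with pytest.raises(ValueError, match="k="):
            glm.kfold_cv(LstsqFitter, df, "y", k=10, runs=1, seed=0)
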