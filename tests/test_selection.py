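"""Covariate-selection protocol tests: screening, stepwise, interactions."""

import numpy as np
import pandas as pd
import pytest

from whalekrill import glm, selection
from whalekrill.glm import DesignSpec, Term
from whalekrill.synthetic import simulate_climate


def nb_response(rng, eta, theta=2.0):
    mu = np.exp(eta)
    return rng.negative_binomial(theta, theta / (theta + mu))


class TestScreening:
    def test_quadratic_response_selects_quadratic(self):
        # recovery frequency of the true functional form at n=2000
        hits = 0
        n_rep = 40
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            d = pd.DataFrame({"x": rng.normal(size=2000)})
            d["y"] = nb_response(rng, 0.8 + 0.5 * d.x - 0.5 * d.x**2)
            res = selection.screen_variable("x", "polynomial", d, "y", "negbin")
            hits += res.chosen is not None and res.chosen.transform == "quadratic"
        assert hits >= 0.9 * n_rep

    def test_pure_noise_covariate_excluded(self):
        # exclusion rate tracks the test level (~95%); assert >= 85%
        excluded = 0
        n_rep = 40
        for s in range(n_rep):
            rng = np.random.default_rng(2000 + s)
            d = pd.DataFrame({"x": rng.normal(size=1000)})
            d["y"] = nb_response(rng, np.full(1000, 0.8))
            res = selection.screen_variable("x", "polynomial", d, "y", "negbin")
            excluded += res.chosen is None
        assert excluded >= 0.85 * n_rep

    def test_lagged_climate_driver_recovered(self):
        # response driven only by the 3-month lag of an AR(1) index
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            rng = np.random.default_rng(3000 + s)
            series = simulate_climate(120, 0.6, 1.0, rng=rng)
            t = rng.integers(3, 120, size=1500)
            d = pd.DataFrame({f"soi_lag{l}": series[t - l] for l in range(4)})
            d["y"] = nb_response(rng, 0.5 + 0.8 * d.soi_lag3, theta=3.0)
            res = selection.screen_variable(
                "soi", "climate", d, "y", "negbin", climate_form="linear"
            )
            hits += res.chosen is not None and res.chosen.lag == 3
        assert hits > n_rep / 2

    def test_distance_transform_most_significant_wins(self):
        rng = np.random.default_rng(4000)
        d = pd.DataFrame({"dist": rng.uniform(0, 40, size=3000)})
        d["y"] = nb_response(rng, 1.5 - 1.2 * np.log1p(d.dist) * 0.5)
        res = selection.screen_variable("dist", "distance", d, "y", "negbin")
        assert res.chosen is not None
        assert set(res.candidates.label) == {"linear", "quadratic", "log", "invlog"}

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            selection.screen_variable(
                "x", "mystery", pd.DataFrame({"x": [1.0], "y": [1]}), "y", "negbin"
            )


class TestBackwardStepwise:
    def make_truth_frame(self, seed, n=3000):
        rng = np.random.default_rng(seed)
        d = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(1, 6)})
        d["y"] = nb_response(rng, 0.5 + 0.6 * d.x1 - 0.4 * d.x1**2 + 0.5 * d.x2)
        return d

    def test_single_significant_term_returns_unchanged(self):
        rng = np.random.default_rng(5000)
        d = pd.DataFrame({"x": rng.normal(size=2000)})
        d["y"] = nb_response(rng, 1.0 + 0.6 * d.x)
        path = selection.backward_stepwise(DesignSpec("y", [Term("x")]), d)
        assert len(path.models) == 1
        assert [t.covariate for t in path.final.terms] == ["x"]

    def test_marginality_polynomial_drops_top_order_first(self):
        term = Term("x", "quartic")
        top, reduced = selection._droppable(term)
        assert top == "x^4" and reduced.transform == "cubic"
        top, reduced = selection._droppable(Term("x", "linear"))
        assert top == "x" and reduced is None

    def test_noise_terms_eliminated(self):
        d = self.make_truth_frame(seed=5001)
        full = DesignSpec("y", [Term("x1", "quadratic"), Term("x2"),
                                Term("x3"), Term("x4"), Term("x5")])
        path = selection.backward_stepwise(full, d)
        kept = {t.covariate for t in path.final.terms}
        assert {"x1", "x2"} <= kept
        assert path.steps.aic.is_monotonic_decreasing or path.aic_conflicts

    def test_bic_tiebreak_branch(self):
        # with weak noise terms the path's last models sit within 2 AIC and
        # the lowest-BIC (most parsimonious) model is selected
        d = self.make_truth_frame(seed=5002)
        full = DesignSpec("y", [Term("x1", "quadratic"), Term("x2"), Term("x3")])
        path = selection.backward_stepwise(full, d)
        assert path.rule in ("bic_tiebreak", "delta_aic_gt2")
        if path.rule == "bic_tiebreak":
            final_bic = selection.fit_family(path.final, d).bic
            for m in path.models:
                assert final_bic <= selection.fit_family(m, d).bic + 1e-9

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="no terms"):
            selection.backward_stepwise(
                DesignSpec("y", []), pd.DataFrame({"y": [1, 2]})
            )


class TestYearInteraction:
    def make_yearly_frame(self, seed, n=4000, interaction=0.0):
        rng = np.random.default_rng(seed)
        d = pd.DataFrame(
            {
                "contour_index": rng.uniform(0, 100, size=n),
                "year": rng.choice([2004, 2005, 2006, 2007], size=n),
            }
        )
        slope = 0.01 + interaction * (d.year - 2004) / 3.0
        d["y"] = nb_response(rng, 0.2 + slope * d.contour_index, theta=2.0)
        return d

    def test_interaction_power(self):
        hits = 0
        n_rep = 25
        for s in range(n_rep):
            d = self.make_yearly_frame(6000 + s, interaction=0.012)
            base = DesignSpec("y", [Term("contour_index")])
            table, aug = selection.year_interaction_test(base, d, ["contour_index"])
            hits += bool(table.retained.iloc[0])
        assert hits >= 0.8 * n_rep

    def test_interaction_size_near_alpha(self):
        false_pos = 0
        n_rep = 25
        for s in range(n_rep):
            d = self.make_yearly_frame(7000 + s, interaction=0.0)
            base = DesignSpec("y", [Term("contour_index")])
            table, _ = selection.year_interaction_test(base, d, ["contour_index"])
            false_pos += bool(table.retained.iloc[0])
        assert false_pos <= 0.1 * n_rep + 2

    def test_retained_interaction_augments_design(self):
        d = self.make_yearly_frame(6001, interaction=0.02)
        base = DesignSpec("y", [Term("contour_index")])
        table, aug = selection.year_interaction_test(base, d, ["contour_index"])
        if table.retained.iloc[0]:
            assert aug.terms[0].by_year

    def test_missing_static_variable_rejected(self):
        d = self.make_yearly_frame(6002)
        base = DesignSpec("y", [Term("contour_index")])
        with pytest.raises(ValueError, match="depth"):
            selection.year_interaction_test(base, d, ["depth"])

    def test_sparse_year_level_skipped_with_warning(self):
        d = self.make_yearly_frame(6003)
        d.loc[d.index[:-1], "year"] = d.year.iloc[:-1]
        d.loc[d.index[-1], "year"] = 1999  # singleton level
        base = DesignSpec("y", [Term("contour_index")])
        with pytest.warns(UserWarning, match="<2 observations"):
            table, _ = selection.year_interaction_test(base, d, ["contour_index"])
        assert not table.retained.iloc[0]


def test_stepwise_never_breaks_polynomial_marginality():
    """Along any elimination path a polynomial term keeps all lower orders."""
    rng = np.random.default_rng(8000)
    d = pd.DataFrame({"a": rng.normal(size=2000), "b": rng.normal(size=2000)})
    d["y"] = nb_response(rng, 0.5 + 0.3 * d.a - 0.3 * d.a**2)
    full = DesignSpec("y", [Term("a", "quartic"), Term("b", "cubic")])
    path = selection.backward_stepwise(full, d)
    for model in path.models:
        for t in model.terms:
            cols = t.design_columns()
            # design_columns always includes the complete ladder below top
            orders = [c.count("^") and int(c.split("^")[1]) or 1 for c in cols]
            assert orders == list(range(1, len(cols) + 1))
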