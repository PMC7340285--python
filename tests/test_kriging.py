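"""Kriging tests: variogram estimation, OK exactness, QC gates, detrending."""

import numpy as np
import pytest

from whalekrill import kriging as kg
from whalekrill.synthetic import simulate_field


def pure_nugget(c=1.0):
    return kg.VariogramModel("exponential", c, c * (1 + 1e-12), 1.0)


def adversarial_case(seed, n=12, amp=100.0, noise=0.5):
    """Sparse sampling of a steep corner-quadratic plus correlated noise;
    plain stationary kriging fails the mean-error QC gate on some seeds."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 30, size=(n, 2))
    z = amp * (pts[:, 0] ** 2 + pts[:, 1] ** 2) / 900.0
    z = z + simulate_field(pts, noise, 3.0, noise / 2, seed=seed + 1000)
    return pts, z


class TestEmpiricalVariogram:
    def test_constant_field_zero_semivariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, size=(20, 2))
        lt = kg.empirical_variogram(pts, np.full(20, 7.0))
        assert np.allclose(lt.gamma, 0.0)

    def test_two_point_semivariance(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="single pair"):
            lt = kg.empirical_variogram(
                pts, np.array([0.0, 2.0]), n_lags=1, max_lag=2.0
            )
        assert len(lt) == 1
        assert lt.gamma.iloc[0] == pytest.approx(2.0)  # 0.5 * (2-0)^2

    def test_pure_nugget_flat_at_nugget_level(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 30, size=(250, 2))
        f = simulate_field(pts, sill=1.0, range_km=5.0, nugget=1.0, seed=2)
        lt = kg.empirical_variogram(pts, f)
        assert np.all(np.abs(lt.gamma - 1.0) < 0.25)


class TestFitVariogram:
    def test_exponential_recovery(self):
        # the sill of any single 200-point realization fluctuates with the
        # realization's own variance, so calibration is checked on the
        # median over replicates
        sills, ranges = [], []
        for s in range(15):
            rng = np.random.default_rng(100 + s)
            pts = rng.uniform(0, 60, size=(200, 2))
            f = simulate_field(pts, sill=1.0, range_km=5.0, seed=500 + s)
            lt = kg.empirical_variogram(pts, f)
            vgm = kg.fit_variogram(lt, families=("exponential",))
            sills.append(vgm.sill)
            ranges.append(vgm.range_km)
        assert np.median(sills) == pytest.approx(1.0, rel=0.25)
        assert np.median(ranges) == pytest.approx(5.0, rel=0.50)

    def test_single_candidate_family_returned(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 30, size=(60, 2))
        f = simulate_field(pts, sill=1.0, range_km=5.0, seed=6)
        lt = kg.empirical_variogram(pts, f)
        assert kg.fit_variogram(lt, families=("spherical",)).family == "spherical"

    def test_degenerate_fit_falls_back_to_nugget(self):
        import pandas as pd

        flat = pd.DataFrame(
            {"lag": [1.0, 2.0, 3.0, 4.0], "gamma": [0.5] * 4, "n_pairs": [50] * 4}
        )
        with pytest.warns(UserWarning, match="pure nugget"):
            vgm = kg.fit_variogram(flat)
        assert vgm.nugget == pytest.approx(0.5, rel=0.01)
        assert vgm.sill - vgm.nugget < 1e-6

    def test_empty_lag_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            kg.fit_variogram(pd.DataFrame(columns=["lag", "gamma", "n_pairs"]))


class TestOrdinaryKrige:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.pts = rng.uniform(0, 30, size=(60, 2))
        self.z = simulate_field(self.pts, 1.0, 5.0, 0.05, seed=8)
        lt = kg.empirical_variogram(self.pts, self.z)
        self.vgm = kg.fit_variogram(lt, families=("exponential",))

    def test_exact_interpolation_at_data(self):
        pred, var = kg.ordinary_krige(self.pts, self.z, self.vgm, self.pts)
        assert np.max(np.abs(pred - self.z)) < 1e-8
        assert np.max(np.abs(var)) < 1e-8

    def test_constant_data_constant_prediction(self):
        rng = np.random.default_rng(9)
        targets = rng.uniform(0, 30, size=(25, 2))
        pred, _ = kg.ordinary_krige(self.pts, np.full(60, 4.2), self.vgm, targets)
        assert np.allclose(pred, 4.2)

    def test_pure_nugget_reduces_to_global_mean(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        vals = np.array([0.0, 1.0, 1.0])
        pred, _ = kg.ordinary_krige(pts, vals, pure_nugget(), [[1.0, 1.0]])
        assert pred[0] == pytest.approx(2.0 / 3.0, abs=1e-10)

    def test_duplicate_locations_averaged(self):
        pts = np.vstack([self.pts, self.pts[:1]])
        vals = np.append(self.z, self.z[0] + 2.0)
        with pytest.warns(UserWarning, match="duplicate"):
            pred, _ = kg.ordinary_krige(pts, vals, self.vgm, self.pts[:1])
        assert pred[0] == pytest.approx(self.z[0] + 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            kg.ordinary_krige(self.pts[:2], self.z[:2], self.vgm, self.pts)

    def test_variance_grows_with_distance_from_data(self):
        # monotone variogram: kriging variance along a ray leaving the
        # data cloud is non-decreasing
        targets = np.column_stack([np.linspace(31, 60, 20), np.full(20, 15.0)])
        _, var = kg.ordinary_krige(self.pts, self.z, self.vgm, targets)
        assert np.all(np.diff(var) >= -1e-9)
        assert np.all(var >= 0)

    def test_predictions_within_data_range_for_pure_nugget(self):
        rng = np.random.default_rng(10)
        targets = rng.uniform(0, 30, size=(40, 2))
        pred, _ = kg.ordinary_krige(self.pts, self.z, pure_nugget(), targets)
        assert np.all(pred >= self.z.min() - 1e-9)
        assert np.all(pred <= self.z.max() + 1e-9)


class TestLoocvQC:
    def test_constant_field_passes_flagged(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 10, size=(15, 2))
        qc = kg.loocv_qc(pts, np.full(15, 1.0), pure_nugget(0.1))
        assert qc.passed and qc.constant_field

    def test_too_few_points_rejected(self):
        pts = np.random.default_rng(0).uniform(0, 10, size=(5, 2))
        with pytest.raises(ValueError, match=">= 10"):
            kg.loocv_qc(pts, np.zeros(5), pure_nugget())

    def test_well_specified_field_passes(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 30, size=(150, 2))
        z = simulate_field(pts, 1.0, 6.0, 0.05, seed=13)
        lt = kg.empirical_variogram(pts, z)
        vgm = kg.fit_variogram(lt, families=("exponential",))
        qc = kg.loocv_qc(pts, z, vgm)
        assert qc.passed

    def test_steep_trend_fails_qc(self):
        # frozen constructed failure: the percent-mean-error gate fires
        pts, z = adversarial_case(seed=22)
        lt = kg.empirical_variogram(pts, z)
        vgm = kg.fit_variogram(lt, points=pts, values=z)
        qc = kg.loocv_qc(pts, z, vgm)
        assert not qc.passed
        assert qc.pct_me > 2.0


class TestDetrendKrige:
    def test_exact_quadratic_reproduced(self):
        rng = np.random.default_rng(14)
        pts = rng.uniform(0, 10, size=(30, 2))
        z = 1.0 + 0.5 * pts[:, 0] - 0.2 * pts[:, 1] + 0.05 * pts[:, 0] * pts[:, 1]
        targets = rng.uniform(0, 10, size=(10, 2))
        pred, var, qc, _ = kg.detrend_krige(pts, z, targets)
        truth = (1.0 + 0.5 * targets[:, 0] - 0.2 * targets[:, 1]
                 + 0.05 * targets[:, 0] * targets[:, 1])
        assert np.max(np.abs(pred - truth)) < 1e-6
        assert qc.detrended

    def test_detrend_rescues_failing_surface(self):
        pts, z = adversarial_case(seed=22)
        _, _, qc, _ = kg.detrend_krige(pts, z, pts[:2])
        assert qc.passed and qc.detrended

    def test_precondition_passing_input_rejected(self):
        rng = np.random.default_rng(15)
        pts = rng.uniform(0, 30, size=(20, 2))
        ok = kg.QCReport(100, 100, 1.0, 0.1, passed=True)
        with pytest.raises(ValueError, match="passed QC"):
            kg.detrend_krige(pts, np.ones(20), pts, qc_before=ok)


def test_krige_surface_detrend_fallback():
    """The per-surface driver falls back to trend removal when QC fails."""
    pts, z = adversarial_case(seed=22)
    rng = np.random.default_rng(16)
    targets = rng.uniform(0, 30, size=(10, 2))
    surf = kg.krige_surface(pts, z, targets, "C0", "temperature", "surface")
    assert surf.qc.detrended
    assert surf.qc.passed
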