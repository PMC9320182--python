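"""NN-PSO trend fitting, AIC architecture selection, residual kriging and
surface composition."""

import math

import numpy as np
import pytest

from aquarisk.mapping import (
    GridSpec,
    Variogram,
    build_surface,
    fit_variogram,
    idw_predict,
    krige_residuals,
    lonlat_to_planar,
    select_architecture,
    train_nn_pso,
)


def plane(xy, a=0.7, b=-0.4, c=2.0):
    return a * xy[:, 0] + b * xy[:, 1] + c


@pytest.fixture(scope="module")
def plane_sites():
    rng = np.random.default_rng(0)
    xy = rng.uniform(0, 10, size=(60, 2))
    return xy, plane(xy)


class TestTrainNNPSO:
    def test_recovers_noiseless_plane(self, plane_sites):
        """tanh networks represent affine maps near the origin: R >= 0.999."""
        xy, v = plane_sites
        for h in (1, 3):
            model, report = train_nn_pso(xy, v, n_hidden=h, n_particles=30,
                                         n_iterations=400, seed=1)
            assert report.r_validation >= 0.999
            pred = model.predict(xy)
            assert np.corrcoef(pred, v)[0, 1] >= 0.999

    def test_constant_field_gives_constant_model(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 5, size=(20, 2))
        v = np.full(20, 4.2)
        model, report = train_nn_pso(xy, v, n_hidden=3, seed=0)
        assert np.allclose(model.predict(xy), 4.2)
        assert report.mse_train == 0.0

    def test_determinism(self, plane_sites):
        xy, v = plane_sites
        m1, r1 = train_nn_pso(xy, v, n_hidden=2, n_particles=10,
                              n_iterations=50, seed=9)
        m2, r2 = train_nn_pso(xy, v, n_hidden=2, n_particles=10,
                              n_iterations=50, seed=9)
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.w2, m2.w2)
        assert r1.mse_train == r2.mse_train and r1.aic == r2.aic

    def test_best_mse_trace_monotone(self, plane_sites):
        xy, v = plane_sites
        _, report = train_nn_pso(xy, v, n_hidden=4, n_particles=15,
                                 n_iterations=120, seed=3)
        assert np.all(np.diff(report.best_mse_trace) <= 1e-15)

    def test_standardization_round_trip(self, plane_sites):
        """De-standardised predictions match direct evaluation to 1e-10."""
        xy, v = plane_sites
        model, _ = train_nn_pso(xy, v, n_hidden=2, n_particles=10,
                                n_iterations=40, seed=4)
        z = (xy - model.x_mean) / model.x_std
        direct = (np.tanh(z @ model.w1.T + model.b1) @ model.w2 + model.b2) \
            * model.y_std + model.y_mean
        assert np.allclose(model.predict(xy), direct, atol=1e-10)

    def test_too_few_sites_rejected_and_overparam_warns(self):
        xy = np.array([[0.0, 0], [1, 0], [0, 1]])
        with pytest.raises(ValueError):
            train_nn_pso(xy, np.array([1.0, 2, 3]), n_hidden=1)
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 1, size=(8, 2))
        with pytest.warns(UserWarning, match="weights"):
            train_nn_pso(xy, rng.normal(size=8), n_hidden=10,
                         n_particles=5, n_iterations=10, seed=0)

    def test_report_weight_count_identity(self, plane_sites):
        xy, v = plane_sites
        model, _ = train_nn_pso(xy, v, n_hidden=6, n_particles=5,
                                n_iterations=10, seed=0)
        assert model.n_weights == 4 * 6 + 1


class TestSelectArchitecture:
    def test_small_generator_selects_small_network(self):
        """Data from a 1-hidden-unit generator + small noise: AIC picks a
        small architecture and the curve rises past its minimum."""
        rng = np.random.default_rng(10)
        xy = rng.uniform(-3, 3, size=(120, 2))
        v = 2.0 * np.tanh(0.8 * xy[:, 0] - 0.5 * xy[:, 1]) + 0.05 * rng.standard_normal(120)
        model, best_rep, sweep = select_architecture(
            xy, v, n_hidden_range=range(1, 9), n_particles=25,
            n_iterations=250, seed=2,
        )
        assert model.n_hidden <= 5
        aics = [r.aic for r in sweep]
        # independent check of the AIC arithmetic on the best report
        n_tr = round(0.70 * 120)
        k = 4 * best_rep.n_hidden + 1
        assert best_rep.aic == pytest.approx(
            n_tr * math.log(best_rep.mse_train) + 2 * k, rel=1e-12
        )
        assert aics[-1] > min(aics)

    def test_identical_mse_smallest_k_wins(self):
        """Constant field: every candidate fits exactly, penalty dominates."""
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 1, size=(30, 2))
        v = np.full(30, 2.0)
        model, _, _ = select_architecture(xy, v, n_hidden_range=[1, 2, 3],
                                          n_particles=5, n_iterations=10, seed=0)
        assert model.n_hidden == 1

    def test_single_candidate_returned(self, plane_sites):
        xy, v = plane_sites
        model, _, sweep = select_architecture(xy, v, n_hidden_range=[4],
                                              n_particles=5, n_iterations=20, seed=0)
        assert model.n_hidden == 4 and len(sweep) == 1

    def test_empty_or_invalid_range_rejected(self, plane_sites):
        xy, v = plane_sites
        with pytest.raises(ValueError):
            select_architecture(xy, v, n_hidden_range=[])
        with pytest.raises(ValueError):
            select_architecture(xy, v, n_hidden_range=[0, 31])


def simulate_exponential_field(rng, n, range_=5.0, sill=1.0, extent=20.0):
    """Gaussian field with exponential covariance (oracle by Cholesky)."""
    from scipy.spatial import distance_matrix

    xy = rng.uniform(0, extent, size=(n, 2))
    C = sill * np.exp(-distance_matrix(xy, xy) / range_)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    return xy, L @ rng.standard_normal(n)


class TestKriging:
    def test_exact_interpolation_at_zero_nugget(self):
        rng = np.random.default_rng(3)
        xy, v = simulate_exponential_field(rng, 60)
        vgm = Variogram(0.0, float(v.var()), 5.0)
        pred = krige_residuals(xy, v, xy, variogram=vgm)
        assert np.allclose(pred, v, atol=1e-6)

    def test_zero_residuals_give_zero_layer(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 10, size=(25, 2))
        pred = krige_residuals(xy, np.zeros(25), rng.uniform(0, 10, size=(40, 2)))
        assert np.allclose(pred, 0.0)

    def test_variogram_fit_recovers_scales(self):
        rng = np.random.default_rng(6)
        xy, v = simulate_exponential_field(rng, 250, range_=5.0, sill=1.0)
        vgm = fit_variogram(xy, v)
        assert 0.0 <= vgm.nugget < 0.5
        assert 0.3 < vgm.nugget + vgm.psill < 3.0

    def test_cross_validated_kriging_beats_idw(self):
        """Known exponential-variogram field, n = 200: leave-out predictions
        from kriging have lower RMSE than the independent IDW baseline."""
        rng = np.random.default_rng(7)
        xy, v = simulate_exponential_field(rng, 200, range_=5.0, sill=1.0)
        train, test = np.arange(150), np.arange(150, 200)
        krig = krige_residuals(xy[train], v[train], xy[test])
        idw = idw_predict(xy[train], v[train], xy[test])
        rmse_k = np.sqrt(np.mean((krig - v[test]) ** 2))
        rmse_i = np.sqrt(np.mean((idw - v[test]) ** 2))
        assert rmse_k < rmse_i

    def test_ebk_flavoured_mode_runs_and_is_seeded(self):
        rng = np.random.default_rng(8)
        xy, v = simulate_exponential_field(rng, 80)
        t = rng.uniform(0, 20, size=(30, 2))
        a = krige_residuals(xy, v, t, ebk_bootstrap=5, seed=1)
        b = krige_residuals(xy, v, t, ebk_bootstrap=5, seed=1)
        assert np.array_equal(a, b)
        assert np.corrcoef(a, krige_residuals(xy, v, t))[0, 1] > 0.9

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            krige_residuals(np.zeros((3, 2)), np.arange(3.0), np.zeros((1, 2)))


class TestSurface:
    def test_perfect_trend_fit_surface_equals_trend(self):
        rng = np.random.default_rng(9)
        xy = rng.uniform(0, 10, size=(40, 2))
        v = plane(xy)
        spec = GridSpec(0.0, 0.0, 1.0, 10, 10)
        surf = build_surface(xy, v, spec, n_hidden=2, n_particles=30,
                             n_iterations=400, seed=1)
        # residuals are tiny, surface ~ trend layer
        assert np.allclose(surf.values, surf.trend, atol=0.05 * np.ptp(v))

    def test_constant_field_gives_constant_surface(self):
        rng = np.random.default_rng(11)
        xy = rng.uniform(0, 10, size=(20, 2))
        spec = GridSpec(0.0, 0.0, 2.0, 5, 5)
        surf = build_surface(xy, np.full(20, 3.3), spec, n_hidden=2,
                             n_particles=5, n_iterations=10, seed=0)
        assert np.allclose(surf.values, 3.3)

    def test_extrapolation_flag_and_frames(self):
        xy = np.array([[2.0, 2], [8, 2], [8, 8], [2, 8], [5, 5]])
        v = plane(xy)
        spec = GridSpec(0.0, 0.0, 1.0, 10, 10)
        surf = build_surface(xy, v, spec, n_hidden=1, n_particles=10,
                             n_iterations=30, seed=0)
        df = surf.to_frame()
        assert len(df) == 100
        centers = spec.centers()
        inside = (centers[:, 0] > 2) & (centers[:, 0] < 8) & \
                 (centers[:, 1] > 2) & (centers[:, 1] < 8)
        assert not surf.extrapolated[inside].any()
        corner = (centers[:, 0] < 1) & (centers[:, 1] < 1)
        assert surf.extrapolated[corner].all()
        gj = surf.to_geojson()
        assert gj["type"] == "FeatureCollection" and len(gj["features"]) == 100

    def test_smooth_field_recovery(self):
        """150 sites on a cosine-mode latent field: surface correlates with
        the generator's ground truth at R >= 0.9 on a held-out grid."""
        from aquarisk.campaign import CampaignConfig, make_latent_field

        cfg = CampaignConfig(seed=21, trend_amplitude=1.0, correlation_length=10.0)
        f = make_latent_field(cfg)
        rng = np.random.default_rng(22)
        xy = np.column_stack([rng.uniform(0, 40, 150), rng.uniform(0, 30, 150)])
        v = f(xy[:, 0], xy[:, 1])
        spec = GridSpec(0.0, 0.0, 2.0, 15, 20)
        surf = build_surface(xy, v, spec, n_hidden=6, n_particles=30,
                             n_iterations=300, seed=23)
        centers = spec.centers()
        truth = f(centers[:, 0], centers[:, 1])
        inside = ~surf.extrapolated
        r = np.corrcoef(surf.values[inside], truth[inside])[0, 1]
        assert r >= 0.9

    def test_recovery_improves_with_site_count(self):
        """Average RMSE against ground truth decreases as sites grow 50->150->400."""
        from aquarisk.campaign import CampaignConfig, make_latent_field

        cfg = CampaignConfig(seed=30, trend_amplitude=1.0, correlation_length=10.0)
        f = make_latent_field(cfg)
        spec = GridSpec(2.0, 2.0, 3.0, 8, 11)
        centers = spec.centers()
        truth = f(centers[:, 0], centers[:, 1])
        rmses = []
        for n in (50, 150, 400):
            errs = []
            for seed in range(5):
                rng = np.random.default_rng(100 * n + seed)
                xy = np.column_stack([rng.uniform(0, 40, n), rng.uniform(0, 30, n)])
                v = f(xy[:, 0], xy[:, 1])
                surf = build_surface(xy, v, spec, n_hidden=4, n_particles=15,
                                     n_iterations=100, seed=seed)
                errs.append(np.sqrt(np.mean((surf.values - truth) ** 2)))
            rmses.append(np.mean(errs))
        assert rmses[0] > rmses[1] > rmses[2]


def test_lonlat_projection_is_locally_metric():
    lon = np.array([121.8, 121.9, 122.0])
    lat = np.array([13.3, 13.4, 13.5])
    x, y = lonlat_to_planar(lon, lat)
    # 0.1 deg latitude ~ 11.1 km; longitude shrunk by cos(lat)
    assert np.diff(y)[0] == pytest.approx(11.132, rel=1e-3)
    assert np.diff(x)[0] == pytest.approx(11.132 * math.cos(math.radians(13.4)), rel=1e-2)
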