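"""MAP reconstruction: schedules, stopping rule, objective and the loop."""

import numpy as np
import pytest
from scipy.special import expit

from flowct.glow3d import FlowConfig, Glow3D
from flowct.io_preprocess import Projection
from flowct.map_recon import (ReconSettings, alpha, compute_Tb2, objective,
                              reconstruct, step, stop_check)
from flowct.projection import project_array


class TestComputeTb2:
    @pytest.mark.parametrize("dims,expected", [
        ((128, 128, 128), 1.0 / (np.log(2) * 128 ** 3)),
        ((1, 1, 1), 1.0 / np.log(2)),
        ((32, 32, 32), 1.0 / (np.log(2) * 32 ** 3)),
    ])
    def test_printed_values(self, dims, expected):
        assert compute_Tb2(*dims) == pytest.approx(expected, rel=1e-12)

    def test_zero_dims_rejected(self):
        with pytest.raises(ValueError):
            compute_Tb2(0, 4, 4)


class TestAlphaSchedule:
    def test_zero_at_n_zero_for_both_protocols(self):
        assert alpha(0, "standard", 100.0) == 0.0
        assert alpha(0, "ultralow", 100.0) == 0.0

    def test_ultralow_asymptote_is_09(self):
        assert alpha(10 ** 9, "ultralow") == pytest.approx(0.9)

    def test_standard_value_at_n100_sigma1(self):
        assert alpha(100, "standard", sigma2=1.0) \
            == pytest.approx(0.2 * (1 - np.exp(-1.0)), rel=1e-9)

    def test_amplitude_override(self):
        assert alpha(10 ** 9, "ultralow", amplitude=0.5) == pytest.approx(0.5)


class TestStopCheck:
    def _settings(self, **kw):
        return ReconSettings(protocol="standard", **kw)

    def test_threshold_for_biplanar_128(self):
        s = self._settings(tau=3.0)
        stop, reason = stop_check(5, 294_912.0, 2, 128 * 128, s)
        assert stop and reason == "residual-met"  # boundary inclusive
        stop, _ = stop_check(5, 294_913.0, 2, 128 * 128, s)
        assert not stop

    def test_iteration_cap(self):
        s = self._settings()
        stop, reason = stop_check(1001, 1e12, 2, 128 * 128, s)
        assert stop and reason == "n_max"
        stop, _ = stop_check(1000, 1e12, 2, 128 * 128, s)
        assert not stop

    def test_latent_convergence_only_after_ramp(self):
        s = self._settings(latent_tol=1e-4)
        stop, _ = stop_check(5, 1e12, 1, 16, s, latent_step=1e-9)
        assert not stop  # alpha still ramping
        stop, reason = stop_check(200, 1e12, 1, 16, s, latent_step=1e-9)
        assert stop and reason == "latent-converged"


@pytest.fixture(scope="module")
def toy_model():
    """Identity-initialized single-level flow on a 2-voxel volume; the
    decoder is the closed-form map x = [z1, z2 / c], c = sigmoid(2) + eps."""
    cfg = FlowConfig(shape=(1, 1, 2, 1), levels=1, depth=1, width=4,
                     squeeze_factor=(1, 1, 2), permutation="identity",
                     identity_init=True, seed=0)
    return Glow3D(cfg)


class TestObjective:
    def test_cycle_zero_at_ground_truth_latents(self, flow16, rng):
        x = rng.random((1, 16, 16, 16, 1))
        zs, _, _ = flow16.encode(x)
        projs = [Projection(project_array(x[0], v) * 255.0, view=v)
                 for v in ("coronal", "sagittal")]
        settings = ReconSettings(protocol="standard")
        e, comps = objective([z.data for z in zs], projs, settings, flow16)
        assert comps["residual"] < 1e-10
        assert float(e.data) < 1e-14

    def test_doubling_residuals_quadruples_cycle(self, flow16, rng):
        x = rng.random((1, 16, 16, 16, 1))
        zs, _, _ = flow16.encode(x)
        z = [zv.data for zv in zs]
        yhat = project_array(x[0], "coronal")
        r = rng.normal(0, 0.05, yhat.shape)
        settings = ReconSettings(protocol="standard")
        _, c1 = objective(z, [Projection((yhat + r) * 255, view="coronal")],
                          settings, flow16)
        _, c2 = objective(z, [Projection((yhat + 2 * r) * 255, view="coronal")],
                          settings, flow16)
        assert c2["residual"] == pytest.approx(4 * c1["residual"], rel=1e-9)

    def test_matches_naive_recomposition(self, flow16, rng):
        """E equals a separate decode + project + likelihood recomputation."""
        zs = [rng.standard_normal((1,) + s) * 0.3 for s in flow16.z_shapes]
        projs = [Projection(rng.uniform(0, 255, (16, 16)), view="coronal"),
                 Projection(rng.uniform(0, 255, (16, 16)), view="sagittal")]
        settings = ReconSettings(protocol="ultralow", sigma2=100.0)
        e, comps = objective(zs, projs, settings, flow16)
        x, _ = flow16.decode(zs)
        xd = x.data
        cycle = 0.0
        for p in projs:
            cycle += np.sum((project_array(xd[0], p.view) - p.pixels / 255.0) ** 2)
        logp = flow16.log_likelihood(xd)[0]
        tb2 = compute_Tb2(16, 16, 16)
        sigma2_unit = 100.0 / 255.0 ** 2
        expected = cycle / (2 * sigma2_unit) - tb2 * logp
        assert float(e.data) == pytest.approx(expected, rel=1e-9)
        assert comps["residual"] == pytest.approx(cycle * 255.0 ** 2, rel=1e-9)


class TestStep:
    def test_zero_alpha_at_n0_leaves_latents(self, toy_model):
        z = [np.array([[[[[0.4, 0.7]]]]])]
        y = Projection(np.array([[60.0, 90.0]]), view="coronal")
        z_new, info = step(z, 0, [y], ReconSettings(protocol="standard"),
                           toy_model)
        np.testing.assert_array_equal(z_new[0], z[0])
        assert info["alpha"] == 0.0

    def test_matches_hand_computed_gradient_descent(self, toy_model):
        """One step on the closed-form two-voxel decoder."""
        c = expit(2.0) + 1e-3
        z1, z2 = 0.4, 0.7
        y1, y2 = 0.2, 0.3  # unit scale
        z = [np.array([[[[[z1, z2]]]]])]
        proj = Projection(np.array([[y1 * 255, y2 * 255]]), view="coronal")
        amplitude, n = 0.5, 50
        a = amplitude * (1 - np.exp(-0.01 * n))
        # x = [z1, z2/c]; E = 1/2 ((z1-y1)^2 + (z2/c - y2)^2)
        g1 = z1 - y1
        g2 = (z2 / c - y2) / c
        expected = [z1 - a * g1, z2 - a * g2]
        settings = ReconSettings(protocol="standard", alpha_amplitude=amplitude)
        z_new, _ = step(z, n, [proj], settings, toy_model)
        np.testing.assert_allclose(z_new[0].ravel(), expected, rtol=1e-10)

    def test_zero_gradient_fixed_point(self, toy_model):
        c = expit(2.0) + 1e-3
        z = [np.array([[[[[0.2, 0.3 * c]]]]])]
        proj = Projection(np.array([[0.2 * 255, 0.3 * 255]]), view="coronal")
        z_new, info = step(z, 400, [proj],
                           ReconSettings(protocol="standard"), toy_model)
        np.testing.assert_allclose(z_new[0], z[0], atol=1e-12)


class TestReconstructLoop:
    def test_fixed_point_stops_immediately(self, flow16):
        """Projections of a decoded sample, initialized at that latent."""
        x, zs = flow16.sample(temperature=0.4, seed=2)
        projs = [Projection(project_array(x[0], v) * 255.0, view=v)
                 for v in ("coronal", "sagittal")]
        settings = ReconSettings(protocol="standard", seed=2)
        vol, trace = reconstruct(projs, flow16, settings, z_init=zs)
        assert trace.stop_reason == "residual-met"
        assert len(trace.rows) == 0
        np.testing.assert_allclose(vol.voxels[..., 0],
                                   np.clip(x[0, ..., 0], 0, 1), atol=1e-10)

    def test_same_seed_gives_identical_reconstruction(self, flow16, rng):
        x = rng.random((1, 16, 16, 16, 1))
        projs = [Projection(project_array(x[0], "coronal") * 255.0,
                            view="coronal")]
        settings = ReconSettings(protocol="standard", n_max=5, seed=3)
        v1, t1 = reconstruct(projs, flow16, settings)
        v2, t2 = reconstruct(projs, flow16, settings)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        assert t1.stop_reason == t2.stop_reason

    def test_duplicate_views_rejected(self, flow16):
        p = Projection(np.zeros((16, 16)), view="coronal")
        with pytest.raises(ValueError):
            reconstruct([p, p], flow16, ReconSettings(protocol="standard"))
        with pytest.raises(ValueError):
            reconstruct([], flow16, ReconSettings(protocol="standard"))

    def test_trace_records_monotone_alpha_ramp_fields(self, flow16, rng):
        x = rng.random((1, 16, 16, 16, 1))
        projs = [Projection(project_array(x[0], "coronal") * 255.0,
                            view="coronal")]
        settings = ReconSettings(protocol="standard", n_max=4, seed=1,
                                 adaptive=False)
        _, trace = reconstruct(projs, flow16, settings)
        assert [r["n"] for r in trace.rows] == [1, 2, 3, 4]
        alphas = [r["alpha"] for r in trace.rows]
        assert all(b > a for a, b in zip(alphas, alphas[1:]))
        assert trace.stop_reason == "n_max"

    def test_ultralow_limit_matches_standard_path(self, flow16, rng):
        """With sigma^2 -> 0 and the amplitude rescaled by sigma^2, the
        ultralow iterates coincide with the standard protocol's."""
        x = rng.random((1, 16, 16, 16, 1))
        projs = [Projection(project_array(x[0], v) * 255.0, view=v)
                 for v in ("coronal", "sagittal")]
        sigma2_8bit = 1e-8
        sigma2_unit = sigma2_8bit / 255.0 ** 2
        std = ReconSettings(protocol="standard", alpha_amplitude=0.2,
                            adaptive=False, n_max=5, seed=6)
        ul = ReconSettings(protocol="ultralow", sigma2=sigma2_8bit,
                           alpha_amplitude=0.2 * sigma2_unit,
                           adaptive=False, n_max=5, seed=6)
        v_std, t_std = reconstruct(projs, flow16, std)
        v_ul, t_ul = reconstruct(projs, flow16, ul)
        np.testing.assert_allclose(v_ul.voxels, v_std.voxels, atol=1e-6)
        np.testing.assert_allclose(t_ul.residuals, t_std.residuals, rtol=1e-6)


class TestRestarts:
    def test_restart_seeds_keep_best_residual_trajectory(self, flow16, rng):
        x = rng.random((1, 16, 16, 16, 1))
        projs = [Projection(project_array(x[0], "coronal") * 255.0,
                            view="coronal")]
        settings = ReconSettings(protocol="standard", n_max=3, seed=0)
        singles = []
        for s in (4, 5):
            _, t = reconstruct(projs, flow16,
                               ReconSettings(protocol="standard", n_max=3, seed=s))
            singles.append(t.residuals[-1])
        _, trace = reconstruct(projs, flow16, settings, restart_seeds=[4, 5])
        assert trace.residuals[-1] == min(singles)


class TestSettingsValidation:
    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            ReconSettings(protocol="megadose")

    def test_ultralow_requires_positive_sigma2(self):
        with pytest.raises(ValueError):
            ReconSettings(protocol="ultralow", sigma2=0.0)

    def test_desk_settings_amplitudes(self):
        std = ReconSettings.desk("standard")
        ul = ReconSettings.desk("ultralow", sigma2=100.0)
        assert std.alpha_amplitude == pytest.approx(0.2 * 255 ** 2)
        assert ul.alpha_amplitude == pytest.approx(0.2 * 100 / 255 ** 2)
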