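"""FRAP simulation, photobleach correction and grid fitting."""

import math

import numpy as np
import pytest
import scipy.integrate as si
from scipy.special import erf

from ras1zone.frap import (
    FitResult,
    PhotobleachModel,
    RecoveryTrace,
    RecruitmentParams,
    UniformExchangeParams,
    correct_photobleaching,
    fit_diffusion_params,
    fusion_focus_protocol,
    half_tip_protocol,
    make_synthetic_frap_fixture,
    recruitment_steady_state,
    side_bleach_protocol,
    simulate_frap_recruitment,
    simulate_frap_uniform,
    trace_from_csv,
    trace_to_csv,
)
from ras1zone.frap import StabilityError
from ras1zone.mesh import region_mask


def strip_oracle(a, D, t):
    """Mean recovery over [-a, a] of 1D diffusion from an indicator bleach."""
    if t <= 0:
        return 0.0
    s = math.sqrt(4 * D * t)
    f = lambda x: 1 - 0.5 * (erf((a - x) / s) + erf((a + x) / s))
    v, _ = si.quad(f, -a, a)
    return v / (2 * a)


class TestUniform:
    def test_no_transport_stays_bleached(self, coarse_interphase_mesh):
        protocol = side_bleach_protocol(coarse_interphase_mesh, width=1.5)
        trace = simulate_frap_uniform(
            coarse_interphase_mesh, UniformExchangeParams(D=0.0, r=0.0),
            protocol, duration=10.0)
        post = trace.times >= 0
        assert np.all(trace.regions["bleached"][post] == 0)

    def test_long_time_returns_to_steady_state(self, coarse_interphase_mesh):
        protocol = side_bleach_protocol(coarse_interphase_mesh, width=1.5)
        trace = simulate_frap_uniform(
            coarse_interphase_mesh, UniformExchangeParams(D=0.1, r=0.05, j_plus=0.05),
            protocol, duration=250.0)
        assert trace.regions["bleached"][-1] == pytest.approx(1.0, abs=1e-4)

    def test_matches_1d_strip_oracle(self, long_flat_mesh):
        """Full-circumference strip bleaches on the flat cylindrical
        section match the 1D diffusion oracle within 3%."""
        D = 0.15
        for width in (1.5, 4.0):
            protocol = side_bleach_protocol(
                long_flat_mesh, width=width, circ_extent=4 * math.pi,
                slab_half_width=None)
            mask = region_mask(long_flat_mesh, protocol.bleach_region)
            a_eff = long_flat_mesh.areas[mask].sum() / (4 * math.pi * 2.0)
            trace = simulate_frap_uniform(
                long_flat_mesh, UniformExchangeParams(D=D, r=0.0),
                protocol, duration=10.0)
            for t in (1.0, 2.0, 4.0, 6.0, 10.0):
                sim = float(np.interp(t, trace.times, trace.regions["bleached"]))
                assert sim == pytest.approx(strip_oracle(a_eff, D, t), abs=0.03)

    def test_small_strip_recovers_faster(self, long_flat_mesh):
        def t_half(width):
            protocol = side_bleach_protocol(long_flat_mesh, width=width)
            tr = simulate_frap_uniform(
                long_flat_mesh, UniformExchangeParams(D=0.15, r=0.0),
                protocol, duration=30.0)
            post = tr.times >= 0
            return float(np.interp(0.5, tr.regions["bleached"][post],
                                   tr.times[post]))
        assert t_half(1.5) < t_half(4.0)

    def test_unstable_step_refused(self, coarse_interphase_mesh):
        protocol = side_bleach_protocol(coarse_interphase_mesh, width=1.5)
        with pytest.raises(StabilityError):
            simulate_frap_uniform(
                coarse_interphase_mesh, UniformExchangeParams(D=0.15, r=0.0),
                protocol, duration=1.0, dt=50.0)


class TestRecruitment:
    def test_steady_state_linearity(self, coarse_mesh):
        p1 = RecruitmentParams(D=0.2, r=0.02, A=100.0, sigma=0.4)
        p2 = RecruitmentParams(D=0.2, r=0.02, A=200.0, sigma=0.4)
        c1 = recruitment_steady_state(coarse_mesh, p1)
        c2 = recruitment_steady_state(coarse_mesh, p2)
        assert np.allclose(c2, 2 * c1, rtol=1e-6)

    def test_middle_recovers_faster_than_sides(self, ref_mesh):
        """Fusion-focus protocol with the best-fit Gap1 transport rates:
        the patch center refills before the flanks (recruitment at the
        tip followed by lateral spreading)."""
        params = RecruitmentParams(D=0.2, r=0.02, sigma=0.4,
                                   post_bleach_amp_factor=0.5)
        protocol = fusion_focus_protocol(ref_mesh)
        trace = simulate_frap_recruitment(ref_mesh, params, protocol, 40.0)
        for t in (5.0, 10.0, 20.0):
            mid = np.interp(t, trace.times, trace.regions["middle"])
            side = np.interp(t, trace.times, trace.regions["sides"])
            assert mid > side

    def test_half_tip_requires_membrane_diffusion(self, coarse_interphase_mesh):
        """With D = 0 the non-bleached half cannot lose material to the
        bleached half; membrane diffusion (D = 0.2) produces a markedly
        deeper dip of the non-bleached signal."""
        protocol = half_tip_protocol(coarse_interphase_mesh)
        tr_d0 = simulate_frap_recruitment(
            coarse_interphase_mesh,
            RecruitmentParams(D=0.0, r=0.08, sigma=0.8,
                              post_bleach_amp_factor=0.7),
            protocol, 60.0)
        tr_d = simulate_frap_recruitment(
            coarse_interphase_mesh,
            RecruitmentParams(D=0.2, r=0.02, sigma=0.8,
                              post_bleach_amp_factor=0.7),
            protocol, 60.0)
        t_probe = 10.0
        nb_d0 = np.interp(t_probe, tr_d0.times, tr_d0.regions["non_bleached"])
        nb_d = np.interp(t_probe, tr_d.times, tr_d.regions["non_bleached"])
        assert nb_d < nb_d0 - 0.05


class TestPhotobleachCorrection:
    def _trace(self, values, times):
        return RecoveryTrace(times=times, regions={"bleached": values}, raw=True)

    def test_constant_cytosol_gives_zero_rate(self):
        times = np.arange(-2.0, 30.0)
        raw = self._trace(np.linspace(0.4, 1.0, len(times)), times)
        out = correct_photobleaching(raw, np.full(len(times), 5.0))
        pre = times < 0
        expect = raw.regions["bleached"] / raw.regions["bleached"][pre].mean()
        assert np.allclose(out.regions["bleached"], expect, atol=1e-6)

    def test_inverts_constructed_decay(self):
        times = np.arange(-2.0, 60.0)
        true = 1 - 0.6 * np.exp(-0.05 * np.maximum(times, 0))
        background = 10.0
        r_pb = 0.01
        decay = np.exp(-r_pb * (times - times[0]))
        raw = self._trace(true * decay + background, times)
        cytosol = 50.0 * decay + background
        out = correct_photobleaching(
            raw, cytosol, PhotobleachModel(background=background))
        pre = times < 0
        expect = true / true[pre].mean()
        assert np.max(np.abs(out.regions["bleached"] - expect)) < 0.01

    def test_nonpositive_cytosol_rejected(self):
        times = np.arange(-2.0, 10.0)
        raw = self._trace(np.ones(len(times)), times)
        with pytest.raises(ValueError, match="cytosol"):
            correct_photobleaching(raw, np.full(len(times), 1.0),
                                   PhotobleachModel(background=2.0))


@pytest.fixture(scope="module")
def fit_setup(coarse_interphase_mesh):
    mesh = coarse_interphase_mesh
    protocols = [side_bleach_protocol(mesh, width=w) for w in (1.5, 4.0)]
    return mesh, protocols


class TestFitting:
    def test_noise_free_self_consistency(self, fit_setup):
        mesh, protocols = fit_setup
        truth = UniformExchangeParams(D=0.15, r=0.001, j_plus=0.001)
        traces = [
            simulate_frap_uniform(mesh, truth, pr, 40.0) for pr in protocols
        ]
        fit = fit_diffusion_params(
            traces, "uniform", np.array([0.05, 0.1, 0.15, 0.2]),
            np.array([0.001, 0.011, 0.021]), mesh, protocols, duration=40.0)
        assert fit.best == (0.15, 0.001)

    def test_infinite_band_accepts_everything(self, fit_setup):
        mesh, protocols = fit_setup
        truth = UniformExchangeParams(D=0.1, r=0.001, j_plus=0.001)
        trace = simulate_frap_uniform(mesh, truth, protocols[0], 20.0)
        trace.sd = {"bleached": np.full(len(trace.times), 1e9)}
        fit = fit_diffusion_params(
            [trace], "uniform", np.array([0.05, 0.1]), np.array([0.001, 0.011]),
            mesh, protocols[:1], duration=20.0)
        assert fit.acceptable.all()
        assert fit.in_band

    def test_parameter_recovery_within_one_grid_step(self, fit_setup):
        """5% frame noise on (D=0.04, r=0.02) synthetic curves: the best
        grid point lands within one step of the truth in >= 90% of 20
        replicates."""
        mesh, protocols = fit_setup
        truth = UniformExchangeParams(D=0.04, r=0.02, j_plus=0.02)
        D_grid = np.arange(0.02, 0.0601, 0.01)
        r_grid = np.arange(0.010, 0.0301, 0.005)
        base = [simulate_frap_uniform(mesh, truth, pr, 60.0) for pr in protocols]
        cache: dict = {}
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            traces = [
                make_synthetic_frap_fixture(
                    truth, pr, noise_sd=0.05, n_cells=1, seed=1000 + rep * 2 + k,
                    mesh=mesh, duration=60.0, base_trace=bt)
                for k, (pr, bt) in enumerate(zip(protocols, base))
            ]
            fit = fit_diffusion_params(
                traces, "uniform", D_grid, r_grid, mesh, protocols,
                duration=60.0, sim_cache=cache)
            d_ok = abs(fit.best[0] - 0.04) <= 0.01 + 1e-12
            r_ok = abs(fit.best[1] - 0.02) <= 0.005 + 1e-12
            hits += d_ok and r_ok
        assert hits >= 0.9 * n_rep


class TestFixture:
    def test_zero_noise_zero_sd(self, coarse_interphase_mesh):
        protocol = side_bleach_protocol(coarse_interphase_mesh, width=4.0)
        truth = UniformExchangeParams(D=0.15, r=0.001, j_plus=0.001)
        tr = make_synthetic_frap_fixture(
            truth, protocol, noise_sd=0.0, n_cells=5, seed=1,
            mesh=coarse_interphase_mesh, duration=20.0)
        assert np.all(tr.sd["bleached"] == 0)

    def test_sd_matches_noise_scale_and_determinism(self, coarse_interphase_mesh):
        protocol = side_bleach_protocol(coarse_interphase_mesh, width=4.0)
        truth = UniformExchangeParams(D=0.15, r=0.001, j_plus=0.001)
        base = simulate_frap_uniform(coarse_interphase_mesh, truth, protocol, 60.0)
        tr1 = make_synthetic_frap_fixture(
            truth, protocol, noise_sd=0.05, n_cells=5, seed=7,
            mesh=coarse_interphase_mesh, duration=60.0, base_trace=base)
        tr2 = make_synthetic_frap_fixture(
            truth, protocol, noise_sd=0.05, n_cells=5, seed=7,
            mesh=coarse_interphase_mesh, duration=60.0, base_trace=base)
        assert np.array_equal(tr1.regions["bleached"], tr2.regions["bleached"])
        # per-frame sample SD estimates the injected noise scale
        assert tr1.sd["bleached"].mean() == pytest.approx(0.05, abs=0.01)

    def test_invalid_args(self, coarse_interphase_mesh):
        protocol = side_bleach_protocol(coarse_interphase_mesh, width=4.0)
        truth = UniformExchangeParams(D=0.15, r=0.001)
        with pytest.raises(ValueError):
            make_synthetic_frap_fixture(truth, protocol, -0.1, 5, 1,
                                        coarse_interphase_mesh, 10.0)

    def test_csv_round_trip(self, coarse_interphase_mesh, tmp_path):
        protocol = side_bleach_protocol(coarse_interphase_mesh, width=4.0)
        truth = UniformExchangeParams(D=0.15, r=0.001, j_plus=0.001)
        tr = make_synthetic_frap_fixture(
            truth, protocol, noise_sd=0.05, n_cells=5, seed=3,
            mesh=coarse_interphase_mesh, duration=20.0)
        path = tmp_path / "trace.csv"
        trace_to_csv(tr, path, comment="round trip")
        back = trace_from_csv(path)
        assert np.allclose(back.times, tr.times)
        assert np.allclose(back.regions["bleached"], tr.regions["bleached"])
        assert np.allclose(back.sd["bleached"], tr.sd["bleached"])
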