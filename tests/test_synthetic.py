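"""Model landscapes, the Brownian pulling simulator, and fixture generators."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import smdroutes as sr
from smdroutes.synthetic import PMFTerm


class TestEvaluatePMF:
    @pytest.mark.parametrize("model,x,expected", [
        (sr.flat_model(), 2.0, (0.0, 0.0)),
        (sr.harmonic_model(2.0), 3.0, (9.0, -6.0)),
        (sr.barrier_model(23.66, center=5.0, width=1.5), 5.0, (23.66, 0.0)),
    ])
    def test_examples(self, model, x, expected):
        energy, force = sr.evaluate_pmf(model, x)
        assert energy == pytest.approx(expected[0])
        assert force == pytest.approx(expected[1])

    def test_outside_domain_raises(self):
        model = sr.flat_model(domain=(0.0, 1.0))
        with pytest.raises(ValueError, match="domain"):
            sr.evaluate_pmf(model, 2.0)

    def test_sum_of_terms_and_analytic_derivative(self):
        model = sr.ModelPMF(terms=(
            PMFTerm("harmonic", center=1.0, height=3.0),
            PMFTerm("gaussian_bump", center=4.0, height=10.0, width=1.2),
            PMFTerm("linear", center=0.0, height=0.5),
        ))
        x = 2.7
        e, f = sr.evaluate_pmf(model, x)
        assert e == pytest.approx(sum(t.energy(x) for t in model.terms))
        h = 1e-6
        numeric = -(model.energy(x + h) - model.energy(x - h)) / (2 * h)
        assert f == pytest.approx(numeric, abs=1e-6)


class TestSimulatePulling:
    def test_zero_velocity_means_zero_work(self):
        proto = sr.PullingProtocol(velocity=0.0, duration=50.0, seed=3)
        traj = sr.simulate_pulling(sr.harmonic_model(1.0), proto)
        assert np.all(traj.work == 0.0)
        assert np.all(traj.lam == proto.lambda0)

    def test_deterministic_lag_matches_linear_response(self):
        # noise off, flat landscape: the ODE dξ/dt = βDk_s(λ−ξ) has terminal
        # lag v/(βDk_s) and work rate k_s·v·lag
        proto = sr.PullingProtocol(duration=400.0, noise=False, seed=0,
                                   equilibration=0.0)
        traj = sr.simulate_pulling(sr.flat_model(domain=(-5, 20)), proto)
        beta_d = proto.beta * proto.diffusion_coefficient
        lag_pred = proto.velocity / (beta_d * proto.spring_constant)
        lag_end = traj.lam[-1] - traj.xi[-1]
        assert lag_end == pytest.approx(lag_pred, rel=1e-3)
        # terminal work rate from the last two samples
        rate = (traj.work[-1] - traj.work[-2]) / (traj.t[-1] - traj.t[-2])
        assert rate == pytest.approx(
            proto.spring_constant * proto.velocity * lag_pred, rel=1e-3)

    def test_harmonic_noise_free_work_matches_ode_oracle(self):
        # independent oracle: high-resolution numeric solve of the coupled
        # deterministic ODE, work integrated alongside
        k = 1.5
        proto = sr.PullingProtocol(velocity=0.005, duration=400.0, noise=False,
                                   equilibration=0.0, seed=0)
        model = sr.harmonic_model(k, domain=(-20, 20))
        traj = sr.simulate_pulling(model, proto)

        beta_d = proto.beta * proto.diffusion_coefficient
        ks, v = proto.spring_constant, proto.velocity

        def rhs(t, y):
            x, w = y
            lam = v * t
            f_spring = ks * (lam - x)
            return [beta_d * (-k * x + f_spring), v * f_spring]

        sol = solve_ivp(rhs, (0.0, proto.duration), [0.0, 0.0],
                        rtol=1e-10, atol=1e-12)
        assert traj.final_work == pytest.approx(sol.y[1, -1], rel=1e-3)
        # and the quasi-static closed form: W → ½·k·k_s/(k+k_s)·λ_f²
        lam_f = v * proto.duration
        quasi = 0.5 * k * ks / (k + ks) * lam_f ** 2
        assert sol.y[1, -1] == pytest.approx(quasi, rel=0.05)

    def test_work_trapezoid_of_recorded_force(self):
        # with every step recorded, stored work is exactly the trapezoid of
        # the stored force against restraint displacement
        proto = sr.PullingProtocol(duration=20.0, seed=9, sample_interval=1)
        traj = sr.simulate_pulling(sr.flat_model(domain=(-5, 10)), proto)
        w_trapz = np.concatenate(
            [[0.0], np.cumsum(0.5 * (traj.force[1:] + traj.force[:-1])
                              * np.diff(traj.displacement))])
        assert np.allclose(w_trapz, traj.work, rtol=1e-8, atol=1e-12)

    def test_domain_exit_truncates_and_flags(self):
        # strong downhill ramp pushes ξ past the domain edge
        model = sr.ModelPMF(terms=(PMFTerm("linear", height=-50.0),),
                            domain=(-8.0, 8.0))
        proto = sr.PullingProtocol(velocity=0.001, duration=200.0, seed=2,
                                   equilibration=0.0)
        traj = sr.simulate_pulling(model, proto)
        assert not traj.completed
        assert traj.t[-1] < proto.duration


class TestGenerateEnsemble:
    def test_counts_and_corruption(self):
        model = sr.flat_model(domain=(-10, 20))
        proto = sr.PullingProtocol(duration=20.0, seed=8)
        ens = sr.generate_ensemble(model, proto, 40, corrupt_fraction=0.475)
        assert len(ens) == 40
        completed = [tr.completed for tr in ens.trajectories]
        assert sum(completed) == 21
        assert sum(not c for c in completed) == 19

    def test_singleton(self):
        ens = sr.generate_ensemble(
            sr.flat_model(domain=(-10, 20)),
            sr.PullingProtocol(duration=10.0, seed=1), 1, 0.0)
        assert len(ens) == 1 and ens.trajectories[0].completed

    def test_determinism_bitwise(self):
        model = sr.harmonic_model(1.0, domain=(-20, 20))
        proto = sr.PullingProtocol(duration=30.0, seed=77)
        a = sr.generate_ensemble(model, proto, 4, 0.25)
        b = sr.generate_ensemble(model, proto, 4, 0.25)
        for ta, tb in zip(a.trajectories, b.trajectories):
            for fieldname in ("t", "lam", "xi", "force", "work"):
                assert np.array_equal(getattr(ta, fieldname), getattr(tb, fieldname))
            assert ta.completed == tb.completed

    def test_extending_ensemble_preserves_replicas(self):
        model = sr.flat_model(domain=(-10, 20))
        proto = sr.PullingProtocol(duration=10.0, seed=12)
        small = sr.generate_ensemble(model, proto, 3)
        large = sr.generate_ensemble(model, proto, 6)
        for ts, tl in zip(small.trajectories, large.trajectories[:3]):
            assert np.array_equal(ts.work, tl.work)


class TestThermodynamicSanity:
    def test_second_law_and_slow_limit(self, harmonic_slow_ensemble):
        ens = harmonic_slow_ensemble
        finals = ens.final_works
        model = sr.harmonic_model(2.0, domain=(-30.0, 30.0))
        lam_f = ens.protocol.velocity * ens.protocol.duration
        dF = sr.restrained_free_energy(model, ens.protocol.spring_constant,
                                       ens.kBT, [0.0, lam_f])[-1]
        assert finals.mean() >= dF - 3.0 * finals.std(ddof=1) / math.sqrt(len(finals))
        # slow limit: mean final work close to the analytic ΔF, spread small
        assert finals.mean() == pytest.approx(dF, abs=0.15)
        assert finals.std(ddof=1) < 0.5

    def test_flat_free_energy_is_zero(self, flat_ensemble):
        # with U flat the restrained free energy is λ-independent
        model = sr.flat_model(domain=(-10.0, 20.0))
        prof = sr.restrained_free_energy(model, 5.0, 0.616, [0.0, 1.0, 2.6])
        assert np.allclose(prof, 0.0, atol=1e-8)


class TestCarvedStructures:
    def test_single_channel_axis_clearance(self):
        s = sr.carve_tunnel_structure(3.0, [((1, 0, 0), 2.0, 5.0)],
                                      cavity_radius=4.0)
        # analytic clearance along the channel axis: min is the carved
        # bottleneck (sampled finely from the cavity to the channel end)
        ax = np.linspace(0.5, 8.8, 300)
        pts = np.column_stack([ax, np.zeros_like(ax), np.zeros_like(ax)])
        d = np.linalg.norm(pts[:, None, :] - s.coords[None, :, :], axis=2)
        clearance = (d - s.radii[None, :]).min(axis=1)
        assert clearance.min() == pytest.approx(2.0, abs=0.05)

    def test_metadata_orders_wide_short_first(self):
        s = sr.carve_tunnel_structure(
            2.9, [((-1, 0, 0), 1.35, 15.65), ((1, 0, 0), 4.23, 2.90)],
            cavity_radius=6.5)
        truth = s.metadata["tunnels"]
        assert truth[0].bottleneck_radius == pytest.approx(4.23)
        assert truth[1].length == pytest.approx(15.65)

    def test_overlapping_specs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sr.carve_tunnel_structure(
                3.0, [((1, 0, 0), 2.0, 5.0), ((0.99, 0.14, 0), 2.0, 5.0)],
                cavity_radius=4.0)


class TestFluctuationFrames:
    def test_zero_sigma_gives_identical_frames(self):
        series = sr.generate_fluctuation_frames(5, 4, [0.0] * 5, seed=1)
        assert np.array_equal(series.frames[0], series.frames[3])

    def test_rmsf_tends_to_sigma_sqrt3(self):
        sigma = 0.5
        series = sr.generate_fluctuation_frames(6, 20000, [sigma] * 6, seed=2)
        rmsf = np.sqrt(np.mean(np.sum(
            (series.frames - series.frames.mean(axis=0)) ** 2, axis=2), axis=0))
        assert np.allclose(rmsf, sigma * math.sqrt(3), rtol=0.03)

    def test_rigid_motion_removed_by_superposition(self):
        series = sr.generate_fluctuation_frames(5, 10, [0.0] * 5, seed=3,
                                                rigid_motions=True)
        # frames are rotated copies: raw frames differ, superposed RMSD = 0
        assert not np.allclose(series.frames[0], series.frames[1])
        rmsd = sr.rmsd_series(series, reference_frame=0)
        assert np.all(rmsd < 1e-10)
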