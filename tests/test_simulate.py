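"""The noisy Kuramoto simulators and the bioluminescence renderer."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from scnsync.simulate import (
    CONDITION_PRESETS,
    OneCommunityParams,
    RenderOptions,
    TwoCommunityParams,
    calibrate_condition,
    instantaneous_order_parameter,
    make_slice_fixture,
    phase_zero_crossings,
    render_bioluminescence,
    simulate_one_community,
    simulate_two_community,
    stationary_order_parameter,
    two_community_fixed_point,
)


def _mean_field_fixed_point(K, D=1.0):
    """Independent oracle: bisection on r = V(2Kr/D^2)."""
    f = lambda r: i1e(2 * K * r / D**2) / i0e(2 * K * r / D**2) - r
    return brentq(f, 1e-6, 1 - 1e-12)


class TestOneCommunity:
    def test_noiseless_synchronized_fixed_point(self):
        p = OneCommunityParams(
            n_oscillators=20, K=1.0, D=0.0, n_cycles=3, seed=0, init_phase_sd=0.0
        )
        traj = simulate_one_community(p)
        assert np.allclose(traj.phases, traj.phases[0], atol=1e-12)
        assert np.allclose(instantaneous_order_parameter(traj), 1.0, atol=1e-12)

    def test_free_rotation(self):
        p = OneCommunityParams(
            n_oscillators=5, K=0.0, D=0.0, n_cycles=2, seed=0, init_phase_sd=0.3
        )
        traj = simulate_one_community(p)
        expected = traj.phases[:, :1] + 2 * np.pi / p.tau * traj.times[None, :]
        assert np.allclose(traj.phases, expected, atol=1e-9)

    def test_seed_reproducibility(self):
        p = OneCommunityParams(n_oscillators=30, K=2.0, D=1.0, n_cycles=2, seed=9)
        a = simulate_one_community(p)
        b = simulate_one_community(p)
        assert np.array_equal(a.phases, b.phases)

    def test_adding_cells_preserves_noise_streams(self):
        # with K=0 there is no interaction, so the first cells' paths must be
        # bit-identical regardless of how many extra cells are simulated
        pa = OneCommunityParams(n_oscillators=10, K=0.0, D=1.0, n_cycles=2, seed=4)
        pb = OneCommunityParams(n_oscillators=14, K=0.0, D=1.0, n_cycles=2, seed=4)
        a = simulate_one_community(pa)
        b = simulate_one_community(pb)
        assert np.array_equal(a.phases, b.phases[:10])

    def test_phase_diffusion_variance(self):
        p = OneCommunityParams(
            n_oscillators=200, K=0.0, D=0.5, n_cycles=4, seed=2, init_phase_sd=0.0
        )
        traj = simulate_one_community(p)
        lag = 25  # steps
        omega = 2 * np.pi / p.tau
        inc = traj.phases[:, lag::lag] - traj.phases[:, :-lag:lag] - omega * lag * traj.dt
        expected = p.D**2 * lag * traj.dt
        assert inc.var() == pytest.approx(expected, rel=0.1)

    def test_noiseless_order_parameter_nondecreasing(self):
        p = OneCommunityParams(
            n_oscillators=100, K=1.5, D=0.0, n_cycles=4, seed=6, init_phase_sd=1.0
        )
        r = instantaneous_order_parameter(simulate_one_community(p))
        assert np.all(np.diff(r) > -1e-6)

    def test_stationary_r_matches_self_consistency(self):
        p = OneCommunityParams(
            n_oscillators=400, K=2.0, D=1.0, dt=24.0 / 500, n_cycles=20, seed=3,
            init_phase_sd=0.5,
        )
        r = stationary_order_parameter(simulate_one_community(p))
        assert r == pytest.approx(_mean_field_fixed_point(2.0), abs=0.03)

    def test_subcritical_desynchronizes(self):
        # C = 2K/D < 2 has only the incoherent state
        p = OneCommunityParams(
            n_oscillators=300, K=0.5, D=1.0, n_cycles=10, seed=8, init_phase_sd=0.3
        )
        r = stationary_order_parameter(simulate_one_community(p), discard_fraction=0.7)
        assert r < 3.0 / np.sqrt(300) + 0.1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            OneCommunityParams(n_oscillators=1, K=1.0, D=1.0)
        with pytest.raises(ValueError):
            OneCommunityParams(n_oscillators=10, K=-1.0, D=1.0)
        with pytest.raises(ValueError):
            OneCommunityParams(n_oscillators=10, K=1.0, D=1.0, dt=1.0)  # > tau/100
        with pytest.raises(ValueError):
            OneCommunityParams(n_oscillators=10, K=np.inf, D=1.0)


class TestTwoCommunity:
    def test_decoupled_community_matches_one_community_run(self):
        # L = 0 and the 2N divisor make community 1 an independent
        # one-community system with effective coupling K1/2, fed by the same
        # per-cell noise substreams -> bit-identical trajectories
        n = 40
        p2 = TwoCommunityParams(
            n_per_community=n, K1=4.0, K2=3.0, L1=0.0, L2=0.0, D=1.0,
            n_cycles=3, seed=5,
        )
        p1 = OneCommunityParams(
            n_oscillators=n, K=2.0, D=1.0, n_cycles=3, seed=5
        )
        t2 = simulate_two_community(p2)
        t1 = simulate_one_community(p1)
        assert np.allclose(t2.phases[:n], t1.phases, atol=1e-12)

    def test_exchangeable_communities_have_equal_coherence(self):
        p = TwoCommunityParams(
            n_per_community=150, K1=4.0, K2=4.0, L1=4.0, L2=4.0, D=1.0,
            n_cycles=10, seed=21, init_phase_sd=0.5,
        )
        traj = simulate_two_community(p)
        r1 = stationary_order_parameter(traj, community=1)
        r2 = stationary_order_parameter(traj, community=2)
        assert r1 == pytest.approx(r2, abs=0.05)

    def test_stationary_coherence_solves_coupled_self_consistency(self):
        p = TwoCommunityParams(
            n_per_community=300, K1=4.0, K2=3.0, L1=1.0, L2=2.0, D=1.0,
            dt=24.0 / 500, n_cycles=20, seed=5, init_phase_sd=0.5,
        )
        traj = simulate_two_community(p)
        r1 = stationary_order_parameter(traj, community=1)
        r2 = stationary_order_parameter(traj, community=2)
        V = lambda x: i1e(x) / i0e(x)
        assert V(p.K1 * r1 + p.L1 * r2) == pytest.approx(r1, abs=0.03)
        assert V(p.K2 * r2 + p.L2 * r1) == pytest.approx(r2, abs=0.03)

    def test_fixed_point_solver_agrees_with_bessel_ratio(self):
        r1, r2 = two_community_fixed_point(4.0, 1.0, 3.0, 2.0, 1.0)
        V = lambda x: i1e(x) / i0e(x)
        assert V(4 * r1 + r2) == pytest.approx(r1, abs=1e-10)
        assert V(3 * r2 + 2 * r1) == pytest.approx(r2, abs=1e-10)

    def test_labels_and_shapes(self):
        p = TwoCommunityParams(
            n_per_community=5, K1=1.0, K2=1.0, L1=0.5, L2=0.5, D=0.5, n_cycles=1, seed=0
        )
        traj = simulate_two_community(p)
        assert list(traj.community_labels) == [1] * 5 + [2] * 5


class TestRender:
    def test_peaks_at_phase_zero_with_unit_amplitude(self):
        p = OneCommunityParams(
            n_oscillators=3, K=0.0, D=0.0, n_cycles=3, seed=0, init_phase_sd=0.0
        )
        traj = simulate_one_community(p)
        opts = RenderOptions(
            baseline_mean=0.0, baseline_sd=0.0, amplitude_mean=2.0, amplitude_sd=0.0,
            noise_sd=0.0,
        )
        times, intensities = render_bioluminescence(traj, opts)
        assert intensities.max() == pytest.approx(2.0, abs=1e-9)
        # phases start at 0 -> maxima at t = 0, 24, 48, 72
        peak_idx = np.flatnonzero(intensities[0] > 2.0 - 1e-9)
        assert np.allclose(times[peak_idx] % 24.0, 0.0, atol=1e-9)

    def test_constant_antiphase_gives_flat_baseline(self):
        traj_phases = np.full((2, 50), np.pi)
        from scnsync.simulate import PhaseTrajectory

        traj = PhaseTrajectory(
            times=np.arange(50) * 0.5, phases=traj_phases,
            community_labels=np.ones(2, int), tau=24.0,
        )
        opts = RenderOptions(
            baseline_mean=7.0, baseline_sd=0.0, amplitude_mean=2.0, amplitude_sd=0.0,
            noise_sd=0.0,
        )
        _, intensities = render_bioluminescence(traj, opts)
        assert np.allclose(intensities, 7.0, atol=1e-9)

    def test_peak_detection_recovers_noiseless_crossings(self, noiseless_slice):
        _, fixture, series = noiseless_slice
        ids = {c: i for i, c in enumerate(fixture.cell_ids)}
        truth = fixture.ground_truth["phase_zero_crossings_h"]
        errors = []
        for cid, peaks in zip(series.cell_ids, series.peak_times_h):
            gt = np.asarray(truth[ids[cid]])
            for t in peaks:
                errors.append(np.min(np.abs(gt - t)))
        assert np.mean(np.asarray(errors) <= 0.5) >= 0.95


class TestCalibrateCondition:
    def test_symmetric_targets_give_equal_couplings(self):
        p = calibrate_condition(0.94, 0.94, L_choice=1.0)
        assert p.K1 == pytest.approx(p.K2, rel=1e-12)

    def test_zero_between_coupling_intercept(self):
        from scnsync.one_community import solve_coherence_concentration

        p = calibrate_condition(0.77, 0.81, L_choice=0.0)
        assert p.K1 == pytest.approx(solve_coherence_concentration(0.77) / 0.77)
        assert p.K2 == pytest.approx(solve_coherence_concentration(0.81) / 0.81)

    def test_returned_params_lie_on_the_lines(self):
        from scnsync.two_community import condition_lines, point_on_line

        for r1, r2 in CONDITION_PRESETS.values():
            p = calibrate_condition(r1, r2, L_choice=0.8)
            lines = condition_lines(r1, r2)
            k1, _ = point_on_line(lines, 1, L=p.L1)
            k2, _ = point_on_line(lines, 2, L=p.L2)
            assert p.K1 == pytest.approx(k1, abs=1e-9)
            assert p.K2 == pytest.approx(k2, abs=1e-9)

    def test_rejects_bad_targets(self):
        with pytest.raises(ValueError):
            calibrate_condition(1.0, 0.9)
        with pytest.raises(ValueError):
            calibrate_condition(0.5, 0.9, L_choice=100.0)  # implied K < 0

    def test_simulated_coherence_hits_targets(self):
        r1, r2 = CONDITION_PRESETS["young_SP"]
        p = calibrate_condition(
            r1, r2, L_choice=1.0, n_per_community=200, n_cycles=10, seed=33
        )
        p = TwoCommunityParams(**{**p.__dict__, "dt": 24.0 / 500})
        traj = simulate_two_community(p)
        assert stationary_order_parameter(traj, community=1) == pytest.approx(r1, abs=0.05)
        assert stationary_order_parameter(traj, community=2) == pytest.approx(r2, abs=0.05)


class TestFixtureIO:
    def test_write_and_reload_round_trip(self, tmp_path, noiseless_slice):
        import json

        import pandas as pd

        from scnsync.traces import TraceMatrix

        _, fixture, _ = noiseless_slice
        prefix = tmp_path / "slice"
        fixture.write(prefix)
        tm = TraceMatrix.read_csv(f"{prefix}_traces.csv")
        assert tm.n_cells == len(fixture.cell_ids)
        labels = pd.read_csv(f"{prefix}_labels.csv")
        assert list(labels["community"]) == list(fixture.community_labels)
        with open(f"{prefix}_truth.json") as fh:
            truth = json.load(fh)
        assert truth["ground_truth"]["model"] == "one_community"

    def test_metadata_vocabulary_enforced(self, noiseless_slice):
        params, _, _ = noiseless_slice
        with pytest.raises(ValueError):
            make_slice_fixture(params, metadata={"age": "middle-aged"})
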