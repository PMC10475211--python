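"""Synthetic SCN slices: noisy Kuramoto SDEs rendered as bioluminescence traces.

This module is the ground-truth generator for the whole pipeline. It
simulates the one- and two-community noisy Kuramoto models,

    dθ_i = (K/N) Σ_j sin(θ_j − θ_i) dt + D dW_i                    (one community)

    dθ_{1,i} = (K1/2N) Σ_k sin(θ_{1,k} − θ_{1,i}) dt
             + (L1/2N) Σ_l sin(θ_{2,l} − θ_{1,i}) dt + D dW_{1,i}  (two communities)

(and symmetrically for community 2), then renders the phase trajectories as
hourly PER2::LUC-like intensity traces with per-cell baseline and amplitude
variation and additive measurement noise.

Conventions
-----------
* Simulation runs in the lab frame with a common natural frequency 2π/τ; the
  mean-field analysis is frame-invariant, so this is equivalent to the
  rotating-frame model with zero frequency.
* The between- and within-community mean-field divisor of the two-community
  model is 2N (N oscillators per community), matching the model equations
  this package analyses. With D = 1 the stationary order parameters then
  satisfy the self-consistency pair V(K1·r1 + L1·r2) = r1 and
  V(K2·r2 + L2·r1) = r2.
* Integrator: Euler–Maruyama with dt = τ/200 by default.
* Randomness: one master seed; every cell draws its initial phase and its
  noise path from its own spawned substream, so enlarging the population
  never perturbs existing cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from scnsync.one_community import (
    bessel_ratio,
    solve_coherence_concentration,
)

__all__ = [
    "OneCommunityParams",
    "TwoCommunityParams",
    "PhaseTrajectory",
    "RenderOptions",
    "SliceFixture",
    "simulate_one_community",
    "simulate_two_community",
    "render_bioluminescence",
    "calibrate_condition",
    "make_slice_fixture",
    "instantaneous_order_parameter",
    "phase_zero_crossings",
    "stationary_order_parameter",
    "two_community_fixed_point",
    "CONDITION_PRESETS",
]

_AGE_VOCAB = {"young", "old"}
_PHOTOPERIOD_VOCAB = {"LP", "SP"}
_POSITION_VOCAB = {"anterior", "posterior"}

#: Default SD (radians) of the wrapped-normal initial phase distribution.
DEFAULT_INIT_PHASE_SD = 1.0


def _validate_common(tau, dt, n_cycles):
    if not np.isfinite(tau) or tau <= 0:
        raise ValueError("tau must be positive and finite")
    if not np.isfinite(dt) or dt <= 0 or dt > tau / 100.0:
        raise ValueError(f"dt must satisfy 0 < dt <= tau/100 (= {tau/100.0:g} h)")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")


@dataclass(frozen=True)
class OneCommunityParams:
    """Parameters of the one-community noisy Kuramoto SDE."""

    n_oscillators: int
    K: float
    D: float
    tau: float = 24.0
    dt: float = 24.0 / 200.0
    n_cycles: int = 10
    seed: int = 0
    init_phase_sd: float = DEFAULT_INIT_PHASE_SD

    def __post_init__(self):
        if self.n_oscillators < 2:
            raise ValueError("need at least 2 oscillators")
        if not (np.isfinite(self.K) and self.K >= 0):
            raise ValueError("K must be finite and non-negative")
        if not (np.isfinite(self.D) and self.D >= 0):
            raise ValueError("D must be finite and non-negative")
        _validate_common(self.tau, self.dt, self.n_cycles)


@dataclass(frozen=True)
class TwoCommunityParams:
    """Parameters of the two-community noisy Kuramoto SDE.

    L1 couples community 2 onto community 1 and L2 community 1 onto
    community 2; either may be negative (repulsive). Both community mean
    phases are assumed equal (ψ1 = ψ2 = 0), which the common natural
    frequency and symmetric initial law realize automatically.
    """

    n_per_community: int
    K1: float
    K2: float
    L1: float
    L2: float
    D: float
    tau: float = 24.0
    dt: float = 24.0 / 200.0
    n_cycles: int = 10
    seed: int = 0
    init_phase_sd: float = DEFAULT_INIT_PHASE_SD
    #: initial mean phase of community 2 relative to community 1 (rad); a
    #: nonzero offset seeds a phase-split state (e.g. under repulsive L)
    init_phase_offset: float = 0.0

    def __post_init__(self):
        if self.n_per_community < 2:
            raise ValueError("need at least 2 oscillators per community")
        for name in ("K1", "K2", "L1", "L2", "D"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.K1 < 0 or self.K2 < 0:
            raise ValueError("within-community couplings K1, K2 must be >= 0")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        _validate_common(self.tau, self.dt, self.n_cycles)


@dataclass(frozen=True)
class PhaseTrajectory:
    """Unwrapped phase trajectories: oscillators × time."""

    times: np.ndarray
    phases: np.ndarray
    community_labels: np.ndarray
    tau: float

    def __post_init__(self):
        t = np.asarray(self.times, float)
        p = np.asarray(self.phases, float)
        lab = np.asarray(self.community_labels, int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "phases", p)
        object.__setattr__(self, "community_labels", lab)
        if p.shape != (len(lab), len(t)):
            raise ValueError("phases must be (n_oscillators, n_times)")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be strictly increasing and uniform")
        if not np.all(np.isfinite(p)):
            raise ValueError("phases must be finite")

    @property
    def n_oscillators(self) -> int:
        return self.phases.shape[0]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _initial_phases_and_noise(n, n_steps, seed, init_sd):
    """Per-cell substreams: initial phase + the cell's whole noise path."""
    children = np.random.SeedSequence(seed).spawn(n)
    theta0 = np.empty(n)
    noise = np.empty((n, n_steps))
    for i, child in enumerate(children):
        g = np.random.default_rng(child)
        theta0[i] = g.normal(0.0, init_sd)
        noise[i] = g.standard_normal(n_steps)
    return theta0, noise


def simulate_one_community(params: OneCommunityParams) -> PhaseTrajectory:
    """Euler–Maruyama integration of the one-community model.

    The mean-field form of the interaction is used: with
    r e^{iψ} = (1/N) Σ_j e^{iθ_j}, each oscillator feels a drift
    ω + K·r·sin(ψ − θ_i) with ω = 2π/τ the common natural frequency.
    """
    p = params
    n_steps = int(round(p.n_cycles * p.tau / p.dt))
    theta0, noise = _initial_phases_and_noise(
        p.n_oscillators, n_steps, p.seed, p.init_phase_sd
    )
    omega = 2.0 * np.pi / p.tau
    sqdt = np.sqrt(p.dt)
    theta = theta0.copy()
    out = np.empty((p.n_oscillators, n_steps + 1))
    out[:, 0] = theta
    for s in range(n_steps):
        z = np.exp(1j * theta).mean()
        r, psi = np.abs(z), np.angle(z)
        drift = omega + p.K * r * np.sin(psi - theta)
        theta = theta + drift * p.dt + p.D * sqdt * noise[:, s]
        out[:, s + 1] = theta
    times = np.arange(n_steps + 1) * p.dt
    return PhaseTrajectory(times, out, np.ones(p.n_oscillators, int), p.tau)


def simulate_two_community(params: TwoCommunityParams) -> PhaseTrajectory:
    """Euler–Maruyama integration of the two-community model.

    Both the within- and between-community mean fields carry the 2N divisor,
    so with r_c e^{iψ_c} the community mean phasors, community 1 feels the
    drift ω + (K1/2)·r1·sin(ψ1 − θ) + (L1/2)·r2·sin(ψ2 − θ).
    """
    p = params
    n = p.n_per_community
    n_steps = int(round(p.n_cycles * p.tau / p.dt))
    theta0, noise = _initial_phases_and_noise(2 * n, n_steps, p.seed, p.init_phase_sd)
    theta0[n:] += p.init_phase_offset
    omega = 2.0 * np.pi / p.tau
    sqdt = np.sqrt(p.dt)
    theta = theta0.copy()
    out = np.empty((2 * n, n_steps + 1))
    out[:, 0] = theta
    sl1, sl2 = slice(0, n), slice(n, 2 * n)
    for s in range(n_steps):
        z1 = np.exp(1j * theta[sl1]).mean()
        z2 = np.exp(1j * theta[sl2]).mean()
        r1, psi1 = np.abs(z1), np.angle(z1)
        r2, psi2 = np.abs(z2), np.angle(z2)
        d1 = (
            omega
            + 0.5 * p.K1 * r1 * np.sin(psi1 - theta[sl1])
            + 0.5 * p.L1 * r2 * np.sin(psi2 - theta[sl1])
        )
        d2 = (
            omega
            + 0.5 * p.K2 * r2 * np.sin(psi2 - theta[sl2])
            + 0.5 * p.L2 * r1 * np.sin(psi1 - theta[sl2])
        )
        theta[sl1] = theta[sl1] + d1 * p.dt + p.D * sqdt * noise[sl1, s]
        theta[sl2] = theta[sl2] + d2 * p.dt + p.D * sqdt * noise[sl2, s]
        out[:, s + 1] = theta
    times = np.arange(n_steps + 1) * p.dt
    labels = np.concatenate([np.ones(n, int), np.full(n, 2, int)])
    return PhaseTrajectory(times, out, labels, p.tau)


# ---------------------------------------------------------------------------
# Trajectory summaries
# ---------------------------------------------------------------------------

def instantaneous_order_parameter(traj: PhaseTrajectory, community: int | None = None):
    """r(t): magnitude of the mean unit phasor at every stored time."""
    phases = traj.phases
    if community is not None:
        phases = phases[traj.community_labels == community]
    return np.abs(np.exp(1j * phases).mean(axis=0))


def stationary_order_parameter(
    traj: PhaseTrajectory, community: int | None = None, discard_fraction: float = 0.5
) -> float:
    """Time-averaged r(t) after discarding the initial transient."""
    r = instantaneous_order_parameter(traj, community)
    start = int(len(r) * discard_fraction)
    return float(np.mean(r[start:]))


def phase_zero_crossings(traj: PhaseTrajectory) -> list:
    """Per cell, the times where the unwrapped phase crosses 0 (mod 2π).

    These are the peak times of the noiseless raised-cosine waveform and
    serve as ground truth for peak-detection accuracy checks.
    """
    out = []
    for row in traj.phases:
        k_lo = np.ceil(row[0] / (2 * np.pi))
        k_hi = np.floor(row[-1] / (2 * np.pi))
        targets = 2 * np.pi * np.arange(k_lo, k_hi + 1)
        # phase is noisy, not monotone; take the first upward crossing per level
        crossings = []
        for tgt in targets:
            above = row >= tgt
            idx = np.flatnonzero(~above[:-1] & above[1:])
            if len(idx) == 0:
                continue
            i = idx[0]
            f = (tgt - row[i]) / (row[i + 1] - row[i])
            crossings.append(traj.times[i] + f * traj.dt)
        out.append(np.asarray(crossings))
    return out


def two_community_fixed_point(
    K1: float, L1: float, K2: float, L2: float, D: float = 1.0,
    r_init: tuple = (0.9, 0.9), max_iter: int = 10_000, tol: float = 1e-12,
) -> tuple:
    """Solve the coupled self-consistency pair for (r1, r2) by fixed-point iteration.

    r1 = V((K1·r1 + L1·r2)/D²),  r2 = V((K2·r2 + L2·r1)/D²).

    With D = 1 this is the stationary prediction for the 2N-divisor
    two-community simulation. Damped iteration from a synchronized start
    converges to the coherent branch; (0, 0) is always a trivial solution.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    r1, r2 = r_init
    for _ in range(max_iter):
        x1 = (K1 * r1 + L1 * r2) / D**2
        x2 = (K2 * r2 + L2 * r1) / D**2
        new1 = float(bessel_ratio(max(x1, 0.0)))
        new2 = float(bessel_ratio(max(x2, 0.0)))
        n1 = 0.5 * r1 + 0.5 * new1
        n2 = 0.5 * r2 + 0.5 * new2
        if abs(n1 - r1) < tol and abs(n2 - r2) < tol:
            return n1, n2
        r1, r2 = n1, n2
    return r1, r2


# ---------------------------------------------------------------------------
# Rendering and fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderOptions:
    """Phase → intensity rendering options (arbitrary units, hours)."""

    baseline_mean: float = 100.0
    baseline_sd: float = 20.0
    amplitude_mean: float = 200.0
    amplitude_sd: float = 40.0
    noise_sd: float = 5.0
    sampling_interval_h: float = 1.0
    #: amplitude draws below this positive floor are clipped to it
    amplitude_floor: float = 1e-3

    def __post_init__(self):
        if self.amplitude_mean <= 0:
            raise ValueError("amplitude_mean must be positive")
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling_interval_h must be positive")


@dataclass(frozen=True)
class SliceFixture:
    """A rendered synthetic slice with its ground truth."""

    times_h: np.ndarray
    intensities: np.ndarray
    cell_ids: list
    community_labels: np.ndarray
    metadata: dict
    ground_truth: dict

    def __post_init__(self):
        meta = self.metadata
        for key, vocab in (
            ("age", _AGE_VOCAB),
            ("photoperiod", _PHOTOPERIOD_VOCAB),
            ("position", _POSITION_VOCAB),
        ):
            if key in meta and meta[key] not in vocab:
                raise ValueError(f"metadata {key}={meta[key]!r} not in {sorted(vocab)}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("trace values must be finite")

    def trace_matrix(self):
        from scnsync.traces import TraceMatrix

        return TraceMatrix(
            times_h=self.times_h,
            intensities=self.intensities,
            cell_ids=self.cell_ids,
            metadata=dict(self.metadata),
        )

    def write(self, prefix) -> None:
        """Write trace CSV, ground-truth/metadata JSON and labels CSV."""
        self.trace_matrix().write_csv(f"{prefix}_traces.csv")
        pd.DataFrame(
            {"cell_id": self.cell_ids, "community": self.community_labels}
        ).to_csv(f"{prefix}_labels.csv", index=False)
        payload = {"metadata": self.metadata, "ground_truth": self.ground_truth}
        with open(f"{prefix}_truth.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def render_bioluminescence(
    traj: PhaseTrajectory,
    opts: RenderOptions = RenderOptions(),
    seed: int = 0,
) -> np.ndarray:
    """Render phases as sampled intensity traces.

    Per cell i: I_i(t) = b_i + a_i·(1 + cos θ_i(t))/2 + ε with
    b_i ~ N(baseline_mean, baseline_sd²), a_i ~ N(amplitude_mean,
    amplitude_sd²) clipped at a small positive floor, and
    ε ~ N(0, noise_sd²) i.i.d. per sample. Peaks of the noiseless waveform
    sit exactly at θ_i = 0 (mod 2π). Returns (times_h, intensities).
    """
    if traj.phases.size == 0:
        raise ValueError("empty trajectory")
    step = opts.sampling_interval_h
    n_samples = int(np.floor(traj.times[-1] / step)) + 1
    sample_times = np.arange(n_samples) * step
    # trajectory grid is uniform; sample by linear interpolation of phase
    idx = np.clip(sample_times / traj.dt, 0, len(traj.times) - 1)
    i0 = np.floor(idx).astype(int)
    i1 = np.minimum(i0 + 1, len(traj.times) - 1)
    frac = idx - i0
    phases = traj.phases[:, i0] * (1 - frac) + traj.phases[:, i1] * frac

    children = np.random.SeedSequence((seed, 0xB10)).spawn(traj.n_oscillators)
    intensities = np.empty_like(phases)
    for i, child in enumerate(children):
        g = np.random.default_rng(child)
        baseline = g.normal(opts.baseline_mean, opts.baseline_sd)
        amplitude = max(
            g.normal(opts.amplitude_mean, opts.amplitude_sd), opts.amplitude_floor
        )
        eps = g.normal(0.0, opts.noise_sd, n_samples)
        intensities[i] = baseline + amplitude * (1 + np.cos(phases[i])) / 2.0 + eps
    return sample_times, intensities


def calibrate_condition(
    r1_target: float,
    r2_target: float,
    L_choice: float = 1.0,
    D: float = 1.0,
    *,
    n_per_community: int = 300,
    tau: float = 24.0,
    n_cycles: int = 10,
    seed: int = 0,
) -> TwoCommunityParams:
    """Pick two-community couplings whose stationary coherence hits the targets.

    Inverts the self-consistency lines: with C_c the root of V(C_c) = r_c,
    the within-community couplings K_c = (C_c·D² − L_c·r_other)/r_c put the
    system (at the chosen between-community couplings L1 = L2 = L_choice) on
    the stationary manifold with order parameters (r1_target, r2_target).
    """
    for r in (r1_target, r2_target):
        if not (0.0 < r < 1.0):
            raise ValueError("target order parameters must lie in (0, 1)")
    C1 = solve_coherence_concentration(r1_target)
    C2 = solve_coherence_concentration(r2_target)
    K1 = (C1 * D**2 - L_choice * r2_target) / r1_target
    K2 = (C2 * D**2 - L_choice * r1_target) / r2_target
    if K1 < 0 or K2 < 0:
        raise ValueError(
            "L_choice too large: implied within-community coupling is negative"
        )
    return TwoCommunityParams(
        n_per_community=n_per_community,
        K1=K1,
        K2=K2,
        L1=L_choice,
        L2=L_choice,
        D=D,
        tau=tau,
        n_cycles=n_cycles,
        seed=seed,
        init_phase_sd=0.5,
    )


#: Averaged per-condition order parameters (medial, lateral) reported for
#: young/old mice under long/short photoperiod.
CONDITION_PRESETS = {
    "young_LP": (0.77, 0.81),
    "young_SP": (0.94, 0.94),
    "old_LP": (0.84, 0.77),
    "old_SP": (0.91, 0.90),
}


def make_slice_fixture(
    params: OneCommunityParams | TwoCommunityParams,
    opts: RenderOptions = RenderOptions(),
    metadata: dict | None = None,
    render_seed: int | None = None,
) -> SliceFixture:
    """Simulate, render, and package a slice with its ground truth."""
    if isinstance(params, OneCommunityParams):
        traj = simulate_one_community(params)
    else:
        traj = simulate_two_community(params)
    if render_seed is None:
        render_seed = params.seed + 1
    times_h, intensities = render_bioluminescence(traj, opts, seed=render_seed)
    gt = {
        "params": asdict(params),
        "model": "one_community" if isinstance(params, OneCommunityParams) else "two_community",
        "stationary_r": stationary_order_parameter(traj),
        "phase_zero_crossings_h": [list(c) for c in phase_zero_crossings(traj)],
    }
    if isinstance(params, TwoCommunityParams):
        gt["stationary_r1"] = stationary_order_parameter(traj, community=1)
        gt["stationary_r2"] = stationary_order_parameter(traj, community=2)
    n = traj.n_oscillators
    return SliceFixture(
        times_h=times_h,
        intensities=intensities,
        cell_ids=[f"cell_{i:04d}" for i in range(n)],
        community_labels=traj.community_labels,
        metadata=metadata or {},
        ground_truth=gt,
    )
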