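"""Simulate a one-community SCN slice and check mean-field self-consistency.

Runs the noisy Kuramoto SDE for 300 coupled cells (K=2, D=1), measures the
stationary order parameter, and compares it with the fixed point of the
self-consistency equation r = V(2Kr/D^2).
"""

from scipy.optimize import brentq

from scnsync import OneCommunityParams, bessel_ratio, make_slice_fixture
from scnsync.simulate import stationary_order_parameter, simulate_one_community

params = OneCommunityParams(
    n_oscillators=300, K=2.0, D=1.0, dt=24.0 / 500, n_cycles=15, seed=42,
    init_phase_sd=0.5,
)
traj = simulate_one_community(params)
r_sim = stationary_order_parameter(traj)
r_theory = brentq(lambda r: bessel_ratio(2 * params.K * r) - r, 1e-6, 1 - 1e-9)

print(f"simulated stationary order parameter r = {r_sim:.3f}")
print(f"mean-field fixed point of r = V(2Kr)    = {r_theory:.3f}")
print("Close agreement means the simulated population sits on the coherent")
print("branch the inference modules assume; r ~ 0.83 at K=2, D=1.")

fixture = make_slice_fixture(params)
print(
    f"rendered {fixture.intensities.shape[0]} cells x "
    f"{fixture.intensities.shape[1]} hourly samples of bioluminescence"
)
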