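"""Generalized leaky integrate-and-fire FSI unit with two internal ionic
currents and an adaptive firing threshold (Mihalas-Niebur form).

State: two ionic currents I1, I2 decaying at rates k1, k2; membrane potential
V with leak G toward E_L; instantaneous threshold Theta attracted to
Theta_inf + (a/b)(V - E_L). On a spike (V >= Theta) each current is updated as
I_j <- R_j * I_j + A_j (the Class-2 set uses A_j = 0, so I1 is reset and I2
kept), the membrane is held at the threshold value for 1 ms
(approximating the action-potential width so current can flow through gap
junctions) and then reset to V_r, and the threshold is raised to at least
Theta_r. With the Class-2 parameter set the unit shows type 2 excitability:
firing begins at a nonzero minimum rate at rheobase.

Units: voltages in volts; C = 1 so currents are expressed in V/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["NeuronParams", "NeuronState", "step", "run_neuron", "fi_curve"]


@dataclass(frozen=True)
class NeuronParams:
    """Class-2 FSI parameters.

    k1, k2 are the ionic-current decay rates of the original generalized
    integrate-and-fire model's Class-2 set; the remaining values follow the
    model configuration used throughout the network simulations.
    """

    k1: float = 200.0  # 1/s
    k2: float = 20.0  # 1/s
    a: float = 5.0  # 1/s, threshold-voltage coupling
    b: float = 10.0  # 1/s, threshold relaxation
    C: float = 1.0  # normalized capacitance
    G: float = 50.0  # 1/s, leak rate
    E_L: float = -0.07  # V
    Theta_inf: float = -0.05  # V
    V_r: float = -0.07  # V
    Theta_r: float = -0.06  # V
    R1: float = 0.0  # multiplicative current reset on spike
    R2: float = 1.0
    A1: float = 0.0  # additive current increment on spike (V/s)
    A2: float = 0.0
    t_hold: float = 0.001  # s, spike hold duration

    @classmethod
    def from_profile(cls, name: str = "class2_default") -> "NeuronParams":
        """Load a named parameter profile shipped with the package."""
        from importlib.resources import files

        import yaml

        text = files("striatal_gamma").joinpath(f"profiles/{name}.yaml").read_text()
        return cls(**yaml.safe_load(text))

    def __post_init__(self):
        if self.G <= 0 or self.b <= 0:
            raise ValueError("G and b must be positive")
        if self.Theta_r <= self.V_r:
            raise ValueError("Theta_r must exceed V_r")
        if self.t_hold < 0:
            raise ValueError("t_hold must be >= 0")


@dataclass(frozen=True)
class NeuronState:
    V: float = -0.07
    Theta: float = -0.05
    I1: float = 0.0
    I2: float = 0.0
    hold_until: float = -1.0  # end time of the current spike hold
    hold_voltage: float = 0.0  # clamped value during the hold
    t: float = 0.0

    @property
    def in_hold(self) -> bool:
        return self.t < self.hold_until


class IntegrationDivergedError(RuntimeError):
    pass


def step(
    state: NeuronState,
    params: NeuronParams,
    I_ext: float = 0.0,
    I_syn: float = 0.0,
    I_gap: float = 0.0,
    dt: float = 5e-5,
) -> tuple[NeuronState, bool]:
    """One forward-Euler step; returns the new state and a spike flag.

    During a spike hold the membrane is clamped at the threshold value
    recorded at spike time (so gap junctions see the depolarization) while
    the threshold equation keeps evolving; at the end of the hold the
    membrane jumps to V_r.
    """
    if dt > 1e-4:
        raise ValueError("dt must be <= 0.1 ms")
    p = params
    if not all(np.isfinite([state.V, state.Theta, state.I1, state.I2])):
        raise IntegrationDivergedError(f"non-finite state at t={state.t}")

    I1 = state.I1 * (1 - p.k1 * dt)
    I2 = state.I2 * (1 - p.k2 * dt)
    t_next = state.t + dt

    if state.in_hold:
        V_eff = state.hold_voltage
        Theta = state.Theta + dt * (p.a * (V_eff - p.E_L) - p.b * (state.Theta - p.Theta_inf))
        if t_next < state.hold_until:
            V = V_eff
            return (
                replace(state, V=V, Theta=Theta, I1=I1, I2=I2, t=t_next),
                False,
            )
        V = p.V_r  # hold expired: reset
        return (
            replace(state, V=V, Theta=Theta, I1=I1, I2=I2, t=t_next, hold_until=-1.0),
            False,
        )

    dV = (I_ext + I1 + I2 + I_syn + I_gap) / p.C - p.G * (state.V - p.E_L)
    V = state.V + dt * dV
    Theta = state.Theta + dt * (p.a * (state.V - p.E_L) - p.b * (state.Theta - p.Theta_inf))

    if V >= Theta:
        theta_spike = Theta
        I1 = p.R1 * I1 + p.A1
        I2 = p.R2 * I2 + p.A2
        Theta = max(Theta, p.Theta_r)
        new = NeuronState(
            V=theta_spike,
            Theta=Theta,
            I1=I1,
            I2=I2,
            hold_until=t_next + p.t_hold,
            hold_voltage=theta_spike,
            t=t_next,
        )
        return new, True

    return replace(state, V=V, Theta=Theta, I1=I1, I2=I2, t=t_next), False


def run_neuron(
    params: NeuronParams,
    I_ext,
    duration: float,
    dt: float = 5e-5,
    state: NeuronState | None = None,
):
    """Simulate a single unit under external drive.

    ``I_ext`` is a scalar or a per-step array. Returns (spike_times, V_trace,
    Theta_trace).
    """
    n = int(round(duration / dt))
    drive = np.broadcast_to(np.asarray(I_ext, dtype=float), (n,)) if np.ndim(I_ext) else np.full(n, float(I_ext))
    st = state or NeuronState(V=params.E_L, Theta=params.Theta_inf)
    spikes = []
    V = np.empty(n)
    Th = np.empty(n)
    for i in range(n):
        st, spiked = step(st, params, I_ext=drive[i], dt=dt)
        if spiked:
            spikes.append(st.t)
        V[i] = st.V
        Th[i] = st.Theta
    return np.array(spikes), V, Th


def fi_curve(
    params: NeuronParams,
    currents,
    duration: float = 5.0,
    discard: float = 1.0,
    dt: float = 5e-5,
) -> np.ndarray:
    """Steady-state firing rate (Hz) for each constant input current.

    Each current is simulated for ``discard + duration`` seconds and the rate
    is counted after the discard. With Class-2 parameters the first nonzero
    rate is bounded well away from zero (discontinuous F-I curve).
    """
    currents = np.asarray(currents, dtype=float)
    rates = np.empty(currents.size)
    for i, I in enumerate(currents):
        spikes, _, _ = run_neuron(params, I, discard + duration, dt=dt)
        rates[i] = np.sum(spikes > discard) / duration
    return rates
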