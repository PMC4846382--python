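"""Time-stepping of the full network: exponential Euler, spikes, recording.

The integrator is the exponential-Euler scheme at a default step of 0.1 ms.
For each variable with first-order relaxation dynamics the scheme is exact
over a step with frozen coefficients; for the voltage the membrane equation
is rewritten as dV/dt = (V_inf - V)/tau_V with tau_V = C/sum(g) and
V_inf = sum(g*E)/sum(g), coefficients frozen per step.

A spike is an upward threshold crossing (V_prev < threshold <= V_curr), at
most one per step; synaptic increments driven by a spike are applied at the
start of the following step (no explicit conduction delay).  Results are
reported only after a discarded startup transient (default 20 s) so that the
random initial conditions do not matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model_core import GATES, HHNeuronParams, HHState, steady_state, time_constant
from .network import NetworkModel, initial_conditions

__all__ = [
    "SimulationConfig",
    "SpikeRaster",
    "TrajectoryRecord",
    "SimulationUnstable",
    "detect_spikes",
    "step_exponential_euler",
    "simulate_network",
    "hh_rhs",
]


class SimulationUnstable(RuntimeError):
    """Raised when the integrator produces a non-finite state (instability)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and recording settings for one network simulation."""

    dt: float = 0.1  # ms
    duration: float = 50_000.0  # ms
    discard: float = 20_000.0  # ms of startup transient removed from outputs
    record_voltage_ids: tuple[int, ...] = ()
    record_dt: float = 1.0  # ms between recorded trace samples
    seed_init: int = 0
    slave_m_nap: bool = False  # slave m_NaP to its steady state (tau <= 1 ms)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.discard <= self.duration:
            raise ValueError("discard must satisfy 0 <= discard <= duration")


@dataclass
class SpikeRaster:
    """Per-neuron ordered spike times (ms), restricted to (discard, duration]."""

    spike_times: list[np.ndarray]
    E_L: np.ndarray
    duration: float
    discard: float

    @property
    def N(self) -> int:
        return len(self.spike_times)

    @property
    def window(self) -> float:
        """Length of the analyzed window in ms."""
        return self.duration - self.discard

    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.spike_times))

    def sorted_by_excitability(self) -> "SpikeRaster":
        """Reorder neurons by ascending E_L (Neuron-ID convention)."""
        order = np.argsort(self.E_L, kind="stable")
        return SpikeRaster(
            spike_times=[self.spike_times[i] for i in order],
            E_L=self.E_L[order],
            duration=self.duration,
            discard=self.discard,
        )


@dataclass
class TrajectoryRecord:
    """Decimated (V, h_NaP) traces for a subset of neurons."""

    t: np.ndarray  # ms, absolute simulation time
    V: np.ndarray  # shape (len(t), n_recorded)
    h_NaP: np.ndarray
    neuron_ids: tuple[int, ...]


def detect_spikes(V_prev: np.ndarray, V_curr: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean spike indicator: upward crossing V_prev < threshold <= V_curr."""
    V_prev = np.asarray(V_prev)
    V_curr = np.asarray(V_curr)
    return (V_prev < threshold) & (V_curr >= threshold)


def step_exponential_euler(x, x_inf, tau, dt: float):
    """One exponential-Euler update x <- x_inf + (x - x_inf) exp(-dt/tau).

    Exact for scalar linear relaxation with frozen coefficients; exposed for
    tests and for stepping individual gates outside the compiled loop.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return x_inf + (np.asarray(x) - x_inf) * np.exp(-dt / np.asarray(tau))


def _states_to_arrays(states: list[HHState]):
    get = lambda name: np.array([getattr(s, name) for s in states], dtype=float)
    return {k: get(k) for k in ("V", "m_Na", "h_Na", "m_NaP", "h_NaP", "m_K", "g_syn")}


def simulate_network(
    network: NetworkModel,
    config: SimulationConfig,
    init: list[HHState] | None = None,
) -> tuple[SpikeRaster, TrajectoryRecord]:
    """Run the full network and return spikes plus recorded traces.

    Deterministic: identical (network, config, initial conditions) give
    bit-identical outputs.  The startup transient (``config.discard``) is
    removed from both the raster and the traces.
    """
    if init is None:
        init = initial_conditions(network, config.seed_init)
    if len(init) != network.N:
        raise ValueError("initial-condition list does not match network size")
    arrs = _states_to_arrays(init)
    base = network.neurons[0]
    syn = network.synapse

    n_steps = int(round(config.duration / config.dt))
    record_every = max(1, int(round(config.record_dt / config.dt)))
    rec_ids = np.asarray(config.record_voltage_ids, dtype=np.int64)
    n_rec_steps = n_steps // record_every if len(rec_ids) else 0
    V_rec = np.empty((n_rec_steps, len(rec_ids)))
    h_rec = np.empty((n_rec_steps, len(rec_ids)))

    # generous cap: sustained 200 Hz across the whole population
    max_spikes = int(network.N * config.duration / 1000.0 * 200) + 1000
    spike_neuron = np.empty(max_spikes, dtype=np.int64)
    spike_step = np.empty(max_spikes, dtype=np.int64)

    status, n_spikes, last_step = _kernels.hh_network_loop(
        config.dt, n_steps,
        arrs["V"], arrs["m_Na"], arrs["h_Na"], arrs["m_NaP"], arrs["h_NaP"],
        arrs["m_K"], arrs["g_syn"],
        network.E_L, network.gbar_NaP, network.weights,
        base.C, base.gbar_Na, base.gbar_K, base.gbar_L,
        base.E_Na, base.E_K, base.E_SynE,
        syn.gbar_SynE, syn.tau_SynE, syn.spike_threshold,
        spike_neuron, spike_step, max_spikes,
        rec_ids, record_every if len(rec_ids) else 0, V_rec, h_rec,
        config.slave_m_nap,
    )
    if status != _kernels.STATUS_OK:
        raise SimulationUnstable(
            f"non-finite membrane potential at t = {last_step * config.dt:.1f} ms"
        )
    if n_spikes >= max_spikes:
        raise SimulationUnstable("spike buffer overflow (implausible firing rate)")

    times = spike_step[:n_spikes] * config.dt
    neurons = spike_neuron[:n_spikes]
    keep = times > config.discard
    times, neurons = times[keep], neurons[keep]
    spike_times = [
        np.sort(times[neurons == i]) for i in range(network.N)
    ]
    raster = SpikeRaster(
        spike_times=spike_times,
        E_L=network.E_L,
        duration=config.duration,
        discard=config.discard,
    )
    t_rec = (np.arange(1, n_rec_steps + 1) * record_every) * config.dt
    keep_t = t_rec > config.discard
    traces = TrajectoryRecord(
        t=t_rec[keep_t],
        V=V_rec[keep_t],
        h_NaP=h_rec[keep_t],
        neuron_ids=tuple(int(i) for i in rec_ids),
    )
    return raster, traces


def hh_rhs(t: float, y: np.ndarray, params: HHNeuronParams) -> np.ndarray:
    """Right-hand side of one uncoupled neuron, y = (V, m_Na, h_Na, m_NaP,
    h_NaP, m_K), for use with adaptive reference integrators in tests."""
    V, m_na, h_na, m_nap, h_nap, m_k = y
    g = params.gating
    i_na = params.gbar_Na * m_na**3 * h_na * (V - params.E_Na)
    i_nap = params.gbar_NaP * m_nap * h_nap * (V - params.E_Na)
    i_k = params.gbar_K * m_k**4 * (V - params.E_K)
    i_l = params.gbar_L * (V - params.E_L)
    dV = -(i_na + i_nap + i_k + i_l) / params.C
    out = [dV]
    for name, x in (("m_Na", m_na), ("h_Na", h_na), ("m_NaP", m_nap),
                    ("h_NaP", h_nap), ("m_K", m_k)):
        out.append((steady_state(g[name], V) - x) / time_constant(g[name], V))
    return np.array(out)
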