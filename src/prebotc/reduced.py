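"""Reduced activity-based model: three mutually excitatory non-spiking units.

Each unit stands for a cluster of neurons with a common excitability level and
carries two variables, a fast membrane potential V and the slow persistent-
sodium inactivation h_NaP:

    C dV_i/dt = -I_NaP_i - I_L_i - I_SynE_i
    tau_h(V_i) dh_i/dt = h_inf(V_i) - h_i

with I_NaP = gbar_NaP * m_inf(V) * h * (V - E_Na) (activation instantaneous),
I_L = gbar_L * (V - E_L_i), and synaptic input
I_SynE_i = sum_{j != i} w * f(V_j) * gbar_SynE * (V_i - E_SynE) where f is a
piecewise-linear output (normalized firing rate) clamped between V_min and
V_max.  The three leak reversals (-54.5, -59.0, -63.5 mV) produce a
high-excitability (HE) burster, a moderate (ME) burster and a silent
low-excitability (LE) unit when uncoupled.

A network burst is LA exactly when the LE unit activates; the number N of
network burst events per LE-to-LE period labels the quantal regime "1:N".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels

__all__ = [
    "ReducedNeuronParams",
    "ReducedNetwork",
    "ReducedTrajectory",
    "ActivationEvent",
    "NetworkEvent",
    "output_function",
    "m_nap_inf",
    "h_nap_inf",
    "tau_h_nap",
    "reduced_derivatives",
    "simulate_reduced",
    "detect_activation_events",
    "detect_cycles",
    "quantal_counts",
    "classify_regime",
    "classify_single_neuron",
    "scan_excitability",
    "scan_weights",
    "le_emergence_threshold",
    "HE", "ME", "LE",
]

HE, ME, LE = 0, 1, 2  # unit indices by decreasing excitability

#: Default f(V) threshold defining an activation event (small but robust
#: against numerical ripple on the silent branch).
ACTIVE_THRESHOLD = 0.05

#: Consecutive identical LA-to-LA event counts required to call a regime stable.
STABLE_PERIODS = 5


@dataclass(frozen=True)
class ReducedNeuronParams:
    """Parameters of one activity-based unit (defaults = reduced-model table)."""

    C: float = 20.0  # pF
    gbar_NaP: float = 5.0  # nS
    gbar_L: float = 2.8  # nS
    gbar_SynE: float = 0.1  # nS
    E_Na: float = 50.0  # mV
    E_L: float = -59.0  # mV
    E_SynE: float = -10.0  # mV
    V_mNaP: float = -40.0  # mV
    k_mNaP: float = -6.0  # mV (negative: activation increases with V)
    V_hNaP: float = -59.0  # mV
    k_hNaP: float = 10.0  # mV
    V_tauhNaP: float = -59.0  # mV
    k_tauhNaP: float = 20.0  # mV
    tau_hNaP_max: float = 5000.0  # ms
    V_min: float = -50.0  # mV, f(V) threshold
    V_max: float = 0.0  # mV, f(V) saturation

    def __post_init__(self) -> None:
        if self.V_min >= self.V_max:
            raise ValueError("output function requires V_min < V_max")
        if self.tau_hNaP_max <= 0:
            raise ValueError("tau_hNaP_max must be positive")


#: Leak reversal potentials of the (HE, ME, LE) units, mV.
DEFAULT_E_L = (-54.5, -59.0, -63.5)


@dataclass
class ReducedNetwork:
    """Three units with all-to-all coupling of uniform weight w."""

    neurons: list[ReducedNeuronParams] = field(
        default_factory=lambda: [
            replace(ReducedNeuronParams(), E_L=e) for e in DEFAULT_E_L
        ]
    )
    w: float = 0.0

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("weight w must be non-negative")
        if len(self.neurons) == 3:
            e = [n.E_L for n in self.neurons]
            if not (e[HE] > e[ME] > e[LE]):
                raise ValueError("excitability must order E_L(HE) > E_L(ME) > E_L(LE)")

    @property
    def n(self) -> int:
        return len(self.neurons)

    @property
    def E_L(self) -> np.ndarray:
        return np.array([p.E_L for p in self.neurons])

    def weight_matrix(self) -> np.ndarray:
        W = np.full((self.n, self.n), self.w, dtype=float)
        np.fill_diagonal(W, 0.0)
        return W


def output_function(V, params: ReducedNeuronParams):
    """Piecewise-linear output f(V): 0 below V_min, linear to 1 at V_max."""
    V = np.asarray(V, dtype=float)
    out = np.clip((V - params.V_min) / (params.V_max - params.V_min), 0.0, 1.0)
    return out if out.ndim else float(out)


def m_nap_inf(V, params: ReducedNeuronParams):
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp((V - params.V_mNaP) / params.k_mNaP))
    return out if out.ndim else float(out)


def h_nap_inf(V, params: ReducedNeuronParams):
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp((V - params.V_hNaP) / params.k_hNaP))
    return out if out.ndim else float(out)


def tau_h_nap(V, params: ReducedNeuronParams):
    V = np.asarray(V, dtype=float)
    out = params.tau_hNaP_max / np.cosh((V - params.V_tauhNaP) / params.k_tauhNaP)
    return out if out.ndim else float(out)


def reduced_derivatives(
    V: np.ndarray, h: np.ndarray, network: ReducedNetwork
) -> tuple[np.ndarray, np.ndarray]:
    """(dV/dt, dh/dt) of the coupled system; plain-numpy reference RHS."""
    p = network.neurons[0]
    V = np.asarray(V, dtype=float)
    h = np.asarray(h, dtype=float)
    W = network.weight_matrix()
    f = output_function(V, p)
    drive = W.T @ f  # drive[i] = sum_j W[j, i] f(V_j)
    i_nap = p.gbar_NaP * m_nap_inf(V, p) * h * (V - p.E_Na)
    i_l = p.gbar_L * (V - network.E_L)
    i_syn = drive * p.gbar_SynE * (V - p.E_SynE)
    dV = -(i_nap + i_l + i_syn) / p.C
    dh = (h_nap_inf(V, p) - h) / tau_h_nap(V, p)
    return dV, dh


@dataclass
class ReducedTrajectory:
    """Recorded reduced-model run (transient already removed)."""

    t: np.ndarray  # ms
    V: np.ndarray  # (len(t), n)
    h: np.ndarray
    f: np.ndarray
    network: ReducedNetwork

    @property
    def summed_output(self) -> np.ndarray:
        return self.f.sum(axis=1)


def simulate_reduced(
    network: ReducedNetwork,
    duration: float = 300_000.0,
    dt: float = 0.5,
    discard: float = 50_000.0,
    record_dt: float = 5.0,
    V0: np.ndarray | None = None,
    h0: np.ndarray | None = None,
    el_perturbation: tuple[float, float, float] | None = None,
) -> ReducedTrajectory:
    """Integrate the reduced model with fixed-step RK4 and record traces.

    ``el_perturbation = (t_start_ms, t_end_ms, factor)`` multiplies every E_L
    by ``factor`` inside the window (e.g. 0.92 or 0.90 for the 8% / 10%
    excitability-reduction protocols).  Deterministic given identical inputs.
    """
    p = network.neurons[0]
    n = network.n
    V = np.array(V0, dtype=float) if V0 is not None else np.full(n, -60.0)
    h = np.array(h0, dtype=float) if h0 is not None else np.linspace(0.4, 0.6, n)
    n_steps = int(round(duration / dt))
    record_every = max(1, int(round(record_dt / dt)))
    n_rec = n_steps // record_every
    V_rec = np.empty((n_rec, n))
    h_rec = np.empty((n_rec, n))
    if el_perturbation is not None:
        t0, t1, fac = el_perturbation
        pert = (int(round(t0 / dt)), int(round(t1 / dt)), float(fac))
    else:
        pert = (0, 0, 1.0)
    status, last = _kernels.reduced_rk4_loop(
        dt, n_steps, V, h, network.E_L, network.weight_matrix(),
        p.C, p.gbar_NaP, p.gbar_L, p.gbar_SynE, p.E_Na, p.E_SynE,
        p.V_mNaP, p.k_mNaP, p.V_hNaP, p.k_hNaP,
        p.V_tauhNaP, p.k_tauhNaP, p.tau_hNaP_max, p.V_min, p.V_max,
        record_every, V_rec, h_rec,
        pert[0], pert[1], pert[2],
    )
    if status != _kernels.STATUS_OK:
        raise RuntimeError(f"reduced model diverged at t = {last * dt:.1f} ms")
    t = np.arange(1, n_rec + 1) * record_every * dt
    keep = t > discard
    f = output_function(V_rec[keep], p)
    return ReducedTrajectory(t=t[keep], V=V_rec[keep], h=h_rec[keep],
                             f=np.asarray(f), network=network)


@dataclass(frozen=True)
class ActivationEvent:
    """Maximal interval during which one unit's output exceeds threshold."""

    neuron: int
    onset: float  # ms
    offset: float  # ms


@dataclass
class NetworkEvent:
    """Temporally overlapping activation events merged across units."""

    onset: float
    offset: float
    participants: frozenset[int]

    @property
    def is_LA(self) -> bool:
        return LE in self.participants


def _runs_above(t: np.ndarray, x: np.ndarray, threshold: float) -> list[tuple[float, float]]:
    above = x > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]
    return [(float(t[s]), float(t[e - 1])) for s, e in zip(starts, ends)]


def detect_activation_events(
    traj: ReducedTrajectory, active_threshold: float = ACTIVE_THRESHOLD
) -> list[list[ActivationEvent]]:
    """Per-unit activation events: maximal runs of f(V) above threshold."""
    if not 0.0 < active_threshold < 1.0:
        raise ValueError("active_threshold must lie in (0, 1)")
    out: list[list[ActivationEvent]] = []
    for i in range(traj.network.n):
        out.append(
            [ActivationEvent(i, a, b)
             for a, b in _runs_above(traj.t, traj.f[:, i], active_threshold)]
        )
    return out


def detect_cycles(
    traj: ReducedTrajectory, active_threshold: float = ACTIVE_THRESHOLD
) -> tuple[list[list[ActivationEvent]], list[NetworkEvent]]:
    """Activation events per unit plus network events merged by overlap.

    A network event is LA exactly when the LE unit participates — the model's
    defining property of large-amplitude bursts.
    """
    per_neuron = detect_activation_events(traj, active_threshold)
    intervals = sorted(
        ((ev.onset, ev.offset, ev.neuron) for evs in per_neuron for ev in evs)
    )
    events: list[NetworkEvent] = []
    for a, b, i in intervals:
        if events and a <= events[-1].offset:
            ev = events[-1]
            ev.offset = max(ev.offset, b)
            ev.participants = ev.participants | {i}
        else:
            events.append(NetworkEvent(onset=a, offset=b, participants=frozenset({i})))
    return per_neuron, events


def quantal_counts(events: list[NetworkEvent]) -> list[int]:
    """Total burst events per LA-to-LA period (one count per complete period)."""
    la_onsets = [ev.onset for ev in events if ev.is_LA]
    counts = []
    for a, b in zip(la_onsets[:-1], la_onsets[1:]):
        counts.append(sum(1 for ev in events if a <= ev.onset < b))
    return counts


def classify_regime(events: list[NetworkEvent]) -> dict:
    """Quantal-regime label from a network-event sequence.

    Returns a dict with keys ``label`` ("1:N", "SA-only", "silent" or
    "irregular"), ``N`` (modal events per LA period or None) and ``counts``.
    A regime is called stable 1:N only if at least ``STABLE_PERIODS``
    consecutive LA-to-LA periods contain the same number of events.
    """
    if not events:
        return {"label": "silent", "N": None, "counts": []}
    counts = quantal_counts(events)
    if not counts:
        if any(ev.is_LA for ev in events):
            return {"label": "irregular", "N": None, "counts": []}
        return {"label": "SA-only", "N": None, "counts": []}
    modal = Counter(counts).most_common(1)[0][0]
    stable = any(
        all(c == counts[k] for c in counts[k:k + STABLE_PERIODS])
        for k in range(len(counts) - STABLE_PERIODS + 1)
    ) if len(counts) >= STABLE_PERIODS else False
    label = f"1:{modal}" if stable else "irregular"
    return {"label": label, "N": modal, "counts": counts}


def classify_single_neuron(
    E_L: float,
    duration: float = 200_000.0,
    discard: float = 50_000.0,
    dt: float = 0.5,
    active_threshold: float = ACTIVE_THRESHOLD,
) -> str:
    """Classify an uncoupled unit as 'silent', 'bursting' or 'tonic'.

    Bursting = sustained relaxation oscillation (the voltage keeps swinging
    between the hyperpolarized and depolarized nullcline branches through the
    second half of the analysis window); otherwise the unit has settled and
    is tonic when its steady output f(V) is depolarized, silent when not.
    """
    net = ReducedNetwork(neurons=[replace(ReducedNeuronParams(), E_L=E_L)], w=0.0)
    traj = simulate_reduced(net, duration=duration + discard, discard=discard, dt=dt,
                            V0=np.array([-60.0]), h0=np.array([0.5]))
    v = traj.V[:, 0]
    late = v[len(v) // 2:]
    # near the upper (Hopf) boundary the limit cycle shrinks continuously, so
    # any persistent swing well above integration noise counts as oscillation
    if late.max() - late.min() > 1.0:  # mV
        return "bursting"
    f_late = float(np.mean(output_function(late, net.neurons[0])))
    return "tonic" if f_late > active_threshold else "silent"


def scan_excitability(
    E_L_grid: np.ndarray,
    duration: float = 200_000.0,
    discard: float = 50_000.0,
    dt: float = 0.5,
) -> dict[float, str]:
    """Mode ('silent'/'bursting'/'tonic') for each E_L of an uncoupled unit."""
    return {
        float(e): classify_single_neuron(float(e), duration, discard, dt)
        for e in np.asarray(E_L_grid, dtype=float)
    }


def scan_weights(
    w_grid: np.ndarray,
    duration: float = 300_000.0,
    discard: float = 50_000.0,
    dt: float = 0.5,
) -> list[dict]:
    """Per-weight cycle periods and quantal regime for the coupled model.

    For each w, returns a dict with the per-unit onset-to-onset period lists,
    the regime classification, and whether the LE unit ever activated.
    """
    results = []
    for w in np.asarray(w_grid, dtype=float):
        net = ReducedNetwork(w=float(w))
        traj = simulate_reduced(net, duration=duration + discard, discard=discard, dt=dt)
        per_neuron, events = detect_cycles(traj)
        periods = {}
        for i in (HE, ME, LE):
            evs = per_neuron[i]
            # an event already in progress at the window start has an unknown
            # true onset; exclude it from onset-to-onset periods
            if evs and evs[0].onset == traj.t[0]:
                evs = evs[1:]
            periods[i] = np.diff([ev.onset for ev in evs])
        results.append(
            {
                "w": float(w),
                "periods": periods,
                "regime": classify_regime(events),
                "le_active": len(per_neuron[LE]) > 0,
            }
        )
    return results


def he_intervals_by_preceding_class(
    traj: ReducedTrajectory, active_threshold: float = ACTIVE_THRESHOLD
) -> tuple[list[float], list[float]]:
    """HE onset-to-onset intervals split by the class of the preceding burst.

    Returns ``(after_LA, after_SA)``.  In every mixed quantal regime the
    recovery after a full-network (LA) event is longer, because network-wide
    excitation pushes the right knee of the V-nullcline to lower h_NaP, so
    the active phase ends with deeper I_NaP inactivation.
    """
    per_neuron, events = detect_cycles(traj, active_threshold)
    he_events = per_neuron[HE]
    after_la: list[float] = []
    after_sa: list[float] = []
    for e0, e1 in zip(he_events[:-1], he_events[1:]):
        cls = None
        for ev in events:
            if ev.onset <= e0.onset <= ev.offset:
                cls = ev.is_LA
                break
        if cls is None:
            continue
        (after_la if cls else after_sa).append(e1.onset - e0.onset)
    return after_la, after_sa


def le_emergence_threshold(scan: list[dict]) -> float | None:
    """Smallest scanned weight at which the LE unit activates at least once."""
    for row in sorted(scan, key=lambda r: r["w"]):
        if row["le_active"]:
            return row["w"]
    return None
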