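"""Single-neuron biophysics of the large-scale network model.

Each neuron is a single-compartment Hodgkin-Huxley-style model whose membrane
potential obeys

    C dV/dt = -I_Na - I_NaP - I_K - I_L - I_SynE,

with a fast sodium current (``I_Na``), a persistent, slowly inactivating
sodium current (``I_NaP``) that endows neurons with conditional bursting, a
delayed-rectifier potassium current (``I_K``), an ohmic leak (``I_L``) and an
excitatory synaptic current (``I_SynE``).  Gating variables relax first-order
toward voltage-dependent steady states,

    tau_x(V) dx/dt = x_inf(V) - x,

with sigmoid steady states and 1/cosh-shaped time constants, except the K+
activation which uses classical alpha/beta rate functions.

Units are consistent without conversion factors: conductances in nS, voltages
in mV, capacitance in pF, time in ms, so that nS*mV = pA and pA/pF = mV/ms.

The synaptic conductance of neuron *i* is a sum of single-exponential kernels,
one per presynaptic spike: each spike of neuron *j* at time ``t_k`` adds
``gbar_SynE * w_ji * exp(-(t - t_k)/tau_SynE)`` for ``t > t_k``.  The
incremental update implemented here (decay plus instantaneous increments) is
mathematically identical to that sum.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FunctionalForm",
    "GatingSpec",
    "HHNeuronParams",
    "SynapseParams",
    "HHState",
    "GATES",
    "steady_state",
    "time_constant",
    "ionic_currents",
    "synaptic_conductance_update",
    "default_neuron_params",
    "default_synapse_params",
]


class FunctionalForm(str, enum.Enum):
    """Kinetic parameterization of a gating variable."""

    SIGMOID_COSH = "sigmoid_cosh"
    ALPHA_BETA = "alpha_beta"


@dataclass(frozen=True)
class GatingSpec:
    """Voltage dependence of one gating variable.

    For the ``sigmoid_cosh`` form::

        x_inf(V) = 1 / (1 + exp((V - half_voltage) / slope))
        tau_x(V) = tau_max / cosh((V - tau_half_voltage) / tau_slope)

    Activation gates have ``slope < 0`` (x_inf increasing in V), inactivation
    gates ``slope > 0``.  The ``alpha_beta`` form (K+ activation only) uses::

        alpha(V) = 0.01 (V + 45) / (1 - exp(-(V + 45)/5))
        beta(V)  = 0.17 exp(-(V + 49)/40)
        x_inf = alpha / (alpha + beta);  tau = 1 / (alpha + beta)
    """

    name: str
    functional_form: FunctionalForm = FunctionalForm.SIGMOID_COSH
    half_voltage: float = 0.0  # mV
    slope: float = 1.0  # mV; sign encodes activation (<0) vs inactivation (>0)
    tau_max: float = 1.0  # ms
    tau_half_voltage: float = 0.0  # mV
    tau_slope: float = 1.0  # mV


def _alpha_K(V: np.ndarray | float) -> np.ndarray | float:
    """K+ activation opening rate; removable singularity at V = -45 mV."""
    x = np.asarray(V, dtype=float) + 45.0
    with np.errstate(invalid="ignore", divide="ignore"):
        a = 0.01 * x / (1.0 - np.exp(-x / 5.0))
    a = np.where(np.abs(x) < 1e-7, 0.05, a)
    return a if a.ndim else float(a)


def _beta_K(V: np.ndarray | float):
    b = 0.17 * np.exp(-(np.asarray(V, dtype=float) + 49.0) / 40.0)
    return b if b.ndim else float(b)


def steady_state(gate: GatingSpec, V):
    """Steady-state open fraction x_inf(V) of a gating variable (in (0, 1))."""
    if gate.functional_form is FunctionalForm.ALPHA_BETA:
        a, b = _alpha_K(V), _beta_K(V)
        return a / (a + b)
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp((V - gate.half_voltage) / gate.slope))
    return out if out.ndim else float(out)


def time_constant(gate: GatingSpec, V):
    """Voltage-dependent relaxation time tau_x(V) in ms (strictly positive)."""
    if gate.functional_form is FunctionalForm.ALPHA_BETA:
        a, b = _alpha_K(V), _beta_K(V)
        return 1.0 / (a + b)
    V = np.asarray(V, dtype=float)
    out = gate.tau_max / np.cosh((V - gate.tau_half_voltage) / gate.tau_slope)
    return out if out.ndim else float(out)


# Gating kinetics of the large-scale model, one spec per dynamic variable.
GATES: dict[str, GatingSpec] = {
    "m_Na": GatingSpec("m_Na", half_voltage=-43.8, slope=-6.0,
                       tau_max=0.25, tau_half_voltage=-43.8, tau_slope=14.0),
    "h_Na": GatingSpec("h_Na", half_voltage=-67.5, slope=10.8,
                       tau_max=8.46, tau_half_voltage=-67.5, tau_slope=12.8),
    "m_NaP": GatingSpec("m_NaP", half_voltage=-47.1, slope=-3.1,
                        tau_max=1.0, tau_half_voltage=-47.1, tau_slope=6.2),
    "h_NaP": GatingSpec("h_NaP", half_voltage=-60.0, slope=9.0,
                        tau_max=6000.0, tau_half_voltage=-60.0, tau_slope=9.0),
    "m_K": GatingSpec("m_K", functional_form=FunctionalForm.ALPHA_BETA),
}


@dataclass
class HHNeuronParams:
    """Fixed parameters of one conductance-based neuron (Table-of-constants).

    Only ``E_L`` and ``gbar_NaP`` are heterogeneous across the population; the
    remaining values are shared.
    """

    C: float = 36.2  # pF
    gbar_Na: float = 170.0  # nS
    gbar_NaP: float = 5.0  # nS
    gbar_K: float = 180.0  # nS
    gbar_L: float = 2.5  # nS
    E_Na: float = 60.0  # mV
    E_K: float = -94.0  # mV
    E_L: float = -62.0  # mV
    E_SynE: float = -10.0  # mV
    gating: dict[str, GatingSpec] = field(default_factory=lambda: dict(GATES))

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("membrane capacitance must be positive")
        for name in ("gbar_Na", "gbar_NaP", "gbar_K", "gbar_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.E_K < self.E_L < self.E_Na):
            raise ValueError("reversal potentials must order E_K < E_L < E_Na")


@dataclass(frozen=True)
class SynapseParams:
    """Excitatory synapse model: increment scale, decay, spike threshold."""

    gbar_SynE: float = 0.05  # nS added per spike per unit weight
    tau_SynE: float = 5.0  # ms
    spike_threshold: float = -35.0  # mV

    def __post_init__(self) -> None:
        if self.gbar_SynE < 0:
            raise ValueError("gbar_SynE must be non-negative")
        if self.tau_SynE <= 0:
            raise ValueError("tau_SynE must be positive")


@dataclass
class HHState:
    """Dynamic state of one neuron (voltage, gates, aggregate synaptic g)."""

    V: float = -62.0
    m_Na: float = 0.0
    h_Na: float = 1.0
    m_NaP: float = 0.0
    h_NaP: float = 0.5
    m_K: float = 0.0
    g_syn: float = 0.0  # nS

    @classmethod
    def at_rest(cls, V: float, h_NaP: float, params: HHNeuronParams) -> "HHState":
        """State with fast gates at their steady values for voltage ``V``."""
        g = params.gating
        return cls(
            V=V,
            m_Na=steady_state(g["m_Na"], V),
            h_Na=steady_state(g["h_Na"], V),
            m_NaP=steady_state(g["m_NaP"], V),
            h_NaP=h_NaP,
            m_K=steady_state(g["m_K"], V),
            g_syn=0.0,
        )


def ionic_currents(state: HHState, params: HHNeuronParams) -> dict[str, float]:
    """All membrane currents in pA; positive values hyperpolarize.

    I_Na  = gbar_Na  * m_Na^3 * h_Na  * (V - E_Na)
    I_NaP = gbar_NaP * m_NaP  * h_NaP * (V - E_Na)
    I_K   = gbar_K   * m_K^4          * (V - E_K)
    I_L   = gbar_L                    * (V - E_L)
    I_SynE = g_syn                    * (V - E_SynE)
    """
    V = state.V
    return {
        "I_Na": params.gbar_Na * state.m_Na**3 * state.h_Na * (V - params.E_Na),
        "I_NaP": params.gbar_NaP * state.m_NaP * state.h_NaP * (V - params.E_Na),
        "I_K": params.gbar_K * state.m_K**4 * (V - params.E_K),
        "I_L": params.gbar_L * (V - params.E_L),
        "I_SynE": state.g_syn * (V - params.E_SynE),
    }


def synaptic_conductance_update(
    g_syn: float,
    dt: float,
    incoming: list[tuple[float, int]] | None = None,
    synapse: SynapseParams | None = None,
) -> float:
    """Advance the aggregate synaptic conductance by one step of length ``dt``.

    Applies instantaneous increments ``gbar_SynE * weight`` per presynaptic
    spike (``incoming`` is a list of ``(weight, spike_count)`` pairs), then
    decays exponentially with ``tau_SynE``.  Equivalent to evaluating the
    explicit sum of exponential kernels over the entire spike history.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    syn = synapse or SynapseParams()
    g = float(g_syn)
    for weight, count in incoming or []:
        if weight < 0:
            raise ValueError("synaptic weights are non-negative (excitation only)")
        g += syn.gbar_SynE * weight * count
    return g * math.exp(-dt / syn.tau_SynE)


def default_neuron_params(**overrides) -> HHNeuronParams:
    """A neuron with every parameter at its default (population-mean) value."""
    return replace(HHNeuronParams(), **overrides) if overrides else HHNeuronParams()


def default_synapse_params(**overrides) -> SynapseParams:
    return replace(SynapseParams(), **overrides) if overrides else SynapseParams()
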