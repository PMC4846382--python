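"""Seeded construction of the heterogeneous population and its connectivity.

The population of N neurons is heterogeneous in exactly two parameters: the
leak reversal potential ``E_L`` (the excitability proxy) and the maximal
persistent-sodium conductance ``gbar_NaP``, both drawn from independent
Gaussians.  Connectivity is a directed Erdos-Renyi graph: every ordered pair
(j, i), j != i, is connected independently with probability ``p`` and every
present edge carries the same weight ``w``, so that ``p * N`` is the mean
number of postsynaptic targets per neuron.

Three independent seed streams (population parameters, topology, initial
conditions) make every experiment reproducible and let any one ingredient be
resampled without disturbing the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .model_core import GATES, HHNeuronParams, HHState, SynapseParams, steady_state

__all__ = [
    "PopulationSpec",
    "ConnectivitySpec",
    "NetworkModel",
    "build_population",
    "build_connectivity",
    "build_network",
    "initial_conditions",
    "save_network",
    "load_network",
]

#: Initial-condition ranges (chosen, physiologically plausible; the discarded
#: startup transient makes downstream results insensitive to them).
V_INIT_RANGE = (-70.0, -50.0)  # mV
H_NAP_INIT_RANGE = (0.2, 0.8)


@dataclass(frozen=True)
class PopulationSpec:
    """Gaussian heterogeneity of the population (means +/- SD)."""

    N: int = 100
    E_L_mean: float = -62.0  # mV
    E_L_sd: float = 0.93  # mV
    gbar_NaP_mean: float = 5.0  # nS
    gbar_NaP_sd: float = 0.5  # nS
    seed_population: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("population size N must be >= 1")
        if self.E_L_sd < 0 or self.gbar_NaP_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class ConnectivitySpec:
    """Directed Bernoulli connectivity: probability p, uniform weight w."""

    p: float = 0.15
    w: float = 2.5
    seed_topology: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("connection probability p must lie in [0, 1]")
        if self.w < 0:
            raise ValueError("weight w must be non-negative (excitation only)")


@dataclass
class NetworkModel:
    """Fully realized network: per-neuron parameters + weighted adjacency.

    ``weights[j, i]`` is the synaptic weight from presynaptic neuron j onto
    postsynaptic neuron i (zero where no edge exists).  No self-connections.
    """

    neurons: list[HHNeuronParams]
    weights: np.ndarray
    synapse: SynapseParams = field(default_factory=SynapseParams)
    population_spec: PopulationSpec | None = None
    connectivity_spec: ConnectivitySpec | None = None

    def __post_init__(self) -> None:
        n = len(self.neurons)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n, n):
            raise ValueError("adjacency must be N x N")
        if np.any(np.diagonal(self.weights) != 0.0):
            raise ValueError("self-connections are not allowed")
        if np.any(self.weights < 0.0):
            raise ValueError("weights must be non-negative")

    @property
    def N(self) -> int:
        return len(self.neurons)

    @property
    def E_L(self) -> np.ndarray:
        return np.array([nrn.E_L for nrn in self.neurons])

    @property
    def gbar_NaP(self) -> np.ndarray:
        return np.array([nrn.gbar_NaP for nrn in self.neurons])

    def excitability_order(self) -> np.ndarray:
        """Neuron indices sorted by ascending E_L (the 'Neuron ID' convention:
        ID 1 = most negative E_L)."""
        return np.argsort(self.E_L, kind="stable")


def build_population(spec: PopulationSpec) -> list[HHNeuronParams]:
    """Draw N neurons with Gaussian E_L and gbar_NaP; all else at defaults.

    Gaussians are untruncated; a (vanishingly improbable) non-positive
    conductance draw is redrawn rather than clipped, keeping all conductances
    physical without distorting the distribution.
    """
    rng = np.random.default_rng(spec.seed_population)
    e_l = rng.normal(spec.E_L_mean, spec.E_L_sd, size=spec.N)
    g_nap = rng.normal(spec.gbar_NaP_mean, spec.gbar_NaP_sd, size=spec.N)
    while np.any(g_nap <= 0):
        bad = g_nap <= 0
        g_nap[bad] = rng.normal(spec.gbar_NaP_mean, spec.gbar_NaP_sd, size=bad.sum())
    base = HHNeuronParams()
    return [replace(base, E_L=float(e), gbar_NaP=float(g)) for e, g in zip(e_l, g_nap)]


def build_connectivity(N: int, spec: ConnectivitySpec) -> np.ndarray:
    """Directed Bernoulli(p) adjacency with uniform weight w, no self-edges."""
    rng = np.random.default_rng(spec.seed_topology)
    mask = rng.random((N, N)) < spec.p
    np.fill_diagonal(mask, False)
    return np.where(mask, spec.w, 0.0)


def build_network(
    population: PopulationSpec | None = None,
    connectivity: ConnectivitySpec | None = None,
    synapse: SynapseParams | None = None,
) -> NetworkModel:
    """Convenience constructor combining population and topology generation."""
    pop_spec = population or PopulationSpec()
    conn_spec = connectivity or ConnectivitySpec()
    return NetworkModel(
        neurons=build_population(pop_spec),
        weights=build_connectivity(pop_spec.N, conn_spec),
        synapse=synapse or SynapseParams(),
        population_spec=pop_spec,
        connectivity_spec=conn_spec,
    )


def initial_conditions(network: NetworkModel, seed_init: int = 0) -> list[HHState]:
    """Random initial states: V ~ U(-70, -50) mV, h_NaP ~ U(0.2, 0.8), fast
    gates at their steady states for the drawn V, g_syn = 0."""
    rng = np.random.default_rng(seed_init)
    v = rng.uniform(*V_INIT_RANGE, size=network.N)
    h = rng.uniform(*H_NAP_INIT_RANGE, size=network.N)
    return [
        HHState.at_rest(float(vi), float(hi), nrn)
        for vi, hi, nrn in zip(v, h, network.neurons)
    ]


def save_network(network: NetworkModel, directory: str | Path) -> None:
    """Persist a realized network as JSON (parameters) + CSV edge list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "N": network.N,
        "E_L": network.E_L.tolist(),
        "gbar_NaP": network.gbar_NaP.tolist(),
        "synapse": {
            "gbar_SynE": network.synapse.gbar_SynE,
            "tau_SynE": network.synapse.tau_SynE,
            "spike_threshold": network.synapse.spike_threshold,
        },
    }
    (directory / "network.json").write_text(json.dumps(meta, indent=1))
    src, dst = np.nonzero(network.weights)
    with open(directory / "edges.csv", "w") as fh:
        fh.write("source,target,weight\n")
        for j, i in zip(src, dst):
            fh.write(f"{j},{i},{float(network.weights[j, i])!r}\n")


def load_network(directory: str | Path) -> NetworkModel:
    """Inverse of :func:`save_network`; round-trips bit-exactly."""
    directory = Path(directory)
    meta = json.loads((directory / "network.json").read_text())
    base = HHNeuronParams()
    neurons = [
        replace(base, E_L=e, gbar_NaP=g)
        for e, g in zip(meta["E_L"], meta["gbar_NaP"])
    ]
    weights = np.zeros((meta["N"], meta["N"]))
    with open(directory / "edges.csv") as fh:
        next(fh)
        for line in fh:
            j, i, w = line.strip().split(",")
            weights[int(j), int(i)] = float(w)
    synapse = SynapseParams(**meta["synapse"])
    return NetworkModel(neurons=neurons, weights=weights, synapse=synapse)
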