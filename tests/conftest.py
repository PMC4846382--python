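"""Shared fixtures: expensive simulations are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import prebotc as pb

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uncoupled_rasters():
    """Five seeded uncoupled (w = 0) 100-neuron populations, 50 s each."""
    out = []
    for seed in range(1, 6):
        net = pb.build_network(
            pb.PopulationSpec(seed_population=seed),
            pb.ConnectivitySpec(p=0.15, w=0.0, seed_topology=seed + 100),
        )
        raster, _ = pb.simulate_network(
            net, pb.SimulationConfig(duration=50_000, discard=20_000, seed_init=seed + 200)
        )
        out.append((net, raster))
    return out


@pytest.fixture(scope="session")
def coupled_rasters_w18():
    """Five seeded coupled runs at w = 1.8, p = 0.15; 50 s, final 40 s kept."""
    out = []
    for seed in range(1, 6):
        net = pb.build_network(
            pb.PopulationSpec(seed_population=seed),
            pb.ConnectivitySpec(p=0.15, w=1.8, seed_topology=seed + 100),
        )
        raster, _ = pb.simulate_network(
            net, pb.SimulationConfig(duration=50_000, discard=10_000, seed_init=seed + 200)
        )
        out.append((net, raster))
    return out


@pytest.fixture(scope="session")
def reduced_runs():
    """Reduced-model trajectories for the coupling weights used throughout."""
    runs = {}
    for w in (1.7, 2.0, 3.0, 4.0):
        runs[w] = pb.simulate_reduced(
            pb.ReducedNetwork(w=w), duration=350_000, discard=50_000
        )
    return runs
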