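"""Figure-level experiment runners producing tabular artifact directories.

``run_experiment`` executes one configured simulation (either model) and
writes its raster/trajectory, histogram, burst table, regime summary and an
echo of the resolved configuration, so that the directory alone reproduces
the run.  ``run_sweep`` maps a two-parameter grid to regime summaries
(heat-map reproduction at configurable resolution) and is resumable:
completed cells are skipped on re-run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, reduced
from .config import ExperimentConfig, save_config
from .engine import SimulationConfig, simulate_network
from .network import ConnectivitySpec, PopulationSpec, build_network

__all__ = ["run_experiment", "run_sweep", "make_sweep_cell_runner"]


def _write_raster(raster, path: Path) -> None:
    rows = [
        (i, t) for i, times in enumerate(raster.spike_times) for t in times
    ]
    pd.DataFrame(rows, columns=["neuron_id", "spike_time_ms"]).to_csv(path, index=False)


def _write_events(events, path: Path) -> None:
    pd.DataFrame(
        [
            {"onset_ms": ev.onset, "offset_ms": ev.offset,
             "peak_spikes_per_bin": ev.peak_amplitude, "class": ev.cls}
            for ev in events
        ]
    ).to_csv(path, index=False)


def _summary_dict(summary) -> dict:
    return dataclasses.asdict(summary)


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Run one experiment and write all artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    if config.model == "large_scale":
        network = build_network(config.population, config.connectivity)
        raster, traces = simulate_network(network, config.simulation)
        hist, events, summary = analysis.analyze_raster(raster)
        _write_raster(raster, out / "raster.csv")
        pd.DataFrame({"t_ms": hist.centers, "spikes_per_bin": hist.counts}).to_csv(
            out / "histogram.csv", index=False
        )
        _write_events(events, out / "bursts.csv")
        if len(traces.neuron_ids):
            df = pd.DataFrame({"t_ms": traces.t})
            for k, nid in enumerate(traces.neuron_ids):
                df[f"V_{nid}"] = traces.V[:, k]
                df[f"h_NaP_{nid}"] = traces.h_NaP[:, k]
            df.to_csv(out / "traces.csv", index=False)
    else:
        rc = config.reduced
        net = reduced.ReducedNetwork(w=rc.w)
        traj = reduced.simulate_reduced(
            net, duration=rc.duration, dt=rc.dt, discard=rc.discard,
            record_dt=rc.record_dt, el_perturbation=rc.el_perturbation,
        )
        per_neuron, events = reduced.detect_cycles(traj)
        summary = reduced.classify_regime(events)
        df = pd.DataFrame({"t_ms": traj.t})
        for i, name in enumerate(("HE", "ME", "LE")):
            df[f"V_{name}"] = traj.V[:, i]
            df[f"h_{name}"] = traj.h[:, i]
            df[f"f_{name}"] = traj.f[:, i]
        df["sum"] = traj.summed_output
        df.to_csv(out / "trajectory.csv", index=False)
        pd.DataFrame(
            [
                {"onset_ms": ev.onset, "offset_ms": ev.offset,
                 "participants": "|".join(map(str, sorted(ev.participants))),
                 "class": "LA" if ev.is_LA else "SA"}
                for ev in events
            ]
        ).to_csv(out / "events.csv", index=False)
    if dataclasses.is_dataclass(summary):
        summary = _summary_dict(summary)
    (out / "regime.json").write_text(json.dumps(summary, indent=1))
    return out


def make_sweep_cell_runner(
    base_population: PopulationSpec | None = None,
    base_connectivity: ConnectivitySpec | None = None,
    simulation: SimulationConfig | None = None,
):
    """Cell runner for :func:`prebotc.analysis.heatmap_sweep`.

    Accepts keyword overrides among ``w``, ``p`` and ``gnap_mean`` (the
    g_NaP SD is scaled proportionally with its mean) and returns the sweep-
    rule regime summary of one 50 s simulation with the final 40 s analyzed.
    """
    pop0 = base_population or PopulationSpec()
    conn0 = base_connectivity or ConnectivitySpec()
    sim = simulation or SimulationConfig(duration=50_000.0, discard=10_000.0)

    def run_cell(**kw) -> analysis.RegimeSummary:
        pop, conn = pop0, conn0
        if "gnap_mean" in kw:
            mean = kw.pop("gnap_mean")
            pop = dataclasses.replace(
                pop0, gbar_NaP_mean=mean,
                gbar_NaP_sd=pop0.gbar_NaP_sd * mean / pop0.gbar_NaP_mean,
            )
        if "w" in kw:
            conn = dataclasses.replace(conn, w=kw.pop("w"))
        if "p" in kw:
            conn = dataclasses.replace(conn, p=kw.pop("p"))
        if kw:
            raise ValueError(f"unknown sweep parameter(s): {sorted(kw)}")
        network = build_network(pop, conn)
        raster, _ = simulate_network(network, sim)
        _, _, summary = analysis.analyze_raster(raster, rule="window")
        return summary

    return run_cell


def run_sweep(
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    out_dir: str | Path,
    base_population: PopulationSpec | None = None,
    base_connectivity: ConnectivitySpec | None = None,
    simulation: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Two-parameter regime sweep written as one CSV row per grid cell.

    Resumable: cells already present in ``out_dir/sweep.csv`` are not re-run.
    Per-cell failures are recorded (label 'failed') and the sweep continues.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "sweep.csv"
    done: set[tuple[float, float]] = set()
    rows: list[dict] = []
    if csv_path.exists():
        prev = pd.read_csv(csv_path)
        rows = prev.to_dict("records")
        done = {(r[axis1[0]], r[axis2[0]]) for r in rows}
    run_cell = make_sweep_cell_runner(base_population, base_connectivity, simulation)
    name1, vals1 = axis1
    name2, vals2 = axis2
    for v1 in np.asarray(vals1, dtype=float):
        for v2 in np.asarray(vals2, dtype=float):
            if (v1, v2) in done:
                continue
            try:
                s = run_cell(**{name1: v1, name2: v2})
                rows.append(
                    {name1: v1, name2: v2, "label": s.label, "N": s.N,
                     "n_LA": s.n_LA, "n_SA": s.n_SA}
                )
            except Exception as exc:  # unstable cells are flagged, not fatal
                rows.append({name1: v1, name2: v2, "label": "failed", "N": None,
                             "n_LA": 0, "n_SA": 0, "error": str(exc)})
            pd.DataFrame(rows).to_csv(csv_path, index=False)
    df = pd.DataFrame(rows)
    (out / "sweep_meta.json").write_text(
        json.dumps({"axis1": {name1: list(map(float, vals1))},
                    "axis2": {name2: list(map(float, vals2))}}, indent=1)
    )
    return df
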