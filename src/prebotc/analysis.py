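"""Population-level readouts: histograms, burst segmentation and
classification, quantal-regime summaries, per-neuron statistics,
participation clustering, and parameter-sweep grids.

Integrated population activity is a histogram of spikes across all neurons
per 10 ms bin.  Two large-amplitude (LA) classification rules coexist on
purpose, each used by its own pipeline:

* main analyses: a burst is LA iff its peak amplitude exceeds 50 spikes per
  10 ms bin (strictly; a peak of exactly 50 is SA);
* parameter sweeps (heat maps): a burst is LA iff activity exceeds 20 spikes
  within some 100 ms window, every other bursting event being SA.

Burst segmentation itself (onset/offset) is package plumbing: maximal runs of
bins at or above a small on-threshold, with runs separated by less than a
minimum gap merged.  A single segmented "event" covering essentially the
whole analysis window is sustained tonic activity, not a burst, and is
excluded from burst-based summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .engine import SpikeRaster, TrajectoryRecord

__all__ = [
    "PopulationHistogram",
    "BurstEvent",
    "RegimeSummary",
    "population_histogram",
    "segment_bursts",
    "classify_bursts",
    "classify_bursts_windowed",
    "regime_summary",
    "neuron_burst_stats",
    "cluster_by_participation",
    "heatmap_sweep",
]

DEFAULT_BIN_WIDTH = 10.0  # ms
LA_THRESHOLD = 50.0  # spikes per 10 ms bin, main-analysis rule
SWEEP_LA_SPIKES = 20.0  # spikes ...
SWEEP_LA_WINDOW = 100.0  # ... per 100 ms window, sweep rule
ON_THRESHOLD = 5.0  # spikes/bin, burst-segmentation on-threshold
MIN_GAP = 50.0  # ms, runs closer than this are merged
TONIC_SPAN_FRACTION = 0.9  # an "event" this long is tonic, not a burst
ISI_BURST_GAP = 300.0  # ms, per-neuron ISI gap starting a new burst


@dataclass
class PopulationHistogram:
    """Spike counts of the whole population in fixed-width time bins."""

    bin_width: float  # ms
    counts: np.ndarray
    t_start: float  # ms, left edge of the first bin

    @property
    def edges(self) -> np.ndarray:
        return self.t_start + np.arange(len(self.counts) + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return self.t_start + (np.arange(len(self.counts)) + 0.5) * self.bin_width


@dataclass
class BurstEvent:
    """One detected population burst."""

    onset: float  # ms
    offset: float  # ms
    peak_amplitude: float  # spikes/bin
    cls: str | None = None  # "LA" or "SA"
    participants: frozenset[int] = field(default_factory=frozenset)


@dataclass
class RegimeSummary:
    """Quantal-regime description of one simulation window."""

    n_LA: int
    n_SA: int
    label: str  # "1:N", "SA-only", "silent", "tonic" or "irregular"
    N: int | None
    LA_frequency: float  # Hz
    SA_frequency: float  # Hz
    mean_IBI_after_LA: float | None  # ms, onset-to-onset
    mean_IBI_after_SA: float | None
    sa_counts: list[int] = field(default_factory=list)


def population_histogram(
    raster: SpikeRaster,
    bin_width: float = DEFAULT_BIN_WIDTH,
    t_start: float | None = None,
    t_end: float | None = None,
) -> PopulationHistogram:
    """Histogram of all spikes per ``bin_width`` ms bin over the window."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t0 = raster.discard if t_start is None else t_start
    t1 = raster.duration if t_end is None else t_end
    n_bins = max(1, int(np.ceil((t1 - t0) / bin_width)))
    counts = np.zeros(n_bins)
    all_times = (
        np.concatenate(raster.spike_times) if raster.total_spikes() else np.empty(0)
    )
    sel = all_times[(all_times > t0) & (all_times <= t1)]
    if len(sel):
        idx = np.minimum(((sel - t0) / bin_width).astype(int), n_bins - 1)
        counts += np.bincount(idx, minlength=n_bins)
    return PopulationHistogram(bin_width=bin_width, counts=counts, t_start=t0)


def segment_bursts(
    hist: PopulationHistogram,
    on_threshold: float = ON_THRESHOLD,
    min_gap: float = MIN_GAP,
) -> list[BurstEvent]:
    """Maximal runs of bins with counts >= on_threshold, gap-merged.

    Runs separated by less than ``min_gap`` ms are merged into one burst;
    ``peak_amplitude`` is the maximum bin count inside the (merged) run.
    """
    if on_threshold <= 0 or min_gap < 0:
        raise ValueError("thresholds must be positive")
    above = hist.counts >= on_threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) * hist.bin_width < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        events.append(
            BurstEvent(
                onset=hist.t_start + s * hist.bin_width,
                offset=hist.t_start + e * hist.bin_width,
                peak_amplitude=float(hist.counts[s:e].max()),
            )
        )
    return events


def classify_bursts(
    events: list[BurstEvent], la_threshold: float = LA_THRESHOLD
) -> list[BurstEvent]:
    """Main-analysis rule: LA iff peak amplitude strictly exceeds threshold."""
    for ev in events:
        ev.cls = "LA" if ev.peak_amplitude > la_threshold else "SA"
    return events


def classify_bursts_windowed(
    events: list[BurstEvent],
    hist: PopulationHistogram,
    la_spikes: float = SWEEP_LA_SPIKES,
    la_window: float = SWEEP_LA_WINDOW,
) -> list[BurstEvent]:
    """Sweep rule: LA iff some ``la_window`` ms window within the burst holds
    more than ``la_spikes`` spikes (computed as a rolling sum of bins)."""
    k = max(1, int(round(la_window / hist.bin_width)))
    rolling = np.convolve(hist.counts, np.ones(k), mode="full")[: len(hist.counts)]
    for ev in events:
        s = int((ev.onset - hist.t_start) / hist.bin_width)
        e = int((ev.offset - hist.t_start) / hist.bin_width)
        # windows ending within (or just after) the burst
        hi = min(len(rolling), e + k)
        ev.cls = "LA" if rolling[s:hi].max(initial=0.0) > la_spikes else "SA"
    return events


def classify_bursts_by_participation(
    events: list[BurstEvent], raster: SpikeRaster, fraction: float = 0.9
) -> list[BurstEvent]:
    """Mechanism-level rule: LA iff the burst recruits at least ``fraction``
    of the population.  Large-amplitude bursts are full-network recruitment
    events (they engage even the least excitable neurons), so participation
    identifies them independently of absolute histogram amplitude."""
    attach_participants(events, raster)
    for ev in events:
        ev.cls = "LA" if len(ev.participants) >= fraction * raster.N else "SA"
    return events


def attach_participants(events: list[BurstEvent], raster: SpikeRaster) -> list[BurstEvent]:
    """Record, per burst, the set of neurons spiking within [onset, offset]."""
    for ev in events:
        members = {
            i
            for i, times in enumerate(raster.spike_times)
            if len(times) and np.any((times >= ev.onset) & (times <= ev.offset))
        }
        ev.participants = frozenset(members)
    return events


def _drop_tonic(events: list[BurstEvent], window: float) -> list[BurstEvent]:
    return [ev for ev in events if (ev.offset - ev.onset) < TONIC_SPAN_FRACTION * window]


def regime_summary(events: list[BurstEvent], window: float) -> RegimeSummary:
    """Counts, 1:N label, burst frequencies and class-conditioned IBIs.

    ``N`` is the modal number of burst events per LA-to-LA period (equal to
    one plus the modal SA count between consecutive LA bursts).  IBIs are
    onset-to-onset gaps partitioned by the class of the *preceding* burst.
    """
    bursts = _drop_tonic(sorted(events, key=lambda e: e.onset), window)
    if len(bursts) < len(events):  # sustained supra-threshold activity
        if not bursts:
            return RegimeSummary(0, 0, "tonic", None, 0.0, 0.0, None, None)
    if not bursts:
        return RegimeSummary(0, 0, "silent", None, 0.0, 0.0, None, None)
    if any(ev.cls is None for ev in bursts):
        raise ValueError("events must be classified before summarizing")
    n_la = sum(ev.cls == "LA" for ev in bursts)
    n_sa = len(bursts) - n_la
    window_s = window / 1000.0
    ibi_after = {"LA": [], "SA": []}
    for prev, nxt in zip(bursts[:-1], bursts[1:]):
        ibi_after[prev.cls].append(nxt.onset - prev.onset)
    la_onsets = [ev.onset for ev in bursts if ev.cls == "LA"]
    counts = []
    for a, b in zip(la_onsets[:-1], la_onsets[1:]):
        counts.append(sum(1 for ev in bursts if a <= ev.onset < b))
    if n_la == 0:
        label, modal = "SA-only", None
    elif len(bursts) == 1:
        label, modal = "irregular", None
    elif not counts:
        label, modal = "irregular", None
    else:
        modal = Counter(counts).most_common(1)[0][0]
        label = f"1:{modal}"
    return RegimeSummary(
        n_LA=n_la,
        n_SA=n_sa,
        label=label,
        N=modal,
        LA_frequency=n_la / window_s,
        SA_frequency=n_sa / window_s,
        mean_IBI_after_LA=float(np.mean(ibi_after["LA"])) if ibi_after["LA"] else None,
        mean_IBI_after_SA=float(np.mean(ibi_after["SA"])) if ibi_after["SA"] else None,
        sa_counts=[c - 1 for c in counts],
    )


def analyze_raster(
    raster: SpikeRaster,
    bin_width: float = DEFAULT_BIN_WIDTH,
    rule: str = "peak",
) -> tuple[PopulationHistogram, list[BurstEvent], RegimeSummary]:
    """One-call pipeline: histogram -> segmentation -> classification -> summary.

    ``rule`` selects the LA definition: "peak" (main analyses, >50 spikes per
    10 ms bin) or "window" (sweeps, >20 spikes per 100 ms window).
    """
    hist = population_histogram(raster, bin_width)
    events = segment_bursts(hist)
    if rule == "peak":
        classify_bursts(events)
    elif rule == "window":
        classify_bursts_windowed(events, hist)
    else:
        raise ValueError("rule must be 'peak' or 'window'")
    return hist, events, regime_summary(events, raster.window)


def neuron_burst_stats(
    raster: SpikeRaster, isi_gap: float = ISI_BURST_GAP
) -> list[dict]:
    """Per-neuron firing mode and frequencies from ISI-based burst grouping.

    A gap of more than ``isi_gap`` ms between consecutive spikes starts a new
    burst.  Modes: 'silent' (no spikes), 'tonic' (spiking with no supra-gap
    ISI), 'bursting' otherwise.  ``burst_frequency`` is burst onsets per
    second of analysis window; ``intraburst_spike_frequency`` averages
    (n_spikes - 1)/burst-duration over multi-spike bursts.
    """
    out = []
    window_s = raster.window / 1000.0
    for i, times in enumerate(raster.spike_times):
        if len(times) == 0:
            out.append({"neuron": i, "mode": "silent",
                        "burst_frequency": 0.0, "intraburst_spike_frequency": 0.0})
            continue
        isis = np.diff(times)
        if len(times) > 1 and not np.any(isis > isi_gap):
            out.append({"neuron": i, "mode": "tonic",
                        "burst_frequency": 0.0,
                        "intraburst_spike_frequency": 1000.0 / float(np.mean(isis))})
            continue
        breaks = np.flatnonzero(isis > isi_gap) + 1
        groups = np.split(times, breaks)
        intr = [
            1000.0 * (len(g) - 1) / (g[-1] - g[0]) for g in groups if len(g) > 1
        ]
        out.append(
            {
                "neuron": i,
                "mode": "bursting",
                "burst_frequency": len(groups) / window_s,
                "intraburst_spike_frequency": float(np.mean(intr)) if intr else 0.0,
            }
        )
    return out


def cluster_by_participation(
    events: list[BurstEvent], raster: SpikeRaster
) -> dict[tuple[bool, ...], list[int]]:
    """Group neurons by the identical set of bursts they participate in.

    Keys are participation bit-vectors over the analyzed bursts (one bool per
    burst); values are sorted neuron-id lists.  With no events every neuron
    falls into the single all-False cluster.
    """
    if events and not events[0].participants and raster.total_spikes():
        attach_participants(events, raster)
    clusters: dict[tuple[bool, ...], list[int]] = {}
    for i in range(raster.N):
        key = tuple(i in ev.participants for ev in events)
        clusters.setdefault(key, []).append(i)
    return clusters


def heatmap_sweep(
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    run_cell,
) -> list[list[RegimeSummary | None]]:
    """Grid of regime summaries over two swept parameters.

    ``axis1``/``axis2`` are ``(name, values)`` pairs; ``run_cell(name1=v1,
    name2=v2)`` must run one simulation and return a :class:`RegimeSummary`
    (see :func:`prebotc.experiments.make_sweep_cell_runner`).  Unstable cells
    are recorded as None rather than aborting the sweep.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    grid: list[list[RegimeSummary | None]] = []
    for v1 in vals1:
        row: list[RegimeSummary | None] = []
        for v2 in vals2:
            try:
                row.append(run_cell(**{name1: float(v1), name2: float(v2)}))
            except Exception:
                row.append(None)
        grid.append(row)
    return grid
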