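"""Histogramming, burst segmentation/classification and regime summaries."""

import numpy as np
import pytest

import prebotc as pb
from prebotc.analysis import (
    BurstEvent,
    PopulationHistogram,
    classify_bursts,
    regime_summary,
    segment_bursts,
)
from prebotc.engine import SpikeRaster


def _raster(spikes_per_neuron, duration=1_000.0, discard=0.0):
    n = len(spikes_per_neuron)
    return SpikeRaster(
        spike_times=[np.asarray(s, dtype=float) for s in spikes_per_neuron],
        E_L=np.linspace(-63, -61, n),
        duration=duration,
        discard=discard,
    )


class TestPopulationHistogram:
    def test_basic_binning(self):
        r = _raster([[5.0, 12.0]], duration=20.0)
        h = pb.population_histogram(r, bin_width=10.0)
        assert list(h.counts) == [1, 1]

    def test_empty_raster_gives_zeros(self):
        r = _raster([[], []], duration=100.0)
        h = pb.population_histogram(r)
        assert h.counts.sum() == 0

    def test_conservation(self):
        rng = np.random.default_rng(0)
        spikes = [np.sort(rng.uniform(0, 1000, rng.integers(0, 50))) for _ in range(5)]
        r = _raster(spikes)
        h = pb.population_histogram(r, bin_width=10)
        assert h.counts.sum() == sum(len(s) for s in spikes)


def _brute_force_segments(counts, threshold, min_gap_bins):
    """Independent enumeration oracle: scan runs, merge short gaps."""
    runs = []
    i = 0
    while i < len(counts):
        if counts[i] >= threshold:
            j = i
            while j < len(counts) and counts[j] >= threshold:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < min_gap_bins:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [(s, e, max(counts[s:e])) for s, e in merged]


class TestSegmentation:
    def test_single_burst(self):
        h = PopulationHistogram(10.0, np.array([0, 0, 60, 70, 0, 0.0]), 0.0)
        ev = segment_bursts(h, on_threshold=5)
        assert len(ev) == 1 and ev[0].peak_amplitude == 70

    def test_gap_merging(self):
        h = PopulationHistogram(10.0, np.array([0, 40, 2, 40, 0.0]), 0.0)
        assert len(segment_bursts(h, on_threshold=5, min_gap=30)) == 1
        assert len(segment_bursts(h, on_threshold=5, min_gap=5)) == 2

    def test_all_zero(self):
        h = PopulationHistogram(10.0, np.zeros(20), 0.0)
        assert segment_bursts(h) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 80, 20).astype(float)
            h = PopulationHistogram(10.0, counts, 0.0)
            got = segment_bursts(h, on_threshold=5, min_gap=30)
            exp = _brute_force_segments(counts, 5, 3)
            assert len(got) == len(exp)
            for g, (s, e, peak) in zip(got, exp):
                assert g.onset == s * 10.0 and g.offset == e * 10.0
                assert g.peak_amplitude == peak


class TestClassification:
    @pytest.mark.parametrize("peak,cls", [(70, "LA"), (30, "SA"), (50, "SA")])
    def test_amplitude_rule_with_strict_boundary(self, peak, cls):
        ev = [BurstEvent(0, 10, peak)]
        assert classify_bursts(ev)[0].cls == cls

    def test_windowed_rule(self):
        # 30 spikes inside 100 ms -> LA; 15 -> SA
        counts = np.zeros(40)
        counts[5:8] = 10  # 30 spikes within 3 adjacent 10-ms bins
        counts[25:28] = 5  # 15 spikes
        h = PopulationHistogram(10.0, counts, 0.0)
        ev = segment_bursts(h, on_threshold=5)
        ev = pb.classify_bursts_windowed(ev, h)
        assert [e.cls for e in ev] == ["LA", "SA"]


def _events(pattern, period=1_000.0):
    """Build a classified event sequence from a string like 'LSSSSSL'."""
    out = []
    for k, c in enumerate(pattern):
        peak = 80.0 if c == "L" else 20.0
        out.append(BurstEvent(k * period, k * period + 300, peak, cls="LA" if c == "L" else "SA"))
    return out


class TestRegimeSummary:
    def test_one_la_per_five_sa(self):
        # five SA between LA pairs -> six events per LA period -> 1:6
        ev = _events("LSSSSSLSSSSSLSSSSSL")
        s = regime_summary(ev, window=20_000.0)
        assert s.label == "1:6" and s.N == 6
        assert s.sa_counts == [5, 5, 5]

    def test_all_la_is_one_to_one(self):
        s = regime_summary(_events("LLLLLL"), window=6_000.0)
        assert s.label == "1:1"

    def test_sa_only_and_silent_flags(self):
        assert regime_summary(_events("SSSS"), window=4_000.0).label == "SA-only"
        assert regime_summary([], window=4_000.0).label == "silent"

    def test_single_burst_flagged(self):
        assert regime_summary(_events("L"), window=4_000.0).label == "irregular"

    def test_ibi_partitioned_by_preceding_class(self):
        ev = _events("LSL")
        ev[1].onset, ev[1].offset = 1_500.0, 1_800.0  # short gap after LA? no:
        # gaps: LA->SA = 1500, SA->LA = 500
        s = regime_summary(ev, window=4_000.0)
        assert s.mean_IBI_after_LA == pytest.approx(1_500.0)
        assert s.mean_IBI_after_SA == pytest.approx(500.0)

    def test_sustained_activity_is_tonic_not_burst(self):
        ev = [BurstEvent(0.0, 39_000.0, 60.0, cls="LA")]
        assert regime_summary(ev, window=40_000.0).label == "tonic"


class TestNeuronBurstStats:
    def test_modes(self):
        r = _raster(
            [
                [],  # silent
                np.arange(50.0, 30_000.0, 100.0),  # 10 Hz, no gaps -> tonic
                [100, 130, 160, 2_100, 2_130, 2_160, 4_100, 4_130, 4_160],  # bursting
            ],
            duration=30_000.0,
        )
        stats = pb.neuron_burst_stats(r)
        assert [s["mode"] for s in stats] == ["silent", "tonic", "bursting"]
        b = stats[2]
        assert b["burst_frequency"] == pytest.approx(3 / 30.0)
        # two 30-ms ISIs per burst -> 2 spikes / 60 ms
        assert b["intraburst_spike_frequency"] == pytest.approx(1000.0 * 2 / 60.0)


class TestParticipationClustering:
    def test_identical_participation_single_cluster(self):
        r = _raster([[105.0, 505.0], [110.0, 510.0]], duration=1_000.0)
        ev = [BurstEvent(100, 200, 60), BurstEvent(500, 600, 60)]
        clusters = pb.cluster_by_participation(ev, r)
        assert len(clusters) == 1
        assert sorted(sum(clusters.values(), [])) == [0, 1]

    def test_la_only_neurons_form_distinct_cluster(self):
        # neuron 1 joins only the second (LA) burst
        r = _raster([[105.0, 505.0], [510.0]], duration=1_000.0)
        ev = [BurstEvent(100, 200, 20, cls="SA"), BurstEvent(500, 600, 80, cls="LA")]
        clusters = pb.cluster_by_participation(ev, r)
        assert clusters[(True, True)] == [0]
        assert clusters[(False, True)] == [1]

    def test_empty_events_single_trivial_cluster(self):
        r = _raster([[1.0], [2.0], []], duration=10.0)
        clusters = pb.cluster_by_participation([], r)
        assert list(clusters.keys()) == [()]
        assert clusters[()] == [0, 1, 2]


def test_burst_spike_conservation(coupled_rasters_w18):
    """Spikes attributed to bursts can never exceed the total spike count."""
    _, raster = coupled_rasters_w18[0]
    hist = pb.population_histogram(raster)
    events = segment_bursts(hist)
    in_bursts = 0
    all_times = np.concatenate([t for t in raster.spike_times if len(t)])
    for ev in events:
        in_bursts += int(np.sum((all_times >= ev.onset) & (all_times <= ev.offset)))
    assert in_bursts <= raster.total_spikes()
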