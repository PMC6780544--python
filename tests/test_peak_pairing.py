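"""Clustering, channel classification, pairing, and cross-run alignment."""

import numpy as np
import pytest

from iroapairs import (
    CentroidPeak,
    DELTA_C13,
    LabelingScheme,
    align_pairs_across_samples,
    carbon_isotopologue_envelope,
    classify_cluster_channel,
    cluster_isotopologues,
    find_peak_pairs,
)
from iroapairs.peak_pairing import IsotopologueCluster, PeakPair


def peaks_from_envelope(base_mz, rt, envelope, scale, sample_id="S1", start_k=0):
    """Centroid peaks of an envelope ladder (noise-free)."""
    return [
        CentroidPeak(
            mz=base_mz + (start_k + k) * DELTA_C13,
            rt=rt,
            intensity=float(scale * v),
            sample_id=sample_id,
        )
        for k, v in enumerate(envelope)
        if scale * v > 0
    ]


def make_pair_channels(mz12, rt, n, area_s, area_i, floor_frac=0.005, sample_id="S1"):
    """Both channels of an n-carbon metabolite with sub-floor members dropped,
    coincident isotopologues summed (as a centroided instrument reports them)."""
    total = area_s * carbon_isotopologue_envelope(n, 0.05) + area_i * carbon_isotopologue_envelope(n, 0.95)
    floor = floor_frac * total.max()
    return [
        CentroidPeak(mz=mz12 + k * DELTA_C13, rt=rt, intensity=float(v), sample_id=sample_id)
        for k, v in enumerate(total)
        if v >= floor
    ]


class TestClustering:
    def test_two_peaks_one_spacing_apart_chain(self):
        peaks = [
            CentroidPeak(mz=132.1019, rt=300.0, intensity=1000.0),
            CentroidPeak(mz=133.1053, rt=300.0, intensity=300.0),
        ]
        clusters = cluster_isotopologues(peaks)
        assert len(clusters) == 1 and len(clusters[0].peaks) == 2

    def test_isolated_peak_is_singleton(self):
        clusters = cluster_isotopologues([CentroidPeak(mz=200.0, rt=10.0, intensity=5.0)])
        assert len(clusters) == 1 and len(clusters[0].peaks) == 1

    def test_half_dalton_gap_does_not_chain_at_z1(self):
        peaks = [
            CentroidPeak(mz=132.1019, rt=300.0, intensity=1000.0),
            CentroidPeak(mz=132.6019, rt=300.0, intensity=300.0),
        ]
        clusters = cluster_isotopologues(peaks, charges={1})
        assert len(clusters) == 2

    def test_half_spacing_chains_at_z2(self):
        peaks = [
            CentroidPeak(mz=400.2000, rt=300.0, intensity=1000.0),
            CentroidPeak(mz=400.2000 + DELTA_C13 / 2, rt=300.0, intensity=300.0),
        ]
        clusters = cluster_isotopologues(peaks, charges={1, 2})
        assert len(clusters) == 1 and clusters[0].charge == 2

    def test_rt_gate(self):
        peaks = [
            CentroidPeak(mz=132.1019, rt=300.0, intensity=1000.0),
            CentroidPeak(mz=133.1053, rt=330.0, intensity=300.0),
        ]
        assert len(cluster_isotopologues(peaks, rt_tol=6.0)) == 2

    def test_every_peak_in_exactly_one_cluster(self):
        rng = np.random.default_rng(4)
        peaks = [
            CentroidPeak(mz=float(m), rt=float(r), intensity=float(i))
            for m, r, i in zip(
                rng.uniform(100, 500, 300), rng.uniform(0, 600, 300), rng.uniform(1, 100, 300)
            )
        ]
        clusters = cluster_isotopologues(peaks)
        assert sum(len(c.peaks) for c in clusters) == len(peaks)

    def test_empty_input(self):
        assert cluster_isotopologues([]) == []


class TestChannelClassification:
    def test_light_binomial_envelope_is_sample(self):
        peaks = peaks_from_envelope(132.1019, 300.0, carbon_isotopologue_envelope(6, 0.05), 1e5)
        cluster = IsotopologueCluster(peaks=peaks)
        assert classify_cluster_channel(cluster) == "sample"
        assert cluster.n_best == 6
        assert cluster.channel_score == pytest.approx(1.0, abs=1e-9)

    def test_mirrored_envelope_is_internal_standard(self):
        peaks = peaks_from_envelope(138.1220, 300.0, carbon_isotopologue_envelope(6, 0.95), 1e5)
        cluster = IsotopologueCluster(peaks=peaks)
        assert classify_cluster_channel(cluster) == "is"
        assert cluster.n_best == 6

    def test_flat_envelope_unclassified(self):
        # a 50:50 doublet matches no binomial channel template with up to
        # ten carbons at the 0.95 score floor (very large n light templates
        # flatten enough to score ~0.97, hence the bounded candidate range)
        peaks = peaks_from_envelope(132.1019, 300.0, np.array([0.5, 0.5]), 1e5)
        cluster = IsotopologueCluster(peaks=peaks)
        assert classify_cluster_channel(cluster, min_score=0.95, max_carbons=10) == "unclassified"

    def test_singleton_unclassified(self):
        cluster = IsotopologueCluster(peaks=[CentroidPeak(mz=100.0, rt=1.0, intensity=1.0)])
        assert classify_cluster_channel(cluster) == "unclassified"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            classify_cluster_channel(IsotopologueCluster(peaks=[]))


class TestPairing:
    def _classified(self, peak_lists):
        clusters = cluster_isotopologues([p for pl in peak_lists for p in pl])
        for cl in clusters:
            classify_cluster_channel(cl)
        return clusters

    def test_leucine_like_pair(self):
        """Separated 6-carbon channels at a 6-spacing monoisotopic gap."""
        sample = peaks_from_envelope(132.1019, 300.0, carbon_isotopologue_envelope(6, 0.05)[:3], 1e5)
        is_ch = peaks_from_envelope(
            132.1019 + 4 * DELTA_C13, 300.0, carbon_isotopologue_envelope(6, 0.95)[4:], 1e5, start_k=0
        )
        pairs = find_peak_pairs(self._classified([sample, is_ch]))
        assert len(pairs) == 1
        assert pairs[0].carbon_count == 6
        assert pairs[0].mono12_mz == pytest.approx(132.1019)
        assert pairs[0].mono13_mz == pytest.approx(132.1019 + 6 * DELTA_C13)

    def test_lone_sample_cluster_excluded(self):
        sample = peaks_from_envelope(132.1019, 300.0, carbon_isotopologue_envelope(6, 0.05)[:3], 1e5)
        assert find_peak_pairs(self._classified([sample])) == []

    def test_rt_separation_blocks_pairing(self):
        sample = peaks_from_envelope(132.1019, 300.0, carbon_isotopologue_envelope(6, 0.05)[:3], 1e5)
        is_ch = peaks_from_envelope(
            132.1019 + 4 * DELTA_C13, 318.0, carbon_isotopologue_envelope(6, 0.95)[4:], 1e5
        )
        assert find_peak_pairs(self._classified([sample, is_ch]), rt_tol=6.0) == []

    def test_merged_small_carbon_ladder_resolved(self):
        """A 3-carbon metabolite arrives as one contiguous two-channel ladder."""
        peaks = make_pair_channels(90.0550, 120.0, 3, area_s=2e5, area_i=1e5)
        clusters = self._classified([peaks])
        assert len(clusters) == 1  # contiguous ladder
        pairs = find_peak_pairs(clusters)
        assert len(pairs) == 1
        pair = pairs[0]
        assert pair.carbon_count == 3
        assert pair.area_sample == pytest.approx(2e5, rel=1e-6)
        assert pair.area_is == pytest.approx(1e5, rel=1e-6)

    def test_single_channel_ladder_not_misread_as_merged(self):
        """The top members of a lone heavy envelope must not become a
        small-carbon pair."""
        is_only = peaks_from_envelope(
            200.0, 50.0, carbon_isotopologue_envelope(7, 0.95)[5:], 1e5
        )
        assert find_peak_pairs(self._classified([is_only])) == []

    def test_minimum_carbon_count(self):
        """1-carbon gaps are suppressed (n_min = 2)."""
        peaks = make_pair_channels(61.0283, 415.0, 1, area_s=1e5, area_i=1e5)
        assert find_peak_pairs(self._classified([peaks]), n_range=(2, 60)) == []


def _pair(mz12=132.1019, rt=300.0, n=6, sid="S1", a_s=100.0, a_i=50.0, score=1.0):
    return PeakPair(
        carbon_count=n,
        mono12_mz=mz12,
        mono13_mz=mz12 + n * DELTA_C13,
        rt=rt,
        polarity="positive",
        area_sample=a_s,
        area_is=a_i,
        pair_score=score,
        sample_id=sid,
    )


class TestAlignment:
    def test_identical_pair_in_eight_runs(self):
        runs = {f"S{i}": [_pair(sid=f"S{i}")] for i in range(8)}
        table = align_pairs_across_samples(runs)
        assert len(table.features) == 1
        assert int(table.area_sample.notna().sum().sum()) == 8

    def test_pair_absent_from_one_run_leaves_missing_cell(self):
        runs = {f"S{i}": [_pair(sid=f"S{i}")] for i in range(7)}
        runs["S7"] = []
        table = align_pairs_across_samples(runs)
        assert len(table.features) == 1
        assert np.isnan(table.area_sample.at[table.features.index[0], "S7"])

    def test_fifty_ppm_apart_make_two_rows(self):
        mz_a = 400.0
        mz_b = 400.0 * (1 + 50e-6)
        runs = {"S1": [_pair(mz12=mz_a)], "S2": [_pair(mz12=mz_b, sid="S2")]}
        table = align_pairs_across_samples(runs, ppm_tol=10.0)
        assert len(table.features) == 2

    def test_carbon_count_must_match_exactly(self):
        runs = {"S1": [_pair(n=6)], "S2": [_pair(n=7, sid="S2")]}
        assert len(align_pairs_across_samples(runs).features) == 2

    def test_collision_keeps_higher_score(self):
        runs = {"S1": [_pair(a_s=1.0, score=0.9), _pair(a_s=2.0, score=0.99)]}
        table = align_pairs_across_samples(runs)
        assert len(table.features) == 1
        assert table.area_sample.iloc[0, 0] == 2.0

    def test_alignment_idempotent(self):
        rng = np.random.default_rng(11)
        runs = {}
        for i in range(4):
            runs[f"S{i}"] = [
                _pair(mz12=float(m), rt=float(r), n=int(n), sid=f"S{i}")
                for m, r, n in zip(
                    rng.uniform(100, 500, 20), rng.uniform(60, 600, 20), rng.integers(2, 30, 20)
                )
            ]
        table1 = align_pairs_across_samples(runs)
        table2 = align_pairs_across_samples(table1.to_pairs())
        assert table1.features[["polarity", "carbon_count"]].equals(
            table2.features[["polarity", "carbon_count"]]
        )
        assert np.allclose(table1.features["mz12"], table2.features["mz12"])
        assert table1.area_sample.fillna(-1).equals(table2.area_sample.fillna(-1))
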