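"""Coverage normalization, the Poisson local-background peak caller and the
replicate-consensus TSS classification."""

import numpy as np
import pytest

from poisedpol.annotation import GeneModel
from poisedpol.coverage import (
    CoverageTrack,
    LibraryStats,
    Peak,
    call_peaks,
    consensus_call,
    load_bedgraph,
    nearest_peak_distance,
    rpm_normalize,
    spike_scale_cuttag,
    spike_scale_proseq,
    write_bedgraph,
)
from poisedpol.annotation import Interval

from conftest import make_track


def peak_at(chrom, start, end, summit):
    return Peak(Interval(chrom, start, end), summit, 10.0, 5.0)


class TestNormalization:
    def test_rpm_identity_at_one_million(self):
        t = make_track([5.0] * 10)
        out = rpm_normalize(t, LibraryStats(mapped_reads=10**6))
        assert out.values["chr1"][0] == pytest.approx(5.0)

    def test_rpm_scales_by_depth(self):
        t = make_track([5.0] * 10)
        out = rpm_normalize(t, LibraryStats(mapped_reads=2 * 10**6))
        assert out.values["chr1"][0] == pytest.approx(2.5)
        assert out.normalization == "rpm"

    def test_double_normalization_refused(self):
        t = make_track([1.0], normalization="rpm")
        with pytest.raises(ValueError, match="double normalization"):
            rpm_normalize(t, LibraryStats(mapped_reads=100))

    def test_rpm_zero_mapped_errors(self):
        with pytest.raises(ValueError):
            rpm_normalize(make_track([1.0]), LibraryStats(mapped_reads=0))

    @pytest.mark.parametrize(
        "spike,mapped,ploidy,expected",
        [
            (10**4, 10**6, 1.0, 1.0),  # 100 * 1e4/1e6
            (10**4, 10**6, 0.5, 0.5),  # haploid round spermatids: halved
            (10**6, 10**6, 1.0, 100.0),  # spike == mapped: unchanged
        ],
    )
    def test_proseq_spike_factor(self, spike, mapped, ploidy, expected):
        t = make_track([100.0])
        stats = LibraryStats(mapped_reads=mapped, spikein_reads=spike,
                             ploidy_factor=ploidy, assay="proseq")
        out = spike_scale_proseq(t, stats)
        assert out.values["chr1"][0] == pytest.approx(expected)
        assert out.normalization == "spike_scaled"
        assert out.metadata["spike_mode"] == "as-stated"

    def test_proseq_reciprocal_mode(self):
        t = make_track([100.0])
        stats = LibraryStats(mapped_reads=10**6, spikein_reads=10**4)
        out = spike_scale_proseq(t, stats, mode="reciprocal")
        assert out.values["chr1"][0] == pytest.approx(100 * 1e6 / 1e4)
        assert out.metadata["spike_mode"] == "reciprocal"

    def test_proseq_zero_spike_errors(self):
        with pytest.raises(ValueError):
            spike_scale_proseq(make_track([1.0]), LibraryStats(mapped_reads=10))

    @pytest.mark.parametrize("ecoli,expected", [(10_000, 3.0), (20_000, 1.5)])
    def test_cuttag_scale(self, ecoli, expected):
        t = make_track([3.0])
        out = spike_scale_cuttag(t, LibraryStats(mapped_reads=10, spikein_reads=ecoli))
        assert out.values["chr1"][0] == pytest.approx(expected)

    def test_cuttag_zero_signal_stays_zero(self):
        t = make_track([0.0, 0.0])
        out = spike_scale_cuttag(t, LibraryStats(mapped_reads=1, spikein_reads=10_000))
        assert out.total() == 0.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            make_track([-1.0])


class TestCallPeaks:
    def test_planted_enrichment_recovered(self, rng):
        arr = rng.poisson(1.0, 100_000).astype(float)
        arr[50_000:50_400] += rng.poisson(10.0, 400)
        peaks = call_peaks(make_track(arr), fdr=0.01)
        assert len(peaks) == 1
        (p,) = peaks
        assert p.interval.start <= 50_000 and p.interval.end >= 50_400
        assert 50_000 <= p.summit < 50_400
        assert p.fold_enrichment > 3

    def test_short_enrichment_below_min_length_dropped(self, rng):
        arr = rng.poisson(1.0, 100_000).astype(float)
        arr[50_000:50_100] += rng.poisson(10.0, 100)
        peaks = call_peaks(make_track(arr), fdr=0.01, min_length=150,
                           window=100, merge_gap=0)
        assert peaks == []

    def test_empty_track_empty_result(self):
        assert call_peaks(make_track(np.zeros(1000))) == []

    def test_background_chromosome_mismatch_errors(self, rng):
        t = make_track(rng.poisson(1.0, 1000).astype(float))
        bg = CoverageTrack(values={"chr2": np.ones(1000)})
        with pytest.raises(ValueError, match="background"):
            call_peaks(t, background=bg)

    def test_scale_invariance(self, rng):
        arr = rng.poisson(1.0, 50_000).astype(float)
        arr[20_000:20_400] += rng.poisson(8.0, 400)
        p1 = call_peaks(make_track(arr), fdr=0.01)
        p2 = call_peaks(make_track(arr * 7.3), fdr=0.01)
        assert [(p.interval.start, p.interval.end, p.summit) for p in p1] == [
            (p.interval.start, p.interval.end, p.summit) for p in p2
        ]

    def test_igg_background_suppresses_shared_enrichment(self, rng):
        arr = rng.poisson(1.0, 100_000).astype(float)
        arr[50_000:50_400] += rng.poisson(10.0, 400)
        bg = arr.copy()  # control shows the same enrichment
        assert call_peaks(make_track(arr), background=make_track(bg), fdr=0.01) == []

    def test_false_discovery_controlled_on_noise(self):
        """On pure Poisson noise the in-peak genome fraction stays at or
        below twice the nominal FDR across seeds."""
        fractions = []
        n = 2_000_000
        for seed in range(20):
            arr = np.random.default_rng(seed).poisson(1.0, n).astype(float)
            peaks = call_peaks(make_track(arr), fdr=0.01)
            fractions.append(sum(len(p.interval) for p in peaks) / n)
        assert np.mean(fractions) <= 0.02


class TestNearestPeakDistance:
    def test_summit_distance(self):
        g = GeneModel("g", "chr1", 990, 2000, "+", tss_list=(1000,))
        peaks = [peak_at("chr1", 1100, 1300, 1158), peak_at("chr1", 8900, 9100, 9000)]
        assert nearest_peak_distance(g, peaks) == 158

    def test_summit_at_tss(self):
        g = GeneModel("g", "chr1", 1000, 2000, "+")
        assert nearest_peak_distance(g, [peak_at("chr1", 900, 1200, 1000)]) == 0

    def test_min_over_multiple_tss(self):
        g = GeneModel("g", "chr1", 1000, 9000, "+", tss_list=(1000, 8000))
        peaks = [peak_at("chr1", 8000, 8300, 8100)]
        assert nearest_peak_distance(g, peaks) == 100

    def test_absent_when_chromosome_empty(self):
        g = GeneModel("g", "chr2", 0, 100, "+")
        assert nearest_peak_distance(g, [peak_at("chr1", 0, 200, 50)]) is None

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            tss = tuple(int(t) for t in rng.integers(0, 10_000, rng.integers(1, 4)))
            g = GeneModel("g", "chr1", min(tss), max(tss) + 10, "+", tss_list=tss)
            summits = rng.integers(0, 10_000, rng.integers(1, 20))
            peaks = [peak_at("chr1", int(s), int(s) + 10, int(s)) for s in summits]
            expected = min(abs(int(s) - t) for s in summits for t in tss)
            assert nearest_peak_distance(g, peaks) == expected


class TestConsensusCall:
    def gene(self):
        return GeneModel("g", "chr1", 10_000, 20_000, "+")

    def reps_with_distances(self, dists):
        g = self.gene()
        return [
            [peak_at("chr1", g.start + d, g.start + d + 200, g.canonical_tss + d)]
            for d in dists
        ]

    def test_two_of_three_supporting(self):
        call = consensus_call(self.gene(), self.reps_with_distances([100, 1500, 5000]))
        assert call.status and call.n_supporting == 2

    def test_all_outside_window(self):
        call = consensus_call(self.gene(), self.reps_with_distances([2500, 3000, 2100]))
        assert not call.status

    def test_any_tss_qualifies(self):
        g = GeneModel("g", "chr1", 10_000, 40_000, "+", tss_list=(10_000, 30_000))
        reps = [
            [peak_at("chr1", 30_100, 30_300, 30_100)],  # near TSS2 only
            [peak_at("chr1", 30_050, 30_250, 30_050)],
            [peak_at("chr1", 20_000, 20_200, 20_000)],  # near neither
        ]
        assert consensus_call(g, reps).status

    def test_monotone_in_added_replicates(self, rng):
        g = self.gene()
        dists = [int(d) for d in rng.integers(0, 6000, 5)]
        reps = self.reps_with_distances(dists)
        before = consensus_call(g, reps).status
        after = consensus_call(g, reps + self.reps_with_distances([50])).status
        assert (not before) or after

    def test_no_replicates_errors(self):
        with pytest.raises(ValueError):
            consensus_call(self.gene(), [])


class TestBedgraphIO:
    def test_round_trip(self, tmp_path, rng):
        arr = rng.poisson(0.5, 5000).astype(float)
        t = make_track(arr)
        path = tmp_path / "t.bedgraph"
        write_bedgraph(t, path)
        loaded = load_bedgraph(path, {"chr1": 5000})
        np.testing.assert_allclose(loaded.values["chr1"], arr)

    def test_bad_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t10\tx\t2.0\n")
        with pytest.raises(ValueError, match=":2:"):
            load_bedgraph(p, {"chr1": 100})
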