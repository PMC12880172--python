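"""Peak caller behaviour and overlap-partition analytics."""

import numpy as np
import pytest

from conftest import brute_force_partition
from spikenorm import (
    Peak,
    SignalTrack,
    call_peaks,
    consensus_peaks,
    method_consensus_comparison,
    overlap_partition,
    read_bed,
    write_bed,
    write_narrowpeak,
)
from spikenorm.peaks import poisson_count_threshold


def track_from(values, window=20):
    values = np.asarray(values, dtype=float)
    return SignalTrack(window_width=window,
                       chrom_lengths={"chr1": len(values) * window},
                       values={"chr1": values}, scale="raw")


def iv(contig, start, end):
    return Peak(contig=contig, start=start, end=end)


class TestCallPeaks:
    def test_single_hot_window(self):
        vals = np.zeros(500)
        vals[100] = 1000
        peaks = call_peaks(track_from(vals), peak_width=20)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.start <= 100 * 20 < p.end
        assert p.start <= p.summit < p.end
        assert p.p_value < 1e-10

    def test_empty_track(self):
        assert call_peaks(track_from(np.zeros(100))) == []

    def test_contig_order_invariance(self, rng):
        vals1 = rng.poisson(0.5, 1000).astype(float)
        vals2 = rng.poisson(0.5, 1000).astype(float)
        vals1[500] = vals2[100] = 200
        a = SignalTrack(20, {"chr1": 20_000, "chr2": 20_000},
                        {"chr1": vals1.copy(), "chr2": vals2.copy()})
        b = SignalTrack(20, {"chr2": 20_000, "chr1": 20_000},
                        {"chr2": vals2.copy(), "chr1": vals1.copy()})
        assert call_peaks(a) == call_peaks(b)

    def test_monotone_in_thresholds(self, rng):
        vals = rng.poisson(1.0, 5000).astype(float)
        for w in rng.choice(5000, 30, replace=False):
            vals[w] += rng.poisson(8)
        t = track_from(vals)
        n_loose = len(call_peaks(t, fold_min=2, p_max=1e-3))
        n_mid = len(call_peaks(t, fold_min=4, p_max=1e-3))
        n_tight = len(call_peaks(t, fold_min=4, p_max=1e-6))
        assert n_loose >= n_mid >= n_tight

    def test_threshold_definition(self):
        """c is the smallest count passing both the fold and tail cutoffs."""
        from scipy.stats import poisson

        for lam, k in [(0.3, 1), (1.0, 10), (2.5, 10), (0.05, 10)]:
            c = poisson_count_threshold(lam, k, fold_min=4.0, p_max=1e-4)
            mu = lam * k
            assert poisson.sf(c - 1, mu) <= 1e-4
            assert c >= np.ceil(4 * mu)
            # c - 1 must fail at least one of the two conditions
            assert (c - 1 < np.ceil(4 * mu)) or poisson.sf(c - 2, mu) > 1e-4


class TestOverlapPartition:
    def test_two_sample_overlap(self):
        part = overlap_partition([[iv("chr1", 0, 100)], [iv("chr1", 50, 150)]],
                                 sample_ids=["A", "B"])
        assert len(part.regions) == 1
        assert part.regions[0].mask == 0b11
        assert part.venn_counts == {0b01: 0, 0b10: 0, 0b11: 1}

    def test_three_disjoint_singletons(self):
        part = overlap_partition([
            [iv("chr1", 0, 10)], [iv("chr1", 100, 110)], [iv("chr1", 200, 210)],
        ])
        assert len(part.regions) == 3
        assert part.exclusive_count() == 3
        assert consensus_peaks(part) == []

    def test_adjacent_intervals_do_not_merge(self):
        part = overlap_partition([[iv("chr1", 0, 100)], [iv("chr1", 100, 200)]])
        assert len(part.regions) == 2

    def test_transitive_chain(self):
        part = overlap_partition([
            [iv("chr1", 0, 60)], [iv("chr1", 50, 120)], [iv("chr1", 110, 200)],
        ])
        assert len(part.regions) == 1
        assert part.regions[0].mask == 0b111
        assert len(consensus_peaks(part)) == 1

    def test_covered_peak_joins_region(self):
        base = [[iv("chr1", 0, 100)], [iv("chr1", 50, 150)]]
        n0 = len(overlap_partition(base).regions)
        base[0].append(iv("chr1", 60, 90))
        assert len(overlap_partition(base).regions) == n0

    def test_permutation_invariance(self, rng):
        sets = [
            [iv("chr1", int(s), int(s) + 30) for s in rng.integers(0, 2000, 15)]
            for _ in range(3)
        ]
        p0 = overlap_partition(sets, sample_ids=["a", "b", "c"])
        p1 = overlap_partition([sets[2], sets[0], sets[1]],
                               sample_ids=["c", "a", "b"])
        assert p0.labelled_counts() == {
            "&".join(sorted(k.split("&"))): v
            for k, v in p0.labelled_counts().items()}  # labels well-formed
        a = {frozenset(k.split("&")): v for k, v in p0.labelled_counts().items()}
        b = {frozenset(k.split("&")): v for k, v in p1.labelled_counts().items()}
        assert a == b

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            sets = [
                [("chr%d" % rng.integers(1, 3), int(s), int(s + rng.integers(10, 80)))
                 for s in rng.integers(0, 1500, rng.integers(3, 25))]
                for _ in range(3)
            ]
            part = overlap_partition(
                [[iv(c, s, e) for c, s, e in sset] for sset in sets])
            assert part.venn_counts == brute_force_partition(sets)

    def test_method_consensus_comparison(self):
        shared = [iv("chr1", 0, 100), iv("chr1", 500, 600)]
        part = method_consensus_comparison({
            "cpm": list(shared),
            "spikein": list(shared),
            "input_adjusted": shared + [iv("chr1", 900, 950)],
        })
        counts = part.labelled_counts()
        assert counts["cpm&spikein&input_adjusted"] == 2
        assert counts["input_adjusted"] == 1
        assert part.exclusive_count() == 1


class TestPeakIO:
    def test_bed_roundtrip(self, tmp_path):
        peaks = [Peak("chr1", 100, 300, summit=180, score=12.5, p_value=1e-8),
                 Peak("chr2", 50, 90)]
        p = tmp_path / "peaks.bed"
        write_bed(peaks, p)
        back = read_bed(p)
        assert [(q.contig, q.start, q.end) for q in back] == \
            [(q.contig, q.start, q.end) for q in peaks]

    def test_narrowpeak_roundtrip(self, tmp_path):
        peaks = [Peak("chr1", 100, 300, summit=180, score=12.5, p_value=1e-8)]
        p = tmp_path / "peaks.narrowPeak"
        write_narrowpeak(peaks, p)
        q = read_bed(p)[0]
        assert (q.contig, q.start, q.end, q.summit) == ("chr1", 100, 300, 180)
        assert q.p_value == pytest.approx(1e-8, rel=1e-3)

    def test_invalid_peak_rejected(self):
        with pytest.raises(ValueError):
            Peak("chr1", 10, 10)
        with pytest.raises(ValueError):
            Peak("chr1", 10, 20, summit=30)
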