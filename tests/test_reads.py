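"""Read classification, counting and seeded fractional downsampling."""

import numpy as np
import pysam
import pytest

from spikenorm import classify_and_count, downsample, retained_count, retention_mask
from spikenorm.reads import retain_read

CONTIGS = {"chr1": 10_000, "chr2": 10_000, "spikein_2L": 5_000}


class TestClassifyAndCount:
    def test_composite_example(self, sam_factory):
        """3 non-dup chr1 + 1 dup chr1 + 2 non-dup spike -> (6,6,3,2)."""
        reads = [
            ("r1", "chr1", 100, 50, 0),
            ("r2", "chr1", 200, 50, 0),
            ("r3", "chr1", 300, 50, 0),
            ("r4", "chr1", 400, 50, 1024),
            ("r5", "spikein_2L", 100, 50, 0),
            ("r6", "spikein_2L", 200, 50, 0),
        ]
        rc = classify_and_count(sam_factory(reads, CONTIGS))
        assert (rc.total, rc.mapped, rc.unique_sample, rc.unique_spikein) == (6, 6, 3, 2)

    def test_empty_file(self, sam_factory):
        rc = classify_and_count(sam_factory([], CONTIGS))
        assert (rc.total, rc.mapped, rc.unique_sample, rc.unique_spikein) == (0, 0, 0, 0)

    def test_unmapped_secondary_excluded(self, sam_factory):
        reads = [
            ("r1", "chr1", 100, 50, 0),
            ("r2", None, 0, 50, 4),       # unmapped: total only
            ("r3", "chr1", 150, 50, 256),  # secondary: ignored entirely
        ]
        rc = classify_and_count(sam_factory(reads, CONTIGS))
        assert (rc.total, rc.mapped, rc.unique_sample) == (2, 1, 1)

    def test_two_file_layout(self, sam_factory):
        sample = sam_factory([("a", "chr1", 10, 40, 0), ("b", "chr2", 10, 40, 0)],
                             {"chr1": 10_000, "chr2": 10_000})
        spike = sam_factory([("c", "2L", 10, 40, 0)], {"2L": 5_000})
        rc = classify_and_count(sample, spike)
        assert (rc.unique_sample, rc.unique_spikein) == (2, 1)

    def test_unassignable_contig_rejected(self, sam_factory):
        path = sam_factory([("a", "chrX", 10, 40, 0)], {"chrX": 10_000})
        with pytest.raises(ValueError, match="chrX"):
            classify_and_count(path, known_contigs={"chr1": "sample"})


class TestDownsample:
    def _reads(self, n):
        return [(f"r{i}", "chr1", 10 + 2 * i, 40, 0) for i in range(n)]

    def test_nf_one_is_identity(self, sam_factory, tmp_path):
        src = sam_factory(self._reads(50), CONTIGS)
        out = tmp_path / "out.sam"
        kept = downsample(src, out, nf=1.0, seed=3)
        assert kept == 50
        with pysam.AlignmentFile(str(out)) as fh:
            assert sum(1 for _ in fh) == 50

    def test_deterministic_and_matches_name_rule(self, sam_factory, tmp_path):
        src = sam_factory(self._reads(200), CONTIGS)
        out1, out2 = tmp_path / "a.sam", tmp_path / "b.sam"
        k1 = downsample(src, out1, nf=0.4, seed=9)
        k2 = downsample(src, out2, nf=0.4, seed=9)
        assert k1 == k2
        names1 = [r.query_name for r in pysam.AlignmentFile(str(out1))]
        names2 = [r.query_name for r in pysam.AlignmentFile(str(out2))]
        assert names1 == names2
        # every retained read is exactly one the decision rule retains
        expected = {f"r{i}" for i in range(200) if retain_read(f"r{i}", 0.4, 9)}
        assert set(names1) == expected

    def test_different_seeds_differ(self, sam_factory, tmp_path):
        src = sam_factory(self._reads(300), CONTIGS)
        downsample(src, tmp_path / "s1.sam", nf=0.5, seed=1)
        downsample(src, tmp_path / "s2.sam", nf=0.5, seed=2)
        n1 = {r.query_name for r in pysam.AlignmentFile(str(tmp_path / "s1.sam"))}
        n2 = {r.query_name for r in pysam.AlignmentFile(str(tmp_path / "s2.sam"))}
        assert n1 != n2

    def test_pair_consistency(self, sam_factory, tmp_path):
        reads = []
        for i in range(150):
            reads.append((f"p{i}", "chr1", 100 + i, 40, 0x1 | 0x40))
            reads.append((f"p{i}", "chr1", 300 + i, 40, 0x1 | 0x80))
        src = sam_factory(reads, CONTIGS)
        out = tmp_path / "pairs.sam"
        downsample(src, out, nf=0.5, seed=5, pair_consistent=True)
        from collections import Counter
        counts = Counter(r.query_name for r in pysam.AlignmentFile(str(out)))
        assert all(v == 2 for v in counts.values())

    def test_invalid_fraction(self, sam_factory, tmp_path):
        src = sam_factory(self._reads(5), CONTIGS)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                downsample(src, tmp_path / "x.sam", nf=bad, seed=0)


class TestRetentionStatistics:
    def test_binomial_moments(self):
        """Retained counts across seeds behave like Binomial(n, nf)."""
        n, nf = 100_000, 0.5
        draws = np.array([retained_count(n, nf, seed) for seed in range(60)])
        sd = np.sqrt(n * nf * (1 - nf))  # ~158
        assert abs(draws.mean() - n * nf) < 3 * sd / np.sqrt(len(draws))
        assert 0.5 * sd < draws.std() < 1.5 * sd

    def test_mask_matches_counts_and_is_order_free(self):
        keys = np.arange(10_000, dtype=np.uint64)
        mask = retention_mask(keys, 0.3, 42)
        assert retained_count(10_000, 0.3, 42) == int(mask.sum())
        perm = np.random.default_rng(0).permutation(10_000)
        assert np.array_equal(retention_mask(keys[perm], 0.3, 42), mask[perm])

    def test_nf_one_keeps_all(self):
        assert retention_mask(np.arange(100, dtype=np.uint64), 1.0, 7).all()


def test_downsampled_composition(small_experiment, tmp_path):
    """Downsampling the experimental genome leaves spike-in counts unchanged."""
    from spikenorm.simulate import write_sam

    sample = small_experiment.samples[0]
    src = tmp_path / "s.sam"
    write_sam(sample, small_experiment.config, src)
    rc0 = classify_and_count(src)
    # spike-in reads live on spike contigs; retention of sample reads at nf
    nf = 0.5
    intervals = sample.unique_intervals(nf=nf, seed=1)
    kept = sum(len(s) for s, _ in intervals.values())
    sd = np.sqrt(rc0.unique_sample * nf * (1 - nf))
    assert abs(kept - nf * rc0.unique_sample) < 4 * sd
    spike = sample.unique_intervals(nf=nf, seed=1, spikein=True)
    assert sum(len(s) for s, _ in spike.values()) == rc0.unique_spikein
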