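import numpy as np
import pysam
import pytest

from spikenorm import SampleConfig, SimulationConfig, simulate_experiment


def make_sam(path, reads, contigs):
    """Write a minimal SAM file.

    ``reads`` is a list of (name, contig, start, length, flag) tuples;
    ``contigs`` maps contig name to length. flag=4 writes an unmapped read.
    """
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in contigs.items()],
    }
    names = list(contigs)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, contig, start, length, flag in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            if flag & 4:
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.reference_id = names.index(contig)
                a.reference_start = start
                a.cigarstring = f"{length}M"
                a.mapping_quality = 60
            a.query_sequence = "N" * length
            out.write(a)
    return path


@pytest.fixture
def sam_factory(tmp_path):
    counter = {"n": 0}

    def _make(reads, contigs):
        counter["n"] += 1
        return make_sam(tmp_path / f"reads{counter['n']}.sam", reads, contigs)

    return _make


def small_config(**overrides):
    """A fast three-sample simulation config for unit tests."""
    defaults = dict(
        sample_genome={"chr1": 400_000, "chr2": 300_000},
        spikein_genome={"spikein_2L": 100_000},
        n_sites=20,
        min_gap=2_000,
    )
    sample_kw = overrides.pop("sample_kw", {})
    defaults.update(overrides)
    samples = tuple(
        SampleConfig(sample_id=f"s{i+1}", input_dna_mass=500.0,
                     spikein_mass=62.5, depth=8_000, **sample_kw)
        for i in range(3)
    )
    return SimulationConfig(samples=defaults.pop("samples", samples), **defaults)


@pytest.fixture
def small_experiment():
    return simulate_experiment(small_config(), seed=11)


def brute_force_partition(interval_sets):
    """Independent union-find oracle for the overlap decomposition.

    Builds the pairwise-overlap graph over all intervals across sets and
    merges connected components; returns {bitmask: count} over merged
    regions (every non-empty mask present, zero counts included).
    """
    items = []
    for i, intervals in enumerate(interval_sets):
        for contig, start, end in intervals:
            items.append((contig, start, end, i))
    n = len(items)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a in range(n):
        for b in range(a + 1, n):
            ca, sa, ea, _ = items[a]
            cb, sb, eb, _ = items[b]
            if ca == cb and sa < eb and sb < ea:
                union(a, b)

    masks = {}
    for idx, (_, _, _, i) in enumerate(items):
        root = find(idx)
        masks[root] = masks.get(root, 0) | (1 << i)
    counts = {m: 0 for m in range(1, 2 ** len(interval_sets))}
    for m in masks.values():
        counts[m] += 1
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
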