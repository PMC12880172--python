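"""Peak calling and multi-sample overlap analytics.

The caller is a deliberately minimal, documented stand-in for a full-featured
narrow-peak caller: it slides a fixed-width window over a raw signal track,
flags positions whose summed count clears both a fold-enrichment cutoff over
the global Poisson background and a Poisson upper-tail p-value cutoff, and
merges overlapping flagged spans. Because the background rate is global, the
two cutoffs collapse into a single integer count threshold, which makes the
caller's false-positive behaviour analytically predictable (the expected
number of spurious calls on a site-free track is the number of tested
windows times the Poisson tail mass beyond the threshold).

Overlap analysis uses the >= 1 bp interval-overlap criterion with transitive
merging: peaks from k samples whose intervals chain together form one merged
region, whose membership bitmask records the contributing samples. The
2^k - 1 bitmask categories are the cells of a k-set Venn diagram; regions
carrying the full mask are the consensus peaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import poisson

from .tracks import SignalTrack

__all__ = [
    "Peak", "Region", "OverlapPartition",
    "call_peaks", "poisson_count_threshold",
    "overlap_partition", "consensus_peaks", "method_consensus_comparison",
    "read_bed", "write_bed", "write_narrowpeak",
]


@dataclass(frozen=True)
class Peak:
    """A called enriched interval (0-based half-open)."""

    contig: str
    start: int
    end: int
    summit: int | None = None
    score: float = 0.0  # fold enrichment over global background
    p_value: float = 1.0
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.contig}:{self.start}-{self.end} is empty")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie inside the peak interval")


@dataclass(frozen=True)
class Region:
    """A merged interval with the bitmask of samples contributing peaks."""

    contig: str
    start: int
    end: int
    mask: int


@dataclass
class OverlapPartition:
    """Transitive overlap decomposition of k peak sets.

    ``venn_counts`` maps every non-empty membership bitmask (bit ``i`` set =
    sample ``sample_ids[i]`` contributed) to the number of merged regions
    with exactly that membership; the counts sum to ``len(regions)``.
    """

    sample_ids: list[str]
    regions: list[Region]
    venn_counts: dict[int, int]

    def mask_label(self, mask: int) -> str:
        return "&".join(
            sid for i, sid in enumerate(self.sample_ids) if mask >> i & 1
        )

    def labelled_counts(self) -> dict[str, int]:
        return {self.mask_label(m): c for m, c in sorted(self.venn_counts.items())}

    def exclusive_count(self, sample_id: str | None = None) -> int:
        """Number of single-sample regions (optionally for one sample)."""
        if sample_id is not None:
            bit = 1 << self.sample_ids.index(sample_id)
            return self.venn_counts.get(bit, 0)
        return sum(
            c for m, c in self.venn_counts.items() if bin(m).count("1") == 1
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "sample_ids": self.sample_ids,
                "venn_counts": self.labelled_counts(),
                "n_regions": len(self.regions),
            },
            indent=2,
        ) + "\n")


def poisson_count_threshold(lam: float, width_windows: int,
                            fold_min: float, p_max: float) -> int:
    """Smallest integer count a window sum must reach to be called.

    ``lam`` is the per-window background rate; a span of ``width_windows``
    windows has background mean ``lam * width_windows``. The threshold is the
    smaller count satisfying BOTH fold >= fold_min and
    P(Poisson(mean) >= count) <= p_max.
    """
    mu = lam * width_windows
    c_fold = int(np.ceil(fold_min * mu))
    c = max(1, int(poisson.isf(p_max, mu)))
    while c > 1 and poisson.sf(c - 2, mu) <= p_max:
        c -= 1
    while poisson.sf(c - 1, mu) > p_max:
        c += 1
    return max(c, c_fold, 1)


def call_peaks(
    track: SignalTrack,
    peak_width: int = 200,
    fold_min: float = 4.0,
    p_max: float = 1e-4,
) -> list[Peak]:
    """Call enriched regions on a raw windowed track.

    A ``peak_width`` window slides one track-window at a time; spans whose
    summed count clears :func:`poisson_count_threshold` (global background
    ``lam`` = total coverage / total windows) become candidates, overlapping
    candidates are merged, and the summit is the centre of the maximal track
    window inside each merged region. Deterministic and independent of contig
    processing order. An all-zero track yields no peaks.
    """
    if track.scale != "raw":
        raise ValueError("peak calling requires a raw-count track")
    W = track.window_width
    k = max(1, peak_width // W)
    total_windows = sum(len(v) for v in track.values.values())
    if total_windows == 0:
        raise ValueError("degenerate background: track has no windows")
    total = track.total()
    if total == 0:
        return []
    lam = total / total_windows
    threshold = poisson_count_threshold(lam, k, fold_min, p_max)
    mu = lam * k

    peaks: list[Peak] = []
    for contig in sorted(track.chrom_lengths):
        vals = track.values[contig]
        nw = len(vals)
        if nw < k:
            continue
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        rolling = csum[k:] - csum[:-k]  # rolling[i] = sum of windows [i, i+k)
        cand = np.flatnonzero(rolling >= threshold)
        if len(cand) == 0:
            continue
        # merge candidate spans [i, i+k) that overlap (gap in start < k)
        breaks = np.flatnonzero(np.diff(cand) >= k)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(cand) - 1]])
        length = track.chrom_lengths[contig]
        for a, b in zip(starts, ends):
            w_lo = int(cand[a])
            w_hi = int(cand[b]) + k  # exclusive window bound
            seg = vals[w_lo:w_hi]
            summit_w = w_lo + int(np.argmax(seg))
            obs = float(rolling[cand[a]:cand[b] + 1].max())
            peaks.append(Peak(
                contig=contig,
                start=w_lo * W,
                end=min(w_hi * W, length),
                summit=min(summit_w * W + W // 2, length - 1),
                score=obs / mu,
                p_value=float(poisson.sf(obs - 1, mu)),
            ))
    return peaks


def _as_interval_list(peaks: Sequence) -> list[tuple[str, int, int]]:
    return [(p.contig, p.start, p.end) for p in peaks]


def overlap_partition(
    peak_sets: Sequence[Sequence],
    sample_ids: Sequence[str] | None = None,
) -> OverlapPartition:
    """Decompose k peak sets into transitively merged regions with Venn counts.

    Peaks across samples whose intervals overlap by >= 1 bp (directly or
    through a chain of overlaps) form one merged region. Input order is
    irrelevant: intervals are sorted internally. Permuting the sample order
    permutes the bitmask bits correspondingly but not the region set.
    """
    k = len(peak_sets)
    if k < 2:
        raise ValueError(f"need at least 2 peak sets, got {k}")
    if sample_ids is None:
        sample_ids = [f"set{i + 1}" for i in range(k)]
    sample_ids = list(sample_ids)
    if len(sample_ids) != k:
        raise ValueError("sample_ids must match the number of peak sets")

    items: list[tuple[str, int, int, int]] = []
    for i, peaks in enumerate(peak_sets):
        for contig, start, end in _as_interval_list(peaks):
            items.append((contig, start, end, i))
    items.sort(key=lambda t: (t[0], t[1], t[2]))

    regions: list[Region] = []
    cur: list | None = None  # [contig, start, end, mask]
    for contig, start, end, i in items:
        if cur is not None and contig == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3] |= 1 << i
        else:
            if cur is not None:
                regions.append(Region(*cur))
            cur = [contig, start, end, 1 << i]
    if cur is not None:
        regions.append(Region(*cur))

    venn: dict[int, int] = {m: 0 for m in range(1, 2 ** k)}
    for r in regions:
        venn[r.mask] += 1
    return OverlapPartition(sample_ids=sample_ids, regions=regions,
                            venn_counts=venn)


def consensus_peaks(partition: OverlapPartition) -> list[Region]:
    """Merged regions present in every sample, ordered by contig then start."""
    full = (1 << len(partition.sample_ids)) - 1
    return sorted(
        (r for r in partition.regions if r.mask == full),
        key=lambda r: (r.contig, r.start),
    )


def method_consensus_comparison(
    consensus_by_method: Mapping[str, Sequence],
) -> OverlapPartition:
    """Overlap partition across normalization methods instead of replicates."""
    methods = list(consensus_by_method)
    return overlap_partition(
        [consensus_by_method[m] for m in methods], sample_ids=methods
    )


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED (>=3 columns) or ENCODE narrowPeak into Peak records."""
    peaks: list[Peak] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        contig, start, end = f[0], int(f[1]), int(f[2])
        name = f[3] if len(f) > 3 and f[3] != "." else None
        summit = None
        score = 0.0
        p_value = 1.0
        if len(f) >= 10:  # narrowPeak
            score = float(f[6])
            if float(f[7]) >= 0:
                p_value = 10.0 ** (-float(f[7]))
            if int(f[9]) >= 0:
                summit = start + int(f[9])
        peaks.append(Peak(contig=contig, start=start, end=end, summit=summit,
                          score=score, p_value=p_value, name=name))
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED6 (score = fold enrichment capped at 1000)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            name = p.name or f"peak_{i}"
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{name}"
                     f"\t{min(int(round(p.score * 10)), 1000)}\t.\n")


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks in ENCODE narrowPeak format (qValue column unset)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            name = p.name or f"peak_{i}"
            neglog_p = -np.log10(max(p.p_value, 1e-300))
            summit_off = (p.summit - p.start) if p.summit is not None else -1
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{name}"
                f"\t{min(int(round(p.score * 10)), 1000)}\t."
                f"\t{p.score:.4f}\t{neglog_p:.4f}\t-1\t{summit_off}\n"
            )
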