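"""End-to-end workflow: counts -> factors -> downsampling -> tracks -> peaks.

Given per-sample alignments (composite-genome SAM/BAM with prefixed spike-in
contigs) and a metadata table carrying the wet-lab masses, the pipeline runs
every requested normalization method, writes the normalized alignments,
bedGraph tracks and narrowPeak calls, computes the replicate-overlap Venn
decomposition per method, and emits a bench-table-style summary TSV (reads
before/after each normalization, peaks per method) plus a factor report.
All intermediate files carry the method name; everything is seeded, so a
re-run with the same seed reproduces the outputs exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .factors import compute_factors
from .peaks import call_peaks, consensus_peaks, overlap_partition, write_narrowpeak
from .reads import DEFAULT_SPIKE_PREFIX, classify_and_count, downsample
from .samples import ReadCounts, SampleStats, read_metadata
from .tracks import apply_cpm, windowed_coverage, write_bedgraph

logger = logging.getLogger(__name__)

ALL_METHODS = ("cpm", "equal_read", "spikein", "input_adjusted_spikein")


@dataclass
class PipelineResult:
    outdir: Path
    counts: dict[str, ReadCounts]
    factor_reports: dict[str, dict]
    retained: dict[str, dict[str, int]]      # method -> sample -> reads kept
    peak_counts: dict[str, dict[str, int]]   # method -> sample -> peaks
    venn: dict[str, dict[str, int]]          # method -> labelled venn counts
    summary: pd.DataFrame = field(repr=False, default=None)


def run_pipeline(
    sample_paths: Mapping[str, str | Path],
    metadata_path: str | Path,
    outdir: str | Path,
    methods: Sequence[str] = ALL_METHODS,
    seed: int = 0,
    window_width: int = 20,
    peak_width: int = 200,
    fold_min: float = 4.0,
    p_max: float = 1e-4,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
) -> PipelineResult:
    """Run the full comparison workflow on aligned reads plus metadata.

    ``sample_paths`` maps sample id to its composite-genome alignment.
    Read counts (X_i, S_i) are taken from the alignments; masses come from
    the metadata table. Spike-in reads are never downsampled; only
    experimental-genome contigs enter tracks and peak calling.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {s.sample_id: s for s in read_metadata(metadata_path)}
    missing = [sid for sid in sample_paths if sid not in meta]
    if missing:
        raise ValueError(f"metadata has no rows for samples: {missing}")

    counts: dict[str, ReadCounts] = {}
    stats: list[SampleStats] = []
    for sid, path in sample_paths.items():
        rc = classify_and_count(path, spike_prefix=spike_prefix)
        counts[sid] = rc
        stats.append(SampleStats(
            sample_id=sid,
            unique_sample_reads=rc.unique_sample,
            unique_spikein_reads=rc.unique_spikein,
            input_dna_mass=meta[sid].input_dna_mass,
            spikein_mass=meta[sid].spikein_mass,
        ))

    factor_reports: dict[str, dict] = {}
    retained: dict[str, dict[str, int]] = {}
    peak_counts: dict[str, dict[str, int]] = {}
    venn: dict[str, dict[str, int]] = {}

    for method in methods:
        nfs = compute_factors(method, stats)
        factor_reports[method] = nfs.to_report(stats)
        retained[method] = {}
        peak_sets = []
        for i, (sid, path) in enumerate(sample_paths.items()):
            nf = nfs.factors.get(sid, 1.0)
            norm_path = outdir / f"{sid}.{method}{Path(str(path)).suffix}"
            downsample(path, norm_path, nf=nf,
                       seed=(seed * 97 + i) % (2**31 - 1),
                       keep_contig_prefix=spike_prefix)
            retained[method][sid] = classify_and_count(
                norm_path, spike_prefix=spike_prefix).unique_sample
            track = windowed_coverage(norm_path, window_width=window_width)
            # drop spike-in contigs from signal tracks and peak calling
            sample_contigs = {
                c: l for c, l in track.chrom_lengths.items()
                if not c.startswith(spike_prefix)
            }
            track.chrom_lengths = sample_contigs
            track.values = {c: track.values[c] for c in sample_contigs}
            write_bedgraph(track, outdir / f"{sid}.{method}.bedGraph")
            if method == "cpm" and counts[sid].unique_sample > 0:
                write_bedgraph(apply_cpm(track, counts[sid].unique_sample),
                               outdir / f"{sid}.{method}.cpm.bedGraph")
            peaks = call_peaks(track, peak_width=peak_width,
                               fold_min=fold_min, p_max=p_max)
            write_narrowpeak(peaks, outdir / f"{sid}.{method}.narrowPeak")
            peak_sets.append(peaks)
        peak_counts[method] = {
            sid: len(ps) for sid, ps in zip(sample_paths, peak_sets)
        }
        if len(peak_sets) >= 2 and all(len(p) > 0 for p in peak_sets):
            part = overlap_partition(peak_sets, sample_ids=list(sample_paths))
            venn[method] = part.labelled_counts()
            venn[method]["consensus"] = len(consensus_peaks(part))
            part.to_json(outdir / f"venn.{method}.json")
        else:
            venn[method] = {}

    (outdir / "factors.json").write_text(
        json.dumps(factor_reports, indent=2) + "\n")

    rows = {}
    sids = list(sample_paths)
    rows["total_reads"] = [counts[s].total for s in sids]
    rows["mapped_reads"] = [counts[s].mapped for s in sids]
    rows["unique_sample_reads"] = [counts[s].unique_sample for s in sids]
    rows["unique_spikein_reads"] = [counts[s].unique_spikein for s in sids]
    for method in methods:
        rows[f"reads_after_{method}"] = [retained[method][s] for s in sids]
    for method in methods:
        rows[f"peaks_{method}"] = [peak_counts[method][s] for s in sids]
    summary = pd.DataFrame(rows, index=sids).T
    summary.to_csv(outdir / "summary.tsv", sep="\t")

    return PipelineResult(
        outdir=outdir, counts=counts, factor_reports=factor_reports,
        retained=retained, peak_counts=peak_counts, venn=venn,
        summary=summary,
    )
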