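"""Alignment-file operations: classify/count reads and fractional downsampling.

Reads are consumed as already-aligned, duplicate-flagged SAM/BAM (alignment,
adapter trimming and duplicate marking are upstream concerns). Two layouts are
supported, mirroring how dual-genome spike-in experiments are aligned in
practice:

* two files per sample — one alignment against the experimental genome and
  one against the spike-in genome; or
* one composite-genome alignment whose spike-in contigs carry a configurable
  name prefix (default ``"spikein_"``).

"Unique reads" throughout means mapped, primary, non-duplicate alignments —
the quantity entering every normalization-factor formula. Counts are in read
units (each mate of a pair counts once), matching per-sample bench tables.

Downsampling replicates the samtools ``-s`` contract (retain each read, or
read pair, independently with probability ``nf``, decided by a seeded hash of
the read name) without promising byte compatibility with samtools' own hash.
The decision rule is ``mix64(name_key XOR mix64(seed)) / 2**64 < nf`` with a
splitmix64 finalizer, so retention is deterministic, order-independent and
pair-consistent (mates share a name, hence a decision).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam

from .samples import ReadCounts

logger = logging.getLogger(__name__)

DEFAULT_SPIKE_PREFIX = "spikein_"

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = 0xFFFFFFFFFFFFFFFF


def fnv1a64(data: bytes) -> int:
    """64-bit FNV-1a hash of a byte string (stable across runs/platforms)."""
    h = _FNV_OFFSET
    for b in data:
        h = ((h ^ b) * _FNV_PRIME) & _MASK64
    return h


def _splitmix64_int(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def _splitmix64_array(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(_MASK64)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def retain_read(name: str, nf: float, seed: int) -> bool:
    """Seeded Bernoulli(nf) retention decision for one read name."""
    salt = _splitmix64_int(seed & _MASK64)
    h = _splitmix64_int(fnv1a64(name.encode()) ^ salt)
    return h < nf * 2.0**64


def retention_mask(keys: np.ndarray, nf: float, seed: int) -> np.ndarray:
    """Vectorized retention decisions for an array of 64-bit read keys.

    Identical decision rule to :func:`retain_read` applied to pre-hashed
    integer keys; used by the simulator's in-memory read sets and by
    large-scale retention accounting.
    """
    if not (0.0 < nf <= 1.0):
        raise ValueError(f"nf must lie in (0, 1], got {nf}")
    keys = np.asarray(keys, dtype=np.uint64)
    salt = np.uint64(_splitmix64_int(seed & _MASK64))
    h = _splitmix64_array(keys ^ salt)
    if nf == 1.0:
        return np.ones(keys.shape, dtype=bool)
    return h < np.uint64(int(nf * 2.0**64))


def retained_count(n_reads: int, nf: float, seed: int,
                   chunk: int = 4_000_000) -> int:
    """Number of reads retained when downsampling ``n_reads`` anonymous reads.

    Runs the same seeded Bernoulli retention the SAM path applies, over read
    keys 0..n-1, in chunks to bound memory. The result is one realized
    Binomial(n_reads, nf) draw, reproducible for a given seed.
    """
    total = 0
    for start in range(0, n_reads, chunk):
        stop = min(start + chunk, n_reads)
        keys = np.arange(start, stop, dtype=np.uint64)
        total += int(retention_mask(keys, nf, seed).sum())
    return total


def _is_primary(read: pysam.AlignedSegment) -> bool:
    return not (read.is_secondary or read.is_supplementary)


def _classify_contig(contig: str, spike_prefix: str) -> str:
    return "spikein" if contig.startswith(spike_prefix) else "sample"


def classify_and_count(
    sample_path: str | Path,
    spike_path: str | Path | None = None,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
    known_contigs: Mapping[str, str] | None = None,
) -> ReadCounts:
    """Count total / mapped / unique-sample / unique-spike-in reads.

    With ``spike_path`` given, the two files are the per-genome alignments of
    one sample. Otherwise ``sample_path`` is a composite-genome alignment and
    contigs are assigned by ``spike_prefix`` (or an explicit
    ``known_contigs`` map contig -> {"sample", "spikein"}).

    Counts are deterministic and independent of record order. Reads lacking
    duplicate flags are treated as non-duplicate (a note is logged once).
    """
    total = mapped = uniq_sample = uniq_spike = 0
    any_dup_flag = False

    def consume(path: str | Path, forced_origin: str | None) -> None:
        nonlocal total, mapped, uniq_sample, uniq_spike, any_dup_flag
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for read in fh:
                if not _is_primary(read):
                    continue
                total += 1
                if read.is_unmapped:
                    continue
                mapped += 1
                if read.is_duplicate:
                    any_dup_flag = True
                    continue
                contig = read.reference_name
                if forced_origin is not None:
                    origin = forced_origin
                elif known_contigs is not None:
                    try:
                        origin = known_contigs[contig]
                    except KeyError:
                        raise ValueError(
                            f"contig {contig!r} in {path} is not assignable "
                            "to the sample or spike-in namespace"
                        ) from None
                else:
                    origin = _classify_contig(contig, spike_prefix)
                if origin == "spikein":
                    uniq_spike += 1
                else:
                    uniq_sample += 1

    if spike_path is not None:
        consume(sample_path, "sample")
        consume(spike_path, "spikein")
    else:
        consume(sample_path, None)

    if mapped and not any_dup_flag:
        logger.info(
            "no duplicate flags seen in %s; counting all mapped reads as unique",
            sample_path,
        )
    return ReadCounts(
        total=total, mapped=mapped,
        unique_sample=uniq_sample, unique_spikein=uniq_spike,
    )


def downsample(
    in_path: str | Path,
    out_path: str | Path,
    nf: float,
    seed: int,
    pair_consistent: bool = True,
    keep_contig_prefix: str | None = None,
) -> int:
    """Write a seeded Bernoulli(nf) subsample of ``in_path`` to ``out_path``.

    Record order is preserved. When ``pair_consistent`` (default) the decision
    is a function of the read name only, so both mates of a pair share one
    retention decision and no orphaned mates are created; otherwise each mate
    decides independently (mate flags enter the hash). Reads mapped to
    contigs starting with ``keep_contig_prefix`` are always retained — the
    normalization workflow downsamples experimental-genome reads only and
    leaves spike-in reads untouched. ``nf = 1`` copies every read. Returns
    the number of retained reads (primary records).
    """
    if not (0.0 < nf <= 1.0):
        raise ValueError(f"nf must lie in (0, 1], got {nf}")
    in_path, out_path = str(in_path), str(out_path)
    mode = "wb" if out_path.endswith(".bam") else "w"
    retained = 0
    salt = _splitmix64_int(seed & _MASK64)
    threshold = nf * 2.0**64
    with pysam.AlignmentFile(in_path, check_sq=False) as src:
        with pysam.AlignmentFile(out_path, mode, template=src) as dst:
            for read in src:
                exempt = (
                    keep_contig_prefix is not None
                    and not read.is_unmapped
                    and read.reference_name.startswith(keep_contig_prefix)
                )
                if nf < 1.0 and not exempt:
                    name = read.query_name
                    if not pair_consistent and read.is_paired:
                        name = f"{name}/{2 if read.is_read2 else 1}"
                    h = _splitmix64_int(fnv1a64(name.encode()) ^ salt)
                    if h >= threshold:
                        continue
                dst.write(read)
                if _is_primary(read):
                    retained += 1
    return retained


def count_group(
    sample_paths: Iterable[str | Path],
    spike_paths: Iterable[str | Path] | None = None,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
) -> list[ReadCounts]:
    """Classify-and-count a group of samples (convenience for the pipeline)."""
    sample_paths = list(sample_paths)
    if spike_paths is None:
        return [classify_and_count(p, spike_prefix=spike_prefix) for p in sample_paths]
    spike_paths = list(spike_paths)
    if len(spike_paths) != len(sample_paths):
        raise ValueError("sample_paths and spike_paths must align one-to-one")
    return [
        classify_and_count(p, q, spike_prefix=spike_prefix)
        for p, q in zip(sample_paths, spike_paths)
    ]
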