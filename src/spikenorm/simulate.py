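"""Synthetic dual-genome ChIP-seq experiments with ground truth.

The generator emulates the read-level structure of a spike-in ChIP-seq
experiment without any sequence-level realism: reads are emitted as
already-aligned records on toy genomes (contigs ``chr1``/``chr2`` for the
experimental genome, ``spikein_2L`` for the spike-in genome), so alignment is
bypassed entirely.

Generative model (per sample ``i``)
-----------------------------------
The immunoprecipitation recovers three pools of chromatin, in arbitrary
units proportional to:

* sample signal:      ``e_i * (1 - b) * C_i``
* sample background:  ``e_i * b * C_i``
* spike-in:           ``e_i * rho * r_i * M_i``

where ``C_i`` is the input DNA mass (ng), ``M_i`` the spike-in chromatin
mass (ng), ``b`` the background fraction, ``rho`` the spike-in recovery per
ng relative to sample chromatin, ``e_i`` the per-sample ChIP efficiency and
``r_i`` an optional per-sample spike-in recovery distortion. Sequencing
draws ``depth_i`` mapped reads multinomially from the pools; each read is
independently flagged duplicate with probability ``duplicate_rate_i``.

The efficiency ``e_i`` scales all three pools equally — the core assumption
of spike-in normalization — so it cancels from read composition and is
observable only through library complexity (duplicate load / unique depth).
Input mass ``C_i`` enters the sample-side pools only, which is exactly the
asymmetry that makes input adjustment necessary: the expected spike-in read
share is ``rho*r_i*M_i / (C_i + rho*r_i*M_i)``, hence
``S_i/X_i ∝ (M_i/C_i) * r_i``. With ``r_i = 1`` the sample-to-spike read
ratio tracks the mass ratio and input-adjusted factors are flat; a Table-like
``r_i`` pattern reproduces the technical recovery distortions that
input-adjusted normalization is designed to remove.

Signal reads are distributed over planted binding sites proportionally to
site intensity (log-normal across shared sites, plus optional weak
sample-specific sites modelling biological variance); background and
spike-in reads are uniform over their genomes. Everything is seeded and
reproducible: identical config + seed gives identical output, including the
SAM files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .reads import retention_mask
from .samples import SampleStats, write_metadata
from .tracks import SignalTrack, coverage_from_intervals

DEFAULT_SAMPLE_GENOME = {"chr1": 10_000_000, "chr2": 10_000_000}
DEFAULT_SPIKE_GENOME = {"spikein_2L": 200_000}


@dataclass(frozen=True)
class SampleConfig:
    """Wet-lab parameters of one simulated sample."""

    sample_id: str
    input_dna_mass: float          # ng (concentration x volume)
    spikein_mass: float = 62.5     # ng
    chip_efficiency: float = 1.0   # scales all recovered pools equally
    depth: int = 100_000           # emitted mapped reads
    duplicate_rate: float = 0.0
    spikein_recovery_distortion: float = 1.0  # r_i, technical S/X distortion

    def __post_init__(self) -> None:
        if self.input_dna_mass <= 0 or self.spikein_mass <= 0:
            raise ValueError(f"sample {self.sample_id!r}: masses must be positive")
        if not (0.0 < self.chip_efficiency <= 1.0):
            raise ValueError(f"sample {self.sample_id!r}: efficiency must be in (0, 1]")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ValueError(f"sample {self.sample_id!r}: duplicate_rate must be in [0, 1)")
        if self.depth <= 0 or self.spikein_recovery_distortion <= 0:
            raise ValueError(f"sample {self.sample_id!r}: depth and distortion must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    samples: tuple[SampleConfig, ...]
    sample_genome: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLE_GENOME))
    spikein_genome: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPIKE_GENOME))
    n_sites: int = 100
    site_intensity_sigma: float = 0.4   # log-normal sigma of shared-site weights
    noise_sites_per_sample: int = 0     # weak sample-specific sites
    noise_site_intensity: float = 0.03  # relative to the mean shared-site weight
    background_fraction: float = 0.3
    spikein_recovery: float = 0.2       # rho: spike-in pool per ng vs sample per ng
    read_length: int = 50
    site_halfwidth: int = 100           # signal read centres fall within +/- this
    min_gap: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ValueError("need at least one sample")
        if not (0.0 < self.background_fraction < 1.0):
            raise ValueError("background_fraction must be in (0, 1)")
        if self.n_sites < 1 or self.spikein_recovery <= 0:
            raise ValueError("n_sites and spikein_recovery must be positive")
        for s in self.samples:
            if s.depth < self.n_sites:
                raise ValueError(
                    f"infeasible config: sample {s.sample_id!r} depth {s.depth} "
                    f"< n_sites {self.n_sites}"
                )

    def expected_spike_share(self, sample: SampleConfig) -> float:
        """Expected fraction of mapped reads on the spike-in genome."""
        w_spike = self.spikein_recovery * sample.spikein_recovery_distortion * sample.spikein_mass
        return w_spike / (sample.input_dna_mass + w_spike)


@dataclass(frozen=True)
class Site:
    contig: str
    center: int
    intensity: float  # relative read weight (mean shared-site weight = 1)


@dataclass
class SimulatedSample:
    """In-memory read set of one sample: unique/duplicate reads per contig."""

    sample_id: str
    config: SampleConfig
    # per contig: (starts, ends, is_duplicate, keys) aligned arrays
    reads: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    spike_contigs: frozenset[str]
    unique_sample_reads: int
    unique_spikein_reads: int

    def stats(self) -> SampleStats:
        return SampleStats(
            sample_id=self.sample_id,
            unique_sample_reads=self.unique_sample_reads,
            unique_spikein_reads=self.unique_spikein_reads,
            input_dna_mass=self.config.input_dna_mass,
            spikein_mass=self.config.spikein_mass,
        )

    def unique_intervals(
        self, nf: float = 1.0, seed: int = 0, spikein: bool = False
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Unique-read intervals, optionally Bernoulli(nf)-downsampled.

        Downsampling uses the same seeded hash retention as the SAM path,
        applied to the experimental-genome reads only (spike-in reads are
        never downsampled).
        """
        out = {}
        for contig, (starts, ends, dup, keys) in self.reads.items():
            if (contig in self.spike_contigs) != spikein:
                continue
            keep = ~dup
            if nf < 1.0 and not spikein:
                keep = keep & retention_mask(keys, nf, seed)
            out[contig] = (starts[keep], ends[keep])
        return out


@dataclass
class SimulationTruth:
    """Ground truth sufficient to predict expected normalized signal."""

    sites: list[Site]
    noise_sites: dict[str, list[Site]]
    expected_spike_share: dict[str, float]
    background_fraction: float
    realized: dict[str, dict[str, int]]  # sample_id -> {"X":..., "S":...}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sites": [asdict(s) for s in self.sites],
            "noise_sites": {
                k: [asdict(s) for s in v] for k, v in self.noise_sites.items()
            },
            "expected_spike_share": self.expected_spike_share,
            "background_fraction": self.background_fraction,
            "realized": self.realized,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class SimulationResult:
    config: SimulationConfig
    samples: list[SimulatedSample]
    truth: SimulationTruth

    def stats(self) -> list[SampleStats]:
        return [s.stats() for s in self.samples]


def _place_sites(config: SimulationConfig, rng: np.random.Generator) -> tuple[
        list[Site], dict[str, list[Site]]]:
    """Place shared and sample-specific sites on a non-overlapping grid.

    Sites occupy distinct cells of a grid whose pitch guarantees at least
    ``min_gap`` between site footprints, so peak-calling truth is
    unambiguous.
    """
    footprint = 2 * config.site_halfwidth + config.read_length
    pitch = config.min_gap + footprint
    cells: list[tuple[str, int]] = []
    for contig, length in config.sample_genome.items():
        n_cells = (length - footprint) // pitch
        for j in range(n_cells):
            cells.append((contig, j * pitch + footprint // 2 + config.min_gap // 2))
    n_noise = config.noise_sites_per_sample * len(config.samples)
    n_total = config.n_sites + n_noise
    if n_total > len(cells):
        raise ValueError(
            f"genome too small for {n_total} sites at min_gap {config.min_gap}"
        )
    chosen = rng.choice(len(cells), size=n_total, replace=False)
    weights = rng.lognormal(mean=0.0, sigma=config.site_intensity_sigma,
                            size=config.n_sites)
    weights /= weights.mean()  # mean shared-site weight = 1
    shared = [
        Site(cells[c][0], cells[c][1], float(w))
        for c, w in zip(chosen[:config.n_sites], weights)
    ]
    noise: dict[str, list[Site]] = {}
    k = config.n_sites
    for s in config.samples:
        own = []
        for c in chosen[k:k + config.noise_sites_per_sample]:
            own.append(Site(cells[c][0], cells[c][1],
                            float(config.noise_site_intensity)))
        noise[s.sample_id] = own
        k += config.noise_sites_per_sample
    return shared, noise


def _uniform_reads(rng: np.random.Generator, n: int,
                   genome: Mapping[str, int], read_length: int
                   ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    contigs = list(genome)
    lengths = np.array([genome[c] for c in contigs], dtype=float)
    if n == 0:
        return {c: (np.empty(0, np.int64), np.empty(0, np.int64)) for c in contigs}
    which = rng.choice(len(contigs), size=n, p=lengths / lengths.sum())
    out = {}
    for i, contig in enumerate(contigs):
        m = int((which == i).sum())
        starts = rng.integers(0, max(genome[contig] - read_length, 1), size=m)
        out[contig] = (starts.astype(np.int64),
                       (starts + read_length).astype(np.int64))
    return out


def simulate_experiment(config: SimulationConfig,
                        seed: int | None = None) -> SimulationResult:
    """Draw one experiment: per-sample read sets plus ground truth.

    Fully deterministic for a given (config, seed); ``seed`` defaults to
    ``config.seed``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    shared, noise = _place_sites(config, rng)

    samples: list[SimulatedSample] = []
    realized: dict[str, dict[str, int]] = {}
    spike_contigs = frozenset(config.spikein_genome)
    for idx, sc in enumerate(config.samples):
        share = config.expected_spike_share(sc)
        n_spike = int(rng.binomial(sc.depth, share))
        n_sample = sc.depth - n_spike
        n_bg = int(rng.binomial(n_sample, config.background_fraction))
        n_sig = n_sample - n_bg

        own_sites = shared + noise.get(sc.sample_id, [])
        w = np.array([s.intensity for s in own_sites], dtype=float)
        site_reads = rng.multinomial(n_sig, w / w.sum())

        per_contig: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
            c: [] for c in list(config.sample_genome) + list(config.spikein_genome)
        }
        for site, m in zip(own_sites, site_reads):
            if m == 0:
                continue
            centers = rng.integers(site.center - config.site_halfwidth,
                                   site.center + config.site_halfwidth + 1,
                                   size=int(m))
            starts = np.clip(centers - config.read_length // 2, 0,
                             config.sample_genome[site.contig] - config.read_length)
            per_contig[site.contig].append(
                (starts.astype(np.int64),
                 (starts + config.read_length).astype(np.int64)))
        for contig, (s, e) in _uniform_reads(
                rng, n_bg, config.sample_genome, config.read_length).items():
            per_contig[contig].append((s, e))
        for contig, (s, e) in _uniform_reads(
                rng, n_spike, config.spikein_genome, config.read_length).items():
            per_contig[contig].append((s, e))

        reads: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        key_base = np.uint64(idx) << np.uint64(32)
        offset = 0
        uniq_sample = uniq_spike = 0
        for contig in per_contig:
            if per_contig[contig]:
                starts = np.concatenate([p[0] for p in per_contig[contig]])
                ends = np.concatenate([p[1] for p in per_contig[contig]])
            else:
                starts = np.empty(0, np.int64)
                ends = np.empty(0, np.int64)
            dup = rng.random(len(starts)) < sc.duplicate_rate
            keys = key_base + np.arange(offset, offset + len(starts), dtype=np.uint64)
            offset += len(starts)
            reads[contig] = (starts, ends, dup, keys)
            n_uniq = int((~dup).sum())
            if contig in spike_contigs:
                uniq_spike += n_uniq
            else:
                uniq_sample += n_uniq

        samples.append(SimulatedSample(
            sample_id=sc.sample_id, config=sc, reads=reads,
            spike_contigs=spike_contigs,
            unique_sample_reads=uniq_sample,
            unique_spikein_reads=uniq_spike,
        ))
        realized[sc.sample_id] = {"X": uniq_sample, "S": uniq_spike}

    truth = SimulationTruth(
        sites=shared,
        noise_sites=noise,
        expected_spike_share={
            sc.sample_id: config.expected_spike_share(sc) for sc in config.samples
        },
        background_fraction=config.background_fraction,
        realized=realized,
    )
    return SimulationResult(config=config, samples=samples, truth=truth)


def expected_site_signal(
    result: SimulationResult,
    method: str,
    factors: Mapping[str, float],
) -> dict[str, float]:
    """Closed-form expected mean per-site signal reads after normalization.

    For a downsampling method with retention fractions ``factors``, the
    expected number of signal reads at an average shared site in sample i is
    ``f_i * X_i * (1 - b) * 1/(n_sites + noise weight)``; for CPM the
    "factor" is the display scaling ``1e6 / X_i``. Ratios of these values
    across samples predict the systematic bias each normalization leaves.
    """
    config = result.config
    out = {}
    for s in result.samples:
        total_weight = config.n_sites + (
            config.noise_sites_per_sample * config.noise_site_intensity)
        per_site = (1.0 - config.background_fraction) / total_weight
        x = s.unique_sample_reads
        f = 1e6 / x if method == "cpm" else factors[s.sample_id]
        out[s.sample_id] = f * x * per_site
    return out


def sample_coverage(sample: SimulatedSample, config: SimulationConfig,
                    nf: float = 1.0, seed: int = 0,
                    window_width: int = 20,
                    counting: str = "overlap") -> SignalTrack:
    """Raw windowed coverage of a sample's (optionally downsampled) unique reads."""
    return coverage_from_intervals(
        sample.unique_intervals(nf=nf, seed=seed),
        config.sample_genome, window_width=window_width, counting=counting,
    )


def write_sam(sample: SimulatedSample, config: SimulationConfig,
              path: str | Path) -> None:
    """Write one sample's reads (duplicates flagged) as coordinate-sorted SAM."""
    contigs = list(config.sample_genome) + list(config.spikein_genome)
    lengths = {**config.sample_genome, **config.spikein_genome}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(lengths[c])} for c in contigs],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for tid, contig in enumerate(contigs):
            if contig not in sample.reads:
                continue
            starts, ends, dup, keys = sample.reads[contig]
            order = np.argsort(starts, kind="stable")
            for i in order:
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"{sample.sample_id}:{int(keys[i])}"
                a.reference_id = tid
                a.reference_start = int(starts[i])
                a.mapping_quality = 60
                length = int(ends[i] - starts[i])
                a.cigarstring = f"{length}M"
                a.query_sequence = "N" * length
                a.flag = (16 if int(keys[i]) & 1 else 0) | (1024 if dup[i] else 0)
                out.write(a)


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-sample SAM files, metadata TSV and truth JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in result.samples:
        p = outdir / f"{sample.sample_id}.sam"
        write_sam(sample, result.config, p)
        paths[sample.sample_id] = p
    write_metadata(result.stats(), outdir / "metadata.tsv")
    result.truth.to_json(outdir / "truth.json")
    paths["metadata"] = outdir / "metadata.tsv"
    paths["truth"] = outdir / "truth.json"
    return paths
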