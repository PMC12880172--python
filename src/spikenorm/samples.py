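"""Per-sample metadata and read-count containers.

The quantities here mirror the bench-side bookkeeping of a spike-in ChIP-seq
experiment: for each sample we track the deduplicated read counts on the
experimental genome (``X_i``) and on the exogenous spike-in genome (``S_i``),
together with the wet-lab masses that enter input-adjusted normalization —
the input DNA mass (concentration x volume, ng) and the spike-in chromatin
mass (ng).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

METADATA_COLUMNS = [
    "sample_id",
    "unique_sample_reads",
    "unique_spikein_reads",
    "input_conc_ng_per_ul",
    "input_volume_ul",
    "spikein_mass_ng",
]


@dataclass(frozen=True)
class SampleStats:
    """Read counts and chromatin masses for one ChIP-seq sample.

    Parameters
    ----------
    sample_id:
        Label of the sample (e.g. a replicate name).
    unique_sample_reads:
        Deduplicated, primary, mapped reads on the experimental genome (X_i).
    unique_spikein_reads:
        Same on the spike-in genome (S_i).
    input_dna_mass:
        Input DNA mass in ng (concentration ng/uL x volume uL).
    spikein_mass:
        Spike-in chromatin mass in ng added to the sample before IP.
    """

    sample_id: str
    unique_sample_reads: int
    unique_spikein_reads: int = 0
    input_dna_mass: float = 0.0
    spikein_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.unique_sample_reads < 0 or self.unique_spikein_reads < 0:
            raise ValueError(
                f"negative read count for sample {self.sample_id!r}"
            )

    @classmethod
    def from_concentration(
        cls,
        sample_id: str,
        unique_sample_reads: int,
        unique_spikein_reads: int,
        input_conc_ng_per_ul: float,
        input_volume_ul: float,
        spikein_mass_ng: float,
    ) -> "SampleStats":
        """Build stats from a concentration + volume pair (mass = conc x vol)."""
        return cls(
            sample_id=sample_id,
            unique_sample_reads=int(unique_sample_reads),
            unique_spikein_reads=int(unique_spikein_reads),
            input_dna_mass=float(input_conc_ng_per_ul) * float(input_volume_ul),
            spikein_mass=float(spikein_mass_ng),
        )


@dataclass(frozen=True)
class NormFactorSet:
    """Per-sample retention fractions for one normalization method.

    ``factors`` maps sample id to the fraction of experimental-genome reads
    randomly retained during downsampling; exactly one sample (the
    ``reference_sample``) has factor 1 and is passed through unchanged. CPM
    is a display-time scaling rather than a downsampling, so its factor set
    is empty.
    """

    method: str
    factors: Mapping[str, float] = field(default_factory=dict)
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        for sid, f in self.factors.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(
                    f"factor for sample {sid!r} is {f}; must lie in (0, 1]"
                )

    def expected_retained(self, stats: Iterable[SampleStats]) -> dict[str, float]:
        """Expected retained read count X_i x factor_i per sample."""
        return {
            s.sample_id: s.unique_sample_reads * self.factors[s.sample_id]
            for s in stats
            if s.sample_id in self.factors
        }

    def to_report(self, stats: Iterable[SampleStats] | None = None) -> dict:
        report: dict = {
            "method": self.method,
            "factors": dict(self.factors),
            "reference_sample": self.reference_sample,
        }
        if stats is not None:
            report["expected_retained_reads"] = self.expected_retained(stats)
        return report


@dataclass(frozen=True)
class ReadCounts:
    """Table-style count hierarchy: total >= mapped >= unique sample + spike-in."""

    total: int
    mapped: int
    unique_sample: int
    unique_spikein: int

    def __post_init__(self) -> None:
        if not (self.total >= self.mapped >= self.unique_sample + self.unique_spikein):
            raise ValueError(
                "inconsistent counts: require total >= mapped >= "
                "unique_sample + unique_spikein, got "
                f"{self.total} / {self.mapped} / {self.unique_sample} / {self.unique_spikein}"
            )


def read_metadata(path: str | Path) -> list[SampleStats]:
    """Read per-sample metadata from TSV (or JSON) into SampleStats.

    The TSV mirrors the layout of a per-sample bench table with columns
    ``sample_id, unique_sample_reads, unique_spikein_reads,
    input_conc_ng_per_ul, input_volume_ul, spikein_mass_ng``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata file {path} is missing columns: {missing}")
        records = df.to_dict(orient="records")
    return [
        SampleStats.from_concentration(
            sample_id=str(r["sample_id"]),
            unique_sample_reads=int(r["unique_sample_reads"]),
            unique_spikein_reads=int(r["unique_spikein_reads"]),
            input_conc_ng_per_ul=float(r["input_conc_ng_per_ul"]),
            input_volume_ul=float(r["input_volume_ul"]),
            spikein_mass_ng=float(r["spikein_mass_ng"]),
        )
        for r in records
    ]


def write_metadata(stats: Iterable[SampleStats], path: str | Path,
                   input_volume_ul: float = 20.0) -> None:
    """Write SampleStats to the TSV layout read back by :func:`read_metadata`.

    Masses are stored as concentration x the given volume, so a round trip
    preserves ``input_dna_mass`` exactly.
    """
    rows = []
    for s in stats:
        rows.append(
            {
                "sample_id": s.sample_id,
                "unique_sample_reads": s.unique_sample_reads,
                "unique_spikein_reads": s.unique_spikein_reads,
                "input_conc_ng_per_ul": s.input_dna_mass / input_volume_ul,
                "input_volume_ul": input_volume_ul,
                "spikein_mass_ng": s.spikein_mass,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)
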