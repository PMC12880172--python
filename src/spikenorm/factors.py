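"""Normalization factors for multi-sample ChIP-seq comparison.

Four strategies are provided:

* **CPM** — counts-per-million display scaling of signal tracks,
  ``1e6 / total_reads``. It never triggers downsampling; peak calling on a
  CPM-scaled sample is identical to calling on the raw sample.
* **equal-read** — downsample every sample to the lowest unique read count in
  the group: ``NF_i = min(X) / X_i``.
* **spike-in** — downsample so the recovered exogenous (spike-in) reads are
  equalized: ``NF_i = min(S) / S_i``. Because the same mass of spike-in
  chromatin goes through IP, library prep and sequencing alongside each
  sample, equalizing S corrects per-sample technical efficiency.
* **input-adjusted spike-in** — additionally corrects for unequal input
  chromatin amounts: the raw factor ``(C_sample,i / C_spike,i) / (X_i / S_i)``
  rescales each sample so its sample-to-spike read ratio matches its
  sample-to-spike mass ratio. Raw factors are divided by the group maximum so
  the reference sample retains all of its reads and no sample would need
  upsampling.

All downsampling factors lie in (0, 1]; the sample attaining factor 1 is the
``reference_sample`` of the returned :class:`~spikenorm.samples.NormFactorSet`.
Reference selection is done on exact rational arithmetic (argmin/argmax of
integer counts and exact mass ratios) before any floating division.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

from .samples import NormFactorSet, SampleStats

__all__ = [
    "cpm_scale_factor",
    "equal_read_factors",
    "spikein_factors",
    "input_adjusted_factors",
    "compute_factors",
]


def _require_group(stats: Sequence[SampleStats]) -> None:
    if len(stats) < 2:
        raise ValueError(
            f"normalization needs at least 2 samples, got {len(stats)}"
        )
    ids = [s.sample_id for s in stats]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in group: {ids}")


def cpm_scale_factor(total_reads: int) -> float:
    """Counts-per-million multiplier, ``1e6 / total_reads``.

    Applied to raw window values at display time; it is not a downsampling.
    """
    if total_reads <= 0:
        raise ValueError(f"total_reads must be positive, got {total_reads}")
    return 1e6 / total_reads


def equal_read_factors(stats: Sequence[SampleStats]) -> NormFactorSet:
    """``NF_i = min(X) / X_i`` — downsample all samples to the lowest depth."""
    _require_group(stats)
    for s in stats:
        if s.unique_sample_reads == 0:
            raise ValueError(
                f"sample {s.sample_id!r} has zero unique sample reads; "
                "equal-read normalization is undefined"
            )
    lowest = min(stats, key=lambda s: (s.unique_sample_reads, s.sample_id))
    m = lowest.unique_sample_reads
    factors = {
        s.sample_id: float(Fraction(m, s.unique_sample_reads)) for s in stats
    }
    return NormFactorSet(
        method="equal_read", factors=factors, reference_sample=lowest.sample_id
    )


def spikein_factors(stats: Sequence[SampleStats]) -> NormFactorSet:
    """``NF_i = min(S) / S_i`` — equalize spike-in read recovery."""
    _require_group(stats)
    for s in stats:
        if s.unique_spikein_reads == 0:
            raise ValueError(
                f"sample {s.sample_id!r} has zero unique spike-in reads; "
                "spike-in normalization is undefined"
            )
    lowest = min(stats, key=lambda s: (s.unique_spikein_reads, s.sample_id))
    m = lowest.unique_spikein_reads
    factors = {
        s.sample_id: float(Fraction(m, s.unique_spikein_reads)) for s in stats
    }
    return NormFactorSet(
        method="spikein", factors=factors, reference_sample=lowest.sample_id
    )


def _input_adjusted_raw(s: SampleStats) -> Fraction:
    # (C_sample / C_spike) / (X / S), exact rational
    if s.unique_sample_reads <= 0 or s.unique_spikein_reads <= 0:
        raise ValueError(
            f"sample {s.sample_id!r} needs positive sample and spike-in read "
            "counts for input-adjusted normalization"
        )
    if s.input_dna_mass <= 0 or s.spikein_mass <= 0:
        raise ValueError(
            f"sample {s.sample_id!r} needs positive input DNA and spike-in "
            "masses for input-adjusted normalization"
        )
    mass_ratio = Fraction(s.input_dna_mass) / Fraction(s.spikein_mass)
    read_ratio = Fraction(s.unique_sample_reads, s.unique_spikein_reads)
    return mass_ratio / read_ratio


def input_adjusted_factors(stats: Sequence[SampleStats]) -> NormFactorSet:
    """Input-adjusted spike-in factors, rescaled by the group maximum.

    Raw factor ``(C_sample,i / C_spike,i) / (X_i / S_i)`` makes the retained
    sample-to-spike read ratio proportional to the sample-to-spike mass
    ratio. Dividing by the largest raw factor keeps every factor in (0, 1]
    and lets the reference sample retain all of its reads.
    """
    _require_group(stats)
    raw = {s.sample_id: _input_adjusted_raw(s) for s in stats}
    ref_id = max(stats, key=lambda s: (raw[s.sample_id], s.sample_id)).sample_id
    top = raw[ref_id]
    factors = {sid: float(r / top) for sid, r in raw.items()}
    return NormFactorSet(
        method="input_adjusted_spikein", factors=factors, reference_sample=ref_id
    )


_METHODS = {
    "equal_read": equal_read_factors,
    "spikein": spikein_factors,
    "input_adjusted_spikein": input_adjusted_factors,
}


def compute_factors(method: str, stats: Sequence[SampleStats]) -> NormFactorSet:
    """Dispatch on method name; ``cpm`` yields an empty (no-downsampling) set."""
    if method == "cpm":
        return NormFactorSet(method="cpm", factors={}, reference_sample=None)
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown normalization method {method!r}; expected one of "
            f"cpm, {', '.join(_METHODS)}"
        ) from None
    return fn(stats)
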