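"""Bundled example metadata: a triplicate tissue ChIP-seq bench table.

Foxa1 ChIP-seq performed in prostate tumor tissue from three mice, each
spiked with 62.5 ng of Drosophila chromatin before immunoprecipitation. The
three replicates differ in input chromatin amount (tumor size), ChIP
enrichment and sequencing yield, which is what makes them a useful worked
example for comparing normalization strategies.
"""

from __future__ import annotations

from .samples import SampleStats

INPUT_VOLUME_UL = 20.0

#: (sample_id, unique sample reads X, unique spike-in reads S,
#:  input DNA concentration ng/uL, spike-in chromatin ng)
_ROWS = [
    ("Rep1", 4_190_041, 142_086, 29.6, 62.5),
    ("Rep2", 23_728_210, 268_064, 17.3, 62.5),
    ("Rep3", 22_990_981, 319_773, 35.6, 62.5),
]


def foxa1_triplicate() -> list[SampleStats]:
    """Per-sample stats of the triplicate Foxa1 tissue ChIP-seq experiment."""
    return [
        SampleStats.from_concentration(
            sample_id=sid,
            unique_sample_reads=x,
            unique_spikein_reads=s,
            input_conc_ng_per_ul=conc,
            input_volume_ul=INPUT_VOLUME_UL,
            spikein_mass_ng=spike,
        )
        for sid, x, s, conc, spike in _ROWS
    ]
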