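"""Windowed signal tracks, CPM scaling, and peak-centered matrices.

Builds a 20 bp coverage track from a simulated sample, scales it to counts
per million, and quantifies signal around called peak centers.
"""

import numpy as np

from spikenorm import SampleConfig, SimulationConfig, apply_cpm, call_peaks, peak_signal_matrix, simulate_experiment
from spikenorm.simulate import sample_coverage

config = SimulationConfig(
    samples=(SampleConfig("Rep1", input_dna_mass=500.0, depth=30_000),),
    sample_genome={"chr1": 2_000_000},
    spikein_genome={"spikein_2L": 200_000},
    n_sites=40,
)
result = simulate_experiment(config, seed=5)
sample = result.samples[0]

track = sample_coverage(sample, config, window_width=20)
print(f"track: {sum(len(v) for v in track.values.values()):,} windows of 20 bp, "
      f"total coverage {track.total():,.0f}")

cpm = apply_cpm(track, sample.unique_sample_reads)
w = result.truth.sites[0].center // 20
print(f"window at first planted site: raw={track.values['chr1'][w]:.0f}, "
      f"cpm={cpm.values['chr1'][w]:.2f}")

peaks = call_peaks(sample_coverage(sample, config, counting="start"))
m = peak_signal_matrix(track, peaks, flank=1000, step=20)
print(f"called {len(peaks)} peaks; signal matrix shape {m.values.shape} "
      f"(peaks x positions, +/-1 kb at 20 bp)")
profile = m.values.mean(axis=0)
center = len(profile) // 2
print(f"mean profile: center={profile[center]:.1f}, edge={profile[0]:.2f} "
      "(signal peaks at the site center and decays to background)")
assert np.argmax(profile) in range(center - 3, center + 4)
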