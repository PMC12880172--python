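# Methods

## The normalization problem

ChIP-seq signal is only comparable across samples after correcting for
technical differences in sequencing depth, ChIP enrichment and — for tissue
experiments especially — the amount of input chromatin each sample started
from. `spikenorm` implements four strategies on the per-sample quantities

* `X_i` — unique (mapped, primary, non-duplicate) reads on the experimental
  genome,
* `S_i` — unique reads on the exogenous spike-in genome,
* `C_i` — input DNA mass in ng (concentration × volume),
* `M_i` — spike-in chromatin mass in ng,

as retention fractions `NF_i ∈ (0, 1]` used to randomly downsample each
sample's experimental-genome reads:

| method | factor | corrects |
|---|---|---|
| CPM | display scaling `1e6 / X_i` (no downsampling) | depth, at visualization time |
| equal-read | `min(X) / X_i` | depth |
| spike-in | `min(S) / S_i` | depth + per-sample technical efficiency |
| input-adjusted spike-in | `(C_i/M_i) / (X_i/S_i)`, rescaled by the group maximum | additionally, unequal input chromatin |

The input-adjusted factor makes the retained sample-to-spike read ratio
`X'_i/S_i` proportional to the mass ratio `C_i/M_i` across samples — the
identity `(X_i·NF_i)·S_j·C_j·M_i = (X_j·NF_j)·S_i·C_i·M_j` holds for every
pair. The raw factors are divided by the group maximum so that exactly one
sample (the reference) keeps all of its reads and nobody would need
upsampling; this retains the most data compatible with the ratio contract.
Masses are used rather than concentrations (`C = concentration × volume`),
so unequal volumes are handled; the spike-in "concentration" is represented
by its mass, since only ratios enter the formula. Reference-sample selection
(argmin/argmax) happens on exact rational arithmetic before any floating
division; CPM never triggers downsampling because it cannot change which
peaks are called within a sample.

Spike-in reads are never downsampled — only experimental-genome reads are,
matching the "sample reads after normalization" semantics of a bench table.

## Downsampling

Retention replicates the samtools `-s` contract without promising its exact
hash: a read (or read pair — mates share a name, hence a decision) is kept
iff `splitmix64(fnv1a64(name) XOR splitmix64(seed)) < nf·2^64`. Decisions
are deterministic, order-independent and byte-reproducible for a given
(input, nf, seed); retained counts are one realized Binomial(N, nf) draw.
The same rule is exposed vectorized over integer read keys
(`retention_mask`, `retained_count`) for in-memory read sets.

## Signal tracks

Signal is the read count per fixed-width window (default 20 bp), 0-based
half-open everywhere. Two counting rules are available: `overlap` (a read
increments every window it touches — the per-bin coverage semantics of
standard track tools; the default for quantification) and `start` (one count
per read, in the window of its leftmost position). The `start` rule keeps
window counts independent, which is what a Poisson background model assumes;
peak calling in the simulation study therefore runs on `start`-counted
tracks. Reads are not fragment-extended by default (fragment length is
experiment-specific); `extend_to` enables 3′ extension. CPM scaling is exact
and invertible. Tracks round-trip through bedGraph at 6 significant digits;
bigWig output is available when pyBigWig is installed.

Peak-centered quantification samples the track at regular offsets within
±flank of each peak's summit (default ±2 kb at the window width), returning
a peaks × positions matrix whose row sums feed scatterplot-style
comparisons.

## Peak calling

The caller is a minimal, deliberately transparent stand-in for a
full-featured narrow-peak caller (which is upstream tooling, not this
package's contribution): a `peak_width` window (default 200 bp) slides one
track window at a time; a span is a candidate when its summed count reaches
the smaller integer satisfying both fold ≥ `fold_min` (default 4) over the
global background rate λ = total coverage / total windows and Poisson
upper-tail `P(X ≥ c; λ·k) ≤ p_max` (default 1e-4). Overlapping candidates
merge; the summit is the maximal window. Collapsing both cutoffs into one
integer threshold makes the false-positive behaviour exact: on a site-free
track the expected number of spurious calls is (tested windows) ×
`P(Poisson(λk) ≥ c)`, which is what the calibration test checks. There is no
local background, no input-chromatin correction, and no multiple-testing
adjustment — a fixed `p_max` with a predictable genome-wide false count,
as in threshold-style callers. All parameters are exposed.

## Overlap analysis

Peaks from k samples merge transitively on ≥ 1 bp interval overlap
(sorted-sweep union); each merged region carries the bitmask of contributing
samples, and the 2^k − 1 bitmask categories are the Venn cells. Regions with
the full mask are the consensus peaks; single-sample regions ("exclusives")
are the working proxy for irreproducible calls. The same machinery compares
consensus peak sets across normalization methods. Center-distance overlap
rules used by some tools are intentionally not replicated; the ≥ 1 bp
criterion is documented and version-stable.

## The simulator

The generator emulates the read-level structure of a dual-genome spike-in
experiment; reads are emitted as already-aligned records (no sequences, no
error model, no mappability — alignment is out of scope). Per sample, the
IP recovers pools proportional to

```
signal      e_i · (1 − b) · C_i
background  e_i · b · C_i
spike-in    e_i · ρ · r_i · M_i
```

and `depth_i` mapped reads are drawn multinomially from them; duplicates are
flagged per read at `duplicate_rate_i`. Key assumptions:

* **Efficiency `e_i` scales all pools equally** — the core assumption of
  spike-in normalization. It cancels from read composition and is
  observable only as library complexity (duplicate load), which is how
  "poor enrichment, few unique reads" presents in the generator.
* **Input mass `C_i` enters the sample side only**, so the expected
  spike-in read share is `ρ·r_i·M_i / (C_i + ρ·r_i·M_i)` and
  `S_i/X_i ∝ (M_i/C_i)·r_i`. This is the asymmetry that makes input
  adjustment necessary and is the regime in which the input-adjusted factor
  is the correct estimator.
* `ρ` (default 0.2) is the spike-in recovery per ng relative to sample
  chromatin, chosen so simulated `S/X` magnitudes (1–4%) match real
  dual-genome experiments; `r_i` (default 1) is a per-sample technical
  recovery distortion for emulating real tables whose `S/X` ordering does
  not follow the mass ratios.

Signal reads are spread over planted sites (log-normal intensities,
non-overlapping placement with ≥ 2 kb gaps, so calling truth is
unambiguous), background and spike-in reads are uniform. Optional weak
sample-specific sites model biological variance. Everything is seeded;
identical config + seed reproduces byte-identical SAM output.

What the generator does **not** model — structured/accessible-chromatin
background, GC and mappability bias, fragment-length variation,
PCR-family duplicate structure, contaminating genomes — bounds what passing
tests show: they validate the normalization arithmetic and its statistical
consequences under the stated generative model, not performance on any
particular real dataset.

## The reproducibility study

The study (module `spikenorm.study`) uses triplicates with the bench-table
input masses 592 : 346 : 712 ng and 62.5 ng spike-in, 100 000 reads per
sample, 20 replicate simulations, in two arms:

* **Signal-ratio arm** (no recovery distortion, duplicate-free): per-site
  mean signal is measured from each sample's retained reads at the planted
  shared sites. Spike-in-only normalization leaves cross-sample ratios equal
  to the input-mass ratios (1.71, 2.06, 1.20 for the three pairs);
  input-adjusted normalization brings them within a few percent of 1. The
  arm is run at equal unique depth because downsampling factors depend on
  `X/S`, which is depth-free: no downsampling scheme can equalize per-site
  signal across unequal unique depths, and the real bench table's retained
  counts are indeed unequal.
* **Reproducibility arm** (table-fit distortions `r_i` = 1 : 0.195 : 0.493,
  duplicate loads 0.72 / 0.27 / 0.33, plus 60 weak sample-specific sites per
  sample at 3% of the mean shared-site intensity — near the detection limit
  at study depths): peaks are called per sample for each method on
  `start`-counted tracks at `p_max = 1e-5` (with ~10^6 tested windows this
  keeps expected background flukes in the single digits per sample), and
  single-sample exclusive regions are counted. Input-adjusted normalization
  retains full depth where the data are clean while cutting the
  distortion-inflated sample hardest, and ends with the fewest exclusives;
  CPM/no-normalization keeps every weak sample-specific site in the deep
  samples, spike-in-only inherits the recovery distortion, and equal-read
  throws away depth everywhere.

The two arms are separate because the per-site ratio algebra requires
distortion-free composition while the exclusive-peak ranking only manifests
when such distortions exist; both statements are asserted over the same
20-replicate budget.

## Numerical choices and degenerate inputs

* Factors are computed in double precision from exact rationals; ties for
  the reference sample break lexicographically on sample id.
* Zero read counts or non-positive masses raise errors naming the sample;
  groups need ≥ 2 samples.
* Empty tracks yield empty peak lists; a track with no windows is a
  degenerate-background error.
* Reads beyond declared contig bounds are clipped with a logged notice;
  peaks whose flank crosses a contig edge are zero-padded and flagged.
* Counts are in read units (each mate counts once), not fragments.

## Problem sizes

Defaults were chosen so the whole validation suite runs on a laptop: toy
genomes of 20 Mb (+0.2 Mb spike-in), 100 shared sites, 10^5 reads per
sample, 20 replicate simulations per study arm. The bench-table worked
example uses the full printed read counts (2.3–2.4 × 10^7) since factor
arithmetic and vectorized retention are cheap at that scale.

## Known limitations

* The peak caller is a calibrated stand-in, not an emulation of any
  published caller; absolute peak numbers on real data will differ.
* Input-adjusted normalization corrects mass-ratio and recovery distortions
  but, being pure downsampling, cannot equalize per-site signal across
  samples with very different unique depths.
* CRAM input, broad-domain calling, IDR, per-locus regression normalization
  and figure rendering are out of scope.
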