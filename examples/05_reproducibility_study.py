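"""The reproducibility study: what each normalization leaves behind.

Runs scaled-down versions of the two study arms. Arm 1 measures per-site
signal ratios across samples with unequal input masses (592:346:712 ng):
spike-in-only normalization leaves the input-mass bias, input adjustment
removes it. Arm 2 adds bench-table-like technical distortions and counts
single-sample exclusive peaks per method.
"""

from spikenorm.study import run_reproducibility_study, run_signal_ratio_study

arm1 = run_signal_ratio_study(n_replicates=5, base_seed=1)
print("per-site signal ratios (mean over 5 simulated triplicates):")
for method in ("spikein", "input_adjusted_spikein"):
    print(f"  {method}:")
    for (a, b), r in sorted(arm1["ratios"][method].items()):
        if a < b:
            print(f"    {a}/{b}: {r:.3f}   (input-mass ratio "
                  f"{arm1['mass_ratio'][(a, b)]:.3f})")
print("spike-in tracks the mass ratios; input-adjusted sits near 1.\n")

arm2 = run_reproducibility_study(n_replicates=5, base_seed=1)
print("single-sample exclusive peaks, summed over 5 triplicates:")
for method, total in sorted(arm2["totals"].items(), key=lambda kv: kv[1]):
    print(f"  {method:24s} {total}")
print("input-adjusted spike-in normalization keeps irreproducible")
print("(single-replicate) peaks lowest.")
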