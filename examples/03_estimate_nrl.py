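"""Estimate per-gene NRL and array regularity by template cross-correlation.

Each gene's TSS-anchored profile is correlated with idealized Gaussian
arrays over a grid of repeat lengths (150-210 bp) and phase offsets
(40-120 bp); the best fit gives the NRL estimate and the correlation is
the regularity score.
"""

import nucarray as na

ds = na.simulate_dataset(n_genes=200, true_nrl=165.0, jitter_sd=20.0,
                         depth=2000, seed=11)
frags = na.filter_by_length(ds.fragments, 140, 160)
track = na.build_dyad_track(frags, ds.chrom_sizes, halfwidth=25)
matrix = na.extract_profiles(track, ds.genes, anchor="tss", window=(0, 1000))

bank = na.build_bank()  # 61 NRLs x 81 offsets, footprint-matched templates
stats = na.estimate_all(matrix, bank, min_coverage=50, footprint=51)
passed = stats[stats["qc_pass"]]

print(f"genes passing QC:   {len(passed)}/{len(stats)}")
print(f"median NRL:         {passed['nrl_est'].median():.1f} bp (true 165)")
print(f"median regularity:  {passed['regularity'].median():.3f}")
print(f"median offset:      {passed['best_offset'].median():.0f} bp (true +1 dyad at +60)")
print(passed.head().to_string(index=False))
# The cohort median recovers the simulated repeat length; regularity
# below 1 reflects the 20 bp positional jitter.
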