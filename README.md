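# nucarray

MNase-seq nucleosome array analysis: from aligned paired-end fragments to
per-gene **nucleosome repeat length (NRL)** and **array regularity**
estimates, with composite dyad-density profiling, cohort statistics, and a
synthetic MNase-seq generator that provides ground truth for every stage.

## The problem

In budding yeast (and most eukaryotes), nucleosomes downstream of promoters
form regular arrays phased to the transcription start site (TSS): the +1
nucleosome sits at a stereotyped distance from the TSS and subsequent
nucleosomes follow at a characteristic center-to-center spacing, the NRL.
ATP-dependent chromatin remodelers (INO80, ISW1/2, CHD1) establish and
maintain this organization; deleting remodeler subunits shortens the NRL and
blurs the arrays. Quantifying those changes gene-by-gene — and asking whether
remodeler-bound or differentially expressed gene cohorts are affected more
than the rest of the genome — requires a per-gene spacing statistic, which is
what this package computes.

## The statistic

For each gene, the dyad-density profile in a window downstream of the TSS
(default 0 to +1000 bp) is Pearson-correlated against a bank of idealized
nucleosome-array templates: sums of Gaussian peaks at positions
*offset + k·NRL* over a grid of repeat lengths (150–210 bp) and phase
offsets (40–120 bp), convolved with the same ~50 bp footprint used to build
the dyad track. Then

- **NRL estimate** = repeat length of the best-correlating template,
- **regularity** = that maximal correlation coefficient r ∈ [−1, 1],

so a gene with a perfectly even, TSS-phased array scores r ≈ 1, and jittered
or unphased chromatin scores progressively lower. Because templates are
anchored at fixed offsets from the TSS rather than slid freely, the score
specifically measures *TSS-phased* regularity.

The upstream processing follows standard MNase-seq practice: fragments are
size-selected to the mononucleosome range (140–160 bp, closed interval),
dyads are inferred as fragment midpoints and extended by 25 bp per side, and
samples can be subsampled to a fixed fragment count before spacing
statistics are compared across conditions.

## Worked example

```python
import nucarray as na

ds = na.simulate_dataset(n_genes=200, true_nrl=165.0, jitter_sd=20.0,
                         depth=2000, seed=11)
frags = na.filter_by_length(ds.fragments, 140, 160)
track = na.build_dyad_track(frags, ds.chrom_sizes, halfwidth=25)
matrix = na.extract_profiles(track, ds.genes, anchor="tss", window=(0, 1000))
stats = na.estimate_all(matrix, na.build_bank(), min_coverage=50, footprint=51)
```

Running this (`python examples/03_estimate_nrl.py`) prints:

```
genes passing QC:   200/200
median NRL:         165.0 bp (true 165)
median regularity:  0.879
median offset:      60 bp (true +1 dyad at +60)
```

The cohort median recovers the simulated 165 bp repeat length exactly and
locates the +1 dyad at its true +60 bp offset; the regularity of ~0.88
reflects the 20 bp of positional jitter each nucleosome was given. The other
scripts in `examples/` walk through dataset simulation, composite
dyad-density profiles, and cohort contrasts (bound vs rest, altered-NRL gene
sets, Venn overlaps, Welch's t-test on replicate medians).

A thin CLI mirrors the library:

```bash
nucarray simulate --n-genes 100 --out-dir sim/
nucarray dyads --fragments sim/fragments.bed --chrom-sizes sim/chrom.sizes \
    --min-len 140 --max-len 160 --halfwidth 25 --out track.bedgraph
nucarray nrl --fragments sim/fragments.bed --chrom-sizes sim/chrom.sizes \
    --annotation sim/annotation.tsv --out stats.tsv
nucarray run-all --seed 1 --out-dir run/
```

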