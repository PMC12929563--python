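# Methods

## Signal model

MNase digestion protects the ~147 bp of DNA wrapped around each
nucleosome; sequencing the protected fragments and taking paired-end
fragment midpoints gives an estimate of nucleosome dyad positions.
The package models the resulting per-gene signal downstream of a TSS as

    dyads ~ mixture over k of  N(offset + k·NRL, jitter²),  k = 0, 1, …

with mixing weights proportional to `decay^k` (occupancy falling along
the array), plus a uniform background component. The dyad-density track
is this point process convolved with a boxcar footprint of
`2·halfwidth + 1` bp.

### Processing conventions

- Coordinates are 0-based, half-open (BED). BAM records are converted on
  read; only properly paired templates are used, with the fragment span
  taken from the template length. Unpaired/discordant records are
  skipped with a logged count.
- Size selection keeps fragment lengths in a **closed** interval,
  default 140–160 bp (the mononucleosome range).
- The dyad is the **floor** of the fragment interval midpoint:
  deterministic and left-biased for even-length fragments. The
  simulator centres fragments so this rule recovers the generating dyad
  exactly for both length parities.
- "Extension by 50 bp" is implemented as a symmetric halfwidth of 25 bp
  around the dyad, giving a 51 bp footprint; the halfwidth is a
  parameter, so a ±50 bp (101 bp) reading is selectable.
- Subsampling draws fragments (after size selection) uniformly without
  replacement, seeded. The subsampling unit is the fragment — whether a
  "read" count on paired-end data means mates or templates is a
  convention choice, so the depth flag is documented in fragment units.
  Order of operations is fixed: filter → subsample → track.

## NRL and regularity estimation

Each gene's TSS-anchored profile over the scoring window (default
0…+1000 bp, strand-aware) is standardized and Pearson-correlated with a
bank of idealized array templates. A template is a sum of Gaussian
peaks with centres `offset + k·NRL`, standardized over the window. The
best (NRL, offset) grid point gives the estimates; ties break toward
smaller NRL, then smaller offset (the bank's row order makes the argmax
realize this). Pearson correlation makes the score invariant to profile
scale and offset, so subsampled and full-depth samples are comparable.

Two template-design choices matter and were made deliberately:

1. **Footprint matching.** The scored profile is dyad density convolved
   with a 51 bp boxcar, so templates are convolved with the same boxcar
   before standardization. Without this, even a noise-free regular
   array correlates at only ~0.9 with its own ideal — the mismatch
   between a narrow Gaussian and a flat-topped footprint puts a ceiling
   on regularity that has nothing to do with chromatin. `footprint`
   should equal `2·halfwidth + 1` (or 0 when scoring raw midpoint
   profiles, which is selectable).
2. **Peak extension.** An idealized regular array has no natural end
   inside the scoring window, so bank templates continue their peak
   train until the window is filled; `n_peaks` acts as a per-template
   minimum. With a fixed peak count, genes whose windows hold more
   nucleosomes than the template models would be penalized for signal
   that is perfectly regular. `build_template` itself keeps an exact
   peak count and errors when the window cannot hold the array.

Default template parameters: `sigma0 = 2` bp, `sigma_step = 0`. With
the footprint carrying the peak width, the Gaussians act as markers of
idealized dyad positions; widening them (or growing them along the
array) only blurs the match — positional jitter in data lowers the
correlation, which is exactly what the regularity score is supposed to
measure. Measured on noise-free in-grid arrays, these defaults give
regularity ≥ 0.96 and exact NRL recovery; regularity then declines
strictly monotonically as simulated jitter rises through 5, 20, 40,
80 bp.

Grids: NRL 150–210 bp and offset 40–120 bp, both step 1 bp. These
bracket yeast repeat lengths and +1-dyad positions with margin; the
offset grid must contain the true phase for the fixed-offset
correlation to find it. The full bank is 61 × 81 = 4941 templates;
scoring one gene is a single (4941 × 1001) matrix–vector product.

**QC.** Genes with zero profile variance or fewer than `min_coverage`
dyads in the scoring window (default 50; row sums divided by the
footprint length) carry no estimates. Sparse profiles can correlate
spuriously well with some template, so low-coverage estimates are worse
than none.

**+1 calling.** When no external +1 annotation is supplied, the +1
dyad is called as the signal maximum in a strand-aware window
(default 0…+200 bp) downstream of the TSS, ties toward the TSS, genes
with empty windows flagged rather than dropped. Composite dyad-density
profiles anchored at this +1 are column means over genes (padded
off-chromosome cells excluded) normalized to a window mean of exactly 1.

## Cohort statistics

- Boxplot summaries: quartiles by linear interpolation between order
  statistics (documented because boxplot conventions differ), whiskers
  at the most extreme points within 1.5×IQR of the quartiles.
- Welch's two-tailed t-test (unequal variances, Welch–Satterthwaite
  df; scipy's implementation) on per-replicate **median** NRL or
  regularity values, annotated `*` for p < 0.05, `**` for p < 0.01,
  `n.s.` otherwise. The test is honoured at n = 2 replicates per
  condition — the common MNase-seq design — with a logged warning:
  at that size the test has minimal power and is *conservative* under
  the null (measured ~2–3% rejection at α = 0.05 over 1000 null
  simulations, because the Satterthwaite df is estimated from
  two-point variances). Calibration at the nominal 5% is reached from
  about 4 replicates per group (measured 4–5.3% at n = 4–10).
- Cohort contrasts split the shared QC-passing gene universe into a
  member set and its complement and report per-group summaries and the
  condition change of group medians. Per-gene ΔNRL tables join on
  gene id and keep only genes passing QC in both conditions.
- Altered-NRL gene sets use a strict `|ΔNRL| > threshold` cutoff; the
  threshold is always explicit (no silent default in the CLI). Venn
  counts partition a declared universe exactly.

## Synthetic data: what it does and does not emulate

The generator produces non-overlapping genes on a toy chromosome (TSS
at each slot centre, random strands), per-gene dyads from the mixture
model above, and fragments with rounded-Gaussian lengths
(mean 150, sd 5, clipped at ≥ 50 bp — ~96% of mass inside 140–160 bp)
centred on their dyads. Minus-strand genes are mirrored around the TSS
so strand handling is exercised everywhere. Defaults describe a
yeast-like array: NRL 165 bp, +1 dyad +60 bp, 6 nucleosomes, 20 bp
jitter, occupancy decay 0.9 per position, 10% background, 2000 dyads
per gene. Real yeast arrays are not quantitatively calibrated in the
sources this package draws on, so these are chosen-once, realistic
values rather than fitted ones.

Not modelled: DNA sequence (no FASTQ, no read errors, no mappability),
MNase sequence preference, inter-gene signal spillover, replication or
transcription dynamics. Passing tests therefore demonstrate that the
*estimator* recovers known array structure from ideal-but-noisy dyad
data; they do not certify accuracy under MNase digestion bias or
alignment artifacts, which real data add on top.

Jitter is drawn independently per nucleosome (no cumulative drift), so
NRL errors do not accumulate along the array; biological arrays may
drift, which the offset/NRL grid search absorbs only partially.

## Problem sizes and determinism

Benchmark cohorts use 100–500 genes at 500–2000 dyads per gene —
large enough that cohort medians are stable to well under 1 bp, small
enough to run interactively. All randomness flows from explicit seeds:
per-gene seeds derive from a dataset seed via `SeedSequence`, and the
pipeline derives per-sample seeds from one global seed, so reruns are
byte-identical for all deterministic outputs.

## Known limitations

- NRL estimates are grid-quantized (1 bp); sub-bp spacing changes are
  invisible per gene and only emerge in cohort medians.
- The fixed-offset correlation intentionally penalizes arrays that are
  regular but not TSS-phased; it is not a general periodicity detector
  (no phasogram/spectral mode).
- With two replicates per condition the Welch test under-rejects; treat
  `n.s.` at n = 2 as weak evidence either way.
- The +1 caller is a windowed argmax; on sparse or noisy tracks an
  external +1 annotation is preferable and is accepted wherever an
  anchor is needed.
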