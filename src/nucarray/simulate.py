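"""Synthetic MNase-seq generator with per-gene ground truth.

Emulates the signal the downstream estimator is built to detect: regularly
spaced nucleosome arrays phased to the TSS of each gene.  For every gene a
ground-truth record fixes the true nucleosome repeat length (NRL), the
phase offset of the first (+1) dyad, per-nucleosome positional jitter,
occupancy decay along the array, and a uniform background fraction; dyads
are then wrapped into mononucleosome-sized paired-end fragments.

The defaults describe a budding-yeast-like genome: NRL 165 bp, +1 dyad
~60 bp downstream of the TSS, ~6 nucleosomes per array, 20 bp jitter, 10%
background, fragment lengths ~N(150, 5) so most mass falls in 140-160 bp.

Deliberately not modelled: DNA sequence (no FASTQ or read errors),
MNase sequence preference, mappability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fragments import Fragment, write_chrom_sizes, write_fragments_bed
from .profiles import GeneAnnotation

# Study-condition defaults for a yeast-like phased array.
DEFAULT_TRUE_NRL = 165.0
DEFAULT_PHASE_OFFSET = 60.0
DEFAULT_N_NUCLEOSOMES = 6
DEFAULT_JITTER_SD = 20.0
DEFAULT_OCCUPANCY_DECAY = 0.9
DEFAULT_BACKGROUND_RATE = 0.1
DEFAULT_DEPTH = 2000
DEFAULT_FRAGLEN_MEAN = 150.0
DEFAULT_FRAGLEN_SD = 5.0
MIN_FRAGLEN = 50  # fragments shorter than this are clipped up


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth array parameters for one gene.

    ``occupancy_decay`` is the multiplicative weight retained per
    successive nucleosome (peak k sampled with weight decay**k);
    1.0 means flat occupancy along the array.
    """

    gene_id: str
    true_nrl: float = DEFAULT_TRUE_NRL
    phase_offset: float = DEFAULT_PHASE_OFFSET
    n_nucleosomes: int = DEFAULT_N_NUCLEOSOMES
    jitter_sd: float = DEFAULT_JITTER_SD
    occupancy_decay: float = DEFAULT_OCCUPANCY_DECAY
    background_rate: float = DEFAULT_BACKGROUND_RATE
    depth: int = DEFAULT_DEPTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_nrl <= 0:
            raise ValueError("true_nrl must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        if not 0.0 <= self.occupancy_decay <= 1.0:
            raise ValueError("occupancy_decay must be in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.n_nucleosomes < 1:
            raise ValueError("n_nucleosomes must be >= 1")


@dataclass
class SyntheticDataset:
    """A toy genome bundle: chromosome sizes, annotation, fragments, truth."""

    chrom_sizes: dict[str, int]
    genes: list[GeneAnnotation]
    fragments: list[Fragment]
    truth: list[SyntheticTruth] = field(default_factory=list)


def generate_annotation(
    n_genes: int,
    chrom_length: int,
    min_gene_spacing: int = 3000,
    seed: int = 0,
    chrom: str = "chrS",
) -> list[GeneAnnotation]:
    """Place ``n_genes`` non-overlapping genes on one toy chromosome.

    The chromosome is divided into equal slots; each gene's TSS sits at
    its slot centre so arrays fit within the slot on either strand.
    Strands are assigned at random (seeded).

    Raises a capacity error if the genes cannot fit at the stated spacing.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes * min_gene_spacing > chrom_length:
        raise ValueError(
            f"cannot place {n_genes} genes with spacing {min_gene_spacing} bp "
            f"on a {chrom_length} bp chromosome"
        )
    slot = chrom_length // n_genes
    rng = np.random.default_rng(seed)
    strands = rng.choice(["+", "-"], size=n_genes)
    width = len(str(n_genes - 1))
    return [
        GeneAnnotation(
            gene_id=f"g{str(i).zfill(width)}",
            chrom=chrom,
            tss=i * slot + slot // 2,
            strand=str(strands[i]),
        )
        for i in range(n_genes)
    ]


def simulate_gene_dyads(truth: SyntheticTruth, gene: GeneAnnotation) -> np.ndarray:
    """Draw ``truth.depth`` dyad positions (genomic bp) for one gene.

    Signal dyads sit at ``phase_offset + k * true_nrl`` downstream of the
    TSS (strand-aware; minus-strand genes mirror around the TSS), each
    perturbed by rounded Gaussian jitter; peak k is picked with weight
    ``occupancy_decay**k``.  A ``background_rate`` fraction of dyads is
    uniform over the array extent of the gene.
    """
    rng = np.random.default_rng(truth.seed)
    n_bg = int(round(truth.background_rate * truth.depth))
    n_sig = truth.depth - n_bg

    k_weights = truth.occupancy_decay ** np.arange(truth.n_nucleosomes)
    k_weights = k_weights / k_weights.sum()
    ks = rng.choice(truth.n_nucleosomes, size=n_sig, p=k_weights)
    rel = truth.phase_offset + ks * truth.true_nrl
    if truth.jitter_sd > 0:
        rel = rel + rng.normal(0.0, truth.jitter_sd, size=n_sig)

    extent = truth.phase_offset + truth.n_nucleosomes * truth.true_nrl
    bg = rng.uniform(0.0, extent, size=n_bg)

    rel_all = np.concatenate([rel, bg])
    sign = 1 if gene.strand == "+" else -1
    return gene.tss + sign * np.rint(rel_all).astype(np.int64)


def dyads_to_fragments(
    dyads: Sequence[int] | np.ndarray,
    chrom: str,
    fraglen_mean: float = DEFAULT_FRAGLEN_MEAN,
    fraglen_sd: float = DEFAULT_FRAGLEN_SD,
    seed: int = 0,
    chrom_length: int | None = None,
) -> list[Fragment]:
    """Wrap each dyad in a fragment centred on it.

    Lengths are rounded Gaussian draws clipped at >= 50 bp; a fragment of
    length L spans ``[dyad - L//2, dyad - L//2 + L)``, so the downstream
    floor-midpoint rule recovers the dyad exactly for both parities of L.
    Fragments are clipped to chromosome bounds when ``chrom_length`` is given.
    """
    if fraglen_mean <= 0:
        raise ValueError("fraglen_mean must be > 0")
    dyads = np.asarray(dyads, dtype=np.int64)
    rng = np.random.default_rng(seed)
    lengths = np.rint(rng.normal(fraglen_mean, fraglen_sd, size=dyads.size))
    lengths = np.maximum(lengths, MIN_FRAGLEN).astype(np.int64)
    starts = dyads - lengths // 2
    ends = starts + lengths
    if chrom_length is not None:
        shift = np.maximum(-starts, 0) - np.maximum(ends - chrom_length, 0)
        starts, ends = starts + shift, ends + shift
    return [Fragment(chrom, int(s), int(e)) for s, e in zip(starts, ends)]


def simulate_dataset(
    n_genes: int = 100,
    true_nrl: float = DEFAULT_TRUE_NRL,
    phase_offset: float = DEFAULT_PHASE_OFFSET,
    n_nucleosomes: int = DEFAULT_N_NUCLEOSOMES,
    jitter_sd: float = DEFAULT_JITTER_SD,
    occupancy_decay: float = DEFAULT_OCCUPANCY_DECAY,
    background_rate: float = DEFAULT_BACKGROUND_RATE,
    depth: int = DEFAULT_DEPTH,
    fraglen_mean: float = DEFAULT_FRAGLEN_MEAN,
    fraglen_sd: float = DEFAULT_FRAGLEN_SD,
    min_gene_spacing: int = 3000,
    seed: int = 0,
    nrl_by_gene: Sequence[float] | None = None,
) -> SyntheticDataset:
    """Simulate a complete dataset with one shared parameter set.

    ``nrl_by_gene`` optionally overrides ``true_nrl`` per gene (same
    length as ``n_genes``), e.g. to build cohorts with shifted spacing.
    Per-gene seeds are derived deterministically from the global seed.
    """
    chrom_length = n_genes * min_gene_spacing
    genes = generate_annotation(
        n_genes, chrom_length, min_gene_spacing, seed=seed
    )
    if nrl_by_gene is not None and len(nrl_by_gene) != n_genes:
        raise ValueError("nrl_by_gene length must equal n_genes")

    ss = np.random.SeedSequence(seed)
    gene_seeds = ss.generate_state(2 * n_genes) % (2**31)
    truths: list[SyntheticTruth] = []
    fragments: list[Fragment] = []
    for i, gene in enumerate(genes):
        t = SyntheticTruth(
            gene_id=gene.gene_id,
            true_nrl=float(nrl_by_gene[i]) if nrl_by_gene is not None else true_nrl,
            phase_offset=phase_offset,
            n_nucleosomes=n_nucleosomes,
            jitter_sd=jitter_sd,
            occupancy_decay=occupancy_decay,
            background_rate=background_rate,
            depth=depth,
            seed=int(gene_seeds[2 * i]),
        )
        truths.append(t)
        dyads = simulate_gene_dyads(t, gene)
        fragments.extend(
            dyads_to_fragments(
                dyads,
                gene.chrom,
                fraglen_mean,
                fraglen_sd,
                seed=int(gene_seeds[2 * i + 1]),
                chrom_length=chrom_length,
            )
        )
    return SyntheticDataset(
        chrom_sizes={genes[0].chrom: chrom_length},
        genes=genes,
        fragments=fragments,
        truth=truths,
    )


def truth_frame(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truths])


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write fragments (BED), annotation (TSV), truth (TSV), chrom sizes.

    Files round-trip through the readers in :mod:`nucarray.fragments` and
    :mod:`nucarray.profiles`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fragments": out / "fragments.bed",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.tsv",
        "chrom_sizes": out / "chrom.sizes",
    }
    try:
        write_fragments_bed(dataset.fragments, paths["fragments"])
        pd.DataFrame(
            [
                {"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss, "strand": g.strand}
                for g in dataset.genes
            ]
        ).to_csv(paths["annotation"], sep="\t", index=False)
        truth_frame(dataset.truth).to_csv(paths["truth"], sep="\t", index=False)
        write_chrom_sizes(dataset.chrom_sizes, paths["chrom_sizes"])
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out}: {exc}") from exc
    return paths
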