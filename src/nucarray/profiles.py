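"""Strand-aware per-gene signal matrices and composite (metagene) profiles.

Genes are anchored at the TSS or at the +1 nucleosome (the first
nucleosome downstream of the TSS); profiles are oriented so increasing
column index always means downstream in the gene's own sense, which lets
plus- and minus-strand genes be averaged together.

Windows ``(a, b)`` are in bp relative to the anchor and inclusive at both
ends: the matrix has ``b - a + 1`` columns.  Genes whose window leaves
the chromosome are zero-padded and flagged; composite means exclude the
padded cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fragments import DyadTrack

DEFAULT_TSS_WINDOW = (-200, 1200)
DEFAULT_PLUS_ONE_WINDOW = (-1000, 1000)
DEFAULT_PLUS_ONE_SEARCH = (0, 200)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene anchor: TSS coordinate (0-based) and strand, plus optional
    +1-nucleosome dyad coordinate."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    plus_one: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0")


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV with columns gene_id, chrom, tss, strand
    (and optionally plus_one)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    has_p1 = "plus_one" in df.columns
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            tss=int(r.tss),
            strand=str(r.strand),
            plus_one=int(r.plus_one) if has_p1 and pd.notna(r.plus_one) else None,
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class ProfileMatrix:
    """genes x relative-position signal matrix, strand-oriented downstream.

    ``values[i, j]`` is the track signal for gene i at strand-aware
    position ``anchor + a + j`` (plus strand) or ``anchor - a - j``
    (minus strand).  ``valid`` marks cells inside chromosome bounds;
    ``clipped`` flags genes with any padded cell.
    """

    gene_ids: list[str]
    window: tuple[int, int]
    anchor: str  # "tss" or "plus_one"
    values: np.ndarray
    valid: np.ndarray
    clipped: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.window[1] - self.window[0] + 1

    def to_frame(self) -> pd.DataFrame:
        cols = np.arange(self.window[0], self.window[1] + 1)
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


def _anchor_position(gene: GeneAnnotation, anchor: str) -> int:
    if anchor == "tss":
        return gene.tss
    if anchor == "plus_one":
        if gene.plus_one is None:
            raise ValueError(f"gene {gene.gene_id} has no +1-nucleosome anchor")
        return gene.plus_one
    raise ValueError(f"unknown anchor {anchor!r}")


def extract_profiles(
    track: DyadTrack,
    genes: Sequence[GeneAnnotation],
    anchor: str = "tss",
    window: tuple[int, int] = DEFAULT_TSS_WINDOW,
) -> ProfileMatrix:
    """Build the genes x positions signal matrix around the chosen anchor.

    Minus-strand profiles are mirrored so that column order runs
    upstream -> downstream for every gene.
    """
    a, b = window
    if a >= b:
        raise ValueError(f"window must satisfy a < b, got {window}")
    missing = [
        g.gene_id for g in genes if anchor == "plus_one" and g.plus_one is None
    ]
    if missing:
        raise ValueError(f"genes missing +1 anchor: {missing}")
    width = b - a + 1
    values = np.zeros((len(genes), width), dtype=np.int64)
    valid = np.ones((len(genes), width), dtype=bool)
    for i, gene in enumerate(genes):
        pos0 = _anchor_position(gene, anchor)
        size = track.chrom_sizes[gene.chrom]
        if gene.strand == "+":
            start, end = pos0 + a, pos0 + b + 1
            values[i] = track.values(gene.chrom, start, end)
            idx = np.arange(start, end)
        else:
            start, end = pos0 - b, pos0 - a + 1
            values[i] = track.values(gene.chrom, start, end)[::-1]
            idx = np.arange(end - 1, start - 1, -1)
        valid[i] = (idx >= 0) & (idx < size)
    clipped = ~valid.all(axis=1)
    return ProfileMatrix(
        gene_ids=[g.gene_id for g in genes],
        window=(a, b),
        anchor=anchor,
        values=values,
        valid=valid,
        clipped=clipped,
    )


def call_plus_one(
    track: DyadTrack,
    gene: GeneAnnotation,
    search_window: tuple[int, int] = DEFAULT_PLUS_ONE_SEARCH,
) -> int | None:
    """Call the +1-nucleosome dyad as the maximal-signal position in a
    strand-aware window downstream of the TSS.

    Ties break toward the position closest to the TSS.  Returns ``None``
    (flagged undefined) when the window carries no signal.
    """
    a, b = search_window
    rel = np.arange(a, b + 1)
    sign = 1 if gene.strand == "+" else -1
    pos = gene.tss + sign * rel
    lo, hi = int(pos.min()), int(pos.max()) + 1
    vals = track.values(gene.chrom, lo, hi)
    sig = vals[pos - lo]
    if sig.max() == 0:
        return None
    best = np.flatnonzero(sig == sig.max())
    k = best[np.argmin(np.abs(rel[best]))]
    return int(pos[k])


def annotate_plus_one(
    track: DyadTrack,
    genes: Sequence[GeneAnnotation],
    search_window: tuple[int, int] = DEFAULT_PLUS_ONE_SEARCH,
) -> list[GeneAnnotation]:
    """Return annotation records with data-driven +1 calls filled in.

    Genes with no signal in the search window keep ``plus_one=None``.
    """
    out = []
    for g in genes:
        p1 = call_plus_one(track, g, search_window)
        out.append(
            GeneAnnotation(g.gene_id, g.chrom, g.tss, g.strand, plus_one=p1)
        )
    return out


def composite_profile(matrix: ProfileMatrix, normalize: bool = True) -> np.ndarray:
    """Column-wise mean over genes; padded cells are excluded from means.

    With ``normalize=True`` the composite is divided by its own mean over
    the window, so the returned vector has mean exactly 1 — the
    convention used for gene-averaged dyad-density plots.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("empty profile matrix")
    vals = matrix.values.astype(float)
    n_valid = matrix.valid.sum(axis=0)
    sums = np.where(matrix.valid, vals, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), 0.0)
    if normalize:
        m = comp.mean()
        if m == 0:
            raise ValueError("cannot normalize an all-zero composite")
        comp = comp / m
    return comp


def write_composite(
    composite: np.ndarray, window: tuple[int, int], path: str | Path
) -> None:
    pos = np.arange(window[0], window[1] + 1)
    pd.DataFrame({"position": pos, "signal": composite}).to_csv(
        path, sep="\t", index=False
    )


def plot_composite(
    composites: dict[str, np.ndarray],
    window: tuple[int, int],
    path: str | Path,
    title: str = "Composite dyad density",
) -> None:
    """Plot one or more labelled composites (dyad-density style figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = np.arange(window[0], window[1] + 1)
    fig, ax = plt.subplots(figsize=(7, 3.2))
    for label, comp in composites.items():
        ax.plot(pos, comp, label=label, lw=1.2)
    ax.axvline(0, color="grey", lw=0.6, ls="--")
    ax.set_xlabel("position relative to anchor (bp)")
    ax.set_ylabel("normalized dyad density")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
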