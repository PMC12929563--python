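"""Paired-end fragment ingest, size selection, dyad inference and dyad tracks.

MNase-seq protects nucleosomal DNA from digestion; the midpoint of a
mononucleosome-sized sequenced fragment approximates the nucleosome dyad
(the central base pair of the wrapped DNA).  This module turns aligned
fragment intervals into a genome-wide per-base-pair dyad-density signal:

1. size-select fragments to the mononucleosome range (default 140-160 bp,
   closed interval),
2. infer one dyad per fragment as ``floor((start + end) / 2)``,
3. optionally subsample to a fixed fragment count for cross-sample
   comparability,
4. extend each dyad symmetrically by ``halfwidth`` bp and accumulate
   counts into a per-chromosome track.

All coordinates are 0-based, half-open (BED convention); BAM records are
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Mononucleosome size-selection bounds (bp, closed interval).
DEFAULT_MIN_LEN = 140
DEFAULT_MAX_LEN = 160
#: Symmetric dyad extension (bp each side), giving a ~50 bp footprint.
DEFAULT_HALFWIDTH = 25


@dataclass(frozen=True)
class Fragment:
    """An aligned paired-end fragment as a genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid fragment {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Dyad position inferred as the floor of the interval midpoint."""
        return (self.start + self.end) // 2


def fragment_midpoint(frag: Fragment) -> int:
    """Dyad position of a fragment: ``floor((start + end) / 2)``.

    Even-length intervals have no central base; the floor rule is
    left-biased and deterministic.
    """
    return frag.midpoint


class FragmentParseError(ValueError):
    """Raised for malformed fragment records, carrying the record number."""


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` text file (name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FragmentParseError(
                    f"{path}: line {lineno}: expected 'chrom<TAB>length'"
                )
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def _read_bed(path: str | Path) -> list[Fragment]:
    frags: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FragmentParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FragmentParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            try:
                frags.append(Fragment(chrom, start, end))
            except ValueError as exc:
                raise FragmentParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    return frags


def _read_bam(path: str | Path) -> list[Fragment]:
    import pysam

    frags: list[Fragment] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            # one fragment per template: take the leftmost mate of a proper pair
            if (
                rec.is_unmapped
                or rec.mate_is_unmapped
                or not rec.is_proper_pair
                or rec.is_secondary
                or rec.is_supplementary
            ):
                skipped += 1
                continue
            if rec.template_length <= 0:  # count each template once
                continue
            frags.append(
                Fragment(
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_start + rec.template_length,
                )
            )
    if skipped:
        logger.info("skipped %d unpaired/discordant BAM records", skipped)
    return frags


def read_fragments(path: str | Path, format: str = "bed") -> list[Fragment]:
    """Read aligned paired-end fragments from BED3+ or a coordinate-sorted BAM.

    For BAM, the fragment span is the template length of each properly
    paired record; unpaired/discordant records are skipped with a logged
    count.  Input order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bed":
        return _read_bed(path)
    if format == "bam":
        return _read_bam(path)
    raise ValueError(f"unknown fragment format: {format!r} (expected 'bed' or 'bam')")


def write_fragments_bed(frags: Iterable[Fragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in frags:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def filter_by_length(
    frags: Iterable[Fragment],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[Fragment]:
    """Retain fragments with ``min_len <= length <= max_len`` (closed interval).

    The mononucleosome default of 140-160 bp keeps fragments whose
    protected length is consistent with a single nucleosome core particle.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    return [f for f in frags if min_len <= f.length <= max_len]


def subsample(frags: list[Fragment], n: int, seed: int) -> list[Fragment]:
    """Draw exactly ``n`` fragments uniformly without replacement (seeded).

    Subsampling equalizes sequencing depth across samples before spacing
    statistics are computed.  Input order is preserved among the kept
    fragments; identical seeds give identical output.
    """
    if n > len(frags):
        raise ValueError(f"requested {n} fragments but only {len(frags)} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(frags), size=n, replace=False)
    idx.sort()
    return [frags[i] for i in idx]


@dataclass
class DyadTrack:
    """Per-chromosome per-bp signal of symmetrically extended dyad counts."""

    chrom_sizes: dict[str, int]
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    halfwidth: int = DEFAULT_HALFWIDTH

    def total_signal(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal on [start, end) with out-of-bounds positions read as 0."""
        size = self.chrom_sizes[chrom]
        out = np.zeros(end - start, dtype=np.int64)
        lo, hi = max(start, 0), min(end, size)
        if lo < hi:
            out[lo - start : hi - start] = self.counts[chrom][lo:hi]
        return out


def build_dyad_track(
    frags: Iterable[Fragment],
    chrom_sizes: Mapping[str, int],
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> DyadTrack:
    """Accumulate extended dyads into a per-bp track.

    Each fragment contributes +1 to every base pair in
    ``[midpoint - halfwidth, midpoint + halfwidth]`` (inclusive), clipped
    at chromosome edges, so one unclipped dyad adds ``2*halfwidth + 1``
    to the total signal.  Implemented as a difference array + cumulative
    sum, O(n_fragments + genome_length).
    """
    diffs = {c: np.zeros(size + 1, dtype=np.int64) for c, size in chrom_sizes.items()}
    for f in frags:
        if f.chrom not in diffs:
            raise ValueError(
                f"fragment {f.chrom}:{f.start}-{f.end} on undeclared chromosome"
            )
        size = chrom_sizes[f.chrom]
        if f.start < 0 or f.end > size:
            raise ValueError(
                f"fragment {f.chrom}:{f.start}-{f.end} outside chromosome "
                f"bounds [0, {size})"
            )
        mid = f.midpoint
        lo = max(mid - halfwidth, 0)
        hi = min(mid + halfwidth + 1, size)  # exclusive
        diffs[f.chrom][lo] += 1
        diffs[f.chrom][hi] -= 1
    counts = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return DyadTrack(chrom_sizes=dict(chrom_sizes), counts=counts, halfwidth=halfwidth)


def midpoint_track(
    frags: Iterable[Fragment], chrom_sizes: Mapping[str, int]
) -> DyadTrack:
    """Raw (unextended) dyad counts: halfwidth 0."""
    return build_dyad_track(frags, chrom_sizes, halfwidth=0)


def write_bedgraph(track: DyadTrack, path: str | Path) -> None:
    """Write the track as bedGraph, merging runs of equal signal; zero runs skipped."""
    with open(path, "w") as fh:
        for chrom in track.chrom_sizes:
            c = track.counts[chrom]
            if c.size == 0:
                continue
            change = np.flatnonzero(np.diff(c)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [c.size]))
            for s, e in zip(starts, ends):
                v = int(c[s])
                if v:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def write_bigwig(track: DyadTrack, path: str | Path) -> None:
    """Write the track as bigWig (requires pyBigWig)."""
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader(list(track.chrom_sizes.items()))
        for chrom in track.chrom_sizes:
            c = track.counts[chrom]
            if c.size == 0:
                continue
            change = np.flatnonzero(np.diff(c)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [c.size]))
            vals = c[starts].astype(float)
            keep = vals != 0
            if keep.any():
                bw.addEntries(
                    [chrom] * int(keep.sum()),
                    starts[keep].tolist(),
                    ends=ends[keep].tolist(),
                    values=vals[keep].tolist(),
                )
    finally:
        bw.close()
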