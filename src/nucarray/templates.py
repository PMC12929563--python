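"""Idealized Gaussian array templates for NRL estimation.

A template is the per-bp signal of a perfectly regular, TSS-phased
nucleosome array: a sum of Gaussian bumps with peak k centred at
``offset + k * nrl`` and width ``sigma0 + k * sigma_step``.  Templates
are standardized (zero mean, unit variance over the scoring window) so
that the dot product with a standardized profile is a Pearson
correlation.

Two choices make the template live in the same signal space as the
data it is correlated with:

* ``footprint``: the scored profile is built from dyads extended to a
  nucleosome-sized footprint (51 bp for halfwidth 25), so templates are
  convolved with the same boxcar.  Without this, even a perfectly
  regular array correlates only ~0.9 with its own ideal, because a
  narrow Gaussian is a poor model of a flat-topped footprint.
* peak extension (bank-level): an idealized regular array has no
  natural end inside the scoring window, so the bank continues each
  template's peaks until the window is filled.  Otherwise genes whose
  windows hold more nucleosomes than the template models are penalized
  for signal that is perfectly regular.

A bank holds one template per (nrl, offset) grid point; the grids
bracket plausible yeast NRLs (150-210 bp) and +1 dyad offsets
(40-120 bp from the TSS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_NRL_GRID = (150, 210, 1)  # start, stop (inclusive), step
DEFAULT_OFFSET_GRID = (40, 120, 1)
DEFAULT_N_PEAKS = 5
DEFAULT_SIGMA0 = 2.0
DEFAULT_SIGMA_STEP = 0.0
DEFAULT_FOOTPRINT = 51
DEFAULT_SCORING_WINDOW = (0, 1000)


def build_template(
    nrl: float,
    n_peaks: int = DEFAULT_N_PEAKS,
    sigma0: float = DEFAULT_SIGMA0,
    sigma_step: float = DEFAULT_SIGMA_STEP,
    offset: float = 60.0,
    window_len: int = 1001,
    footprint: int = 0,
) -> "Template":
    """Build one standardized Gaussian-array template.

    Requires the full array to fit: ``window_len >= offset + (n_peaks-1)*nrl``.
    ``footprint`` > 0 convolves the Gaussian train with a centred boxcar
    of that many bp, mirroring the dyad extension applied to the data.
    """
    if nrl <= 0:
        raise ValueError("nrl must be > 0")
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be > 0")
    if window_len < offset + (n_peaks - 1) * nrl:
        raise ValueError(
            f"window of {window_len} bp too short for {n_peaks} peaks at "
            f"NRL {nrl} and offset {offset}"
        )
    x = np.arange(window_len, dtype=float)
    values = np.zeros(window_len)
    for k in range(n_peaks):
        center = offset + k * nrl
        sigma = sigma0 + k * sigma_step
        values += np.exp(-0.5 * ((x - center) / sigma) ** 2)
    if footprint > 0:
        values = np.convolve(values, np.ones(footprint) / footprint, mode="same")
    values = (values - values.mean()) / values.std()
    return Template(
        nrl=nrl,
        n_peaks=n_peaks,
        sigma0=sigma0,
        sigma_step=sigma_step,
        offset=offset,
        values=values,
    )


@dataclass(frozen=True)
class Template:
    nrl: float
    n_peaks: int
    sigma0: float
    sigma_step: float
    offset: float
    values: np.ndarray


@dataclass
class TemplateBank:
    """One standardized template per (nrl, offset) grid point.

    ``matrix`` stacks template values row-wise in (nrl-major, offset-minor)
    order, enabling all Pearson correlations for one profile in a single
    matrix-vector product.  With ``extend_peaks`` each template's array
    is continued until the scoring window is filled, so ``n_peaks`` acts
    as a per-template minimum.
    """

    nrl_grid: np.ndarray
    offset_grid: np.ndarray
    n_peaks: int
    sigma0: float
    sigma_step: float
    window: tuple[int, int]
    footprint: int
    extend_peaks: bool
    matrix: np.ndarray = field(repr=False)

    @property
    def window_len(self) -> int:
        return self.window[1] - self.window[0] + 1

    def pairs(self) -> list[tuple[float, float]]:
        """(nrl, offset) in matrix row order."""
        return [(float(n), float(o)) for n in self.nrl_grid for o in self.offset_grid]


def build_bank(
    nrl_grid: tuple[int, int, int] = DEFAULT_NRL_GRID,
    offset_grid: tuple[int, int, int] = DEFAULT_OFFSET_GRID,
    n_peaks: int = DEFAULT_N_PEAKS,
    sigma0: float = DEFAULT_SIGMA0,
    sigma_step: float = DEFAULT_SIGMA_STEP,
    window: tuple[int, int] = DEFAULT_SCORING_WINDOW,
    footprint: int = DEFAULT_FOOTPRINT,
    extend_peaks: bool = True,
) -> TemplateBank:
    """Build the full template bank over the (nrl, offset) grid.

    Grid tuples are (start, stop, step) with stop inclusive.  With
    ``extend_peaks`` (default) each template carries as many peaks as
    fit in the window, but never fewer than ``n_peaks``; ``footprint``
    should match the dyad-extension footprint of the scored profiles
    (``2 * halfwidth + 1``), or 0 for raw-midpoint profiles.
    """
    nrls = np.arange(nrl_grid[0], nrl_grid[1] + 1, nrl_grid[2], dtype=float)
    offsets = np.arange(
        offset_grid[0], offset_grid[1] + 1, offset_grid[2], dtype=float
    )
    if nrls.size == 0 or offsets.size == 0:
        raise ValueError("empty template grid")
    window_len = window[1] - window[0] + 1
    mat = np.empty((nrls.size * offsets.size, window_len))
    r = 0
    for nrl in nrls:
        for off in offsets:
            n_pk = n_peaks
            if extend_peaks:
                n_pk = max(n_peaks, 1 + int((window_len - 1 - off) // nrl))
            mat[r] = build_template(
                nrl, n_pk, sigma0, sigma_step, off, window_len, footprint
            ).values
            r += 1
    return TemplateBank(
        nrl_grid=nrls,
        offset_grid=offsets,
        n_peaks=n_peaks,
        sigma0=sigma0,
        sigma_step=sigma_step,
        window=window,
        footprint=footprint,
        extend_peaks=extend_peaks,
        matrix=mat,
    )
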