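"""Pipeline configuration: every tunable of the analysis in one record.

The config mirrors the CLI flags and can be loaded from a YAML file;
``validate_config`` checks every field against its stage's preconditions
and reports *all* violations at once rather than failing on the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # simulation (used by the simulate and run-all commands)
    n_genes: int = 100
    true_nrl: float = 165.0
    mutant_nrl: float = 162.0
    phase_offset: float = 60.0
    n_nucleosomes: int = 6
    jitter_sd: float = 20.0
    occupancy_decay: float = 0.9
    background_rate: float = 0.1
    depth: int = 2000
    fraglen_mean: float = 150.0
    fraglen_sd: float = 5.0
    min_gene_spacing: int = 3000
    n_replicates: int = 2

    # fragment processing
    min_len: int = 140
    max_len: int = 160
    subsample_depth: int | None = None  # None = keep all fragments
    halfwidth: int = 25

    # profiles
    tss_window: tuple[int, int] = (-200, 1200)
    plus_one_window: tuple[int, int] = (-1000, 1000)
    plus_one_search: tuple[int, int] = (0, 200)

    # NRL estimation
    scoring_window: tuple[int, int] = (0, 1000)
    nrl_grid: tuple[int, int, int] = (150, 210, 1)
    offset_grid: tuple[int, int, int] = (40, 120, 1)
    n_peaks: int = 5
    sigma0: float = 2.0
    sigma_step: float = 0.0
    min_coverage: float = 50.0

    # cohort statistics
    delta_nrl_threshold: float = 5.0

    # global
    seed: int = 0
    condition_labels: tuple[str, str] = ("wt", "mut")
    out_dir: str = "nucarray_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML key/value file; unknown keys error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("tss_window", "plus_one_window", "plus_one_search",
                "scoring_window", "nrl_grid", "offset_grid",
                "condition_labels"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of all precondition violations (empty = valid)."""
    errors: list[str] = []
    c = config
    if c.n_genes < 1:
        errors.append("n_genes must be >= 1")
    if c.true_nrl <= 0 or c.mutant_nrl <= 0:
        errors.append("true_nrl and mutant_nrl must be > 0")
    if c.jitter_sd < 0:
        errors.append("jitter_sd must be >= 0")
    if not 0 <= c.background_rate <= 1:
        errors.append("background_rate must be in [0, 1]")
    if not 0 <= c.occupancy_decay <= 1:
        errors.append("occupancy_decay must be in [0, 1]")
    if c.depth < 0:
        errors.append("depth must be >= 0")
    if c.fraglen_mean <= 0:
        errors.append("fraglen_mean must be > 0")
    if c.n_genes * c.min_gene_spacing <= 0:
        errors.append("min_gene_spacing must be > 0")
    if c.min_len > c.max_len:
        errors.append(f"min_len ({c.min_len}) > max_len ({c.max_len})")
    if c.subsample_depth is not None and c.subsample_depth < 0:
        errors.append("subsample_depth must be >= 0")
    if c.halfwidth < 0:
        errors.append("halfwidth must be >= 0")
    for name in ("tss_window", "plus_one_window", "plus_one_search",
                 "scoring_window"):
        a, b = getattr(c, name)
        if a >= b:
            errors.append(f"{name}: require a < b, got ({a}, {b})")
    for name in ("nrl_grid", "offset_grid"):
        start, stop, step = getattr(c, name)
        if start > stop or step < 1:
            errors.append(f"{name}: require start <= stop and step >= 1")
    if c.n_peaks < 2:
        errors.append("n_peaks must be >= 2")
    if c.sigma0 <= 0:
        errors.append("sigma0 must be > 0")
    if c.min_coverage < 0:
        errors.append("min_coverage must be >= 0")
    if c.delta_nrl_threshold <= 0:
        errors.append("delta_nrl_threshold must be > 0")
    if c.n_replicates < 1:
        errors.append("n_replicates must be >= 1")
    # cross-stage consistency: templates must fit the scoring window
    win_len = c.scoring_window[1] - c.scoring_window[0] + 1
    max_span = c.offset_grid[1] + (c.n_peaks - 1) * c.nrl_grid[1]
    if win_len < max_span:
        errors.append(
            f"scoring window ({win_len} bp) too short for the largest template "
            f"(offset {c.offset_grid[1]} + {c.n_peaks - 1} peaks x NRL "
            f"{c.nrl_grid[1]} = {max_span} bp)"
        )
    return errors


def require_valid(config: PipelineConfig) -> PipelineConfig:
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return config
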