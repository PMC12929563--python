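"""Cohort comparisons: boxplot summaries, Welch's t-test, gene-set contrasts.

The central question these helpers serve: when a chromatin remodeler
subunit is removed, do genes bound by the remodeler (or genes whose
expression changes) lose nucleosome spacing and regularity more than the
rest of the genome?  Groups of per-gene NRL/regularity estimates are
summarized with Tukey boxplot statistics; condition differences of
replicate medians are tested with a two-tailed Welch's t-test; gene sets
with altered NRL are intersected with differential-expression sets via
exact Venn partition counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

# significance stars: * p < 0.05, ** p < 0.01, n.s. otherwise
STAR_THRESHOLDS = ((0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def read_gene_set(path: str | Path, label: str | None = None) -> GeneSet:
    """Read a gene set: one id per line, or a TSV whose first column is ids."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line.split("\t")[0])
    if ids and ids[0].lower() in ("gene_id", "gene", "id"):  # header row
        ids = ids[1:]
    return GeneSet(label=label or Path(path).stem, members=frozenset(ids))


def boxplot_summary(values: Sequence[float]) -> dict:
    """Tukey five-number boxplot summary.

    Quartiles use linear interpolation between order statistics; whiskers
    reach the most extreme data points within 1.5x IQR of the quartiles;
    points beyond the whiskers are counted as outliers.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return {
        "n": int(arr.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(((arr < lo_fence) | (arr > hi_fence)).sum()),
    }


def stars(p_value: float) -> str:
    """Map a p-value to its significance annotation."""
    for threshold, symbol in STAR_THRESHOLDS:
        if p_value < threshold:
            return symbol
    return "n.s."


def welch_test(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-tailed Welch's t-test (unequal variances).

    t = (mean a - mean b) / sqrt(s2_a/n_a + s2_b/n_b) with
    Welch-Satterthwaite degrees of freedom.  Designed for small groups —
    the field convention is to test the two per-replicate median NRLs per
    condition (n=2 per group); a warning is logged below n=3.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; Welch test undefined")
    if min(a.size, b.size) < 3:
        logger.warning(
            "Welch test with n=%d vs n=%d has minimal power", a.size, b.size
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    return {
        "welch_t": float(res.statistic),
        "welch_df": float(res.df),
        "p_value": float(res.pvalue),
        "stars": stars(float(res.pvalue)),
    }


def compare_cohorts(
    stats_wt: pd.DataFrame,
    stats_mut: pd.DataFrame,
    partition: GeneSet,
    metric: str = "nrl_est",
) -> dict:
    """Contrast in-set genes against the rest for a condition pair.

    Splits the shared QC-passing gene universe into partition members and
    complement, returns per-group boxplot summaries for each condition
    and the condition change (mut - wt) of the group medians.
    """
    wt = stats_wt[stats_wt["qc_pass"]].set_index("gene_id")[metric]
    mut = stats_mut[stats_mut["qc_pass"]].set_index("gene_id")[metric]
    universe = wt.index.intersection(mut.index)
    members = [g for g in universe if g in partition.members]
    rest = [g for g in universe if g not in partition.members]
    if not members:
        raise ValueError(f"partition {partition.label!r}: no member genes in universe")
    if not rest:
        raise ValueError(f"partition {partition.label!r}: complement is empty")

    def group(ids: list[str], label: str) -> dict:
        return {
            "label": label,
            "wt": boxplot_summary(wt.loc[ids]),
            "mut": boxplot_summary(mut.loc[ids]),
            "delta_median": float(
                np.median(mut.loc[ids]) - np.median(wt.loc[ids])
            ),
        }

    return {
        "metric": metric,
        "in_set": group(members, partition.label),
        "rest": group(rest, f"not {partition.label}"),
    }


def altered_nrl_set(
    delta_table: pd.DataFrame, threshold: float, label: str = "altered_nrl"
) -> GeneSet:
    """Genes with ``|delta NRL| > threshold`` bp (strict inequality)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    hits = delta_table.loc[
        delta_table["delta_nrl"].abs() > threshold, "gene_id"
    ]
    return GeneSet(label=label, members=frozenset(hits))


def venn_overlap(set_a: GeneSet, set_b: GeneSet, universe: GeneSet) -> dict:
    """Exact two-set Venn partition counts over a fixed gene universe.

    The four counts always partition the universe:
    a_only + b_only + both + neither = |universe|.
    """
    for s in (set_a, set_b):
        outside = s.members - universe.members
        if outside:
            raise ValueError(
                f"set {s.label!r} has members outside the universe: "
                f"{sorted(outside)[:5]}..."
                if len(outside) > 5
                else f"set {s.label!r} has members outside the universe: "
                f"{sorted(outside)}"
            )
    both = set_a.members & set_b.members
    return {
        "a_only": len(set_a.members - set_b.members),
        "b_only": len(set_b.members - set_a.members),
        "both": len(both),
        "neither": len(universe.members - set_a.members - set_b.members),
    }


def replicate_median_test(
    wt_tables: Iterable[pd.DataFrame],
    mut_tables: Iterable[pd.DataFrame],
    metric: str = "nrl_est",
) -> dict:
    """Welch test on per-replicate medians of a per-gene metric.

    Each replicate contributes one number — the median of its QC-passing
    per-gene estimates — and the two conditions' median lists are compared.
    """
    med = lambda df: float(df.loc[df["qc_pass"], metric].median())
    a = [med(t) for t in wt_tables]
    b = [med(t) for t in mut_tables]
    res = welch_test(a, b)
    res.update({"medians_wt": a, "medians_mut": b, "metric": metric})
    return res
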