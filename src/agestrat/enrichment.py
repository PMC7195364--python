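"""Differential-expression filters and age-group enrichment statistics.

The DE call is ``|log2FC| > 1 and FDR < 0.01`` (both strict).  Per age
group the enrichment statistic is the *normalized DE ratio*

    ratio_g = (de_g / n_g) / (de_total / n_total)

i.e. the group's DE fraction over the genome-wide DE fraction, so 1 means
no enrichment and the group-size-weighted mean of the ratios is exactly 1.
Each group is tested against the rest of the measured genome with a
two-sided Fisher's exact test on the 2x2 table

    [[de_g, n_g - de_g], [de_rest, n_rest - de_rest]]

and Benjamini-Hochberg adjusted p-values are reported alongside the raw
ones (the raw two-sided p is the figure-level statistic; BH accounts for
the multiple groups tested per condition).

Also here: the replicate-noise filter (drop genes whose relative standard
deviation sd/mean exceeds 1 in any condition), TPM normalization, the
percentile-bootstrap confidence interval for the median, and cross-condition
overlap counts for shared up-/down-regulated genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ages import AgeAssignment, WGD_LABEL
from .errors import ValidationError
from .io import CountsMatrix, ExpressionTable

__all__ = [
    "DEFlagTable",
    "filter_rsd",
    "flag_de",
    "fisher_two_sided",
    "enrichment_table",
    "overlap_counts",
    "tpm",
    "median_ci",
]


@dataclass(frozen=True)
class DEFlagTable:
    """Per-gene DE flags for one condition.

    ``flags`` has columns gene, is_de, direction; ``is_de`` iff direction
    is "up" or "down".
    """

    condition: str
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.flags
        if missing := {"gene", "is_de", "direction"} - set(df.columns):
            raise ValidationError(f"flag table missing columns {sorted(missing)}")
        if ((df["direction"] != "none") != df["is_de"]).any():
            raise ValidationError("is_de inconsistent with direction")

    def genes_with(self, direction: str) -> set[str]:
        """Genes flagged in a direction: 'up', 'down' or 'any' (either)."""
        if direction == "any":
            return set(self.flags.loc[self.flags["is_de"], "gene"])
        return set(self.flags.loc[self.flags["direction"] == direction, "gene"])


def flag_de(expr: ExpressionTable, lfc_cut: float = 1.0, fdr_cut: float = 0.01) -> DEFlagTable:
    """Flag DE genes at strict cutoffs |log2FC| > lfc_cut and FDR < fdr_cut."""
    df = expr.records
    is_de = (df["log2fc"].abs() > lfc_cut) & (df["fdr"] < fdr_cut)
    direction = np.where(~is_de, "none", np.where(df["log2fc"] > 0, "up", "down"))
    out = pd.DataFrame({"gene": df["gene"], "is_de": is_de, "direction": direction})
    return DEFlagTable(condition=expr.condition, flags=out)


def filter_rsd(
    counts: CountsMatrix,
    threshold: float = 1.0,
    conditions: Sequence[str] | None = None,
) -> set[str]:
    """Genes whose replicate RSD (sample sd / mean) is <= threshold in every
    condition under comparison.  Genes with zero mean in a condition are
    removed (their RSD is undefined)."""
    conds = list(conditions) if conditions is not None else counts.conditions
    keep = pd.Series(True, index=counts.counts.index)
    for cond in conds:
        cols = counts.samples_for(cond)
        if len(cols) < 2:
            raise ValidationError(f"condition {cond!r} has fewer than 2 replicates")
        block = counts.counts[cols]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rsd = sd / mean
        keep &= (mean > 0) & (rsd <= threshold)
    return set(counts.counts.index[keep])


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of every table with
    the same margins whose probability does not exceed that of the observed
    table.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValidationError("Fisher table cells must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def _group_order(labels: Iterable[str], ages: Sequence[AgeAssignment]) -> list[str]:
    """Order groups oldest first (descending rung), WGD last."""
    rung_by_label: dict[str, int] = {}
    for a in ages:
        rung_by_label.setdefault(a.age_group, a.deepest_rung)
    ordered = sorted(
        (lbl for lbl in labels if lbl != WGD_LABEL),
        key=lambda lbl: -rung_by_label[lbl],
    )
    if WGD_LABEL in labels:
        ordered.append(WGD_LABEL)
    return ordered


def enrichment_table(
    ages: Sequence[AgeAssignment],
    flags: DEFlagTable,
    scope: str = "all",
) -> pd.DataFrame:
    """Per-age-group normalized DE ratios with Fisher exact tests.

    ``scope`` selects which flags count as DE: "all" (either direction),
    "up" or "down".  The totals in the normalization cover every measured
    gene with an age assignment.  When no gene is DE the ratio is undefined
    and reported as NaN.
    """
    if scope not in ("all", "up", "down"):
        raise ValidationError(f"unknown scope {scope!r}")
    if not ages:
        raise ValidationError("no age assignments supplied")
    flagged = set(flags.flags["gene"])
    missing = [a.gene for a in ages if a.gene not in flagged]
    if missing:
        raise ValidationError(
            f"gene {missing[0]!r} has an age assignment but no DE flags"
        )
    de_genes = flags.genes_with("any" if scope == "all" else scope)

    members: dict[str, list[str]] = {}
    for a in ages:
        members.setdefault(a.age_group, []).append(a.gene)
    n_total = sum(len(v) for v in members.values())
    de_total = sum(1 for a in ages if a.gene in de_genes)

    rows = []
    for label in _group_order(members, ages):
        genes = members[label]
        n_g = len(genes)
        de_g = sum(1 for g in genes if g in de_genes)
        ratio = (de_g / n_g) / (de_total / n_total) if de_total > 0 else np.nan
        p = fisher_two_sided(
            de_g, n_g - de_g, de_total - de_g, (n_total - n_g) - (de_total - de_g)
        )
        rows.append(
            {
                "condition": flags.condition,
                "group": label,
                "n_group": n_g,
                "de_group": de_g,
                "ratio": ratio,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def overlap_counts(
    flags_by_condition: Sequence[DEFlagTable],
    gene_subset: Iterable[str],
    direction: str = "up",
) -> dict[tuple[str, ...], int]:
    """Counts of genes DE in exactly each non-empty combination of conditions.

    Restricted to ``gene_subset`` (e.g. the young groups IV and V) and to
    one direction ("up" or "down").  The returned counts are disjoint, so
    they sum to the size of the union of the per-condition DE sets.
    """
    if len(flags_by_condition) < 2:
        raise ValidationError("overlap requires at least two conditions")
    if direction not in ("up", "down"):
        raise ValidationError(f"unknown direction {direction!r}")
    subset = set(gene_subset)
    conds = [f.condition for f in flags_by_condition]
    if len(set(conds)) != len(conds):
        raise ValidationError("duplicate condition labels in overlap input")
    sets = {f.condition: f.genes_with(direction) & subset for f in flags_by_condition}

    combos: dict[tuple[str, ...], int] = {}
    for r in range(1, len(conds) + 1):
        for combo in itertools.combinations(conds, r):
            inside = set(subset)
            for c in combo:
                inside &= sets[c]
            for c in conds:
                if c not in combo:
                    inside -= sets[c]
            combos[combo] = len(inside)
    return combos


def tpm(counts: CountsMatrix) -> pd.DataFrame:
    """Transcripts-per-million: per sample, counts are divided by gene
    length (reads per base) and scaled so each column sums to 1e6."""
    rate = counts.counts.div(counts.lengths, axis=0)
    col_sums = rate.sum(axis=0)
    zero = col_sums[col_sums == 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has no reads")
    return rate.div(col_sums, axis=1) * 1e6


def median_ci(
    values: Sequence[float],
    level: float = 0.95,
    reps: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Median with a percentile-bootstrap confidence interval.

    Deterministic given ``seed`` (or a caller-supplied generator).  With a
    single value, or a constant vector, the interval collapses to a point.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("median_ci requires at least one value")
    if not 0 < level < 1:
        raise ValidationError("confidence level must be in (0, 1)")
    med = float(np.median(arr))
    if arr.size == 1 or np.ptp(arr) == 0:
        return med, med, med
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(reps, arr.size))
    meds = np.median(arr[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    return med, float(lo), float(hi)
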