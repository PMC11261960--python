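"""Raw-vs-processed comparison statistics over annotated cell tables.

All statistics operate on tables produced by the phenotyper: scaled marker
columns, a phenotype column (``metacluster`` or ``subcluster``) and the
pipe-joined ``top_markers`` column.  "Positive" throughout means scaled
expression strictly greater than zero, consistent with the rule engine.

Undefined quantities (empty phenotype, zero denominator in a ratio form)
return NaN sentinels rather than raising; a zero out-rate denominator in the
specificity ratio returns +inf.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotype import parse_top_markers

DEFAULT_CONFLICT_PAIRS = {
    "human": [("CD20", "CD4"), ("CD20", "CD8"), ("CD3", "CD20")],
    "mouse": [
        ("B220", "CD4"),
        ("B220", "CD8"),
        ("CD3", "B220"),
        ("CD11c", "CD3"),
        ("CD11c", "B220"),
    ],
}


def positive_rate(
    table: pd.DataFrame,
    phenotype: str,
    marker: str,
    phenotype_col: str = "metacluster",
) -> float:
    """Percent of the phenotype's cells with scaled ``marker`` > 0."""
    cells = table[table[phenotype_col] == phenotype]
    if len(cells) == 0:
        return float("nan")
    return 100.0 * float((cells[marker] > 0).sum()) / len(cells)


def relative_change(
    after: float,
    before: float,
    form: str = "ratio",
    total: float | None = None,
) -> float:
    """Relative change of a percentage/proportion after pre-processing.

    ``form='ratio'`` (default): 100 * (after - before) / before.
    ``form='fig6'``: (after - before) / total, for positive-cell percentages
    normalized by the total raw cell count (the alternate legend convention);
    ``total`` is required.
    """
    if form == "ratio":
        if before == 0:
            return float("nan")
        return 100.0 * (after - before) / before
    if form == "fig6":
        if total is None or total == 0:
            return float("nan")
        return (after - before) / total
    raise ValueError(f"unknown relative-change form {form!r}")


def specificity_ratio(
    table: pd.DataFrame,
    phenotype: str,
    marker: str,
    phenotype_col: str = "metacluster",
) -> float:
    """Positive rate inside the phenotype over the positive rate outside it."""
    inside = positive_rate(table, phenotype, marker, phenotype_col)
    complement = table[table[phenotype_col] != phenotype]
    if len(complement) == 0 or np.isnan(inside):
        return float("nan")
    outside = 100.0 * float((complement[marker] > 0).sum()) / len(complement)
    if outside == 0:
        return float("inf")
    return inside / outside


def median_fold_change(
    raw: pd.DataFrame,
    processed: pd.DataFrame,
    phenotype: str,
    marker: str,
    phenotype_col: str = "metacluster",
) -> float:
    """median(processed expression) / median(raw expression) for a phenotype."""
    raw_cells = raw.loc[raw[phenotype_col] == phenotype, marker]
    proc_cells = processed.loc[processed[phenotype_col] == phenotype, marker]
    if len(raw_cells) == 0 or len(proc_cells) == 0:
        return float("nan")
    raw_median = float(raw_cells.median())
    if raw_median == 0:
        return float("inf")
    return float(proc_cells.median()) / raw_median


def mixed_phenotype_rate(
    table: pd.DataFrame,
    conflict_pairs: list[tuple[str, str]],
) -> dict[tuple[str, str], float]:
    """Percent of all cells whose top-k contains both markers of a pair with
    both scaled values positive (cells expressing high levels of two
    different lineage markers)."""
    n = len(table)
    rates: dict[tuple[str, str], float] = {}
    if n == 0:
        return {tuple(pair): float("nan") for pair in conflict_pairs}
    tops = parse_top_markers(table["top_markers"])
    for a, b in conflict_pairs:
        pos_a = table[a].to_numpy() > 0
        pos_b = table[b].to_numpy() > 0
        count = sum(
            1
            for i, top in enumerate(tops)
            if a in top and b in top and pos_a[i] and pos_b[i]
        )
        rates[(a, b)] = 100.0 * count / n
    return rates


def composition(
    table: pd.DataFrame,
    phenotype_col: str = "metacluster",
    sample_col: str = "sample_id",
) -> tuple[pd.Series, pd.Series]:
    """Per-phenotype percent of all cells, and the median across samples of
    per-sample proportions.  The overall percentages sum to 100."""
    overall = 100.0 * table[phenotype_col].value_counts(normalize=True)
    overall.name = "percent"
    per_sample = (
        table.groupby(sample_col)[phenotype_col]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    median_prop = per_sample.median(axis=0)
    median_prop.name = "median_proportion"
    return overall, median_prop


def compare_datasets(
    raw: pd.DataFrame,
    processed: pd.DataFrame,
    markers: list[str],
    conflict_pairs: list[tuple[str, str]],
    phenotype_col: str = "metacluster",
) -> dict:
    """The full report: per-(phenotype, marker) positive rates and relative
    changes, per-phenotype specificity ratios and median fold changes, and
    mixed-phenotype rates per conflict pair for both datasets."""
    phenotypes = sorted(
        set(raw[phenotype_col].unique()) | set(processed[phenotype_col].unique())
    )
    report: dict = {
        "phenotypes": phenotypes,
        "positive_rates": {},
        "relative_changes": {},
        "specificity_ratios": {},
        "median_fold_changes": {},
        "mixed_phenotype_rates": {
            "raw": {
                f"{a}+{b}": v
                for (a, b), v in mixed_phenotype_rate(raw, conflict_pairs).items()
            },
            "processed": {
                f"{a}+{b}": v
                for (a, b), v in mixed_phenotype_rate(processed, conflict_pairs).items()
            },
        },
        "relative_change_form": "ratio",
    }
    for phenotype in phenotypes:
        for marker in markers:
            key = f"{phenotype}::{marker}"
            before = positive_rate(raw, phenotype, marker, phenotype_col)
            after = positive_rate(processed, phenotype, marker, phenotype_col)
            report["positive_rates"][key] = {"raw": before, "processed": after}
            report["relative_changes"][key] = relative_change(after, before)
            report["specificity_ratios"][key] = {
                "raw": specificity_ratio(raw, phenotype, marker, phenotype_col),
                "processed": specificity_ratio(processed, phenotype, marker, phenotype_col),
            }
            report["median_fold_changes"][key] = median_fold_change(
                raw, processed, phenotype, marker, phenotype_col
            )
    return report
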