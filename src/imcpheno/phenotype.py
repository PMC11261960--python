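"""Scaling, marker ranking and rule-based metacluster assignment.

The supervised stage of the two-stage phenotyper: raw per-cell mean
intensities are variance-stabilized with an inverse hyperbolic sine
(``asinh(x / cofactor)``, cytometry convention, cofactor 5 by default) and
z-scored per channel; each cell is summarized by its top-k ranked markers and
its dominant lineage marker; an ordered :class:`~imcpheno.rules.RuleSet` then
assigns a metacluster label to every cell, with a negative-selection fallback
for cells matching no rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError
from .rules import COMPARATORS, RuleSet

TOPK_SEPARATOR = "|"


def transform_scale(
    cells: pd.DataFrame,
    markers: list[str],
    cofactor: float = 5.0,
    method: str = "asinh",
) -> pd.DataFrame:
    """asinh-transform then per-channel z-score the marker columns.

    Returns a copy of ``cells`` with marker columns replaced by scaled values;
    all other columns pass through.  Zero-variance channels standardize to 0
    rather than NaN.  ``method='arcsin'`` applies a literal arcsine to inputs
    clipped into [0, 1] (fidelity option); the default is the inverse
    hyperbolic sine.
    """
    if cofactor <= 0:
        raise ParameterError("cofactor must be > 0")
    if method not in ("asinh", "arcsin"):
        raise ParameterError(f"unknown transform method {method!r}")
    out = cells.copy()
    values = out[markers].to_numpy(dtype=float)
    if method == "asinh":
        transformed = np.arcsinh(values / cofactor)
    else:
        transformed = np.arcsin(np.clip(values, 0.0, 1.0))
    mean = transformed.mean(axis=0)
    sd = transformed.std(axis=0)
    live = sd > 1e-10 * (np.abs(mean) + 1.0)  # constant channels -> all zero
    scaled = np.where(live, (transformed - mean) / np.where(live, sd, 1.0), 0.0)
    out[markers] = scaled
    return out


def pooled_transform_scale(
    tables: list[pd.DataFrame],
    markers: list[str],
    cofactor: float = 5.0,
) -> list[pd.DataFrame]:
    """Scale several tables with channel statistics pooled across all of them.

    Used for raw-vs-processed comparisons ("standardized after integration"):
    both datasets share one mean/sd per channel so their scaled values are on
    a common footing.
    """
    if cofactor <= 0:
        raise ParameterError("cofactor must be > 0")
    pooled = np.arcsinh(
        np.concatenate([t[markers].to_numpy(dtype=float) for t in tables]) / cofactor
    )
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    live = sd > 1e-10 * (np.abs(mean) + 1.0)
    outs = []
    for t in tables:
        out = t.copy()
        transformed = np.arcsinh(out[markers].to_numpy(dtype=float) / cofactor)
        out[markers] = np.where(
            live, (transformed - mean) / np.where(live, sd, 1.0), 0.0
        )
        outs.append(out)
    return outs


def _rank_order(scaled: pd.DataFrame, markers: list[str]) -> np.ndarray:
    """Per-cell marker indices in descending scaled order; ties break by the
    position of the marker in ``markers`` (stable sort on the negated values)."""
    values = scaled[markers].to_numpy(dtype=float)
    return np.argsort(-values, axis=1, kind="stable")


def rank_top_markers(scaled: pd.DataFrame, markers: list[str], k: int = 3) -> list[tuple[str, ...]]:
    """The k highest-expressing markers per cell, in descending order."""
    if k < 1 or k > len(markers):
        raise ParameterError(f"k must be in [1, {len(markers)}], got {k}")
    order = _rank_order(scaled, markers)[:, :k]
    names = np.asarray(markers, dtype=object)
    return [tuple(names[row]) for row in order]


def dominant_lineage(scaled: pd.DataFrame, lineage_markers: list[str]) -> pd.Series:
    """The lineage marker with the highest scaled expression per cell.

    Ties break toward the earlier marker in ``lineage_markers`` (argmax takes
    the first maximum), so pass the list in panel order.
    """
    if not lineage_markers:
        raise ParameterError("lineage marker list must be non-empty")
    values = scaled[lineage_markers].to_numpy(dtype=float)
    idx = np.argmax(values, axis=1)
    names = np.asarray(lineage_markers, dtype=object)
    return pd.Series(names[idx], index=scaled.index, name="lineage_marker")


def assign_metaclusters(
    scaled: pd.DataFrame,
    ruleset: RuleSet,
    markers: list[str],
    k: int | None = None,
) -> pd.DataFrame:
    """Evaluate the rule set in order and label every cell.

    Returns a copy of ``scaled`` with three added columns: ``lineage_marker``,
    ``top_markers`` (pipe-joined, at the rule set's global k) and
    ``metacluster``.  Assignment is total (fallback) and deterministic.
    """
    ruleset.validate(markers)
    k = k if k is not None else ruleset.rank_k
    out = scaled.copy()
    n = len(out)
    order = _rank_order(out, markers)
    marker_index = {m: i for i, m in enumerate(markers)}

    # membership[i, j] == True iff marker j is among cell i's top-k_r markers;
    # built lazily per distinct k (rules may override, e.g. top-5 macrophages).
    membership_cache: dict[int, np.ndarray] = {}

    def membership(k_r: int) -> np.ndarray:
        if k_r not in membership_cache:
            memb = np.zeros((n, len(markers)), dtype=bool)
            rows = np.repeat(np.arange(n), k_r)
            memb[rows, order[:, :k_r].ravel()] = True
            membership_cache[k_r] = memb
        return membership_cache[k_r]

    lineage = dominant_lineage(out, ruleset.lineage_markers)
    labels = np.full(n, None, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in ruleset.rules:
        if not unassigned.any():
            break
        match = unassigned.copy()
        if rule.lineage_marker is not None:
            match &= (lineage == rule.lineage_marker).to_numpy()
        for marker, cmp, threshold in rule.conditions:
            match &= COMPARATORS[cmp](out[marker].to_numpy(dtype=float), threshold)
        k_r = rule.rank_k if rule.rank_k is not None else k
        memb = membership(k_r)
        if rule.topk_exclude:
            cols = [marker_index[m] for m in rule.topk_exclude]
            match &= ~memb[:, cols].any(axis=1)
        if rule.topk_require:
            cols = [marker_index[m] for m in rule.topk_require]
            match &= memb[:, cols].any(axis=1)
        labels[match] = rule.label
        unassigned &= ~match
    labels[unassigned] = ruleset.fallback_label

    names = np.asarray(markers, dtype=object)
    out["lineage_marker"] = lineage
    out["top_markers"] = [
        TOPK_SEPARATOR.join(names[row]) for row in order[:, :k]
    ]
    out["metacluster"] = labels
    return out


def split_by_threshold(
    subset: pd.DataFrame, marker: str, threshold: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (scaled value > threshold) and (<= threshold) branches."""
    above = subset[subset[marker] > threshold]
    below = subset[subset[marker] <= threshold]
    return above, below


def parse_top_markers(series: pd.Series) -> list[tuple[str, ...]]:
    """Inverse of the pipe-joined ``top_markers`` column."""
    return [tuple(s.split(TOPK_SEPARATOR)) if s else () for s in series]
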