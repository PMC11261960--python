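"""Independent brute-force reference implementations used only by the tests.

Each function re-derives an operator's contract with explicit per-pixel
loops (and, for the rule engine, literal per-cell rule evaluation), sharing
no code with the package implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def _reflect_pad(img: np.ndarray, pad: int) -> np.ndarray:
    # "symmetric" padding == scipy.ndimage mode="reflect" (d c b a | a b c d)
    return np.pad(img, pad, mode="symmetric") if pad > 0 else img.copy()


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.array([math.exp(-(xi**2) / (2.0 * sigma**2)) for xi in x])
    return k / k.sum()


def gaussian_smooth_oracle(img: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return img.copy()
    k = gaussian_kernel_1d(sigma)
    radius = (len(k) - 1) // 2
    padded = _reflect_pad(np.asarray(img, dtype=float), radius)
    h, w = img.shape
    tmp = np.zeros((h, w + 2 * radius))
    for i in range(h):
        for j in range(w + 2 * radius):
            tmp[i, j] = sum(k[t] * padded[i + t, j] for t in range(len(k)))
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = sum(k[t] * tmp[i, j + t] for t in range(len(k)))
    return out


def cap_oracle(img: np.ndarray, cap: float) -> np.ndarray:
    out = np.asarray(img, dtype=float).copy()
    for idx in np.ndindex(out.shape):
        if out[idx] > cap:
            out[idx] = cap
    return out


def binarize_oracle(img: np.ndarray, threshold: float) -> np.ndarray:
    out = np.zeros_like(np.asarray(img, dtype=float))
    for idx in np.ndindex(out.shape):
        out[idx] = 1.0 if img[idx] > threshold else 0.0
    return out.astype(np.uint8)


def spillover_oracle(target: np.ndarray, mask: np.ndarray, removal: float) -> np.ndarray:
    out = np.asarray(target, dtype=float).copy()
    for idx in np.ndindex(out.shape):
        if mask[idx] > 0:
            out[idx] = max(out[idx] - removal, 0.0)
    return out


def denoise_oracle(img: np.ndarray, floor: float, window: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    floored = img.copy()
    for idx in np.ndindex(img.shape):
        if img[idx] < floor:
            floored[idx] = 0.0
    pad = window // 2
    padded = _reflect_pad(floored, pad)
    out = np.zeros_like(floored)
    h, w = img.shape
    for i in range(h):
        for j in range(w):
            local_mean = padded[i : i + window, j : j + window].mean()
            out[i, j] = floored[i, j] if local_mean > 0 else 0.0
    return out


def _flood_components(mask: np.ndarray, connectivity: int) -> list[list[tuple[int, int]]]:
    h, w = mask.shape
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros((h, w), dtype=bool)
    components = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = []
                while stack:
                    a, b = stack.pop()
                    comp.append((a, b))
                    for da, db in steps:
                        na, nb = a + da, b + db
                        if 0 <= na < h and 0 <= nb < w and mask[na, nb] and not seen[na, nb]:
                            seen[na, nb] = True
                            stack.append((na, nb))
                components.append(comp)
    return components


def remove_aggregates_oracle(
    img: np.ndarray,
    blur_radius: float,
    binarize_threshold: float,
    size_threshold: int,
    connectivity: int = 8,
) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    blurred = gaussian_smooth_oracle(img, blur_radius)
    mask = blurred > binarize_threshold
    out = img.copy()
    for comp in _flood_components(mask, connectivity):
        if len(comp) < size_threshold:
            for i, j in comp:
                out[i, j] = 0.0
    return out


def assign_metaclusters_oracle(scaled_df, ruleset, markers, k):
    """Literal per-cell, rule-by-rule evaluation of the metacluster contract."""
    import operator as _op

    comparators = {">": _op.gt, ">=": _op.ge, "<": _op.lt, "<=": _op.le}
    labels = []
    for _, row in scaled_df.iterrows():
        values = {m: float(row[m]) for m in markers}
        lineage = max(
            ruleset.lineage_markers,
            key=lambda m: (values[m], -ruleset.lineage_markers.index(m)),
        )
        # panel-order tie-break: earliest lineage marker with the max value
        best = max(values[m] for m in ruleset.lineage_markers)
        lineage = next(m for m in ruleset.lineage_markers if values[m] == best)
        label = None
        for rule in ruleset.rules:
            if rule.lineage_marker is not None and lineage != rule.lineage_marker:
                continue
            if not all(comparators[c](values[m], t) for m, c, t in rule.conditions):
                continue
            k_r = rule.rank_k if rule.rank_k is not None else k
            ranked = sorted(markers, key=lambda m: (-values[m], markers.index(m)))
            top = set(ranked[:k_r])
            if rule.topk_exclude & top:
                continue
            if rule.topk_require and not (rule.topk_require & top):
                continue
            label = rule.label
            break
        labels.append(label if label is not None else ruleset.fallback_label)
    return labels
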