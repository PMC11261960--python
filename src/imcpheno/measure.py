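"""Single-cell measurement from an image stack plus an integer label mask.

This is the segmentation adapter: segmentation itself (Mesmer, Ilastik,
CellProfiler) is external and arrives here as a label mask (0 = background,
k > 0 = cell id).  Per cell we record the arithmetic mean of each channel over
the cell's pixels, the pixel-count area and the unweighted centroid, yielding
the expression/morphology table everything downstream consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import regionprops_table

from .errors import DimensionError, ParameterError
from .imclean import ImageStack

ID_COLUMNS = ["cell_id", "roi_id", "sample_id", "condition", "area", "centroid_row", "centroid_col"]


@dataclass
class LabelMask:
    """Integer cell-label grid sharing the ROI's channel dimensions."""

    labels: np.ndarray
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DimensionError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ParameterError("label mask must be integer-valued")
        if self.labels.min() < 0:
            raise ParameterError("label mask must be non-negative")


def measure_cells(
    stack: ImageStack,
    mask: LabelMask | np.ndarray,
    sample_id: str = "",
    condition: str = "",
) -> pd.DataFrame:
    """One row per positive label: per-marker mean intensity + morphology.

    An empty mask yields an empty (but well-formed) table, not an error.
    """
    if isinstance(mask, np.ndarray):
        mask = LabelMask(labels=mask)
    if mask.labels.shape != stack.shape:
        raise DimensionError(
            f"mask shape {mask.labels.shape} != stack shape {stack.shape}"
        )
    markers = list(stack.panel)
    roi_id = mask.roi_id or stack.roi_id
    if mask.labels.max() == 0:
        return pd.DataFrame(columns=ID_COLUMNS + markers)
    intensity = np.moveaxis(stack.pixels(), 0, -1)  # (rows, cols, channels)
    props = regionprops_table(
        mask.labels,
        intensity_image=intensity,
        properties=("label", "area", "centroid", "intensity_mean"),
    )
    table = pd.DataFrame(
        {
            "cell_id": props["label"].astype(int),
            "roi_id": roi_id,
            "sample_id": sample_id,
            "condition": condition,
            "area": props["area"].astype(int),
            "centroid_row": props["centroid-0"],
            "centroid_col": props["centroid-1"],
        }
    )
    for i, marker in enumerate(markers):
        table[marker] = props[f"intensity_mean-{i}"]
    return table.sort_values("cell_id").reset_index(drop=True)


def spatial_neighbors(mask: LabelMask | np.ndarray, max_distance: float) -> set[tuple[int, int]]:
    """Unordered pairs of cell ids whose centroids lie within ``max_distance``."""
    if max_distance <= 0:
        raise ParameterError("max_distance must be > 0")
    if isinstance(mask, np.ndarray):
        mask = LabelMask(labels=mask)
    if mask.labels.max() == 0:
        return set()
    props = regionprops_table(mask.labels, properties=("label", "centroid"))
    ids = props["label"].astype(int)
    centroids = np.column_stack([props["centroid-0"], props["centroid-1"]])
    if len(ids) < 2:
        return set()
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(r=max_distance)
    return {tuple(sorted((int(ids[i]), int(ids[j])))) for i, j in pairs}
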