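"""Ground-truth synthetic multiplexed-tissue data.

Two generators back the test and acceptance suites:

* :func:`simulate_roi` renders a full ROI -- disk-shaped cells with
  phenotype-specific Poisson ion counts, additive channel crosstalk
  (Poisson-thinned fraction of a source channel), sparse low-intensity
  background speckles, and small high-intensity aggregate blobs -- together
  with the matching label mask, a per-cell truth table and a complete
  artifact log;
* :func:`simulate_expression_table` skips rendering and draws per-cell marker
  means directly (signature mean + Gaussian noise, optional mixed-phenotype
  contamination), for fast clustering/metrics fixtures.

Design notes.  Cells are rasterized disks placed with a one-pixel gap;
every pixel inside a cell receives a small constant pedestal on top of its
Poisson draw so that each cell body is one fully 8-connected positive
component in every channel (logged truth means include the pedestal).
Aggregates are 1-6 px blobs placed with a one-pixel margin from cells and
from each other, and background speckles avoid aggregate neighborhoods, so
each aggregate is its own connected component: size-thresholding separates
artifacts from cells exactly, and the artifact log is sufficient to verify
removal pixel-by-pixel.  Identical seed and config reproduce a byte-identical
ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk

from .errors import ConfigurationError, PlacementError
from .imclean import ChannelImage, ImageStack, build_stack
from .io import PreprocessSettings
from .measure import LabelMask

# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


@dataclass
class SignatureMatrix:
    """Per-phenotype mean intensity per marker plus prevalence weights."""

    means: pd.DataFrame  # index = phenotype, columns = markers
    weights: pd.Series  # index = phenotype, sums to 1

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ConfigurationError("phenotype prevalence weights must sum to 1")
        if list(self.means.index) != list(self.weights.index):
            raise ConfigurationError("means and weights must list the same phenotypes")
        if self.means.isna().any().any() or (self.means < 0).any().any():
            raise ConfigurationError("signature means must be non-negative and complete")

    @property
    def phenotypes(self) -> list[str]:
        return list(self.means.index)

    @property
    def markers(self) -> list[str]:
        return list(self.means.columns)

    def lineage_of(self, phenotype: str) -> str:
        """The marker with the highest mean for a phenotype (its lineage proxy)."""
        return str(self.means.loc[phenotype].idxmax())


HUMAN_PANEL = [
    "CD4", "CD8", "CD20", "CD68", "CD163", "CD11b", "CD66b", "CD31", "CK7",
    "CD138", "CD3", "CD45", "CD45RO", "HLADR", "CD16", "CD28", "CD11c",
    "Ki67", "FoxP3", "PD1", "GranzymeB", "CD57",
]

MOUSE_PANEL = [
    "CD3", "CD4", "CD8", "B220", "CD68", "CD11c", "F480", "CD206", "CD11b",
    "Ly6G", "MHCII", "CD161", "CD31", "CD29", "Ecad", "aSMA", "CD45", "PD1",
    "FoxP3", "Ki67", "GranzymeB", "PDL1", "CD86", "S100A9", "S100A4",
]

_BASELINE = 0.5

# Stylized human liver signatures: each of the 10 phenotypes is keyed to one
# of the 10 lineage markers of the default rule tree (hepatocytes are the
# negative-selection phenotype and stay at baseline everywhere).
_HUMAN_SIGNATURES = {
    "CD4+ T-cells": {"CD4": 22, "CD3": 20, "CD45": 14},
    "CD8+ T-cells": {"CD8": 22, "CD3": 20, "CD45": 12, "GranzymeB": 1.0},
    "B cells": {"CD20": 24, "CD45": 14, "HLADR": 12, "Ki67": 2},
    # Kupffer-like tissue-resident macrophages: CD11b-low
    "Macrophages": {
        "CD68": 26, "CD163": 14, "CD16": 8, "HLADR": 10, "CD45": 12,
        "CD11c": 4, "CD45RO": 3,
    },
    "Monocytes": {
        "CD11b": 22, "CD16": 10, "CD45": 14, "HLADR": 8, "CD11c": 8,
        "CD45RO": 3, "GranzymeB": 1.5,
    },
    "Plasma cells": {"CD138": 26, "CD45": 12, "HLADR": 6},
    "Neutrophils": {"CD66b": 24, "CD11b": 10, "CD16": 8, "CD45": 12, "GranzymeB": 2},
    "Endothelial cells": {"CD31": 24, "CD57": 2},
    "Cholangiocytes": {"CK7": 24, "HLADR": 3, "Ki67": 3},
    "Hepatocytes": {"Ki67": 1.5},
}

_HUMAN_WEIGHTS = {
    "CD4+ T-cells": 0.14,
    "CD8+ T-cells": 0.12,
    "B cells": 0.10,
    "Macrophages": 0.12,
    "Monocytes": 0.08,
    "Plasma cells": 0.06,
    "Neutrophils": 0.08,
    "Endothelial cells": 0.08,
    "Cholangiocytes": 0.07,
    "Hepatocytes": 0.15,
}

_MOUSE_SIGNATURES = {
    "CD4+ T-cells": {"CD4": 22, "CD3": 20, "CD45": 14},
    "CD8+ T-cells": {"CD8": 22, "CD3": 20, "CD45": 12, "GranzymeB": 1.5},
    "NK cells": {"CD161": 20, "GranzymeB": 6, "CD3": 4, "CD45": 10},
    "B cells": {"B220": 24, "CD45": 14, "MHCII": 10},
    "Dendritic cells": {"CD11c": 22, "MHCII": 14, "CD86": 6, "CD11b": 6, "CD45": 12},
    "Macrophages": {
        "CD68": 24, "F480": 20, "CD206": 10, "CD11b": 6, "MHCII": 10, "CD45": 12,
    },
    "PMNs": {"Ly6G": 24, "CD11b": 10, "S100A9": 10, "CD45": 10},
    "Myofibroblasts": {"aSMA": 24, "CD29": 12, "S100A4": 6},
    "Epithelial cells": {"Ecad": 24, "CD29": 10, "Ki67": 2},
    "Endothelial cells": {"CD31": 24, "CD29": 8},
    "Other non-immune": {"CD29": 3},
}

_MOUSE_WEIGHTS = {
    "CD4+ T-cells": 0.10,
    "CD8+ T-cells": 0.10,
    "NK cells": 0.05,
    "B cells": 0.08,
    "Dendritic cells": 0.07,
    "Macrophages": 0.15,
    "PMNs": 0.07,
    "Myofibroblasts": 0.08,
    "Epithelial cells": 0.10,
    "Endothelial cells": 0.08,
    "Other non-immune": 0.12,
}


def _build_signatures(panel, spec, weights) -> SignatureMatrix:
    means = pd.DataFrame(_BASELINE, index=list(spec), columns=panel, dtype=float)
    for phenotype, entries in spec.items():
        for marker, value in entries.items():
            means.loc[phenotype, marker] = float(value)
    return SignatureMatrix(means=means, weights=pd.Series(weights, dtype=float))


def default_human_signatures() -> SignatureMatrix:
    return _build_signatures(HUMAN_PANEL, _HUMAN_SIGNATURES, _HUMAN_WEIGHTS)


def default_mouse_signatures() -> SignatureMatrix:
    return _build_signatures(MOUSE_PANEL, _MOUSE_SIGNATURES, _MOUSE_WEIGHTS)


def default_panel(species: str = "human") -> pd.DataFrame:
    markers = HUMAN_PANEL if species == "human" else MOUSE_PANEL
    sig = default_human_signatures() if species == "human" else default_mouse_signatures()
    lineage = {sig.lineage_of(p) for p in sig.phenotypes if sig.means.loc[p].max() > _BASELINE}
    return pd.DataFrame(
        {
            "channel": range(1, len(markers) + 1),
            "marker": markers,
            "lineage_flag": [int(m in lineage) for m in markers],
        }
    )


# Channel crosstalk injected into the human image fixtures: the dominant
# macrophage channel contaminates the other lineage channels (the classic
# source used for whole-dataset correction), the endothelial channel leaks
# into the macrophage channels, and the T-cell channels leak into CD20 --
# together these produce both inflated off-phenotype positive rates and
# mixed B/T-cell top-marker phenotypes in the raw branch.
DEFAULT_HUMAN_SPILLOVER: dict[str, dict[str, float]] = {
    "CD68": {
        "CD3": 0.5, "CD4": 0.5, "CD8": 0.5, "CD20": 0.5, "CD11b": 0.5,
        "CD66b": 0.5, "CD31": 0.5, "CK7": 0.5, "CD138": 0.5,
    },
    "CD31": {"CD68": 0.4, "CD163": 0.4},
    "CD4": {"CD20": 0.6},
    "CD8": {"CD20": 0.6},
}

# 1..6-pixel blob footprints used for aggregates (row, col offsets).
_BLOB_SHAPES = {
    1: [(0, 0)],
    2: [(0, 0), (0, 1)],
    3: [(0, 0), (0, 1), (1, 0)],
    4: [(0, 0), (0, 1), (1, 0), (1, 1)],
    5: [(0, 0), (0, 1), (1, 0), (1, 1), (0, 2)],
    6: [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)],
}


@dataclass
class ROIConfig:
    """Rendering parameters of one synthetic ROI."""

    shape: tuple[int, int] = (224, 224)
    n_cells: int = 200
    radius_range: tuple[int, int] = (4, 6)
    signatures: SignatureMatrix = field(default_factory=default_human_signatures)
    spillover: dict[str, dict[str, float]] = field(default_factory=dict)
    background_rate: float = 0.02
    background_mean: float = 1.0
    aggregates_per_channel: int = 25
    aggregate_size_range: tuple[int, int] = (1, 6)
    aggregate_amplitude: float = 60.0
    cell_pedestal: float = 0.5
    roi_id: str = "sim"
    max_attempts: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.aggregate_size_range
        if lo < 1 or hi > 6 or lo > hi:
            raise ConfigurationError("aggregate sizes must lie in [1, 6]")
        for src, targets in self.spillover.items():
            if src not in self.signatures.markers:
                raise ConfigurationError(f"spillover source {src!r} not in panel")
            for tgt in targets:
                if tgt not in self.signatures.markers:
                    raise ConfigurationError(f"spillover target {tgt!r} not in panel")


@dataclass
class SyntheticROI:
    stack: ImageStack
    mask: LabelMask
    truth: pd.DataFrame
    aggregates: dict[str, list[dict]]
    config: ROIConfig
    seed: int

    def aggregate_pixel_index(self, marker: str) -> tuple[np.ndarray, np.ndarray]:
        """All logged aggregate pixel coordinates of one channel."""
        rows, cols = [], []
        for blob in self.aggregates.get(marker, []):
            rows.extend(blob["rows"])
            cols.extend(blob["cols"])
        return np.asarray(rows, dtype=int), np.asarray(cols, dtype=int)


def _place_cells(config: ROIConfig, rng: np.random.Generator):
    H, W = config.shape
    lo, hi = config.radius_range
    centers: list[tuple[int, int, int]] = []  # (row, col, radius)
    for i in range(config.n_cells):
        for _ in range(config.max_attempts):
            r = int(rng.integers(lo, hi + 1))
            row = int(rng.integers(r + 1, H - r - 1))
            col = int(rng.integers(r + 1, W - r - 1))
            if all(
                (row - r2[0]) ** 2 + (col - r2[1]) ** 2 > (r + r2[2] + 1) ** 2
                for r2 in centers
            ):
                centers.append((row, col, r))
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{config.n_cells} after "
                f"{config.max_attempts} attempts; reduce n_cells or radii"
            )
    return centers


def simulate_roi(config: ROIConfig, seed: int = 0) -> SyntheticROI:
    """Render one ROI: channels, label mask, truth table and artifact log."""
    rng = np.random.default_rng(seed)
    H, W = config.shape
    sig = config.signatures
    markers = sig.markers
    phenotype_names = sig.phenotypes

    centers = _place_cells(config, rng)
    assigned = rng.choice(
        len(phenotype_names), size=len(centers), p=sig.weights.to_numpy()
    )
    mask = np.zeros((H, W), dtype=np.int32)
    footprints = []
    for cell_id, (row, col, r) in enumerate(centers, start=1):
        rr, cc = disk((row, col), r + 0.5, shape=(H, W))
        mask[rr, cc] = cell_id
        footprints.append((rr, cc))

    cell_mask = mask > 0
    struct8 = np.ones((3, 3), dtype=bool)
    cell_zone = ndimage.binary_dilation(cell_mask, structure=struct8)

    # phenotype mean image per marker, Poisson emission + pedestal inside cells
    channels: dict[str, np.ndarray] = {}
    for j, marker in enumerate(markers):
        mean_img = np.zeros((H, W))
        for cell_idx, (rr, cc) in enumerate(footprints):
            mean_img[rr, cc] = sig.means.iloc[assigned[cell_idx], j]
        img = np.zeros((H, W))
        inside = cell_mask
        img[inside] = rng.poisson(mean_img[inside]).astype(float) + config.cell_pedestal
        channels[marker] = img

    # channel crosstalk: Poisson-thinned fraction of the pre-spill source
    pre_spill = {m: channels[m].copy() for m in config.spillover}
    for src, targets in config.spillover.items():
        for tgt, alpha in targets.items():
            channels[tgt] = channels[tgt] + rng.poisson(alpha * pre_spill[src])

    # aggregates: small bright blobs, one connected component each,
    # never adjacent to a cell or another aggregate of the same channel
    aggregates: dict[str, list[dict]] = {m: [] for m in markers}
    lo, hi = config.aggregate_size_range
    for marker in markers:
        agg_zone = np.zeros((H, W), dtype=bool)
        for _ in range(config.aggregates_per_channel):
            placed = False
            for _ in range(config.max_attempts):
                size = int(rng.integers(lo, hi + 1))
                offsets = _BLOB_SHAPES[size]
                row = int(rng.integers(1, H - 3))
                col = int(rng.integers(1, W - 4))
                rr = np.array([row + dr for dr, dc in offsets])
                cc = np.array([col + dc for dr, dc in offsets])
                region = (slice(rr.min() - 1, rr.max() + 2), slice(cc.min() - 1, cc.max() + 2))
                if cell_zone[region].any() or agg_zone[region].any():
                    continue
                values = rng.poisson(config.aggregate_amplitude, size=size) + 1.0
                channels[marker][rr, cc] = values
                blob_mask = np.zeros((H, W), dtype=bool)
                blob_mask[rr, cc] = True
                agg_zone |= ndimage.binary_dilation(blob_mask, structure=struct8)
                aggregates[marker].append(
                    {"rows": rr.tolist(), "cols": cc.tolist(), "size": size,
                     "amplitude": values.tolist()}
                )
                placed = True
                break
            if not placed:
                break  # image too crowded for more aggregates; log stays exact

        # sparse low-intensity background off cells and away from aggregates
        if config.background_rate > 0:
            allowed = ~cell_mask & ~ndimage.binary_dilation(agg_zone, structure=struct8)
            candidates = np.flatnonzero(allowed)
            n_bg = min(int(round(config.background_rate * H * W)), len(candidates))
            chosen = rng.choice(candidates, size=n_bg, replace=False)
            values = rng.poisson(config.background_mean, size=n_bg) + 1.0
            flat = channels[marker].ravel()
            flat[chosen] = values
            channels[marker] = flat.reshape(H, W)

    stack = build_stack(
        [ChannelImage(pixels=channels[m], marker=m, roi_id=config.roi_id) for m in markers],
        markers,
    )
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(centers) + 1),
            "phenotype": [phenotype_names[i] for i in assigned],
            "centroid_row": [c[0] for c in centers],
            "centroid_col": [c[1] for c in centers],
            "radius": [c[2] for c in centers],
        }
    )
    for j, marker in enumerate(markers):
        truth[f"mean_{marker}"] = (
            sig.means.iloc[assigned, j].to_numpy() + config.cell_pedestal
        )
    return SyntheticROI(
        stack=stack,
        mask=LabelMask(labels=mask, roi_id=config.roi_id),
        truth=truth,
        aggregates=aggregates,
        config=config,
        seed=seed,
    )


def recommended_settings(config: ROIConfig) -> PreprocessSettings:
    """Artifact-correction settings matched to a synthetic ROI's generative
    parameters: one spillover entry per (source, coefficient) with the removal
    value set to coefficient x peak source signature mean, a floor threshold
    just above the background speckle mode, and exact (blur 0) aggregate
    removal sized above the largest possible blob."""
    spill_entries = []
    for src, targets in config.spillover.items():
        peak = float(config.signatures.means[src].max())
        by_alpha: dict[float, list[str]] = {}
        for tgt, alpha in targets.items():
            by_alpha.setdefault(alpha, []).append(tgt)
        for alpha, tgts in by_alpha.items():
            spill_entries.append(
                {
                    "source": src,
                    "targets": sorted(tgts),
                    "cap_threshold": 20.0,
                    "gauss_radius": 1.0,
                    "binarize_threshold": 3.0,
                    "removal_value": alpha * peak,
                }
            )
    return PreprocessSettings(
        {
            "default": {
                "spillover": spill_entries,
                "noise": {"floor_threshold": 1.5, "window_size": 3},
                "aggregates": {
                    "blur_radius": 0.0,
                    "binarize_threshold": 0.0,
                    "size_threshold": config.aggregate_size_range[1] + 2,
                    "connectivity": 8,
                },
            }
        }
    )


def simulate_expression_table(
    n_cells: int,
    signatures: SignatureMatrix,
    noise_sd: float = 1.0,
    contamination: float = 0.05,
    seed: int = 0,
    n_samples: int = 4,
    roi_id: str = "sim",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cell table directly: mean + Gaussian noise, clipped at zero.

    The noise is heteroscedastic in the ion-counting sense: the sd of a
    marker's draw is ``noise_sd * sqrt(mean)``, so ``noise_sd = 1`` matches
    Poisson variance and larger values model additional technical spread.
    A ``contamination`` fraction of cells receives a second phenotype's
    lineage marker added at full strength (mixed-phenotype ground truth).
    Returns ``(cells, truth)``; truth lists the planted phenotype and, for
    contaminated cells, the donor phenotype.
    """
    rng = np.random.default_rng(seed)
    phenotypes = signatures.phenotypes
    markers = signatures.markers
    assigned = rng.choice(len(phenotypes), size=n_cells, p=signatures.weights.to_numpy())
    means = signatures.means.to_numpy()[assigned]
    values = means + rng.normal(0.0, 1.0, size=means.shape) * noise_sd * np.sqrt(means)
    values = np.clip(values, 0.0, None)

    donors = np.full(n_cells, -1)
    if contamination > 0:
        n_cont = int(round(contamination * n_cells))
        contaminated = rng.choice(n_cells, size=n_cont, replace=False)
        marker_index = {m: i for i, m in enumerate(markers)}
        for i in contaminated:
            choices = [p for p in range(len(phenotypes)) if p != assigned[i]]
            donor = int(rng.choice(choices))
            donors[i] = donor
            lineage = signatures.lineage_of(phenotypes[donor])
            values[i, marker_index[lineage]] += float(
                signatures.means.iloc[donor][lineage]
            )

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "roi_id": roi_id,
            "sample_id": [f"S{1 + int(s)}" for s in rng.integers(0, n_samples, n_cells)],
            "condition": "sim",
            "area": 1,
            "centroid_row": 0.0,
            "centroid_col": 0.0,
        }
    )
    for j, marker in enumerate(markers):
        cells[marker] = values[:, j]
    truth = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "phenotype": [phenotypes[i] for i in assigned],
            "contaminant": [phenotypes[d] if d >= 0 else "" for d in donors],
        }
    )
    return cells, truth
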