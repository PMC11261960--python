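"""TIFF / CSV / YAML plumbing: per-ROI channel folders, stacks, panels, masks.

Layout conventions:

* one folder per ROI containing one single-channel grayscale TIFF per marker,
  filename stem = marker name;
* multi-page TIFF stacks (page order = panel order) with a sidecar panel CSV
  (columns ``channel, marker, lineage_flag``);
* integer label masks as single-channel TIFF (0 = background).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError
from .imclean import (
    AggregateParams,
    ChannelImage,
    ImageStack,
    NoiseParams,
    SpilloverParams,
    build_stack,
)

PANEL_COLUMNS = ["channel", "marker", "lineage_flag"]


def read_channel(path: str | Path, roi_id: str = "") -> ChannelImage:
    path = Path(path)
    pixels = np.asarray(tifffile.imread(path), dtype=float)
    return ChannelImage(pixels=pixels, marker=path.stem, roi_id=roi_id or path.parent.name)


def write_channel(img: ChannelImage, path: str | Path) -> None:
    tifffile.imwrite(Path(path), img.pixels.astype(np.float32))


def read_mask(path: str | Path) -> np.ndarray:
    mask = np.asarray(tifffile.imread(Path(path)))
    return mask.astype(np.int64)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask).astype(np.int32))


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ConfigurationError(f"panel file missing columns: {missing}")
    if panel["marker"].duplicated().any():
        dupes = sorted(panel.loc[panel["marker"].duplicated(), "marker"])
        raise ConfigurationError(f"duplicate markers in panel: {dupes}")
    return panel.sort_values("channel").reset_index(drop=True)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def read_roi_dir(roi_dir: str | Path, panel: pd.DataFrame) -> ImageStack:
    """Load one ROI folder of single-channel TIFFs into a panel-ordered stack."""
    roi_dir = Path(roi_dir)
    channels = [
        read_channel(p, roi_id=roi_dir.name)
        for p in sorted(roi_dir.glob("*.tif*"))
        if p.stem in set(panel["marker"])
    ]
    return build_stack(channels, list(panel["marker"]))


def write_roi_dir(stack: ImageStack, roi_dir: str | Path) -> None:
    roi_dir = Path(roi_dir)
    roi_dir.mkdir(parents=True, exist_ok=True)
    for ch in stack.channels:
        write_channel(ch, roi_dir / f"{ch.marker}.tiff")


def write_stack(stack: ImageStack, path: str | Path, panel: pd.DataFrame | None = None) -> None:
    """Write a multi-page TIFF (page order = panel order) plus sidecar panel CSV."""
    path = Path(path)
    tifffile.imwrite(path, stack.pixels().astype(np.float32))
    if panel is None:
        panel = pd.DataFrame(
            {
                "channel": range(1, len(stack.panel) + 1),
                "marker": stack.panel,
                "lineage_flag": [0] * len(stack.panel),
            }
        )
    write_panel(panel, path.with_suffix(".panel.csv"))


def read_stack(path: str | Path, panel: pd.DataFrame | None = None, roi_id: str = "") -> ImageStack:
    path = Path(path)
    if panel is None:
        panel = read_panel(path.with_suffix(".panel.csv"))
    pages = np.asarray(tifffile.imread(path), dtype=float)
    if pages.ndim == 2:
        pages = pages[None]
    markers = list(panel["marker"])
    if len(markers) != pages.shape[0]:
        raise ConfigurationError(
            f"stack has {pages.shape[0]} pages but panel lists {len(markers)} markers"
        )
    channels = [
        ChannelImage(pixels=pages[i], marker=m, roi_id=roi_id or path.stem)
        for i, m in enumerate(markers)
    ]
    return build_stack(channels, markers)


# ---------------------------------------------------------------------------
# per-(batch, channel) pre-processing settings
# ---------------------------------------------------------------------------


class PreprocessSettings:
    """Per-(batch, channel) artifact-correction parameters.

    The YAML layout is::

        default:
          spillover:
            - source: CD68
              targets: [CD3, CD4, ...]
              cap_threshold: 20
              gauss_radius: 1.0
              binarize_threshold: 5.0
              removal_value: 12.0
          noise: {floor_threshold: 1.5, window_size: 3}
          aggregates: {blur_radius: 0, binarize_threshold: 0, size_threshold: 8}
        batches:
          TCMR:
            channels:
              CD20:
                noise: {floor_threshold: 2.0, window_size: 3}

    A batch inherits the defaults; a channel entry overrides per step.  This
    mirrors per-clinical-batch tuning (e.g. NR/TCMR/CR staining batches).
    """

    def __init__(self, config: dict | None = None):
        config = config or {}
        unknown = set(config) - {"default", "batches"}
        if unknown:
            raise ConfigurationError(f"unknown top-level keys: {sorted(unknown)}")
        self.default = config.get("default", {}) or {}
        self.batches = config.get("batches", {}) or {}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessSettings":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def _section(self, batch: str, marker: str, step: str):
        batch_cfg = self.batches.get(batch, {}) or {}
        chan_cfg = (batch_cfg.get("channels", {}) or {}).get(marker, {}) or {}
        for scope in (chan_cfg, batch_cfg, self.default):
            if step in scope:
                return scope[step]
        return None

    def spillover_for(self, batch: str, marker: str) -> list[SpilloverParams]:
        """Spillover corrections whose target list contains ``marker``."""
        section = self._section(batch, marker, "spillover")
        if not section:
            return []
        if isinstance(section, dict):
            section = [section]
        params = []
        for entry in section:
            targets = entry.get("targets", [])
            if marker not in targets:
                continue
            params.append(
                SpilloverParams(
                    source_marker=entry["source"],
                    cap_threshold=float(entry["cap_threshold"]),
                    gauss_radius=float(entry.get("gauss_radius", 1.0)),
                    binarize_threshold=float(entry.get("binarize_threshold", 0.0)),
                    removal_value=float(entry["removal_value"]),
                )
            )
        return params

    def noise_for(self, batch: str, marker: str) -> NoiseParams | None:
        section = self._section(batch, marker, "noise")
        if section is None:
            return None
        return NoiseParams(
            floor_threshold=float(section.get("floor_threshold", 0.0)),
            window_size=int(section.get("window_size", 3)),
            erosion=bool(section.get("erosion", False)),
        )

    def aggregates_for(self, batch: str, marker: str) -> AggregateParams | None:
        section = self._section(batch, marker, "aggregates")
        if section is None:
            return None
        return AggregateParams(
            blur_radius=float(section.get("blur_radius", 1.0)),
            binarize_threshold=float(section.get("binarize_threshold", 0.0)),
            size_threshold=int(section.get("size_threshold", 8)),
            connectivity=int(section.get("connectivity", 8)),
        )


def preprocess_stack(stack: ImageStack, settings: PreprocessSettings, batch: str = "default") -> ImageStack:
    """Apply spillover -> denoise -> aggregate removal to every channel.

    Source masks are built from the *raw* input channels, so the correction of
    one channel never depends on the correction of another.
    """
    from .imclean import denoise, remove_aggregates, spillover_correct, spillover_mask

    raw = {ch.marker: ch.pixels for ch in stack.channels}
    out_channels = []
    for ch in stack.channels:
        px = ch.pixels.copy()
        for spill in settings.spillover_for(batch, ch.marker):
            if spill.source_marker not in raw:
                raise ConfigurationError(
                    f"spillover source {spill.source_marker!r} not in stack"
                )
            mask = spillover_mask(raw[spill.source_marker], spill)
            px = spillover_correct(px, mask, spill.removal_value)
        noise = settings.noise_for(batch, ch.marker)
        if noise is not None:
            px = denoise(px, noise)
        agg = settings.aggregates_for(batch, ch.marker)
        if agg is not None:
            px = remove_aggregates(px, agg)
        out_channels.append(ch.with_pixels(px))
    return ImageStack(channels=out_channels, panel=list(stack.panel))
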