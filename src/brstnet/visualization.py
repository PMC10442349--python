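"""Spot-level expression maps and overlays on tissue images.

Values are normalized to a color scale (viridis by default: low = blue,
high = yellow) and painted as filled circles at the spot centers, either on
a blank canvas or alpha-blended over the tissue image.  Truth/prediction
panels share one normalization so colors are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # file output only; no display server assumed
import numpy as np
from matplotlib import colormaps
from skimage.draw import disk

from .core_io import SpotTable, ValidationError

__all__ = ["OverlayConfig", "render_spot_map", "render_overlay", "render_panel"]


@dataclass
class OverlayConfig:
    colormap: str = "viridis"
    radius: int = 8
    alpha: float = 1.0
    vmin: float | None = None
    vmax: float | None = None
    percentile_range: tuple[float, float] = (1.0, 99.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        if self.radius <= 0:
            raise ValidationError("radius must be positive")


def _normalize(values: np.ndarray, config: OverlayConfig) -> np.ndarray:
    vmin = config.vmin
    vmax = config.vmax
    if vmin is None or vmax is None:
        lo, hi = np.percentile(values, config.percentile_range)
        vmin = lo if vmin is None else vmin
        vmax = hi if vmax is None else vmax
    if vmax <= vmin:
        return np.full(values.shape, 0.5)
    return np.clip((values - vmin) / (vmax - vmin), 0.0, 1.0)


def _spot_colors(values: np.ndarray, config: OverlayConfig) -> np.ndarray:
    cmap = colormaps[config.colormap]
    rgba = cmap(_normalize(values, config))
    return (rgba[:, :3] * 255.0).round().astype(np.uint8)


def _check_values(spot_table: SpotTable, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if len(values) != len(spot_table):
        raise ValidationError(
            f"{len(values)} values for {len(spot_table)} spots"
        )
    if not np.isfinite(values).all():
        bad = spot_table.frame["spot_id"][~np.isfinite(values)].tolist()
        raise ValidationError(f"non-finite values at spots {bad[:5]}")
    return values


def render_spot_map(
    spot_table: SpotTable,
    values: np.ndarray,
    image_size: tuple[int, int],
    config: OverlayConfig | None = None,
) -> np.ndarray:
    """Filled circles colored by value on a white canvas of ``image_size``."""
    config = config or OverlayConfig()
    values = _check_values(spot_table, values)
    canvas = np.full((*image_size, 3), 255, dtype=np.uint8)
    colors = _spot_colors(values, config)
    for (x, y), color in zip(
        spot_table.frame[["x", "y"]].to_numpy(), colors
    ):
        rr, cc = disk((y, x), config.radius, shape=image_size)
        canvas[rr, cc] = color
    return canvas


def render_overlay(
    section_image: np.ndarray,
    spot_table: SpotTable,
    values: np.ndarray,
    config: OverlayConfig | None = None,
) -> np.ndarray:
    """Alpha-blend colored spot circles over the tissue image."""
    config = config or OverlayConfig(alpha=0.6)
    values = _check_values(spot_table, values)
    h, w = section_image.shape[:2]
    xy = spot_table.frame[["x", "y"]].to_numpy()
    if (xy[:, 0] >= w).any() or (xy[:, 1] >= h).any():
        raise ValidationError("spot coordinates outside the image")
    out = section_image.astype(float).copy()
    colors = _spot_colors(values, config)
    for (x, y), color in zip(xy, colors):
        rr, cc = disk((y, x), config.radius, shape=(h, w))
        out[rr, cc] = (1 - config.alpha) * out[rr, cc] + config.alpha * color
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def render_panel(
    section_image: np.ndarray,
    spot_table: SpotTable,
    truth: np.ndarray,
    prediction: np.ndarray,
    config: OverlayConfig | None = None,
) -> np.ndarray:
    """Side-by-side truth/prediction overlays with one shared color scale."""
    config = config or OverlayConfig(alpha=0.6)
    both = np.concatenate([np.asarray(truth, float), np.asarray(prediction, float)])
    lo, hi = np.percentile(both, config.percentile_range)
    shared = OverlayConfig(
        colormap=config.colormap,
        radius=config.radius,
        alpha=config.alpha,
        vmin=lo,
        vmax=hi,
    )
    left = render_overlay(section_image, spot_table, truth, shared)
    right = render_overlay(section_image, spot_table, prediction, shared)
    return np.concatenate([left, right], axis=1)
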