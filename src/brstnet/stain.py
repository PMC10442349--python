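"""Sparse-factorization (Vahadane-style) H&E stain normalization.

Stain mixing is approximately linear in optical density (Beer-Lambert):
``OD = C @ S`` where ``S`` is a 2x3 matrix of unit-norm stain color vectors
(hematoxylin, eosin) and ``C`` the per-pixel stain concentrations.  The stain
matrix of an image is estimated by sparse non-negative dictionary learning on
the OD of its tissue pixels; an image is normalized to a reference by
rescaling its concentrations to the reference's 99th-percentile levels and
re-composing through the reference stain matrix.  A luminosity standardizer
rescales the LAB lightness channel by its 95th percentile.

Numeric conventions: optical density uses the natural logarithm with
background intensity 255 and intensities clamped at 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import color as skcolor
from sklearn.decomposition import DictionaryLearning

logger = logging.getLogger(__name__)

__all__ = [
    "StainProfile",
    "rgb_to_od",
    "od_to_rgb",
    "tissue_mask",
    "estimate_stain_profile",
    "normalize_stains",
    "standardize_luminosity",
    "mix_stains",
]

_BACKGROUND = 255.0
_MIN_TISSUE_PIXELS = 100


class StainError(ValueError):
    pass


@dataclass
class StainProfile:
    """Stain color basis and concentration scale of one image.

    stain_matrix
        2x3, rows are unit-Euclidean-norm OD color vectors; row 0 is
        hematoxylin, row 1 eosin.
    concentration_ref
        99th percentile of each stain's per-pixel concentration over tissue;
        used as the scale reference during normalization.
    """

    stain_matrix: np.ndarray
    concentration_ref: np.ndarray

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.concentration_ref = np.asarray(self.concentration_ref, dtype=float)
        if self.stain_matrix.shape != (2, 3):
            raise StainError(f"stain matrix must be 2x3, got {self.stain_matrix.shape}")
        if (self.stain_matrix < -1e-9).any():
            raise StainError("stain matrix entries must be non-negative")
        norms = np.linalg.norm(self.stain_matrix, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise StainError(f"stain rows must have unit norm, got {norms}")
        if (self.concentration_ref <= 0).any():
            raise StainError("concentration_ref must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "stain_matrix": self.stain_matrix.tolist(),
                    "concentration_ref": self.concentration_ref.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StainProfile":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["stain_matrix"]), np.asarray(d["concentration_ref"]))


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise StainError(f"expected HxWx3 RGB image, got shape {image.shape}")
    return image


def rgb_to_od(image: np.ndarray, background_intensity: float = _BACKGROUND) -> np.ndarray:
    """Convert 8-bit RGB to optical density: ``-ln(clamp(I,1,255)/background)``."""
    image = _check_rgb(image).astype(float)
    clamped = np.clip(image, 1.0, 255.0)
    return -np.log(clamped / background_intensity)


def od_to_rgb(od: np.ndarray, background_intensity: float = _BACKGROUND) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded back to 8-bit."""
    intensity = background_intensity * np.exp(-np.asarray(od, dtype=float))
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def tissue_mask(image: np.ndarray, luminosity_threshold: float = 0.8) -> np.ndarray:
    """True where a pixel is tissue: LAB lightness (scaled 0-1) below threshold."""
    image = _check_rgb(image)
    lum = skcolor.rgb2lab(image.astype(np.uint8))[:, :, 0] / 100.0
    return lum < luminosity_threshold


def _nonneg_concentrations(od_pixels: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Per-pixel stain concentrations: least squares onto the 2-stain basis,
    clipped at zero (fast vectorized stand-in for a per-pixel NNLS)."""
    pinv = np.linalg.pinv(stain_matrix)  # (3, 2)
    return np.maximum(od_pixels @ pinv, 0.0)


def estimate_stain_profile(
    image: np.ndarray,
    sparsity_weight: float = 0.1,
    seed: int = 0,
    max_pixels: int = 50_000,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> StainProfile:
    """Estimate the two stain OD vectors of an H&E image.

    Solves a sparse non-negative factorization ``OD ~ C @ S`` over (at most
    ``max_pixels`` subsampled) tissue pixels, with 2 unit-normalized
    non-negative stain rows and an L1 penalty on the concentrations.  Rows are
    ordered so that row 0 (hematoxylin) is the stain absorbing red most
    strongly.
    """
    image = _check_rgb(image)
    mask = tissue_mask(image)
    n_tissue = int(mask.sum())
    if n_tissue < _MIN_TISSUE_PIXELS:
        raise StainError(f"no tissue: only {n_tissue} tissue pixels (< {_MIN_TISSUE_PIXELS})")

    od = rgb_to_od(image)[mask]
    rng = np.random.default_rng(seed)
    if len(od) > max_pixels:
        od = od[rng.choice(len(od), size=max_pixels, replace=False)]

    dl = DictionaryLearning(
        n_components=2,
        alpha=sparsity_weight,
        max_iter=max_iter,
        tol=tol,
        fit_algorithm="cd",
        transform_algorithm="lasso_cd",
        positive_code=True,
        positive_dict=True,
        random_state=int(seed),
    )
    try:
        conc = dl.fit_transform(od)
    except Exception as exc:  # noqa: BLE001
        raise StainError(
            f"stain factorization failed to converge within {max_iter} iterations: {exc}"
        ) from exc
    stains = dl.components_  # (2, 3), unit-norm rows up to the <=1 constraint

    norms = np.linalg.norm(stains, axis=1)
    degenerate = norms < 1e-6
    if degenerate.any():
        logger.warning(
            "degenerate stain row(s) %s: image may contain a single stain; "
            "low-confidence profile", np.where(degenerate)[0].tolist(),
        )
        # replace a collapsed row with the OD direction least explained by the
        # surviving one, keeping a 2-row profile
        good = stains[~degenerate][0]
        good = good / np.linalg.norm(good)
        resid = od - np.outer(od @ good, good)
        fallback = np.maximum(resid.mean(axis=0), 1e-3)
        stains[degenerate] = fallback
        norms = np.linalg.norm(stains, axis=1)
    stains = stains / norms[:, None]
    conc = conc * norms[None, :]

    # hematoxylin (blue-purple) absorbs red strongly -> larger OD in channel 0
    if stains[0, 0] < stains[1, 0]:
        stains = stains[::-1]
        conc = conc[:, ::-1]

    ref = np.percentile(conc, 99, axis=0)
    ref = np.maximum(ref, 1e-6)
    return StainProfile(stain_matrix=stains, concentration_ref=ref)


def normalize_stains(
    source_image: np.ndarray,
    source_profile: StainProfile,
    reference_profile: StainProfile,
) -> np.ndarray:
    """Re-express an image in the reference image's stain basis and scale.

    Source concentrations are rescaled channel-wise by the ratio of reference
    to source 99th-percentile concentrations and re-composed through the
    reference stain matrix.  Images with too little tissue are returned
    unchanged.
    """
    source_image = _check_rgb(source_image)
    if (source_profile.concentration_ref <= 0).any():
        raise StainError("source concentration_ref must be positive")
    if tissue_mask(source_image).sum() < _MIN_TISSUE_PIXELS:
        return source_image.copy()

    h, w = source_image.shape[:2]
    od = rgb_to_od(source_image).reshape(-1, 3)
    conc = _nonneg_concentrations(od, source_profile.stain_matrix)
    scale = reference_profile.concentration_ref / source_profile.concentration_ref
    od_new = (conc * scale[None, :]) @ reference_profile.stain_matrix
    return od_to_rgb(od_new.reshape(h, w, 3))


def standardize_luminosity(image: np.ndarray, target_p95: float = 0.995) -> np.ndarray:
    """Rescale LAB lightness so its 95th percentile reaches (near) maximum.

    Each pass divides L by its 95th percentile and clips to [0, 1].  Because
    out-of-gamut colors are clipped on conversion back to RGB, one pass can
    undershoot on strongly stained images, so passes repeat (at most 4) until
    the 95th percentile of L is at least ``target_p95``; this makes the
    operation idempotent up to 8-bit rounding.
    """
    image = _check_rgb(image).astype(np.uint8)
    out = image
    for _ in range(4):
        lab = skcolor.rgb2lab(out)
        l_scaled = lab[:, :, 0] / 100.0
        p95 = np.percentile(l_scaled, 95)
        if p95 <= 0 or p95 >= target_p95:
            break
        lab[:, :, 0] = np.clip(l_scaled / p95, 0.0, 1.0) * 100.0
        rgb = skcolor.lab2rgb(lab)
        out = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    return out.copy() if out is image else out


def mix_stains(
    concentrations: np.ndarray, stain_matrix: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Compose an RGB image from per-pixel concentrations and a stain basis.

    The forward model that stain estimation inverts; used to build synthetic
    two-stain images with known ground truth.
    """
    od = np.asarray(concentrations) @ np.asarray(stain_matrix)
    return od_to_rgb(od.reshape(shape[0], shape[1], 3))


def angular_distance_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two stain vectors (direction only)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
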