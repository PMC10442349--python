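"""Gene/spot filtering, log transform, top-K gene selection and patch extraction.

The fixed pipeline order is: gene filter (drop genes whose pooled mean
expression is zero) -> spot filter (keep spots with at least ``min_total``
total counts) -> patch extraction with white-pixel exclusion -> log transform
and top-K gene selection on the retained spots.

Patch boxes are half-open pixel intervals
``[y - s//2, y - s//2 + s) x [x - s//2, x - s//2 + s)`` centered on the spot.
A pixel is "white" when all three channels are >= ``white_threshold``; a patch
is excluded when its white fraction is strictly greater than
``white_fraction`` (an exactly-half-white patch is retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix, Section, SpotBundle, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PatchSet",
    "GeneSelection",
    "filter_genes",
    "filter_spots",
    "log_transform",
    "select_genes",
    "extract_patches",
    "augment_patch",
    "standardize_patch",
    "preprocess_dataset",
    "PreprocessResult",
]

DEFAULT_MIN_TOTAL = 1000
DEFAULT_PATCH_SIZE = 224
DEFAULT_N_MAIN = 250
DEFAULT_WHITE_THRESHOLD = 220
DEFAULT_WHITE_FRACTION = 0.5


@dataclass
class PatchSet:
    """Image patches for retained spots, channels-first uint8.

    ``spot_refs`` is a DataFrame parallel to ``patches`` with columns
    (patient, section, spot_id).  ``n_skipped_bounds`` / ``n_excluded_white``
    report spots lost to the image border and to the white-pixel rule.
    """

    patches: np.ndarray  # (N, 3, s, s) uint8
    spot_refs: pd.DataFrame
    n_skipped_bounds: int = 0
    n_excluded_white: int = 0

    def __post_init__(self) -> None:
        if len(self.patches) != len(self.spot_refs):
            raise ValidationError("patches and spot_refs must be parallel")

    def flattened(self) -> np.ndarray:
        """N x (3*m*n) view used by flat feature baselines."""
        return self.patches.reshape(len(self.patches), -1)

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class GeneSelection:
    """Partition of the post-filter gene set into main (top-K) and auxiliary genes."""

    main_genes: list[str]
    aux_genes: list[str]

    def __post_init__(self) -> None:
        if set(self.main_genes) & set(self.aux_genes):
            raise ValidationError("main and aux gene sets overlap")

    @property
    def all_genes(self) -> list[str]:
        return list(self.main_genes) + list(self.aux_genes)


def filter_genes(counts: CountMatrix) -> CountMatrix:
    """Drop genes whose mean expression pooled over all spots is zero.

    Equivalent to dropping all-zero columns; column order is preserved.
    """
    if counts.values.size == 0:
        raise ValidationError("empty count matrix")
    keep = counts.values.mean(axis=0) > 0
    return CountMatrix(counts.values.loc[:, keep])


def filter_spots(counts: CountMatrix, min_total: int = DEFAULT_MIN_TOTAL) -> CountMatrix:
    """Keep spots with at least ``min_total`` total read counts (inclusive)."""
    totals = counts.values.sum(axis=1)
    keep = totals >= min_total
    if not keep.any():
        logger.warning("filter_spots: no spot reaches %d total counts", min_total)
    return CountMatrix(counts.values.loc[keep])


def log_transform(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Element-wise ``ln(1 + x)`` of the counts."""
    values = counts.values if isinstance(counts, CountMatrix) else counts
    if (values.to_numpy() < 0).any():
        raise ValidationError("log transform requires non-negative counts")
    return np.log1p(values.astype(float))


def select_genes(counts: CountMatrix, k: int = DEFAULT_N_MAIN) -> GeneSelection:
    """Split genes into the top-``k`` by mean expression (main) and the rest (aux).

    Ranking uses mean expression across all retained spots; ties break
    lexicographically by gene id, so the result is independent of the input
    column order.
    """
    genes = list(counts.values.columns)
    if k > len(genes):
        raise ValidationError(f"k={k} exceeds gene count {len(genes)}")
    means = counts.values.mean(axis=0)
    order = sorted(genes, key=lambda g: (-means[g], g))
    return GeneSelection(main_genes=order[:k], aux_genes=order[k:])


def patch_box(x: int, y: int, size: int) -> tuple[int, int, int, int]:
    """Half-open patch box (row_start, row_stop, col_start, col_stop)."""
    r0 = y - size // 2
    c0 = x - size // 2
    return r0, r0 + size, c0, c0 + size


def white_fraction_of(patch_hwc: np.ndarray, white_threshold: int) -> float:
    white = (patch_hwc >= white_threshold).all(axis=-1)
    return float(white.mean())


def extract_patches(
    section: Section,
    retained_spots: list[str],
    patch_size: int = DEFAULT_PATCH_SIZE,
    white_threshold: int = DEFAULT_WHITE_THRESHOLD,
    white_fraction: float = DEFAULT_WHITE_FRACTION,
) -> PatchSet:
    """Cut one patch per retained spot, skipping border spots and white patches.

    Spots whose box exceeds the image bounds are skipped (never padded) and
    counted; patches whose white-pixel fraction strictly exceeds
    ``white_fraction`` are excluded and counted.
    """
    h, w = section.image.shape[:2]
    if patch_size > min(h, w):
        raise ValidationError(f"patch_size {patch_size} larger than image {h}x{w}")
    coords = section.spots.frame.set_index("spot_id")
    patches, refs = [], []
    n_bounds = n_white = 0
    for sid in retained_spots:
        if sid not in coords.index:
            continue
        x, y = int(coords.at[sid, "x"]), int(coords.at[sid, "y"])
        r0, r1, c0, c1 = patch_box(x, y, patch_size)
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            n_bounds += 1
            continue
        patch = section.image[r0:r1, c0:c1]
        if white_fraction_of(patch, white_threshold) > white_fraction:
            n_white += 1
            continue
        patches.append(np.moveaxis(patch, -1, 0))
        refs.append((section.patient_id, section.section_id, sid))
    if n_bounds:
        logger.info(
            "section %s/%s: skipped %d border spot(s)",
            section.patient_id, section.section_id, n_bounds,
        )
    arr = (
        np.stack(patches)
        if patches
        else np.empty((0, 3, patch_size, patch_size), dtype=np.uint8)
    )
    return PatchSet(
        patches=arr,
        spot_refs=pd.DataFrame(refs, columns=["patient", "section", "spot_id"]),
        n_skipped_bounds=n_bounds,
        n_excluded_white=n_white,
    )


def augment_patch(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal/vertical flip and 90-degree rotation (each p=0.5).

    Operates on a channels-first square patch; the pixel multiset is
    preserved.  Deterministic for a fixed generator state.
    """
    if patch.shape[-1] != patch.shape[-2]:
        raise ValidationError(f"rotation requires a square patch, got {patch.shape}")
    out = patch
    if rng.random() < 0.5:
        out = out[..., :, ::-1]  # horizontal flip (reverse columns)
    if rng.random() < 0.5:
        out = out[..., ::-1, :]  # vertical flip
    if rng.random() < 0.5:
        out = np.rot90(out, k=1, axes=(-2, -1))
    return np.ascontiguousarray(out)


def standardize_patch(
    patch: np.ndarray,
    channel_means: np.ndarray | None = None,
    channel_stds: np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel ``(x - mean) / std`` as float32.

    With ``None`` statistics, per-patch statistics are used, giving each
    channel mean ~0 and std ~1.
    """
    x = patch.astype(np.float32)
    if channel_means is None:
        channel_means = x.mean(axis=(-2, -1), keepdims=True)
    else:
        channel_means = np.asarray(channel_means, np.float32).reshape(-1, 1, 1)
    if channel_stds is None:
        channel_stds = x.std(axis=(-2, -1), keepdims=True)
    else:
        channel_stds = np.asarray(channel_stds, np.float32).reshape(-1, 1, 1)
    if (np.asarray(channel_stds) <= 0).any():
        raise ValidationError("channel std must be positive")
    return (x - channel_means) / channel_stds


@dataclass
class PreprocessResult:
    """Everything downstream training needs, plus exclusion bookkeeping."""

    bundle: SpotBundle
    patches: PatchSet
    selection: GeneSelection
    log_counts: pd.DataFrame  # rows parallel to patches/bundle
    report: dict = field(default_factory=dict)


def preprocess_dataset(
    sections: list[Section],
    min_total: int = DEFAULT_MIN_TOTAL,
    patch_size: int = DEFAULT_PATCH_SIZE,
    n_main_genes: int = DEFAULT_N_MAIN,
    white_threshold: int = DEFAULT_WHITE_THRESHOLD,
    white_fraction: float = DEFAULT_WHITE_FRACTION,
    rank_on_log: bool = False,
) -> PreprocessResult:
    """Run the full preprocessing pipeline over a multi-section dataset.

    Gene filtering pools counts over every spot of every section; spot
    filtering, patch extraction and the white-pixel rule are per-section; gene
    selection ranks mean expression over all retained spots (raw counts by
    default, log counts with ``rank_on_log``).
    """
    if not sections:
        raise ValidationError("no sections given")
    keyed = []
    for sec in sections:
        df = sec.counts.values.copy()
        df.index = [f"{sec.patient_id}|{sec.section_id}|{s}" for s in df.index]
        keyed.append(df)
    pooled = CountMatrix(pd.concat(keyed, axis=0))

    pooled = filter_genes(pooled)
    pooled = filter_spots(pooled, min_total=min_total)
    retained = set(pooled.values.index)

    all_patches, all_refs, counts_rows, pixels, patients, sect_ids, spot_ids = (
        [], [], [], [], [], [], []
    )
    n_bounds = n_white = 0
    for sec in sections:
        sec_retained = [
            s
            for s in sec.counts.spot_ids
            if f"{sec.patient_id}|{sec.section_id}|{s}" in retained
        ]
        ps = extract_patches(
            sec, sec_retained, patch_size, white_threshold, white_fraction
        )
        n_bounds += ps.n_skipped_bounds
        n_white += ps.n_excluded_white
        if len(ps) == 0:
            continue
        all_patches.append(ps.patches)
        all_refs.append(ps.spot_refs)
        kept = ps.spot_refs["spot_id"].tolist()
        counts_rows.append(
            pooled.values.loc[
                [f"{sec.patient_id}|{sec.section_id}|{s}" for s in kept]
            ]
        )
        coords = sec.spots.frame.set_index("spot_id")
        pixels.append(coords.loc[kept, ["x", "y"]].to_numpy())
        patients.extend([sec.patient_id] * len(kept))
        sect_ids.extend([sec.section_id] * len(kept))
        spot_ids.extend(kept)

    if not all_patches:
        raise ValidationError("preprocessing retained no spots")
    patches = PatchSet(
        patches=np.concatenate(all_patches),
        spot_refs=pd.concat(all_refs, ignore_index=True),
        n_skipped_bounds=n_bounds,
        n_excluded_white=n_white,
    )
    counts_kept = CountMatrix(pd.concat(counts_rows, axis=0))

    selection = select_genes(
        CountMatrix(log_transform(counts_kept)) if rank_on_log else counts_kept,
        k=min(n_main_genes, len(counts_kept.values.columns)),
    )
    log_counts = log_transform(counts_kept)

    bundle = SpotBundle(
        count=counts_kept.values.to_numpy(),
        pixel=np.vstack(pixels),
        patient=np.asarray(patients, dtype=str),
        index=np.arange(len(spot_ids)),
        gene_ids=list(counts_kept.values.columns),
        spot_ids=spot_ids,
        section_ids=sect_ids,
    )
    report = {
        "n_sections": len(sections),
        "n_spots_retained": len(bundle),
        "n_genes_retained": len(counts_kept.values.columns),
        "n_skipped_bounds": n_bounds,
        "n_excluded_white": n_white,
    }
    return PreprocessResult(bundle, patches, selection, log_counts, report)
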