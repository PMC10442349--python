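"""Domain types and I/O for spatial-transcriptomics sections.

A *section* is one stained tissue slide: an RGB image, a table of spot
coordinates on that image, and a spots x genes count matrix.  Spot tables and
count matrices are plain tab- or comma-separated text; images are ordinary
raster files (JPEG/PNG/TIFF).  Filtered per-spot records are serialized as a
zip archive of named numeric arrays (``.npz``) holding parallel ``count``,
``pixel``, ``patient`` and ``index`` arrays.

Conventions: pixel coordinates are 0-based with ``x`` = column and ``y`` =
row; patch boxes elsewhere in the package are half-open intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneIndex",
    "SpotTable",
    "CountMatrix",
    "Section",
    "SpotBundle",
    "ConversionReport",
    "load_section",
    "load_dataset",
    "convert_gene_ids",
    "read_count_matrix",
    "read_spot_table",
    "read_gene_mapping",
    "write_spot_bundle",
    "read_spot_bundle",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class GeneIndex:
    """Ordered gene identifiers with a parallel list of symbols.

    ``symbols[i]`` is the display symbol of ``ids[i]``; identifiers that could
    not be mapped retain their original id as symbol.
    """

    ids: list[str]
    symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if self.symbols is None:
            self.symbols = list(self.ids)
        self.symbols = [str(s) for s in self.symbols]
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(self.symbols) != len(self.ids):
            raise ValidationError(
                f"symbols length {len(self.symbols)} != ids length {len(self.ids)}"
            )

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ConversionReport:
    n_total: int
    n_mapped: int
    n_unmapped: int
    unmapped_ids: list[str] = field(default_factory=list)


@dataclass
class SpotTable:
    """Spot grid labels and their pixel-center coordinates on the image."""

    frame: pd.DataFrame  # columns: spot_id, x, y
    spot_diameter_um: float = 100.0

    def __post_init__(self) -> None:
        required = {"spot_id", "x", "y"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(
                f"spot table needs columns {sorted(required)}, got {list(self.frame.columns)}"
            )
        if self.frame["spot_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["spot_id"].duplicated(), "spot_id"]
            raise ValidationError(f"duplicate spot ids: {list(dupes)[:5]}")
        if (self.frame[["x", "y"]].to_numpy() < 0).any():
            raise ValidationError("negative spot pixel coordinates")

    @property
    def spot_ids(self) -> list[str]:
        return self.frame["spot_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CountMatrix:
    """Spots x genes non-negative integer counts."""

    values: pd.DataFrame  # index: spot ids, columns: gene ids

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ValidationError(f"duplicate gene columns: {list(dupes)[:5]}")
        arr = self.values.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValidationError("negative counts")

    @property
    def genes(self) -> GeneIndex:
        return GeneIndex(list(self.values.columns))

    @property
    def spot_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Section:
    """One tissue slide: image + spots + counts plus its patient/section ids."""

    patient_id: str
    section_id: str
    image: np.ndarray
    spots: SpotTable
    counts: CountMatrix
    n_dropped_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValidationError(f"image must be HxWx3, got shape {self.image.shape}")
        missing = set(self.counts.spot_ids) - set(self.spots.spot_ids)
        if missing:
            raise ValidationError(f"count rows without spot entries: {sorted(missing)[:5]}")


@dataclass
class SpotBundle:
    """Filtered per-spot records: counts, pixel coords, patient id, ordinal index.

    All four arrays are parallel along the first axis; ``index`` is unique and
    contiguous from 0 so the bundle can be addressed positionally after
    shuffling or splitting.
    """

    count: np.ndarray  # (N, G)
    pixel: np.ndarray  # (N, 2) -> (x, y)
    patient: np.ndarray  # (N,) strings
    index: np.ndarray  # (N,) ints
    gene_ids: list[str] | None = None
    spot_ids: list[str] | None = None
    section_ids: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.count)
        for name in ("pixel", "patient", "index"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"bundle array '{name}' has length {len(getattr(self, name))}, expected {n}"
                )
        idx = np.asarray(self.index)
        if n and (np.sort(idx) != np.arange(n)).any():
            raise ValidationError("bundle indices must be unique and contiguous from 0")

    def __len__(self) -> int:
        return len(self.count)


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    # dialect auto-detection: the public dataset ships plain text with either
    # tabs or commas and no formal schema
    return pd.read_csv(path, sep=None, engine="python", **kwargs)


def read_count_matrix(path: str | Path) -> CountMatrix:
    # pandas silently mangles duplicate header names (g1 -> g1.1), so check
    # the raw header line before parsing
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    genes = header.split(sep)[1:]
    if len(genes) != len(set(genes)):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValidationError(f"duplicate gene columns in {path}: {dupes[:5]}")
    df = _read_table(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


_SPOT_COL_ALIASES = {
    "spot_id": {"spot_id", "spot", "id", "barcode"},
    "x": {"x", "pixel_x", "px", "x_coord", "pixel_x_coord"},
    "y": {"y", "pixel_y", "py", "y_coord", "pixel_y_coord"},
}


def read_spot_table(path: str | Path, spot_diameter_um: float = 100.0) -> SpotTable:
    df = _read_table(path)
    cols = {c.lower().strip(): c for c in df.columns}
    rename = {}
    for canon, aliases in _SPOT_COL_ALIASES.items():
        for alias in aliases:
            if alias in cols:
                rename[cols[alias]] = canon
                break
    df = df.rename(columns=rename)
    if not {"spot_id", "x", "y"}.issubset(df.columns):
        if df.shape[1] >= 3:  # headerless: positional spot_id, x, y
            df = _read_table(path, header=None)
            df = df.iloc[:, :3]
            df.columns = ["spot_id", "x", "y"]
        else:
            raise ValidationError(f"cannot interpret spot table columns in {path}")
    df = df[["spot_id", "x", "y"]].copy()
    df["spot_id"] = df["spot_id"].astype(str)
    df["x"] = pd.to_numeric(df["x"]).round().astype(int)
    df["y"] = pd.to_numeric(df["y"]).round().astype(int)
    return SpotTable(df.reset_index(drop=True), spot_diameter_um=spot_diameter_um)


def read_gene_mapping(path: str | Path) -> dict[str, str]:
    """Two-column id -> symbol table (TSV/CSV, header optional)."""
    df = _read_table(path, header=None)
    if df.shape[1] < 2:
        raise ValidationError(f"gene mapping {path} needs two columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"id", "ensembl", "ensembl_id", "gene_id"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def load_section(
    image_path: str | Path,
    spots_path: str | Path,
    counts_path: str | Path,
    patient_id: str = "",
    section_id: str = "",
    max_mismatch_fraction: float = 0.2,
) -> Section:
    """Load and cross-validate one section from its three files.

    Spots whose pixel coordinates fall outside the image are dropped with a
    logged warning.  If the fraction of count rows without a matching spot (or
    vice versa) exceeds ``max_mismatch_fraction``, loading fails naming the
    offending ids.
    """
    try:
        image = np.asarray(iio.imread(image_path))
    except Exception as exc:  # noqa: BLE001 - normalize into IOError
        raise IOError(f"cannot read image {image_path}: {exc}") from exc
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim == 3 and image.shape[2] == 4:
        image = image[:, :, :3]
    image = image.astype(np.uint8, copy=False)

    spots = read_spot_table(spots_path)
    counts = read_count_matrix(counts_path)

    h, w = image.shape[:2]
    in_bounds = (
        (spots.frame["x"] >= 0)
        & (spots.frame["x"] < w)
        & (spots.frame["y"] >= 0)
        & (spots.frame["y"] < h)
    )
    n_dropped = int((~in_bounds).sum())
    if n_dropped:
        logger.warning(
            "section %s/%s: dropping %d spot(s) outside the %dx%d image",
            patient_id, section_id, n_dropped, h, w,
        )
        spots = SpotTable(
            spots.frame[in_bounds].reset_index(drop=True), spots.spot_diameter_um
        )

    spot_set = set(spots.spot_ids)
    count_set = set(counts.spot_ids)
    mismatched = sorted((spot_set - count_set) | (count_set - spot_set))
    denom = max(len(spot_set | count_set), 1)
    if len(mismatched) / denom > max_mismatch_fraction:
        raise ValidationError(
            f"spot/count row mismatch {len(mismatched)}/{denom} exceeds "
            f"{max_mismatch_fraction:.0%}; e.g. {mismatched[:5]}"
        )
    common = [s for s in spots.spot_ids if s in count_set]
    spots = SpotTable(
        spots.frame[spots.frame["spot_id"].isin(common)].reset_index(drop=True),
        spots.spot_diameter_um,
    )
    counts = CountMatrix(counts.values.loc[common])

    return Section(
        patient_id=patient_id or Path(image_path).parent.name,
        section_id=section_id or Path(image_path).stem,
        image=image,
        spots=spots,
        counts=counts,
        n_dropped_out_of_bounds=n_dropped,
    )


def load_dataset(root: str | Path) -> tuple[list[Section], dict[str, str]]:
    """Load every section below ``root``.

    Expects the layout written by :func:`brstnet.synthetic.generate_dataset`:
    ``<root>/<patient>/<section>/{image.png,spots.tsv,counts.tsv}`` plus an
    optional ``gene_mapping.tsv`` at the root.
    """
    root = Path(root)
    sections = []
    for img in sorted(root.glob("*/*/image.png")):
        sec_dir = img.parent
        sections.append(
            load_section(
                img,
                sec_dir / "spots.tsv",
                sec_dir / "counts.tsv",
                patient_id=sec_dir.parent.name,
                section_id=sec_dir.name,
            )
        )
    if not sections:
        raise IOError(f"no sections found under {root}")
    mapping_path = root / "gene_mapping.tsv"
    mapping = read_gene_mapping(mapping_path) if mapping_path.exists() else {}
    return sections, mapping


# ---------------------------------------------------------------------------
# gene symbol conversion


def convert_gene_ids(
    gene_index: GeneIndex, mapping_table: Mapping[str, str]
) -> tuple[GeneIndex, ConversionReport]:
    """Translate Ensembl-style ids to gene symbols.

    Ids absent from the table keep their original id as symbol (they are not
    dropped) and are counted in the returned report.
    """
    if not mapping_table:
        raise ValidationError("empty gene mapping table")
    symbols, unmapped = [], []
    for gid in gene_index.ids:
        sym = mapping_table.get(gid)
        if sym is None:
            symbols.append(gid)
            unmapped.append(gid)
        else:
            symbols.append(sym)
    report = ConversionReport(
        n_total=len(gene_index),
        n_mapped=len(gene_index) - len(unmapped),
        n_unmapped=len(unmapped),
        unmapped_ids=unmapped,
    )
    return GeneIndex(list(gene_index.ids), symbols), report


# ---------------------------------------------------------------------------
# spot-bundle archive


def write_spot_bundle(bundle: SpotBundle, path: str | Path) -> None:
    """Serialize a bundle as a zip of named arrays (``.npz``)."""
    extras = {}
    if bundle.gene_ids is not None:
        extras["gene_ids"] = np.asarray(bundle.gene_ids, dtype=str)
    if bundle.spot_ids is not None:
        extras["spot_ids"] = np.asarray(bundle.spot_ids, dtype=str)
    if bundle.section_ids is not None:
        extras["section_ids"] = np.asarray(bundle.section_ids, dtype=str)
    np.savez(
        path,
        count=np.asarray(bundle.count),
        pixel=np.asarray(bundle.pixel),
        patient=np.asarray(bundle.patient, dtype=str),
        index=np.asarray(bundle.index),
        **extras,
    )


def _bundle_from_npz(data) -> SpotBundle:
    def opt(key):
        return list(data[key]) if key in data.files else None

    return SpotBundle(
        count=data["count"],
        pixel=data["pixel"],
        patient=data["patient"].astype(str),
        index=data["index"],
        gene_ids=opt("gene_ids"),
        spot_ids=opt("spot_ids"),
        section_ids=opt("section_ids"),
    )


def read_spot_bundle(path: str | Path) -> SpotBundle:
    """Read a bundle archive.

    ``path`` may be one ``.npz`` holding the whole dataset, or a directory of
    per-spot ``.npz`` files (each with singleton arrays) which are concatenated
    in sorted filename order and re-indexed.
    """
    path = Path(path)
    if path.is_dir():
        parts = []
        for f in sorted(path.glob("*.npz")):
            with np.load(f, allow_pickle=False) as data:
                parts.append(
                    {k: np.atleast_1d(data[k]) for k in ("count", "pixel", "patient")}
                )
        if not parts:
            raise IOError(f"no .npz files under {path}")
        count = np.vstack([np.atleast_2d(p["count"]) for p in parts])
        pixel = np.vstack([np.atleast_2d(p["pixel"]) for p in parts])
        patient = np.concatenate([p["patient"].astype(str) for p in parts])
        return SpotBundle(count, pixel, patient, np.arange(len(count)))
    try:
        with np.load(path, allow_pickle=False) as data:
            return _bundle_from_npz(data)
    except (OSError, ValueError, KeyError) as exc:
        raise IOError(f"cannot read spot bundle {path}: {exc}") from exc


def bundles_equal(a: SpotBundle, b: SpotBundle) -> bool:
    return (
        np.array_equal(a.count, b.count)
        and np.array_equal(a.pixel, b.pixel)
        and np.array_equal(np.asarray(a.patient, dtype=str), np.asarray(b.patient, dtype=str))
        and np.array_equal(a.index, b.index)
    )
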