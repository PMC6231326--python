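"""Shared I/O and configuration.

Images and label masks are exchanged as single-plane grayscale TIFFs; tables
as RFC-4180 CSV with a header row; configuration as JSON.

Coordinate convention: row-major, 0-based ``(row, column)`` with the origin at
the top-left pixel, matching raster microscopy formats. Every radius, ring
width or patch index in this package uses this convention.

Intensities are never rescaled or normalized on read: downstream scores are
either invariant to intensity scaling (anisotropy, ratios) or define their own
normalization.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclasses.dataclass(frozen=True)
class ImageField:
    """A 2D grayscale intensity image with float pixels.

    Attributes
    ----------
    pixels : ndarray, shape (height, width), dtype float64
        Non-negative intensities in arbitrary units. Finite everywhere.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"ImageField requires a 2D array, got {px.ndim}D")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("ImageField must be at least 1x1")
        if not np.all(np.isfinite(px)):
            raise ValueError("ImageField intensities must be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclasses.dataclass(frozen=True)
class LabelMask:
    """Integer label image: 0 = background, k > 0 = object k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"LabelMask requires a 2D array, got {lab.ndim}D")
        if np.issubdtype(lab.dtype, np.floating):
            if not np.all(lab == np.round(lab)):
                raise ValueError("LabelMask values must be integral")
            lab = lab.astype(np.int64)
        elif not np.issubdtype(lab.dtype, np.integer):
            raise ValueError(f"LabelMask requires integer values, got {lab.dtype}")
        else:
            lab = lab.astype(np.int64)
        if lab.min() < 0:
            raise ValueError("LabelMask values must be non-negative")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def object_labels(self) -> np.ndarray:
        """Sorted positive labels present in the mask."""
        vals = np.unique(self.labels)
        return vals[vals > 0]

    def as_bool(self) -> np.ndarray:
        return self.labels > 0


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnisotropyConfig:
    min_patch_px: int = 10          # minimum patch side, px
    min_valid_pixels: int = 100     # minimum weighted samples per processed patch
    weighting: str = "unit"         # "unit" or "grad2" (gradient-magnitude-squared)
    scale_base: str = "powers"      # "powers": N in {2^i} u {3^i}; "multiples": {2i} u {3i}

    def validate(self) -> None:
        if self.min_patch_px < 2:
            raise ValueError("min_patch_px must be >= 2")
        if self.min_valid_pixels < 1:
            raise ValueError("min_valid_pixels must be >= 1")
        if self.weighting not in ("unit", "grad2"):
            raise ValueError(f"unknown weighting mode {self.weighting!r}")
        if self.scale_base not in ("powers", "multiples"):
            raise ValueError(f"unknown scale_base {self.scale_base!r}")


@dataclasses.dataclass
class NCQuantConfig:
    smoothing_sigma: float = 2.0    # Gaussian sigma for nucleus segmentation, px
    min_area: float = 50.0          # nucleus area bounds, px^2
    max_area: float = 5000.0
    mitotic_factor: float = 2.0     # mitotic if mean Hoechst > factor x population median
    min_roundness: float = 0.8      # aberrant if 4*pi*A/P^2 below this; a 3:1
                                    # ellipse has continuum roundness ~0.66 and
                                    # a disk ~1.0, so 0.8 splits the classes
    ring_width: int = 4             # perinuclear ring width, px
    max_grow_px: int = 40           # cap on cytosol growth from the nucleus, px
    delta: float = 0.2              # N/C classification band half-width

    def validate(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if not 0 < self.min_area <= self.max_area:
            raise ValueError("need 0 < min_area <= max_area")
        if self.mitotic_factor <= 1:
            raise ValueError("mitotic_factor must exceed 1")
        if not 0 < self.min_roundness <= 1:
            raise ValueError("min_roundness must be in (0, 1]")
        if self.ring_width < 1:
            raise ValueError("ring_width must be >= 1")
        if self.max_grow_px < 1:
            raise ValueError("max_grow_px must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


@dataclasses.dataclass
class ScreenConfig:
    threshold: float = 2.5          # |mean Z| hit threshold (strict inequality)
    per_plate: bool = True          # normalize against each plate's own controls
    specificity_margin: float | None = None  # optional |Z_other| bound for specific hits

    def validate(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.specificity_margin is not None and self.specificity_margin <= 0:
            raise ValueError("specificity_margin must be > 0 when set")


@dataclasses.dataclass
class Config:
    """Grouped parameters for the full pipeline; JSON round-trippable."""

    anisotropy: AnisotropyConfig = dataclasses.field(default_factory=AnisotropyConfig)
    nc_quant: NCQuantConfig = dataclasses.field(default_factory=NCQuantConfig)
    screen: ScreenConfig = dataclasses.field(default_factory=ScreenConfig)

    def validate(self) -> None:
        self.anisotropy.validate()
        self.nc_quant.validate()
        self.screen.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "Config":
        groups = {"anisotropy": AnisotropyConfig, "nc_quant": NCQuantConfig,
                  "screen": ScreenConfig}
        unknown = set(data) - set(groups)
        if unknown:
            raise ValueError(f"unknown config groups: {sorted(unknown)}")
        kwargs = {}
        for name, group_cls in groups.items():
            if name not in data:
                continue
            fields = {f.name for f in dataclasses.fields(group_cls)}
            extra = set(data[name]) - fields
            if extra:
                raise ValueError(f"unknown keys in config group {name!r}: {sorted(extra)}")
            kwargs[name] = group_cls(**data[name])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "Config":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> ImageField:
    """Read a single-plane grayscale TIFF as an ImageField.

    Intensities are cast to float64 without rescaling. Multichannel or
    3D inputs are rejected: plane selection must happen upstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"multichannel input requires plane selection: {path} has shape {arr.shape}"
        )
    return ImageField(arr.astype(np.float64))


def write_image(field: ImageField, path: str | Path, dtype=np.float32) -> None:
    """Write an ImageField as a single-plane TIFF (default 32-bit float)."""
    tifffile.imwrite(Path(path), field.pixels.astype(dtype))


def read_mask(path: str | Path) -> LabelMask:
    """Read an integer-valued TIFF as a LabelMask.

    Float TIFFs are accepted when every value is integral; negative or
    fractional values are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"mask must be single-plane 2D: {path} has shape {arr.shape}")
    return LabelMask(arr)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    maxlab = int(mask.labels.max()) if mask.labels.size else 0
    dtype = np.uint16 if maxlab < 2**16 else np.uint32
    tifffile.imwrite(Path(path), mask.labels.astype(dtype))


def write_table(records: Sequence[Mapping] | pd.DataFrame, path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write keyed records to CSV with a header row.

    All records must share the same key set. An empty record sequence yields a
    header-only CSV; the header then comes from ``columns``, which must be
    given in that case.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, index=False)
        return
    records = list(records)
    if not records:
        if columns is None:
            raise ValueError("empty record sequence needs explicit columns for the header")
        pd.DataFrame(columns=list(columns)).to_csv(path, index=False)
        return
    keys = list(records[0].keys())
    for rec in records[1:]:
        if list(rec.keys()) != keys:
            raise ValueError("records have mismatched keys")
    pd.DataFrame.from_records(records, columns=keys).to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path)
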