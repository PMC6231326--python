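"""Multiscale nematic-tensor anisotropy of fibrous textures.

The fiber-organization score works on local intensity gradients. At each
interior pixel the gradient ``(gx, gy)`` (central differences) is rotated by
90 degrees to give the local fiber direction ``theta`` (defined modulo pi).
Orientations are summarized by the mean nematic tensor — the symmetric
traceless 2x2 matrix built from the weighted averages of ``cos(2*theta)`` and
``sin(2*theta)`` — whose eigenvalue difference

    score = lambda_1 - lambda_2 = sqrt(<cos 2theta>^2 + <sin 2theta>^2)

is the anisotropy / nematic order parameter: 0 for an isotropic texture, 1 for
perfectly parallel fibers.

The multiscale score tiles the image into N x N non-overlapping patches for
every N in a scale plan (powers of 2 and of 3, down to a minimum patch side of
10 px), scores every patch with enough oriented pixels, assigns each pixel the
mean score of the processed patches that contain it across all scales, and
averages those per-pixel values into a single global score.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .core_io import AnisotropyConfig, ImageField, LabelMask

__all__ = [
    "OrientationField",
    "NematicTensor",
    "ScalePlan",
    "PatchScore",
    "AnisotropyResult",
    "local_orientations",
    "patch_tensor",
    "patch_anisotropy",
    "build_scale_plan",
    "multiscale_anisotropy",
]


class NoQuantifiableTextureError(ValueError):
    """Raised when no patch at any scale has enough oriented pixels."""


@dataclasses.dataclass(frozen=True)
class OrientationField:
    """Per-pixel doubled-angle orientation samples.

    ``cos2t[i, j]`` and ``sin2t[i, j]`` hold cos/sin of twice the local fiber
    angle; ``weight[i, j]`` is the sample weight, zero exactly where the local
    gradient vanishes (or the pixel is masked out / on the border).
    """

    cos2t: np.ndarray
    sin2t: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        if not (self.cos2t.shape == self.sin2t.shape == self.weight.shape):
            raise ValueError("orientation component shapes differ")
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.weight.shape

    def theta(self) -> np.ndarray:
        """Fiber angles in [0, pi); meaningful only where weight > 0."""
        return np.mod(np.arctan2(self.sin2t, self.cos2t) / 2.0, np.pi)


@dataclasses.dataclass(frozen=True)
class NematicTensor:
    """Weighted mean nematic tensor of a pixel set.

    ``c`` and ``s`` are the weighted means of cos(2 theta) and sin(2 theta);
    the tensor itself is [[c, s], [s, -c]] / 2. ``w_total`` is the summed
    weight and ``n_pixels`` the count of contributing (weight > 0) pixels.
    """

    c: float
    s: float
    w_total: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.w_total < 0:
            raise ValueError("w_total must be >= 0")
        if self.w_total == 0 and (self.c != 0.0 or self.s != 0.0):
            raise ValueError("zero-weight tensor must have c = s = 0")
        if self.c**2 + self.s**2 > 1 + 1e-12:
            raise ValueError("invalid tensor: c^2 + s^2 > 1")

    def matrix(self) -> np.ndarray:
        """The traceless 2x2 matrix [[c, s], [s, -c]] / 2."""
        return np.array([[self.c, self.s], [self.s, -self.c]]) / 2.0


@dataclasses.dataclass(frozen=True)
class ScalePlan:
    """Ordered grid sizes N used for patch tiling; first entry is 1."""

    grid_sizes: tuple[int, ...]
    min_patch_px: int = 10

    def __post_init__(self) -> None:
        gs = tuple(int(n) for n in self.grid_sizes)
        if not gs:
            raise ValueError("grid_sizes must be non-empty")
        if gs[0] != 1:
            raise ValueError("grid_sizes must start at 1 (the whole image)")
        if any(b <= a for a, b in zip(gs, gs[1:])):
            raise ValueError("grid_sizes must be strictly increasing")
        if self.min_patch_px < 2:
            raise ValueError("min_patch_px must be >= 2")
        object.__setattr__(self, "grid_sizes", gs)


@dataclasses.dataclass(frozen=True)
class PatchScore:
    """Score of one processed patch at one scale."""

    grid_size: int
    row: int
    col: int
    score: float
    n_valid_pixels: int


@dataclasses.dataclass(frozen=True)
class AnisotropyResult:
    """Output of the multiscale analysis.

    ``pixel_map`` holds per-pixel anisotropy in [0, 1], NaN where a pixel is
    outside the mask or contained in no processed patch. ``global_score`` is
    the arithmetic mean of the defined pixel_map entries.
    """

    pixel_map: np.ndarray
    patch_scores: tuple[PatchScore, ...]
    global_score: float
    scales_used: tuple[int, ...]


# ---------------------------------------------------------------------------
# Local orientation extraction
# ---------------------------------------------------------------------------

def local_orientations(image: ImageField, mask: LabelMask | None = None,
                       weighting: str = "unit") -> OrientationField:
    """Per-pixel fiber orientation from intensity gradients.

    The gradient is estimated by central differences on interior pixels;
    border pixels carry zero weight. The fiber direction is the gradient
    rotated by 90 degrees, which on the doubled circle reads

        cos 2theta = (gy^2 - gx^2) / g2,   sin 2theta = -2 gx gy / g2

    with ``g2 = gx^2 + gy^2``. ``weighting="unit"`` gives every oriented pixel
    weight 1 (pure orientation statistics); ``"grad2"`` weights by g2 so
    strong edges dominate. Pixels with zero gradient, on the image border, or
    outside ``mask`` get weight 0.
    """
    px = image.pixels
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for gradient estimation")
    if mask is not None and mask.shape != px.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {px.shape}")
    if weighting not in ("unit", "grad2"):
        raise ValueError(f"unknown weighting mode {weighting!r}")

    gx = np.zeros_like(px)  # d/dcolumn
    gy = np.zeros_like(px)  # d/drow
    gx[:, 1:-1] = (px[:, 2:] - px[:, :-2]) / 2.0
    gy[1:-1, :] = (px[2:, :] - px[:-2, :]) / 2.0

    g2 = gx * gx + gy * gy
    valid = g2 > 0
    valid[0, :] = valid[-1, :] = False
    valid[:, 0] = valid[:, -1] = False
    if mask is not None:
        valid &= mask.as_bool()

    cos2t = np.zeros_like(px)
    sin2t = np.zeros_like(px)
    np.divide(gy * gy - gx * gx, g2, out=cos2t, where=valid)
    np.divide(-2.0 * gx * gy, g2, out=sin2t, where=valid)
    cos2t[~valid] = 0.0
    sin2t[~valid] = 0.0

    if weighting == "unit":
        weight = valid.astype(np.float64)
    else:
        weight = np.where(valid, g2, 0.0)
    return OrientationField(cos2t=cos2t, sin2t=sin2t, weight=weight)


def patch_tensor(samples: OrientationField,
                 patch: tuple[int, int, int, int]) -> NematicTensor:
    """Weighted mean nematic tensor over a rectangular patch.

    ``patch`` is ``(row0, row1, col0, col1)`` with half-open bounds. A patch
    whose total weight is zero yields the isotropic tensor (c = s = 0).
    """
    r0, r1, c0, c1 = patch
    h, w = samples.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"patch {patch} empty or out of bounds for shape {samples.shape}")
    wgt = samples.weight[r0:r1, c0:c1]
    w_total = float(wgt.sum())
    n_pixels = int(np.count_nonzero(wgt))
    if w_total == 0.0:
        return NematicTensor(0.0, 0.0, 0.0, 0)
    c = float((samples.cos2t[r0:r1, c0:c1] * wgt).sum() / w_total)
    s = float((samples.sin2t[r0:r1, c0:c1] * wgt).sum() / w_total)
    # guard against rounding pushing c^2+s^2 microscopically above 1
    norm = np.hypot(c, s)
    if norm > 1.0:
        c, s = c / norm, s / norm
    return NematicTensor(c, s, w_total, n_pixels)


def patch_anisotropy(t: NematicTensor) -> float:
    """Anisotropy score of a nematic tensor: the eigenvalue difference.

    For [[c, s], [s, -c]] / 2 the eigenvalues are +-sqrt(c^2 + s^2)/2, so the
    difference is sqrt(c^2 + s^2) — the circular resultant length of the
    doubled angles. Zero-weight tensors score 0.
    """
    if t.w_total == 0.0:
        return 0.0
    return float(min(np.hypot(t.c, t.s), 1.0))


# ---------------------------------------------------------------------------
# Scale plan and multiscale aggregation
# ---------------------------------------------------------------------------

def _scale_candidates(limit: int, base: str) -> list[int]:
    """Candidate grid sizes up to ``limit``, deduplicated and sorted."""
    out: set[int] = set()
    if base == "powers":
        for b in (2, 3):
            n = 1
            while n <= limit:
                out.add(n)
                n *= b
    elif base == "multiples":
        out.add(1)  # whole image always included
        for b in (2, 3):
            n = b
            while n <= limit:
                out.add(n)
                n += b
    else:
        raise ValueError(f"unknown scale_base {base!r}")
    return sorted(out)


def build_scale_plan(height: int, width: int, min_patch_px: int = 10,
                     scale_base: str = "powers") -> ScalePlan:
    """Grid sizes usable for an image of the given shape.

    Keeps every candidate N (powers of 2 and 3 by default, i.e. N in
    {2^i} u {3^i}, i >= 0) whose floor-divided patch sides are at least
    ``min_patch_px`` in both dimensions.
    """
    if min_patch_px < 2:
        raise ValueError("min_patch_px must be >= 2")
    if height < min_patch_px or width < min_patch_px:
        raise ValueError(
            f"image {height}x{width} smaller than the minimum patch side {min_patch_px}"
        )
    limit = min(height, width) // min_patch_px
    sizes = [n for n in _scale_candidates(limit, scale_base)
             if height // n >= min_patch_px and width // n >= min_patch_px]
    return ScalePlan(grid_sizes=tuple(sizes), min_patch_px=min_patch_px)


def _patch_edges(extent: int, n: int) -> np.ndarray:
    """Half-open patch boundaries along one axis.

    Patches have side ``extent // n``; the last patch absorbs the remainder so
    the tiling is exact and non-overlapping.
    """
    side = extent // n
    edges = np.arange(n + 1) * side
    edges[-1] = extent
    return edges


def multiscale_anisotropy(image: ImageField, mask: LabelMask | None = None,
                          plan: ScalePlan | None = None,
                          min_valid_pixels: int = 100,
                          weighting: str = "unit") -> AnisotropyResult:
    """Multiscale anisotropy score of a fibrous image.

    For each grid size N in ``plan`` the image is tiled into N x N
    non-overlapping patches (the last row/column of patches absorbs any
    remainder). A patch is processed when it contains at least
    ``min_valid_pixels`` oriented (weight > 0) pixels; its nematic-tensor
    score is then spread to every pixel of the patch (restricted to the mask).
    Each pixel's value is the mean score of the processed patches containing
    it across all scales; the global score is the mean over pixels with at
    least one contribution.

    Raises
    ------
    NoQuantifiableTextureError
        If no patch at any scale reaches ``min_valid_pixels`` — e.g. a
        constant image, or a mask covering too few pixels.
    """
    if plan is None:
        plan = build_scale_plan(image.height, image.width)
    field = local_orientations(image, mask=mask, weighting=weighting)
    h, w = field.shape

    score_sum = np.zeros((h, w))
    score_cnt = np.zeros((h, w), dtype=np.int64)
    patch_scores: list[PatchScore] = []
    scales_used: list[int] = []

    for n in plan.grid_sizes:
        row_edges = _patch_edges(h, n)
        col_edges = _patch_edges(w, n)
        any_processed = False
        for pr in range(n):
            r0, r1 = int(row_edges[pr]), int(row_edges[pr + 1])
            for pc in range(n):
                c0, c1 = int(col_edges[pc]), int(col_edges[pc + 1])
                tensor = patch_tensor(field, (r0, r1, c0, c1))
                if tensor.n_pixels < min_valid_pixels:
                    continue
                score = patch_anisotropy(tensor)
                patch_scores.append(PatchScore(n, pr, pc, score, tensor.n_pixels))
                score_sum[r0:r1, c0:c1] += score
                score_cnt[r0:r1, c0:c1] += 1
                any_processed = True
        if any_processed:
            scales_used.append(n)

    included = score_cnt > 0
    if mask is not None:
        included &= mask.as_bool()
    if not included.any():
        raise NoQuantifiableTextureError(
            "no quantifiable texture: no patch at any scale has enough oriented pixels"
        )

    pixel_map = np.full((h, w), np.nan)
    pixel_map[included] = score_sum[included] / score_cnt[included]
    values = pixel_map[included]
    if np.all(values == values[0]):
        # mean of identical values, taken exactly (keeps the single-scale
        # result bit-identical to the whole-image patch score)
        global_score = float(values[0])
    else:
        global_score = float(values.mean())
    return AnisotropyResult(
        pixel_map=pixel_map,
        patch_scores=tuple(patch_scores),
        global_score=global_score,
        scales_used=tuple(scales_used),
    )


def multiscale_anisotropy_cfg(image: ImageField, mask: LabelMask | None,
                              cfg: AnisotropyConfig) -> AnisotropyResult:
    """Config-driven wrapper around :func:`multiscale_anisotropy`."""
    cfg.validate()
    plan = build_scale_plan(image.height, image.width,
                            min_patch_px=cfg.min_patch_px,
                            scale_base=cfg.scale_base)
    return multiscale_anisotropy(image, mask=mask, plan=plan,
                                 min_valid_pixels=cfg.min_valid_pixels,
                                 weighting=cfg.weighting)
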