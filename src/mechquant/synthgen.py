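"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the inputs the real pipeline consumes:

* fibrous textures (stand-in for phalloidin/actin micrographs) with fiber
  angles drawn from a von Mises distribution on the doubled circle, so the
  planted order parameter lives on the same scale as the anisotropy score;
* fields of non-overlapping cells (Hoechst + marker channel) with a planted
  nuclear:cytosolic marker ratio and planted QC defects (border-touching,
  bright "mitotic", elongated "aberrant" nuclei);
* screen plates of control and siRNA wells with planted effects in control-SD
  units, mirroring a 3-replicate, 4-wells-per-siRNA layout.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .core_io import ImageField

__all__ = [
    "FiberSpec",
    "CellFieldSpec",
    "ScreenSimSpec",
    "generate_fibers",
    "generate_cell_field",
    "simulate_screen",
    "stripe_texture",
    "four_orientation_composite",
    "order_parameter",
]


# ---------------------------------------------------------------------------
# Deterministic benchmark textures
# ---------------------------------------------------------------------------

def stripe_texture(height: int = 256, width: int = 256, period: float = 8.0,
                   angle: float = 0.0, offset: float = 2.0) -> ImageField:
    """Sinusoidal grating whose fibers run along ``angle`` (radians, mod pi).

    ``angle = 0`` gives horizontal stripes (intensity varies along rows), the
    fully anisotropic reference texture; the anisotropy score of any pure
    grating is 1 up to discretization.
    """
    r = np.arange(height, dtype=np.float64)[:, None]
    c = np.arange(width, dtype=np.float64)[None, :]
    # intensity varies perpendicular to the fiber direction
    u = r * np.cos(angle) + c * np.sin(angle)
    return ImageField(np.sin(2.0 * np.pi * u / period) + offset)


def four_orientation_composite(height: int = 256, width: int = 256,
                               tile: int = 4, period: float = 8.0,
                               offset: float = 10.0) -> ImageField:
    """Balanced composite of gratings at 0, 45, 90 and 135 degrees.

    The image is tiled with ``tile`` x ``tile`` px blocks; a Latin-square
    layout assigns each block one of the four orientations so that every
    aligned 2x2 block of tiles — hence every analysis patch larger than
    2*tile — contains all four in equal measure. The orientation content is
    4-fold symmetric, so the nematic mean cancels and the anisotropy score is
    near 0 (residual comes from tile-boundary gradients).
    """
    r = np.arange(height, dtype=np.float64)[:, None] * np.ones((1, width))
    c = np.arange(width, dtype=np.float64)[None, :] * np.ones((height, 1))
    k = 2.0 * np.pi / period
    patterns = [np.sin(k * r), np.sin(k * c),
                np.sin(k * (r + c)), np.sin(k * (r - c))]
    tr = (r // tile).astype(int)
    tc = (c // tile).astype(int)
    idx = (tr + 2 * tc) % 4
    return ImageField(np.choose(idx, patterns) + offset)


# ---------------------------------------------------------------------------
# Fibrous textures
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FiberSpec:
    """Parameters of a synthetic fiber image.

    ``kappa`` is the von Mises concentration on the doubled angle 2*theta;
    kappa = 0 gives isotropic (uniform) fiber angles. ``fiber_width`` is the
    Gaussian ridge full width at half maximum in px.
    """

    height: int = 512
    width: int = 512
    n_fibers: int = 300
    mu: float = 0.0
    kappa: float = 0.0
    fiber_width: float = 3.0
    intensity: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("image must be at least 8x8")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.fiber_width <= 0 or self.intensity <= 0:
            raise ValueError("fiber_width and intensity must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sample_fiber_angles(spec: FiberSpec, rng: np.random.Generator) -> np.ndarray:
    """Fiber angles theta in [0, pi): 2*theta ~ von Mises(2*mu, kappa)."""
    if spec.kappa == 0:
        doubled = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_fibers)
    else:
        doubled = rng.vonmises(2.0 * spec.mu, spec.kappa, size=spec.n_fibers)
    return np.mod(doubled / 2.0, np.pi)


def order_parameter(theta: np.ndarray) -> float:
    """Nematic order parameter |mean exp(2i*theta)| of a set of angles."""
    z = np.exp(2j * np.asarray(theta, dtype=np.float64))
    return float(np.abs(z.mean()))


def generate_fibers(spec: FiberSpec) -> tuple[ImageField, float]:
    """Render a fiber image; returns (image, planted order parameter).

    Fibers are full-length chords through random anchor points, drawn as
    Gaussian-profile ridges (additive intensity), plus additive Gaussian
    noise clipped at zero. The returned truth is the empirical order
    parameter of the sampled angles — the quantity an ideal anisotropy
    measurement would recover.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    theta = _sample_fiber_angles(spec, rng)
    truth = order_parameter(theta)

    h, w = spec.height, spec.width
    img = np.zeros((h, w))
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    sigma = spec.fiber_width / 2.3548  # FWHM -> Gaussian sigma
    cutoff = 3.0 * sigma

    centers_r = rng.uniform(0, h, size=spec.n_fibers)
    centers_c = rng.uniform(0, w, size=spec.n_fibers)
    for t, cr, cc in zip(theta, centers_r, centers_c):
        # image rows grow downward, so the angle convention (measured from
        # the +column axis, counter-clockwise in xy) maps to direction
        # (dr, dc) = (-sin t, cos t); distance to the infinite line through
        # (cr, cc) is |(r - cr) cos t + (c - cc) sin t|
        d = np.abs((rows - cr) * np.cos(t) + (cols - cc) * np.sin(t))
        band = d < cutoff
        img[band] += spec.intensity * np.exp(-0.5 * (d[band] / sigma) ** 2)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, None, out=img)
    return ImageField(img), truth


# ---------------------------------------------------------------------------
# Cell fields
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CellFieldSpec:
    """Parameters of a synthetic two-channel cell field.

    Each cell is a nuclear disk of ``nucleus_radius`` inside a cytoplasmic
    disk of ``cytoplasm_radius``. The marker channel carries intensity
    ``marker_base`` in the cytoplasm and ``nc_ratio_true * marker_base`` in
    the nucleus, with multiplicative lognormal noise of coefficient of
    variation ``noise_cv``. Fractions of cells are planted as QC defects:
    border-touching, mitotic (2.5x Hoechst), aberrant (3:1 elliptical
    nucleus).
    """

    height: int = 1024
    width: int = 1024
    n_cells: int = 50
    nucleus_radius: float = 9.0
    cytoplasm_radius: float = 20.0
    nc_ratio_true: float = 2.0
    marker_base: float = 100.0
    noise_cv: float = 0.1
    frac_border: float = 0.0
    frac_mitotic: float = 0.0
    frac_aberrant: float = 0.0
    hoechst_intensity: float = 200.0
    mitotic_intensity_factor: float = 2.5
    aberrant_axis_ratio: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.cytoplasm_radius <= self.nucleus_radius:
            raise ValueError("cytoplasm_radius must exceed nucleus_radius")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.nc_ratio_true <= 0:
            raise ValueError("nc_ratio_true must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        fracs = (self.frac_border, self.frac_mitotic, self.frac_aberrant)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("QC fractions must lie in [0,1] and sum to <= 1")


_PLACEMENT_ATTEMPTS = 10_000


def _place_cells(spec: CellFieldSpec, rng: np.random.Generator,
                 categories: list[str]) -> np.ndarray:
    """Rejection-sample non-overlapping cell centers; border cells hug an edge."""
    r_cell = spec.cytoplasm_radius
    min_sep = 2.0 * r_cell + 2.0
    centers: list[tuple[float, float]] = []
    for cat in categories:
        placed = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            if cat == "border":
                # nucleus must touch the frame: center within nucleus_radius of an edge
                edge = rng.integers(4)
                off = rng.uniform(0, spec.nucleus_radius - 1.0)
                if edge == 0:
                    cr, cc = off, rng.uniform(r_cell, spec.width - r_cell)
                elif edge == 1:
                    cr, cc = spec.height - 1 - off, rng.uniform(r_cell, spec.width - r_cell)
                elif edge == 2:
                    cr, cc = rng.uniform(r_cell, spec.height - r_cell), off
                else:
                    cr, cc = rng.uniform(r_cell, spec.height - r_cell), spec.width - 1 - off
            else:
                cr = rng.uniform(r_cell + 1, spec.height - r_cell - 1)
                cc = rng.uniform(r_cell + 1, spec.width - r_cell - 1)
            if all((cr - pr) ** 2 + (cc - pc) ** 2 >= min_sep**2 for pr, pc in centers):
                centers.append((cr, cc))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"cell packing failed after {_PLACEMENT_ATTEMPTS} attempts; "
                "reduce n_cells or cell radius"
            )
    return np.asarray(centers)


def generate_cell_field(
    spec: CellFieldSpec,
) -> tuple[ImageField, ImageField, pd.DataFrame]:
    """Render a cell field; returns (hoechst, marker, truth table).

    The truth table has one row per rendered cell: ``cell`` (1-based id,
    raster order of centers), ``row``/``col`` center, ``category`` in
    {normal, border, mitotic, aberrant}, ``nc_ratio_true``, and ``qc_expect``
    — False for planted defects (they should be excluded by QC).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_border = int(round(spec.frac_border * spec.n_cells))
    n_mitotic = int(round(spec.frac_mitotic * spec.n_cells))
    n_aberrant = int(round(spec.frac_aberrant * spec.n_cells))
    n_normal = spec.n_cells - n_border - n_mitotic - n_aberrant
    categories = (["normal"] * n_normal + ["border"] * n_border
                  + ["mitotic"] * n_mitotic + ["aberrant"] * n_aberrant)
    centers = _place_cells(spec, rng, categories)

    # raster order so labels from segmentation align with truth rows
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    centers = centers[order]
    categories = [categories[i] for i in order]

    h, w = spec.height, spec.width
    hoechst = np.zeros((h, w))
    marker = np.zeros((h, w))
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]

    records = []
    for idx, ((cr, cc), cat) in enumerate(zip(centers, categories), start=1):
        r_nuc = spec.nucleus_radius
        r_cyt = spec.cytoplasm_radius
        lo_r = max(0, int(cr - r_cyt - 2))
        hi_r = min(h, int(cr + r_cyt + 3))
        lo_c = max(0, int(cc - r_cyt - 2))
        hi_c = min(w, int(cc + r_cyt + 3))
        rr = rows[lo_r:hi_r] - cr
        cc_ = cols[:, lo_c:hi_c] - cc

        if cat == "aberrant":
            # same-area ellipse with 3:1 axes, random orientation
            q = np.sqrt(spec.aberrant_axis_ratio)
            a, b = r_nuc * q, r_nuc / q
            phi = rng.uniform(0, np.pi)
            u = rr * np.cos(phi) + cc_ * np.sin(phi)
            v = -rr * np.sin(phi) + cc_ * np.cos(phi)
            nuc = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        else:
            nuc = rr**2 + cc_**2 <= r_nuc**2
        cyt = (rr**2 + cc_**2 <= r_cyt**2) & ~nuc

        hv = spec.hoechst_intensity
        if cat == "mitotic":
            hv *= spec.mitotic_intensity_factor
        hoechst[lo_r:hi_r, lo_c:hi_c][nuc] = hv
        marker[lo_r:hi_r, lo_c:hi_c][nuc] = spec.nc_ratio_true * spec.marker_base
        marker[lo_r:hi_r, lo_c:hi_c][cyt] = spec.marker_base

        records.append({
            "cell": idx, "row": cr, "col": cc, "category": cat,
            "nc_ratio_true": spec.nc_ratio_true,
            "qc_expect": cat == "normal",
        })

    if spec.noise_cv > 0:
        # lognormal multiplicative noise with unit mean and the requested CV
        sig2 = np.log1p(spec.noise_cv**2)
        noise = rng.lognormal(-sig2 / 2.0, np.sqrt(sig2), size=marker.shape)
        marker *= noise
        hoechst *= rng.lognormal(-sig2 / 2.0, np.sqrt(sig2), size=hoechst.shape)

    truth = pd.DataFrame.from_records(records)
    return ImageField(hoechst), ImageField(marker), truth


# ---------------------------------------------------------------------------
# Screen plates
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ScreenSimSpec:
    """Parameters of a simulated siRNA screen.

    ``planted_effects`` maps siRNA ids to effect sizes in control-SD units;
    unlisted siRNAs have effect 0. The layout is one plate per replicate with
    ``wells_per_sirna`` wells per siRNA plus ``n_control_wells`` non-targeting
    control wells.
    """

    n_sirnas: int = 89
    n_control_wells: int = 32
    wells_per_sirna: int = 4
    n_replicates: int = 3
    control_mean: float = 1.0
    control_sd: float = 0.1
    planted_effects: Mapping[str, float] = dataclasses.field(default_factory=dict)
    genotype: str = "WT"
    seed: int = 0

    def validate(self) -> None:
        if self.n_control_wells < 2:
            raise ValueError("need at least 2 control wells")
        if self.wells_per_sirna < 1 or self.n_replicates < 1 or self.n_sirnas < 1:
            raise ValueError("counts must be >= 1")
        if self.control_sd <= 0:
            raise ValueError("control_sd must be > 0")
        known = {f"siRNA_{i:03d}" for i in range(1, self.n_sirnas + 1)}
        unknown = set(self.planted_effects) - known
        if unknown:
            raise ValueError(f"planted effects for unknown siRNAs: {sorted(unknown)}")


def simulate_screen(spec: ScreenSimSpec) -> pd.DataFrame:
    """Simulate per-well screen measurements.

    Returns a table with columns (plate, well, sirna, genotype, replicate,
    is_control, value): control wells ~ Normal(control_mean, control_sd),
    siRNA wells ~ Normal(control_mean + effect * control_sd, control_sd),
    independent across wells and replicates. siRNA ids are ``siRNA_001`` ...;
    controls are ``NT_ctrl``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(1, spec.n_replicates + 1):
        plate = f"plate_r{rep}"
        well = 0
        for _ in range(spec.n_control_wells):
            well += 1
            rows.append({
                "plate": plate, "well": f"W{well:03d}", "sirna": "NT_ctrl",
                "genotype": spec.genotype, "replicate": rep, "is_control": True,
                "value": rng.normal(spec.control_mean, spec.control_sd),
            })
        for i in range(1, spec.n_sirnas + 1):
            sid = f"siRNA_{i:03d}"
            effect = float(spec.planted_effects.get(sid, 0.0))
            mean = spec.control_mean + effect * spec.control_sd
            for _ in range(spec.wells_per_sirna):
                well += 1
                rows.append({
                    "plate": plate, "well": f"W{well:03d}", "sirna": sid,
                    "genotype": spec.genotype, "replicate": rep,
                    "is_control": False,
                    "value": rng.normal(mean, spec.control_sd),
                })
    return pd.DataFrame.from_records(rows)
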