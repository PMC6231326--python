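"""Per-cell nucleocytoplasmic marker quantification.

Pipeline: segment nuclei from the DNA (Hoechst) channel, drop nuclei that
fail quality control (mitotic-bright, aberrantly shaped, out-of-range area,
or touching the image border), build a fixed-width perinuclear ring as the
cytosolic region of interest, optionally grow a whole-cell region for the
nuclear-to-total readout, and compute per-cell intensity ratios and a
categorical localization call (predominantly nuclear N, predominantly
cytosolic C, or even N/C).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters, measure, segmentation

from .core_io import ImageField, LabelMask, NCQuantConfig

__all__ = [
    "NucleusRecord",
    "CellMeasurement",
    "segment_nuclei",
    "qc_filter",
    "perinuclear_ring",
    "grow_cell_region",
    "measure_cells",
    "classify_distribution",
    "summarize_fractions",
]


@dataclasses.dataclass(frozen=True)
class NucleusRecord:
    """Morphology, intensity and QC verdict of one segmented nucleus.

    ``roundness`` is 4*pi*area/perimeter^2 (1 for a perfect circle; digital
    circles can slightly exceed 1). ``qc_reasons`` lists the failed checks
    from {mitotic_intensity, aberrant_roundness, area_out_of_range, border};
    ``qc_pass`` is true exactly when the list is empty.
    """

    label: int
    area: float
    perimeter: float
    roundness: float
    mean_hoechst: float
    touches_border: bool
    qc_pass: bool
    qc_reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.qc_pass != (len(self.qc_reasons) == 0):
            raise ValueError("qc_pass must mirror an empty qc_reasons list")


@dataclasses.dataclass(frozen=True)
class CellMeasurement:
    """Marker intensities and localization call for one QC-passing cell.

    ``nc_ratio`` = nuclear mean / perinuclear-ring mean (NaN when the ring
    mean is zero); ``nuclear_to_total`` = summed nuclear marker / summed
    whole-cell marker, in [0, 1]. ``loc_class`` is "N", "C", "NC", or ""
    when the ratio is undefined.
    """

    label: int
    nuclear_mean: float
    ring_mean: float
    total_mean: float
    nc_ratio: float
    nuclear_to_total: float
    loc_class: str


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _raster_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber objects 1..K by raster order of their centroids."""
    objs = measure.regionprops(labels)
    if not objs:
        return labels
    order = sorted(objs, key=lambda o: (o.centroid[0], o.centroid[1]))
    out = np.zeros_like(labels)
    for new, obj in enumerate(order, start=1):
        out[labels == obj.label] = new
    return out


def segment_nuclei(hoechst: ImageField, min_area: float = 50.0,
                   smoothing_sigma: float = 2.0) -> LabelMask:
    """Segment nuclei from the DNA channel.

    Gaussian smoothing, global Otsu threshold, hole filling, then a
    distance-transform watershed to split touching nuclei; components below
    ``min_area`` px^2 are removed and labels are assigned in raster order of
    centroids. An image where thresholding finds nothing returns an empty
    mask with a warning; a constant image raises, since no threshold exists.
    """
    px = hoechst.pixels
    if px.max() == px.min():
        raise ValueError("constant image: no threshold separates nuclei from background")
    smoothed = filters.gaussian(px, sigma=smoothing_sigma, preserve_range=True)
    thr = filters.threshold_otsu(smoothed)
    binary = ndi.binary_fill_holes(smoothed > thr)

    if not binary.any():
        warnings.warn("no nuclei found; returning empty mask", stacklevel=2)
        return LabelMask(np.zeros(px.shape, dtype=np.int64))

    # distance-transform watershed; the distance map is smoothed so noise on
    # the object boundary does not spawn spurious seeds inside one nucleus
    distance = ndi.distance_transform_edt(binary)
    dist_smooth = ndi.gaussian_filter(distance, sigma=max(1.0, smoothing_sigma))
    components = measure.label(binary)
    min_radius = max(3, int(round(np.sqrt(min_area / np.pi))))
    peaks = feature.peak_local_max(
        dist_smooth, labels=components, min_distance=min_radius,
        exclude_border=False,
    )
    seeds = np.zeros(px.shape, dtype=np.int64)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    labels = segmentation.watershed(-dist_smooth, markers=seeds, mask=binary)

    # per-nucleus half-max refinement: a single global threshold hands bright
    # nuclei an oversized dim halo, so each label is re-cut at half of its own
    # upper (90th percentile) intensity. The boundary is taken from a finer
    # smoothing scale than detection, so high-curvature shape detail (e.g.
    # the tips of elongated nuclei) survives.
    fine = filters.gaussian(px, sigma=min(1.0, smoothing_sigma),
                            preserve_range=True)
    refined = np.zeros_like(labels)
    for obj in measure.regionprops(labels, intensity_image=fine):
        sl = obj.slice
        in_label = labels[sl] == obj.label
        local = fine[sl]
        cut = 0.5 * np.percentile(local[in_label], 90)
        keep = in_label & (local >= cut)
        keep = ndi.binary_fill_holes(keep)
        refined[sl][keep] = obj.label
    labels = refined

    # drop components below min_area (strictly smaller objects are removed)
    sizes = np.bincount(labels.ravel())
    too_small = np.flatnonzero(sizes < min_area)
    labels[np.isin(labels, too_small)] = 0
    if not labels.any():
        warnings.warn("no nuclei found after size filtering; returning empty mask",
                      stacklevel=2)
        return LabelMask(np.zeros(px.shape, dtype=np.int64))
    return LabelMask(_raster_relabel(labels))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(mask: LabelMask, hoechst: ImageField,
              cfg: NCQuantConfig | None = None) -> list[NucleusRecord]:
    """Score every nucleus against the QC rules.

    Flags: ``mitotic_intensity`` when the nuclear mean Hoechst exceeds the
    population median by ``cfg.mitotic_factor``; ``aberrant_roundness`` when
    4*pi*A/P^2 falls below ``cfg.min_roundness``; ``area_out_of_range``
    outside [min_area, max_area]; ``border`` when any nucleus pixel lies in
    the outermost row or column. Nuclei failing any check have
    ``qc_pass=False``; an empty mask yields an empty list.
    """
    cfg = cfg or NCQuantConfig()
    cfg.validate()
    if mask.shape != hoechst.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {hoechst.shape}")
    labels = mask.labels
    props = measure.regionprops(labels, intensity_image=hoechst.pixels)
    if not props:
        return []

    mean_hoechst = {p.label: float(p.intensity_mean) for p in props}
    pop_median = float(np.median(list(mean_hoechst.values())))
    h, w = labels.shape
    border_labels = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])))
    border_labels.discard(0)

    records = []
    for p in props:
        area = float(p.area)
        perimeter = float(p.perimeter)
        roundness = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
        reasons = []
        if mean_hoechst[p.label] > cfg.mitotic_factor * pop_median:
            reasons.append("mitotic_intensity")
        if roundness < cfg.min_roundness:
            reasons.append("aberrant_roundness")
        if not (cfg.min_area <= area <= cfg.max_area):
            reasons.append("area_out_of_range")
        if p.label in border_labels:
            reasons.append("border")
        records.append(NucleusRecord(
            label=int(p.label), area=area, perimeter=perimeter,
            roundness=float(roundness), mean_hoechst=mean_hoechst[p.label],
            touches_border=p.label in border_labels,
            qc_pass=not reasons, qc_reasons=tuple(reasons),
        ))
    return records


# ---------------------------------------------------------------------------
# Regions of interest
# ---------------------------------------------------------------------------

def perinuclear_ring(mask: LabelMask, width_px: int = 4) -> LabelMask:
    """Fixed-width cytosolic ring grown radially from each nuclear border.

    Each ring is the Euclidean dilation of its nucleus by ``width_px`` minus
    all nuclear pixels; where rings of neighboring nuclei would overlap, each
    pixel goes to the nearest nucleus (ties broken by the smaller label, via
    the distance-transform assignment).
    """
    if width_px < 1:
        raise ValueError("ring width must be >= 1 px")
    labels = mask.labels
    # expand_labels assigns each background pixel within the distance to its
    # nearest labeled object — exactly the nearest-nucleus conflict rule
    expanded = segmentation.expand_labels(labels, distance=width_px)
    rings = np.where(labels > 0, 0, expanded)
    return LabelMask(rings)


def grow_cell_region(mask: LabelMask, marker: ImageField,
                     max_grow_px: int = 40,
                     smoothing_sigma: float = 2.0,
                     support: np.ndarray | None = None) -> LabelMask:
    """Whole-cell region per nucleus for the nuclear-to-total readout.

    Grows each nuclear label outward by nearest-nucleus assignment over a
    cell-area support (by default: Otsu threshold of the smoothed marker
    channel, union the nuclei), capped at ``max_grow_px``. Neighboring cells
    partition the support — regions never overlap.
    """
    if mask.shape != marker.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {marker.shape}")
    labels = mask.labels
    if support is None:
        px = marker.pixels
        if px.max() > px.min():
            smoothed = filters.gaussian(px, sigma=smoothing_sigma, preserve_range=True)
            support = smoothed > filters.threshold_otsu(smoothed)
        else:
            support = np.zeros(px.shape, dtype=bool)
    support = support | (labels > 0)
    grown = segmentation.expand_labels(labels, distance=max_grow_px)
    return LabelMask(np.where(support, grown, 0))


# ---------------------------------------------------------------------------
# Measurement and classification
# ---------------------------------------------------------------------------

def classify_distribution(nc_ratio: float, delta: float = 0.2) -> str:
    """Categorical localization call from the nuclear:cytosolic ratio.

    "N" (predominantly nuclear) when ratio > 1 + delta, "C" (predominantly
    cytosolic) when ratio < 1/(1 + delta), otherwise "NC" (even). The band is
    symmetric on the log scale, so a ratio r and its reciprocal 1/r always
    fall in mirror classes.
    """
    if not np.isfinite(nc_ratio) or nc_ratio <= 0:
        raise ValueError(f"nc_ratio must be positive and finite, got {nc_ratio}")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if nc_ratio > 1.0 + delta:
        return "N"
    if nc_ratio < 1.0 / (1.0 + delta):
        return "C"
    return "NC"


def measure_cells(marker: ImageField, nuclei: LabelMask, rings: LabelMask,
                  cells: LabelMask | None, records: list[NucleusRecord],
                  cfg: NCQuantConfig | None = None) -> list[CellMeasurement]:
    """Marker readouts for every QC-passing nucleus.

    ``nc_ratio`` divides the nuclear mean by the perinuclear-ring mean; cells
    whose ring mean is zero get NaN and an empty localization class (they are
    excluded from ratio summaries). ``nuclear_to_total`` divides the summed
    nuclear marker by the summed marker over the whole-cell region (the
    nucleus itself when ``cells`` is None).
    """
    cfg = cfg or NCQuantConfig()
    if not (marker.shape == nuclei.shape == rings.shape):
        raise ValueError("marker, nuclei and rings shapes differ")
    if cells is not None and cells.shape != marker.shape:
        raise ValueError("cells mask shape differs from marker")

    px = marker.pixels
    nuc = nuclei.labels
    ring = rings.labels
    cell = cells.labels if cells is not None else nuc

    ring_labels = set(np.unique(ring)) - {0}
    out = []
    for rec in records:
        if not rec.qc_pass:
            continue
        lab = rec.label
        if lab not in ring_labels:
            raise ValueError(f"nucleus label {lab} has no perinuclear ring")
        nuc_px = px[nuc == lab]
        ring_px = px[ring == lab]
        cell_sel = cell == lab
        if not cell_sel.any():
            cell_sel = nuc == lab
        cell_px = px[cell_sel]

        nuclear_mean = float(nuc_px.mean())
        ring_mean = float(ring_px.mean()) if ring_px.size else 0.0
        total_mean = float(cell_px.mean())
        nuclear_sum = float(nuc_px.sum())
        total_sum = float(cell_px.sum())

        if ring_mean > 0:
            nc_ratio = nuclear_mean / ring_mean
            loc_class = classify_distribution(nc_ratio, delta=cfg.delta)
        else:
            nc_ratio = float("nan")
            loc_class = ""
        nuclear_to_total = nuclear_sum / total_sum if total_sum > 0 else 0.0

        out.append(CellMeasurement(
            label=lab, nuclear_mean=nuclear_mean, ring_mean=ring_mean,
            total_mean=total_mean, nc_ratio=nc_ratio,
            nuclear_to_total=float(np.clip(nuclear_to_total, 0.0, 1.0)),
            loc_class=loc_class,
        ))
    return out


def summarize_fractions(measurements: list[CellMeasurement]) -> dict[str, float]:
    """Percentages of cells called N, C and NC (summing to 100)."""
    classes = [m.loc_class for m in measurements if m.loc_class]
    if not classes:
        raise ValueError("no classified cells to summarize")
    n = len(classes)
    return {cls: 100.0 * classes.count(cls) / n for cls in ("N", "C", "NC")}


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def quantify_field(hoechst: ImageField, marker: ImageField,
                   cfg: NCQuantConfig | None = None,
                   nuclei: LabelMask | None = None
                   ) -> tuple[list[NucleusRecord], list[CellMeasurement]]:
    """Run the full per-field pipeline: segment, QC, rings, cells, measure.

    Pass ``nuclei`` to bypass segmentation with an externally supplied mask.
    """
    cfg = cfg or NCQuantConfig()
    cfg.validate()
    if nuclei is None:
        nuclei = segment_nuclei(hoechst, min_area=cfg.min_area,
                                smoothing_sigma=cfg.smoothing_sigma)
    records = qc_filter(nuclei, hoechst, cfg)
    rings = perinuclear_ring(nuclei, width_px=cfg.ring_width)
    cells = grow_cell_region(nuclei, marker, max_grow_px=cfg.max_grow_px,
                             smoothing_sigma=cfg.smoothing_sigma)
    measurements = measure_cells(marker, nuclei, rings, cells, records, cfg)
    return records, measurements


def measurements_frame(records: list[NucleusRecord],
                       measurements: list[CellMeasurement]) -> pd.DataFrame:
    """Join nucleus QC records with cell measurements into one table."""
    rec_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if rec_df.empty:
        return rec_df
    rec_df["qc_reasons"] = rec_df["qc_reasons"].map(lambda r: ";".join(r))
    meas_df = pd.DataFrame([dataclasses.asdict(m) for m in measurements])
    if meas_df.empty:
        return rec_df
    return rec_df.merge(meas_df, on="label", how="left")
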