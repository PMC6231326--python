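import numpy as np
import pytest
from skimage import measure

from mechquant import (
    CellFieldSpec,
    ImageField,
    LabelMask,
    classify_distribution,
    generate_cell_field,
    grow_cell_region,
    measure_cells,
    perinuclear_ring,
    qc_filter,
    quantify_field,
    segment_nuclei,
    summarize_fractions,
)
from mechquant.core_io import NCQuantConfig
from mechquant.nc_quant import NucleusRecord

from conftest import qc_confusion


def disk_image(shape, centers, radius, value=200.0, background=1.0):
    """Bright disks on a dim background (synthetic DNA channel)."""
    img = np.full(shape, background)
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    for cr, cc in centers:
        img[(r - cr) ** 2 + (c - cc) ** 2 <= radius**2] = value
    return ImageField(img)


def disk_mask(shape, centers, radius):
    lab = np.zeros(shape, dtype=np.int64)
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    for k, (cr, cc) in enumerate(centers, start=1):
        lab[(r - cr) ** 2 + (c - cc) ** 2 <= radius**2] = k
    return LabelMask(lab)


class TestSegmentNuclei:
    def test_single_disk_area_matches_analytic(self):
        img = disk_image((128, 128), [(64, 64)], radius=15)
        mask = segment_nuclei(img)
        assert len(mask.object_labels) == 1
        area = np.count_nonzero(mask.labels)
        assert area == pytest.approx(np.pi * 15**2, rel=0.10)

    def test_two_separated_disks(self):
        img = disk_image((128, 128), [(40, 40), (88, 88)], radius=12)
        mask = segment_nuclei(img)
        assert len(mask.object_labels) == 2

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="constant"):
            segment_nuclei(ImageField(np.zeros((64, 64))))

    def test_labels_in_raster_order(self):
        img = disk_image((128, 128), [(100, 20), (20, 100)], radius=10)
        mask = segment_nuclei(img)
        props = {p.label: p.centroid for p in measure.regionprops(mask.labels)}
        assert props[1][0] < props[2][0]  # label 1 is the upper nucleus


class TestQCFilter:
    def test_interior_circular_nucleus_passes(self):
        img = disk_image((128, 128), [(64, 64), (30, 30)], radius=10)
        mask = disk_mask((128, 128), [(64, 64), (30, 30)], radius=10)
        records = qc_filter(mask, img)
        assert all(r.qc_pass for r in records)

    def test_border_touching_nucleus_flagged(self):
        img = disk_image((128, 128), [(0, 64), (64, 64)], radius=10)
        mask = disk_mask((128, 128), [(0, 64), (64, 64)], radius=10)
        records = {r.label: r for r in qc_filter(mask, img)}
        assert "border" in records[1].qc_reasons
        assert records[2].qc_pass

    def test_bright_nucleus_flagged_mitotic(self):
        img = disk_image((128, 128), [(30, 30), (64, 64), (100, 100)], radius=10)
        px = img.pixels.copy()
        r = np.arange(128)[:, None]
        c = np.arange(128)[None, :]
        px[(r - 100) ** 2 + (c - 100) ** 2 <= 100] = 200 * 2.5
        mask = disk_mask((128, 128), [(30, 30), (64, 64), (100, 100)], radius=10)
        records = {x.label: x for x in qc_filter(mask, ImageField(px))}
        assert "mitotic_intensity" in records[3].qc_reasons
        assert records[1].qc_pass and records[2].qc_pass

    def test_elongated_nucleus_has_low_roundness(self):
        """A rendered 3:1 ellipse measures roundness ~0.64 by pixel-counting
        perimeter, well below a disk's ~0.9+."""
        shape = (128, 128)
        r = np.arange(shape[0])[:, None] - 64.0
        c = np.arange(shape[1])[None, :] - 64.0
        q = np.sqrt(3.0)
        a, b = 9 * q, 9 / q
        lab = np.zeros(shape, dtype=np.int64)
        lab[(r / a) ** 2 + (c / b) ** 2 <= 1.0] = 1
        lab[(r - 40) ** 2 + (c - 40) ** 2 <= 81] = 2  # reference disk
        img = ImageField(np.where(lab > 0, 200.0, 1.0))
        records = {x.label: x for x in qc_filter(LabelMask(lab), img)}
        assert records[1].roundness == pytest.approx(0.64, abs=0.03)
        assert "aberrant_roundness" in records[1].qc_reasons
        assert records[2].qc_pass

    def test_area_bounds(self):
        img = disk_image((128, 128), [(30, 30), (90, 90)], radius=10)
        mask = disk_mask((128, 128), [(30, 30), (90, 90)], radius=10)
        cfg = NCQuantConfig(min_area=400.0)  # disks of ~314 px^2 are too small
        records = qc_filter(mask, img, cfg)
        assert all("area_out_of_range" in r.qc_reasons for r in records)

    def test_empty_mask_gives_empty_list(self):
        img = disk_image((32, 32), [], radius=5)
        assert qc_filter(LabelMask(np.zeros((32, 32), dtype=np.int64)), img) == []

    def test_qc_pass_mirrors_reasons(self):
        with pytest.raises(ValueError):
            NucleusRecord(label=1, area=100, perimeter=35, roundness=1.0,
                          mean_hoechst=200, touches_border=False,
                          qc_pass=True, qc_reasons=("border",))


class TestPerinuclearRing:
    def test_annulus_area_matches_analytic(self):
        mask = disk_mask((128, 128), [(64, 64)], radius=10)
        rings = perinuclear_ring(mask, width_px=4)
        area = np.count_nonzero(rings.labels == 1)
        assert area == pytest.approx(np.pi * (14**2 - 10**2), rel=0.12)

    def test_zero_width_rejected(self):
        mask = disk_mask((64, 64), [(32, 32)], radius=8)
        with pytest.raises(ValueError, match="width"):
            perinuclear_ring(mask, width_px=0)

    def test_adjacent_nuclei_rings_disjoint_and_exclusive(self):
        # two nuclei 5 px apart edge to edge: rings would overlap unresolved
        mask = disk_mask((128, 128), [(64, 50), (64, 75)], radius=10)
        rings = perinuclear_ring(mask, width_px=4)
        assert np.all((rings.labels > 0) <= (mask.labels == 0))  # excludes nuclei
        # every ring pixel belongs to exactly one label by construction;
        # check both rings are present and split at the midline
        assert set(rings.object_labels) == {1, 2}
        # nearest-nucleus conflict rule: every ring pixel is at least as close
        # to its own nucleus as to the other one
        from scipy import ndimage as ndi
        d1 = ndi.distance_transform_edt(mask.labels != 1)
        d2 = ndi.distance_transform_edt(mask.labels != 2)
        assert np.all(d1[rings.labels == 1] <= d2[rings.labels == 1])
        assert np.all(d2[rings.labels == 2] <= d1[rings.labels == 2])

    def test_ring_assigned_to_nearest_nucleus(self):
        mask = disk_mask((64, 128), [(32, 30), (32, 90)], radius=10)
        rings = perinuclear_ring(mask, width_px=4)
        ys, xs = np.nonzero(rings.labels == 1)
        assert xs.max() <= 60  # ring 1 stays near nucleus 1


class TestGrowCellRegion:
    def test_region_contains_nucleus_within_blob(self):
        hoechst = disk_mask((128, 128), [(64, 64)], radius=8)
        blob = disk_image((128, 128), [(64, 64)], radius=25, value=100, background=0)
        cells = grow_cell_region(hoechst, blob)
        nuc = hoechst.labels == 1
        cell = cells.labels == 1
        assert np.all(cell[nuc])          # contains the nucleus
        assert np.all(blob.pixels[cell] > 0)  # stays inside the blob

    def test_no_support_means_region_equals_nucleus(self):
        nuclei = disk_mask((64, 64), [(32, 32)], radius=8)
        marker = ImageField(np.zeros((64, 64)))
        cells = grow_cell_region(nuclei, marker)
        assert np.array_equal(cells.labels, nuclei.labels)

    def test_two_cells_partition_support(self):
        nuclei = disk_mask((128, 128), [(64, 45), (64, 83)], radius=8)
        blob = disk_image((128, 128), [(64, 64)], radius=40, value=100, background=0)
        cells = grow_cell_region(nuclei, blob)
        assert set(cells.object_labels) == {1, 2}
        # regions are disjoint by construction of the label image; check both
        # nuclei kept their own labels
        for k in (1, 2):
            assert np.all(cells.labels[nuclei.labels == k] == k)


class TestMeasureCells:
    def _setup(self, nuc_value, ring_value):
        nuclei = disk_mask((64, 64), [(32, 32)], radius=8)
        rings = perinuclear_ring(nuclei, width_px=4)
        marker = np.zeros((64, 64))
        marker[nuclei.labels == 1] = nuc_value
        marker[rings.labels == 1] = ring_value
        records = [NucleusRecord(1, 200.0, 50.0, 1.0, 200.0, False, True, ())]
        return ImageField(marker), nuclei, rings, records

    def test_ratio_arithmetic(self):
        marker, nuclei, rings, records = self._setup(200.0, 100.0)
        (m,) = measure_cells(marker, nuclei, rings, None, records)
        assert m.nc_ratio == pytest.approx(2.0)
        assert m.loc_class == "N"

    def test_uniform_marker_ratio_one_and_area_fraction(self):
        nuclei = disk_mask((64, 64), [(32, 32)], radius=8)
        rings = perinuclear_ring(nuclei, width_px=4)
        cells = disk_mask((64, 64), [(32, 32)], radius=16)
        marker = ImageField(np.full((64, 64), 50.0))
        records = [NucleusRecord(1, 200.0, 50.0, 1.0, 200.0, False, True, ())]
        (m,) = measure_cells(marker, nuclei, rings, cells, records)
        assert m.nc_ratio == pytest.approx(1.0)
        area_nuc = np.count_nonzero(nuclei.labels == 1)
        area_cell = np.count_nonzero(cells.labels == 1)
        assert m.nuclear_to_total == pytest.approx(area_nuc / area_cell)
        assert m.loc_class == "NC"

    def test_zero_ring_mean_marks_undefined(self):
        marker, nuclei, rings, records = self._setup(200.0, 0.0)
        (m,) = measure_cells(marker, nuclei, rings, None, records)
        assert np.isnan(m.nc_ratio)
        assert m.loc_class == ""

    def test_failed_qc_not_measured(self):
        marker, nuclei, rings, _ = self._setup(200.0, 100.0)
        records = [NucleusRecord(1, 200.0, 50.0, 1.0, 200.0, True, False, ("border",))]
        assert measure_cells(marker, nuclei, rings, None, records) == []

    def test_missing_ring_label_is_error(self):
        marker, nuclei, _, records = self._setup(200.0, 100.0)
        empty_rings = LabelMask(np.zeros((64, 64), dtype=np.int64))
        with pytest.raises(ValueError, match="ring"):
            measure_cells(marker, nuclei, empty_rings, None, records)


class TestClassifyAndSummarize:
    @pytest.mark.parametrize("ratio,expected", [
        (2.0, "N"), (1.0, "NC"), (0.5, "C"),
        (1.21, "N"), (1.19, "NC"), (1 / 1.21, "C"), (1 / 1.19, "NC"),
    ])
    def test_classification_bands(self, ratio, expected):
        assert classify_distribution(ratio, delta=0.2) == expected

    def test_reciprocal_symmetry(self):
        for r in (1.5, 2.0, 3.7):
            a = classify_distribution(r, delta=0.2)
            b = classify_distribution(1 / r, delta=0.2)
            assert {a, b} in ({"N", "C"}, {"NC"})

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            classify_distribution(0.0)

    def test_fraction_percentages(self):
        def cm(cls):
            from mechquant.nc_quant import CellMeasurement
            return CellMeasurement(1, 1, 1, 1, 1.0, 0.5, cls)
        fr = summarize_fractions([cm("N"), cm("N"), cm("C"), cm("NC")])
        assert fr == {"N": 50.0, "C": 25.0, "NC": 25.0}
        assert sum(fr.values()) == pytest.approx(100.0, abs=1e-9)

    def test_all_nuclear(self):
        from mechquant.nc_quant import CellMeasurement
        fr = summarize_fractions([CellMeasurement(1, 1, 1, 1, 2.0, 0.5, "N")] * 3)
        assert fr == {"N": 100.0, "C": 0.0, "NC": 0.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_fractions([])


class TestPipelineRecovery:
    def test_planted_ratio_recovered(self):
        spec = CellFieldSpec(n_cells=30, nc_ratio_true=2.0, noise_cv=0.1,
                             height=800, width=800, seed=1)
        hoechst, marker, truth = generate_cell_field(spec)
        _, measurements = quantify_field(hoechst, marker)
        ratios = [m.nc_ratio for m in measurements if np.isfinite(m.nc_ratio)]
        assert len(ratios) >= 25
        assert np.median(ratios) == pytest.approx(2.0, rel=0.1)

    def test_uniform_marker_classified_even(self):
        spec = CellFieldSpec(n_cells=30, nc_ratio_true=1.0, noise_cv=0.1,
                             height=800, width=800, seed=2)
        hoechst, marker, truth = generate_cell_field(spec)
        _, measurements = quantify_field(hoechst, marker)
        classes = [m.loc_class for m in measurements if m.loc_class]
        assert classes.count("NC") / len(classes) >= 0.9

    def test_nucleus_ring_disjoint_everywhere(self):
        spec = CellFieldSpec(n_cells=20, seed=3, height=700, width=700)
        hoechst, marker, _ = generate_cell_field(spec)
        nuclei = segment_nuclei(hoechst)
        rings = perinuclear_ring(nuclei)
        assert not np.any((nuclei.labels > 0) & (rings.labels > 0))

    def test_planted_defects_excluded(self):
        spec = CellFieldSpec(n_cells=40, frac_border=0.1, frac_mitotic=0.1,
                             frac_aberrant=0.1, seed=5, height=900, width=900)
        tp, fp, fn, tn = qc_confusion(spec)
        assert tp / (tp + fn) >= 0.9
        assert tp / (tp + fp) >= 0.9
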