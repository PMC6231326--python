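"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage import measure

from mechquant import CellFieldSpec, generate_cell_field, qc_filter, segment_nuclei


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


def brute_force_resultant(theta: np.ndarray, weights: np.ndarray) -> float:
    """Independent oracle: circular resultant length |sum w e^{2i theta}| / sum w."""
    w = np.asarray(weights, dtype=np.float64)
    if w.sum() == 0:
        return 0.0
    z = np.sum(w * np.exp(2j * np.asarray(theta, dtype=np.float64))) / w.sum()
    return float(np.abs(z))


def qc_confusion(spec: CellFieldSpec) -> tuple[int, int, int, int]:
    """Run segmentation + QC on a planted field; return (tp, fp, fn, tn) of
    the exclusion decision, matching nuclei to truth cells by centroid."""
    hoechst, marker, truth = generate_cell_field(spec)
    nuclei = segment_nuclei(hoechst)
    records = qc_filter(nuclei, hoechst)
    centroids = {p.label: p.centroid for p in measure.regionprops(nuclei.labels)}
    tree = cKDTree(truth[["row", "col"]].to_numpy())
    tp = fp = fn = tn = 0
    for rec in records:
        _, i = tree.query(list(centroids[rec.label]))
        should_exclude = not truth.iloc[i]["qc_expect"]
        excluded = not rec.qc_pass
        tp += excluded and should_exclude
        fp += excluded and not should_exclude
        fn += (not excluded) and should_exclude
        tn += (not excluded) and not should_exclude
    return tp, fp, fn, tn
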