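"""Screen statistics and small assay computations.

* Z-scoring of an arrayed siRNA screen against non-targeting control wells:
  Z = (x - control mean) / control SD per plate and replicate, averaged over
  replicates, with hit calling at a strict |mean Z| threshold (default 2.5).
* Genotype-specificity partition of hits between two cell backgrounds.
* Fisher exact (hypergeometric) enrichment of a gene set in a selection.
* Dual-luciferase normalization (experimental reporter over a constitutive
  secreted control, as fold change versus a reference condition).
* Collagen gel contraction index and fold change from gel-area masks.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .core_io import LabelMask

__all__ = [
    "ZScoreResult",
    "ContingencyTable",
    "zscore_screen",
    "genotype_specific_hits",
    "fisher_enrichment",
    "normalize_luciferase",
    "gel_contraction",
]

SCREEN_COLUMNS = ("plate", "well", "sirna", "genotype", "replicate",
                  "is_control", "value")


@dataclasses.dataclass(frozen=True)
class ZScoreResult:
    """Replicate-averaged Z-score of one siRNA in one genotype."""

    sirna: str
    genotype: str
    z_per_replicate: tuple[float, ...]
    mean_z: float
    is_hit: bool
    direction: str  # "up", "down", or "none"


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = in-set & selected, b = in-set & not selected,
    c = out-of-set & selected, d = out-of-set & not selected."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError("contingency counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("contingency table must have at least one count")


# ---------------------------------------------------------------------------
# Screen Z-scores
# ---------------------------------------------------------------------------

def _validate_screen_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(SCREEN_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    if table.duplicated(subset=["plate", "well", "replicate"]).any():
        raise ValueError("duplicate (plate, well, replicate) rows in screen table")
    if not np.isfinite(table["value"]).all():
        raise ValueError("screen values must be finite")
    return table


def zscore_screen(table: pd.DataFrame, threshold: float = 2.5,
                  per_plate: bool = True) -> list[ZScoreResult]:
    """Replicate-averaged control-normalized Z-scores with hit calls.

    Per replicate (and per plate when ``per_plate``), the control wells give
    the normalization: Z = (x - control mean) / control SD, with x the mean of
    the siRNA's wells on that plate/replicate and SD the sample standard
    deviation (n - 1). ``mean_z`` averages Z over the replicates in which the
    siRNA appears; a hit requires |mean_z| strictly above ``threshold``.

    Raises on plates with fewer than 2 control wells or zero control SD.
    """
    table = _validate_screen_table(table)
    group_cols = ["plate", "replicate"] if per_plate else ["replicate"]

    # control statistics per normalization group
    ctrl_stats: dict[tuple, tuple[float, float]] = {}
    for key, grp in table.groupby(group_cols, sort=False):
        ctrl = grp.loc[grp["is_control"], "value"]
        if len(ctrl) < 2:
            raise ValueError(f"normalization group {key} has < 2 control wells")
        sd = float(ctrl.std(ddof=1))
        if sd == 0:
            raise ValueError(f"degenerate plate: control SD is 0 in group {key}")
        ctrl_stats[key if isinstance(key, tuple) else (key,)] = (float(ctrl.mean()), sd)

    results = []
    targets = table[~table["is_control"]]
    for (sirna, genotype), grp in targets.groupby(["sirna", "genotype"], sort=False):
        zs = []
        for key, rep_grp in grp.groupby(group_cols, sort=False):
            key = key if isinstance(key, tuple) else (key,)
            mean, sd = ctrl_stats[key]
            x = float(rep_grp["value"].mean())  # well mean, then Z
            zs.append((x - mean) / sd)
        if not zs:
            raise ValueError(f"siRNA {sirna!r} has no replicate measurements")
        mean_z = float(np.mean(zs))
        is_hit = abs(mean_z) > threshold
        direction = "none" if not is_hit else ("up" if mean_z > 0 else "down")
        results.append(ZScoreResult(
            sirna=str(sirna), genotype=str(genotype),
            z_per_replicate=tuple(zs), mean_z=mean_z,
            is_hit=is_hit, direction=direction,
        ))
    return results


def genotype_specific_hits(wt: Sequence[ZScoreResult], ko: Sequence[ZScoreResult],
                           threshold: float = 2.5,
                           other_margin: float | None = None
                           ) -> dict[str, list[str]]:
    """Partition siRNAs by genotype specificity of their hit status.

    A siRNA is genotype-specific when it is a hit in that genotype and not in
    the other (optionally also requiring |mean_z| in the other genotype below
    ``other_margin``); "shared" requires a hit in both with the same sign.
    Both inputs must cover the same siRNA universe.
    """
    wt_by = {r.sirna: r for r in wt}
    ko_by = {r.sirna: r for r in ko}
    if set(wt_by) != set(ko_by):
        raise ValueError("WT and KO results cover different siRNA sets")

    def hit(r: ZScoreResult) -> bool:
        return abs(r.mean_z) > threshold

    def quiet(r: ZScoreResult) -> bool:
        return other_margin is None or abs(r.mean_z) < other_margin

    out: dict[str, list[str]] = {"WT-specific": [], "KO-specific": [],
                                 "shared": [], "none": []}
    for sid in sorted(wt_by):
        rw, rk = wt_by[sid], ko_by[sid]
        hw, hk = hit(rw), hit(rk)
        if hw and not hk and quiet(rk):
            out["WT-specific"].append(sid)
        elif hk and not hw and quiet(rw):
            out["KO-specific"].append(sid)
        elif hw and hk and np.sign(rw.mean_z) == np.sign(rk.mean_z):
            out["shared"].append(sid)
        else:
            out["none"].append(sid)
    return out


# ---------------------------------------------------------------------------
# Fisher exact enrichment
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(k: int, n_in: int, n_out: int, n_sel: int) -> float:
    """log P(X = k) for X ~ Hypergeom(pop = n_in + n_out, in-set = n_in,
    draws = n_sel), via log-factorials."""
    lf = math.lgamma
    return (
        lf(n_in + 1) - lf(k + 1) - lf(n_in - k + 1)
        + lf(n_out + 1) - lf(n_sel - k + 1) - lf(n_out - n_sel + k + 1)
        - (lf(n_in + n_out + 1) - lf(n_sel + 1) - lf(n_in + n_out - n_sel + 1))
    )


def fisher_enrichment(t: ContingencyTable,
                      alternative: str = "greater") -> tuple[float, float]:
    """Fisher exact test on a 2x2 table; returns (odds ratio, p-value).

    The p-value is the exact hypergeometric tail with the margins fixed:
    "greater" sums P(X >= a) (enrichment of the gene set in the selection),
    "less" sums P(X <= a), and "two_sided" sums every outcome whose point
    probability does not exceed that of the observed table (within a 1 + 1e-7
    relative guard against rounding). The odds ratio is a*d / (b*c), NaN when
    the denominator is zero.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b, c, d = t.a, t.b, t.c, t.d
    n_in, n_out, n_sel = a + b, c + d, a + c
    k_min = max(0, n_sel - n_out)
    k_max = min(n_in, n_sel)
    log_pmf = {k: _log_hypergeom_pmf(k, n_in, n_out, n_sel)
               for k in range(k_min, k_max + 1)}

    if alternative == "greater":
        ks = [k for k in log_pmf if k >= a]
    elif alternative == "less":
        ks = [k for k in log_pmf if k <= a]
    else:
        cut = log_pmf[a] + math.log1p(1e-7)
        ks = [k for k, lp in log_pmf.items() if lp <= cut]
    # sum in linear space; tables here are small enough for no underflow tricks
    p = float(min(1.0, sum(math.exp(log_pmf[k]) for k in ks)))

    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    return odds, p


# ---------------------------------------------------------------------------
# Small assay operations
# ---------------------------------------------------------------------------

def normalize_luciferase(firefly: Sequence[float], metluc: Sequence[float],
                         reference: Sequence[bool] | Sequence[int]
                         ) -> np.ndarray:
    """Dual-luciferase normalization to a reference condition.

    Per sample, the experimental (firefly) activity is divided by the
    constitutive secreted (Metridia) activity to control for transfection
    efficiency; the ratios are then expressed as fold change over the mean
    ratio of the reference samples (``reference`` flags them).
    """
    ff = np.asarray(firefly, dtype=np.float64)
    ml = np.asarray(metluc, dtype=np.float64)
    ref = np.asarray(reference, dtype=bool)
    if not (ff.shape == ml.shape == ref.shape):
        raise ValueError("firefly, metluc and reference must have equal length")
    if np.any(ml <= 0):
        raise ValueError("Metridia luciferase activities must be > 0")
    if not ref.any():
        raise ValueError("reference condition is empty")
    ratio = ff / ml
    return ratio / ratio[ref].mean()


def gel_contraction(gel_mask: LabelMask, control_mask: LabelMask,
                    well_area: float | None = None) -> float:
    """Fold change in gel contraction versus a control gel.

    Each mask must contain exactly one gel object; its foreground area A is
    compared with the initial area A0 (the full frame by default, or an
    explicit ``well_area``). The contraction index is (A0 - A) / A0 and the
    returned fold change is index_condition / index_control.
    """
    def area_of(mask: LabelMask, name: str) -> tuple[float, float]:
        labels = mask.object_labels
        if len(labels) != 1:
            raise ValueError(f"{name} mask must contain exactly one gel object, "
                             f"found {len(labels)}")
        a = float(np.count_nonzero(mask.labels))
        a0 = float(well_area) if well_area is not None else float(mask.labels.size)
        if a > a0:
            raise ValueError(f"{name} gel area {a} exceeds initial area {a0}")
        return a, a0

    a_cond, a0_cond = area_of(gel_mask, "condition")
    a_ctrl, a0_ctrl = area_of(control_mask, "control")
    idx_cond = (a0_cond - a_cond) / a0_cond
    idx_ctrl = (a0_ctrl - a_ctrl) / a0_ctrl
    if idx_ctrl == 0:
        raise ValueError("control gel shows no contraction; fold change undefined")
    return idx_cond / idx_ctrl
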