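"""Clarke Error Grid Analysis, limit of detection and repeatability.

The Clarke (1987) grid partitions the (reference, predicted) glucose plane
into five clinical-accuracy zones, A (benign) through E (dangerous).  The
region boundaries below follow the published grid; each zone is encoded as
a closed region and a point lying exactly on a shared boundary is assigned
to the alphabetically earlier (clinically better) zone by evaluating the
zones in order A, B, C, D, E.

Canonical closed regions (R = reference, P = predicted, both mg/dl):

* A: ``|P - R| <= 0.2 R`` or ``(R <= 70 and P <= 70)``
* B: upper wedge ``R >= 70, P >= 1.2 R`` excluding the open upper-C
  region, plus lower wedge ``R >= 70, P <= 0.8 R`` excluding the open
  lower-C, lower-D and lower-E regions
* C: ``70 <= R <= 290 and P >= R + 110`` (overcorrection) or
  ``130 <= R <= 180 and P <= 1.4 R - 182``
* D: ``R <= 175/3 and 70 <= P <= 180`` or
  ``175/3 <= R <= 70 and 1.2 R <= P <= 180`` (missed hypoglycemia) or
  ``R >= 240 and 70 <= P <= 180`` (missed hyperglycemia)
* E: ``R <= 70 and P >= 180`` or ``R >= 180 and P <= 70``
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .concentration import fit_linear
from .types import CEGAResult

_R_D_LEFT = 175.0 / 3.0  # reference where the 1.2R line crosses P = 70

ZONES = ("A", "B", "C", "D", "E")


def _zone_masks(r: np.ndarray, p: np.ndarray) -> dict:
    """Closed-region membership masks for all five zones (vectorized)."""
    in_a = (np.abs(p - r) <= 0.2 * r) | ((r <= 70) & (p <= 70))

    upper_c = (r >= 70) & (r <= 290) & (p >= r + 110)
    lower_c = (r >= 130) & (r <= 180) & (p <= 1.4 * r - 182)
    in_c = upper_c | lower_c

    in_d = (
        ((r <= _R_D_LEFT) & (p >= 70) & (p <= 180))
        | ((r >= _R_D_LEFT) & (r <= 70) & (p >= 1.2 * r) & (p <= 180))
        | ((r >= 240) & (p >= 70) & (p <= 180))
    )

    in_e = ((r <= 70) & (p >= 180)) | ((r >= 180) & (p <= 70))

    open_upper_c = (r > 70) & (r < 290) & (p > r + 110)
    open_lower_c = (r > 130) & (r < 180) & (p < 1.4 * r - 182)
    open_lower_d = (r > 240) & (p > 70) & (p < 180)
    open_lower_e = (r > 180) & (p < 70)
    upper_b = (r >= 70) & (p >= 1.2 * r) & ~open_upper_c
    lower_b = (
        (r >= 70)
        & (p <= 0.8 * r)
        & ~(open_lower_c | open_lower_d | open_lower_e)
    )
    in_b = upper_b | lower_b

    return {"A": in_a, "B": in_b, "C": in_c, "D": in_d, "E": in_e}


def cega_zones(reference, predicted) -> np.ndarray:
    """Clarke zone label for each (reference, predicted) pair."""
    r = np.atleast_1d(np.asarray(reference, dtype=float))
    p = np.atleast_1d(np.asarray(predicted, dtype=float))
    if r.shape != p.shape:
        raise ValueError("reference and predicted must have the same shape")
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(p))):
        raise ValueError("reference and predicted must be finite")
    if np.any(r < 0) or np.any(p < 0):
        raise ValueError("reference and predicted must be nonnegative")
    masks = _zone_masks(r, p)
    out = np.full(r.shape, "B", dtype="<U1")
    assigned = np.zeros(r.shape, dtype=bool)
    for zone in ZONES:  # alphabetical priority resolves boundary ties
        pick = masks[zone] & ~assigned
        out[pick] = zone
        assigned |= pick
    if not np.all(assigned):
        raise AssertionError("Clarke regions failed to cover a point")
    return out


def cega_zone(reference: float, predicted: float) -> str:
    """Clarke zone for one (reference, predicted) pair."""
    return str(cega_zones([reference], [predicted])[0])


def zone_percentages(zones) -> CEGAResult:
    """Percentage of points per zone; percentages sum to 100."""
    zones = [str(z) for z in zones]
    if not zones:
        raise ValueError("zones must be non-empty")
    n = len(zones)
    counts = {z: zones.count(z) for z in ZONES}
    percentages = {z: 100.0 * counts[z] / n for z in ZONES}
    return CEGAResult(zones=zones, zone_percentages=percentages, n_points=n)


def estimate_lod(
    reference,
    predicted,
    replicate=None,
    rule: str = "replicate",
) -> float | None:
    """Limit of detection from Zone-A membership.

    The LOD is the smallest reference concentration ``c*`` such that every
    tested concentration at or above ``c*`` stays in Zone A — for every
    replicate (``rule='replicate'``, strict default) or for the mean
    prediction per concentration (``rule='mean'``).  Returns ``None`` when
    no such concentration exists.  ``rule='calibration'`` instead returns
    the classic calibration-curve LOD ``3.3 * sd(residuals) / slope`` from
    a line of predicted against reference.
    """
    r = np.asarray(reference, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if r.size == 0:
        raise ValueError("empty input")
    if r.shape != p.shape:
        raise ValueError("reference and predicted must have the same shape")
    if np.unique(r).size < 2:
        raise ValueError("need at least 2 distinct reference concentrations")

    if rule == "calibration":
        model = fit_linear(r, p)
        if model.slope == 0:
            return None
        resid = p - (model.slope * r + model.intercept)
        sd = float(np.std(resid, ddof=2)) if r.size > 2 else float(np.std(resid))
        return 3.3 * sd / abs(model.slope)
    if rule not in {"replicate", "mean"}:
        raise ValueError("rule must be 'replicate', 'mean' or 'calibration'")

    levels = np.unique(r)
    passing = {}
    for c in levels:
        mask = r == c
        if rule == "mean":
            passing[c] = cega_zone(float(c), float(np.mean(p[mask]))) == "A"
        else:
            passing[c] = bool(np.all(cega_zones(r[mask], p[mask]) == "A"))
    lod = None
    for c in levels[::-1]:  # walk down from the highest concentration
        if passing[c]:
            lod = float(c)
        else:
            break
    return lod


def repeatability(frame: pd.DataFrame, value_col: str = "theta") -> pd.DataFrame:
    """Per-(day, concentration) mean, sample SD and coefficient of variation.

    ``frame`` needs columns ``day``, ``concentration`` and ``value_col``.
    The CV is ``sd / |mean|`` and is NaN for single replicates or a zero
    mean.
    """
    if frame.empty:
        raise ValueError("empty input")
    for col in ("day", "concentration", value_col):
        if col not in frame.columns:
            raise ValueError(f"missing column: {col}")
    grouped = frame.groupby(["day", "concentration"], sort=True)[value_col]
    summary = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        summary["cv"] = summary["sd"] / summary["mean"].abs()
    summary.loc[summary["mean"] == 0, "cv"] = np.nan
    summary["n"] = summary["n"].astype(int)
    return summary


def plot_clarke_grid(reference, predicted, ax=None):
    """Scatter the predictions on the Clarke grid (optional visual check)."""
    import matplotlib.pyplot as plt

    r = np.asarray(reference, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(r, p, s=12, c="k", zorder=3)
    lim = max(400.0, float(np.max(r)), float(np.max(p))) * 1.05
    x = np.linspace(0, lim, 200)
    ax.plot(x, x, "k:", lw=0.8)
    ax.plot(x, 1.2 * x, "k-", lw=0.8)
    ax.plot(x, 0.8 * x, "k-", lw=0.8)
    ax.axvline(70, color="gray", lw=0.6)
    ax.axhline(70, color="gray", lw=0.6)
    ax.axhline(180, color="gray", lw=0.6)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("reference concentration (mg/dl)")
    ax.set_ylabel("predicted concentration (mg/dl)")
    return ax
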