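"""Monitoring-design effort and precision comparison.

Cost functions for the three data-collection schemes (detection/
non-detection surveys, nest-box banding, and both combined), the
relative credible-interval-length precision-gain metric used to compare
single-source and joint fits, and the session-to-annual detection
probability conversion.

Costs are exact integer/decimal arithmetic in currency units (USD in the
bundled defaults, which reproduce the motivating study's example:
point-count startup $21,900, $19/point establishment, $12/point/
occasion/year sampling, $64/occasion/year overhead, etc.).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from numbers import Real

import numpy as np
import pandas as pd


class CostConfigurationError(ValueError):
    """Missing or invalid cost component."""


def _check(spec, fields) -> None:
    for name in fields:
        val = getattr(spec, name)
        if val is None:
            raise CostConfigurationError(f"cost component {name!r} missing")
        if not isinstance(val, Real):
            raise CostConfigurationError(f"cost component {name!r} not numeric")
        if val < 0:
            raise CostConfigurationError(f"cost component {name!r} negative")


@dataclass(frozen=True)
class PointCostSpec:
    """C_P = c0 + c1*s + c2*k*s*t + c3*k*t (startup, establishment,
    per-unit-per-occasion sampling, per-occasion overhead)."""

    c0: Real = 21_900
    c1: Real = 19
    c2: Real = 12
    c3: Real = 64
    s: int = 149
    k: int = 3
    t: int = 8


@dataclass(frozen=True)
class BandCostSpec:
    """C_B = c0 + c4*s + c5*s*t + c6*t with s counted in nest boxes."""

    c0: Real = 23_400
    c4: Real = 105
    c5: Real = 55
    c6: Real = 264
    s: int = 216
    t: int = 8


@dataclass(frozen=True)
class JointCostSpec:
    """C_J = c0 + c1*s_est + c2*k*s_survey*t + c3*k*t
           + c4*s_boxes + c5*s_boxes*t + c6*t.

    The three unit counts differ by term: newly established points, all
    surveyed points, and nest boxes.
    """

    c0: Real = 28_400
    c1: Real = 19
    c2: Real = 10
    c3: Real = 85
    c4: Real = 105
    c5: Real = 46
    c6: Real = 200
    s_establish: int = 77
    s_survey: int = 149
    s_boxes: int = 216
    k: int = 3
    t: int = 8


def cost_detection(spec: PointCostSpec) -> Real:
    """Total cost of a detection/non-detection survey design."""
    _check(spec, ("c0", "c1", "c2", "c3", "s", "k", "t"))
    return (spec.c0 + spec.c1 * spec.s + spec.c2 * spec.k * spec.s * spec.t
            + spec.c3 * spec.k * spec.t)


def cost_banding(spec: BandCostSpec) -> Real:
    """Total cost of a banding design."""
    _check(spec, ("c0", "c4", "c5", "c6", "s", "t"))
    return spec.c0 + spec.c4 * spec.s + spec.c5 * spec.s * spec.t \
        + spec.c6 * spec.t


def cost_joint(spec: JointCostSpec) -> Real:
    """Total cost of the combined design with term-specific unit counts."""
    _check(spec, ("c0", "c1", "c2", "c3", "c4", "c5", "c6",
                  "s_establish", "s_survey", "s_boxes", "k", "t"))
    return (spec.c0
            + spec.c1 * spec.s_establish
            + spec.c2 * spec.k * spec.s_survey * spec.t
            + spec.c3 * spec.k * spec.t
            + spec.c4 * spec.s_boxes
            + spec.c5 * spec.s_boxes * spec.t
            + spec.c6 * spec.t)


def annualize_detection(session_probs) -> float:
    """Annual detection probability from per-session probabilities:
    p_yr = 1 - prod_i (1 - p_i)."""
    p = np.asarray(session_probs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("session probabilities must lie in [0, 1]")
    return float(-np.expm1(np.log1p(-p).sum()))


def relative_bci_difference(single: pd.DataFrame,
                            joint: pd.DataFrame) -> pd.DataFrame:
    """Per-site relative precision gain (single - joint) / joint.

    Both inputs are ``site_year_bci``-style frames (quantity, site, year,
    length).  Zero-length joint intervals yield a missing value with a
    warning.  Positive values mean the joint fit is more precise.
    """
    keys = ["quantity", "site", "year"]
    merged = single.merge(joint, on=keys, suffixes=("_single", "_joint"))
    if len(merged) == 0:
        raise ValueError("no matched parameter/site/year cells to compare")
    zero = merged["length_joint"] <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero-length joint BCI; "
                      "reported as missing", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (merged["length_single"] - merged["length_joint"]) \
            / merged["length_joint"]
    merged["relative_difference"] = rel.where(~zero)
    return merged[keys + ["length_single", "length_joint",
                          "relative_difference"]]


def precision_report(single_fits: dict, joint_fit,
                     quantities=("phi", "N", "G")) -> pd.DataFrame:
    """Aggregate precision gains of a joint fit over single-data fits.

    ``single_fits`` maps model name ('point' and/or 'band') to its
    FitResult; rows report the mean and SD of the relative BCI-length
    difference across all site-years, per parameter and single model.
    """
    rows = []
    for model, fit in single_fits.items():
        avail = {"point": ("phi", "N", "G"), "band": ("phi",)}[model]
        for q in quantities:
            if q not in avail:
                continue
            cells = relative_bci_difference(fit.site_year_bci(q),
                                            joint_fit.site_year_bci(q))
            rel = cells["relative_difference"].dropna()
            rows.append({
                "single_model": model, "quantity": q,
                "mean": float(rel.mean()), "sd": float(rel.std(ddof=1)),
                "n_cells": int(len(rel)),
            })
    return pd.DataFrame(rows)


def plot_precision(cells: pd.DataFrame, path=None):
    """Violin plot of per-cell relative BCI differences by quantity,
    mirroring the cost/precision trade-off figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(cells.groupby("quantity"))
    fig, ax = plt.subplots(figsize=(1.8 * max(len(groups), 1) + 1.5, 4))
    data = [g["relative_difference"].dropna().to_numpy() for _, g in groups]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1))
    ax.set_xticklabels([name for name, _ in groups])
    ax.set_ylabel("(single - joint) / joint BCI length")
    ax.axhline(0.0, color="grey", lw=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
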