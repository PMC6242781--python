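"""qPCR detection-sensitivity modeling.

In a two-species mixture at weight ratio r:1 (major:minor), the minor
component's template amount scales as 1/r, so its quantification cycle
follows Cq = a + b*log10(r) with b > 0. The slope gives the amplification
efficiency E = 10^(1/|b|) - 1 (b = 3.32 cycles/decade corresponds to
perfect doubling, E = 100%), and the detection limit is the largest ratio
whose predicted Cq stays below a cutoff: LOD = 10^((cq_cutoff - a)/b).

Mixtures recorded as "not detected" are treated as right-censored and
excluded from the fit (the instrument's censoring cycle is unknown).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import data_path, normalize_species

__all__ = [
    "QpcrCurve",
    "QpcrFit",
    "FitError",
    "fit_cq_model",
    "efficiency",
    "lod_ratio",
    "check_monotonicity",
    "load_cq_fixture",
]

#: cycles per decade at 100% amplification efficiency: log2(10)
PERFECT_SLOPE = 3.321928094887362


class FitError(RuntimeError):
    """Too few detected points to fit the dilution model."""


@dataclass(frozen=True)
class QpcrCurve:
    """(ratio, Cq) series for one detected species in a mixture dilution."""

    detected_species: str
    mixture_label: str
    ratios: tuple[float, ...]
    cq_mean: tuple[float, ...]
    cq_sd: tuple[float, ...]
    censored: tuple[float, ...] = ()  # ratios recorded as not detected

    def __post_init__(self) -> None:
        if not (len(self.ratios) == len(self.cq_mean) == len(self.cq_sd)):
            raise ValueError("ratios, cq_mean and cq_sd must align")
        if any(r <= 0 for r in self.ratios) or any(r <= 0 for r in self.censored):
            raise ValueError("ratios must be positive")
        if any(np.diff(self.ratios) <= 0):
            raise ValueError("ratios must be strictly increasing")
        if any(sd < 0 for sd in self.cq_sd):
            raise ValueError("cq_sd must be non-negative")
        if self.censored and self.ratios and min(self.censored) <= max(self.ratios):
            raise ValueError("censored ratios must exceed the last detected ratio")


@dataclass(frozen=True)
class QpcrFit:
    """Least-squares fit of Cq on log10(ratio)."""

    detected_species: str
    intercept: float  # a, cycles
    slope: float  # b, cycles per decade
    r_squared: float
    efficiency: float  # fraction (1.0 = 100%)
    lod_ratio: float
    cq_cutoff: float
    n_points: int
    informative: bool = True


def fit_cq_model(
    curve: QpcrCurve,
    cq_cutoff: float = 37.0,
    weighted: bool = False,
) -> QpcrFit:
    """Fit Cq = a + b*log10(r) by (optionally 1/sd^2-weighted) least squares.

    Censored observations are excluded. With fewer than 3 detected points
    a :class:`FitError` is raised. A near-zero slope is flagged
    non-informative (efficiency and LOD are then meaningless).
    """
    if len(curve.ratios) < 3:
        raise FitError(
            f"{curve.detected_species}: {len(curve.ratios)} detected points (< 3)"
        )
    x = np.log10(np.asarray(curve.ratios, dtype=float))
    y = np.asarray(curve.cq_mean, dtype=float)
    if weighted:
        sd = np.asarray(curve.cq_sd, dtype=float)
        w = 1.0 / np.clip(sd, 1e-3, None) ** 2
        W = np.sum(w)
        xbar = np.sum(w * x) / W
        ybar = np.sum(w * y) / W
        b = np.sum(w * (x - xbar) * (y - ybar)) / np.sum(w * (x - xbar) ** 2)
        a = ybar - b * xbar
        yhat = a + b * x
        ss_res = np.sum(w * (y - yhat) ** 2)
        ss_tot = np.sum(w * (y - ybar) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    else:
        res = stats.linregress(x, y)
        a, b, r2 = float(res.intercept), float(res.slope), float(res.rvalue**2)

    informative = abs(b) > 1e-9
    if not informative:
        warnings.warn(
            f"{curve.detected_species}: flat Cq across ratios, fit non-informative",
            stacklevel=2,
        )
        eff = float("nan")
        lod = float("nan")
    else:
        eff = 10.0 ** (1.0 / abs(b)) - 1.0
        lod = 10.0 ** ((cq_cutoff - a) / b)
        if lod < 1:
            warnings.warn(
                "cq_cutoff below the intercept: predicted LOD ratio < 1",
                stacklevel=2,
            )
    return QpcrFit(
        detected_species=curve.detected_species,
        intercept=float(a),
        slope=float(b),
        r_squared=float(r2),
        efficiency=float(eff),
        lod_ratio=float(lod),
        cq_cutoff=cq_cutoff,
        n_points=len(curve.ratios),
        informative=informative,
    )


def efficiency(fit: QpcrFit) -> float:
    """Amplification efficiency E = 10^(1/|b|) - 1 from the fitted slope."""
    if fit.slope == 0:
        raise ZeroDivisionError("efficiency undefined for zero slope")
    return 10.0 ** (1.0 / abs(fit.slope)) - 1.0


def lod_ratio(fit: QpcrFit, cq_cutoff: Optional[float] = None) -> float:
    """Largest ratio with predicted Cq <= cutoff: 10^((cutoff - a)/b)."""
    if fit.slope <= 0:
        raise ValueError("lod_ratio requires a positive slope")
    cutoff = fit.cq_cutoff if cq_cutoff is None else cq_cutoff
    lod = 10.0 ** ((cutoff - fit.intercept) / fit.slope)
    if lod < 1:
        warnings.warn("cutoff below intercept: LOD ratio < 1", stacklevel=2)
    return lod


def check_monotonicity(curve: QpcrCurve) -> list[tuple[float, float, float, float]]:
    """Adjacent-pair violations of Cq non-decrease along the ratio axis.

    Returns (ratio_i, cq_i, ratio_j, cq_j) for every consecutive detected
    pair with cq_j < cq_i. Empty list = monotone.
    """
    out = []
    for i in range(len(curve.ratios) - 1):
        if curve.cq_mean[i + 1] < curve.cq_mean[i]:
            out.append(
                (curve.ratios[i], curve.cq_mean[i],
                 curve.ratios[i + 1], curve.cq_mean[i + 1])
            )
    return out


def load_cq_fixture() -> list[QpcrCurve]:
    """The packaged dilution table as one curve per detected species."""
    df = pd.read_csv(data_path("cq_table.csv"))
    curves: list[QpcrCurve] = []
    for (species, mixture), grp in df.groupby(
        ["detected_species", "mixture"], sort=False
    ):
        grp = grp.sort_values("ratio")
        det = grp[grp["detected"] == 1]
        cen = grp[grp["detected"] == 0]
        curves.append(
            QpcrCurve(
                detected_species=normalize_species(str(species)),
                mixture_label=str(mixture),
                ratios=tuple(float(r) for r in det["ratio"]),
                cq_mean=tuple(float(v) for v in det["cq_mean"]),
                cq_sd=tuple(float(v) for v in det["cq_sd"]),
                censored=tuple(float(r) for r in cen["ratio"]),
            )
        )
    return curves
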