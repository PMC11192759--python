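"""Monotherapy dose sweeps, IC50 fitting, and accuracy flags.

The screening grid is 16 doses: 0 plus 15 log-spaced points from 1 nM to
10,000 nM (log-uniform coverage of the 0-10,000 nM range).  Viability at
each dose is the ensemble survival fraction normalized to the untreated
(same-seed) ensemble, so killrate = 1 - viability.  IC50 is read off a
four-parameter logistic fitted on log10 dose as the dose where fitted
viability crosses the absolute level 0.5; curves that never cross within
the grid are right-censored at > 10,000 nM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .conditioning import CellLineAvatar
from .engine import EnsembleResult, SimulationConfig, run_ensemble
from .errors import InputError, NativeDeadError
from .pharmacology import TargetProfile

GRID_TOP_NM = 10_000.0
GRID_BOTTOM_NM = 1.0
GRID_SIZE = 16
#: log-dose floor standing in for dose 0 on the log axis
ZERO_DOSE_FLOOR_NM = 0.1
IC50_VIABILITY_LEVEL = 0.5


def make_dose_grid(
    n: int = GRID_SIZE, bottom: float = GRID_BOTTOM_NM, top: float = GRID_TOP_NM
) -> np.ndarray:
    """0 plus n-1 log-spaced doses from ``bottom`` to ``top`` (nM)."""
    if n < 2 or not 0 < bottom < top:
        raise InputError("need n >= 2 and 0 < bottom < top")
    return np.concatenate([[0.0], np.geomspace(bottom, top, n - 1)])


@dataclass
class IC50Fit:
    ic50_nM: float  # np.inf when censored
    censored: bool
    params: tuple[float, float, float, float] | None = None  # top, bottom, slope, log10 midpoint

    def __float__(self) -> float:
        return self.ic50_nM


@dataclass
class DoseResponseCurve:
    drug: str
    cell_line: str
    doses_nM: np.ndarray
    viability: np.ndarray
    ic50: IC50Fit = None

    @property
    def killrate(self) -> np.ndarray:
        return 1.0 - self.viability


def _four_pl(x: np.ndarray, top: float, bottom: float, slope: float, mid: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (x - mid)))


def fit_ic50(doses_nM: Sequence[float], viability: Sequence[float]) -> IC50Fit:
    """Fit a 4-parameter logistic on log10 dose and locate viability 0.5.

    Dose 0 is placed at the 0.1 nM floor on the log axis.  The fit is
    censored (> 10,000 nM) when the fitted curve never crosses 0.5 within
    the grid or when the optimizer fails to converge.
    """
    doses = np.asarray(doses_nM, dtype=float)
    v = np.asarray(viability, dtype=float)
    mask = np.isfinite(doses) & np.isfinite(v)
    doses, v = doses[mask], v[mask]
    if len(doses) < 4:
        raise InputError("need at least 4 finite dose/viability points")
    x = np.log10(np.maximum(doses, ZERO_DOSE_FLOOR_NM))
    top0, bot0 = float(v.max()), float(v.min())
    p0 = (top0, bot0, 1.0, float(np.median(x)))
    bounds = ([0.0, 0.0, 0.05, -4.0], [1.5, 1.0, 20.0, 9.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_four_pl, x, v, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return IC50Fit(ic50_nM=np.inf, censored=True, params=None)
    top, bottom, slope, mid = (float(q) for q in popt)
    if not (top > IC50_VIABILITY_LEVEL > bottom):
        return IC50Fit(ic50_nM=np.inf, censored=True, params=(top, bottom, slope, mid))
    x50 = mid + np.log10((top - IC50_VIABILITY_LEVEL) / (IC50_VIABILITY_LEVEL - bottom)) / slope
    ic50 = float(10.0**x50)
    if ic50 > doses.max():
        return IC50Fit(ic50_nM=np.inf, censored=True, params=(top, bottom, slope, mid))
    return IC50Fit(ic50_nM=ic50, censored=False, params=(top, bottom, slope, mid))


def monotherapy_screen(
    avatar: CellLineAvatar,
    profile: TargetProfile,
    grid: Sequence[float] | None = None,
    config: SimulationConfig | None = None,
    _untreated: EnsembleResult | None = None,
) -> DoseResponseCurve:
    """Sweep one drug over the dose grid and fit an IC50.

    Viability is normalized to the same-seed untreated ensemble (dose 0
    therefore has viability exactly 1).  Raises :class:`NativeDeadError`
    when the untreated avatar has zero survival — such cell lines are not
    screenable.  ``_untreated`` lets callers reuse a precomputed baseline
    ensemble.
    """
    grid = make_dose_grid() if grid is None else np.asarray(grid, dtype=float)
    config = config or SimulationConfig()
    base = _untreated if _untreated is not None else run_ensemble(avatar, (), config)
    s0 = base.survival_fraction
    if s0 == 0:
        raise NativeDeadError(f"cell line {avatar.cell_line!r} is natively dead")
    viability = np.empty(len(grid))
    for k, dose in enumerate(grid):
        if dose == 0:
            viability[k] = 1.0
            continue
        res = run_ensemble(avatar, [(profile, float(dose))], config)
        viability[k] = min(res.survival_fraction / s0, 1.0)
    fit = fit_ic50(grid, viability)
    return DoseResponseCurve(
        drug=profile.drug,
        cell_line=avatar.cell_line,
        doses_nM=grid,
        viability=viability,
        ic50=fit,
    )


def accuracy_flag(ic50_in_vitro: float, ic50_in_silico: float) -> str:
    """'accurate' iff the two IC50s agree within one order of magnitude.

    |log10(in vitro) - log10(in silico)| < 1, strictly: an exact 10-fold
    difference is already inaccurate.
    """
    if not (ic50_in_vitro > 0 and ic50_in_silico > 0) or not (
        np.isfinite(ic50_in_vitro) and np.isfinite(ic50_in_silico)
    ):
        raise InputError("IC50 values must be positive and finite")
    delta = abs(np.log10(ic50_in_vitro) - np.log10(ic50_in_silico))
    return "accurate" if delta < 1.0 else "inaccurate"


def curve_to_frame(curve: DoseResponseCurve):
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_line": curve.cell_line,
            "drug": curve.drug,
            "dose_nM": curve.doses_nM,
            "viability": curve.viability,
            "killrate": curve.killrate,
        }
    )
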