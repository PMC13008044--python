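"""Standard curves, amplification efficiency and formula selection.

A standard curve is the ordinary least-squares fit of CT on
log10(input mass) over a serial dilution of fully methylated DNA.  Its
slope yields the amplification efficiency E = 10^(-1/slope) - 1 (E = 1
is perfect doubling, slope -1/log10(2) ~ -3.32).  The fitted line also
anchors the CT cutoff — the predicted CT at the assay's limit-of-
detection mass, above which a CT is treated as non-detection.

Formula selection follows the dilution-design rule: regress
dCT = CT(MIP) - CT(MSP) on log10(mass); when the slope is flat
(|slope| < 0.1 cycles per log10(pg) and its two-sided p > 0.05) the
perfect-doubling Livak ratio is adequate, otherwise the efficiency-
corrected Pfaffl ratio is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .simulate import WellRecord

__all__ = [
    "StandardCurveFit",
    "FormulaChoice",
    "fit_standard_curve",
    "determine_ct_cutoff",
    "select_formula",
    "efficiency_pct_from_slope",
    "DEFAULT_SLOPE_THRESHOLD",
    "DEFAULT_ALPHA",
]

DEFAULT_SLOPE_THRESHOLD = 0.1  # cycles per log10(pg)
DEFAULT_ALPHA = 0.05


def efficiency_pct_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope."""
    if slope >= 0:
        raise ValueError("efficiency is defined only for negative slopes")
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS fit of CT on log10(mass) for one assay.

    ``efficiency_pct`` is None for a flagged (non-amplifying, slope >= 0)
    fit.  ``lod_mass_pg`` is the smallest mass at which every replicate
    amplified; ``ct_cutoff`` is the fitted CT at that mass.
    """

    assay_id: str
    slope: float
    intercept: float
    r2: float
    efficiency_pct: float | None
    n_points: int
    n_undetermined: int
    lod_mass_pg: float
    ct_cutoff: float
    observed_ct_at_lod: float
    mass_min_pg: float = math.nan
    mass_max_pg: float = math.nan

    @property
    def efficiency(self) -> float | None:
        """Fractional per-cycle efficiency E (None for flagged fits)."""
        return None if self.efficiency_pct is None else self.efficiency_pct / 100.0

    @property
    def flagged(self) -> bool:
        return self.efficiency_pct is None

    def predict_ct(self, mass_pg: float) -> float:
        return self.intercept + self.slope * math.log10(mass_pg)


@dataclass(frozen=True)
class FormulaChoice:
    """Outcome of the dCT-slope formula-selection rule for one MSP/MIP pair."""

    element: str
    msp_assay_id: str
    mip_assay_id: str
    dct_slope: float
    p_value: float
    choice: str  # "LIVAK" | "PFAFFL"


def _series_by_mass(wells: Sequence[WellRecord]) -> dict[float, list[float | None]]:
    by_mass: dict[float, list[float | None]] = {}
    for w in wells:
        by_mass.setdefault(w.input_mass_pg, []).append(w.ct)
    return by_mass


def fit_standard_curve(wells: Sequence[WellRecord], assay_id: str | None = None) -> StandardCurveFit:
    """Fit a dilution series for one assay.

    Undetermined wells are excluded from the regression but counted, and
    they disqualify their mass from the limit of detection.  Requires at
    least 3 distinct masses with determined CTs.
    """
    if assay_id is not None:
        wells = [w for w in wells if w.assay_id == assay_id]
    if not wells:
        raise ValueError("no wells to fit")
    aid = assay_id if assay_id is not None else wells[0].assay_id
    by_mass = _series_by_mass(wells)

    xs, ys = [], []
    n_undet = 0
    fully_detected: list[float] = []
    for mass, cts in by_mass.items():
        det = [c for c in cts if c is not None]
        n_undet += len(cts) - len(det)
        if len(det) == len(cts):
            fully_detected.append(mass)
        xs.extend([math.log10(mass)] * len(det))
        ys.extend(det)
    if len({x for x in xs}) < 3:
        raise ValueError("standard curve needs >= 3 distinct masses with determined CTs")
    if not fully_detected:
        raise ValueError("no mass with full detection; cannot anchor the CT cutoff")

    res = stats.linregress(xs, ys)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2
    eff = None if slope >= 0 else efficiency_pct_from_slope(slope)

    lod = min(fully_detected)
    cutoff = intercept + slope * math.log10(lod)
    observed = float(np.mean([c for c in by_mass[lod] if c is not None]))
    fitted_masses = [m for m in by_mass if any(c is not None for c in by_mass[m])]
    return StandardCurveFit(
        assay_id=aid,
        slope=slope,
        intercept=intercept,
        r2=r2,
        efficiency_pct=eff,
        n_points=len(ys),
        n_undetermined=n_undet,
        lod_mass_pg=lod,
        ct_cutoff=cutoff,
        observed_ct_at_lod=observed,
        mass_min_pg=min(fitted_masses),
        mass_max_pg=max(fitted_masses),
    )


def determine_ct_cutoff(fit: StandardCurveFit, lod_mass_pg: float | None = None) -> float:
    """CT cutoff: the fitted line's predicted CT at the limit-of-detection mass.

    ``lod_mass_pg`` defaults to the fit's own data-driven limit of
    detection and must lie within the fitted mass range.
    """
    if lod_mass_pg is None:
        lod_mass_pg = fit.lod_mass_pg
    if lod_mass_pg <= 0:
        raise ValueError("lod_mass_pg must be positive")
    lo, hi = fit.mass_min_pg, fit.mass_max_pg
    if not math.isnan(lo) and not (lo <= lod_mass_pg <= hi):
        raise ValueError(
            f"lod mass {lod_mass_pg} pg is outside the fitted mass range [{lo}, {hi}] pg"
        )
    return fit.predict_ct(lod_mass_pg)


def select_formula(
    msp_wells: Sequence[WellRecord],
    mip_wells: Sequence[WellRecord],
    element: str = "",
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> FormulaChoice:
    """Select Livak vs Pfaffl from paired dilution series.

    Per-mass replicate CTs are averaged; dCT = mean CT(MIP) - mean CT(MSP)
    is regressed on log10(mass).  LIVAK iff |slope| < ``slope_threshold``
    and the slope's two-sided p-value > ``alpha``; PFAFFL otherwise.
    """
    msp_by = _series_by_mass(msp_wells)
    mip_by = _series_by_mass(mip_wells)
    if set(msp_by) != set(mip_by):
        raise ValueError("MSP and MIP dilution series must cover the same masses")
    xs, dcts = [], []
    for mass in sorted(msp_by, reverse=True):
        msp_det = [c for c in msp_by[mass] if c is not None]
        mip_det = [c for c in mip_by[mass] if c is not None]
        if not msp_det or not mip_det:
            continue
        xs.append(math.log10(mass))
        dcts.append(float(np.mean(mip_det)) - float(np.mean(msp_det)))
    if len(xs) < 3:
        raise ValueError("need >= 3 masses with determined CTs in both series")
    res = stats.linregress(xs, dcts)
    slope = float(res.slope)
    # identical per-mass CTs give a zero-variance residual; slope test is then exact
    p = float(res.pvalue) if not math.isnan(res.pvalue) else 1.0
    choice = "LIVAK" if (abs(slope) < slope_threshold and p > alpha) else "PFAFFL"
    return FormulaChoice(
        element=element,
        msp_assay_id=msp_wells[0].assay_id if msp_wells else "",
        mip_assay_id=mip_wells[0].assay_id if mip_wells else "",
        dct_slope=slope,
        p_value=p,
        choice=choice,
    )
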