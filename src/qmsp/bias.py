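"""PCR amplification-bias assessment on defined-methylation mixtures.

A mixture panel of fully methylated and fully unmethylated DNA (0-100%
methylation) is quantified exactly like a study sample, and the
recovered methylation level is regressed on the input level.  An
unbiased MSP+MIP primer pair tracks the identity line; a reference that
amplifies one template class preferentially bends the recovered curve
away from it, most strongly at low input methylation.  The verdict is a
tolerance band on the regression: slope within 1 +/- slope_tol and
|intercept| <= intercept_tol percentage points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtTable, RunConfig
from .quantify import quantify_samples
from .simulate import WellRecord
from .standard_curve import StandardCurveFit

__all__ = [
    "RecoveredPoint",
    "BiasVerdict",
    "recovered_series",
    "classify_bias",
    "mip_ct_by_level",
    "DEFAULT_SLOPE_TOL",
    "DEFAULT_INTERCEPT_TOL",
]

DEFAULT_SLOPE_TOL = 0.1
DEFAULT_INTERCEPT_TOL = 5.0  # percentage points


@dataclass(frozen=True)
class RecoveredPoint:
    """One mixture level: declared input vs recovered methylation percent."""

    input_pct: float
    recovered_pct: float
    n_used: int


@dataclass(frozen=True)
class BiasVerdict:
    """Recovered-vs-input regression and the biased/unbiased call."""

    msp_assay_id: str
    mip_assay_id: str
    slope: float
    intercept: float
    r2: float
    verdict: str  # "UNBIASED" | "BIASED"
    deviations: tuple[float, ...]  # recovered - input, per point
    slope_tol: float = DEFAULT_SLOPE_TOL
    intercept_tol: float = DEFAULT_INTERCEPT_TOL


def recovered_series(
    wells: Sequence[WellRecord] | CtTable,
    truth: pd.DataFrame,
    config: RunConfig,
    fits: Mapping[str, StandardCurveFit] | None = None,
    choices: Mapping | None = None,
    drop_zero_signal: bool = False,
) -> list[RecoveredPoint]:
    """Quantify a mixture panel and pair recovered with input levels.

    ``truth`` carries columns sample_id and input_pct (the mixture grid);
    the panel must include the run's 100% calibrator sample.  ZERO_SIGNAL
    levels (no methylated signal at 0% input) enter as recovered 0 unless
    ``drop_zero_signal``.
    """
    table = wells if isinstance(wells, CtTable) else CtTable(records=list(wells), run_id="mixture")
    if not table.wells(sample_id=config.calibrator_sample_id):
        raise ValueError(
            f"mixture panel lacks the calibrator sample {config.calibrator_sample_id!r}"
        )
    results = quantify_samples(table, config, fits=fits, choices=choices)
    input_by_sample = dict(zip(truth["sample_id"], truth["input_pct"]))
    points: list[RecoveredPoint] = []
    # the fully methylated control is the calibrator itself; quantified
    # against its own wells it recovers exactly 100% (self-reference)
    if config.calibrator_sample_id in input_by_sample:
        n_cal = len(
            {w.replicate for w in table.wells(sample_id=config.calibrator_sample_id)}
        )
        points.append(
            RecoveredPoint(
                input_pct=float(input_by_sample[config.calibrator_sample_id]),
                recovered_pct=100.0,
                n_used=n_cal,
            )
        )
    for r in results:
        if r.sample_id not in input_by_sample:
            continue
        if r.status == "EXCLUDED":
            continue
        if r.status == "ZERO_SIGNAL" and drop_zero_signal:
            continue
        points.append(
            RecoveredPoint(
                input_pct=float(input_by_sample[r.sample_id]),
                recovered_pct=float(r.methylation_pct),
                n_used=max(r.n_used_target, r.n_used_reference),
            )
        )
    points.sort(key=lambda p: p.input_pct)
    return points


def classify_bias(
    series: Sequence[RecoveredPoint],
    slope_tol: float = DEFAULT_SLOPE_TOL,
    intercept_tol: float = DEFAULT_INTERCEPT_TOL,
    msp_assay_id: str = "",
    mip_assay_id: str = "",
) -> BiasVerdict:
    """OLS of recovered on input methylation and the tolerance-band verdict.

    Requires at least 4 points spanning at least 50 percentage points of
    input methylation.
    """
    if len(series) < 4:
        raise ValueError("bias classification needs >= 4 mixture points")
    x = np.array([p.input_pct for p in series], dtype=float)
    y = np.array([p.recovered_pct for p in series], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate series: all input levels equal")
    if np.ptp(x) < 50:
        raise ValueError("mixture grid must span >= 50 percentage points of input methylation")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2 if not math.isnan(res.rvalue) else 1.0
    unbiased = (1.0 - slope_tol <= slope <= 1.0 + slope_tol) and abs(intercept) <= intercept_tol
    return BiasVerdict(
        msp_assay_id=msp_assay_id,
        mip_assay_id=mip_assay_id,
        slope=slope,
        intercept=intercept,
        r2=r2,
        verdict="UNBIASED" if unbiased else "BIASED",
        deviations=tuple(float(d) for d in (y - x)),
        slope_tol=slope_tol,
        intercept_tol=intercept_tol,
    )


def mip_ct_by_level(
    wells: Sequence[WellRecord] | CtTable,
    truth: pd.DataFrame,
    mip_assay_id: str,
) -> pd.DataFrame:
    """Companion diagnostic: mean MIP CT per mixture level.

    An unbiased reference shows a flat CT across input methylation (it
    amplifies every converted template equally); a biased one trends with
    the methylated fraction.
    """
    table = wells if isinstance(wells, CtTable) else CtTable(records=list(wells), run_id="mixture")
    input_by_sample = dict(zip(truth["sample_id"], truth["input_pct"]))
    rows = []
    for sid, input_pct in sorted(input_by_sample.items(), key=lambda kv: kv[1]):
        cts = [w.ct for w in table.wells(sample_id=sid, assay_id=mip_assay_id) if w.ct is not None]
        if cts:
            rows.append({"input_pct": float(input_pct), "mean_ct": float(np.mean(cts)), "n": len(cts)})
    return pd.DataFrame(rows, columns=["input_pct", "mean_ct", "n"])
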