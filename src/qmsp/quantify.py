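"""Calibrator-normalized relative methylation quantification.

Each sample is quantified against a fully methylated calibrator that
defines the 100% level.  The methylated target (MSP assay) is
normalized by a methylation-independent reference (MIP assay), via
either the perfect-doubling Livak ratio

    level = 100 * 2^-(dCT_sample - dCT_calibrator),   dCT = CT_target - CT_reference

or the efficiency-corrected Pfaffl ratio

    level = 100 * (1+E_target)^(CT_cal - CT_sample) / (1+E_ref)^(CT_cal - CT_sample)_ref.

Levels are not capped at 100%: a sample enriched for the target
relative to the calibrator legitimately exceeds it.  Replicates are
averaged after the CT-cutoff exclusion rule: a sample is excluded only
when every replicate of the reference assay is undetermined or above
the reference's CT cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import CtTable, RunConfig
from .simulate import WellRecord
from .standard_curve import FormulaChoice, StandardCurveFit

logger = logging.getLogger("qmsp")

__all__ = [
    "AggregatedCt",
    "MethylationResult",
    "UndeterminedCtError",
    "aggregate_replicates",
    "livak_level",
    "pfaffl_level",
    "quantify_samples",
]


class UndeterminedCtError(ValueError):
    """A quantification formula received an undetermined CT."""


@dataclass(frozen=True)
class AggregatedCt:
    """Replicate-aggregated CT for one sample x assay."""

    sample_id: str
    assay_id: str
    mean_ct: float | None
    n_used: int
    n_total: int
    excluded: bool
    reason: str = ""

    @property
    def partial(self) -> bool:
        """Some but not all replicates passed (single-replicate audit flag)."""
        return not self.excluded and self.n_used < self.n_total


def aggregate_replicates(wells: Sequence[WellRecord], ct_cutoff: float | None = None) -> AggregatedCt:
    """Aggregate replicate wells of one sample x assay.

    A replicate passes when its CT is determined and at or below the
    cutoff (when one is set).  The mean of passing replicates is used;
    the aggregate is excluded only when *no* replicate passes.
    """
    if not wells:
        raise ValueError("need at least one well")
    sid, aid = wells[0].sample_id, wells[0].assay_id
    passing = [
        w.ct
        for w in wells
        if w.ct is not None and (ct_cutoff is None or w.ct <= ct_cutoff)
    ]
    n_total = len(wells)
    if not passing:
        if all(w.ct is None for w in wells):
            reason = "all replicates undetermined"
        else:
            reason = f"all replicates above CT cutoff {ct_cutoff}"
        return AggregatedCt(sid, aid, None, 0, n_total, True, reason)
    reason = "" if len(passing) == n_total else f"{n_total - len(passing)} replicate(s) failed"
    return AggregatedCt(sid, aid, float(sum(passing) / len(passing)), len(passing), n_total, False, reason)


def _require(ct: float | None, what: str) -> float:
    if ct is None:
        raise UndeterminedCtError(f"{what} CT is undetermined")
    return ct


def livak_level(ct_me_s: float, ct_ref_s: float, ct_me_cal: float, ct_ref_cal: float) -> float:
    """Livak ddCT methylation level in percent (assumes perfect doubling)."""
    for ct, what in (
        (ct_me_s, "sample target"),
        (ct_ref_s, "sample reference"),
        (ct_me_cal, "calibrator target"),
        (ct_ref_cal, "calibrator reference"),
    ):
        _require(ct, what)
    ddct = (ct_me_s - ct_ref_s) - (ct_me_cal - ct_ref_cal)
    return 100.0 * 2.0 ** (-ddct)


def pfaffl_level(
    ct_me_s: float,
    ct_me_cal: float,
    e_me: float,
    ct_ref_s: float,
    ct_ref_cal: float,
    e_ref: float,
) -> float:
    """Pfaffl efficiency-corrected methylation level in percent.

    Efficiencies are fractional per-cycle gains in (0, 1] (typically from
    standard-curve fits on fully methylated DNA).
    """
    for e, what in ((e_me, "target"), (e_ref, "reference")):
        if not 0 < e <= 1:
            raise ValueError(f"{what} efficiency must be fractional in (0, 1], got {e}")
    for ct, what in (
        (ct_me_s, "sample target"),
        (ct_me_cal, "calibrator target"),
        (ct_ref_s, "sample reference"),
        (ct_ref_cal, "calibrator reference"),
    ):
        _require(ct, what)
    num = (1.0 + e_me) ** (ct_me_cal - ct_me_s)
    den = (1.0 + e_ref) ** (ct_ref_cal - ct_ref_s)
    return 100.0 * num / den


@dataclass(frozen=True)
class MethylationResult:
    """Calibrator-normalized methylation level for one sample x element x reference."""

    sample_id: str
    group: str
    element: str
    reference_assay_id: str
    formula: str
    methylation_pct: float  # NaN when status is EXCLUDED
    status: str  # OK | EXCLUDED | ZERO_SIGNAL
    n_used_target: int = 0
    n_used_reference: int = 0
    flags: str = ""


def _resolve_formula(
    element: str,
    mip_id: str,
    config: RunConfig,
    choices: Mapping | None,
) -> str:
    declared = config.formula.get(element, "AUTO").upper()
    if declared != "AUTO":
        return declared
    if choices:
        for key in ((element, mip_id), element):
            if key in choices:
                ch = choices[key]
                return ch.choice if isinstance(ch, FormulaChoice) else str(ch).upper()
    raise ValueError(
        f"formula for element {element} is AUTO but no dilution-series choice was supplied"
    )


def _efficiency(assay_id: str, config: RunConfig, fits: Mapping[str, StandardCurveFit] | None) -> float:
    if fits and assay_id in fits and fits[assay_id].efficiency is not None:
        return fits[assay_id].efficiency
    eff = config.assay(assay_id).efficiency
    if eff is None:
        raise ValueError(f"no fitted or declared efficiency for assay {assay_id!r}")
    return eff


def _cutoff(assay_id: str, config: RunConfig, fits: Mapping[str, StandardCurveFit] | None) -> float | None:
    declared = config.assay(assay_id).ct_cutoff
    if declared is not None:
        return declared
    if fits and assay_id in fits:
        return fits[assay_id].ct_cutoff
    return None


def quantify_samples(
    table: CtTable,
    config: RunConfig,
    fits: Mapping[str, StandardCurveFit] | None = None,
    choices: Mapping | None = None,
) -> list[MethylationResult]:
    """Quantify every sample in a CT table against the run's calibrator.

    For each element with a declared MSP assay, levels are computed
    against every declared MIP reference (cross-normalization included).
    Per-sample failures become EXCLUDED / ZERO_SIGNAL rows; a missing or
    undetermined calibrator is a hard error.  Output order is sorted and
    therefore invariant to input row order.
    """
    cal_id = config.calibrator_sample_id
    cal_wells = table.wells(sample_id=cal_id)
    if not cal_wells:
        raise ValueError(f"calibrator sample {cal_id!r} not present in CT table")

    msp_by_element = {}
    for a in config.assays_by(role="MSP"):
        msp_by_element[a.element.upper()] = a
    references = config.assays_by(role="MIP")
    if not msp_by_element or not references:
        raise ValueError("config must declare at least one MSP and one MIP assay")

    # calibrator means, no cutoff applied (a failing calibrator is a run failure)
    cal_ct: dict[str, float] = {}
    for a in config.assays:
        wells = table.wells(sample_id=cal_id, assay_id=a.assay_id)
        if not wells:
            continue
        agg = aggregate_replicates(wells)
        if agg.excluded:
            raise ValueError(f"calibrator has no determined CT for assay {a.assay_id!r}")
        cal_ct[a.assay_id] = agg.mean_ct

    sample_ids = sorted({r.sample_id for r in table.records} - {cal_id})
    results: list[MethylationResult] = []
    n_excluded = 0
    for sid in sample_ids:
        group = table.wells(sample_id=sid)[0].group
        for element, msp in sorted(msp_by_element.items()):
            me_wells = table.wells(sample_id=sid, assay_id=msp.assay_id)
            if not me_wells:
                continue
            for ref in references:
                ref_wells = table.wells(sample_id=sid, assay_id=ref.assay_id)
                if not ref_wells:
                    continue
                if msp.assay_id not in cal_ct or ref.assay_id not in cal_ct:
                    raise ValueError(
                        f"calibrator lacks wells for assay pair {msp.assay_id}/{ref.assay_id}"
                    )
                formula = _resolve_formula(element, ref.assay_id, config, choices)
                agg_ref = aggregate_replicates(ref_wells, _cutoff(ref.assay_id, config, fits))
                agg_me = aggregate_replicates(me_wells, _cutoff(msp.assay_id, config, fits))
                flags = ";".join(
                    f for f in (
                        "partial_target" if agg_me.partial else "",
                        "partial_reference" if agg_ref.partial else "",
                    ) if f
                )
                if agg_ref.excluded:
                    n_excluded += 1
                    results.append(
                        MethylationResult(
                            sid, group, element, ref.assay_id, formula, math.nan,
                            "EXCLUDED", agg_me.n_used, 0, agg_ref.reason,
                        )
                    )
                    continue
                if agg_me.excluded:
                    # no methylated signal but reference detected: level -> 0
                    results.append(
                        MethylationResult(
                            sid, group, element, ref.assay_id, formula, 0.0,
                            "ZERO_SIGNAL", 0, agg_ref.n_used, agg_me.reason,
                        )
                    )
                    continue
                if formula == "LIVAK":
                    pct = livak_level(
                        agg_me.mean_ct, agg_ref.mean_ct,
                        cal_ct[msp.assay_id], cal_ct[ref.assay_id],
                    )
                else:
                    pct = pfaffl_level(
                        agg_me.mean_ct, cal_ct[msp.assay_id],
                        _efficiency(msp.assay_id, config, fits),
                        agg_ref.mean_ct, cal_ct[ref.assay_id],
                        _efficiency(ref.assay_id, config, fits),
                    )
                results.append(
                    MethylationResult(
                        sid, group, element, ref.assay_id, formula, pct,
                        "OK", agg_me.n_used, agg_ref.n_used, flags,
                    )
                )
    logger.info(
        "quantified %d samples (%d result rows, %d excluded) [config %s]",
        len(sample_ids), len(results), n_excluded, config.config_hash(),
    )
    return results
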