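"""Mechanistic simulator for bisulfite-converted qPCR (qMSP) experiments.

The model tracks two template pools per reaction — molecules that were
methylated before bisulfite conversion and molecules that were not — and
grows each exponentially at its own per-cycle amplification efficiency.
The threshold cycle (CT) is the continuous cycle number at which the
summed amplicon count crosses the instrument threshold.  Everything the
downstream pipeline consumes (standard curves, mixture panels, cohorts)
is produced from this single primitive, so amplification bias, bisulfite
conversion failure and input-mass effects propagate exactly as they
would on a real instrument.

Efficiencies are fractional: an efficiency ``e`` means each cycle
multiplies the pool by ``(1 + e)``; ``e = 1`` is perfect doubling.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "AlleleEfficiencyProfile",
    "AssaySpec",
    "SampleSpec",
    "SimulationConfig",
    "CohortGroupSpec",
    "WellRecord",
    "NoTemplateError",
    "InvalidThresholdError",
    "closed_form_ct",
    "mixture_ct",
    "simulate_well",
    "simulate_dilution_series",
    "simulate_mixture_panel",
    "simulate_cohort",
    "saturating_conversion_failure",
    "default_copies_per_pg",
    "DEFAULT_DILUTION_MASSES_PG",
    "DEFAULT_MIXTURE_LEVELS_PCT",
]

# Haploid genome equivalents per picogram of human DNA (1 pg ~ 0.303
# haploid genomes), and element copies per haploid genome.  These only
# shift CT intercepts; no pipeline statistic depends on them.
HAPLOID_GENOMES_PER_PG = 0.303
ELEMENT_COPIES_PER_HAPLOID = {"LINE1": 1.5e5, "ALU": 1.1e6}

DEFAULT_DILUTION_MASSES_PG = (1000.0, 250.0, 62.5, 15.625, 3.125)
DEFAULT_MIXTURE_LEVELS_PCT = (0.0, 12.5, 25.0, 50.0, 75.0, 100.0)


class NoTemplateError(ValueError):
    """No amplifiable template in the reaction (caller maps to UNDETERMINED)."""


class InvalidThresholdError(ValueError):
    """Detection threshold not above the initial copy number."""


def default_copies_per_pg(element: str) -> float:
    """Element copies per picogram of genomic DNA (LINE1 or ALU)."""
    try:
        per_haploid = ELEMENT_COPIES_PER_HAPLOID[element.upper()]
    except KeyError:
        raise ValueError(f"unknown element {element!r}; expected LINE1 or ALU")
    return HAPLOID_GENOMES_PER_PG * per_haploid


def saturating_conversion_failure(f_max: float = 0.15, k_pg: float = 5000.0) -> Callable[[float], float]:
    """Conversion-failure rate that rises with bisulfite input mass.

    Returns ``failure(mass) = f_max * mass / (mass + k_pg)``, a saturating
    curve emulating incomplete bisulfite conversion at excess DNA input:
    heavier inputs leave more unmethylated cytosines unconverted, which
    then read as methylated.
    """
    if not 0 <= f_max < 1:
        raise ValueError("f_max must be in [0, 1)")
    return lambda mass_pg: f_max * mass_pg / (mass_pg + k_pg)


@dataclass(frozen=True)
class AlleleEfficiencyProfile:
    """Per-cycle amplification efficiencies of one primer set on the two
    bisulfite-converted template classes.

    ``e_meth`` applies to originally-methylated templates, ``e_unmeth`` to
    originally-unmethylated ones; both are fractions in (0, 1].  A profile
    is unbiased iff the two are equal.
    """

    e_meth: float
    e_unmeth: float

    def __post_init__(self) -> None:
        for name, e in (("e_meth", self.e_meth), ("e_unmeth", self.e_unmeth)):
            if not 0 < e <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {e}")

    @property
    def unbiased(self) -> bool:
        return self.e_meth == self.e_unmeth


@dataclass(frozen=True)
class AssaySpec:
    """One primer set: methylation-specific (MSP) or methylation-independent (MIP).

    ``cross_reactivity`` is the fraction of converted-unmethylated template
    an MSP assay can still amplify (initial copy weight); MIP assays amplify
    all converted templates, so it is fixed at 1 for them.
    ``threshold_copies`` is the amplicon count Q at which fluorescence
    crosses the detection threshold; the default of 1e13 copies puts CTs
    for picogram-scale repeat-element inputs in the instrument-typical
    15-35 cycle range and exceeds any realistic initial copy number
    (including multi-nanogram inputs of the high-copy Alu element).
    """

    assay_id: str
    role: str  # "MSP" | "MIP"
    element: str  # "LINE1" | "ALU"
    profile: AlleleEfficiencyProfile
    cross_reactivity: float | None = None
    threshold_copies: float = 1e13
    max_cycles: int = 40

    def __post_init__(self) -> None:
        role = self.role.upper()
        if role not in ("MSP", "MIP"):
            raise ValueError(f"role must be MSP or MIP, got {self.role!r}")
        object.__setattr__(self, "role", role)
        object.__setattr__(self, "element", self.element.upper())
        if self.element not in ("LINE1", "ALU"):
            raise ValueError(f"element must be LINE1 or ALU, got {self.element!r}")
        xr = self.cross_reactivity
        if role == "MIP":
            if xr is not None and xr != 1.0:
                raise ValueError("MIP assays amplify all converted templates (cross_reactivity 1)")
            object.__setattr__(self, "cross_reactivity", 1.0)
        else:
            object.__setattr__(self, "cross_reactivity", 0.0 if xr is None else xr)
            if not 0 <= self.cross_reactivity <= 1:
                raise ValueError("cross_reactivity must be in [0, 1]")
        if self.threshold_copies <= 0:
            raise ValueError("threshold_copies must be positive")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be a positive integer")


@dataclass(frozen=True)
class SampleSpec:
    """One DNA sample entering bisulfite conversion.

    ``true_methylation`` is the fraction m of element copies methylated.
    ``copies_per_pg`` is the element copy density of the genomic input —
    a scalar when only one element is assayed, or a mapping from element
    name (LINE1/ALU) to density when the sample is run with assays for
    both.  ``conversion_failure`` is the fraction of unmethylated
    molecules that read as methylated after conversion; it may be a
    constant or an increasing function of ``input_mass_pg`` (see
    :func:`saturating_conversion_failure`).
    """

    sample_id: str
    group: str
    true_methylation: float
    input_mass_pg: float
    copies_per_pg: float | Mapping[str, float]
    bisulfite_recovery: float = 1.0
    conversion_failure: float | Callable[[float], float] = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.true_methylation <= 1:
            raise ValueError("true_methylation must be in [0, 1]")
        if self.input_mass_pg <= 0:
            raise ValueError("input_mass_pg must be positive")
        densities = (
            self.copies_per_pg.values()
            if isinstance(self.copies_per_pg, Mapping)
            else (self.copies_per_pg,)
        )
        if any(d <= 0 for d in densities):
            raise ValueError("copies_per_pg must be positive")
        if not 0 < self.bisulfite_recovery <= 1:
            raise ValueError("bisulfite_recovery must be in (0, 1]")
        cf = self.conversion_failure_at(self.input_mass_pg)
        if not 0 <= cf < 1:
            raise ValueError("conversion_failure must be in [0, 1)")

    def conversion_failure_at(self, mass_pg: float) -> float:
        cf = self.conversion_failure
        return cf(mass_pg) if callable(cf) else cf

    def copies_for(self, element: str) -> float:
        if isinstance(self.copies_per_pg, Mapping):
            try:
                return self.copies_per_pg[element.upper()]
            except KeyError:
                raise ValueError(f"sample {self.sample_id!r} has no copy density for element {element!r}")
        return self.copies_per_pg

    def template_pools(self, template_fraction: float, element: str) -> tuple[float, float]:
        """Initial (methylated-reading, unmethylated-reading) copies per well."""
        total = self.input_mass_pg * self.copies_for(element) * self.bisulfite_recovery * template_fraction
        cf = self.conversion_failure_at(self.input_mass_pg)
        m_eff = self.true_methylation + (1.0 - self.true_methylation) * cf
        return total * m_eff, total * (1.0 - m_eff)


@dataclass(frozen=True)
class SimulationConfig:
    """Instrument / run settings shared by every simulated well."""

    seed: int = 0
    ct_noise_sd: float = 0.1
    n_replicates: int = 2
    template_fraction_per_reaction: float = 2.0 / 20.0

    def __post_init__(self) -> None:
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.template_fraction_per_reaction <= 1:
            raise ValueError("template_fraction_per_reaction must be in (0, 1]")


@dataclass(frozen=True)
class WellRecord:
    """One qPCR well; ``ct`` is None when the threshold was never crossed."""

    sample_id: str
    assay_id: str
    replicate: int
    ct: float | None
    input_mass_pg: float
    group: str

    @property
    def undetermined(self) -> bool:
        return self.ct is None


@dataclass(frozen=True)
class CohortGroupSpec:
    """One cohort arm: n subjects with Gaussian methylation heterogeneity.

    Methylation per subject is ``clip(mean + sd * z, 0, 1)``; in paired
    designs the standard-normal subject effect ``z`` is shared across arms
    so that arm means differ while subjects stay matched.
    """

    label: str
    n: int
    mean_methylation: float
    sd_methylation: float
    mass_pg: float = 200.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")
        if not 0 <= self.mean_methylation <= 1:
            raise ValueError("mean_methylation must be in [0, 1]")
        if self.sd_methylation < 0:
            raise ValueError("sd_methylation must be nonnegative")
        if self.mass_pg <= 0:
            raise ValueError("mass_pg must be positive")


def closed_form_ct(n0: float, e: float, q: float) -> float:
    """Continuous threshold cycle for single-pool exponential growth.

    Solves ``n0 * (1 + e)**t = q`` for t.
    """
    if n0 <= 0:
        raise NoTemplateError("no template (n0 <= 0)")
    if not 0 < e <= 1:
        raise ValueError(f"efficiency must be in (0, 1], got {e}")
    if q <= n0:
        raise InvalidThresholdError(f"threshold q={q} must exceed initial copies n0={n0}")
    return math.log(q / n0) / math.log(1.0 + e)


def mixture_ct(n_m: float, n_u: float, e_m: float, e_u: float, q: float) -> float:
    """Threshold cycle of a two-pool reaction.

    Finds the unique t with ``n_m*(1+e_m)**t + n_u*(1+e_u)**t = q`` by
    bracketed root-finding (absolute tolerance < 1e-9 cycles).  Collapses
    to :func:`closed_form_ct` when one pool is empty or the efficiencies
    coincide.
    """
    if n_m < 0 or n_u < 0:
        raise ValueError("pool copy numbers must be nonnegative")
    if n_m + n_u <= 0:
        raise NoTemplateError("no template in either pool")
    if q <= n_m + n_u:
        raise InvalidThresholdError(f"threshold q={q} must exceed total initial copies {n_m + n_u}")
    if n_m == 0:
        return closed_form_ct(n_u, e_u, q)
    if n_u == 0 or e_m == e_u:
        # equal efficiencies: pools grow in lockstep
        if e_m == e_u:
            return closed_form_ct(n_m + n_u, e_m, q)
        return closed_form_ct(n_m, e_m, q)

    def f(t: float) -> float:
        return n_m * (1.0 + e_m) ** t + n_u * (1.0 + e_u) ** t - q

    # the mixture crosses threshold no later than either pool alone would
    hi = min(closed_form_ct(n_m, e_m, q), closed_form_ct(n_u, e_u, q))
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16))


def _well_ct(sample: SampleSpec, assay: AssaySpec, config: SimulationConfig) -> float | None:
    """Noise-free CT for one well, or None when nothing amplifies."""
    n_m, n_u = sample.template_pools(config.template_fraction_per_reaction, assay.element)
    n_u_amp = n_u * assay.cross_reactivity
    try:
        ct = mixture_ct(n_m, n_u_amp, assay.profile.e_meth, assay.profile.e_unmeth, assay.threshold_copies)
    except NoTemplateError:
        return None
    return ct


def simulate_well(
    sample: SampleSpec,
    assay: AssaySpec,
    config: SimulationConfig,
    rng: np.random.Generator,
    replicate: int = 1,
) -> WellRecord:
    """Simulate one qPCR well: pool bookkeeping, CT, Gaussian noise, truncation."""
    ct = _well_ct(sample, assay, config)
    if ct is not None and config.ct_noise_sd > 0:
        ct += rng.normal(0.0, config.ct_noise_sd)
    if ct is not None and ct > assay.max_cycles:
        ct = None
    return WellRecord(
        sample_id=sample.sample_id,
        assay_id=assay.assay_id,
        replicate=replicate,
        ct=ct,
        input_mass_pg=sample.input_mass_pg,
        group=sample.group,
    )


def _stream_rng(seed: int, sample_index: int, assay_id: str) -> np.random.Generator:
    """Independent RNG substream per sample x assay.

    Keying on the assay identity keeps noise independent between assays
    even when separate simulation calls share one seed (two assays'
    dilution series must not carry correlated noise, or their dCT would
    be artificially exact)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, sample_index, zlib.crc32(assay_id.encode())])
    )


def _wells_for_samples(
    samples: Sequence[SampleSpec],
    assays: Sequence[AssaySpec],
    config: SimulationConfig,
) -> list[WellRecord]:
    wells: list[WellRecord] = []
    for idx, sample in enumerate(samples):
        for assay in assays:
            rng = _stream_rng(config.seed, idx, assay.assay_id)
            for rep in range(1, config.n_replicates + 1):
                wells.append(simulate_well(sample, assay, config, rng, replicate=rep))
    return wells


def simulate_dilution_series(
    assay: AssaySpec,
    masses_pg: Sequence[float] | None = None,
    config: SimulationConfig = SimulationConfig(),
) -> list[WellRecord]:
    """Serial dilution of fully methylated calibrator DNA for one assay.

    Default mass grid 1000 → 3.125 pg in the standard-curve design; every
    well carries its input mass for the downstream log-linear fit.
    """
    masses = tuple(DEFAULT_DILUTION_MASSES_PG if masses_pg is None else masses_pg)
    if len(masses) == 0:
        raise ValueError("mass list must be non-empty")
    if any(m <= 0 for m in masses):
        raise ValueError("all masses must be positive")
    if any(b >= a for a, b in zip(masses, masses[1:])):
        raise ValueError("masses must be strictly descending")
    samples = [
        SampleSpec(
            sample_id=f"std_{mass:g}pg",
            group="standard",
            true_methylation=1.0,
            input_mass_pg=mass,
            copies_per_pg=default_copies_per_pg(assay.element),
        )
        for mass in masses
    ]
    return _wells_for_samples(samples, [assay], config)


def simulate_mixture_panel(
    msp: AssaySpec,
    mip: AssaySpec,
    levels_pct: Sequence[float] | None = None,
    mass_pg: float = 200.0,
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[WellRecord], pd.DataFrame]:
    """Defined-methylation mixture panel (fully methylated + fully
    unmethylated DNA mixed at given percentages) including the 100%
    calibrator.

    The fully methylated control doubles as the run's calibrator — it is
    the same material in the same wells, exactly as in the bias
    experiment's design — so the 100% level is emitted once, as the
    sample ``calibrator``.  Returns the wells and a truth table
    (sample_id, group, input_pct) for recovery checks.
    """
    levels = tuple(DEFAULT_MIXTURE_LEVELS_PCT if levels_pct is None else levels_pct)
    if any(not 0 <= lvl <= 100 for lvl in levels):
        raise ValueError("mixture levels must be in [0, 100] percent")
    if msp.element != mip.element:
        raise ValueError("MSP and MIP assays must target the same element")
    copies = default_copies_per_pg(msp.element)
    samples = [
        SampleSpec(
            sample_id=f"mix_{lvl:g}",
            group="mixture",
            true_methylation=lvl / 100.0,
            input_mass_pg=mass_pg,
            copies_per_pg=copies,
        )
        for lvl in levels
        if lvl < 100
    ]
    samples.append(
        SampleSpec(
            sample_id="calibrator",
            group="calibrator",
            true_methylation=1.0,
            input_mass_pg=mass_pg,
            copies_per_pg=copies,
        )
    )
    wells = _wells_for_samples(samples, [msp, mip], config)
    truth = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "input_pct": [100.0 * s.true_methylation for s in samples],
        }
    )
    return wells, truth


def simulate_cohort(
    groups: Sequence[CohortGroupSpec],
    assays: Sequence[AssaySpec],
    config: SimulationConfig = SimulationConfig(),
    paired: bool = False,
    include_calibrator: bool = True,
    calibrator_mass_pg: float = 200.0,
    conversion_failure: float | Callable[[float], float] = 0.0,
) -> tuple[list[WellRecord], pd.DataFrame]:
    """Simulate a study cohort: per-subject methylation, all assays, duplicates.

    In a paired design all groups must have equal n; subject effects are
    shared across groups so sample index i in each group is the same
    subject.  A fully methylated calibrator sample is appended (the
    quantification step requires one per run).

    Returns the wells and a truth table (sample_id, group, true_methylation).
    """
    if len(groups) == 0:
        raise ValueError("at least one group required")
    if paired and len({g.n for g in groups}) != 1:
        raise ValueError("paired groups must have equal n")
    # distinct entropy from the per-sample well-noise streams
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    densities = {el: default_copies_per_pg(el) for el in ("LINE1", "ALU")}
    samples: list[SampleSpec] = []
    if paired:
        z = rng.standard_normal(groups[0].n)
    for g in groups:
        z_g = z if paired else rng.standard_normal(g.n)
        m = np.clip(g.mean_methylation + g.sd_methylation * z_g, 0.0, 1.0)
        for i in range(g.n):
            sid = f"subj{i + 1:04d}_{g.label}" if paired else f"{g.label}_{i + 1:04d}"
            samples.append(
                SampleSpec(
                    sample_id=sid,
                    group=g.label,
                    true_methylation=float(m[i]),
                    input_mass_pg=g.mass_pg,
                    copies_per_pg=densities,
                    conversion_failure=conversion_failure,
                )
            )
    if include_calibrator:
        samples.append(
            SampleSpec(
                sample_id="calibrator",
                group="calibrator",
                true_methylation=1.0,
                input_mass_pg=calibrator_mass_pg,
                copies_per_pg=densities,
            )
        )
    wells = _wells_for_samples(samples, assays, config)
    truth = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "true_methylation": [s.true_methylation for s in samples],
        }
    )
    return wells, truth
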