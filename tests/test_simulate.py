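"""Unit and property tests for the bisulfite-qPCR simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qmsp import (
    AlleleEfficiencyProfile,
    AssaySpec,
    InvalidThresholdError,
    NoTemplateError,
    SampleSpec,
    SimulationConfig,
    CohortGroupSpec,
    closed_form_ct,
    default_copies_per_pg,
    mixture_ct,
    saturating_conversion_failure,
    simulate_cohort,
    simulate_dilution_series,
    simulate_mixture_panel,
    simulate_well,
)
from qmsp.simulate import _well_ct

from conftest import brute_force_ct


class TestClosedFormCt:
    @pytest.mark.parametrize(
        "n0,e,q,expected",
        [
            (1000, 1.0, 1_024_000, 10.0),  # 2^10 = 1024
            (500, 0.9, 1e7, 15.42950469863816),  # log(2e4)/log(1.9)
        ],
    )
    def test_known_values(self, n0, e, q, expected):
        assert closed_form_ct(n0, e, q) == pytest.approx(expected, abs=1e-12)

    def test_exact_inverse_of_growth(self):
        t = closed_form_ct(1234.5, 0.87, 3.3e9)
        assert 1234.5 * 1.87**t == pytest.approx(3.3e9, rel=1e-12)

    def test_degenerate_threshold_rejected(self):
        with pytest.raises(InvalidThresholdError):
            closed_form_ct(1000, 1.0, 1000)

    def test_no_template_signalled(self):
        with pytest.raises(NoTemplateError):
            closed_form_ct(0, 1.0, 1e6)


class TestMixtureCt:
    def test_equal_efficiency_collapse(self):
        assert mixture_ct(500, 500, 0.9, 0.9, 1e7) == pytest.approx(
            closed_form_ct(1000, 0.9, 1e7), abs=1e-9
        )

    def test_single_allele_limit(self):
        assert mixture_ct(0, 1000, 0.8, 1.0, 1_024_000) == pytest.approx(10.0, abs=1e-9)
        assert mixture_ct(1000, 0, 1.0, 0.8, 1_024_000) == pytest.approx(10.0, abs=1e-9)

    def test_bracketed_by_single_allele_cts(self):
        ct = mixture_ct(900, 100, 0.85, 0.95, 1e7)
        ct_m = closed_form_ct(900, 0.85, 1e7)
        ct_u = closed_form_ct(100, 0.95, 1e7)
        assert ct <= min(ct_m, ct_u)
        assert ct == pytest.approx(brute_force_ct(900, 100, 0.85, 0.95, 1e7), abs=0.01)

    def test_no_template(self):
        with pytest.raises(NoTemplateError):
            mixture_ct(0, 0, 0.9, 0.9, 1e7)

    def test_equal_efficiency_collapse_fuzzed(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            e = rng.uniform(0.5, 1.0)
            n_m = rng.uniform(1, 1e6)
            n_u = rng.uniform(1, 1e6)
            q = (n_m + n_u) * rng.uniform(1e3, 1e9)
            assert mixture_ct(n_m, n_u, e, e, q) == pytest.approx(
                closed_form_ct(n_m + n_u, e, q), abs=1e-9
            )

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_m = rng.uniform(10, 1e5)
            n_u = rng.uniform(10, 1e5)
            e_m = rng.uniform(0.6, 1.0)
            e_u = rng.uniform(0.6, 1.0)
            q = (n_m + n_u) * 10 ** rng.uniform(3, 8)
            assert mixture_ct(n_m, n_u, e_m, e_u, q) == pytest.approx(
                brute_force_ct(n_m, n_u, e_m, e_u, q), abs=0.01
            )

    @given(
        st.floats(1.0, 1e5),
        st.floats(1.0, 1e5),
        st.floats(0.6, 0.99),
        st.floats(0.6, 0.99),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_decreasing_in_copies_and_efficiency(self, n_m, n_u, e_m, e_u):
        q = 1e12
        ct = mixture_ct(n_m, n_u, e_m, e_u, q)
        assert mixture_ct(n_m * 1.5, n_u, e_m, e_u, q) < ct
        assert mixture_ct(n_m, n_u * 1.5, e_m, e_u, q) < ct
        assert mixture_ct(n_m, n_u, min(e_m + 0.01, 1.0), e_u, q) < ct
        assert mixture_ct(n_m, n_u, e_m, min(e_u + 0.01, 1.0), q) < ct


class TestSimulateWell:
    def test_fully_methylated_mip_matches_closed_form(self, noise_free):
        mip = AssaySpec("Alu-Ref", "MIP", "ALU", AlleleEfficiencyProfile(0.9, 0.8))
        s = SampleSpec("s", "g", 1.0, 200.0, default_copies_per_pg("ALU"))
        rng = np.random.default_rng(0)
        w = simulate_well(s, mip, noise_free, rng)
        n0 = 200.0 * default_copies_per_pg("ALU") * 0.1
        assert w.ct == pytest.approx(closed_form_ct(n0, 0.9, mip.threshold_copies), abs=1e-12)

    def test_unmethylated_sample_msp_undetermined(self, unbiased_pair, noise_free):
        msp, _ = unbiased_pair
        s = SampleSpec("s", "g", 0.0, 200.0, default_copies_per_pg("LINE1"))
        w = simulate_well(s, msp, noise_free, np.random.default_rng(0))
        assert w.undetermined

    def test_msp_cross_reactivity_restores_signal(self, noise_free):
        msp = AssaySpec(
            "L1-Me", "MSP", "LINE1", AlleleEfficiencyProfile(0.9, 0.9), cross_reactivity=0.01
        )
        s = SampleSpec("s", "g", 0.0, 200.0, default_copies_per_pg("LINE1"))
        w = simulate_well(s, msp, noise_free, np.random.default_rng(0))
        assert w.ct is not None

    def test_biased_mip_amplifies_half_methylated_faster(self, noise_free):
        # a faster unmethylated allele pulls the mixture CT below the
        # all-slow-allele case; checked against the accumulation oracle
        biased = AssaySpec("R", "MIP", "LINE1", AlleleEfficiencyProfile(0.80, 0.95))
        slow = AssaySpec("R2", "MIP", "LINE1", AlleleEfficiencyProfile(0.80, 0.80))
        s = SampleSpec("s", "g", 0.5, 200.0, default_copies_per_pg("LINE1"))
        ct_biased = _well_ct(s, biased, noise_free)
        ct_slow = _well_ct(s, slow, noise_free)
        assert ct_biased < ct_slow
        n0 = 200.0 * default_copies_per_pg("LINE1") * 0.1
        assert ct_biased == pytest.approx(
            brute_force_ct(n0 / 2, n0 / 2, 0.80, 0.95, biased.threshold_copies), abs=0.01
        )

    def test_noise_truncation_to_undetermined(self):
        assay = AssaySpec(
            "A", "MIP", "LINE1", AlleleEfficiencyProfile(0.9, 0.9), max_cycles=10
        )
        s = SampleSpec("s", "g", 1.0, 3.125, default_copies_per_pg("LINE1"))
        w = simulate_well(s, assay, SimulationConfig(seed=0, ct_noise_sd=0.0), np.random.default_rng(0))
        assert w.undetermined  # true CT ~ 31 cycles > 10


class TestDilutionSeries:
    def test_perfect_doubling_slope(self):
        assay = AssaySpec("A", "MIP", "LINE1", AlleleEfficiencyProfile(1.0, 1.0))
        wells = simulate_dilution_series(assay, None, SimulationConfig(seed=0, ct_noise_sd=0.0))
        by_mass = {}
        for w in wells:
            by_mass.setdefault(w.input_mass_pg, w.ct)
        masses = sorted(by_mass)
        slopes = [
            (by_mass[b] - by_mass[a]) / (math.log10(b) - math.log10(a))
            for a, b in zip(masses, masses[1:])
        ]
        for s in slopes:
            assert s == pytest.approx(-1.0 / math.log10(2.0), abs=1e-9)

    def test_replicate_count_and_masses(self, unbiased_pair):
        msp, _ = unbiased_pair
        wells = simulate_dilution_series(msp, [100.0, 10.0, 1.0], SimulationConfig(seed=1, n_replicates=3))
        assert len(wells) == 9
        assert {w.input_mass_pg for w in wells} == {100.0, 10.0, 1.0}

    @pytest.mark.parametrize("masses", [[], [100.0, 0.0], [10.0, 100.0]])
    def test_invalid_mass_grids_rejected(self, unbiased_pair, masses):
        msp, _ = unbiased_pair
        with pytest.raises(ValueError):
            simulate_dilution_series(msp, masses, SimulationConfig(seed=0))


class TestReproducibility:
    def test_seeded_runs_bit_identical(self, unbiased_pair):
        msp, mip = unbiased_pair
        cfg = SimulationConfig(seed=123, ct_noise_sd=0.15)
        w1, t1 = simulate_mixture_panel(msp, mip, None, 200.0, cfg)
        w2, t2 = simulate_mixture_panel(msp, mip, None, 200.0, cfg)
        assert w1 == w2
        assert t1.equals(t2)

    def test_zero_noise_deterministic_across_seeds(self, unbiased_pair):
        msp, mip = unbiased_pair
        w1, _ = simulate_mixture_panel(msp, mip, None, 200.0, SimulationConfig(seed=1, ct_noise_sd=0.0))
        w2, _ = simulate_mixture_panel(msp, mip, None, 200.0, SimulationConfig(seed=2, ct_noise_sd=0.0))
        assert w1 == w2


class TestConservation:
    def test_pool_totals_conserved(self):
        s = SampleSpec("s", "g", 0.37, 512.0, 1000.0)
        n_m, n_u = s.template_pools(0.1, "LINE1")
        assert n_m + n_u == pytest.approx(512.0 * 1000.0 * 0.1, rel=1e-12)
        assert n_m == pytest.approx(0.37 * 512.0 * 1000.0 * 0.1, rel=1e-12)

    def test_conversion_failure_reassigns_not_creates(self):
        s = SampleSpec("s", "g", 0.4, 100.0, 1000.0, conversion_failure=0.1)
        n_m, n_u = s.template_pools(0.1, "LINE1")
        assert n_m + n_u == pytest.approx(100.0 * 1000.0 * 0.1, rel=1e-12)
        assert n_m == pytest.approx((0.4 + 0.6 * 0.1) * 100.0 * 1000.0 * 0.1, rel=1e-12)


class TestConversionFailure:
    def test_saturating_curve_increases_with_mass(self):
        f = saturating_conversion_failure(f_max=0.15, k_pg=5000.0)
        assert f(200.0) < f(1000.0) < f(50_000.0) < 0.15
        assert f(5000.0) == pytest.approx(0.075)

    def test_higher_input_raises_dct_for_partially_methylated_dna(self, unbiased_pair, noise_free):
        # more input -> more conversion failure -> more methylated-reading
        # template -> MSP CT drops relative to MIP -> dCT (MIP - MSP) rises
        msp, mip = unbiased_pair
        f = saturating_conversion_failure()
        dcts = []
        for mass in (200.0, 5000.0, 50_000.0):
            s = SampleSpec("s", "g", 0.5, mass, default_copies_per_pg("LINE1"), conversion_failure=f)
            dcts.append(_well_ct(s, mip, noise_free) - _well_ct(s, msp, noise_free))
        assert dcts[0] < dcts[1] < dcts[2]


class TestCohort:
    def test_paired_groups_share_subject_effects(self, unbiased_pair):
        msp, mip = unbiased_pair
        groups = [
            CohortGroupSpec("tumour", 10, 0.70, 0.05),
            CohortGroupSpec("adjacent", 10, 0.75, 0.05),
        ]
        _, truth = simulate_cohort(groups, [msp, mip], SimulationConfig(seed=5), paired=True)
        t = truth[truth.group == "tumour"].true_methylation.to_numpy()
        a = truth[truth.group == "adjacent"].true_methylation.to_numpy()
        assert np.allclose(a - t, 0.05)

    def test_four_reactions_per_sample(self, unbiased_pair, biased_mip):
        msp, mip = unbiased_pair
        alu_me = AssaySpec("Alu-Me", "MSP", "ALU", AlleleEfficiencyProfile(0.9, 0.9))
        alu_ref = AssaySpec("Alu-Ref", "MIP", "ALU", AlleleEfficiencyProfile(0.9, 0.9))
        wells, truth = simulate_cohort(
            [CohortGroupSpec("g", 3, 0.8, 0.02)],
            [msp, mip, alu_me, alu_ref],
            SimulationConfig(seed=0, n_replicates=2),
        )
        per_sample = len([w for w in wells if w.sample_id == truth.sample_id[0]])
        assert per_sample == 4 * 2  # four reactions, duplicate wells

    def test_empty_group_rejected(self, unbiased_pair):
        with pytest.raises(ValueError):
            CohortGroupSpec("g", 0, 0.5, 0.1)

    def test_mismatched_paired_sizes_rejected(self, unbiased_pair):
        msp, mip = unbiased_pair
        groups = [CohortGroupSpec("a", 5, 0.7, 0.05), CohortGroupSpec("b", 6, 0.7, 0.05)]
        with pytest.raises(ValueError):
            simulate_cohort(groups, [msp, mip], SimulationConfig(seed=0), paired=True)


class TestSpecValidation:
    def test_efficiency_bounds(self):
        with pytest.raises(ValueError):
            AlleleEfficiencyProfile(0.0, 0.9)
        with pytest.raises(ValueError):
            AlleleEfficiencyProfile(0.9, 1.2)

    def test_mip_cross_reactivity_fixed_to_one(self):
        mip = AssaySpec("R", "MIP", "LINE1", AlleleEfficiencyProfile(0.9, 0.9))
        assert mip.cross_reactivity == 1.0
        with pytest.raises(ValueError):
            AssaySpec("R", "MIP", "LINE1", AlleleEfficiencyProfile(0.9, 0.9), cross_reactivity=0.5)

    def test_msp_defaults_to_no_cross_reactivity(self):
        msp = AssaySpec("M", "MSP", "LINE1", AlleleEfficiencyProfile(0.9, 0.9))
        assert msp.cross_reactivity == 0.0

    def test_unbiased_flag(self):
        assert AlleleEfficiencyProfile(0.9, 0.9).unbiased
        assert not AlleleEfficiencyProfile(0.9, 0.8).unbiased
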