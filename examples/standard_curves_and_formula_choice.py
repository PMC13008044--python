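"""Standard-curve calibration and Livak/Pfaffl formula selection.

Simulates the dilution-series design (1000 -> 3.125 pg of fully
methylated DNA, triplicate wells, CT noise 0.05 cycles) for a LINE-1
MSP/MIP assay pair, fits each standard curve, and applies the
dCT-slope rule that decides between the perfect-doubling Livak formula
and the efficiency-corrected Pfaffl formula.
"""

from qmsp import (
    AlleleEfficiencyProfile,
    AssaySpec,
    SimulationConfig,
    fit_standard_curve,
    select_formula,
    simulate_dilution_series,
)

config = SimulationConfig(seed=7, ct_noise_sd=0.05, n_replicates=3)

# the MSP assay amplifies at E=0.94 per cycle, the MIP reference at 0.86:
# their dCT drifts with input mass, which the selection rule must catch
msp = AssaySpec("L1-Me", "MSP", "LINE1", AlleleEfficiencyProfile(0.94, 0.94))
mip = AssaySpec("L1-Ref", "MIP", "LINE1", AlleleEfficiencyProfile(0.86, 0.86))

msp_wells = simulate_dilution_series(msp, None, config)
mip_wells = simulate_dilution_series(mip, None, config)

for wells in (msp_wells, mip_wells):
    fit = fit_standard_curve(wells)
    print(
        f"{fit.assay_id}: slope {fit.slope:.3f} cycles/log10(pg), "
        f"E = {fit.efficiency_pct:.2f}%, R^2 = {fit.r2:.4f}, "
        f"CT cutoff {fit.ct_cutoff:.2f} at {fit.lod_mass_pg:g} pg"
    )

choice = select_formula(msp_wells, mip_wells, element="LINE1")
print(
    f"dCT slope {choice.dct_slope:+.3f} (p = {choice.p_value:.2g}) "
    f"-> {choice.choice}"
)
# The fitted efficiencies recover the simulated truth within a fraction
# of a percent, R^2 stays above 0.99 under realistic noise, and the
# non-flat dCT slope (|slope| > 0.1, p < 0.05) forces the Pfaffl formula.
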