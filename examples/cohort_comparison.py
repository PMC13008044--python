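"""Paired cohort simulation and group comparison.

Simulates 100 matched tumour/adjacent-tissue pairs whose LINE-1
methylation differs by 5 percentage points (means 0.70 vs 0.75, subject
sd 0.10), runs the full four-reaction qMSP quantification per sample,
and compares the groups with the normality-gated paired test.
"""

from qmsp import (
    AlleleEfficiencyProfile,
    AssayConfig,
    AssaySpec,
    CohortGroupSpec,
    CtTable,
    RunConfig,
    SimulationConfig,
    compare_two_groups,
    quantify_samples,
    simulate_cohort,
    summarize_group,
)

config = SimulationConfig(seed=42, ct_noise_sd=0.1, n_replicates=2)
msp = AssaySpec("L1-Me", "MSP", "LINE1", AlleleEfficiencyProfile(0.90, 0.90))
mip = AssaySpec("L1-Ref", "MIP", "LINE1", AlleleEfficiencyProfile(0.90, 0.90))

groups = [
    CohortGroupSpec("tumour", 100, 0.70, 0.10),
    CohortGroupSpec("adjacent", 100, 0.75, 0.10),
]
wells, truth = simulate_cohort(groups, [msp, mip], config, paired=True)

run = RunConfig(
    assays=[
        AssayConfig("L1-Me", "MSP", "LINE1", efficiency=0.90),
        AssayConfig("L1-Ref", "MIP", "LINE1", efficiency=0.90),
    ],
    formula={"LINE1": "PFAFFL"},
)
results = quantify_samples(CtTable(records=wells), run)

levels = {}
for g in groups:
    rows = [r for r in results if r.group == g.label]
    s = summarize_group(rows, label=g.label)
    levels[g.label] = [r.methylation_pct for r in rows]
    print(
        f"{s.label}: n = {s.n}, median {s.median_pct:.2f}% "
        f"(IQR {s.q1:.2f} - {s.q3:.2f})"
    )

comparison = compare_two_groups(
    levels["tumour"], levels["adjacent"], paired=True, labels=("tumour", "adjacent")
)
print(
    f"{comparison.test_name}: statistic {comparison.statistic:.1f}, "
    f"p = {comparison.p_value:.2e}"
)
# The tumour arm's median sits ~5 points below the adjacent arm's,
# mirroring the simulated hypomethylation, and the paired test finds the
# shift with overwhelming evidence at n = 100 pairs.
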