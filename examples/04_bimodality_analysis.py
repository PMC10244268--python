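"""Detect the two-community structure: dip test, KDE thresholds, SIMPER.

Simulates the two-pool regime (taxa with intermediate TP optima suppressed to
10% of their carrying capacity), computes each site's community TP optimum,
tests it for unimodality, derives the low/"lukewarm"/high group thresholds by
quartile reflection around the two density modes, and ranks the taxa driving
the between-group Bray–Curtis dissimilarity.
"""

from pdise import (
    CalibrationConfig,
    SimulationConfig,
    assign_groups,
    calibrate,
    derive_thresholds,
    dip_test,
    generate_bimodal_regime,
    generate_gradient,
    generate_niches,
    simper,
    site_optima,
)

sim = SimulationConfig(n_sites=400, n_taxa=150, seed=11, bimodal=True,
                       suppression=0.1, tp_sd_log10=0.3)
chem = generate_gradient(sim)
niches = generate_niches(sim)
matrix = generate_bimodal_regime(chem, niches, sim)
profiles = calibrate(matrix, chem, CalibrationConfig(n_repeats=20, base_seed=17))

optima = site_optima(matrix, profiles).dropna()
dip = dip_test(optima.to_numpy(), n_null_reps=1000, seed=17)
print(f"Hartigan's dip on {dip.n} site optima: D = {dip.statistic:.3f}, p = {dip.p_value:.3f}")

thr = derive_thresholds(optima.to_numpy())
print(f"KDE modes at {thr.mode_low:.2f} and {thr.mode_high:.2f} log10 µg/l;")
print(f"group thresholds {thr.t_low:.2f} / {thr.t_high:.2f} log10 "
      f"({thr.t_low_ugl:.1f} / {thr.t_high_ugl:.1f} µg/l)")

groups = assign_groups(10.0**optima, thr.t_low_ugl, thr.t_high_ugl)
print("sites per group:", groups.value_counts().to_dict())

top = simper(matrix.loc[groups.index], groups)["overall"].head(5)
print("\nTop taxa driving between-group dissimilarity:")
print(top[["contribution_pct", "cumulative_pct"]].round(2).to_string())
print(
    "\nA significant dip (p < 0.01) rejects unimodality: sites fall into a\n"
    "low-TP and a high-TP community with few 'lukewarm' sites between the\n"
    "thresholds. SIMPER shows which taxa differentiate the groups."
)
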