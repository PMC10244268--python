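"""Score samples with PDI_SE and regress the index against log10 TP.

PDI_SE = Σ a_j s_j v_j / Σ a_j v_j with a_j the square-root-transformed
relative abundance: an abundance-weighted average of taxon sensitivity
classes, extra-weighted by indicator strength.  On well-behaved data it
responds linearly to log10 TP.
"""

import numpy as np

from pdise import (
    CalibrationConfig,
    SimulationConfig,
    calibrate,
    fit_linear,
    generate_community,
    generate_gradient,
    generate_niches,
    score_matrix,
)

sim = SimulationConfig(n_sites=300, n_taxa=40, seed=12)
chem = generate_gradient(sim)
matrix = generate_community(chem, generate_niches(sim), sim)
profiles = calibrate(matrix, chem, CalibrationConfig(n_repeats=50, base_seed=3))

scores = score_matrix(matrix, profiles)
fit = fit_linear(np.log10(chem["tp_ugl"]), scores["pdi"])

print(scores.head().to_string())
print()
print(f"PDI_SE = {fit.slope:.3f} · log10(TP) + {fit.intercept:.3f}   r² = {fit.r_squared:.2f}")
print(
    "Per site: the index value (1 = very TP-sensitive community, 5 = highly\n"
    "TP-tolerant), the abundance fraction carried by scored taxa (coverage),\n"
    "and how many scored taxa were present. The positive slope and high r²\n"
    "show the index tracking the phosphorus gradient."
)
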