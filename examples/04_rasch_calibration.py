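"""Rasch calibration: item screening, model checks, and the score chart.

The constrained Rasch model P(X=1|theta) = logistic(theta - b_i) makes the
total score sufficient for ability, so the final product is a chart mapping
every total score to an ability in logits and a 0-100 percent scale.
"""

import numpy as np

import icfscale.rasch as rs
# Build a clean 12-item Rasch cohort.
from icfscale.synthetic import ItemSpec, SimulationConfig, simulate_dichotomous

items = [ItemSpec(f"d{j + 1:03d}", float(b)) for j, b in enumerate(np.linspace(-2, 2, 12))]
matrix = simulate_dichotomous(SimulationConfig(600, items, seed=11))

final_items, log, fit = rs.screening_circle(matrix)
print(f"screening circle: {log.n_iterations} iteration(s), removed {log.all_removed or 'none'}")
print(f"model choice: {'constrained (a = 1)' if fit.constrained else 'unconstrained'}, "
      f"logLik = {fit.log_likelihood:.1f}, AIC = {fit.aic:.1f}")

gof = rs.bootstrap_gof(fit, matrix.select_items(final_items), B=99, seed=0)
print(f"global goodness of fit: T_obs = {gof.t_obs:.1f}, p = {gof.p:.3f} "
      f"(> 0.05 supports the model)")

unidim = rs.unidim_test(fit, matrix.select_items(final_items), n_sim=50, seed=1)
print(f"unidimensionality: 2nd eigenvalue {unidim.second_eigenvalue_obs:.2f} vs "
      f"simulated mean {unidim.second_eigenvalues_sim.mean():.2f}, p = {unidim.p:.3f}")

table = rs.score_conversion_table(fit)
b0, b1, b2 = table.coefficients
print(f"score equation: theta = {b0:.3f} + {b1:.4f} TTS + {b2:.5f} TTS^2")
print("total score -> ability (logits) -> percent:")
for r in (0, len(final_items) // 2, len(final_items)):
    print(f"  TTS {r:2d}: theta = {table.theta[r]:+.3f}, percent = {table.percent[r]}")
print()
print("A patient's yes/no answers are summed and read off the chart; the")
print("percent column is the ability rescaled so the minimum score is 0 and")
print("the maximum 100.")
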