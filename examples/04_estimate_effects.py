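"""Stage 2: DML partialling-out versus the naive slope under confounding.

A latent per-subject trait raises both the treatment predictor and the
initiation hazard.  The naive lagged slope absorbs that confounding; the
cross-fitted partialling-out estimate removes most of it.  The generating
mechanism is known, so the true adjusted effect is available from a
Monte-Carlo oracle.
"""

from lagdml import (build_lagged_features, estimate_edge_effect,
                    naive_lagged_slope, simulate_panel, true_effect_oracle)
from lagdml.scenarios import confounded_effect_scenario

sim, lag, eff, edge = confounded_effect_scenario(seed=41)
panel, truth = simulate_panel(sim)
panel = build_lagged_features(panel, lag)

est = estimate_edge_effect(panel, edge, eff)
naive = naive_lagged_slope(panel, edge[0], edge[1])
oracle = true_effect_oracle(truth, "x001", 1, "use", n_mc=100_000)

print(f"edge: {edge[0]} -> {edge[1]} "
      f"({est.n_rows} at-risk rows, {est.n_subjects} subjects)")
print(f"  oracle (true adjusted effect): {oracle:+.4f} per 1 SD")
print(f"  DML theta:                     {est.theta:+.4f} "
      f"(cluster-robust SE {est.se:.4f}, "
      f"95% CI [{est.ci_low:+.4f}, {est.ci_high:+.4f}])")
print(f"  naive lagged slope:            {naive:+.4f}")
print(f"\n|DML - oracle| = {abs(est.theta - oracle):.4f}, "
      f"|naive - oracle| = {abs(naive - oracle):.4f}")
print("the naive estimate overshoots because the latent confounder raises "
      "both treatment and hazard;")
print("residualizing both on the other lagged covariates removes most of "
      "that bias")
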