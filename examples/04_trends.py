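"""Test for directional trends in relative brain mass.

A clade under sustained directional selection accumulates both rate shifts
and residual increase, so its species show larger relative brain mass the
more rate-scaled path length they have traversed. This example injects a
trend into clade G3, fits the variable-rates model, computes posterior-mean
pathwise rates, and regresses relative brain mass on them with per-clade
slopes.
"""

import warnings

from allometree.allometry import AllometryModelSpec, fit_bbm
from allometree.synthgen import generate_study
from allometree.trends import (posterior_pathwise_rates, relative_brain,
                               trend_regression)
from allometree.varrates import MCMCSettings, mean_scaled_tree

warnings.filterwarnings("ignore", category=RuntimeWarning)

tree, table, truth, _ = generate_study(
    {"seed": 77, "tree": {"group_sizes": {"G1": 40, "G2": 20, "G3": 40}},
     "shifts": {"G2": 10.0, "G3": 4.0}, "trends": {"G3": 0.01}})
print(f"truth: rate shifts {truth.shifts}, trend {truth.trends} "
      "(G2 is fast but undirected — the control)")

fit = fit_bbm(tree, table, AllometryModelSpec("quadratic"),
              engine="variable-rates",
              settings=MCMCSettings(n_iter=30000, n_chains=2, seed=7))
post = fit.result
scaled = mean_scaled_tree(post, tree)
pathwise = posterior_pathwise_rates(post, tree, summary="mean")
rel = relative_brain(table, fit)

res = trend_regression(rel, pathwise, table["group"], scaled,
                       per_group=True, n_samples=4000, seed=3)
print("\nper-clade trend slopes (relative brain mass per rate-scaled Myr):")
print(res.table.to_string(index=False))
print("\nA slope with Px < 0.05 marks a directional trend; only the "
      "injected clade should qualify. Undirected rate shifts (G2) raise "
      "pathwise rates without raising relative brain mass.")
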