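"""Reconstruct brain and body change branch by branch.

Imputes body mass at every internal node (BLUP on the body rate-scaled
tree, adjusted by the fitted pathwise-rate relationship), then brain mass
(quadratic prediction + trend term + Brownian residual component),
decomposes every branch into brain and body change, and compares clades by
ANCOVA with a Tukey HSD letter display.
"""

import warnings

import numpy as np

from allometree.allometry import AllometryModelSpec, fit_bbm
from allometree.branchwise import (ancova_tukey, branch_changes,
                                   group_change_summary,
                                   impute_ancestral_body,
                                   impute_ancestral_brain)
from allometree.synthgen import generate_study
from allometree.varrates import MCMCSettings, fit_variable_rates

warnings.filterwarnings("ignore", category=RuntimeWarning)

tree, table, truth, nodes_truth = generate_study(
    {"seed": 77, "tree": {"group_sizes": {"G1": 40, "G2": 20, "G3": 40}},
     "shifts": {"G2": 10.0, "G3": 4.0}, "trends": {"G3": 0.01}})
settings = MCMCSettings(n_iter=30000, n_chains=2, seed=7)

fit = fit_bbm(tree, table, AllometryModelSpec("quadratic"),
              engine="variable-rates", settings=settings)
body_post = fit_variable_rates(tree, np.ones((tree.n_tips, 1)),
                               table["log_body"].to_numpy(),
                               settings=settings, names=["mean_body"])

body = impute_ancestral_body(tree, body_post, table)
print(f"body ~ pathwise-rate relationship: alpha = {body['alpha']:.3f}, "
      f"beta = {body['beta_pathwise']:.4f}")
brain = impute_ancestral_brain(tree, body["node_body"], fit, fit.result,
                               table, trend_slopes={}, common_trend=0.0)

changes = branch_changes(tree, brain["node_brain"], body["node_body"],
                         groups=brain["node_group"])
print("\nper-clade proportions of branches with increases:")
print(group_change_summary(changes).to_string(index=False))

anc = ancova_tukey(changes, include_ancestor=True)
print(f"\nANCOVA (brain change ~ body change + clade): "
      f"clade factor p = {anc.group_p:.2g}")
print("Tukey letters (clades sharing a letter are indistinguishable):")
for g, l in anc.letters.items():
    print(f"  {g}: {l}   adjusted mean {anc.adjusted_means[g]:+.3f}")
print("\nThe trending clade has the highest adjusted mean — its brain "
      "change outruns what its body change predicts — and leads the "
      "letter ordering when the contrast is large enough to separate.")
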