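"""Fit the hierarchical ordinal concordance model and bias-adjust the stages.

Simulates a staged cohort from the model's own generative process (one rater
planted with a +1.5 latent intercept bias), fits the cumulative-link model
``virtual ~ mo(real) * rater + (1 + test | case)`` by MCMC, and shows that
bias adjustment pulls the biased rater back toward the consensus before the
bootstrap concordance correlation is computed.
"""

import numpy as np

from vtstain import concordance as conc
from vtstain import synthetic

spec = synthetic.RaterSimSpec(n_cases=80, seed=17,
                              alpha=(0.0, 0.0, 0.0, 1.5),
                              b_offset=(0.0, 0.0, 0.0, 0.0))
staging, truth = synthetic.simulate_rater_stages(spec)
design = conc.build_design(staging, bound="upper")
print(f"{len(design)} (case, rater, test) rows; "
      f"{(staging.stage_low < staging.stage_high).mean():.0%} interval reports")

post = conc.fit_concordance_model(design, chains=2, seed=3)
print(f"max split-R-hat {post.diagnostics['max_rhat']:.3f}, "
      f"min ESS {post.diagnostics['min_ess']:.0f}")
print(post.summary().head(12).to_string(index=False))

design = design.assign(adjusted=conc.bias_adjusted_stage(post, design))
t1 = design[design["test"] == 0]
consensus = t1[t1["rater_id"] != "R4"].groupby("case_id")["y"].mean()
biased = t1[t1["rater_id"] == "R4"].set_index("case_id")
print(f"biased rater MAD from consensus: raw "
      f"{np.abs(biased['y'] - consensus).mean():.2f}, adjusted "
      f"{np.abs(biased['adjusted'] - consensus).mean():.2f}"
      " (adjustment removes the planted +1-level bias)")

corr = conc.spearman_bootstrap(design["adjusted"].to_numpy(),
                               design["y"].to_numpy(float), n_boot=10_000,
                               seed=0, groups=design["case_id"].to_numpy())
print(f"bias-adjusted concordance rho = {corr['rho']:.3f} "
      f"[{corr['ci_low']:.3f}, {corr['ci_high']:.3f}]; non-inferior at 0.9: "
      f"{corr['non_inferior']}")
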