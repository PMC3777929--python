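"""Discover a subnetwork signature on one cohort and classify an
independent cohort, reporting cumulative accuracy and PPV as subnetworks
are added (k = 1..5), plus the logrank separation of the predicted groups.
"""

import numpy as np

import cranesig as cs

cfg = cs.CohortSimConfig(
    n_genes=400,
    n_sts=50,
    n_lts=50,
    n_middle=100,
    planted=[cs.two_state_design(10, 0.44, 0.0) for _ in range(5)],
    seed=3,
)
train = cs.simulate_cohort(cfg)
disc = cs.run_discovery(
    train.expression, train.clinical, train.network, d_max=10, k=5, seed=3
)
print(f"signature: {len(disc.signature)} disjoint subnetworks, "
      f"{len(disc.signature.genes)} genes total")

# independent test cohort drawn from the same generative truth
test_cfg = cs.CohortSimConfig(**{**cfg.__dict__, "seed": 1003})
test = cs.generate_expression_cohort(
    train.network, train.planted_sets, test_cfg, np.random.default_rng(1003)
)
val = cs.run_validation(
    disc.binarized, disc.labels, test.expression, test.clinical,
    disc.signature, k_max=len(disc.signature), seed=3,
)

print("\ncumulative test performance (k = number of subnetworks used):")
print(val.report[["k", "accuracy", "ppv_sts", "ppv_lts"]].round(2).to_string(index=False))
print(f"\nbest k = {val.best_k}; "
      f"logrank between predicted groups: chi2 = {val.logrank_statistic:.1f}, "
      f"p = {val.logrank_p:.2e}")
print(
    "\nAccuracy is (S + L)/T over the test cohort; PPV_STS is the fraction"
    "\nof predicted short-term survivors that truly are short-term.  A small"
    "\nlogrank p confirms the predicted groups differ in actual survival."
)
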