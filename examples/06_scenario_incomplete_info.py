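"""Run the incomplete-information scenario end to end.

Two sites each lack a disjoint set of planted diagnoses. Missing
diagnosis vectors are compensated with random unit vectors, raw
other-site vectors, or Procrustes-harmonized other-site vectors, and
compared against the pooled-data global model: the expected ordering is
global > harmonized > raw > random ~ 0.5.
"""

import warnings

from clinalign import ScenarioConfig, SyntheticConfig, run_scenario

config = ScenarioConfig(
    scenario="incomplete_info",
    synthetic=SyntheticConfig(n_patients=1000),
    n_folds=10,
    eval_folds=1,  # one train/test split keeps this demo quick
    anchor_fractions=(0.1, 0.4, 0.7),
    seed=17,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_scenario(config)

for arm in ("global", "prot_70", "prot_40", "prot_10", "local", "random"):
    print(f"{arm:>8}: macro AUC = {report.arms[arm]['macro']:.3f}")
# "random" sits at chance; raw cross-site vectors ("local") barely help;
# harmonized compensation ("prot_*") recovers much of the global model's
# accuracy, improving slightly with the anchor fraction.
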