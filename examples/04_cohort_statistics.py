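"""Simulate the 12-surgeon study and build the median/p-value summary table.

Six experts and six novices each run the task with conventional and robotic
equipment. Group contrasts use the exact Mann-Whitney U test; the paired
equipment contrast within each group uses the exact Wilcoxon signed-rank
test. With six subjects per group the attainable two-sided floor of the
signed-rank test is 2/2^6 = 0.03125 — any 'fully consistent' paired effect
lands exactly there.
"""

import pandas as pd

import cathkin as ck
from cathkin.segmentation import binarize, distance_image
from cathkin.stats import summarize_cohort

pd.set_option("display.width", 140)

geometry = ck.default_arch_geometry()
phantom, _ = ck.make_phantom(geometry)
dist = distance_image(binarize(phantom, "auto"))

cohort = ck.simulate_cohort(seed=1, geometry=geometry)
features = ck.features_table(cohort, dist)
summary = summarize_cohort(features)

cols = ["feature", "stage", "median_novice_conventional", "median_expert_conventional",
        "p_mw_conventional", "p_wi_expert"]
print(summary[cols].round(4).to_string(index=False))
print("\np_mw_conventional: novice vs expert (exact Mann-Whitney), conventional runs;")
print("p_wi_expert: conventional vs robotic within experts (exact Wilcoxon).")
print("Values below 0.05 mark significant contrasts; expert T_p and j_d are the")
print("strongly separated features, as hypothesized for skilled manipulation.")
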