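"""Unsupervised discrimination of experience level and equipment type.

Stage-1 features (T_p, v_d, a_d, j_d) are log-scaled, standardized and fed
to 2-cluster k-means and a diagonal Gaussian mixture fitted by EM. Accuracy
is scored against the known labels, maximized over the two cluster-to-label
assignments — the clustering itself never sees the labels.
"""

import cathkin as ck
from cathkin.clustering import run_discrimination
from cathkin.segmentation import binarize, distance_image

geometry = ck.default_arch_geometry()
phantom, _ = ck.make_phantom(geometry)
dist = distance_image(binarize(phantom, "auto"))
cohort = ck.simulate_cohort(seed=1, geometry=geometry)
features = ck.features_table(cohort, dist)

for task in ("experience", "equipment"):
    for algo in ("kmeans", "em"):
        res = run_discrimination(features, task, algorithm=algo, seed=1)
        print(f"{task:10s} {algo:6s}: {res.n_correct}/{res.n} correct "
              f"({100 * res.accuracy:.0f}%)")
print("\nexperience: novice vs expert from conventional stage-1 runs;")
print("equipment: conventional vs robotic within the expert group (T_p, a_d).")
print("EM additionally reports component means/variances and 70% ellipse radii:")
res = run_discrimination(features, "experience", algorithm="em", seed=1)
for k in (0, 1):
    print(f"  component {k}: weight {res.weights[k]:.2f}, "
          f"ellipse radii {res.ellipse_radii[k].round(2)}")
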