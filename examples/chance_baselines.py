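"""Monte-Carlo chance baselines for CSMF accuracy, and chance correction.

Random cause assignment already achieves CSMF accuracy well above zero, so
population-level scores are rescaled against a Monte-Carlo chance mean c:
CCCSMFA = (CSMFA - c) / (1 - c), giving 0 at chance.
"""

import vacoder as vc

print("uniform-simplex null (true CSMF drawn uniformly, uniform prediction):")
for n_causes in (5, 15, 1000):
    baseline = vc.chance_csmfa(
        "dirichlet_null", n_categories=n_causes, iterations=10_000, seed=1
    )
    print(f"  {n_causes:>4} causes: mean chance CSMFA = {baseline.mean:.3f}")
print("  (approaches 1 - 1/e = 0.632 as the number of causes grows)")

print("\ndataset null (uniform random assignment against a fixed skewed truth):")
cats = vc.ADULT_CHILD_CATEGORIES
import numpy as np

rng = np.random.default_rng(0)
labels = [cats[i] for i in rng.choice(15, p=vc.synth.SKEWED_CSMF_15, size=1200)]
baseline = vc.chance_csmfa(
    "dataset_null", true_labels=labels, categories=cats, iterations=10_000, seed=1
)
print(f"  15 causes, n=1200: mean chance CSMFA = {baseline.mean:.3f}")

print("\nchance-correcting published-scale scores with c = 0.643 (adult):")
for csmfa in (0.643, 0.80, 0.948, 1.0):
    print(f"  CSMFA {csmfa:.3f} -> CCCSMFA {vc.cccsmfa(csmfa, 0.643):+.3f}")
print(
    "\nA classifier scoring at the chance mean gets exactly 0; scores below"
    "\nchance are negative, and 1 remains perfect agreement."
)
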