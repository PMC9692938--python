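"""Rank features by symmetrical uncertainty with the class label.

Builds a planted table (8 informative, 4 redundant, 48 noise columns),
computes SU_FC for every feature, and shows that the planted signal columns
dominate the top of the ranking.
"""

import numpy as np

from antcad import SyntheticTableSpec, make_feature_table, relevance_profile

table, truth = make_feature_table(SyntheticTableSpec(seed=0))
profile = relevance_profile(table)

order = np.argsort(-profile.su_fc)
print("top 12 features by SU_FC (feature id, SU, planted role):")
roles = {j: "informative" for j in truth.informative}
roles.update({j: f"redundant(copy of f{truth.redundant_sources[j]})" for j in truth.redundant})
for j in order[:12]:
    print(f"  f{j:<3d} SU_FC={profile.su_fc[j]:.3f}  {roles.get(j, 'noise')}")

inf_mean = profile.su_fc[truth.informative].mean()
noise_mean = profile.su_fc[truth.noise].mean()
print(f"\nmean SU_FC: informative {inf_mean:.3f} vs noise {noise_mean:.3f}")
print("-> class-relevant columns carry an order of magnitude more label information.")

red, src = truth.redundant[0], truth.redundant_sources[truth.redundant[0]]
print(f"SU_FF(f{red}, f{src}) = {profile.su_ff[red, src]:.3f} "
      "(near-duplicate pair flagged by the redundancy matrix)")
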