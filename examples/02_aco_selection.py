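"""Select features with ant colony optimization and verify recovery.

Runs the filter-mode selector (feature-class heuristic) on a planted table
and compares the cross-validated 1-NN accuracy of the selected subset
against a random subset of the same size.
"""

import numpy as np

from antcad import (
    ACOConfig,
    SyntheticTableSpec,
    cross_val_error,
    make_feature_table,
    random_subset_baseline,
    run_aco,
)

table, truth = make_feature_table(SyntheticTableSpec(n_redundant=0, seed=0))
config = ACOConfig(deposit_mode="filter", heuristic_mode="fc",
                   n_ants=20, n_iterations=30, subset_size=8, seed=0)
result = run_aco(table, config)

hits = sorted(set(result.best_subset) & set(truth.informative))
print(f"selected subset: {result.best_subset}")
print(f"planted informative features recovered: {len(hits)}/8")

acc_sel = 1 - cross_val_error(table, result.best_subset, seed=0)
rand = random_subset_baseline(table.n_features, 8, np.random.default_rng(100))
acc_rand = 1 - cross_val_error(table, rand, seed=0)
print(f"1-NN cross-val accuracy: selected {acc_sel:.3f} vs random subset {acc_rand:.3f}")
print("-> pheromone + SU heuristics concentrate the search on the signal columns;")
print("   a random subset of equal size mostly picks noise.")
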