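"""Calibrate regularization weights and the space-blend by grid search.

The prescribed two-stage procedure: evaluate a joint (lambda1, lambda2)
grid under five-fold CV, fix the best pair, then sweep the tradeoff eta
between microbe-space and disease-space scores.
"""

from mdalink import Hyperparams, SyntheticConfig, generate, grid_search

data = generate(SyntheticConfig(nd=15, nm=40, seed=4))
params = Hyperparams(k=10, seed=0)

table, best = grid_search(
    data.dataset, data.disease_similarity, params,
    lambda1_values=[0.02, 0.2],
    lambda2_values=[0.04, 0.05],
    eta_values=[0.15, 0.4, 0.8],
    folds=5, repeats=1, fold_seed=0,
)
print(table.to_string(index=False))
print(f"\nselected: lambda1={best.lambda1}, lambda2={best.lambda2}, eta={best.eta}")
# auc_mean is the five-fold CV AUC at each grid point; the eta sweep rows
# hold the stage-1 winner fixed.
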