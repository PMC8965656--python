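"""Measure what each pipeline component contributes.

Re-runs leave-one-out cross-validation with single components removed:
the BMA functional similarity, the loss weighting, the graph-regularized
least-squares scoring, or the factorization itself.
"""

from mdalink import Hyperparams, SyntheticConfig, ablation, generate

data = generate(SyntheticConfig(nd=15, nm=40, seed=0))
params = Hyperparams(k=10, lambda1=0.2, lambda2=0.05, eta=0.4, seed=0)

for variant in ["full", "no_functional_similarity", "no_weight",
                "no_glaprls", "no_cwnmf"]:
    res = ablation(data.dataset, data.disease_similarity, params, variant,
                   protocol="loocv")
    print(f"{variant:26s} LOOCV AUC = {res.auc:.4f}")
# the weighting term and the factorization carry most of the signal on
# planted-community data; dropping either collapses performance toward
# chance, while the two similarity-side components contribute smaller,
# dataset-dependent margins.
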