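"""Cross-validation protocols, ROC/AUC computation, grid search, ablations.

Evaluation follows the global ranking protocol standard for association
prediction: each known positive pair is hidden from the training matrix,
the full pipeline is re-run (GIP and integrated similarities are
recomputed from the masked matrix, so no information about the held-out
pair leaks into training), and the held-out pair's score is ranked
against every pair with no observed association (the global candidate
set).  LOOCV hides one pair at a time; repeated k-fold hides one random
fold of positives at a time.

AUC is the exact rank statistic P(score_pos > score_cand) + 0.5 P(tie).
Because the candidate set is identical across folds, each fold
contributes a one-positive step ROC on a common FPR grid; the reported
curve is their vertical average and its trapezoidal area equals the mean
per-fold AUC exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cwnmf import Hyperparams
from .data import AssociationDataset, SimilarityMatrix
from .glaprls import ABLATION_VARIANTS, predict

__all__ = ["FoldRecord", "CVResult", "auc_from_scores", "loocv", "kfold_cv",
           "grid_search", "ablation"]


@dataclass
class FoldRecord:
    """One held-out positive: its score and mid-rank among candidates."""

    disease: str
    microbe: str
    score: float
    rank: float          # 1-based mid-rank among {positive} + candidates
    n_candidates: int
    n_greater: int       # candidates scoring strictly above the positive
    n_ties: int
    repeat: int = 0

    @property
    def percentile(self) -> float:
        """Per-fold AUC contribution: fraction of candidates beaten (+ half ties)."""
        wins = self.n_candidates - self.n_greater - self.n_ties
        return (wins + 0.5 * self.n_ties) / self.n_candidates


@dataclass
class CVResult:
    auc: float
    roc_points: np.ndarray              # (n+1, 2) array of (FPR, TPR)
    per_fold: list[FoldRecord]
    protocol: str
    repeats: int = 1
    fold_seed: int | None = None
    auc_sd: float | None = None
    per_repeat_auc: list[float] = field(default_factory=list)


def auc_from_scores(positive_scores, candidate_scores) -> float:
    """Exact rank-based AUC: P(pos > cand) + 0.5 P(pos == cand)."""
    pos = np.asarray(positive_scores, dtype=float)
    cand = np.asarray(candidate_scores, dtype=float)
    if pos.size == 0 or cand.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, cand]), method="average")
    # Mann-Whitney U from the rank sum of the positives
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * cand.size))


def _fold_stats(pos_score: float, cand_scores: np.ndarray) -> tuple[int, int]:
    g = int((cand_scores > pos_score).sum())
    t = int((cand_scores == pos_score).sum())
    return g, t


def _roc_from_records(records: list[FoldRecord]) -> tuple[float, np.ndarray]:
    """Vertical average of the per-positive step ROCs on the common grid.

    Each positive with g candidates above and t ties defines a one-positive
    ROC that is 0 up to FPR = g/n, rises linearly across the tie block (a
    vertical jump when t = 0), and is 1 from FPR = (g+t)/n.  All folds
    share the candidate count n, so averaging TPR at FPR = j/n (j = 0..n)
    gives a piecewise-linear curve whose trapezoidal area is exactly the
    mean per-fold AUC.  Jumps are represented by duplicated FPR points
    (left and right limits), the standard step-ROC encoding.
    """
    n = records[0].n_candidates
    if any(r.n_candidates != n for r in records):
        raise ValueError("folds have different candidate-set sizes")
    g = np.array([r.n_greater for r in records], dtype=float)
    t = np.array([r.n_ties for r in records], dtype=float)
    j = np.arange(n + 1, dtype=float)
    diff = j[:, None] - g[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        interp = np.clip(diff / t[None, :], 0.0, 1.0)  # nan/inf where t == 0
    # left/right limits at each grid point; they differ only for t == 0 folds
    left = np.where(t[None, :] > 0, interp, (diff > 0).astype(float)).mean(axis=1)
    right = np.where(t[None, :] > 0, interp, (diff >= 0).astype(float)).mean(axis=1)
    fpr = np.repeat(j / n, 2)
    tpr = np.column_stack([left, right]).ravel()
    roc = np.column_stack([fpr, tpr])
    auc = float(np.mean([r.percentile for r in records]))
    return auc, roc


def _score_fold(dataset: AssociationDataset, sds: SimilarityMatrix,
                params: Hyperparams, held: np.ndarray, cand_index: np.ndarray,
                variant: str, repeat: int) -> list[FoldRecord]:
    train = dataset.with_masked(held)
    F = predict(train, sds, params, variant=variant).scores
    flat = F.ravel()
    cand_scores = flat[cand_index]
    out = []
    for i, jj in np.atleast_2d(held):
        s = F[i, jj]
        g, t = _fold_stats(s, cand_scores)
        out.append(FoldRecord(
            disease=dataset.disease_labels[i], microbe=dataset.microbe_labels[jj],
            score=float(s), rank=g + 0.5 * t + 1.0,
            n_candidates=cand_scores.size, n_greater=g, n_ties=t, repeat=repeat,
        ))
    return out


def _candidate_index(dataset: AssociationDataset) -> np.ndarray:
    """Flat indices of all pairs with no observed association."""
    return np.flatnonzero(dataset.X.ravel() == 0.0)


def loocv(dataset: AssociationDataset, sds: SimilarityMatrix,
          params: Hyperparams, variant: str = "full") -> CVResult:
    """Global leave-one-out cross-validation over the known positives.

    Each known pair is zeroed in a training copy, similarities and the
    mask are rebuilt from the masked matrix, the pipeline is re-run, and
    the pair's score is ranked against all unobserved pairs.  One ROC/AUC
    aggregates all folds.
    """
    known = dataset.known_pairs()
    if len(known) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    cand_index = _candidate_index(dataset)
    records: list[FoldRecord] = []
    for pair in known:
        records.extend(_score_fold(dataset, sds, params, pair[None, :],
                                   cand_index, variant, repeat=0))
    auc, roc = _roc_from_records(records)
    return CVResult(auc=auc, roc_points=roc, per_fold=records, protocol="loocv")


def kfold_cv(dataset: AssociationDataset, sds: SimilarityMatrix,
             params: Hyperparams, folds: int = 5, repeats: int = 10,
             fold_seed: int = 0, variant: str = "full") -> CVResult:
    """Repeated k-fold cross-validation over the known positives.

    Positives are randomly partitioned into ``folds`` groups; each group
    is masked in turn (similarities recomputed per fold) and its pairs
    are ranked against the global candidate set.  The random split is
    repeated ``repeats`` times; the reported AUC is the mean over
    repeats, with the SD kept for diagnostics.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    known = dataset.known_pairs()
    if folds > len(known):
        raise ValueError(f"folds={folds} exceeds the {len(known)} known associations")
    cand_index = _candidate_index(dataset)
    records: list[FoldRecord] = []
    per_repeat: list[float] = []
    for r in range(repeats):
        rng = np.random.default_rng([fold_seed, r])
        perm = rng.permutation(len(known))
        rep_records: list[FoldRecord] = []
        for chunk in np.array_split(perm, folds):
            rep_records.extend(_score_fold(dataset, sds, params, known[chunk],
                                           cand_index, variant, repeat=r))
        per_repeat.append(float(np.mean([rec.percentile for rec in rep_records])))
        records.extend(rep_records)
    auc, roc = _roc_from_records(records)
    sd = float(np.std(per_repeat, ddof=1)) if repeats > 1 else 0.0
    return CVResult(auc=auc, roc_points=roc, per_fold=records, protocol="kfold",
                    repeats=repeats, fold_seed=fold_seed, auc_sd=sd,
                    per_repeat_auc=per_repeat)


def _run_protocol(dataset, sds, params, protocol, folds, repeats, fold_seed,
                  variant="full") -> CVResult:
    if protocol == "loocv":
        return loocv(dataset, sds, params, variant=variant)
    if protocol == "kfold":
        return kfold_cv(dataset, sds, params, folds=folds, repeats=repeats,
                        fold_seed=fold_seed, variant=variant)
    raise ValueError(f"unknown protocol {protocol!r}")


def grid_search(dataset: AssociationDataset, sds: SimilarityMatrix,
                params: Hyperparams, lambda1_values, lambda2_values,
                eta_values, protocol: str = "kfold", folds: int = 5,
                repeats: int = 1, fold_seed: int = 0,
                ) -> tuple[pd.DataFrame, Hyperparams]:
    """Two-stage hyperparameter search.

    Stage 1 evaluates the joint (lambda1, lambda2) grid at the incoming
    eta; stage 2 sweeps eta with the best pair fixed.  Returns the
    long-format result table (stage, lambda1, lambda2, eta, auc_mean,
    auc_sd) and the best Hyperparams found.
    """
    lambda1_values = list(lambda1_values)
    lambda2_values = list(lambda2_values)
    eta_values = list(eta_values)
    if not lambda1_values or not lambda2_values or not eta_values:
        raise ValueError("grid_search requires non-empty grids")
    rows = []
    best_pair, best_auc = None, -np.inf
    for l1 in lambda1_values:
        for l2 in lambda2_values:
            p = params.replace(lambda1=l1, lambda2=l2)
            res = _run_protocol(dataset, sds, p, protocol, folds, repeats, fold_seed)
            rows.append(("lambda_grid", l1, l2, params.eta, res.auc, res.auc_sd))
            if res.auc > best_auc:
                best_pair, best_auc = (l1, l2), res.auc
    l1, l2 = best_pair
    best_eta, best_eta_auc = None, -np.inf
    for eta in eta_values:
        p = params.replace(lambda1=l1, lambda2=l2, eta=eta)
        res = _run_protocol(dataset, sds, p, protocol, folds, repeats, fold_seed)
        rows.append(("eta_sweep", l1, l2, eta, res.auc, res.auc_sd))
        if res.auc > best_eta_auc:
            best_eta, best_eta_auc = eta, res.auc
    table = pd.DataFrame(rows, columns=["stage", "lambda1", "lambda2", "eta",
                                        "auc_mean", "auc_sd"])
    return table, params.replace(lambda1=l1, lambda2=l2, eta=best_eta)


def ablation(dataset: AssociationDataset, sds: SimilarityMatrix,
             params: Hyperparams, variant: str, protocol: str = "loocv",
             folds: int = 5, repeats: int = 10, fold_seed: int = 0) -> CVResult:
    """Cross-validate one ablated form of the pipeline.

    Variants: full (the complete method), no_functional_similarity
    (microbe GIP only), no_weight (all-ones loss mask), no_glaprls (rank
    by the reconstruction X* directly), no_cwnmf (raw training matrix
    into GLapRLS).
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {ABLATION_VARIANTS}")
    return _run_protocol(dataset, sds, params, protocol, folds, repeats,
                         fold_seed, variant=variant)
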