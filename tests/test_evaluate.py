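"""AUC exactness, cross-validation protocols, grid search, ablations."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mdalink import (
    AssociationDataset,
    Hyperparams,
    SimilarityMatrix,
    ablation,
    auc_from_scores,
    grid_search,
    kfold_cv,
    loocv,
)
from mdalink.evaluate import FoldRecord, _roc_from_records
from mdalink.similarity import integrated_similarities

# hyperparameters calibrated for the planted fixtures by the method's own
# two-stage grid-search protocol (see docs/methods.md)
CAL = dict(lambda1=0.2, lambda2=0.05, eta=0.4)


def brute_force_auc(pos, cand):
    wins = ties = 0
    for p in pos:
        for c in cand:
            if p > c:
                wins += 1
            elif p == c:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(cand))


class TestAucFromScores:
    def test_perfect_separation(self):
        assert auc_from_scores([5, 4], [1, 2, 3]) == 1.0

    def test_all_tied_is_half(self):
        assert auc_from_scores([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    def test_worked_example(self):
        assert auc_from_scores([3, 1], [2, 0]) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        # coarse grid values force plenty of exact ties
        pos = rng.integers(0, 6, size=rng.integers(1, 12)).astype(float)
        cand = rng.integers(0, 6, size=rng.integers(1, 12)).astype(float)
        assert auc_from_scores(pos, cand) == pytest.approx(
            brute_force_auc(pos, cand), abs=1e-12)

    def test_matches_sklearn_on_tie_free_scores(self):
        rng = np.random.default_rng(9)
        pos, cand = rng.random(30), rng.random(70)
        labels = np.r_[np.ones(30), np.zeros(70)]
        assert auc_from_scores(pos, cand) == pytest.approx(
            roc_auc_score(labels, np.r_[pos, cand]), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            auc_from_scores([], [1.0])


class TestRocConstruction:
    @pytest.mark.parametrize("seed", range(5))
    def test_curve_bounds_monotonicity_and_area(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        recs = []
        for _ in range(25):
            g = int(rng.integers(0, n + 1))
            t = int(rng.integers(0, n - g + 1)) if rng.random() < 0.5 else 0
            recs.append(FoldRecord("d", "m", 0.0, g + 0.5 * t + 1, n, g, t))
        auc, roc = _roc_from_records(recs)
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)
        assert (np.diff(roc[:, 0]) >= 0).all() and (np.diff(roc[:, 1]) >= -1e-15).all()
        assert abs(np.trapezoid(roc[:, 1], roc[:, 0]) - auc) < 1e-10
        assert auc == pytest.approx(np.mean([r.percentile for r in recs]), abs=1e-14)


@pytest.fixture(scope="module")
def small_cv():
    """Scaled-down planted benchmark plus its LOOCV result (computed once)."""
    from mdalink import SyntheticConfig, generate
    data = generate(SyntheticConfig(nd=14, nm=40, seed=3))
    params = Hyperparams(k=10, iterations=200, **CAL)
    return data, params, loocv(data.dataset, data.disease_similarity, params)


class TestLoocv:
    def test_recovers_planted_signal(self, small_cv):
        _, _, result = small_cv
        assert result.auc > 0.6  # well above chance on planted structure

    def test_deterministic(self, small_cv):
        data, params, result = small_cv
        again = loocv(data.dataset, data.disease_similarity, params)
        assert again.auc == result.auc
        assert np.array_equal(again.roc_points, result.roc_points)

    def test_one_fold_per_known_pair(self, small_cv):
        data, _, result = small_cv
        assert len(result.per_fold) == data.dataset.n_associations
        assert result.protocol == "loocv"

    def test_roc_area_consistent_with_rank_formula(self, small_cv):
        _, _, result = small_cv
        trap = np.trapezoid(result.roc_points[:, 1], result.roc_points[:, 0])
        assert abs(trap - result.auc) < 1e-10

    def test_masked_only_association_leaves_node_empty_and_unrankable(self):
        """One association per disease and per microbe with SdS = I: hiding a
        pair leaves both its nodes without any training evidence, so the
        held-out pair cannot outrank candidates that retain associations —
        no transferable signal exists (AUC at or below chance)."""
        aucs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n = 8
            perm = rng.permutation(n)
            X = np.zeros((n, n))
            X[np.arange(n), perm] = 1.0
            ds = AssociationDataset([f"d{i}" for i in range(n)],
                                    [f"m{i}" for i in range(n)], X)
            sds = SimilarityMatrix(ds.disease_labels, np.eye(n), role="symptom")
            params = Hyperparams(k=4, iterations=100, seed=seed, **CAL)
            aucs.append(loocv(ds, sds, params).auc)
        assert np.mean(aucs) <= 0.5

    def test_too_few_positives_rejected(self):
        X = np.zeros((2, 2))
        X[0, 0] = 1.0
        ds = AssociationDataset(["d1", "d2"], ["m1", "m2"], X)
        sds = SimilarityMatrix(ds.disease_labels, np.eye(2), role="symptom")
        with pytest.raises(ValueError, match="at least 2"):
            loocv(ds, sds, Hyperparams(k=2))


class TestLeakageGuard:
    def test_training_similarities_depend_only_on_masked_matrix(self, planted_tiny):
        """Within a fold, the recomputed similarities are a function of the
        masked training matrix alone: flipping the held-out cell's value in
        the source data changes nothing after masking."""
        ds = planted_tiny.dataset
        i, j = ds.known_pairs()[0]
        ds_flipped = ds.with_masked(np.array([[i, j]]))  # same cell set to 0
        tr_a = ds.with_masked(np.array([[i, j]]))
        tr_b = ds_flipped.with_masked(np.array([[i, j]]))
        sds = planted_tiny.disease_similarity
        sd_a, sm_a = integrated_similarities(tr_a, sds)
        sd_b, sm_b = integrated_similarities(tr_b, sds)
        assert np.array_equal(sd_a.S, sd_b.S)
        assert np.array_equal(sm_a.S, sm_b.S)


class TestKfold:
    def test_deterministic_with_fixed_fold_seed(self, planted_tiny, tiny_params):
        a = kfold_cv(planted_tiny.dataset, planted_tiny.disease_similarity,
                     tiny_params, folds=5, repeats=1, fold_seed=4)
        b = kfold_cv(planted_tiny.dataset, planted_tiny.disease_similarity,
                     tiny_params, folds=5, repeats=1, fold_seed=4)
        assert a.auc == b.auc

    def test_each_pair_held_out_exactly_once_per_repeat(self, planted_tiny, tiny_params):
        res = kfold_cv(planted_tiny.dataset, planted_tiny.disease_similarity,
                       tiny_params, folds=4, repeats=2, fold_seed=0)
        n_pos = planted_tiny.dataset.n_associations
        for r in range(2):
            held = [(rec.disease, rec.microbe) for rec in res.per_fold if rec.repeat == r]
            assert len(held) == n_pos
            assert len(set(held)) == n_pos

    def test_fold_count_equal_to_positives_reduces_to_loocv(self, small_cv):
        data, params, loo = small_cv
        n_pos = data.dataset.n_associations
        res = kfold_cv(data.dataset, data.disease_similarity, params,
                       folds=n_pos, repeats=1, fold_seed=0)
        assert res.auc == pytest.approx(loo.auc, abs=1e-12)

    def test_five_fold_close_to_loocv_on_same_fixture(self, small_cv):
        data, params, loo = small_cv
        res = kfold_cv(data.dataset, data.disease_similarity, params,
                       folds=5, repeats=3, fold_seed=1)
        assert abs(res.auc - loo.auc) < 0.05

    def test_too_many_folds_rejected(self, planted_tiny, tiny_params):
        with pytest.raises(ValueError, match="folds"):
            kfold_cv(planted_tiny.dataset, planted_tiny.disease_similarity,
                     tiny_params, folds=10_000)


class TestGridSearch:
    def test_bookkeeping_row_counts(self, planted_tiny):
        params = Hyperparams(k=6, iterations=80)
        table, best = grid_search(
            planted_tiny.dataset, planted_tiny.disease_similarity, params,
            [0.02, 0.2], [0.05, 0.2], [0.15, 0.4],
            folds=3, repeats=1, fold_seed=0)
        assert (table.stage == "lambda_grid").sum() == 4
        assert (table.stage == "eta_sweep").sum() == 2
        assert np.isfinite(table.auc_mean).all()

    def test_singleton_grid_returns_those_values(self, planted_tiny):
        params = Hyperparams(k=6, iterations=80)
        table, best = grid_search(
            planted_tiny.dataset, planted_tiny.disease_similarity, params,
            [params.lambda1], [params.lambda2], [params.eta],
            folds=3, repeats=1, fold_seed=0)
        assert (best.lambda1, best.lambda2, best.eta) == (
            params.lambda1, params.lambda2, params.eta)

    def test_empty_grid_rejected(self, planted_tiny):
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(planted_tiny.dataset, planted_tiny.disease_similarity,
                        Hyperparams(k=6), [], [0.1], [0.1])


class TestAblation:
    def test_full_variant_identical_to_plain_loocv(self, small_cv):
        data, params, loo = small_cv
        res = ablation(data.dataset, data.disease_similarity, params, "full",
                       protocol="loocv")
        assert res.auc == loo.auc
        assert np.array_equal(res.roc_points, loo.roc_points)

    @pytest.mark.parametrize("variant", ["no_functional_similarity", "no_weight",
                                         "no_glaprls", "no_cwnmf"])
    def test_variants_run_and_return_valid_auc(self, planted_tiny, tiny_params, variant):
        res = ablation(planted_tiny.dataset, planted_tiny.disease_similarity,
                       tiny_params.replace(**CAL), variant,
                       protocol="kfold", folds=4, repeats=1)
        assert 0.0 <= res.auc <= 1.0

    def test_zero_reconstruction_scores_are_all_tied_at_half(self):
        """A zero score matrix ranks every pair equally: AUC 0.5 by the
        mid-tie convention."""
        assert auc_from_scores(np.zeros(3), np.zeros(10)) == 0.5

    def test_unknown_variant_rejected(self, planted_tiny, tiny_params):
        with pytest.raises(ValueError, match="variant"):
            ablation(planted_tiny.dataset, planted_tiny.disease_similarity,
                     tiny_params, "bogus")
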