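"""Graph-Laplacian regularized least squares (GLapRLS) scoring.

Given the reconstructed association matrix X* and an integrated
similarity S on one side, the score matrix F solves

    min_F ||X*(^T) - F||_F^2 + beta Tr(F^T L F),   F = S alpha,

where L = D - S is the graph Laplacian of S (D = diag of column sums).
The Laplacian term penalizes score differences between similar nodes, so
the least-squares fit is smoothed along the similarity graph.  With the
parametrization F = S alpha the problem has the closed form

    F = S (S + beta L S)^{-1} X*(^T),

evaluated in the microbe space (fitting X*^T) and the disease space
(fitting X*), then blended as F* = eta F_m^T + (1 - eta) F_d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cwnmf import Hyperparams, factorize
from .data import AssociationDataset, SimilarityMatrix, default_mask
from .similarity import integrated_similarities

__all__ = ["LaplacianPair", "ScoreMatrix", "graph_laplacian", "rls_solve",
           "combine", "predict"]

ABLATION_VARIANTS = ("full", "no_functional_similarity", "no_weight",
                     "no_glaprls", "no_cwnmf")


@dataclass
class LaplacianPair:
    """Degree matrix D (diag of column sums of S) and Laplacian L = D - S."""

    D: np.ndarray
    L: np.ndarray


@dataclass
class ScoreMatrix:
    """Real-valued prediction scores with row/column labels.

    role is "microbe_space" (F_m, nm x nd), "disease_space" (F_d, nd x nm)
    or "combined" (F*, nd x nm).  The RLS coefficient matrix alpha is kept
    as an optional diagnostic.
    """

    row_labels: list[str]
    col_labels: list[str]
    scores: np.ndarray
    role: str
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("score matrix shape does not match labels")
        if not np.isfinite(self.scores).all():
            raise ValueError("score matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.row_labels,
                            columns=self.col_labels)


def graph_laplacian(S: SimilarityMatrix | np.ndarray,
                    tol: float = 1e-10) -> LaplacianPair:
    """Unnormalized graph Laplacian of a symmetric non-negative similarity."""
    A = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if np.abs(A - A.T).max(initial=0.0) > tol:
        raise ValueError("similarity matrix is not symmetric")
    if (A < 0).any():
        raise ValueError("similarity matrix has negative entries")
    D = np.diag(A.sum(axis=0))
    return LaplacianPair(D=D, L=D - A)


def _regularized_solve(S: np.ndarray, beta: float, B: np.ndarray,
                       jitter: float) -> np.ndarray:
    """Solve (S + beta L S) alpha = B with a ridge guard on ill-conditioning."""
    L = graph_laplacian(S).L
    A = S + beta * (L @ S)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        A = A + jitter * np.eye(A.shape[0])
    try:
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"GLapRLS system is singular ({exc}); increase ridge_jitter"
        ) from exc


def rls_solve(Xstar: np.ndarray, S: SimilarityMatrix, beta: float,
              side: str, jitter: float = 1e-8) -> ScoreMatrix:
    """Closed-form GLapRLS solution in one prediction space.

    microbe side:  F_m = S_m (S_m + beta L_m S_m)^{-1} X*^T   (nm x nd)
    disease side:  F_d = S_d (S_d + beta L_d S_d)^{-1} X*     (nd x nm)

    beta = 1 reproduces the standard printed closed forms.
    """
    Xstar = np.asarray(Xstar, dtype=float)
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if side == "microbe":
        B, role = Xstar.T, "microbe_space"
    elif side == "disease":
        B, role = Xstar, "disease_space"
    else:
        raise ValueError(f"side must be 'microbe' or 'disease', got {side!r}")
    if B.shape[0] != S.n:
        raise ValueError(f"similarity size {S.n} does not match X* for side {side!r}")
    alpha = _regularized_solve(S.S, beta, B, jitter)
    F = S.S @ alpha
    other = [f"axis{j}" for j in range(B.shape[1])]
    return ScoreMatrix(list(S.labels), other, F, role=role, alpha=alpha)


def combine(Fm: ScoreMatrix | np.ndarray, Fd: ScoreMatrix | np.ndarray,
            eta: float) -> np.ndarray:
    """Blend the two spaces: F* = eta F_m^T + (1 - eta) F_d."""
    if not (0.0 <= eta <= 1.0):
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    Fm = Fm.scores if isinstance(Fm, ScoreMatrix) else np.asarray(Fm, dtype=float)
    Fd = Fd.scores if isinstance(Fd, ScoreMatrix) else np.asarray(Fd, dtype=float)
    if Fm.T.shape != Fd.shape:
        raise ValueError(f"F_m^T shape {Fm.T.shape} != F_d shape {Fd.shape}")
    return eta * Fm.T + (1.0 - eta) * Fd


def predict(dataset: AssociationDataset, sds: SimilarityMatrix,
            params: Hyperparams, variant: str = "full") -> ScoreMatrix:
    """End-to-end scoring of every disease-microbe pair.

    Pipeline: integrated similarities from the (training) association
    matrix, loss mask, CWNMF reconstruction X*, GLapRLS in both spaces,
    eta-blend.  Deterministic given ``params.seed``.

    ``variant`` selects an ablated form of the pipeline (used by the
    component-contribution analysis): "no_functional_similarity" drops
    the BMA microbe similarity (GIP only), "no_weight" uses an all-ones
    loss mask, "no_glaprls" ranks by X* directly, "no_cwnmf" feeds the raw
    association matrix into GLapRLS.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {ABLATION_VARIANTS}")
    sd, sm = integrated_similarities(
        dataset, sds, sigma_prime=params.sigma_prime,
        use_functional=variant != "no_functional_similarity",
    )
    if variant == "no_cwnmf":
        Xstar = dataset.X
    else:
        scheme = "all_ones" if variant == "no_weight" else params.mask_scheme
        mask = default_mask(dataset, scheme, w0=params.mask_w0)
        fact = factorize(dataset.X, mask.Y, sd.S, sm.S, params)
        Xstar = fact.reconstruction
    if variant == "no_glaprls":
        F = Xstar
    else:
        Fm = rls_solve(Xstar, sm, params.beta_m, "microbe", jitter=params.ridge_jitter)
        Fd = rls_solve(Xstar, sd, params.beta_d, "disease", jitter=params.ridge_jitter)
        F = combine(Fm, Fd, params.eta)
    return ScoreMatrix(dataset.disease_labels, dataset.microbe_labels, F,
                       role="combined")
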