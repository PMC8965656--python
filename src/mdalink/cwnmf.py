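"""Collaborative weighted non-negative matrix factorization (CWNMF).

Reconstructs the sparse binary association matrix X as X* = W H^T by
minimizing a weighted squared reconstruction error with two collaborative
similarity penalties and Tikhonov smoothing:

    J = sum_ij Y_ij (X_ij - (W H^T)_ij)^2
        + lambda1 ||Sd - W W^T||_F^2
        + lambda2 ||Sm - H H^T||_F^2
        + alpha (||W||_F^2 + ||H||_F^2),       W >= 0, H >= 0.

The weight matrix Y zeroes the loss on missing cells so the fit is driven
by observed associations only; the collaborative terms ask the latent
factors to reproduce the integrated disease and microbe similarities,
which is what carries signal into the empty rows and columns of X.  The
objective is minimized by multiplicative updates derived from the KKT
conditions; with Y all ones and lambda1 = lambda2 = alpha = 0 they reduce
to the classical two-factor NMF rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import AssociationDataset, MaskMatrix, SimilarityMatrix

__all__ = ["Hyperparams", "FactorizationResult", "objective", "update_once", "factorize"]


@dataclass
class Hyperparams:
    """Model hyperparameters.

    k            latent dimensionality (must satisfy k <= min(nd, nm))
    lambda1/2    collaborative penalty weights (disease / microbe side)
    alpha        Tikhonov (L2) smoothing weight on both factors
    iterations   fixed multiplicative-update count
    beta_m/d     graph-Laplacian regularization weights for the two
                 least-squares scoring problems
    eta          tradeoff between microbe-space and disease-space scores
    sigma_prime  GIP kernel bandwidth adjustment coefficient
    epsilon      additive denominator guard in the multiplicative rules
    stop_tol     optional early stop on relative objective change
                 (None = run all iterations, for reproducible trajectories)
    """

    k: int = 35
    lambda1: float = 0.02
    lambda2: float = 0.04
    alpha: float = 1.0
    iterations: int = 300
    seed: int = 0
    epsilon: float = 1e-12
    beta_m: float = 1.0
    beta_d: float = 1.0
    eta: float = 0.15
    sigma_prime: float = 1.0
    mask_scheme: str = "observed_positives"
    mask_w0: float | None = None
    ridge_jitter: float = 1e-8
    stop_tol: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be positive, got {self.iterations}")
        for name in ("lambda1", "lambda2", "alpha", "beta_m", "beta_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")
        if self.sigma_prime <= 0:
            raise ValueError("sigma_prime must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def replace(self, **kwargs) -> "Hyperparams":
        return replace(self, **kwargs)


@dataclass
class FactorizationResult:
    W: np.ndarray
    H: np.ndarray
    objective_trajectory: list[float] = field(default_factory=list)

    @property
    def reconstruction(self) -> np.ndarray:
        """X* = W H^T."""
        return self.W @ self.H.T


def _arr(x) -> np.ndarray:
    if isinstance(x, AssociationDataset):
        return x.X
    if isinstance(x, SimilarityMatrix):
        return x.S
    if isinstance(x, MaskMatrix):
        return x.Y
    return np.asarray(x, dtype=float)


def objective(X, Y, W, H, Sd, Sm, params: Hyperparams) -> float:
    """Evaluate the CWNMF objective J at (W, H)."""
    X, Y, Sd, Sm = _arr(X), _arr(Y), _arr(Sd), _arr(Sm)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    R = X - W @ H.T
    fit = float(np.sum(Y * R * R))
    coll_d = params.lambda1 * float(np.sum((Sd - W @ W.T) ** 2))
    coll_m = params.lambda2 * float(np.sum((Sm - H @ H.T) ** 2))
    tik = params.alpha * (float(np.sum(W * W)) + float(np.sum(H * H)))
    return fit + coll_d + coll_m + tik


def update_once(W, H, X, Y, Sd, Sm, params: Hyperparams,
                iteration: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative update sweep: W first, then H with the fresh W.

        w <- w * (Y.X H + 2 l1 Sd W) / (Y.(W H^T) H + a W + 2 l1 W W^T W)
        h <- h * ((Y.X)^T W + 2 l2 Sm H) / ((Y.(W H^T))^T W + a H + 2 l2 H H^T H)

    Denominators carry an additive epsilon guard.  Non-negative inputs
    stay non-negative.
    """
    X, Y, Sd, Sm = _arr(X), _arr(Y), _arr(Sd), _arr(Sm)
    l1, l2, a, eps = params.lambda1, params.lambda2, params.alpha, params.epsilon
    YX = Y * X

    num_w = YX @ H + 2.0 * l1 * (Sd @ W)
    den_w = (Y * (W @ H.T)) @ H + a * W + 2.0 * l1 * (W @ (W.T @ W)) + eps
    W = W * (num_w / den_w)

    num_h = YX.T @ W + 2.0 * l2 * (Sm @ H)
    den_h = (Y * (W @ H.T)).T @ W + a * H + 2.0 * l2 * (H @ (H.T @ H)) + eps
    H = H * (num_h / den_h)

    if not (np.isfinite(W).all() and np.isfinite(H).all()):
        where = f" at iteration {iteration}" if iteration is not None else ""
        raise FloatingPointError(f"non-finite factor entries{where}")
    return W, H


def factorize(X, Y, Sd, Sm, params: Hyperparams,
              rng: np.random.Generator | None = None) -> FactorizationResult:
    """Run the full multiplicative-update loop from a seeded random start.

    W and H are initialized uniformly on (0, 1] (strictly positive: a zero
    entry is absorbing under multiplicative updates).  The objective is
    recorded after every iteration.  By default all ``params.iterations``
    sweeps run; ``params.stop_tol`` enables an optional early stop on
    relative objective change.
    """
    Xa, Ya, Sda, Sma = _arr(X), _arr(Y), _arr(Sd), _arr(Sm)
    nd, nm = Xa.shape
    if params.k > min(nd, nm):
        raise ValueError(f"k={params.k} exceeds min(nd, nm)={min(nd, nm)}")
    if Ya.shape != Xa.shape:
        raise ValueError(f"mask shape {Ya.shape} != association shape {Xa.shape}")
    if Sda.shape != (nd, nd) or Sma.shape != (nm, nm):
        raise ValueError("similarity matrix shapes do not match the association matrix")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    W = 1.0 - rng.random((nd, params.k))   # uniform on (0, 1]
    H = 1.0 - rng.random((nm, params.k))

    trajectory: list[float] = []
    for it in range(params.iterations):
        W, H = update_once(W, H, Xa, Ya, Sda, Sma, params, iteration=it)
        J = objective(Xa, Ya, W, H, Sda, Sma, params)
        trajectory.append(J)
        if (params.stop_tol is not None and it > 0
                and abs(trajectory[-2] - J) <= params.stop_tol * max(abs(trajectory[-2]), 1e-30)):
            break
    return FactorizationResult(W=W, H=H, objective_trajectory=trajectory)
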