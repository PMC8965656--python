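"""Similarity construction: GIP kernels, microbe functional similarity, fusion.

Three sources of similarity feed the predictor:

* a symptom-based disease similarity matrix, supplied externally;
* a microbe *functional* similarity derived from it by best-match
  averaging over each microbe pair's associated disease sets;
* Gaussian interaction profile (GIP) kernel similarities computed from
  the association matrix itself, on both the disease and microbe side.

The external/functional matrices are sparse (many structural zeros), so
fusion is conditional: where the primary similarity is nonzero the
integrated value is the mean of primary and GIP, elsewhere the GIP value
is used alone so that it is never diluted by absent evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data import AssociationDataset, SimilarityMatrix

__all__ = [
    "GipBandwidth",
    "gip_bandwidth",
    "gip_kernel",
    "microbe_functional_similarity",
    "integrate",
    "integrated_similarities",
]


@dataclass(frozen=True)
class GipBandwidth:
    """GIP kernel bandwidth: sigma = sigma_prime / mean squared profile norm."""

    sigma_prime: float
    sigma: float


def gip_bandwidth(profiles: np.ndarray, sigma_prime: float = 1.0) -> GipBandwidth:
    """Normalized bandwidth for profiles stacked as rows.

    sigma = sigma_prime / (mean over profiles of ||IP||^2).  Undefined
    (raises) when every profile is all-zero.
    """
    if sigma_prime <= 0:
        raise ValueError(f"sigma_prime must be positive, got {sigma_prime}")
    mean_sq = float(np.mean(np.sum(profiles ** 2, axis=1)))
    if mean_sq == 0.0:
        raise ValueError("bandwidth undefined: all interaction profiles are zero")
    return GipBandwidth(sigma_prime, sigma_prime / mean_sq)


def gip_kernel(dataset: AssociationDataset, side: str,
               sigma_prime: float = 1.0) -> SimilarityMatrix:
    """Gaussian interaction profile kernel similarity for one side.

    S(i, j) = exp(-sigma * ||IP_i - IP_j||^2) with the bandwidth
    normalized by the mean squared profile norm of that side.  Disease
    profiles are rows of X, microbe profiles are columns.
    """
    if side == "disease":
        profiles, labels = dataset.X, dataset.disease_labels
    elif side == "microbe":
        profiles, labels = dataset.X.T, dataset.microbe_labels
    else:
        raise ValueError(f"side must be 'disease' or 'microbe', got {side!r}")
    bw = gip_bandwidth(profiles, sigma_prime)
    sq_dist = squareform(pdist(profiles, metric="sqeuclidean"))
    S = np.exp(-bw.sigma * sq_dist)
    S = 0.5 * (S + S.T)  # pdist output is symmetric; guard rounding
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(labels, S, role="gip")


def microbe_functional_similarity(dataset: AssociationDataset,
                                  sds: SimilarityMatrix) -> SimilarityMatrix:
    """Best-match-average functional similarity between microbes.

    For microbes i, j with associated disease sets D_i (size M) and D_j
    (size N), every disease in D_i is matched to its most similar disease
    in D_j and vice versa; the matches are summed and divided by M + N:

        SmF(i, j) = [ sum_{d in D_i} max_{d' in D_j} SdS(d, d')
                    + sum_{d' in D_j} max_{d in D_i} SdS(d', d) ] / (M + N)

    Pairs where either set is empty get similarity 0 (no evidence); the
    diagonal is forced to 1.
    """
    if list(sds.labels) != list(dataset.disease_labels):
        raise ValueError("disease labels of the similarity matrix do not match the dataset")
    X = dataset.X
    nd, nm = X.shape
    counts = X.sum(axis=0)  # diseases per microbe

    # best[d, j] = max over d' in D_j of SdS[d, d']  (-1 marks empty sets)
    masked = np.where(X[None, :, :] == 1.0, sds.S[:, :, None], -1.0)
    best = masked.max(axis=1)
    best = np.maximum(best, 0.0)

    # sum over d in D_i of best[d, j]  ->  (X^T @ best)[i, j]
    forward = X.T @ best
    total = forward + forward.T
    denom = counts[:, None] + counts[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        SmF = np.where(denom > 0, total / np.where(denom > 0, denom, 1.0), 0.0)
    empty = counts == 0
    SmF[empty, :] = 0.0
    SmF[:, empty] = 0.0
    SmF = 0.5 * (SmF + SmF.T)
    np.fill_diagonal(SmF, 1.0)
    SmF = np.clip(SmF, 0.0, 1.0)
    return SimilarityMatrix(dataset.microbe_labels, SmF, role="functional")


def integrate(primary: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Conditionally fuse a primary similarity with its GIP counterpart.

    Entrywise: mean of the two where the primary entry is nonzero (exact
    zero test — zeros are structural absence of evidence), the GIP value
    elsewhere.
    """
    if list(primary.labels) != list(gip.labels):
        raise ValueError("cannot integrate similarity matrices with different labels")
    S = np.where(primary.S != 0.0, 0.5 * (primary.S + gip.S), gip.S)
    S = 0.5 * (S + S.T)
    return SimilarityMatrix(primary.labels, S, role="integrated")


def integrated_similarities(dataset: AssociationDataset, sds: SimilarityMatrix,
                            sigma_prime: float = 1.0,
                            use_functional: bool = True,
                            ) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Full similarity stage: (integrated disease Sd, integrated microbe Sm).

    Disease side fuses the symptom similarity with the disease GIP kernel;
    microbe side fuses the best-match-average functional similarity with
    the microbe GIP kernel.  With ``use_functional=False`` the microbe
    side is the GIP kernel alone (ablation variant).
    """
    sdg = gip_kernel(dataset, "disease", sigma_prime)
    smg = gip_kernel(dataset, "microbe", sigma_prime)
    sd = integrate(sds, sdg)
    if use_functional:
        smf = microbe_functional_similarity(dataset, sds)
        sm = integrate(smf, smg)
    else:
        sm = SimilarityMatrix(smg.labels, smg.S.copy(), role="integrated")
    return sd, sm
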