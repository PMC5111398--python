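"""Community-level statistics for comparing sample x species data sets.

* Jaccard dissimilarities: binary (1 - |A∩B|/|A∪B|) and quantitative
  (Ružička, ``2B/(1+B)`` over Bray-Curtis ``B``) — the classical behaviour of
  the community-ecology ``vegdist`` routine.
* Non-metric multidimensional scaling (NMDS) minimising Kruskal stress-1,
  with a metric (PCoA) start plus random restarts.
* Symmetric Procrustes superimposition with a permutation test (protest):
  ``m^2`` from the singular values of the cross-product of the two centred,
  unit-scaled configurations, ``r = sqrt(1 - m^2)``, and an add-one
  permutation p-value.
* Bias-corrected Chao2 incidence-based richness with its matching variance,
  and Welch's t-test on two richness estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "ProcrustesResult",
    "RichnessEstimate",
    "WelchResult",
    "jaccard",
    "nmds",
    "kruskal_stress",
    "procrustes_protest",
    "chao2",
    "welch_from_estimates",
]


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("dissimilarity diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    configuration: np.ndarray
    stress: float
    n_restarts_used: int
    converged: bool
    labels: list[str] | None = None


@dataclass
class ProcrustesResult:
    m_squared: float
    correlation_r: float
    p_value: float
    n_permutations: int


@dataclass
class RichnessEstimate:
    s_obs: int
    q1: int
    q2: int
    m: int
    chao2: float
    se: float


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


# -- dissimilarities ----------------------------------------------------------


def jaccard(matrix: pd.DataFrame, binary: bool) -> DissimilarityMatrix:
    """Pairwise Jaccard dissimilarities between columns (samples).

    ``matrix`` is species x samples with non-negative values.  ``binary=True``
    uses presence sets; ``binary=False`` the quantitative Ružička form
    ``2B/(1+B)`` with ``B = sum|x-y| / sum(x+y)`` (Bray-Curtis).
    """
    vals = matrix.to_numpy(dtype=float).T  # samples x species
    if (vals < 0).any():
        raise ValueError("negative abundances")
    empty = np.nonzero(vals.sum(axis=1) == 0)[0]
    if empty.size:
        raise ValueError(f"sample(s) with all-zero abundances: "
                         f"{[matrix.columns[i] for i in empty]}")
    if binary:
        pres = vals > 0
        inter = (pres[:, None, :] & pres[None, :, :]).sum(axis=2)
        union = (pres[:, None, :] | pres[None, :, :]).sum(axis=2)
        d = 1.0 - inter / union
    else:
        num = np.abs(vals[:, None, :] - vals[None, :, :]).sum(axis=2)
        den = (vals[:, None, :] + vals[None, :, :]).sum(axis=2)
        bc = num / den
        d = 2.0 * bc / (1.0 + bc)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix([str(c) for c in matrix.columns], d)


# -- NMDS ---------------------------------------------------------------------


def kruskal_stress(config: np.ndarray, dissim: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities:
    sqrt(sum (d - dhat)^2 / sum d^2), with disparities dhat from isotonic
    (primary, tie-averaging) regression of configuration distances on the
    dissimilarity ranks."""
    d = pdist(config)
    delta = squareform(np.asarray(dissim, dtype=float), checks=False)
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(delta[order], d[order])
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _pcoa_start(dissim: np.ndarray, k: int) -> np.ndarray:
    n = dissim.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (dissim**2) @ j
    w, v = np.linalg.eigh(g)
    idx = np.argsort(w)[::-1][:k]
    coords = v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
    return coords


def nmds(
    dissimilarity: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | np.random.Generator = 0,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Runs SMACOF with a metric (PCoA) start plus ``n_restarts - 1`` random
    starts, and reports the best configuration (centred) with its stress-1
    recomputed by isotonic regression.  ``converged=False`` (never an
    exception) flags a best run that hit ``max_iter``.
    """
    D = dissimilarity.values
    n = D.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, bool] | None = None
    inits: list[np.ndarray | None] = [_pcoa_start(D, k)]
    inits += [None] * max(0, n_restarts - 1)
    for init in inits:
        if init is None:
            init = rng.normal(size=(n, k))
        X, _, n_iter = smacof(
            D, metric=False, n_components=k, init=init, n_init=1,
            max_iter=max_iter, eps=tol, random_state=0, normalized_stress=True,
            return_n_iter=True,
        )
        s1 = kruskal_stress(X, D)
        if best is None or s1 < best[0]:
            best = (s1, X, n_iter < max_iter)
    stress, X, conv = best
    X = X - X.mean(axis=0)
    return OrdinationResult(X, stress, len(inits), conv, dissimilarity.labels)


# -- Procrustes ---------------------------------------------------------------


def _symmetric_m2(X: np.ndarray, Y: np.ndarray) -> float:
    _, _, disparity = _scipy_procrustes(X, Y)
    return float(disparity)


def procrustes_protest(
    X: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 9_999,
    seed: int | np.random.Generator = 0,
) -> ProcrustesResult:
    """Symmetric Procrustes with a row-permutation test.

    Both configurations are centred and scaled to unit sum of squares; the
    optimal rotation comes from the SVD of the cross-product, giving
    ``m^2 = 1 - (sum singular values)^2`` and ``r = sqrt(1 - m^2)``.  The
    p-value counts permutations of Y's rows whose r meets or exceeds the
    observed one: ``p = (count + 1) / (B + 1)``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[1] > X.shape[0] or Y.shape[1] > Y.shape[0]:
        raise ValueError("more columns than rows")
    for M, name in ((X, "X"), (Y, "Y")):
        if np.linalg.matrix_rank(M - M.mean(axis=0)) < M.shape[1]:
            raise ValueError(f"{name} is rank-deficient after centring")
    m2 = _symmetric_m2(X, Y)
    r_obs = float(np.sqrt(max(0.0, 1.0 - m2)))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(Y.shape[0])
        r_perm = np.sqrt(max(0.0, 1.0 - _symmetric_m2(X, Y[perm])))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return ProcrustesResult(m2, r_obs, float(p), n_permutations)


# -- richness -----------------------------------------------------------------


def chao2(incidence_matrix: pd.DataFrame, variant: str = "bias_corrected") -> RichnessEstimate:
    """Chao2 incidence-based richness from a binary species x sample matrix.

    ``variant='bias_corrected'`` (default):
    ``chao2 = S_obs + ((m-1)/m) q1 (q1-1) / (2 (q2+1))`` with q1/q2 the
    counts of species occurring in exactly one/two samples, and the matching
    incidence-based variance.

    ``variant='classic'`` reproduces the legacy small-sample estimator
    (``q1^2 / (2 q2)`` when duplicates exist) and its variance, as used by
    the classical species-pool extrapolation routines.
    """
    inc = incidence_matrix.to_numpy() > 0
    m = inc.shape[1]
    if m < 2:
        raise ValueError("chao2 needs at least 2 samples")
    occ = inc.sum(axis=1)
    s_obs = int((occ > 0).sum())
    q1 = int((occ == 1).sum())
    q2 = int((occ == 2).sum())
    A = (m - 1) / m
    if variant == "bias_corrected":
        est = s_obs + A * q1 * (q1 - 1) / (2 * (q2 + 1))
        var = (
            A * q1 * (q1 - 1) / (2 * (q2 + 1))
            + A**2 * q1 * (2 * q1 - 1) ** 2 / (4 * (q2 + 1) ** 2)
            + A**2 * q1**2 * q2 * (q1 - 1) ** 2 / (4 * (q2 + 1) ** 4)
        )
    elif variant == "classic":
        if q2 > 0:
            est = s_obs + A * q1 * q1 / (2 * q2)
            aa = q1 / q2
            var = q1 * A * (0.5 + A * (1 + aa / 4) * aa) * aa
        else:
            est = s_obs + A * q1 * (q1 - 1) / 2
            var = A * (A * (q1 * (2 * q1 - 1) ** 2 / 4 - q1**4 / (4 * est if est else 1))
                       + q1 * (q1 - 1) / 2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return RichnessEstimate(s_obs, q1, q2, m, float(est), float(np.sqrt(max(0.0, var))))


def welch_from_estimates(
    est1: float, se1: float, m1: int, est2: float, se2: float, m2: int
) -> WelchResult:
    """Welch's t-test on two estimates with standard errors, using per-group
    degrees of freedom ``m - 1`` (m = number of samples behind each
    estimate)."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    if m1 < 2 or m2 < 2:
        raise ValueError("need m >= 2 per group")
    v1, v2 = se1**2, se2**2
    t = (est1 - est2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (m1 - 1) + v2**2 / (m2 - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)
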