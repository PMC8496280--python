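"""Kinship and narrow-sense heritability by restricted maximum likelihood.

The kinship is the allele-sharing proportion between lines over the
binary marker matrix (pairwise-complete over missing genotypes).  Per
gene, the mixed model y = mu + g + e with g ~ N(0, sg2 * K) and
e ~ N(0, se2 * I) is fitted by profile REML over the variance ratio
lambda = sg2/se2.  One eigendecomposition of K is shared across all
genes and permutations; per phenotype the profile restricted likelihood
is maximized on a log-lambda grid refined by golden-section search,
giving h2 = lambda / (1 + lambda) = sg2 / (sg2 + se2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LAMBDA_LOG10_RANGE = (-5.0, 5.0)
_GRID_SIZE = 101
_GOLDEN_ITERS = 45
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def kinship(alleles: pd.DataFrame, clip_negative: bool = True) -> pd.DataFrame:
    """Line x line allele-sharing kinship from a markers x lines matrix.

    K[i, j] is the mean over pairwise-complete markers of
    1 - |x_i - x_j|; identical lines score 1, fully complementary lines
    0.  Small negative eigenvalues arising from missing-data
    normalization are clipped at zero (with re-symmetrization).
    """
    X = alleles.to_numpy(dtype=float)
    M = ~np.isnan(X)
    X0 = np.where(M, X, 0.0)
    X1 = np.where(M, 1.0 - X, 0.0)
    agree = X0.T @ X0 + X1.T @ X1
    counts = M.T.astype(float) @ M.astype(float)
    if (counts == 0).any():
        ii, jj = np.nonzero(counts == 0)
        pair = (alleles.columns[ii[0]], alleles.columns[jj[0]])
        raise ValueError(f"line pair with no shared non-missing markers, e.g. {pair}")
    K = agree / counts
    K = (K + K.T) / 2.0
    if clip_negative:
        w = np.linalg.eigvalsh(K)
        if w[0] < -1e-10:
            w, U = np.linalg.eigh(K)
            K = (U * np.clip(w, 0.0, None)) @ U.T
            K = (K + K.T) / 2.0
    return pd.DataFrame(K, index=alleles.columns, columns=alleles.columns)


@dataclass
class KinshipEigen:
    """Eigendecomposition of a kinship matrix, shared across REML fits."""

    values: np.ndarray  # ascending eigenvalues, clipped at 0
    vectors: np.ndarray
    lines: list[str]

    @classmethod
    def from_kinship(cls, K: pd.DataFrame) -> "KinshipEigen":
        arr = K.to_numpy(dtype=float)
        w, U = np.linalg.eigh((arr + arr.T) / 2.0)
        if w[0] < -1e-8:
            raise ValueError("kinship matrix is not positive semidefinite; adjust it first")
        return cls(np.clip(w, 0.0, None), U, list(K.columns))


def _profile_negll(lam: np.ndarray, Yt: np.ndarray, xt: np.ndarray, s: np.ndarray) -> np.ndarray:
    """-2 x profile restricted log-likelihood, per (phenotype, lambda) pair.

    ``lam`` has one lambda per phenotype column of the rotated matrix
    ``Yt`` (n x P); ``xt`` is the rotated intercept, ``s`` the kinship
    eigenvalues.  Constants independent of lambda are dropped.
    """
    n, P = Yt.shape
    D = lam[:, None] * s[None, :] + 1.0  # P x n
    invD = 1.0 / D
    a = invD @ (xt * xt)  # P
    b = np.einsum("pn,n,np->p", invD, xt, Yt)
    c = np.einsum("pn,np->p", invD, Yt * Yt)
    rss = np.maximum(c - b * b / a, 1e-300)
    logdet = np.log(D).sum(axis=1)
    return (n - 1) * np.log(rss) + logdet + np.log(a)


def _fit_columns(Yt: np.ndarray, xt: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Profile-REML lambda per column: vectorized grid + golden refinement.

    Returns (lambda, -2 loglik at lambda) arrays of length P.
    """
    n, P = Yt.shape
    lo, hi = LAMBDA_LOG10_RANGE
    grid = np.logspace(lo, hi, _GRID_SIZE)
    nll = np.empty((_GRID_SIZE, P))
    for gi, lam in enumerate(grid):
        nll[gi] = _profile_negll(np.full(P, lam), Yt, xt, s)
    best = np.argmin(nll, axis=0)
    step = (hi - lo) / (_GRID_SIZE - 1)
    left = np.log10(grid[best]) - step
    right = np.log10(grid[best]) + step
    # golden-section on log10(lambda), vectorized across columns
    x1 = right - _INVPHI * (right - left)
    x2 = left + _INVPHI * (right - left)
    f1 = _profile_negll(10.0**x1, Yt, xt, s)
    f2 = _profile_negll(10.0**x2, Yt, xt, s)
    for _ in range(_GOLDEN_ITERS):
        take_left = f1 < f2
        right = np.where(take_left, x2, right)
        left = np.where(take_left, left, x1)
        x1n = right - _INVPHI * (right - left)
        x2n = left + _INVPHI * (right - left)
        # shrinking left keeps old x1 as the new x2; only one fresh point per column
        f_new = _profile_negll(10.0 ** np.where(take_left, x1n, x2n), Yt, xt, s)
        f1, f2 = np.where(take_left, f_new, f2), np.where(take_left, f1, f_new)
        x1, x2 = x1n, x2n
    xbest = np.where(f1 < f2, x1, x2)
    lam = 10.0**xbest
    # keep boundary optima honest: compare against the grid extremes
    lam = np.clip(lam, 10.0**lo, 10.0**hi)
    final = _profile_negll(lam, Yt, xt, s)
    at_edge_lo = nll[0] <= final
    at_edge_hi = nll[-1] <= final
    lam = np.where(at_edge_lo, grid[0], np.where(at_edge_hi, grid[-1], lam))
    final = np.minimum(np.minimum(final, nll[0]), nll[-1])
    return lam, final


def _components(lam: np.ndarray, Yt: np.ndarray, xt: np.ndarray, s: np.ndarray):
    """Variance components (sg2, se2) at given per-column lambda."""
    n, P = Yt.shape
    D = lam[:, None] * s[None, :] + 1.0
    invD = 1.0 / D
    a = invD @ (xt * xt)
    b = np.einsum("pn,n,np->p", invD, xt, Yt)
    c = np.einsum("pn,np->p", invD, Yt * Yt)
    rss = np.maximum(c - b * b / a, 0.0)
    se2 = rss / (n - 1)
    return lam * se2, se2


def estimate_h2_many(
    Y: np.ndarray, eig: KinshipEigen
) -> pd.DataFrame:
    """REML heritability for phenotype columns of ``Y`` (n_lines x P).

    Returns a DataFrame with h2, sigma_g2, sigma_e2, loglik (the profile
    restricted log-likelihood up to an additive constant).  Columns with
    zero variance get h2 = 0 with a warning.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim != 2 or Y.shape[0] != len(eig.lines):
        raise ValueError("Y must be n_lines x P")
    n, P = Y.shape
    var = Y.var(axis=0)
    const = var <= 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant phenotype(s); h2 set to 0")
    Yt = eig.vectors.T @ Y
    xt = eig.vectors.T @ np.ones(n)
    lam, negll = _fit_columns(Yt, xt, eig.values)
    sg2, se2 = _components(lam, Yt, xt, eig.values)
    with np.errstate(invalid="ignore"):
        h2 = np.where(const, 0.0, sg2 / (sg2 + se2))
    sg2 = np.where(const, 0.0, sg2)
    se2 = np.where(const, 0.0, se2)
    return pd.DataFrame(
        {"h2": h2, "sigma_g2": sg2, "sigma_e2": se2, "loglik": -0.5 * negll}
    )


def estimate_h2(y: np.ndarray, eig: KinshipEigen) -> tuple[float, float, float, float]:
    """Single-phenotype REML fit: (h2, sigma_g2, sigma_e2, loglik)."""
    res = estimate_h2_many(np.asarray(y, dtype=float)[:, None], eig)
    r = res.iloc[0]
    return float(r.h2), float(r.sigma_g2), float(r.sigma_e2), float(r.loglik)


def permutation_threshold_rank(n_perm: int, quantile: float) -> int:
    """Rank (1-based, from the top) of the permuted value used as threshold."""
    return max(1, int(np.floor((1.0 - quantile) * n_perm)))


def h2_permutation_threshold(
    y: np.ndarray,
    eig: KinshipEigen,
    n_perm: int,
    rng: np.random.Generator,
    quantile: float = 0.95,
) -> float:
    """Per-gene permutation threshold for h2 significance.

    The phenotype is permuted across lines ``n_perm`` times and refit;
    the threshold is the empirical ``quantile`` of the permuted h2
    values (the 5th largest of 100 at the defaults).  A gene is called
    significant when its observed h2 strictly exceeds the threshold.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20: permutation threshold will be unstable")
    y = np.asarray(y, dtype=float)
    perm = np.stack([y[rng.permutation(len(y))] for _ in range(n_perm)], axis=1)
    res = estimate_h2_many(perm, eig)
    k = permutation_threshold_rank(n_perm, quantile)
    return float(np.sort(res["h2"].to_numpy())[-k])


def heritability_analysis(
    Y: pd.DataFrame,
    eig: KinshipEigen,
    n_perm: int,
    rng: np.random.Generator,
    quantile: float = 0.95,
    batch_genes: int = 64,
) -> pd.DataFrame:
    """h2 + per-gene permutation threshold for a genes x lines matrix.

    ``Y`` rows are genes, columns are lines in ``eig.lines`` order.
    Permutations are batched so the rotated phenotype matrix stays
    small; all randomness comes from ``rng``.
    """
    if list(Y.columns) != eig.lines:
        Y = Y.loc[:, eig.lines]
    arr = Y.to_numpy(dtype=float).T  # lines x genes
    base = estimate_h2_many(arr, eig)
    base.index = Y.index
    n = arr.shape[0]
    k = permutation_threshold_rank(n_perm, quantile)
    thresholds = np.empty(arr.shape[1])
    for lo in range(0, arr.shape[1], batch_genes):
        block = arr[:, lo : lo + batch_genes]
        nb = block.shape[1]
        perms = np.empty((n, nb * n_perm))
        for g in range(nb):
            for b in range(n_perm):
                perms[:, g * n_perm + b] = block[rng.permutation(n), g]
        res = estimate_h2_many(perms, eig)
        h2p = res["h2"].to_numpy().reshape(nb, n_perm)
        thresholds[lo : lo + nb] = np.sort(h2p, axis=1)[:, -k]
    base["threshold"] = thresholds
    base["significant"] = base["h2"] > base["threshold"]
    return base
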