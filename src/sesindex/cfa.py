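"""One-factor confirmatory factor analysis for dichotomous items.

Binary items are modeled as discretized bivariate-normal latent
responses: pairwise tetrachoric correlations are estimated by maximum
likelihood with thresholds fixed at the observed margins, and a single
common factor is fit to the tetrachoric matrix by unweighted least
squares (ULS). Fit indices (CFI, TLI, RMSEA) rescale the ULS discrepancy
by (n - 1) against a zero-correlation baseline; the published criteria
for adequate fit (CFI/TLI > 0.95, RMSEA < 0.06) are bound-type checks,
for which this estimator is population-equivalent to heavier categorical
estimators when the one-factor model holds.

Cronbach's alpha (internal-consistency reliability) is computed on
complete cases from the classical variance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import multivariate_normal, norm

from .dataset import ResponseDataset
from .irt import DegenerateItemError


class UndefinedAlphaError(ValueError):
    """Cronbach's alpha is undefined (zero total-score variance)."""


@dataclass
class FactorSolution:
    items: list[str]
    loadings: np.ndarray          # lambda_j in [-1, 1]
    thresholds: np.ndarray        # probit threshold tau_j from the margin
    converged: bool = True

    @property
    def residual_variances(self) -> np.ndarray:
        return 1.0 - self.loadings**2


@dataclass
class FitIndices:
    chisq: float
    df: int
    baseline_chisq: float
    baseline_df: int
    cfi: float
    tli: float
    rmsea: float
    n: int


# ---------------------------------------------------------------------------
# tetrachoric correlation
# ---------------------------------------------------------------------------

def _quadrant_probs(rho: float, tau1: float, tau2: float) -> np.ndarray:
    """Cell probabilities [p00, p01, p10, p11] of the discretized BVN."""
    p11 = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf(
        [-tau1, -tau2]
    )
    m1 = 1.0 - norm.cdf(tau1)  # P(x1 = 1)
    m2 = 1.0 - norm.cdf(tau2)
    p10 = m1 - p11
    p01 = m2 - p11
    p00 = 1.0 - p11 - p10 - p01
    return np.clip(np.array([p00, p01, p10, p11]), 1e-12, 1.0)


def tetrachoric(counts) -> float:
    """Maximum-likelihood tetrachoric correlation from a 2x2 count table.

    ``counts[i][j]`` is the number of observations with item1 = i and
    item2 = j. A zero cell triggers the standard 0.5 continuity
    correction; a zero margin (constant item) raises
    :class:`DegenerateItemError`.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("counts must be a nonnegative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateItemError("a zero margin makes the tetrachoric undefined")
    if np.any(t == 0):
        t = t + 0.5
    n = t.sum()
    p1 = t[1].sum() / n
    p2 = t[:, 1].sum() / n
    tau1, tau2 = norm.ppf(1.0 - p1), norm.ppf(1.0 - p2)
    obs = np.array([t[0, 0], t[0, 1], t[1, 0], t[1, 1]])

    def nll(rho: float) -> float:
        return -float(obs @ np.log(_quadrant_probs(rho, tau1, tau2)))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def tetrachoric_matrix(
    data: ResponseDataset, items: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pairwise-complete tetrachoric matrix, margin thresholds, and the
    median pairwise sample size used for fit-index rescaling."""
    items = list(items or data.items)
    X = data.item_matrix(items)
    O = ~np.isnan(X)
    J = len(items)
    for j in range(J):
        obs = X[O[:, j], j]
        if obs.size == 0 or obs.min() == obs.max():
            raise DegenerateItemError(f"item {items[j]!r} is constant")
    taus = np.array([norm.ppf(1.0 - X[O[:, j], j].mean()) for j in range(J)])
    R = np.eye(J)
    counts = []
    for i in range(J):
        for j in range(i + 1, J):
            both = O[:, i] & O[:, j]
            xi, xj = X[both, i].astype(int), X[both, j].astype(int)
            table = np.bincount(2 * xi + xj, minlength=4).reshape(2, 2)
            R[i, j] = R[j, i] = tetrachoric(table)
            counts.append(both.sum())
    return R, taus, int(np.median(counts))


# ---------------------------------------------------------------------------
# one-factor model
# ---------------------------------------------------------------------------

def _uls_loadings(R: np.ndarray) -> tuple[np.ndarray, bool]:
    J = R.shape[0]
    iu = np.triu_indices(J, 1)

    def objective(lam: np.ndarray) -> tuple[float, np.ndarray]:
        res = R[iu] - (np.outer(lam, lam))[iu]
        resid_full = R - np.outer(lam, lam)
        np.fill_diagonal(resid_full, 0.0)
        grad = -2.0 * resid_full @ lam
        return float(res @ res), grad

    evals, evecs = np.linalg.eigh(R)
    lam0 = np.clip(evecs[:, -1] * np.sqrt(max(evals[-1], 0.0)), -0.95, 0.95)
    if lam0.sum() < 0:
        lam0 = -lam0
    res = optimize.minimize(objective, lam0, jac=True, method="L-BFGS-B",
                            bounds=[(-0.999, 0.999)] * J,
                            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 1000})
    lam = res.x
    if np.sum(lam > 0) < np.sum(lam < 0):  # majority-positive sign convention
        lam = -lam
    return lam, bool(res.success)


def _fit_indices(R: np.ndarray, lam: np.ndarray, n: int) -> FitIndices:
    J = R.shape[0]
    iu = np.triu_indices(J, 1)
    resid = R[iu] - np.outer(lam, lam)[iu]
    T = (n - 1) * float(resid @ resid)
    Tb = (n - 1) * float(R[iu] @ R[iu])
    df = J * (J - 1) // 2 - J
    dfb = J * (J - 1) // 2
    num = max(T - df, 0.0)
    den = max(Tb - dfb, T - df, 1e-12)
    cfi = float(np.clip(1.0 - num / den, 0.0, 1.0))
    if Tb / dfb > 1.0:
        tli = ((Tb / dfb) - (T / df)) / ((Tb / dfb) - 1.0)
    else:
        tli = 1.0
    tli = float(np.clip(tli, 0.0, 1.0))
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * max(n - 1, 1))))
    return FitIndices(T, df, Tb, dfb, cfi, tli, rmsea, n)


def fit_one_factor_corr(
    R: np.ndarray, n: int, items: list[str] | None = None,
    thresholds: np.ndarray | None = None,
) -> tuple[FactorSolution, FitIndices]:
    """Fit the one-factor model to a given correlation matrix."""
    R = np.asarray(R, dtype=float)
    J = R.shape[0]
    if J < 4:
        raise ValueError("one-factor fit needs at least 4 items (df > 0)")
    lam, ok = _uls_loadings(R)
    items = list(items or [f"item{j}" for j in range(J)])
    taus = thresholds if thresholds is not None else np.full(J, np.nan)
    return FactorSolution(items, lam, taus, ok), _fit_indices(R, lam, n)


def fit_one_factor(
    data: ResponseDataset, items: list[str] | None = None
) -> tuple[FactorSolution, FitIndices]:
    """One-factor CFA of dichotomous items via tetrachorics and ULS."""
    items = list(items or data.items)
    R, taus, n = tetrachoric_matrix(data, items)
    return fit_one_factor_corr(R, n, items, taus)


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(data: ResponseDataset | np.ndarray, items: list[str] | None = None) -> float:
    """Cronbach's alpha on complete cases.

    alpha = J/(J-1) * (1 - sum of item variances / variance of the sum).
    """
    if isinstance(data, ResponseDataset):
        X = data.item_matrix(items)
    else:
        X = np.asarray(data, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, J = X.shape
    if J < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 2:
        raise ValueError("alpha needs at least 2 complete cases")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedAlphaError("total-score variance is zero")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(J / (J - 1) * (1.0 - item_var / total_var))
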