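"""Two-parameter logistic (2PL) IRT engine.

Implements the dichotomous 2PL model

    P(x_j = 1 | theta) = 1 / (1 + exp(-a_j (theta - b_j)))

with marginal-maximum-likelihood estimation by the EM algorithm of
Bock-Aitkin type over a fixed quadrature grid, pattern-based expected a
posteriori (EAP) scoring, the Lord-Wingersky recursion for sum-score
distributions, and sum-score -> EAP conversion tables.

The slope ``a`` (discrimination) measures how strongly an item separates
respondents along the latent trait; the threshold ``b`` is the trait
level at which endorsement probability reaches 50%. The logistic metric
is used without the historical 1.7 scaling constant; conversions to and
from normal-ogive factor loadings (``slope_to_loading``) apply the 1.7
approximation explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .dataset import ResponseDataset

#: default quadrature: equally spaced nodes spanning [-6, 6]
GRID_POINTS = 49
GRID_SPAN = (-6.0, 6.0)

#: guards against divergence of near-constant items
MAX_SLOPE = 10.0
MAX_THRESHOLD = 8.0
MIN_SLOPE = 1e-3

#: scaling constant of the normal-ogive approximation
D_SCALING = 1.7


class DegenerateItemError(ValueError):
    """An item with zero observed variance cannot be calibrated."""


class UnscorableError(ValueError):
    """A respondent with no observed items cannot be scored."""


@dataclass
class ItemParameters:
    """2PL parameters for one item; ``group`` is 'anchor' or a site label."""

    item: str
    a: float
    b: float
    group: str = "anchor"


@dataclass
class QuadratureGrid:
    """Latent-trait quadrature nodes and (normalized) prior weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("quadrature nodes must be strictly increasing")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("quadrature weights must be nonnegative and sum to 1")

    @classmethod
    def normal(
        cls,
        mean: float = 0.0,
        sd: float = 1.0,
        n_points: int = GRID_POINTS,
        span: tuple[float, float] = GRID_SPAN,
    ) -> "QuadratureGrid":
        """Equally spaced grid with renormalized normal prior mass."""
        nodes = np.linspace(span[0], span[1], n_points)
        w = norm.pdf(nodes, loc=mean, scale=sd)
        return cls(nodes, w / w.sum())

    def reweight(self, mean: float, sd: float) -> "QuadratureGrid":
        """Same nodes, normal prior with new mean/sd."""
        w = norm.pdf(self.nodes, loc=mean, scale=sd)
        return QuadratureGrid(self.nodes, w / w.sum())


@dataclass
class Fit2PLResult:
    params: list[ItemParameters]
    loglik: float
    n_cycles: int
    converged: bool
    loglik_history: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------

def icc(a: float, b: float, theta) -> np.ndarray | float:
    """Item characteristic curve: endorsement probability at ``theta``."""
    return expit(a * (np.asarray(theta, dtype=float) - b))


def slope_to_loading(a: float) -> float:
    """Normal-ogive factor loading implied by a logistic slope (1.7 approx.)."""
    s = a / D_SCALING
    return s / np.sqrt(1.0 + s * s)


def loading_to_slope(lam: float) -> float:
    """Logistic slope implied by a normal-ogive loading (1.7 approx.)."""
    return D_SCALING * lam / np.sqrt(1.0 - lam * lam)


def _prob_matrix(params: list[ItemParameters], grid: QuadratureGrid) -> np.ndarray:
    """J x Q endorsement probabilities, clipped away from 0/1."""
    a = np.array([p.a for p in params])
    b = np.array([p.b for p in params])
    P = expit(a[:, None] * (grid.nodes[None, :] - b[:, None]))
    return np.clip(P, 1e-12, 1.0 - 1e-12)


def _pattern_logliks(X: np.ndarray, O: np.ndarray, P: np.ndarray) -> np.ndarray:
    """n x Q log-likelihood of each response row at each node (missing skipped)."""
    X0 = np.where(O, X, 0.0)
    return X0 @ np.log(P) + (O - X0) @ np.log1p(-P)


def _posteriors(
    X: np.ndarray, O: np.ndarray, P: np.ndarray, grid: QuadratureGrid
) -> tuple[np.ndarray, float]:
    """Posterior node weights per respondent and the marginal log-likelihood."""
    logjoint = _pattern_logliks(X, O, P) + np.log(grid.weights)[None, :]
    lse = logsumexp(logjoint, axis=1)
    post = np.exp(logjoint - lse[:, None])
    return post, float(lse.sum())


def marginal_loglik(
    params: list[ItemParameters], data: ResponseDataset, grid: QuadratureGrid
) -> float:
    """Marginal log-likelihood of a dataset under fixed item parameters."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    items = [p.item for p in params]
    X = data.item_matrix(items)
    O = ~np.isnan(X)
    _, ll = _posteriors(X, O, _prob_matrix(params, grid), grid)
    return ll


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------

def _item_objective(c: float, a: float, theta: np.ndarray, r: np.ndarray, n: np.ndarray) -> float:
    eta = c + a * theta
    return float(np.sum(r * eta - n * np.logaddexp(0.0, eta)))


def _project(c: float, a: float) -> tuple[float, float]:
    a = float(np.clip(a, MIN_SLOPE, MAX_SLOPE))
    c = float(np.clip(c, -MAX_THRESHOLD * a, MAX_THRESHOLD * a))
    return c, a


def _mstep_item(
    theta: np.ndarray, r: np.ndarray, n: np.ndarray, a0: float, b0: float,
    max_newton: int = 25,
) -> tuple[float, float]:
    """Maximize the expected complete-data log-likelihood for one item.

    Works in the slope-intercept parametrization (logit P = c + a*theta),
    where the objective is concave; projected Newton steps with
    step-halving guarantee no decrease, so the surrounding EM cycle is
    monotone. Returns (a, b).
    """
    c, a = _project(-a0 * b0, a0)
    f = _item_objective(c, a, theta, r, n)
    for _ in range(max_newton):
        P = expit(c + a * theta)
        w = n * P * (1.0 - P)
        resid = r - n * P
        g = np.array([resid.sum(), (theta * resid).sum()])
        h11, h12, h22 = w.sum(), (theta * w).sum(), (theta**2 * w).sum()
        det = h11 * h22 - h12 * h12
        if det <= 1e-12 or h11 <= 1e-12:
            break
        dc = (h22 * g[0] - h12 * g[1]) / det
        da = (h11 * g[1] - h12 * g[0]) / det
        step = 1.0
        improved = False
        for _ in range(30):
            c_new, a_new = _project(c + step * dc, a + step * da)
            f_new = _item_objective(c_new, a_new, theta, r, n)
            if f_new >= f - 1e-12:
                improved = f_new > f + 1e-10
                c, a, f = c_new, a_new, f_new
                break
            step *= 0.5
        if not improved:
            break
    return a, -c / a


def _check_items(X: np.ndarray, O: np.ndarray, items: list[str]) -> None:
    for j, name in enumerate(items):
        obs = X[O[:, j], j]
        if obs.size == 0 or obs.min() == obs.max():
            raise DegenerateItemError(
                f"item {name!r} has zero observed variance; cannot calibrate"
            )


def _start_values(X: np.ndarray, O: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.array([X[O[:, j], j].mean() for j in range(X.shape[1])])
    p = np.clip(p, 1e-3, 1 - 1e-3)
    return np.ones_like(p), -np.log(p / (1 - p))


def fit_2pl(
    data: ResponseDataset,
    grid: QuadratureGrid | None = None,
    *,
    items: list[str] | None = None,
    max_cycles: int = 500,
    tol: float = 1e-4,
) -> Fit2PLResult:
    """Marginal-maximum-likelihood 2PL calibration by EM.

    The latent prior is the (fixed) grid weighting. The marginal
    log-likelihood is non-decreasing across cycles; convergence is
    declared when the largest absolute parameter change falls below
    ``tol``. Non-convergence is reported via the ``converged`` flag,
    never silently.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    grid = grid or QuadratureGrid.normal()
    items = list(items or data.items)
    X = data.item_matrix(items)
    O = ~np.isnan(X)
    _check_items(X, O, items)

    warnings: list[str] = []
    if len(data) < 200:
        warnings.append(f"n={len(data)} is below the recommended minimum of 200")

    a, b = _start_values(X, O)
    params = [ItemParameters(it, ai, bi) for it, ai, bi in zip(items, a, b)]
    X0 = np.where(O, X, 0.0)
    history: list[float] = []
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        P = _prob_matrix(params, grid)
        post, ll = _posteriors(X, O, P, grid)
        history.append(ll)
        r = X0.T @ post
        nn = O.T.astype(float) @ post
        max_change = 0.0
        for j, prm in enumerate(params):
            a_new, b_new = _mstep_item(grid.nodes, r[j], nn[j], prm.a, prm.b)
            max_change = max(max_change, abs(a_new - prm.a), abs(b_new - prm.b))
            prm.a, prm.b = a_new, b_new
        if sum(p.a for p in params) < 0:  # reflect the latent axis
            for prm in params:
                prm.a, prm.b = -prm.a, -prm.b
        if max_change < tol:
            converged = True
            break
    _, final_ll = _posteriors(X, O, _prob_matrix(params, grid), grid)
    history.append(final_ll)
    if any(p.a >= MAX_SLOPE - 1e-9 or abs(p.b) >= MAX_THRESHOLD - 1e-9 for p in params):
        warnings.append("one or more items hit the slope/threshold guard caps")
    return Fit2PLResult(params, final_ll, cycle, converged, history, warnings)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def eap_patterns(
    params: list[ItemParameters],
    grid: QuadratureGrid,
    X: np.ndarray,
    O: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pattern EAP: posterior mean and SD of theta per row.

    Rows with no observed responses get NaN in both outputs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    O = ~np.isnan(X) if O is None else np.atleast_2d(O)
    P = _prob_matrix(params, grid)
    post, _ = _posteriors(X, O, P, grid)
    eap = post @ grid.nodes
    var = post @ grid.nodes**2 - eap**2
    sd = np.sqrt(np.maximum(var, 0.0))
    none_observed = ~O.any(axis=1)
    eap[none_observed] = np.nan
    sd[none_observed] = np.nan
    return eap, sd


def eap_pattern(
    params: list[ItemParameters], grid: QuadratureGrid, response
) -> tuple[float, float]:
    """EAP estimate and posterior SD for a single response pattern.

    Missing items (NaN) are skipped; a fully missing pattern raises
    :class:`UnscorableError`.
    """
    resp = np.asarray(response, dtype=float)
    if np.all(np.isnan(resp)):
        raise UnscorableError("all items missing; pattern cannot be scored")
    eap, sd = eap_patterns(params, grid, resp[None, :])
    return float(eap[0]), float(sd[0])


def sum_score_distribution(
    params: list[ItemParameters], grid: QuadratureGrid
) -> np.ndarray:
    """Lord-Wingersky recursion: L[s, q] = P(S = s | theta_q).

    Items are folded in one at a time; each column sums to 1 exactly (up
    to float error), avoiding 2^J pattern enumeration.
    """
    if len(params) < 1:
        raise ValueError("need at least one item")
    P = _prob_matrix(params, grid)
    Q = grid.nodes.size
    L = np.zeros((1, Q))
    L[0] = 1.0
    for j in range(P.shape[0]):
        pj = P[j]
        new = np.zeros((L.shape[0] + 1, Q))
        new[:-1] += L * (1.0 - pj)
        new[1:] += L * pj
        L = new
    return L


def sum_score_eap_table(
    params: list[ItemParameters], grid: QuadratureGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum-score -> EAP conversion: E[theta | S = s] for s = 0..J.

    Returns ``(eap, sd, marginal)`` arrays of length J+1, where
    ``marginal[s] = P(S = s)`` under the grid prior. Strictly increasing
    in s whenever all slopes are positive.
    """
    L = sum_score_distribution(params, grid)
    joint = L * grid.weights[None, :]
    marginal = joint.sum(axis=1)
    if np.any(marginal <= 0):
        raise FloatingPointError("a sum score has zero marginal probability on the grid")
    eap = joint @ grid.nodes / marginal
    second = joint @ grid.nodes**2 / marginal
    sd = np.sqrt(np.maximum(second - eap**2, 0.0))
    return eap, sd, marginal
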