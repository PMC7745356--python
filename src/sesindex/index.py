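"""Index construction: item selection, cross-site anchoring, concurrent
multi-site 2PL calibration, and 0-100 scoring tables.

The index keeps 10 items per site. Items are screened on one-factor
loading (> 0.4), 2PL slope (> 1.0) and floor/ceiling prevalence; an item
that discriminates well at a site (slope >= 0.9 and loading >= 0.4) is
*anchored* — constrained to a single (a, b) across sites, which links the
sites' latent SES scales — while poorly discriminating items get
site-specific parameters. Items that are essentially absent (or
universal) at a site are removed there and substituted from a replacement
pool, mirroring how scarcely owned assets are handled in multi-country
asset indices.

Calibration is concurrent marginal-maximum-likelihood EM over all sites:
anchor items share parameters, site-specific items are free per site, the
reference site's latent distribution is fixed standard normal and the
other sites' normal means/SDs are estimated. Each site's sum-score -> EAP
conversion (Lord-Wingersky recursion under the site's estimated latent
distribution) is then linearly rescaled so a sum score of 0 maps to 0.00
and the maximum to 100.00.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import ResponseDataset
from .irt import (
    DegenerateItemError,
    ItemParameters,
    QuadratureGrid,
    _mstep_item,
    _posteriors,
    _prob_matrix,
    sum_score_eap_table,
)

#: the ten standard index items (all sites except substitutions)
STANDARD_ITEMS = [
    "finished_floor",
    "flush_toilet",
    "lpg_electricity_fuel",
    "improved_water",
    "electricity",
    "television",
    "refrigerator",
    "smart_phone",
    "car",
    "motorbike",
]

#: lower-SES items available to replace locally absent/universal items
REPLACEMENT_POOL = ["bicycle", "more_than_one_room"]

REFERENCE_TABLE_RESOURCE = "reference_scoring_table.csv"


class IncompleteStatsError(ValueError):
    """A screening statistic required by the rules is missing."""


class DesignError(ValueError):
    """A site cannot be given the required number of usable items."""


class ScoringError(ValueError):
    """A scoring table is degenerate (no information in the item set)."""


@dataclass
class SelectionCriteria:
    """Thresholds of the item-selection and anchoring rules.

    ``min_loading``/``min_slope`` are the keep criteria (strict: loading
    > 0.4, slope > 1.0); an item falls back to site-specific parameters
    where its slope < ``anchor_slope`` or loading < ``anchor_loading``.
    ``floor``/``ceiling`` bound acceptable prevalence for screening;
    ``substitution_floor``/``ceiling`` are the stricter essentially-
    absent/universal bounds that trigger per-site removal+substitution.
    """

    min_loading: float = 0.4
    min_slope: float = 1.0
    anchor_slope: float = 0.9
    anchor_loading: float = 0.4
    floor: float = 0.01
    ceiling: float = 0.99
    substitution_floor: float = 0.001
    substitution_ceiling: float = 0.999

    def __post_init__(self) -> None:
        for name in ("min_loading", "min_slope", "anchor_slope", "anchor_loading",
                     "floor", "ceiling"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.floor >= self.ceiling:
            raise ValueError("floor bound must be below ceiling bound")


@dataclass
class ItemStats:
    """Per-item screening statistics (loading/slope may be unavailable
    for floor/ceiling items, where they are not estimable)."""

    item: str
    prevalence: float
    loading: float | None = None
    slope: float | None = None


@dataclass
class ScreenDecision:
    item: str
    keep: bool
    reason: str | None = None  # first failing criterion


@dataclass
class IndexDesign:
    """Per-site item lists, anchor/site-specific flags, substitution log."""

    site_items: dict[str, list[str]]
    status: dict[str, dict[str, str]]  # site -> item -> 'anchor' | 'site_specific'
    substitutions: dict[str, list[dict]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def sites(self) -> list[str]:
        return list(self.site_items)

    @property
    def anchor_items(self) -> list[str]:
        out: list[str] = []
        for site in self.site_items:
            for item, st in self.status[site].items():
                if st == "anchor" and item not in out:
                    out.append(item)
        return out

    def common_items(self) -> list[str]:
        sets = [set(v) for v in self.site_items.values()]
        common = set.intersection(*sets)
        return [i for i in self.site_items[self.sites[0]] if i in common]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"site_items": self.site_items, "status": self.status,
             "substitutions": self.substitutions, "warnings": self.warnings},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "IndexDesign":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(raw["site_items"], raw["status"],
                   raw.get("substitutions", {}), raw.get("warnings", []))


# ---------------------------------------------------------------------------
# rule engine
# ---------------------------------------------------------------------------

def screen_items(
    item_stats: dict[str, ItemStats], criteria: SelectionCriteria | None = None
) -> dict[str, ScreenDecision]:
    """Keep/drop each candidate item, recording the first failing rule.

    Rule order: floor prevalence, ceiling prevalence, loading, slope.
    Loading and slope are only required for items inside the prevalence
    bounds (outside them the item is dropped regardless).
    """
    criteria = criteria or SelectionCriteria()
    decisions: dict[str, ScreenDecision] = {}
    for name, st in item_stats.items():
        if st.prevalence is None or np.isnan(st.prevalence):
            raise IncompleteStatsError(f"item {name!r}: prevalence missing")
        if st.prevalence < criteria.floor:
            decisions[name] = ScreenDecision(name, False, "floor")
            continue
        if st.prevalence > criteria.ceiling:
            decisions[name] = ScreenDecision(name, False, "ceiling")
            continue
        if st.loading is None or st.slope is None:
            raise IncompleteStatsError(
                f"item {name!r}: loading/slope missing for a non-degenerate item"
            )
        if st.loading <= criteria.min_loading:
            decisions[name] = ScreenDecision(name, False, f"loading <= {criteria.min_loading}")
            continue
        if st.slope <= criteria.min_slope:
            decisions[name] = ScreenDecision(name, False, f"slope <= {criteria.min_slope}")
            continue
        decisions[name] = ScreenDecision(name, True)
    return decisions


def _is_constant(prev: float) -> bool:
    return prev <= 0.0 or prev >= 1.0


def assign_anchors(
    per_site_stats: dict[str, dict[str, ItemStats]],
    criteria: SelectionCriteria | None = None,
    standard_items: list[str] | None = None,
    replacement_pool: list[str] | None = None,
) -> IndexDesign:
    """Build the per-site index design from per-site item statistics.

    Per site: items essentially absent/universal (prevalence beyond the
    substitution bounds) are removed, most extreme first, and replaced
    from the pool while pool items pass the floor/ceiling screen at that
    site; failing items beyond the pool's capacity are retained with a
    warning. Each surviving item is an anchor unless its site slope or
    loading falls below the anchor thresholds, in which case it gets
    site-specific parameters. Items constant at a site can only be
    anchored (their parameters are then informed by the other sites).
    """
    criteria = criteria or SelectionCriteria()
    standard_items = list(standard_items or STANDARD_ITEMS)
    pool_master = list(replacement_pool or REPLACEMENT_POOL)

    site_items: dict[str, list[str]] = {}
    status: dict[str, dict[str, str]] = {}
    substitutions: dict[str, list[dict]] = {}
    warnings: list[str] = []

    for site, stats in per_site_stats.items():
        for item in standard_items:
            if item not in stats:
                raise IncompleteStatsError(f"site {site!r}: no statistics for {item!r}")
        items = list(standard_items)
        failing = sorted(
            (i for i in items
             if stats[i].prevalence < criteria.substitution_floor
             or stats[i].prevalence > criteria.substitution_ceiling),
            key=lambda i: min(stats[i].prevalence, 1.0 - stats[i].prevalence),
        )
        pool = [
            p for p in pool_master
            if p in stats and p not in items
            and criteria.floor <= stats[p].prevalence <= criteria.ceiling
        ]
        subs: list[dict] = []
        retained_failing: list[str] = []
        for item in failing:
            if not pool:
                retained_failing.append(item)
                if _is_constant(stats[item].prevalence):
                    warnings.append(
                        f"{site}: {item} is constant and could not be substituted; "
                        "retained (excluded from linking)"
                    )
                else:
                    warnings.append(
                        f"{site}: {item} fails the substitution bound but the "
                        "replacement pool is exhausted; retained as site-specific"
                    )
                continue
            replacement = pool.pop(0)
            items.remove(item)
            items.append(replacement)
            subs.append({"removed": item, "added": replacement,
                         "reason": f"prevalence {stats[item].prevalence:.4f}"})
        if len(items) != len(standard_items):
            raise DesignError(
                f"site {site!r} has {len(items)} usable items, "
                f"need {len(standard_items)}"
            )
        if subs:
            substitutions[site] = subs

        status[site] = {}
        for item in items:
            st = stats[item]
            if _is_constant(st.prevalence):
                # a constant column cannot be estimated site-specifically;
                # it keeps the anchor parameters but carries no linking
                # information (calibration drops it from that site's likelihood)
                status[site][item] = "anchor"
                continue
            fails_anchor = (
                st.prevalence < criteria.floor
                or st.prevalence > criteria.ceiling
                or (st.slope is not None and st.slope < criteria.anchor_slope)
                or (st.loading is not None and st.loading < criteria.anchor_loading)
            )
            if (st.slope is None and st.loading is None
                    and criteria.floor <= st.prevalence <= criteria.ceiling):
                warnings.append(
                    f"{site}: {item} has no discrimination statistics; anchored by default"
                )
                fails_anchor = False
            status[site][item] = "site_specific" if fails_anchor else "anchor"
        site_items[site] = items

    design = IndexDesign(site_items, status, substitutions, warnings)
    for site in design.sites:  # every site constant item must be anchorable
        for item in design.site_items[site]:
            if (_is_constant(per_site_stats[site][item].prevalence)
                    and design.status[site][item] != "anchor"):
                raise DesignError(f"constant item {item!r} at {site!r} cannot be site-specific")
    return design


def empirical_site_stats(
    data: ResponseDataset,
    items: list[str] | None = None,
    grid: QuadratureGrid | None = None,
) -> dict[str, dict[str, ItemStats]]:
    """Per-site screening statistics estimated from the data.

    For every site: observed prevalence per candidate item; 2PL slopes
    from a single-site fit and one-factor loadings from a single-site CFA
    over the items that vary at that site. Constant items get prevalence
    only (their discrimination is not estimable there).
    """
    from .cfa import fit_one_factor
    from .irt import fit_2pl

    items = list(items or data.items)
    grid = grid or QuadratureGrid.normal()
    out: dict[str, dict[str, ItemStats]] = {}
    for site in data.sites:
        sub = data.for_site(site)
        prev = sub.prevalences()
        X = sub.item_matrix(items)
        estimable = []
        for j, item in enumerate(items):
            col = X[~np.isnan(X[:, j]), j]
            if col.size and 0.0 < col.mean() < 1.0:
                estimable.append(item)
        slopes: dict[str, float] = {}
        loadings: dict[str, float] = {}
        if len(estimable) >= 2:
            fit = fit_2pl(sub, grid, items=estimable)
            slopes = {p.item: p.a for p in fit.params}
        if len(estimable) >= 4:
            solution, _ = fit_one_factor(sub, estimable)
            loadings = dict(zip(solution.items, solution.loadings))
        out[site] = {
            item: ItemStats(item, float(prev[item]),
                            loadings.get(item), slopes.get(item))
            for item in items
        }
    return out


# ---------------------------------------------------------------------------
# concurrent multi-site calibration
# ---------------------------------------------------------------------------

@dataclass
class MultigroupResult:
    params: dict[str, list[ItemParameters]]  # per site, in design item order
    anchors: dict[str, tuple[float, float]]  # one (a, b) per anchor item
    latent: dict[str, tuple[float, float]]
    loglik: float
    n_cycles: int
    converged: bool
    loglik_history: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_json(cls, path, design: IndexDesign) -> "MultigroupResult":
        """Rebuild a calibration result from its serialized parameters."""
        with open(path) as fh:
            raw = json.load(fh)
        anchors = {i: (v["a"], v["b"]) for i, v in raw["anchors"].items()}
        params: dict[str, list[ItemParameters]] = {}
        for site in design.sites:
            plist = []
            for item in design.site_items[site]:
                if design.status[site][item] == "anchor":
                    a, b = anchors[item]
                    plist.append(ItemParameters(item, a, b, "anchor"))
                else:
                    v = raw["site_specific"][site][item]
                    plist.append(ItemParameters(item, v["a"], v["b"], site))
            params[site] = plist
        latent = {s: (v["mean"], v["sd"]) for s, v in raw["latent"].items()}
        return cls(params, anchors, latent, raw.get("loglik", float("nan")), 0,
                   raw.get("converged", True))

    def to_json(self, path=None) -> str:
        site_specific: dict[str, dict] = {}
        for site, plist in self.params.items():
            for p in plist:
                if p.group != "anchor":
                    site_specific.setdefault(site, {})[p.item] = {"a": p.a, "b": p.b}
        payload = json.dumps(
            {
                "anchors": {i: {"a": a, "b": b} for i, (a, b) in self.anchors.items()},
                "site_specific": site_specific,
                "latent": {s: {"mean": m, "sd": sd} for s, (m, sd) in self.latent.items()},
                "loglik": self.loglik,
                "converged": self.converged,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _latent_objective(m: np.ndarray, nodes: np.ndarray, mu: float, sd: float) -> float:
    """Expected complete-data contribution of one group's latent prior."""
    logw = norm.logpdf(nodes, mu, sd)
    logw -= np.log(np.exp(logw - logw.max()).sum()) + logw.max()
    return float(m @ logw)


def _update_latent(
    m: np.ndarray, nodes: np.ndarray, mu: float, sd: float
) -> tuple[float, float]:
    """Monotone update of a group's latent normal (mean, sd).

    The moment update is exact up to grid renormalization; it is accepted
    only if it does not decrease the expected prior term, otherwise a
    direct search from the current value is used.
    """
    n = m.sum()
    mu_new = float(m @ nodes / n)
    sd_new = float(np.sqrt(max(m @ nodes**2 / n - mu_new**2, 1e-4)))
    f0 = _latent_objective(m, nodes, mu, sd)
    if _latent_objective(m, nodes, mu_new, sd_new) >= f0 - 1e-10:
        return mu_new, sd_new
    from scipy.optimize import minimize

    res = minimize(
        lambda x: -_latent_objective(m, nodes, x[0], max(x[1], 1e-2)),
        np.array([mu, sd]), method="Nelder-Mead",
    )
    if -res.fun > f0:
        return float(res.x[0]), float(max(res.x[1], 1e-2))
    return mu, sd


def multigroup_calibrate(
    data: ResponseDataset,
    design: IndexDesign,
    grid: QuadratureGrid | None = None,
    *,
    reference_site: str | None = None,
    max_cycles: int = 500,
    tol: float = 1e-4,
) -> MultigroupResult:
    """Concurrent EM calibration across sites with anchor constraints.

    Anchor items share one (a, b) estimated from all sites whose design
    includes them; site-specific items are free per site. The reference
    site's latent distribution is fixed N(0, 1); other sites' normal
    means/SDs are estimated. The pooled marginal log-likelihood is
    non-decreasing across cycles.
    """
    grid = grid or QuadratureGrid.normal()
    sites = design.sites
    reference_site = reference_site or sites[0]
    if reference_site not in sites:
        raise ValueError(f"reference site {reference_site!r} not in design")

    X: dict[str, np.ndarray] = {}
    O: dict[str, np.ndarray] = {}
    warnings: list[str] = []
    for site in sites:
        sub = data.for_site(site)
        items = design.site_items[site]
        X[site] = sub.item_matrix(items)
        O[site] = ~np.isnan(X[site])
        if O[site].all(axis=1).sum() < 200:
            warnings.append(f"site {site}: fewer than 200 complete responses")
        for j, item in enumerate(items):
            obs = X[site][O[site][:, j], j]
            constant = obs.size == 0 or obs.min() == obs.max()
            if constant and design.status[site][item] == "site_specific":
                raise DegenerateItemError(
                    f"site {site}: site-specific item {item!r} has zero variance"
                )
            if constant:
                # no within-site information; forcing the anchor likelihood
                # onto a constant column would only distort the group mean
                O[site][:, j] = False
                warnings.append(
                    f"site {site}: constant anchor item {item!r} excluded "
                    "from the site likelihood"
                )

    # initial values: unit slopes, thresholds from (pooled) logits
    anchors: dict[str, list[float]] = {}
    site_params: dict[str, dict[str, list[float]]] = {s: {} for s in sites}
    for item in design.anchor_items:
        num = den = 0.0
        for site in sites:
            if item in design.site_items[site] and design.status[site][item] == "anchor":
                j = design.site_items[site].index(item)
                num += X[site][O[site][:, j], j].sum()
                den += O[site][:, j].sum()
        if den == 0:
            raise DegenerateItemError(
                f"anchor item {item!r} has no usable observations in any site"
            )
        p = np.clip(num / den, 1e-3, 1 - 1e-3)
        anchors[item] = [1.0, float(-np.log(p / (1 - p)))]
    for site in sites:
        for j, item in enumerate(design.site_items[site]):
            if design.status[site][item] == "site_specific":
                p = np.clip(np.nanmean(X[site][:, j]), 1e-3, 1 - 1e-3)
                site_params[site][item] = [1.0, float(-np.log(p / (1 - p)))]

    latent = {s: [0.0, 1.0] for s in sites}

    def site_param_list(site: str) -> list[ItemParameters]:
        out = []
        for item in design.site_items[site]:
            if design.status[site][item] == "anchor":
                a, b = anchors[item]
                out.append(ItemParameters(item, a, b, "anchor"))
            else:
                a, b = site_params[site][item]
                out.append(ItemParameters(item, a, b, site))
        return out

    history: list[float] = []
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        total_ll = 0.0
        r_anchor = {i: np.zeros(grid.nodes.size) for i in anchors}
        n_anchor = {i: np.zeros(grid.nodes.size) for i in anchors}
        rn_site: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {s: {} for s in sites}
        post_mass: dict[str, np.ndarray] = {}
        for site in sites:
            plist = site_param_list(site)
            P = _prob_matrix(plist, grid)
            g = grid.reweight(*latent[site])
            post, ll = _posteriors(X[site], O[site], P, g)
            total_ll += ll
            X0 = np.where(O[site], X[site], 0.0)
            r = X0.T @ post
            nn = O[site].T.astype(float) @ post
            for j, item in enumerate(design.site_items[site]):
                if design.status[site][item] == "anchor":
                    r_anchor[item] += r[j]
                    n_anchor[item] += nn[j]
                else:
                    rn_site[site][item] = (r[j], nn[j])
            post_mass[site] = post.sum(axis=0)
        history.append(total_ll)

        max_change = 0.0
        for item, (a0, b0) in anchors.items():
            a, b = _mstep_item(grid.nodes, r_anchor[item], n_anchor[item], a0, b0)
            max_change = max(max_change, abs(a - a0), abs(b - b0))
            anchors[item] = [a, b]
        for site in sites:
            for item, (r, nn) in rn_site[site].items():
                a0, b0 = site_params[site][item]
                a, b = _mstep_item(grid.nodes, r, nn, a0, b0)
                max_change = max(max_change, abs(a - a0), abs(b - b0))
                site_params[site][item] = [a, b]
            if site != reference_site:
                mu0, sd0 = latent[site]
                mu, sd = _update_latent(post_mass[site], grid.nodes, mu0, sd0)
                max_change = max(max_change, abs(mu - mu0), abs(sd - sd0))
                latent[site] = [mu, sd]
        if max_change < tol:
            converged = True
            break

    total_ll = 0.0
    for site in sites:
        plist = site_param_list(site)
        g = grid.reweight(*latent[site])
        _, ll = _posteriors(X[site], O[site], _prob_matrix(plist, grid), g)
        total_ll += ll
    history.append(total_ll)

    return MultigroupResult(
        params={s: site_param_list(s) for s in sites},
        anchors={i: (a, b) for i, (a, b) in anchors.items()},
        latent={s: (m, sd) for s, (m, sd) in latent.items()},
        loglik=total_ll,
        n_cycles=cycle,
        converged=converged,
        loglik_history=history,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# scoring tables
# ---------------------------------------------------------------------------

@dataclass
class ScoringTable:
    """Per-site sum-score -> SES-score lookup (the published-table shape).

    ``scores[site][s]`` is the 0-100 SES score for sum score s, kept at
    full precision internally and rounded to 2 decimals on export.
    """

    site_items: dict[str, list[str]]
    scores: dict[str, np.ndarray]
    eap: dict[str, np.ndarray] | None = None

    @property
    def sites(self) -> list[str]:
        return list(self.scores)

    @property
    def max_score(self) -> int:
        return len(next(iter(self.scores.values()))) - 1

    def lookup(self, site: str, s: int) -> float:
        if site not in self.scores:
            raise KeyError(f"unknown site {site!r}")
        return float(self.scores[site][int(s)])

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        frame = pd.DataFrame(
            {site: np.round(vals, ndigits) for site, vals in self.scores.items()}
        )
        frame.insert(0, "sum_score", np.arange(self.max_score + 1))
        return frame

    def to_csv(self, path, ndigits: int = 2) -> None:
        self.to_frame(ndigits).to_csv(path, index=False, float_format=f"%.{ndigits}f")

    @classmethod
    def from_csv(cls, path, site_items: dict[str, list[str]]) -> "ScoringTable":
        frame = pd.read_csv(path).sort_values("sum_score")
        scores = {c: frame[c].to_numpy(dtype=float) for c in frame.columns if c != "sum_score"}
        return cls(site_items, scores)


def build_scoring_tables(
    result: MultigroupResult,
    grid: QuadratureGrid | None = None,
    design: IndexDesign | None = None,
) -> ScoringTable:
    """Sum-score EAP tables per site, rescaled to 0-100 endpoints.

    Each site's EAPs are computed under that site's estimated latent
    distribution with that site's item parameters, then mapped through
    score(s) = 100 * (EAP(s) - EAP(0)) / (EAP(J) - EAP(0)).
    """
    grid = grid or QuadratureGrid.normal()
    site_items = {s: [p.item for p in plist] for s, plist in result.params.items()}
    scores: dict[str, np.ndarray] = {}
    eaps: dict[str, np.ndarray] = {}
    for site, plist in result.params.items():
        g = grid.reweight(*result.latent[site])
        eap, _, _ = sum_score_eap_table(plist, g)
        span = eap[-1] - eap[0]
        if span <= 1e-9:
            raise ScoringError(f"site {site}: degenerate item set (EAP span is zero)")
        scores[site] = 100.0 * (eap - eap[0]) / span
        eaps[site] = eap
    return ScoringTable(site_items, scores, eaps)


def reference_scoring_table() -> ScoringTable:
    """The packaged published scoring table with its per-site item lists."""
    drc_items = [
        "finished_floor", "flush_toilet", "improved_water", "more_than_one_room",
        "electricity", "television", "smart_phone", "car", "motorbike", "bicycle",
    ]
    ref = importlib.resources.files("sesindex") / "data" / REFERENCE_TABLE_RESOURCE
    import io

    frame = pd.read_csv(io.StringIO(ref.read_text())).sort_values("sum_score")
    scores = {c: frame[c].to_numpy(dtype=float) for c in frame.columns if c != "sum_score"}
    site_items = {
        site: (drc_items if site == "DRC" else list(STANDARD_ITEMS)) for site in scores
    }
    return ScoringTable(site_items, scores)
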