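"""Synthetic multi-site cohort generator.

Generates dichotomous housing/asset item responses from a one-factor
probit model: each respondent has a latent socioeconomic trait
``theta ~ Normal(mu_g, sigma_g)`` for their site g, each item j a latent
response ``y* = lambda_j * theta + sqrt(1 - lambda_j^2) * eps`` with
standard-normal noise, and the observed indicator is ``y* > tau_j``.
Thresholds are chosen so that each item's within-site endorsement
probability matches a configured target prevalence exactly:

    tau_j = lambda_j * mu_g + sqrt(lambda_j^2 sigma_g^2 + 1 - lambda_j^2)
            * PhiInv(1 - p_j),

which reduces to ``PhiInv(1 - p_j)`` for a standard-normal site. This is
exactly the latent-response model a one-factor CFA of binary items
assumes, so factor-structure recovery can be checked against the
configured loadings.

Covariates (education band, antenatal care, facility delivery) are linked
monotonically to theta so that construct-validity contrasts hold by
construction: education bands via ordered cutpoints on theta plus noise,
the two binary covariates via logistic links.

The packaged default configuration (``data/default_cohort.yaml``)
emulates a 7-site pregnancy-registry cohort: site mix, per-site item
prevalences and one-factor loadings are transcribed from the published
site-level tables of the index-development study.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .dataset import ResponseDataset, EDUCATION_BANDS

DEFAULT_CONFIG_RESOURCE = "default_cohort.yaml"

#: prevalence bounds outside which an item is flagged floor/ceiling
FLOOR = 0.005
CEILING = 0.995


class ConfigError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass
class CovariateLinks:
    """Monotone links from the latent trait to the covariates.

    ``education_cutpoints`` are ordered cutpoints on ``theta + N(0, sd^2)``
    defining the four years-of-education bands; the binary covariates use
    ``P(yes) = sigmoid(intercept + slope * theta)``.
    """

    education_cutpoints: tuple[float, float, float] = (-2.079, -1.0776, 1.3678)
    education_noise_sd: float = 0.8
    antenatal_slope: float = 1.0
    antenatal_intercept: float = 4.876
    facility_slope: float = 1.0
    facility_intercept: float = 0.4581


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic multi-site cohort.

    ``prevalences`` and ``loadings`` are per-site, per-item; ``latent``
    maps each site to its latent trait (mean, sd). ``thresholds`` are
    derived, never set directly. ``flags`` records per-site floor/ceiling
    items (still generated, but marked).
    """

    sites: list[str]
    site_weights: dict[str, float]
    items: list[str]
    prevalences: dict[str, dict[str, float]]
    loadings: dict[str, dict[str, float]]
    latent: dict[str, tuple[float, float]]
    thresholds: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: dict[str, dict[str, str]] = field(default_factory=dict)
    covariate_links: CovariateLinks = field(default_factory=CovariateLinks)
    missing_rate: float = 0.0
    seed: int = 0
    pooled: dict | None = None

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = plain(asdict(self))
        d["latent"] = {
            s: {"mean": float(m), "sd": float(sd)} for s, (m, sd) in self.latent.items()
        }
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _threshold(p: float, lam: float, mu: float, sd: float) -> float:
    """Latent-response threshold matching a target within-site prevalence."""
    if p <= 0.0:
        return np.inf
    if p >= 1.0:
        return -np.inf
    scale = np.sqrt(lam**2 * sd**2 + 1.0 - lam**2)
    return lam * mu + scale * norm.ppf(1.0 - p)


def calibrate_generator(
    prevalences: dict[str, dict[str, float]],
    loadings: dict[str, dict[str, float]],
    site_mix: dict[str, float],
    *,
    latent: dict[str, tuple[float, float]] | None = None,
    covariate_links: CovariateLinks | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    pooled: dict | None = None,
) -> GeneratorConfig:
    """Build a validated :class:`GeneratorConfig` from target quantities.

    Raises :class:`ConfigError` for loadings outside [0, 1), prevalences
    outside [0, 1], or site weights not summing to 1. Items with target
    prevalence outside (0.5%, 99.5%) are flagged floor/ceiling but still
    generated (a target of exactly 0 or 1 yields a constant item).
    """
    sites = list(site_mix)
    total = sum(site_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"site weights sum to {total!r}, expected 1")
    if set(prevalences) != set(sites) or set(loadings) != set(sites):
        raise ConfigError("prevalences/loadings must cover exactly the sites in site_mix")
    items = list(prevalences[sites[0]])
    latent = dict(latent or {s: (0.0, 1.0) for s in sites})
    for s in sites:
        latent.setdefault(s, (0.0, 1.0))

    thresholds: dict[str, dict[str, float]] = {}
    flags: dict[str, dict[str, str]] = {}
    for s in sites:
        mu, sd = latent[s]
        thresholds[s] = {}
        flags[s] = {}
        for j in items:
            p, lam = prevalences[s][j], loadings[s][j]
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"prevalence {p!r} for {s}/{j} outside [0, 1]")
            if not 0.0 <= lam < 1.0:
                raise ConfigError(f"loading {lam!r} for {s}/{j} outside [0, 1)")
            thresholds[s][j] = _threshold(p, lam, mu, sd)
            if p < FLOOR:
                flags[s][j] = "floor"
            elif p > CEILING:
                flags[s][j] = "ceiling"

    return GeneratorConfig(
        sites=sites,
        site_weights=dict(site_mix),
        items=items,
        prevalences={s: dict(prevalences[s]) for s in sites},
        loadings={s: dict(loadings[s]) for s in sites},
        latent=latent,
        thresholds=thresholds,
        flags=flags,
        covariate_links=covariate_links or CovariateLinks(),
        missing_rate=missing_rate,
        seed=seed,
        pooled=pooled,
    )


def load_config(path) -> GeneratorConfig:
    """Load a generator configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _config_from_mapping(raw)


def _config_from_mapping(raw: dict) -> GeneratorConfig:
    if not raw:
        raise ConfigError("empty generator configuration")
    links = raw.get("covariate_links", {})
    cov = CovariateLinks(
        education_cutpoints=tuple(links.get("education_cutpoints", (-2.079, -1.0776, 1.3678))),
        education_noise_sd=float(links.get("education_noise_sd", 0.8)),
        antenatal_slope=float(links.get("antenatal_care", {}).get("slope", 1.0)),
        antenatal_intercept=float(links.get("antenatal_care", {}).get("intercept", 4.876)),
        facility_slope=float(links.get("facility_delivery", {}).get("slope", 1.0)),
        facility_intercept=float(links.get("facility_delivery", {}).get("intercept", 0.4581)),
    )
    latent = {
        s: (float(v["mean"]), float(v["sd"]))
        for s, v in raw.get("latent", {}).items()
    }
    return calibrate_generator(
        raw["prevalences"],
        raw["loadings"],
        raw["site_weights"],
        latent=latent or None,
        covariate_links=cov,
        missing_rate=float(raw.get("missing_rate", 0.0)),
        seed=int(raw.get("seed", 0)),
        pooled=raw.get("pooled"),
    )


def default_config(seed: int | None = None) -> GeneratorConfig:
    """The packaged 7-site calibration (published tables transcription)."""
    ref = importlib.resources.files("sesindex") / "data" / DEFAULT_CONFIG_RESOURCE
    config = _config_from_mapping(yaml.safe_load(ref.read_text()))
    if seed is not None:
        config.seed = seed
    return config


def pooled_config(config: GeneratorConfig, seed: int | None = None) -> GeneratorConfig:
    """Single-group configuration using the pooled prevalences/loadings."""
    if not config.pooled:
        raise ConfigError("configuration carries no pooled calibration")
    return calibrate_generator(
        {"Pooled": config.pooled["prevalences"]},
        {"Pooled": config.pooled["loadings"]},
        {"Pooled": 1.0},
        covariate_links=config.covariate_links,
        seed=config.seed if seed is None else seed,
    )


def simulate_responses(
    config: GeneratorConfig,
    n: int,
    seed: int | None = None,
    *,
    sites: list[str] | None = None,
    covariates: bool = True,
) -> ResponseDataset:
    """Draw ``n`` respondents from the configured one-factor model.

    ``sites`` restricts generation to a subset (weights renormalized);
    identical (config, n, seed) yield identical datasets. The generating
    latent trait is retained in a ``theta`` column.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    use_sites = sites or config.sites
    unknown = set(use_sites) - set(config.sites)
    if unknown:
        raise ConfigError(f"unknown sites requested: {sorted(unknown)}")
    weights = np.array([config.site_weights[s] for s in use_sites], dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    site_idx = rng.choice(len(use_sites), size=n, p=weights)
    mus = np.array([config.latent[s][0] for s in use_sites])
    sds = np.array([config.latent[s][1] for s in use_sites])
    theta = rng.standard_normal(n) * sds[site_idx] + mus[site_idx]

    J = len(config.items)
    lam = np.array([[config.loadings[s][j] for j in config.items] for s in use_sites])
    tau = np.array([[config.thresholds[s][j] for j in config.items] for s in use_sites])
    eps = rng.standard_normal((n, J))
    ystar = lam[site_idx] * theta[:, None] + np.sqrt(1.0 - lam[site_idx] ** 2) * eps
    X = (ystar > tau[site_idx]).astype(float)
    if config.missing_rate > 0:
        X[rng.random((n, J)) < config.missing_rate] = np.nan

    frame = pd.DataFrame(X, columns=config.items)
    frame.insert(0, "site", [use_sites[i] for i in site_idx])
    frame.insert(0, "id", np.arange(1, n + 1))
    frame["theta"] = theta
    if covariates:
        cov = simulate_covariates(config, theta, rng=rng)
        frame = pd.concat([frame, cov], axis=1)
    return ResponseDataset(frame, list(config.items))


def simulate_covariates(
    config: GeneratorConfig,
    thetas: np.ndarray,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Covariates linked monotonically to the latent trait.

    Education bands come from ordered cutpoints on ``theta`` plus normal
    noise; education type is "none" for the lowest band, "formal"
    otherwise; antenatal care and facility delivery are Bernoulli with
    logistic probabilities in ``theta``. Zero slopes are allowed and give
    theta-independent covariates.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    thetas = np.asarray(thetas, dtype=float)
    links = config.covariate_links
    star = thetas + rng.standard_normal(thetas.shape) * links.education_noise_sd
    band_idx = np.searchsorted(np.asarray(links.education_cutpoints), star)
    bands = pd.Categorical.from_codes(band_idx, categories=list(EDUCATION_BANDS))

    def bernoulli(intercept: float, slope: float) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-(intercept + slope * thetas)))
        return (rng.random(thetas.shape) < p).astype(int)

    return pd.DataFrame(
        {
            "education_type": np.where(band_idx == 0, "none", "formal"),
            "education_years_band": bands,
            "antenatal_care": bernoulli(links.antenatal_intercept, links.antenatal_slope),
            "facility_delivery": bernoulli(links.facility_intercept, links.facility_slope),
        }
    )
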