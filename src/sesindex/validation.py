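"""Reliability and construct-validity analyses of the scored index.

Covers: Cronbach's alpha (re-exported from :mod:`sesindex.cfa` — a single
implementation); the Pearson correlation between pattern-based EAP scores
and table-based (sum-score) SES scores, which quantifies how much
information the simplified sum-score route loses; and one-way ANOVA
contrasts of mean SES scores across covariate groups expected to be
ordered by socioeconomic status (education, antenatal care, facility
delivery), computed from first principles with mean-difference
coefficients against a reference category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .cfa import cronbach_alpha  # noqa: F401  (single implementation, re-exported)
from .dataset import ResponseDataset
from .index import MultigroupResult, ScoringTable
from .irt import QuadratureGrid, eap_patterns
from .scoring import score_dataset


class ContrastError(ValueError):
    """A group comparison needs at least two non-empty groups."""


@dataclass
class GroupRow:
    group: str
    n: int
    mean: float
    sd: float
    coefficient: float | None  # mean difference vs reference; None for referent
    se: float | None


@dataclass
class Contrast:
    characteristic: str
    reference: str
    groups: list[GroupRow]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class ValidityReport:
    alpha_pooled: float
    alpha_by_site: dict[str, float]
    pattern_sumscore_r: float
    contrasts: list[Contrast] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_text(self) -> str:
        lines = [
            f"Cronbach's alpha (pooled): {self.alpha_pooled:.3f}",
            f"Pattern-EAP vs sum-score SES correlation: r = {self.pattern_sumscore_r:.3f}",
            "",
        ]
        for c in self.contrasts:
            lines.append(f"{c.characteristic} (F = {c.f_statistic:.1f}, "
                         f"p = {c.p_value:.2g})")
            for g in c.groups:
                coef = "Referent" if g.coefficient is None else (
                    f"{g.coefficient:+.2f} ({g.se:.2f})"
                )
                lines.append(f"  {g.group:>12}: {g.mean:6.2f} ({g.sd:.2f})  {coef}")
            lines.append("")
        return "\n".join(lines)


def pattern_sumscore_correlation(
    result: MultigroupResult,
    table: ScoringTable,
    data: ResponseDataset,
    grid: QuadratureGrid | None = None,
    prior: str = "reference",
) -> float:
    """Pearson r between pattern EAPs and table-based SES scores.

    Pattern EAPs use each respondent's site item parameters on the common
    anchored metric. With ``prior="reference"`` (default) the EAP prior is
    the reference latent distribution for everyone, so pattern scores are
    directly comparable across sites — the same role the 0-100 rescaled
    table scores play; ``prior="site"`` uses each site's estimated latent
    distribution instead. The correlation pools complete responders over
    all sites.
    """
    grid = grid or QuadratureGrid.normal()
    scores = score_dataset(table, data)
    eap_col = np.full(len(data), np.nan)
    for site in data.sites:
        rows = (data.data["site"] == site).to_numpy()
        X = data.data.loc[rows, table.site_items[site]].to_numpy(dtype=float)
        g = grid if prior == "reference" else grid.reweight(*result.latent[site])
        eap, _ = eap_patterns(result.params[site], g, X)
        eap_col[rows] = eap
    ok = ~scores["unscorable"].to_numpy() & ~np.isnan(eap_col)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete responders")
    x = eap_col[ok]
    y = scores.loc[ok, "ses_score"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the score vectors")
    return float(np.corrcoef(x, y)[0, 1])


def group_comparison(
    scores: pd.DataFrame,
    grouping: pd.Series | np.ndarray,
    reference: str,
    characteristic: str = "group",
) -> Contrast:
    """Classical one-way ANOVA of SES scores across covariate groups.

    Computes between/within sums of squares, the F statistic and its
    p-value, per-group means/SDs, and mean differences against the
    reference group with pooled-variance standard errors. Complete
    separation (zero within-group variance) yields an infinite F, handled
    without error.
    """
    grouping = pd.Series(np.asarray(grouping, dtype=object), index=scores.index)
    valid = ~scores["unscorable"].to_numpy() & grouping.notna().to_numpy()
    y = scores.loc[valid, "ses_score"].to_numpy()
    g = grouping[valid].astype(str).to_numpy()
    labels = [lab for lab in pd.unique(g)]
    if reference not in labels:
        raise ContrastError(f"reference group {reference!r} is empty or absent")
    if len(labels) < 2:
        raise ContrastError("need at least two non-empty groups")
    labels = [lab for lab in labels if lab != reference] + [reference]

    grand = y.mean()
    ss_between = ss_within = 0.0
    stats: dict[str, tuple[int, float, float]] = {}
    for lab in labels:
        vals = y[g == lab]
        stats[lab] = (vals.size, float(vals.mean()),
                      float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
        ss_between += vals.size * (vals.mean() - grand) ** 2
        ss_within += float(((vals - vals.mean()) ** 2).sum())
    df_b = len(labels) - 1
    df_w = y.size - len(labels)
    if df_w <= 0:
        raise ContrastError("not enough observations for a within-group variance")
    ms_between = ss_between / df_b
    mse = ss_within / df_w
    if mse == 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ms_between / mse
        p = float(f_dist.sf(f_stat, df_b, df_w))

    n_ref, mean_ref, _ = stats[reference]
    rows = []
    for lab in labels:
        n_g, mean_g, sd_g = stats[lab]
        if lab == reference:
            rows.append(GroupRow(lab, n_g, mean_g, sd_g, None, None))
        else:
            se = float(np.sqrt(mse * (1.0 / n_g + 1.0 / n_ref))) if mse > 0 else 0.0
            rows.append(GroupRow(lab, n_g, mean_g, sd_g, mean_g - mean_ref, se))
    return Contrast(characteristic, reference, rows, float(f_stat), df_b, df_w, p)


def validity_report(
    result: MultigroupResult,
    table: ScoringTable,
    data: ResponseDataset,
    grid: QuadratureGrid | None = None,
    common_items: list[str] | None = None,
) -> ValidityReport:
    """Assemble the full reliability/validity report for a scored cohort."""
    items = common_items or [
        i for i in data.items
        if all(i in table.site_items[s] for s in data.sites if s in table.site_items)
    ]
    alpha_sites = {}
    for site in data.sites:
        try:
            alpha_sites[site] = cronbach_alpha(data.for_site(site), items)
        except ValueError:
            alpha_sites[site] = float("nan")
    report = ValidityReport(
        alpha_pooled=cronbach_alpha(data, items),
        alpha_by_site=alpha_sites,
        pattern_sumscore_r=pattern_sumscore_correlation(result, table, data, grid),
    )
    scores = score_dataset(table, data)
    contrast_specs = [
        ("education_type", "formal", "Type of education"),
        ("education_years_band", "13+", "Years of education"),
        ("antenatal_care", "1", "Received antenatal care"),
        ("facility_delivery", "1", "Delivered in facility"),
    ]
    for col, ref, label in contrast_specs:
        if col in data.data.columns:
            report.contrasts.append(
                group_comparison(scores, data.data[col].to_numpy(), ref, label)
            )
    return report
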