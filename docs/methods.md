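# Methods

## Measurement model

Items are dichotomous indicators of household wealth, coded 1 for the
higher-SES state. The latent SES trait θ of a respondent is measured by
the two-parameter logistic (2PL) model

    P(x_j = 1 | θ) = 1 / (1 + exp(−a_j (θ − b_j))),

where the slope `a_j` (discrimination) measures how sharply item j
separates respondents along θ and the threshold `b_j` is the trait level
at which endorsement reaches 50 %. The logistic metric is used without
the historical 1.7 scaling constant, matching common 2PL software
defaults; conversions between slopes and normal-ogive factor loadings use
the 1.7 approximation, λ = (a/1.7)/√(1+(a/1.7)²), and are only ever used
for screening cross-checks, never inside the likelihood.

## Synthetic cohort generator

The generator draws from the one-factor normal-ogive (probit) model that
a categorical one-factor CFA assumes: for a respondent at site g,
θ ~ N(μ_g, σ_g); each item has a latent response
y*_j = λ_j θ + √(1−λ_j²) ε_j with ε_j ~ N(0,1), and x_j = 1 iff
y*_j > τ_j. Thresholds are set so that the within-site endorsement
probability equals the configured target exactly:

    τ_j = λ_j μ_g + √(λ_j² σ_g² + 1 − λ_j²) · Φ⁻¹(1 − p_j),

which reduces to Φ⁻¹(1−p_j) for a standard-normal site. Consequences
worth being explicit about:

- Within-site response distributions are invariant to the configured
  (μ_g, σ_g): site wealth differences live entirely in the per-site
  prevalences. The configured site means (reference Nagpur at 0; other
  sites negative, ordered like the published site SES means) therefore
  matter only for the retained θ column and for the covariate links.
  They are calibration choices, not published quantities.
- Between-site differences are *not* generated as a common-threshold,
  shifted-mean structure. When the anchor model is later imposed, the
  estimated group means absorb a compromise over items whose prevalence
  gaps imply different shifts; this is deliberate — it exercises the
  site-specific fallback exactly where real cross-site item functioning
  differences would.

The packaged default configuration transcribes the published seven-site
tables: site mix (N = 49,536 total), per-site item prevalences, and
per-site one-factor loadings for the twelve index items. Loadings for
"more than one room" and "bicycle" outside DRC are not published (those
items enter the index only at DRC) and default to 0.55, a mid-range
calibration choice with no effect on any benchmark quantity. Items with
a published prevalence of exactly 0 are generated as constant-zero
columns and flagged.

Covariates are linked monotonically to θ so construct-validity contrasts
hold by construction: years-of-education bands (0, 1–6, 7–12, 13+) via
ordered cutpoints on θ plus N(0, 0.8²) noise, calibrated to the published
marginals (18/22/52/7 %); education type is "none" exactly for the lowest
band (18 % ≙ the published no-formal-education share); antenatal care and
facility delivery via logistic links with slope 1.0 on θ and intercepts
calibrated to 97 % and 45 % pooled rates. Missingness is off by default;
an MCAR rate is available for robustness checks. What the generator does
*not* emulate: household clustering within site, non-MCAR missingness,
multidimensional wealth structure, and response error uncorrelated with
θ — so passing tests demonstrate correctness of the pipeline under an
exactly unidimensional data-generating process, not robustness to the
messiness of real registry data. One visible consequence: the pooled
internal consistency of the ten common items comes out slightly above
the published value, because nothing in the generator violates
unidimensionality the way real data do.

## Estimation

**Single-group 2PL.** Bock–Aitkin marginal-maximum-likelihood EM on a
fixed quadrature grid: 49 equally spaced nodes on [−6, 6] with
standard-normal weights renormalized to sum to 1 (robust for the extreme
thresholds produced by near-zero-prevalence items). The E-step computes
posterior node weights per respondent (missing items skipped in the
pattern likelihood); the M-step solves a weighted logistic regression per
item in the concave slope–intercept parametrization (logit P = c + aθ)
by projected Newton steps with step-halving, so the expected
complete-data log-likelihood never decreases and the marginal
log-likelihood is monotone across cycles (checked to 1e-8 in tests).
Convergence: max absolute parameter change < 1e-4 or 500 cycles, with an
explicit non-convergence flag. Guards: slopes confined to [1e-3, 10] and
|b| ≤ 8 (projected inside the M-step, preserving monotonicity); the
latent axis is reflected whenever the summed slope turns negative, fixing
the a > 0 sign convention. Start values: a = 1, b = −logit(p̂).

**Multi-site concurrent calibration.** The pooled marginal likelihood
over sites is maximized with anchor items sharing one (a, b) across all
sites whose design includes them (their expected counts are pooled before
the M-step) and site-specific items free per site. The reference site's
latent distribution is fixed N(0, 1); other sites' normal means and SDs
are updated from posterior moments each cycle, with a fallback direct
search whenever grid renormalization would make the moment update
non-monotone — the pooled log-likelihood is therefore monotone here too.
Two robustness rules, both logged as warnings:

- An item that is *constant* at a site cannot be estimated there and, if
  forced into the anchor likelihood, only drags the group mean toward
  ±∞; it keeps the anchor parameters (estimated from the other sites)
  but is excluded from that site's likelihood.
- An item failing the floor/ceiling screen at a site that cannot be
  substituted (pool exhausted) is retained with site-specific parameters:
  a near-absent item carries essentially no cross-site linking
  information, and anchoring it distorts the site's latent location.

**Scoring.** P(S = s | θ) is computed by the Lord–Wingersky recursion
(items folded in one at a time — exact, no 2^J enumeration; verified
against enumeration to 1e-12 for J ≤ 10). The conversion table maps each
sum score to E[θ | S = s] under the site's estimated latent distribution,
then rescales linearly so score(0) = 0.00 and score(J) = 100.00 per site
(the published table shows exactly that endpoint pattern per column).
Values are kept at full precision internally and rounded to two decimals
on export. Sum scores are defined only for complete responders; pattern
EAP skips missing items. Respondents missing any design item are flagged
unscorable and counted, never imputed.

**Pattern-vs-sum-score agreement.** The headline correlation compares
table-based SES scores with pattern EAPs computed under the *reference*
prior (default): the rescaled tables deliberately remove group-mean
separation, so scoring patterns under per-site priors re-injects
between-site variance on one axis only and understates the within-site
agreement the comparison is about. The per-site-prior variant is
available via `prior="site"`.

## Item selection and anchoring rules

Keep rules (strict): loading > 0.4 and slope > 1.0, prevalence inside
[1 %, 99 %]; the first failing rule is recorded. Anchoring: an item is
site-specific where its slope < 0.9 or loading < 0.4 or its prevalence
falls outside the floor/ceiling bounds; otherwise anchored. Substitution:
items *essentially absent or universal* at a site — prevalence beyond a
stricter bound (default 0.1 %, strict) — are removed there, most extreme
first, and replaced from a configured pool (default: bicycle, more than
one room in home) while pool items pass the floor/ceiling screen at that
site. The two bounds are deliberately separate: with a single 1 % bound,
sites with several rare-but-present items would exhaust a two-item pool,
whereas only the genuinely absent items (0 % prevalence at the DRC site)
should trigger replacement. Both bounds are configurable in
`SelectionCriteria`. Ties among equally extreme items are broken by the
standard item order. The reference site for latent-scale identification
is Nagpur when present (the highest-scoring site), otherwise the site
with the highest summed prevalence.

## Factor analysis and reliability

One-factor CFA for binary items: pairwise-complete tetrachoric
correlations (maximum likelihood with thresholds fixed at the observed
margins; bivariate-normal cell probabilities; 0.5 added to all cells when
any cell is zero), then unweighted-least-squares loadings minimizing
Σ(r_ij − λ_iλ_j)² over the off-diagonal. Fit indices rescale the ULS
discrepancy by (n − 1) against the zero-correlation baseline:
T = (n−1)·Σ res², df = J(J−1)/2 − J, CFI = 1 − max(T−df,0)/max(T_b−df_b,
T−df), TLI from the usual ratio form (both clipped to [0, 1]), RMSEA =
√(max(T−df,0)/(df(n−1))). This is not the weighted categorical estimator
of commercial SEM software; for a correctly specified one-factor model
the loadings agree in population, and all fit checks used here are
bound-type (CFI > 0.95, RMSEA < 0.06), not point-value matches.
Cronbach's alpha uses the classical variance decomposition on complete
cases; a single implementation is shared by the CFA and validation
modules.

Construct validity uses classical (not Welch) one-way ANOVA computed from
first principles — between/within sums of squares, F, p from the F
distribution — with per-group means/SDs and mean-difference coefficients
against a reference category with pooled-variance standard errors; one
model per characteristic. Complete separation (zero within-group
variance) yields an infinite F rather than an error.

## Problem sizes and determinism

Benchmark computations use n = 10,000 pooled respondents (scaled down
from the registry's 49,536, preserving the site mix), n = 7,000 /
n = 7,700 for the single-site scoring checks, and 20 replicates of
n = 5,000 for parameter-recovery error. Every stochastic step takes an
explicit integer seed through `numpy.random.default_rng`; identical
configuration and seed reproduce byte-identical datasets and artifacts
(the CLI manifest records SHA-256 hashes to make this checkable).

## Known limitations

- Anchored calibration on data whose between-site structure is not truly
  common-threshold (this generator, by design) yields group means that
  compromise across items; they should be read as linking constants, not
  as estimates of a configured quantity.
- Tetrachoric estimation with very extreme margins (< ~1 %) is noisy even
  with the continuity correction; per-site screening statistics for such
  items are used only through rules that are robust to this (floor
  checks fire before loading/slope checks).
- The published scoring-table values themselves cannot be reproduced
  cell-by-cell because the original study's fitted item parameters were
  never published; the pipeline reproduces the table's structure
  (endpoints, monotonicity, per-site columns) and, through the packaged
  generator, the downstream site-level score distributions.
- No 1PL/3PL/graded models, no item-parameter standard errors, no
  formal differential-item-functioning tests (threshold rules only), no
  multiple-testing correction in the validity contrasts.
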