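# Methods

This note records the statistical model behind `pvsignal`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer.

## Data model and eligibility

A spontaneous-reporting database is four relational tables keyed by
(case number, version): DEMO (sex, age band, weight band as closed
vocabularies), DRUG (name, role, route, start/end dates), REAC (PT code,
onset date), HIST (comorbidities, carried but unused). Successive
versions of a case supersede earlier ones, so **deduplication keeps the
highest version per case number**. The database never documents its own
duplicate-identification rule; the case-number key is the natural
structural choice, and the removed count is logged so users can audit it.

Dates are ISO `YYYY-MM-DD`, with `YYYY-MM` accepted as a *partial* date:
retained (counting statistics need no dates) but flagged incomplete and
excluded from time-to-onset, which maximises counts where dates are
irrelevant while keeping the TTO sample clean.

A report is *eligible* for a drug when at least one DRUG entry names the
drug (after brand/salt alias normalisation) with role `suspected` and an
allowed route. Route fields are very frequently blank in SRS data, so
`unspecified` is eligible by default (configurable); excluding blanks
would silently drop most reports. Reports where the drug is only
concomitant or interacting never qualify.

## Term aggregation

PT-level membership is the distinct PT codes per report. SMQ-level
membership maps each PT through a user-supplied dictionary restricted to
one scope (narrow by default, for specificity); a report with several
qualifying PTs in one SMQ contributes exactly one membership
(once-per-report rule). PTs absent from the dictionary are unmapped at
SMQ level (coverage is logged) but always analysable at PT level. Only
the flat PT→SMQ relation is modelled — no HLT/SOC navigation, no SMQ
hierarchy, no algorithmic SMQs — and MedDRA version migration is assumed
done upstream of the dictionary.

## Disproportionality statistics

For each drug–term pair over the post-deduplication universe:
a = |eligible ∩ event|, b = |eligible| − a, c = |event| − a, d = rest.

- PRR = [a/(a+b)]/[c/(c+d)]. Not evaluable (NaN, never ±inf) when c = 0.
- χ²: Pearson with the Yates continuity correction,
  Σ max(|O−E|−½, 0)²/E. The truncation at zero (rather than letting the
  correction overshoot) matters only for near-independent tables. The
  corrected variant is the one that reproduces the small-count published
  values the package is tested against (19.19 where the uncorrected
  statistic gives ≈23.1).
- ROR = ad/bc with the Woolf CI exp(ln ROR ± z√(1/a+1/b+1/c+1/d)),
  z = 1.96. Any zero cell makes the CI not-evaluable; no Haldane–Anscombe
  correction is applied because the a ≥ 3 signal floor makes corrected
  sparse tables irrelevant to decisions.
- IC = log₂[(a+½)/(E+½)], E = (a+b)(a+c)/N; IC₀₂₅ replaces a+½ with the
  2.5% quantile of Gamma(a+½, 1). This exact-gamma lower bound matches
  the reference vancomycin row to 2 d.p.; on other published rows it
  deviates by up to ~0.17, so published IC₀₂₅ values are treated as
  verification aids rather than reproduction targets, and the tests
  assert the one row that pins the formulation plus the ic025 < ic
  property.
- Log-scale p-values: ln p = ln 2 + ln Φ(−√χ²) via `scipy.special.log_ndtr`.
  The naive route (`chi2.logsf`) underflows to −∞ near χ² ≈ 1500 because
  it logs an underflowed survival value; the log-normal-CDF route is
  finite and accurate to χ² ≥ 10⁶.
- BH-FDR entirely in log space: sort, candidate_i = ln p_(i) + ln(m/i),
  running minimum from the largest rank down, cap at 0, restore input
  order. Ties are broken by a stable sort on (ln p, term id) so ranks —
  and therefore output files — are reproducible. The family is **per
  drug × per level** (all terms with a ≥ 1 tested for that drug at that
  level); a pooled family is a one-line change in `run_screen` but the
  per-drug family is the default because each drug's screen is reported
  as its own table.
- Signal rule: PRR ≥ 2 ∧ χ² ≥ 4 ∧ a ≥ 3 ∧ BH-adjusted p < 0.05. The four
  booleans are logged per pair for audit.

Volcano coordinates are x = log₂ PRR, y = χ², point size ∝ a/(a+b) (the
within-drug reporting ratio). Figures are always rendered from the
exported coordinate CSVs, never from live state, so plots are
reproducible from artifacts alone.

## Time-to-onset model

TTO = (onset − start) + 1 days, so same-day onset is day 1 — the Weibull
needs strictly positive support and whole-day SRS data makes day 0
common. Eligibility per report: a suspected entry of the drug with a
*complete* start date (earliest such start when several exist; one value
per report prevents double counting), a complete onset (earliest, for
multi-PT SMQ groups), onset ≥ start (else inconsistent), and onset no
more than 14 days (configurable) after a recorded end of administration.
A missing end date is treated as ongoing treatment — the post-cessation
window only applies after discontinuation — with `require_end_date=True`
available for the stricter reading that demands recorded start *and* end.

Fitting: the two-parameter Weibull MLE via the profile-likelihood root
solve (the shape equation Σtᵝln t/Σtᵝ − 1/β − mean(ln t) = 0 is monotone
in β; brentq on an expanding bracket, then α = (mean tᵝ)^{1/β}). The 95%
CIs are Wald intervals on the *untransformed* parameters from the
analytic observed information matrix — the fitdistrplus-style output
whose CIs can dip below 1 while β̂ > 1, which is exactly what the
published classification rule consumes. A minimum of 20 cases is
required (parametric survival fits are unstable below a few dozen
observations); smaller or zero-variance samples return a not-evaluable
fit that still carries the empirical median and IQR (linear-interpolation
sample quantiles).

Classification: wear-out iff CI low > 1, early iff CI high < 1, random
otherwise. The "β ≈ 1" band is operationalised as "CI straddles 1"; every
published hazard label the package is tested against is consistent with
this rule.

Goodness of fit: Anderson–Darling statistic against the fitted CDF, with
the fully-specified-null p-value by the Marsaglia & Marsaglia (2004)
approximation (asymptotic CDF plus finite-n correction), implemented
in-package because no installed library exposes it. Using plug-in
parameters makes the test anti-conservative (true rejection rate above
nominal); that is the conventional practice the published p-values
represent, it is documented here, and `ad_test(..., n_bootstrap=N)`
offers a parametric-bootstrap calibration, off by default. Tied integer
day values simply map to tied CDF values; both tails are evaluated in
log space so extreme observations cannot produce −∞.

## Synthetic generator

The generator emits the exact CSV schemas the loader consumes, plus a
ground-truth JSON. Structure: reports independent; per drug a Bernoulli
presence draw with categorical role/route; per term a Bernoulli event
with rate baseline × Π λ over present drugs carrying a multiplier
(capped at 1; a single-pair baseline × λ > 1 is a config error naming the
pair); onsets from a planted per-pair Weibull (first matching drug in
config order) or a background Weibull, with the continuous draw rounded
*up* to whole days so the extractor's day-1 convention is reproduced
exactly; geometric treatment duration (default mean 14 days) so the
post-cessation window rule is exercised; uniform start dates over a
10-year window; configurable fractions of blanked / year-month-truncated
dates and of injected duplicate case versions (identical content, version
2). Randomness is one seed split into named child streams (demographics,
drugs, events, onsets, missingness, duplicates) in a fixed order, so
adding draws to one table never perturbs another; identical config + seed
gives byte-identical files.

Default demographic band probabilities (≈62% male, ≈67% aged ≥60, weight
most often 40–69 kg or unreported) mirror the profile typical of
hospital-treated severe-infection cohorts in SRS data.

The expected PRR of a planted pair has a closed form under independence
and is computed by exhaustively enumerating the joint presence of every
drug with a multiplier for the term; it feeds the ground-truth file and
the generator's own tests. Note the expected PRR is slightly below λ:
non-cases include present-but-not-suspected reports whose event rate is
also elevated.

Deliberately not modelled: polypharmacy/confounding structure, the Weber
reporting-time effect, and real JADER marginal frequencies. Passing tests
therefore demonstrate correctness of the estimators and decision rules
under independence — not robustness to the biases (channeling,
underreporting, duplicate near-misses with changed keys) that real SRS
analyses must argue about separately.

## Problem sizes used in the checked guarantees

- FDR control: 10 databases of 50,000 reports × 1,000 terms (baselines
  log-spaced 5×10⁻⁴–10⁻²), all multipliers 1; the mean flagged fraction
  under the four-condition rule stays well under the 0.05 BH bound (the
  PRR/χ²/count conditions make it far smaller in practice).
- Signal recovery: λ = 8 at baseline 0.01 in 50,000-report databases is
  flagged in ≥ 95% of 20 seeded runs.
- Weibull CI coverage: for (α, β) ∈ {(10, 0.7), (10, 1.0), (15, 1.8)},
  n = 200, 500 replicates each, β-CI coverage is 95% ± 3%.

## Known limitations

- Disproportionality measures reporting, not incidence or risk; no
  causal or between-drug quantitative comparison is implied.
- The Wald CIs for Weibull parameters are symmetric on the natural scale
  and can be poor for small n or β near its boundary; a likelihood-ratio
  or log-scale interval would be better-calibrated but would not match
  the CI convention the classification rule was built against.
- The plug-in AD p-value is anti-conservative (see above).
- Input encoding is UTF-8 with documented column names; converting a real
  JADER distribution (Shift-JIS, Japanese headers, zip layout) is a
  preprocessing step outside this package.
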