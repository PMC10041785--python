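# Methods

## Model and hypotheses

Spontaneous reporting data are tabulated per adverse event *i* (a MedDRA
Preferred Term or a named composite of terms), drug *j* and host-factor
group *s* ∈ {1, 2}. Counts n⁽ˢ⁾ᵢⱼ are modelled as Poisson with mean
λ⁽ˢ⁾ᵢⱼ·E⁽ˢ⁾ᵢⱼ, where the baseline E⁽ˢ⁾ᵢⱼ = n⁽ˢ⁾ᵢ.·nᵢⱼ/nᵢ. is the expected
group-s count when the host factor does not interact with the drug. The
null hypothesis is λ⁽¹⁾ᵢⱼ = λ⁽²⁾ᵢⱼ = 1 for all drugs of the family;
conditioning on the margins makes the group-1 exposed count
Binomial(nᵢⱼ, pᵢ) with pᵢ = n⁽¹⁾ᵢ./nᵢ..

Two table orientations share all machinery: *by-drug* (fix an event, vary
drugs — "which drugs show a sex disparity for this event?") and *by-AE*
(fix a drug, vary events — "does this event's sex split stand out among
the drug's events?"). Only the margin construction differs.

The conditional-binomial model treats reports as independent and the
margins as ancestral; it does not model reporting biases (stimulated
reporting, channeling) or exposure denominators, so a significant
disparity is a reporting-disparity signal, not an incidence estimate.

## Test statistics

- **LRT**: LR = −n log(n/N) + a₁ log(a₁/M₁) + a₂ log(a₂/M₂), natural
  logarithms, 0·log 0 ≡ 0 (zero exposed cells give finite LR). Null
  distributions by Monte Carlo (below).
- **Normal**: z = √n (a₁/n − p)/√(p(1−p)); two-sided p = 2(1 − Φ(|z|)).
  The signed value is reported so the disparity direction survives.
- **PRR**: (a₁/n)/((M₁−a₁)/(N−n)) with delta-method z-score
  √n(log PRR − c)/σ, c = log(p/((M₁−np)/(N−n))),
  σ² = p(1−p)(M₁/(p(M₁−np)))².
- **ROR**: (a₁/a₂)/((M₁−a₁)/(M₂−a₂)) with
  c = log((p/(1−p))/((M₁/n−p)/(M₂/n−(1−p)))) and
  σ² = p(1−p)[(M₁/n)/(p(M₁/n−p)) + (M₂/n)/((1−p)(M₂/n−(1−p)))]².

### The `variant` switch

The PRR/ROR approximations circulate in two algebraic forms. The package
defaults to the internally **consistent** form above, in which the
centering is the null plug-in value of the log-ratio and the variance is
symmetric in the two groups; simulated at null it yields the moderate
family-wise inflation characteristic of these estimators (the log of a
binomial proportion has heavier tails than its delta-method normal). The
alternative `variant="printed"` substitutes a centering denominator of
N − M₁ in the PRR and a data-dependent term a₁/n − (1−p) in the σ²(ROR);
these forms appear in print but are badly miscalibrated (PRR rejects
almost always, ROR almost never, under the null) and are retained only
for sensitivity analysis. Both variants agree on the point estimates.

## Monte-Carlo nulls

Per family, m replicates draw every unit's a₁* ~ Binomial(n, p)
independently (the constraint that group-1 counts sum to M₁ is ignored —
the conditional model is stated per table, and exposed totals are small
against the margins). Per-unit draws give raw p-values; per-replicate
maxima give the MLR null. The p-value estimator is the inclusive upper
tail, (#draws ≥ observed)/m: on a discrete simulated null the strict
inequality is anti-conservative downstream (inflated FDR under BH).
Empirical p may be exactly 0; presentation layers print "< 1/m". The MLR
quantile uses the 'higher' order-statistic convention so that
P(MLR > q) ≤ α empirically.

Defaults: m = 100 000 for analysis (relative MC error ≈ 4% for p ≈
0.005); m = 5 000 inside the simulation harness, where only the α = 0.05
decision matters. Streams are per-unit substreams of (seed, unit index),
so results do not depend on iteration order.

## Multiplicity

Max-Stat: reject units whose statistic exceeds the (1−α) quantile of the
family maximum under the global null — the Monte-Carlo MLR quantile for
the LRT, and for z-based tests the Φ⁻¹((1−α/2)^(1/J)) approximation to
the max-|z| quantile (exact form Φ⁻¹((1+(1−α)^(1/J))/2) available by
switch; they differ by ~3·10⁻³ even at J ≈ 600). The z-test adjusted
p-value is 1 − (1−p_raw)^J, the independence transform, which reproduces
the published analgesic values to 4 decimals. BH is the standard step-up
rule, delegated to statsmodels; ties are ordered by unit id for
deterministic output (the rejection set is tie-invariant).

## Preprocessing rules

Only primary-suspect drug mentions are counted; records with missing
host-factor values are dropped; exact duplicate (report, drug, event)
triples collapse to one. De-duplication by demographic matching, as done
in full FAERS curation pipelines, is out of scope — the exact-triple rule
is transparent and testable, and makes no claim to reproduce curated
case counts. Numeric age is dichotomized at 65 by default with the
boundary in the "at least 65" group. Tables with any cell below 5 are
excluded (the normal and ratio approximations degrade); families need
more than 5 units; simulation bases additionally exclude families where
some unit's exposed total exceeds the smaller margin (such units could
draw group counts above their margin under the binomial null). Whether
the cell filter is applied before or after the role restriction is a
pipeline choice; this package filters after, and logs removals per rule.

## Simulation harness

The harness re-draws exposed counts for a base of families, stratified by
total event count into small/medium/large at the base's 25%/50% quantiles
(the FAERS-derived cutpoints 674/1337 can be pinned). Per family,
m_k = round(J/5) drugs (half-cases away from zero; configurable fraction)
are selected once and held fixed across that family's iterations, and
follow p′ = p + Δ·(−1)^{1(p>0.5)} (clipped to [0.001, 0.999] if ever
needed; logged). Estimators: FWER = share of global-null runs with ≥ 1
rejection; FDR = mean of false/total rejections with 0/0 ≡ 0;
sensitivity = mean of correct/true-alternative proportions. At Δ = 0 the
truth labels are all null regardless of the selected fraction, since the
alternative coincides with the null.

The Δ grid {0, 0.025, 0.05, 0.1, 0.2} covers negligible to large
disparities. Whether the published 500 000-run budget was per stratum or
overall is ambiguous; the harness parameterizes aes-per-stratum ×
iterations-per-ae directly, so either reading is expressible.

## Synthetic base generator

`generate_synthetic_base` emulates the *marginals* of a preprocessed
reporting database, chosen once: AE totals lognormal with 25%/50%
quantiles at 674/1337; group-1 proportion Beta(47.4, 52.6) (mean 0.474 —
the male share in the analgesic family — sd ≈ 0.05); drugs per AE
6 + Poisson(4); per-drug exposed totals lognormal(median 30, σ = 0.6)
floored at 12. Candidate families are passed through the standard filters
and only survivors are emitted. The generator does **not** emulate
report-level structure (no duplicate reports, no missing-data mechanism,
no drug-name noise, no correlation between drugs within a report), so a
green calibration test establishes the operating characteristics of the
tests under the stated binomial world — not robustness to real-data
artefacts upstream of the count tables.

## Numerical conventions and edge cases

- Tiny negative LR from floating cancellation is clipped to 0.
- Degenerate simulated tables (a zero exposed cell) give non-finite
  ratio z-scores; in the harness a NaN z counts as no evidence (|z| = 0),
  while an infinite |z| rejects — matching the analytic limits of the
  statistics.
- All rounding of "nearest whole number" counts is half-away-from-zero.
- Every stochastic routine takes an explicit integer seed (or Generator)
  and is reproducible bit-for-bit; derived seeds stay below 2³¹.

## Design choices

- The package is a library plus narrative example scripts rather than a
  command-line tool: its users drive analyses from Python, statsmodels
  style, and every pipeline stage exchanges plain data structures that
  serialize to TSV.
- Signed z-scores are reported with two-sided p-values; one-sided tests,
  exact conditional (Fisher-type) tests and Bayesian shrinkage are out of
  scope.
- The harness holds the alternative-drug selection fixed within a
  family's iterations; re-selecting per iteration would estimate the same
  rates with slightly different Monte-Carlo error structure.

## Known limitations

- The by-AE orientation shares one drug's margins across its events, so
  its families are large (hundreds of events) and the MLR null
  correspondingly expensive; the closed-form normal test is the practical
  choice there.
- Monte-Carlo adjusted p-values are bounded below by 1/m.
- PRR/ROR tests are included for comparability, not recommendation: their
  empirical FWER/FDR exceed nominal levels in every simulated setting.
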