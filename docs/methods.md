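# Methods

## Screening model

Each screen is a person-level logistic regression of binary serostatus on
one candidate variable (univariate) or on the variable plus wealth
(5 categories, lowest as reference), age and a rural indicator
(adjusted). Estimation maximises the survey-weighted log-likelihood
Σ<sub>j</sub> w<sub>j</sub>[y<sub>j</sub> log p<sub>j</sub> +
(1−y<sub>j</sub>) log(1−p<sub>j</sub>)] by Newton/IRLS (at most 100
iterations, convergence when the step falls below 1e-8, fitted
probabilities clipped to [1e-10, 1−1e-10]). Weights are normalised to sum
to the analysed sample size, which makes every estimate invariant to
rescaling all weights and gives the pseudo-R² an effective n equal to the
number of analysed rows.

Variance is the cluster-robust sandwich at the primary-sampling-unit
level: bread = inverse weighted information, meat = sum over clusters of
outer products of cluster-summed scores w<sub>j</sub>(y<sub>j</sub> −
p<sub>j</sub>)x<sub>j</sub>, scaled by G/(G−1) for G clusters. No
stratification correction is applied; strata ids are carried through the
containers as a documented extension point. p-values are two-sided Wald
against the standard normal, the convention of survey-regression software.

Fits that do not converge, or converge with |β| > 15, are flagged
*separated* but retained: extreme odds ratios in sparse strata are
information, not failures, and are pooled downstream unless their standard
error is non-finite (always excluded) or the caller opts out of separated
fits. Each model is complete-case in its own columns; there is no
imputation anywhere.

The Nagelkerke pseudo-R² is the Cox–Snell measure rescaled by its
attainable maximum, R²<sub>CS</sub>/R²<sub>max</sub> with
R²<sub>CS</sub> = 1 − exp(2(ℓ₀ − ℓ₁)/n) and
R²<sub>max</sub> = 1 − exp(2ℓ₀/n), clipped to [0, 1]. The null
log-likelihood ℓ₀ is the weighted intercept-only likelihood, i.e. the
outcome prevalence.

## Meta-analysis

Per (variable, sex), survey estimates are pooled with the
DerSimonian–Laird moment estimator: fixed-effect weights 1/v<sub>i</sub>
give Q; τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)); pooling re-weights by
1/(v<sub>i</sub>+τ²). I² = max(0, (Q−(k−1))/Q)·100. Two scopes are
produced: within-country across waves, and pan-region across every
survey. A variable present in a single survey passes through with its
survey estimate, τ² = 0 and I² reported as missing — heterogeneity is
undefined at k = 1, so the single-country bin of the summary table leaves
its I² cells blank. No Knapp–Hartung adjustment and no alternative τ²
estimators are offered; inference is plain Wald, matching the default of
the standard random-effects implementations.

## Discovery

Dual threshold: pan-region p < 1e-6 (the conservative fixed value;
`bonferroni_threshold` gives the exact α/(n_female + n_male) alternative,
0.05/13,539 ≈ 3.7e-6 at the reference screen sizes) *and* mean per-survey
R² above a floor. The floor is either a fixed 0.001 (default) or the 75th
percentile of mean R²; the quantile is computed pooled across sexes by
default since the per-sex variant changes little and the pooled variant
is the simpler estimand. Country-count bins are the non-overlapping
{1, 2–10, 11–19, 20–29} (counts above 29 fall in the last bin); the
summary reports per (sex, bin) the association count and quartiles of
pooled OR, mean R² and I².

## Prediction and risk concentration

Per sex, the top k = 10 identified variables assessed in every country
(ranked by mean R², ties broken lexicographically for determinism) enter
an unweighted logistic model fitted on each country's latest survey
(maximum year, ties by survey id), restricted to respondents with all k
variables observed. Fits are unweighted because the prediction target is
the surveyed sample itself; a survey-weighted variant sits behind a flag.
Scores are in-sample: ROC-AUC as the Mann–Whitney rank statistic (ties
half-counted), PRAUC as average precision over descending thresholds with
no linear interpolation (trapezoidal PR interpolation is optimistic), and
the Gini coefficient of the predicted-probability distribution in its
mean-absolute-difference form, computed from sorted values in O(n log n)
and equal to one minus twice the Lorenz-curve area. For a random scorer
AUC → 0.5 and PRAUC → prevalence, so both read as lift over
prevalence-only prediction; Gini 0 means evenly spread predicted risk.
Countries with fewer than 10 cases after the complete-case restriction
are skipped with a log entry.

## Harmonisation

Men's-file names are rewritten by an ordered first-match-wins prefix
table (strip `_`; `mv304a→v304a_`; `mcase→case`; `mv→v`; `sm6→s8`;
`sm→mm`, falling back to `s` when no `mm` candidate exists on the women's
side; `dm→d`; `m→v`; strip `s`). Specific prefixes are ordered before the
general rules they overlap, otherwise the general rule would shadow them.
Non-exact candidates are ranked by normalised Levenshtein similarity
1 − d/max(|a|,|b|) with a 0.7 floor; only exact post-rule matches are
auto-accepted — near misses and ties are reported for external
adjudication, never guessed.

Value-label conflicts (one stored code, two label texts) are resolved
globally per variable: the complete list of values across every survey is
assembled, an unlabelled claimant keeps its value, otherwise the
first-seen (women's-side) label is canonical and each other distinct
label moves to the next larger unused level — assigned once, so the same
conflict lands on the same new level in every survey. Relevelled labels
are prefixed `[original value]`. A consequence worth knowing: a conflicted
binary variable genuinely fragments into distinct categories across
surveys (that is what conflicting dictionaries mean), which reduces its
cross-survey poolability — the pairwise resolver `resolve_label_conflicts`
implements the same rules for two dictionaries.

Recode merging left-joins individual, household and test-result files
onto the member roster (cluster id, household id, line number), never
dropping roster rows; alerts fire when individual data cover <75% of the
roster, >25% of individual rows match nothing, household data cover <75%,
or test results cover <50%. Without an individual file the survey is not
merged.

Pruning drops per-survey constants, then forms duplicate groups as the
connected components of the graph of pairs with |Pearson r| ≥ 0.9 in any
survey (pairwise-complete, pairs with <30 joint observations skipped),
keeping per group the variable with the largest mean non-missing count
over the surveys where it appears; finally variables <90% complete in a
survey are dropped from that survey. Encoding one-hot expands variables
with ≤30 observed levels — every level gets an indicator, no reference
dropped, because each indicator is screened as its own candidate — and
standardises higher-cardinality variables to mean 0, SD 1 within survey,
storing (mean, SD) so the transform inverts exactly. The level boundary is
≤30 → categorical, >30 → continuous.

## Synthetic generator

The generator emulates the *structure* of a continental survey
collection, not its content: countries × 1–3 waves × two sex-stratified
files; a variable schema shared across surveys (binary prevalences
U(0.15, 0.85), categorical level probabilities Dirichlet(2), continuous
standard normal); per-variable country presence so country-count binning
is exercised; duplicate groups as exact copies (discrete) or noisy copies
placed just above the correlation floor (continuous,
corr(x, x+e) = 1/√(1+var e)); MCAR missingness at per-variable rates from
a configurable range; and value-label dictionaries whose male-file side
can be made to disagree at a configurable rate.

Outcomes follow a logistic model: normal cluster intercepts (default SD
0.3 on the logit scale) induce within-cluster correlation, planted
variables contribute their log-OR (optionally with a between-survey
normal spread to create true heterogeneity), and the survey intercept is
solved by root finding so the expected prevalence equals a target drawn
from the configured range, default U(0.01, 0.25) — the analysed
prevalence band. Weights are gamma draws with shape 1/dispersion²
(positive and right-skewed like inverse inclusion probabilities),
normalised to sum to the survey size. Defaults describe a mid-sized
collection: 10 countries, 1–3 waves, 4000 respondents over 100 clusters,
500 variables (50% binary / 30% categorical / 20% continuous).

What the generator does **not** emulate: real questionnaire content and
inter-variable dependence (variables are independent except duplicates
and planted effects), informative missingness, household rosters beyond
the join keys, stratified or unequal-probability cluster selection (the
weights are noise, uncorrelated with the outcome), and geographic
structure. Passing tests therefore demonstrate the statistical machinery
under a known truthful design — calibration, recovery, heterogeneity,
round trips — not robustness to the confounding and measurement error of
real surveys.

## Reproducibility and problem sizes

A single pipeline seed is expanded through SHA-256 into per-stage
substreams, so stages rerun independently and a same-seed rerun
reproduces every result table byte for byte (checksummed in the run
manifest). The test suite and acceptance script scale the study designs
to desk size — null calibration on 250 variables × 20 surveys of n = 2000
(5000 tests), recovery on 25 replicates of 20 surveys of n = 1500,
heterogeneity on 20 surveys of n = 2500, the full pipeline demonstration
on 20 country-years × 2 sexes of n = 2000 with 60 variables — chosen so
each Monte-Carlo standard error is comfortably inside the asserted bands.

## Known limitations

Wald inference can be liberal in surveys with very few cases (the low end
of the 1%–25% prevalence band); no Firth or exact correction is offered.
The sandwich ignores stratification gains. Complete-case analysis assumes
MCAR, which the generator satisfies by construction but real data will
not. The duplicate-group keeper rule (largest average n over surveys
where present) can prefer a variable observed in few large surveys over
one observed broadly — an inherited property of the rule, visible when
label conflicts fragment a variable. Prediction is in-sample by design; a
held-out split is available behind a flag but is not the reported
quantity.
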