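# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Common data model and cohort semantics

Events are calendar-dated coded facts partitioned by domain (diagnosis,
procedure, medication, observation); only observations carry numeric
values. Dates have day resolution — EHR extracts rarely support reliable
intra-day ordering, and every downstream quantity (index dates, windows,
durations) is defined in whole days. Codes are normalized to uppercase
with dots stripped, and all hierarchy handling is prefix matching on that
form, which is exactly the structure of ICD-10 and OPCS-4 chapters and
categories. Pseudonyms are HMAC-SHA256 of the source id under a secret
salt, truncated to 16 hex characters; collisions are checked at build time
and the construction is deterministic per salt and unlinkable across
salts.

Cohort membership: a patient belongs to a cohort iff every include
criterion has at least one matching event inside its temporal clause and
no exclude criterion does, with the index date equal to the earliest event
matching any `index_candidate` criterion. Include criteria intersect
(AND); alternatives are expressed as a list of prefixes inside one
criterion. Two deliberately conservative readings, both configurable at
the definition level:

- *"subsequent"* exclusions (`on_or_after_index`) include same-day ties —
  at date resolution a same-day event cannot be ordered after the index,
  and treating it as subsequent excludes more, the safer direction for a
  "success" phenotype;
- an unqualified exclusion means *ever*, because absence criteria in
  clinical phenotypes ("never transplanted") are usually meant over the
  whole record.

The engine is validated by exact agreement with an independently written
per-patient double-loop filter on randomized datasets and definitions;
this equivalence, not any single fixture, is the module's real warrant.

## Synthetic-EHR generator

The generator emulates the statistical skeleton the analytics rely on, not
clinical plausibility:

- latent patient groups with fixed proportions; per-group code panels
  where each code is carried with probability `prevalence` and first
  occurs after index with an exponential or Weibull waiting time (clamped
  to the coverage end so a carrier is always observable), or uniformly in
  the year before index;
- ages at index from a mixture of lognormals (two components reproduce
  the infant/teenage bimodality typical of congenital cardiac surgery);
- longitudinal observations at homogeneous-Poisson visit times, with
  values drawn from a SHASH law whose μ(t) and σ(t) are piecewise-linear
  in days since index — so every fitted quantity has a closed-form truth;
- one root seed spawns independent per-patient substreams
  (`numpy.random.SeedSequence`), making generation deterministic and
  stable under patient reordering.

What it does **not** emulate: code co-occurrence structure, visit-process
dependence on health state, measurement error clustering, within-patient
autocorrelation of observation values, or missingness mechanisms. Passing
tests therefore demonstrate correctness of the estimators under the stated
sampling models, not robustness to real-EHR messiness.

The four shipped scenarios mirror the package's canonical questions
(transplant creatinine consult; dialysis medication frequencies with a
96%-prevalence anticoagulant; an effusion-vs-others comparison with
elevated rare comorbidities and a bimodal age contrast; time to first
echocardiogram with mean-3-day exponential waiting). Scenario parameter
values are free choices fixed once in `make_example_scenario` and exposed
via the config; nothing downstream depends on them being "real".

## Descriptive and comparative analytics

Frequencies are patient-level shares: each member contributes at most once
per item, so duplicated administrations cannot inflate a percentage. Ages
are decimal years, days/365.25. Rank comparison uses Kruskal–Wallis with
mid-ranks and the standard tie correction, p from the χ² upper tail with
k−1 df; the implementation is checked to 1e-10 against an independent
reference on random tied data.

Relative risks come from 2×2 patient-level tables at the 3-character code
category (configurable). The interval is the Katz log-normal
CI, `exp(ln RR ± z·sqrt(1/a − 1/n1 + 1/b − 1/n2))`, with the conventional
0.5/1 continuity correction when an event count is zero, flagged in the
output. The scan is a descriptive screen: no multiple-testing adjustment
is applied and the rendered table says so. Ranking ties break by narrower
CI then code, making top-k lists deterministic.

Kernel densities for the age panels use Gaussian KDE with the
normal-reference (Silverman) bandwidth by default. That rule over-smooths
wide bimodal mixtures — with modes near 1 and 15 years it biases the upper
peak outward by most of a year — so the bandwidth is an explicit parameter
and mode-resolution work should set the kernel width to the scale of the
separation being claimed (the tests use ≈0.5 years). The densities are
descriptive; no inference is attached to them.

## Time-to-event

Durations run from the index date to the first matching event on/after
index, in whole days; a same-day event is a time-0 event (a post-operative
echo on the day of surgery is real and cannot be ordered later). Members
without an in-horizon event are censored at min(horizon, coverage end −
index); the default 28-day horizon matches the four-week operational
question the module was built for. The product-limit estimator uses the
events-before-censorings tie convention and is verified to 1e-10 against
an established survival package on random censored samples. The reported
median is the first time S(t) ≤ 0.5, flagged "not reached" when the curve
never crosses; no Greenwood bands are computed (out of scope).

## GAMLSS reference models

Family choices: SHASH (Jones–Pewsey form; F(y) = Φ(sinh(τ·asinh(z) − ν)))
for reference cohorts, Logistic for short single-patient series where four
parameters are unidentifiable. Links: identity for location and skewness,
log for scale and tail weight, which enforces σ(t), τ > 0 everywhere.
Smooths: cubic B-splines (default 20 basis functions on the observed time
range with clamped uniform knots) with an order-2 difference penalty on
adjacent coefficients for μ(t) and log σ(t); ν and τ are constants. A
SHASH fit requires ≥ 50 observations — below that the shape parameters are
noise and the fit is refused with a pointer to the Logistic family.

The penalized log-likelihood is maximized **jointly** over all
coefficients by L-BFGS-B with analytic gradients, rather than by the
classical cyclic per-parameter scoring loop: at these problem sizes
(10²–10⁴ observations, ~40 coefficients) the joint optimizer is simpler,
deterministic, order-invariant, and needs no damping heuristics.
Initialization is deterministic (penalized least squares for the location
coefficients, constant log residual SD for scale, ν = 0, log τ = 0), and
box bounds keep log-scale in [−30, 30], ν in [−10, 10], log τ in [−5, 5];
the sinh argument is clipped at |300| so degenerate line-search points
stay finite. Convergence is reported in the diagnostics, never raised.

Smoothing parameters default to a GAIC (penalty 2, i.e. AIC) grid search
over λ ∈ {1, 10, 100, 1000} per smooth, with effective dimension
tr(H⁻¹(H − P)) from the penalized Hessian H (finite differences of the
analytic gradient at the optimum) and penalty block P. Fixed λ values skip
the grid. Predictions clamp t to the fitted range and flag extrapolation;
centile curves are strictly increasing in the centile at fixed t because
the family quantile is.

The consult fits the comparator with SHASH and the patient with Logistic
(basis dimension auto-shrunk to the patient's series length), restricts
both to a post-index window (default 7–730 days, excluding the immediate
perioperative period and late follow-up), and scores each patient value
through the comparator CDF. Observations are treated as cross-sectionally
independent — within-patient correlation is ignored, as is standard for
reference-centile modelling; consult centiles for densely sampled patients
are therefore correlated across time and should be read as a trajectory,
not as independent tests.

## Disclosure control and reporting

Counts strictly between 0 and the threshold (default 5, a common
disclosure-control floor) are masked together with any derived percentage;
zero is never masked (it reveals only absence). Masking is idempotent and
monotone in the threshold, and rendered documents only ever see the
masked form. Report bundles carry a provenance block (content hash of the
sorted dataset tables, config hash, seed, package version) so a rendered
number can be traced to a reproducible run; HTML is the canonical format
and PDF is typeset directly with matplotlib's PDF backend.

## Problem sizes and verification scope

The test suite and the acceptance script use: 200-patient randomized
datasets × 50 random definitions for engine/oracle equivalence; 2000
simulated 2×2 tables (n = 500 per arm, RR = 2) for interval coverage; 100
random datasets each for the rank-test and survival cross-checks; n = 500
draws for SHASH parameter recovery (median-curve RMSE ≤ 1.0, 75th-centile
coverage 75% ± 4%) and n = 1000 for consult fidelity (90th-centile patient
scoring a median centile in [0.85, 0.95]); 20 rendered reports for the
disclosure scan. These sizes make the whole suite run in well under a
minute while keeping Monte-Carlo error far inside the stated tolerances.

## Known limitations

No OMOP/FHIR interoperability, no free-text data, no SNOMED graph
traversal (codes are flat strings), no general boolean cohort algebra, no
competing risks or hazard modelling, no multivariable adjustment in the
association scan, and no causal interpretation anywhere — the report
disclaimer is part of the design, not boilerplate.
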