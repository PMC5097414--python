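# Methods

This note documents the statistical procedures implemented in `harmsynth`,
the assumptions behind them, the defaults a user may want to change, and
what the synthetic-data tests do and do not establish.

## Data model and scope

All analyses consume *study-level summaries* of two-arm randomized trials:
binary harms as per-arm counts of persons with at least one event in an AE
category, continuous function outcomes as per-arm mean/SD/n. No
patient-level modelling, no time-to-event structure: follow-up duration and
publication year are carried as metadata only and never weight the
analysis. Each study contributes exactly one treatment and one control arm;
multi-arm designs must be reduced to a single comparison upstream.

## Zero cells and the rare-event regime

Serious adverse events in these trials occur at a few percent, so zero
cells are routine. The policy is fixed and explicit:

- a table with zero events in **both** arms carries no information about a
  ratio measure and is excluded from pooling (the exclusion count is
  reported on every pooled estimate);
- a table with a zero in **exactly one** arm stays in; for the
  inverse-variance routes a continuity correction (default `cc = 0.5`,
  configurable) is added to all four cells of that table only. The
  Mantel–Haenszel and exact-conditional routes need no correction and never
  apply one.

The correction constant is exposed because published analyses rarely state
theirs; for tables without zeros it provably has no effect.

## Pooling methods

Four engines, selectable everywhere a pooled estimate is produced, so that
method choice itself can be treated as a sensitivity axis:

- **`iv_fixed`** — inverse-variance fixed effect, weights $1/v_i$, Wald CI.
- **`dl_random`** — DerSimonian–Laird: $\hat\tau^2$ by method of moments
  (truncated at zero), weights $1/(v_i+\hat\tau^2)$, Wald CI; Cochran's Q,
  $\hat\tau^2$ and $I^2$ reported. With $\hat\tau^2 = 0$ it coincides
  exactly with `iv_fixed`.
- **`mh`** — Mantel–Haenszel RR with the Greenland–Robins variance; a
  single stratum reduces exactly to the crude RR.
- **`exact_conditional`** — conditional inference on the common odds
  ratio. Each stratum's treated count, given its margins, is noncentral
  hypergeometric with noncentrality $\psi$; strata are independent given
  $\psi$, so the total follows the convolution of the stratum laws. Point
  estimate: conditional MLE. Interval: exact central CI from inverting the
  one-sided tail tests at $\alpha/2$ (level configurable, default 95 %).
  Root finding is bracketed on $\log\psi \in [-15, 15]$, which covers any
  odds ratio these count sizes can express; boundary observations (total at
  the edge of the conditional support) produce one-sided intervals with an
  open end at 0 or $\infty$, flagged as undefined CI cells in reports.
  Per-study "weights" for this method are Fisher-information shares
  (conditional variances at the MLE, normalized).

The exact method works on the odds-ratio scale — the standard exact
treatment of stratified 2×2 tables — while the others are RR-scale. At the
2–3 % risks these data occupy, OR and RR are numerically close (the test
suite checks median agreement within 5 % on synthetic sets), but reports
always carry the scale tag; the two are not interchangeable in general.

All pooled outputs are exactly invariant to the order studies are supplied
in: summations are internally sorted, and the exact engine canonicalizes
stratum order. Ratio results are kept on the log scale internally and only
back-transformed (never rounded) at the reporting layer.

### Known calibration properties

Long-run null coverage at the default synthetic conditions (k = 10 trials,
100–600 per arm, control risk 2.5 %, true RR 1) is close to but not exactly
nominal for every method: MH sits at ≈95 %, the exact interval ≈95.5–96 %
(exact central intervals are conservative by construction), and the
inverse-variance routes ≈96–97 % — DL random-effects Wald intervals
over-cover under homogeneity because a noisily estimated $\hat\tau^2 > 0$
widens them. This is a property of the estimators, not an implementation
artifact; the acceptance suite measures it directly.

## Effect measures for continuous outcomes

Standardized mean differences use the pooled SD and the Hedges small-sample
factor $J(df) = 1 - 3/(4df-1)$, variance
$(n_t+n_c)/(n_t n_c) + g^2/(2(n_t+n_c))$. The sign convention is fixed:
negative favors treatment (function indices score lower = better). Clinical
interpretation thresholds ship as named constants — a strict MCID of −0.37
and two MCII values, −0.12 and −0.20 — and `exceeds_threshold` requires
both sign agreement and magnitude at least the threshold's.

## AE classification

A classification scheme is a declarative map from AE term to
(severity, locality), with severity ∈ {serious, non_serious, not_an_AE} and
locality ∈ {joint, local_non_joint, other}; `not_an_AE` terms are excluded
from every cell. Matching is exact and case-insensitive by design — term
normalization beyond that is out of scope, and disagreement between schemes
is surfaced by `scheme_diff`, not resolved silently. Unknown terms follow
the scheme's fallback: `use_author_flag` adopts the original authors'
seriousness designation (locality defaults to "other", the systemic
bucket) with a logged warning, mirroring the convention of reviews that
defer to trial authors while keeping the gap visible; `error` refuses.
Counts are persons-with-event per term and are summed across terms within
an arm — overlapping terms can double-count persons, which matches how
trial reports present these data; the aggregate is validated against the
arm size.

## Scenario engine

A scenario is (exclusions, subgroup predicate, event deltas), applied in
that fixed order; deltas targeting a study removed earlier in the same
scenario are skipped (strict mode errors instead). Event deltas are signed
integer changes to one arm's count with a provenance label; applying a
delta list then its inverses restores the input exactly, and every ladder
row carries its full provenance. The "large, blinded trials" subgroup
predicate takes the size threshold as a parameter (default total n ≥ 200)
because published subgroup definitions rarely pin it down. Leave-one-out
reports, for each study, the pooled estimate without it alongside that
study's normalized weight in the full pooling — weights are
method-dependent, so the method tag is always attached.

The outlier-influence property test uses a treated-arm-only 3× rate
distortion at an 8 % baseline risk with MH pooling. The choice is driven by
the diagnostic's signal-to-noise arithmetic: a both-arm high-rate study is
ratio-neutral (its exclusion changes precision, not location), at 2–3 %
risks the remaining studies' sampling noise masks the pull of a single
discrepant trial, and DL deliberately dampens outliers through the inflated
$\hat\tau^2$. The test therefore demonstrates the diagnostic where an
influential, ratio-discrepant study is actually identifiable.

## Hidden-count inversion

Given observed studies, hidden studies with known arm sizes, and a
published pooled triple (point, ci_low, ci_high), the inverter searches
integer completions minimizing the weighted squared log-scale distance
between the re-pooled triple and the target, weights (2, 1, 1) by default —
the CI endpoints are matched as well as the point because both were printed.
Published values rounded to two decimals bound attainable fidelity, so a
candidate "attains" the target when each component is within 0.005;
solutions below that resolution are reported as ties (smallest total event
count first) with `unique = False`. `exhaustive` enumerates the whole grid
(refused above 10⁷ candidates); `coordinate_descent` is block-coordinate
descent over hidden studies — an exhaustive per-study block scan when the
study's grid has ≤ 4096 candidates (block updates are then globally optimal
given the rest), otherwise axis scans plus a diagonal scan along the
ratio ridge and a ±3 window polish — from a rate-matched heuristic start
plus random restarts (default 6, seeded).

## Synthetic data

The binary generator emulates the structure of the motivating trial sets:
k parallel-arm trials, per-arm sizes uniform on a range (default 100–600),
control events Binomial(n, p₀) with p₀ = 0.025 by default (the 2–3 % SAE
regime), treated events Binomial(n, p₀·RR), and optionally one
last-position outlier study with p₀ multiplied (default 3×, both arms —
a high-background trial, ≈7 % event rate, with the same generating RR).
The continuous generator draws patient-level normal outcomes at a
generating SMD (default −0.23) and summarizes them. Generators are pure
functions of their config: per-study substreams derive from the root seed
by counter, so the first k studies are identical regardless of how many
more are generated.

What the generators do **not** emulate: correlated AE categories within a
study, under-reporting and elicitation differences between trials,
non-binomial overdispersion, informative follow-up length, or multi-arm
designs. Passing simulation tests therefore establishes the *arithmetic and
calibration* of the pipeline under its own assumptions, not the real-world
behavior of trial reports.

The margin-matched fixture (`make_paper_fixture`) is explicitly synthetic:
only its aggregate totals (8 SAE studies, 27/1056 vs 16/1017; 10 NSAE
studies, 415/1645 vs 375/1564) match published margins; the per-study split
is invented, including a deliberately high-rate study (S05) for the
outlier scenarios. Its pooled outputs exercise the pipeline end to end and
are not a reproduction of any published pooled estimate.

## Problem sizes used in the acceptance script

Coverage: 1000 null replicates per method at k = 10, 100–600 per arm,
p₀ = 0.025. Parameter recovery: 500 replicates each for the SMD target
(k = 10, 80–120 per arm) and the RR target (k = 14, 100–600 per arm).
Inversion recovery: 100 replicates of 5-study sets (p₀ = 0.02, 100–500 per
arm) with one hidden study, exhaustive search over a 26×26 count grid.
These sizes give Monte-Carlo standard errors comfortably below the
tolerances the test suite asserts (e.g. ≈0.7 pp for a 95 % coverage
proportion at 1000 replicates).

## Numerical choices

- CI level 95 % everywhere, configurable per call.
- Exact-CI root finding: Brent's method on $\log\psi$, bracket [−15, 15],
  converged far below the 10⁻⁸ tail tolerance; enumeration cross-checks in
  the tests hold to 10⁻¹² (probabilities) and 10⁻⁶ (CI endpoints).
- Convolutions renormalize after each stratum to prevent drift; stratum
  pmfs are computed from log binomial coefficients with max-subtraction.
- Degenerate inputs are errors, not NaNs: empty trial sets, all-degenerate
  strata, zero pooled SD, deltas leaving counts outside [0, n].
- Tie-breaking in the inverter is total-events-then-lexicographic, making
  reported assignments deterministic.

## Limitations

- Exact inference is OR-scale; no exact RR interval is provided.
- No Peto OR, Bayesian pooling, meta-regression, or publication-bias
  diagnostics.
- The inverter assumes the published analysis used one of the implemented
  pooling methods; if the source used an unknown proprietary procedure, the
  recovered counts approximate it only as well as the chosen method does.
- Classification is term-exact; synonym handling beyond case folding is the
  caller's responsibility.
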