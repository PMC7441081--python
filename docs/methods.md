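# Methods

## The quasi-experiment

A twin delivery is treated as a random +1 shock to family size, conditional
on the parity and mother age at which it occurs. The estimand is the effect
of that shock on completed fertility. For each delivery in a family history
we record the family's total births NB (children; a twin pair counts as 2),
its children surviving to age 14 NS, a twin indicator, parity (the count of
prior *deliveries* — a twin pair advances parity by one, and the first
delivery is parity 0), the mother's age in completed years, and the interval
in months to the next delivery. The regressions are ordinary least squares
with one observation per delivery:

- **α (parametric):** outcome on the twin indicator plus a dummy per parity
  level and per mother-age year, one level dropped per block.
- **α (nonparametric):** outcome on the twin indicator plus a dummy per
  parity × age cell. This is fitted by within-cell demeaning, which by
  Frisch–Waugh–Lovell is exactly the dummy regression; cells without twin
  deliveries remain in the fixed-effect set and contribute nothing to α.
- **λ:** adds a twin × parity (numeric) regressor; λ = 0 under natural
  fertility, λ > 0 when couples hold surviving-children targets, because a
  late twin is more likely to be the last planned birth.
- **ω:** the twin coefficient with the next birth interval (months) as
  outcome, on deliveries with a recorded successor; a spacing-response
  detector.

Mother ages are pooled below 16 and above 49 into boundary bins to avoid
singleton cells. Standard errors are conventional OLS by default — matching
the source tables this design mirrors — with cluster-robust-by-family errors
available, since families contribute one row per delivery. Estimators raise
an explicit "unidentified" error (rather than returning a number) when the
twin indicator is collinear with the controls: no twin rows, no singleton
rows, or (nonparametric) no cell containing both.

Identification rests on the twin probability depending only on the
controlled covariates (age, parity): conditional on a delivery at (p, k),
the twin flag is independent of everything else about the family, so the
simulator's own twinning gradients do not bias α.

## Closed-form expectations and mixture bounds

With no parity-dependent control a twin delivery adds exactly 1 birth and
2θ_t − θ_s survivors. With complete control (target N surviving children,
attained), extra births are 2(1 − θ_t/θ_s)(1 − ϕ) + ϕ and extra survivors
ϕ(2θ_t − θ_s), with ϕ = 1/mean births, the chance the twin is the last
planned birth. An estimate α̂ between the poles gives the controller share
p̂ = (α_nc − α̂)/(α_nc − α_c), truncated to [0, 1].

The source tables for this design print one-sided confidence intervals for
the controller share without stating their formula; we implement and
document a normal-approximation linear-mixture bound — the one-sided upper
bound at confidence c is (α_nc − (α̂ − z_c·se))/(α_nc − α_c), truncated —
which is equivalent to inverting the normal test of the mixture null, and we
validate it against a Monte-Carlo test-inversion oracle in the test suite.
Reproduction of any particular printed interval is therefore not expected.
`controller_share_probability` reports the analogous normal tail mass
P(p ≤ t); since a share is bounded by 1 by definition, it returns exactly 1
at t ≥ 1. z-quantiles come from the standard normal, not Student-t, given
the sample sizes this method needs. Two closed-form notes: 2θ_t − θ_s for
survival rates 0.47/0.71 is 0.23 where the reference table prints 0.24, and
the expected same-sex ratios printed alongside R_t values do not satisfy
R_SS = 0.5 + 0.4/R_t exactly; both are rounding/input ambiguities in the
printed sources, and we follow the formulas.

## The microsimulator

Each family is stepped monthly from marriage. A susceptible wife conceives
with her current fecundability; gestation is a fixed 9 months (no
twin-specific shortening); a delivery is followed by a postpartum
non-susceptible period (normal, mean 11, sd 3 months, floor 1). Conceptions
are twin with probability `base + 0.0004·(age − 20) + 0.0006·parity`
(clipped to [0, 1]); the gradients are the single-covariate magnitudes
observed in large historical samples. Each child's survival to 14 is an
independent Bernoulli draw, θ_s for singletons and θ_t per twin — no
within-pair correlation, the simplest model consistent with a single θ_t.
Sexes are independent fair coin flips, except that a twin pair is forced
same-sex with probability min(1, 0.004/p_twin), making same-sex-forced pairs
0.4% of deliveries (≈ 0.8% of children, the roughly constant monozygotic
share) so the population same-sex ratio among twin pairs is 0.5 + 0.4/R_t at
full detection — the structure the misclassification diagnostics invert.

Exposure ends at the wife's sterility age (normal, mean 41, sd 4), at age 50,
or at the first parent's death (flat hazard 0.01/parent-year by default;
maternal death in childbirth is not modelled, and fathers do not remarry —
the default unit is the marital union). Fecundability is constant to age 28
and declines linearly to zero at the sterility age. None of these biological
parameters are observable in the printed sources; they were fixed once at
demographically conventional values, and per-preset monthly fecundability
was calibrated so that realized mean births per family (with ≥ 1 birth)
matches each sample's printed value within ±0.3 at 50,000 families
(calibrated constants are frozen in `synthetic_cohort`). Presets are
calibrated to mean births, twin rates, and survival rates only — not to
birth-interval distributions.

Controllers (a configurable fraction of couples) hold a target N ≥ 1 of
surviving children. The default stopping rule is *perfect foresight*: a
couple permanently ceases exposure once the children already born include N
eventual survivors to 14 — the variant matching the exact-attainment
algebra. A *reactive* variant instead suspends exposure while
currently-alive children ≥ N and resumes after a child death before 14
(death months uniform over the first 14 years); it attains targets later and
bears fewer births inside a bounded span. Twinning never feeds back on
timing, so under natural fertility the twin shock passes through at exactly
+1 birth.

## The complete-control validation scenario

The complete-control closed forms assume (i) targets are attained, (ii) the
marriage lasts to the end of planned births, and (iii) a twin is equally
likely at any birth position (that is how ϕ = 1/mean births enters).
`full_control_scenario` realizes these assumptions on top of a preset:
controller fraction 1, no adult mortality, marriage at 22, sterility near
45, constant fecundability to 40, targets drawn from {2, 3, 4}
(probabilities 0.3/0.4/0.3 — >99% attained), and a position-independent twin
risk at the preset's aggregate rate. Under the observational presets
instead, ~10–20% of controllers are censored before attaining and twin
deliveries overweight late (near-target) parities, pulling the estimate
toward the natural-fertility value — a genuine property of sequential
stopping, not an estimator defect.

Even under the scenario's conditions the sequential stopping rule deviates
from the closed form at second order: a twin delivery is more likely than a
singleton to complete a target (it adds two children), and completing from
the last-needed-child state can overshoot by one survivor (probability
θ_t²). At 50,000 families these deviations are below the sampling error of
the estimate; recovery is within 2 standard errors for both outcomes.

## What the generator does and does not emulate

Passing tests show that the estimators recover the twin effects implied by
the simulated data-generating process, and that the closed forms correctly
describe its two polar regimes. The generator emulates the statistical
skeleton of family-reconstitution data — delivery sequences, twinning
gradients, plurality-specific child survival, parental-survival censoring
and the 40/45 inclusion filters, twin misclassification modes — but not
marriage markets, remarriage, breastfeeding heterogeneity, economic shocks
to spacing, within-pair survival correlation, or familial twin propensity
(off by default; a per-family twin-rate multiplier is available). Results on
real reconstitution data therefore inherit only the design's identification
logic, not the simulator's clean randomization.

## Numerical choices and degenerate inputs

Within-cell demeaning uses exact bincount means; the α estimate equals the
brute-force normal-equations solution to 1e-8 relative error (tested on
tables to ~10,000 rows). Residual scale is √(SSR/dof) with dof counting all
absorbed dummies. Single-observation cells contribute zero residual and need
no special handling. Cohort CSV I/O reports malformed rows with line
numbers; deliveries must be strictly ordered in index and months. Unknown
parental death ages are `None` (never a numeric sentinel) and are treated as
survival by the default filter policy, mirroring how missing burial records
are handled in reconstitution studies. Childless families cannot be
represented in the per-delivery CSV schema and are dropped on write;
mean-births statistics are defined over families with ≥ 1 birth throughout.
The implied twin-detection fraction (R_SS inversion) may exceed 1 under
sampling noise; it is reported with a warning, not clamped.

## Problem sizes

Validation experiments use 50,000 families (≈ 290,000 deliveries) for
parameter recovery — chosen so the α standard error (~0.04) is small against
the gap between the regimes (~0.5) — with smaller cohorts (1,500–40,000
families) for module-level behaviour, and 10⁴ replications for the
familial-repetition Monte Carlo.
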