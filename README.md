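# twinstest

**A twin-birth quasi-experiment for detecting parity-dependent fertility
control in historical populations.**

Whether pre-transition couples held target family sizes — practicing
*parity-specific* fertility control (stopping or spacing in response to the
number of children already born) — is a long-standing open question in
historical demography, usually attacked with aggregate age-pattern indices
that rest on untested reference populations. The twin test sidesteps those
assumptions: a twin delivery is an essentially random +1 shock to family
size. Under **natural fertility** the shock simply passes through — completed
births rise by exactly 1, and children surviving to age 14 rise by
2θ_t − θ_s (each twin survives with probability θ_t, the displaced singleton
with θ_s). Under **complete control** — every couple targets N surviving
children and attains it — families absorb the shock, and births rise by only

```
α_b = 2 (1 − θ_t / θ_s) (1 − ϕ) + ϕ ,     α_c = ϕ (2 θ_t − θ_s) ,
```

where ϕ, the fraction of births that are the family's last planned birth, is
the reciprocal of mean completed family size. An estimated twin effect
between the two poles bounds the population share of controllers through the
linear mixture α = (1 − p) α_nc + p α_c.

The package is aimed at historical demographers and economic historians
working with family-reconstitution or genealogical birth histories. It
provides:

- `synthetic_cohort` — a monthly-step microsimulator of marital fertility
  (fecundability, sterility, postpartum non-susceptibility, twinning with
  age/parity gradients, survival to 14, optional target-holding couples),
  with presets emulating six classic samples (Henry France, CAMPOP and FOE
  England, Québec);
- `cohort_model` — the per-delivery analysis table, parental-survival
  inclusion filters, and a documented cohort CSV schema;
- `twin_estimators` — scikit-learn-style OLS estimators of the twin effect
  α on births/survivors (additive or fully interacted parity × mother-age
  controls), the twin × parity interaction λ, and the post-twin birth
  interval ω;
- `control_theory` — the closed-form expected effects, ϕ, and
  normal-approximation mixture bounds on the controller share;
- `data_diagnostics` — the same-sex-ratio test for twin misclassification
  (R_SS = 0.5 + 0.4/R_t), familial twin-repetition simulation, and
  twinning-correlate regressions;
- a `twinstest` CLI (`simulate`, `estimate`, `diagnose`, `theory`, `run`).

## Worked example

Simulate a natural-fertility cohort under the England pre-1880 regime,
filter to near-complete reproductive histories, and estimate the twin
effects:

```python
import twinstest as tt
from twinstest.control_theory import (
    TheoryParams, expected_extra_births, controller_share_bound,
)

cfg = tt.scenario_presets("england_pre1880", n_families=20_000, seed=3)
families = tt.simulate_cohort(cfg)
kept = tt.apply_filters(families, tt.FilterPolicy(unit="union"))
table = tt.build_analysis_table(kept)

alpha_b = tt.estimate_twin_effect(table, "births", "parametric")
alpha_c = tt.estimate_twin_effect(table, "survivors", "parametric")
summary = tt.cohort_summary(kept)
params = TheoryParams.from_summary(summary)
alpha_b_full = expected_extra_births(params, "full_control")
bound = controller_share_bound(
    alpha_b.coefficient, alpha_b.std_error, 1.0, alpha_b_full
)

print(f"families kept          : {summary['n_families_with_birth']}")
print(f"mean births per family : {summary['mean_births']:.2f}")
print(f"alpha_b (births)       : {alpha_b.coefficient:.3f} "
      f"(SE {alpha_b.std_error:.3f}, N {alpha_b.n_obs})")
print(f"alpha_c (survivors)    : {alpha_c.coefficient:.3f} (SE {alpha_c.std_error:.3f})")
print(f"expected alpha_b       : 1.00 (no control), {alpha_b_full:.2f} (complete control)")
print(f"controller share       : <= {bound.upper:.2f} (one-sided 95%)")
```

Output (printed from this exact run):

```
families kept          : 14307
mean births per family : 6.70
alpha_b (births)       : 1.034 (SE 0.052, N 95028)
alpha_c (survivors)    : 0.473 (SE 0.057)
expected alpha_b       : 1.00 (no control), 0.43 (complete control)
controller share       : <= 0.09 (one-sided 95%)
```

Reading: a twin delivery raised completed births by 1.03 ± 0.05 — squarely
the natural-fertility prediction of 1, far from the 0.43 expected if every
couple held a surviving-children target — and the mixture bound says at most
9% of couples could have been controllers at 95% confidence. The survivor
effect 0.47 likewise matches the no-control prediction 2θ_t − θ_s = 0.45.
The same analysis on a cohort simulated with `controller_fraction=1`
recovers the complete-control expectations instead.

The same pipeline runs from the shell:

```sh
twinstest run --preset england_pre1880 --n 20000 --seed 3 -o out/
twinstest theory --preset quebec
```

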