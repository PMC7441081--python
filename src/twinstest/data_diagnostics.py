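"""Data-quality and randomness diagnostics for twin attributions.

Historical twin labels are error-prone (same-day baptisms of non-twins, missed
twin pairs).  Because monozygotic pairs are always same-sex and occur at a
roughly constant 0.8% of births, the same-sex fraction among *true* twin pairs
is ``0.5 + 0.4 / R_t`` where ``R_t`` is the twinning rate per 100 births
(twin children / births).  A same-sex fraction below that expectation implies
a detection/validity fraction ``phi_det < 1``; misattributed singletons bias
the estimated twin effect toward zero, i.e. toward a spurious finding of
fertility control.

Also here: a random-allocation simulation of repeated twinning within the same
family (with its exact binomial expectation), single-covariate twinning
correlate regressions, and utilities that plant the two misclassification
modes in a simulated cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_cohort import Delivery, FamilyHistory

__all__ = [
    "TwinQuality",
    "same_sex_diagnostic",
    "familial_repetition",
    "twinning_correlates",
    "plant_false_twins",
    "hide_true_twins",
]


@dataclass(frozen=True)
class TwinQuality:
    """Same-sex-ratio diagnostic of twin-label quality.

    R_t: twin children per 100 births; R_ss_observed: same-sex fraction among
    twin pairs; R_ss_expected: ``0.5 + 0.4 / R_t`` at full detection;
    phi_det: implied detection/validity fraction (may exceed 1 with sampling
    noise, reported with a warning rather than clamped).
    """

    R_t: float
    R_ss_observed: float
    R_ss_expected: float
    phi_det: float
    n_twin_pairs: int
    n_births: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.R_ss_observed <= 1.0:
            raise ValueError("R_ss_observed must be in [0, 1]")
        if self.R_t <= 0:
            raise ValueError("R_t must be positive for the expected-ratio computation")


def expected_same_sex_ratio(R_t: float, phi_det: float = 1.0) -> float:
    """Expected same-sex fraction among labelled twin pairs: 0.5 + (0.4/R_t) phi."""
    if R_t <= 0:
        raise ValueError(f"R_t must be positive, got {R_t}")
    return 0.5 + (0.4 / R_t) * phi_det


def same_sex_diagnostic(families: Iterable[FamilyHistory]) -> TwinQuality:
    """Compute the same-sex-ratio quality diagnostic for a cohort."""
    n_births = 0
    n_pairs = 0
    n_same = 0
    for fam in families:
        for d in fam.deliveries:
            n_births += d.n_children
            if d.n_children == 2:
                n_pairs += 1
                n_same += int(d.sexes[0] == d.sexes[1])
    if n_pairs == 0:
        raise ValueError("no twin deliveries with recorded sexes in cohort")
    R_t = 100.0 * 2 * n_pairs / n_births
    r_obs = n_same / n_pairs
    phi_det = (r_obs - 0.5) * R_t / 0.4
    if phi_det > 1.0:
        warnings.warn(
            f"implied detection fraction {phi_det:.3f} > 1 (same-sex ratio above the "
            "full-detection expectation): sampling noise or an R_t mismatch",
            stacklevel=2,
        )
    return TwinQuality(
        R_t=R_t,
        R_ss_observed=r_obs,
        R_ss_expected=expected_same_sex_ratio(R_t),
        phi_det=phi_det,
        n_twin_pairs=n_pairs,
        n_births=n_births,
    )


def familial_repetition(
    deliveries_per_family: Sequence[int],
    twin_rate: float,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Random allocation of twin deliveries across families.

    Allocates a twin flag independently to every delivery at the observed rate
    and counts families with >= 2 twin deliveries, returning the Monte-Carlo
    mean and standard error over ``n_reps`` replications together with the
    exact expectation ``sum_f P(Binomial(n_f, rate) >= 2)``.  A repeat count in
    real data far above the expectation would signal a familial twinning
    propensity; in historical samples the excess is slight.
    """
    counts = np.asarray(deliveries_per_family, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("empty family list")
    if (counts < 0).any():
        raise ValueError("delivery counts must be nonnegative")
    if not 0.0 <= twin_rate <= 1.0:
        raise ValueError(f"twin_rate must be in [0, 1], got {twin_rate}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    repeats = np.empty(n_reps, dtype=np.int64)
    chunk = max(1, 10_000_000 // max(1, counts.size))
    done = 0
    while done < n_reps:
        k = min(chunk, n_reps - done)
        twins = rng.binomial(counts, twin_rate, size=(k, counts.size))
        repeats[done : done + k] = (twins >= 2).sum(axis=1)
        done += k
    # exact: P(Bin(n, p) >= 2) = 1 - (1-p)^n - n p (1-p)^(n-1)
    q = 1.0 - twin_rate
    p_ge2 = 1.0 - q**counts - counts * twin_rate * np.where(counts > 0, q ** (counts - 1), 0.0)
    return {
        "mc_mean": float(repeats.mean()),
        "mc_se": float(repeats.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0,
        "mc_sd": float(repeats.std(ddof=1)) if n_reps > 1 else 0.0,
        "exact_mean": float(p_ge2.sum()),
        "n_reps": n_reps,
    }


def twinning_correlates(table: pd.DataFrame, covariate: str) -> tuple[float, float]:
    """Linear-probability regression of the twin indicator on one covariate.

    Returns ``(coefficient, conventional standard error)``; the table must
    contain a ``dtwin`` column and the covariate must vary.
    """
    if covariate not in table.columns:
        raise ValueError(f"covariate {covariate!r} not in table")
    x = table[covariate].to_numpy(dtype=float)
    y = table["dtwin"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    if y.sum() == 0:
        raise ValueError("no twin deliveries in table")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.bse[1])


def plant_false_twins(
    families: Iterable[FamilyHistory], n_fake: int, seed: int | None = None
) -> list[FamilyHistory]:
    """Merge random pairs of consecutive singleton deliveries into fake "twin"
    deliveries — the same-day-baptism misattribution mode.

    The merged delivery keeps the first delivery's timing and carries both
    children's sexes and survival flags; subsequent parities shift down by one.
    Family totals (births, survivors) are unchanged, but the fake pair adds no
    extra birth, biasing the estimated twin effect toward zero, and its sexes
    are independent, diluting the same-sex ratio.
    """
    families = [_copy_family(f) for f in families]
    rng = np.random.default_rng(seed)
    candidates = [
        (fi, di)
        for fi, fam in enumerate(families)
        for di in range(len(fam.deliveries) - 1)
        if fam.deliveries[di].n_children == 1 and fam.deliveries[di + 1].n_children == 1
    ]
    if n_fake > len(candidates):
        raise ValueError(f"requested {n_fake} fake twins but only {len(candidates)} singleton pairs")
    chosen: dict[int, list[int]] = {}
    used: set[tuple[int, int]] = set()
    order = rng.permutation(len(candidates))
    picked = 0
    for j in order:
        if picked == n_fake:
            break
        fi, di = candidates[j]
        if (fi, di) in used or (fi, di + 1) in used or (fi, di - 1) in used:
            continue
        used.add((fi, di))
        chosen.setdefault(fi, []).append(di)
        picked += 1
    for fi, dis in chosen.items():
        fam = families[fi]
        for di in sorted(dis, reverse=True):
            a, b = fam.deliveries[di], fam.deliveries[di + 1]
            merged = Delivery(
                delivery_index=a.delivery_index,
                mother_age=a.mother_age,
                months_since_marriage=a.months_since_marriage,
                n_children=2,
                sexes=(a.sexes[0], b.sexes[0]),
                survives_to_14=(a.survives_to_14[0], b.survives_to_14[0]),
            )
            fam.deliveries[di : di + 2] = [merged]
        _reindex(fam)
    return families


def hide_true_twins(
    families: Iterable[FamilyHistory], fraction: float, seed: int | None = None
) -> list[FamilyHistory]:
    """Record a random fraction of true twin deliveries as two singleton
    deliveries one month apart — the missed-twin misclassification mode."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    families = [_copy_family(f) for f in families]
    rng = np.random.default_rng(seed)
    for fam in families:
        out: list[Delivery] = []
        for d in fam.deliveries:
            if d.n_children == 2 and rng.random() < fraction:
                out.append(
                    Delivery(
                        delivery_index=0,
                        mother_age=d.mother_age,
                        months_since_marriage=d.months_since_marriage,
                        n_children=1,
                        sexes=(d.sexes[0],),
                        survives_to_14=(d.survives_to_14[0],),
                    )
                )
                out.append(
                    Delivery(
                        delivery_index=0,
                        mother_age=d.mother_age,
                        months_since_marriage=d.months_since_marriage + 1,
                        n_children=1,
                        sexes=(d.sexes[1],),
                        survives_to_14=(d.survives_to_14[1],),
                    )
                )
            else:
                out.append(d)
        fam.deliveries = out
        _reindex(fam)
    return families


def _copy_family(fam: FamilyHistory) -> FamilyHistory:
    return replace(fam, deliveries=list(fam.deliveries))


def _reindex(fam: FamilyHistory) -> None:
    fam.deliveries = [replace(d, delivery_index=i) for i, d in enumerate(fam.deliveries)]
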