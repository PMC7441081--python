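"""Closed-form expected twin effects and mixture bounds on the controller share.

Under *no* parity-dependent control a twin delivery raises completed births by
exactly 1 and surviving children by ``2*theta_t - theta_s`` (each twin survives
to 14 with probability theta_t, the displaced singleton with theta_s).  Under
*complete* control — every couple holds a target number of surviving children
and attains it — the extra births are::

    2 * (1 - theta_t / theta_s) * (1 - phi) + phi

and the extra survivors ``phi * (2*theta_t - theta_s)``, where phi is the
fraction of births that are the last planned birth, approximated by the
reciprocal of mean completed births.

An estimated twin effect from a population mixing the two regimes is, to first
order, the linear mixture ``alpha = (1 - p) * alpha_nc + p * alpha_c`` of the
two poles, so a point estimate with a normal standard error yields a
normal-approximation confidence bound on the controller share p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import stats

__all__ = [
    "TheoryParams",
    "MixtureInterval",
    "expected_extra_births",
    "expected_extra_survivors",
    "last_birth_fraction",
    "controller_share_bound",
    "controller_share_probability",
]


@dataclass(frozen=True)
class TheoryParams:
    """Population parameters entering the expected-value formulas.

    theta_s, theta_t: survival-to-14 probabilities of singletons and twins.
    phi: fraction of births that are the last planned birth; if omitted it is
    computed as ``1 / mean_births``.
    """

    theta_s: float
    theta_t: float
    phi: Optional[float] = None
    mean_births: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("theta_s", "theta_t"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.phi is None and self.mean_births is None:
            raise ValueError("provide phi or mean_births")
        if self.phi is None:
            object.__setattr__(self, "phi", last_birth_fraction(self.mean_births))
        if not 0.0 < self.phi <= 1.0:
            raise ValueError(f"phi must be in (0, 1], got {self.phi}")
        if self.mean_births is not None and self.mean_births < 1:
            raise ValueError(f"mean_births must be >= 1, got {self.mean_births}")

    @classmethod
    def from_summary(cls, summary: dict) -> "TheoryParams":
        """Build parameters from a cohort summary (``cohort_summary``)."""
        return cls(
            theta_s=summary["theta_s_hat"],
            theta_t=summary["theta_t_hat"],
            mean_births=summary["mean_births"],
        )


@dataclass(frozen=True)
class MixtureInterval:
    """A confidence interval for the population share of controllers."""

    lower: float
    upper: float
    confidence: float
    side: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(f"need 0 <= lower <= upper <= 1, got [{self.lower}, {self.upper}]")
        if self.side not in ("one_sided_upper", "two_sided"):
            raise ValueError(f"side must be one_sided_upper or two_sided, got {self.side!r}")


def last_birth_fraction(mean_births: float) -> float:
    """Fraction of births that are the last planned birth: 1 / mean births."""
    if mean_births < 1:
        raise ValueError(f"mean_births must be >= 1, got {mean_births}")
    return 1.0 / mean_births


def expected_extra_births(params: TheoryParams, regime: str) -> float:
    """Expected extra completed births caused by a twin delivery."""
    if regime == "no_control":
        return 1.0
    if regime == "full_control":
        if params.theta_s == 0:
            raise ValueError("theta_s must be positive under full control")
        return 2.0 * (1.0 - params.theta_t / params.theta_s) * (1.0 - params.phi) + params.phi
    raise ValueError(f"regime must be 'no_control' or 'full_control', got {regime!r}")


def expected_extra_survivors(params: TheoryParams, regime: str) -> float:
    """Expected extra children surviving to 14 caused by a twin delivery.

    May be negative when theta_t < theta_s / 2 (the surviving twins replace a
    higher-survival singleton).
    """
    base = 2.0 * params.theta_t - params.theta_s
    if regime == "no_control":
        return base
    if regime == "full_control":
        return params.phi * base
    raise ValueError(f"regime must be 'no_control' or 'full_control', got {regime!r}")


def _share_point(alpha_hat: float, alpha_nc: float, alpha_c: float) -> float:
    return (alpha_nc - alpha_hat) / (alpha_nc - alpha_c)


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def controller_share_bound(
    alpha_hat: float,
    se: float,
    alpha_nc: float,
    alpha_c: float,
    confidence: float = 0.95,
    side: str = "one_sided_upper",
) -> MixtureInterval:
    """Normal-approximation mixture bound on the controller share.

    The point share is ``(alpha_nc - alpha_hat) / (alpha_nc - alpha_c)``
    truncated to [0, 1].  The one-sided upper bound at confidence c shifts
    alpha_hat down by ``z_c * se`` before inverting; the two-sided interval
    shifts both ways at ``z_{(1+c)/2}``.  This is equivalent to inverting the
    normal test of ``alpha(p) = (1-p) alpha_nc + p alpha_c`` against the
    observed estimate.
    """
    if alpha_nc == alpha_c:
        raise ValueError("alpha_nc and alpha_c must differ (mixture unidentified)")
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if side == "one_sided_upper":
        z = stats.norm.ppf(confidence)
        lower = 0.0
        upper = _clip01(_share_point(alpha_hat - z * se, alpha_nc, alpha_c))
    elif side == "two_sided":
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        a = _share_point(alpha_hat - z * se, alpha_nc, alpha_c)
        b = _share_point(alpha_hat + z * se, alpha_nc, alpha_c)
        lower, upper = _clip01(min(a, b)), _clip01(max(a, b))
    else:
        raise ValueError(f"side must be one_sided_upper or two_sided, got {side!r}")
    return MixtureInterval(lower=lower, upper=upper, confidence=confidence, side=side)


def controller_share_probability(
    alpha_hat: float,
    se: float,
    alpha_nc: float,
    alpha_c: float,
    threshold: float,
) -> float:
    """Normal-approximation probability that the controller share is <= threshold.

    Treats alpha_hat as normal with the given standard error around the
    mixture value ``(1-p) alpha_nc + p alpha_c``; a share is in [0, 1] by
    definition, so the probability is exactly 1 at threshold >= 1.
    """
    if alpha_nc == alpha_c:
        raise ValueError("alpha_nc and alpha_c must differ (mixture unidentified)")
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if threshold >= 1.0:
        return 1.0
    boundary = alpha_nc - threshold * (alpha_nc - alpha_c)
    if alpha_nc > alpha_c:
        return float(1.0 - stats.norm.cdf((boundary - alpha_hat) / se))
    return float(stats.norm.cdf((boundary - alpha_hat) / se))
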