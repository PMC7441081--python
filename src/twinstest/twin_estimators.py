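"""Least-squares estimators of the twin effect on completed fertility.

All estimators regress a family-level outcome observed per delivery (total
births, surviving children, or the next birth interval) on a twin indicator
plus indicator controls for parity and integer mother age:

* parametric: additive parity and mother-age dummy blocks;
* nonparametric: a dummy per parity x mother-age cell (absorbed by within-cell
  demeaning, which is exactly equivalent by Frisch-Waugh-Lovell);
* parity interaction: adds a ``dtwin * parity`` regressor whose coefficient
  (lambda) should be zero under natural fertility and positive when couples
  hold surviving-children targets;
* post-twin interval: the twin coefficient (omega, months) on the interval to
  the next delivery, a detector of a spacing response to twinning.

Classes follow scikit-learn conventions (`fit`, fitted attributes with a
trailing underscore, `get_params`/`set_params`); the module-level functions
are thin wrappers over them.  Mother ages are pooled below 16 and above 49
into boundary bins.  Standard errors are conventional OLS by default;
cluster-robust-by-family errors are available because families contribute one
row per delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "UnidentifiedError",
    "TwinEffectEstimate",
    "TwinEffectRegression",
    "ParityInteractionRegression",
    "PostTwinIntervalRegression",
    "estimate_twin_effect",
    "estimate_parity_interaction",
    "estimate_post_twin_interval",
    "parity_profile",
]

AGE_MIN, AGE_MAX = 16, 49

_OUTCOME_COLS = {"births": "nb", "survivors": "ns", "interval": "next_interval_months"}


class UnidentifiedError(ValueError):
    """The twin coefficient is not identified on this table (e.g. no twin
    rows, no singleton rows, or the indicator is collinear with the controls)."""


@dataclass(frozen=True)
class TwinEffectEstimate:
    """A fitted twin-effect coefficient (alpha, lambda, or omega)."""

    coefficient: float
    std_error: float
    n_obs: int
    outcome: str
    variant: str
    nuisance: dict[str, float] = field(default_factory=dict, repr=False)
    residual_scale: float = float("nan")

    def __post_init__(self) -> None:
        if self.std_error < 0:
            raise ValueError("std_error must be nonnegative")

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.coefficient - 1.96 * self.std_error, self.coefficient + 1.96 * self.std_error)


def _require_columns(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    needed = {"dtwin", "parity", "mother_age", _OUTCOME_COLS[outcome]}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"analysis table is missing columns: {sorted(missing)}")
    if outcome == "interval":
        table = table[table["next_interval_months"].notna()]
    if len(table) == 0:
        raise UnidentifiedError("empty analysis table")
    return table


def _check_twin_variation(table: pd.DataFrame) -> None:
    n_twin = int((table["dtwin"] == 1).sum())
    if n_twin == 0:
        raise UnidentifiedError("no twin deliveries in table: twin effect unidentified")
    if n_twin == len(table):
        raise UnidentifiedError("no singleton deliveries in table: twin effect unidentified")


def _age_bin(age: np.ndarray) -> np.ndarray:
    return np.clip(age, AGE_MIN, AGE_MAX)


def _dummy_block(values: np.ndarray, prefix: str) -> tuple[list[np.ndarray], list[str]]:
    levels = np.sort(np.unique(values))
    cols = [(values == lv).astype(float) for lv in levels[1:]]
    names = [f"{prefix}_{lv}" for lv in levels[1:]]
    return cols, names


def _parametric_design(
    table: pd.DataFrame, interaction: bool
) -> tuple[pd.DataFrame, list[str]]:
    parity = table["parity"].to_numpy()
    age = _age_bin(table["mother_age"].to_numpy())
    dtwin = table["dtwin"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(table)), "dtwin": dtwin}
    focal = ["dtwin"]
    if interaction:
        cols["dtwin_x_parity"] = dtwin * parity
        focal.append("dtwin_x_parity")
    for block, prefix in ((parity, "parity"), (age, "age")):
        bcols, bnames = _dummy_block(block, prefix)
        for name, col in zip(bnames, bcols):
            cols[name] = col
    return pd.DataFrame(cols, index=table.index), focal


def _check_identified(X: pd.DataFrame, focal: list[str]) -> None:
    """Focal regressors must not be collinear with the control block."""
    controls = X.drop(columns=focal).to_numpy()
    for name in focal:
        y = X[name].to_numpy()
        beta, *_ = np.linalg.lstsq(controls, y, rcond=None)
        resid = y - controls @ beta
        if float(resid @ resid) <= 1e-9 * max(1.0, float(y @ y)):
            raise UnidentifiedError(f"regressor {name!r} is collinear with the parity/age controls")


def _ols(
    y: np.ndarray, X: pd.DataFrame, cluster: Optional[np.ndarray]
) -> sm.regression.linear_model.RegressionResultsWrapper:
    model = sm.OLS(y, X)
    if cluster is not None:
        return model.fit(cov_type="cluster", cov_kwds={"groups": cluster})
    return model.fit()


def _nonparametric_alpha(
    table: pd.DataFrame, ycol: str, cluster: bool
) -> tuple[float, float, int, float, int]:
    """Within parity x age cell demeaning; exact FWL equivalent of a dummy per cell."""
    y = table[ycol].to_numpy(dtype=float)
    d = table["dtwin"].to_numpy(dtype=float)
    cells = pd.MultiIndex.from_arrays(
        [table["parity"].to_numpy(), _age_bin(table["mother_age"].to_numpy())]
    )
    codes, _ = pd.factorize(cells)
    n_cells = int(codes.max()) + 1
    counts = np.bincount(codes)
    y_t = y - (np.bincount(codes, weights=y) / counts)[codes]
    d_t = d - (np.bincount(codes, weights=d) / counts)[codes]
    ssd = float(d_t @ d_t)
    if ssd <= 1e-9:
        raise UnidentifiedError(
            "no parity x mother-age cell contains both twin and singleton deliveries"
        )
    alpha = float(d_t @ y_t) / ssd
    resid = y_t - alpha * d_t
    n = len(y)
    dof = n - n_cells - 1
    if dof <= 0:
        raise UnidentifiedError("more coefficients than observations")
    ssr = float(resid @ resid)
    if cluster:
        groups, _ = pd.factorize(table["family_id"].to_numpy())
        scores = np.bincount(groups, weights=d_t * resid)
        g = len(scores)
        meat = float(scores @ scores) * g / max(g - 1, 1)
        se = float(np.sqrt(meat) / ssd)
    else:
        se = float(np.sqrt(ssr / dof / ssd))
    return alpha, se, n, np.sqrt(ssr / dof), n_cells


class _TableRegression(BaseEstimator):
    """Shared fitting machinery; subclasses fix the outcome/variant semantics."""

    def _fit_parametric(
        self, table: pd.DataFrame, ycol: str, interaction: bool, cluster: bool
    ) -> sm.regression.linear_model.RegressionResultsWrapper:
        X, focal = self._design_cache = _parametric_design(table, interaction)
        _check_identified(X, focal)
        groups = pd.factorize(table["family_id"].to_numpy())[0] if cluster else None
        y = table[ycol].to_numpy(dtype=float)
        return _ols(y, X, groups)

    @staticmethod
    def _estimate_from_fit(res, name: str, outcome: str, variant: str) -> TwinEffectEstimate:
        nuisance = {
            k: float(v)
            for k, v in res.params.items()
            if k not in ("dtwin", "dtwin_x_parity")
        }
        scale = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
        return TwinEffectEstimate(
            coefficient=float(res.params[name]),
            std_error=float(res.bse[name]),
            n_obs=int(res.nobs),
            outcome=outcome,
            variant=variant,
            nuisance=nuisance,
            residual_scale=scale,
        )


class TwinEffectRegression(_TableRegression):
    """Estimate alpha, the effect of a twin delivery on completed fertility.

    Parameters
    ----------
    outcome : {'births', 'survivors'}
        Family total births (alpha_b) or children surviving to 14 (alpha_c).
    variant : {'parametric', 'nonparametric'}
        Additive parity + age dummies, or a dummy per parity x age cell.
    cluster : bool
        Cluster standard errors by family instead of conventional OLS errors.
    """

    def __init__(self, outcome: str = "births", variant: str = "parametric", cluster: bool = False):
        self.outcome = outcome
        self.variant = variant
        self.cluster = cluster

    def fit(self, table: pd.DataFrame, y=None) -> "TwinEffectRegression":
        if self.outcome not in ("births", "survivors"):
            raise ValueError(f"outcome must be 'births' or 'survivors', got {self.outcome!r}")
        if self.variant not in ("parametric", "nonparametric"):
            raise ValueError(f"variant must be 'parametric' or 'nonparametric', got {self.variant!r}")
        table = _require_columns(table, self.outcome)
        _check_twin_variation(table)
        ycol = _OUTCOME_COLS[self.outcome]
        if self.variant == "parametric":
            res = self._fit_parametric(table, ycol, interaction=False, cluster=self.cluster)
            self.estimate_ = self._estimate_from_fit(res, "dtwin", self.outcome, self.variant)
        else:
            alpha, se, n, scale, n_cells = _nonparametric_alpha(table, ycol, self.cluster)
            self.estimate_ = TwinEffectEstimate(
                coefficient=alpha,
                std_error=se,
                n_obs=n,
                outcome=self.outcome,
                variant=self.variant,
                nuisance={"n_cells": float(n_cells)},
                residual_scale=float(scale),
            )
        self.coefficient_ = self.estimate_.coefficient
        self.std_error_ = self.estimate_.std_error
        self.n_obs_ = self.estimate_.n_obs
        return self


class ParityInteractionRegression(_TableRegression):
    """Estimate (alpha, lambda): the twin effect and its trend in parity.

    Under natural fertility lambda = 0; with surviving-children targets the
    twin effect grows with the parity at which the twin birth occurs.
    """

    def __init__(self, outcome: str = "births", cluster: bool = False):
        self.outcome = outcome
        self.cluster = cluster

    def fit(self, table: pd.DataFrame, y=None) -> "ParityInteractionRegression":
        if self.outcome not in ("births", "survivors"):
            raise ValueError(f"outcome must be 'births' or 'survivors', got {self.outcome!r}")
        table = _require_columns(table, self.outcome)
        _check_twin_variation(table)
        if table.loc[table["dtwin"] == 1, "parity"].nunique() < 2:
            raise UnidentifiedError("all twin deliveries occur at a single parity: lambda unidentified")
        ycol = _OUTCOME_COLS[self.outcome]
        res = self._fit_parametric(table, ycol, interaction=True, cluster=self.cluster)
        self.alpha_ = self._estimate_from_fit(res, "dtwin", self.outcome, "parity_interaction")
        self.lambda_ = self._estimate_from_fit(res, "dtwin_x_parity", self.outcome, "parity_interaction")
        return self


class PostTwinIntervalRegression(_TableRegression):
    """Estimate omega, the twin effect on the interval to the next delivery
    (months).  A positive omega signals a post-twin spacing response; only
    deliveries with a recorded successor enter the fit."""

    def __init__(self, cluster: bool = False):
        self.cluster = cluster

    def fit(self, table: pd.DataFrame, y=None) -> "PostTwinIntervalRegression":
        table = _require_columns(table, "interval")
        n_twin = int((table["dtwin"] == 1).sum())
        if n_twin == 0:
            raise UnidentifiedError("no twin delivery with a following delivery: omega unidentified")
        _check_twin_variation(table)
        res = self._fit_parametric(table, "next_interval_months", interaction=False, cluster=self.cluster)
        self.estimate_ = self._estimate_from_fit(res, "dtwin", "interval", "parametric")
        self.coefficient_ = self.estimate_.coefficient
        self.std_error_ = self.estimate_.std_error
        self.n_obs_ = self.estimate_.n_obs
        return self


def estimate_twin_effect(
    table: pd.DataFrame,
    outcome: str = "births",
    variant: str = "parametric",
    cluster: bool = False,
) -> TwinEffectEstimate:
    """Fit the twin-effect regression and return the alpha estimate."""
    return TwinEffectRegression(outcome=outcome, variant=variant, cluster=cluster).fit(table).estimate_


def estimate_parity_interaction(
    table: pd.DataFrame, outcome: str = "births", cluster: bool = False
) -> tuple[TwinEffectEstimate, TwinEffectEstimate]:
    """Fit the parity-interaction regression; returns (alpha, lambda)."""
    m = ParityInteractionRegression(outcome=outcome, cluster=cluster).fit(table)
    return m.alpha_, m.lambda_


def estimate_post_twin_interval(table: pd.DataFrame, cluster: bool = False) -> TwinEffectEstimate:
    """Fit the post-twin birth-interval regression; returns omega (months)."""
    return PostTwinIntervalRegression(cluster=cluster).fit(table).estimate_


def parity_profile(table: pd.DataFrame, outcome: str = "births") -> pd.DataFrame:
    """Mean outcome for twin vs. singleton deliveries at each parity.

    Returns one row per parity that has at least one twin delivery, with twin
    and singleton means, counts, and the twin-singleton gap.
    """
    table = _require_columns(table, outcome)
    ycol = _OUTCOME_COLS[outcome]
    rows = []
    for parity, grp in table.groupby("parity"):
        twin = grp.loc[grp["dtwin"] == 1, ycol]
        single = grp.loc[grp["dtwin"] == 0, ycol]
        if len(twin) == 0:
            continue
        mt = float(twin.mean())
        ms = float(single.mean()) if len(single) else float("nan")
        rows.append(
            {
                "parity": int(parity),
                "mean_twin": mt,
                "mean_singleton": ms,
                "n_twin": int(len(twin)),
                "n_singleton": int(len(single)),
                "gap": mt - ms,
            }
        )
    return pd.DataFrame(rows, columns=["parity", "mean_twin", "mean_singleton", "n_twin", "n_singleton", "gap"])
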