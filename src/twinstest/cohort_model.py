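"""Cohort data model: CSV I/O, sample-inclusion filters, analysis table.

The per-delivery analysis table is the flat container all estimators consume:
one row per delivery carrying the family-level outcomes (total births NB,
children surviving to 14 NS), the twin indicator, parity (count of prior
deliveries — a twin pair advances parity by one), integer mother age, and the
interval in months to the following delivery (missing for the last one).

The cohort CSV schema is one line per delivery with columns::

    family_id, unit, delivery_index, mother_age, months_since_marriage,
    n_children, sex_1, sex_2, survives_1, survives_2,
    mother_age_at_death, father_age_at_death

``sex_2``/``survives_2`` and unknown death ages are blank.  Families with zero
deliveries have no representation in this schema and are dropped on write.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .synthetic_cohort import Delivery, FamilyHistory

__all__ = [
    "FilterPolicy",
    "apply_filters",
    "build_analysis_table",
    "cohort_summary",
    "read_cohort_csv",
    "write_cohort_csv",
    "CSV_COLUMNS",
]

CSV_COLUMNS = [
    "family_id",
    "unit",
    "delivery_index",
    "mother_age",
    "months_since_marriage",
    "n_children",
    "sex_1",
    "sex_2",
    "survives_1",
    "survives_2",
    "mother_age_at_death",
    "father_age_at_death",
]

TABLE_COLUMNS = ["family_id", "dtwin", "parity", "mother_age", "nb", "ns", "next_interval_months"]


@dataclass(frozen=True)
class FilterPolicy:
    """Sample-inclusion rule approximating complete reproductive spans.

    Families are excluded when the unit-relevant parent is *known* to have died
    before the threshold (40 for mothers, 45 for fathers); unknown death ages
    are treated as survival when ``treat_unknown_death_as_survival``.  With
    ``unit='union'`` both parents are checked; with ``unit='father'`` or
    ``'mother'`` only that parent.
    """

    mother_min_age: float = 40.0
    father_min_age: float = 45.0
    unit: str = "union"
    treat_unknown_death_as_survival: bool = True

    def __post_init__(self) -> None:
        if self.mother_min_age <= 0 or self.father_min_age <= 0:
            raise ValueError("filter ages must be positive")
        if self.unit not in ("father", "mother", "union"):
            raise ValueError(f"unit must be father/mother/union, got {self.unit!r}")

    def keeps(self, family: FamilyHistory) -> bool:
        def parent_ok(age_at_death: Optional[float], min_age: float) -> bool:
            if age_at_death is None:
                return self.treat_unknown_death_as_survival
            return age_at_death >= min_age

        mother_ok = parent_ok(family.mother_age_at_death, self.mother_min_age)
        father_ok = parent_ok(family.father_age_at_death, self.father_min_age)
        if self.unit == "mother":
            return mother_ok
        if self.unit == "father":
            return father_ok
        return mother_ok and father_ok


def apply_filters(families: Iterable[FamilyHistory], policy: FilterPolicy) -> list[FamilyHistory]:
    """Keep families passing the parental-survival inclusion rule."""
    return [f for f in families if policy.keeps(f)]


def build_analysis_table(families: Iterable[FamilyHistory]) -> pd.DataFrame:
    """Flatten family histories into the per-delivery analysis table.

    Returns a DataFrame with one row per delivery and columns ``family_id``,
    ``dtwin`` (0/1), ``parity`` (0-based prior-delivery count), ``mother_age``,
    ``nb`` (family total births, twins count as 2), ``ns`` (family children
    surviving to 14) and ``next_interval_months`` (NaN for last deliveries).
    """
    fam_id, dtwin, parity, age, nb, ns, nxt = [], [], [], [], [], [], []
    for fam in families:
        ds = fam.deliveries
        for a, b in zip(ds, ds[1:]):
            if b.delivery_index <= a.delivery_index or b.months_since_marriage <= a.months_since_marriage:
                raise ValueError(f"family {fam.family_id}: deliveries are not strictly ordered")
        total_b = fam.total_births
        total_s = fam.total_survivors
        for i, d in enumerate(ds):
            fam_id.append(fam.family_id)
            dtwin.append(1 if d.n_children == 2 else 0)
            parity.append(i)
            age.append(d.mother_age)
            nb.append(total_b)
            ns.append(total_s)
            nxt.append(
                float(ds[i + 1].months_since_marriage - d.months_since_marriage)
                if i + 1 < len(ds)
                else np.nan
            )
    return pd.DataFrame(
        {
            "family_id": fam_id,
            "dtwin": np.asarray(dtwin, dtype=np.int8),
            "parity": np.asarray(parity, dtype=np.int64),
            "mother_age": np.asarray(age, dtype=np.int64),
            "nb": np.asarray(nb, dtype=np.int64),
            "ns": np.asarray(ns, dtype=np.int64),
            "next_interval_months": np.asarray(nxt, dtype=float),
        }
    )


def cohort_summary(families: Iterable[FamilyHistory]) -> dict:
    """Population summary: mean births (families with >= 1 birth), survival
    rates by plurality, and the twin rate per 100 births."""
    families = list(families)
    births = [f.total_births for f in families if f.deliveries]
    n_singleton = n_singleton_surv = n_twin = n_twin_surv = 0
    twin_deliveries = 0
    for f in families:
        for d in f.deliveries:
            if d.n_children == 2:
                twin_deliveries += 1
                n_twin += 2
                n_twin_surv += d.n_survivors
            else:
                n_singleton += 1
                n_singleton_surv += d.n_survivors
    total_births = n_singleton + n_twin
    return {
        "n_families": len(families),
        "n_families_with_birth": len(births),
        "total_births": total_births,
        "twin_deliveries": twin_deliveries,
        "mean_births": float(np.mean(births)) if births else float("nan"),
        "theta_s_hat": n_singleton_surv / n_singleton if n_singleton else float("nan"),
        "theta_t_hat": n_twin_surv / n_twin if n_twin else float("nan"),
        "twin_rate_per_100_births": 100.0 * n_twin / total_births if total_births else float("nan"),
    }


def _fmt_opt(x) -> str:
    return "" if x is None else str(x)


def write_cohort_csv(families: Iterable[FamilyHistory], path) -> None:
    """Serialize a cohort, one row per delivery (childless families dropped)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for fam in families:
            for d in fam.deliveries:
                w.writerow(
                    [
                        fam.family_id,
                        fam.unit,
                        d.delivery_index,
                        d.mother_age,
                        d.months_since_marriage,
                        d.n_children,
                        d.sexes[0],
                        d.sexes[1] if d.n_children == 2 else "",
                        int(d.survives_to_14[0]),
                        int(d.survives_to_14[1]) if d.n_children == 2 else "",
                        _fmt_opt(fam.mother_age_at_death),
                        _fmt_opt(fam.father_age_at_death),
                    ]
                )


def read_cohort_csv(path) -> list[FamilyHistory]:
    """Parse a cohort CSV; malformed rows are reported with their line number."""
    families: dict[str, FamilyHistory] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != CSV_COLUMNS:
            raise ValueError(f"{path}: expected header {','.join(CSV_COLUMNS)}")
        for row in reader:
            lineno = reader.line_num
            try:
                n_children = int(row["n_children"])
                if n_children not in (1, 2):
                    raise ValueError(f"n_children must be 1 or 2, got {n_children}")
                sexes = (row["sex_1"],) if n_children == 1 else (row["sex_1"], row["sex_2"])
                if any(s not in ("M", "F") for s in sexes):
                    raise ValueError(f"sexes must be M/F, got {sexes}")
                surv = (
                    (bool(int(row["survives_1"])),)
                    if n_children == 1
                    else (bool(int(row["survives_1"])), bool(int(row["survives_2"])))
                )
                delivery = Delivery(
                    delivery_index=int(row["delivery_index"]),
                    mother_age=int(row["mother_age"]),
                    months_since_marriage=int(row["months_since_marriage"]),
                    n_children=n_children,
                    sexes=sexes,
                    survives_to_14=surv,
                )
                raw = row["family_id"]
                fid = int(raw) if raw.lstrip("-").isdigit() else raw
                if fid not in families:
                    families[fid] = FamilyHistory(
                        family_id=fid,
                        unit=row["unit"] or "union",
                        mother_age_at_death=float(row["mother_age_at_death"])
                        if row["mother_age_at_death"]
                        else None,
                        father_age_at_death=float(row["father_age_at_death"])
                        if row["father_age_at_death"]
                        else None,
                    )
                fam = families[fid]
                if fam.deliveries and (
                    delivery.delivery_index <= fam.deliveries[-1].delivery_index
                    or delivery.months_since_marriage <= fam.deliveries[-1].months_since_marriage
                ):
                    raise ValueError("deliveries out of order within family")
                fam.deliveries.append(delivery)
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return list(families.values())
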