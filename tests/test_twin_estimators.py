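"""Twin-effect regressions against brute-force oracles and exact constructions."""

import numpy as np
import pandas as pd
import pytest

from twinstest.twin_estimators import (
    ParityInteractionRegression,
    TwinEffectRegression,
    UnidentifiedError,
    estimate_parity_interaction,
    estimate_post_twin_interval,
    estimate_twin_effect,
    parity_profile,
)


def brute_force_alpha(table, ycol, variant, extra_interaction=False):
    """Normal-equations solve with an explicit dummy design (pinv)."""
    dtwin = table["dtwin"].to_numpy(dtype=float)
    age = np.clip(table["mother_age"].to_numpy(), 16, 49)
    parity = table["parity"].to_numpy()
    cols = [np.ones(len(table)), dtwin]
    if extra_interaction:
        cols.append(dtwin * parity)
    if variant == "parametric":
        for block in (parity, age):
            for lv in np.unique(block)[1:]:
                cols.append((block == lv).astype(float))
    else:
        cells = pd.MultiIndex.from_arrays([parity, age])
        codes, _ = pd.factorize(cells)
        for lv in np.unique(codes)[1:]:
            cols.append((codes == lv).astype(float))
    X = np.column_stack(cols)
    y = table[ycol].to_numpy(dtype=float)
    beta = np.linalg.pinv(X.T @ X) @ (X.T @ y)
    if extra_interaction:
        return beta[1], beta[2]
    return beta[1]


def exact_cell_difference_table(gap_at_parity=None, n_cells=6):
    """Within every parity x age cell, twin rows exceed singleton rows by a
    fixed amount (default 1)."""
    rows = []
    for parity in range(n_cells):
        for age in (24 + parity, 30 + parity):
            base = 3.0 + parity + 0.5 * (age - 24)
            gap = 1.0 if gap_at_parity is None else gap_at_parity(parity)
            rows.append((f"s{parity}{age}a", 0, parity, age, base))
            rows.append((f"s{parity}{age}b", 0, parity, age, base))
            rows.append((f"t{parity}{age}", 1, parity, age, base + gap))
    return pd.DataFrame(rows, columns=["family_id", "dtwin", "parity", "mother_age", "nb"]).assign(
        ns=lambda d: d["nb"], next_interval_months=24.0
    )


class TestAlphaEstimation:
    def test_exact_cell_difference_recovers_unit_effect(self):
        table = exact_cell_difference_table()
        est = estimate_twin_effect(table, "births", "nonparametric")
        assert est.coefficient == pytest.approx(1.0, abs=1e-10)
        assert est.residual_scale == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("variant", ["parametric", "nonparametric"])
    def test_matches_bruteforce_on_simulated_table(self, small_table, variant):
        est = estimate_twin_effect(small_table, "births", variant)
        expected = brute_force_alpha(small_table, "nb", variant)
        assert est.coefficient == pytest.approx(expected, rel=1e-8)

    def test_six_row_hand_table_matches_normal_equations(self):
        table = pd.DataFrame(
            {
                "family_id": list("abcdef"),
                "dtwin": [1, 0, 0, 1, 0, 0],
                "parity": [0, 0, 1, 1, 0, 1],
                "mother_age": [24, 24, 27, 27, 24, 27],
                "nb": [5.0, 4.0, 6.0, 7.0, 3.0, 5.0],
            }
        ).assign(ns=lambda d: d["nb"], next_interval_months=20.0)
        est = estimate_twin_effect(table, "births", "parametric")
        assert est.coefficient == pytest.approx(brute_force_alpha(table, "nb", "parametric"), rel=1e-8)

    def test_parametric_equals_nonparametric_without_interaction(self):
        table = exact_cell_difference_table()
        a = estimate_twin_effect(table, "births", "parametric").coefficient
        b = estimate_twin_effect(table, "births", "nonparametric").coefficient
        assert a == pytest.approx(b, abs=1e-9)

    def test_invariant_to_row_order_and_family_relabeling(self, small_table):
        base = estimate_twin_effect(small_table, "births", "parametric")
        shuffled = small_table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled["family_id"] = shuffled["family_id"].map(lambda x: f"fam-{x}")
        again = estimate_twin_effect(shuffled, "births", "parametric")
        assert again.coefficient == pytest.approx(base.coefficient, rel=1e-10)
        assert again.std_error == pytest.approx(base.std_error, rel=1e-10)

    def test_sklearn_params_protocol(self):
        model = TwinEffectRegression(outcome="survivors", variant="nonparametric")
        assert model.get_params()["outcome"] == "survivors"
        model.set_params(outcome="births")
        assert model.outcome == "births"

    def test_cluster_se_differs_but_coefficient_identical(self, small_table):
        plain = estimate_twin_effect(small_table, "births", "parametric")
        clustered = estimate_twin_effect(small_table, "births", "parametric", cluster=True)
        assert clustered.coefficient == pytest.approx(plain.coefficient, rel=1e-10)
        assert clustered.std_error != pytest.approx(plain.std_error, rel=1e-3)


class TestUnidentified:
    def test_no_twins_raises(self, small_table):
        no_twins = small_table[small_table["dtwin"] == 0]
        for call in (
            lambda: estimate_twin_effect(no_twins, "births", "parametric"),
            lambda: estimate_twin_effect(no_twins, "births", "nonparametric"),
            lambda: estimate_parity_interaction(no_twins, "births"),
            lambda: estimate_post_twin_interval(no_twins),
        ):
            with pytest.raises(UnidentifiedError):
                call()

    def test_all_twins_raises(self, small_table):
        only_twins = small_table[small_table["dtwin"] == 1]
        with pytest.raises(UnidentifiedError):
            estimate_twin_effect(only_twins, "births", "parametric")

    def test_single_parity_twins_unidentified_lambda(self, small_table):
        t = small_table[(small_table["dtwin"] == 0) | (small_table["parity"] == 1)]
        with pytest.raises(UnidentifiedError, match="single parity"):
            estimate_parity_interaction(t, "births")

    def test_no_singleton_cell_overlap_nonparametric(self):
        rows = [("a", 1, 0, 24, 4.0), ("b", 0, 1, 30, 3.0)]
        t = pd.DataFrame(rows, columns=["family_id", "dtwin", "parity", "mother_age", "nb"]).assign(
            ns=lambda d: d["nb"], next_interval_months=np.nan
        )
        with pytest.raises(UnidentifiedError):
            estimate_twin_effect(t, "births", "nonparametric")


class TestParityInteraction:
    def test_exact_linear_gap_recovers_slope(self):
        table = exact_cell_difference_table(gap_at_parity=lambda p: 1.0 + 0.1 * p)
        alpha, lam = estimate_parity_interaction(table, "births")
        assert lam.coefficient == pytest.approx(0.1, abs=1e-9)
        assert alpha.coefficient == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce(self, small_table):
        alpha, lam = estimate_parity_interaction(small_table, "births")
        a_bf, l_bf = brute_force_alpha(small_table, "nb", "parametric", extra_interaction=True)
        assert alpha.coefficient == pytest.approx(a_bf, rel=1e-8)
        assert lam.coefficient == pytest.approx(l_bf, rel=1e-8)

    def test_control_cohort_lambda_positive(self, control_table_50k):
        """With surviving-children targets the twin effect grows in parity."""
        _, lam = estimate_parity_interaction(control_table_50k, "births")
        assert lam.coefficient - 2 * lam.std_error > 0


class TestPostTwinInterval:
    def test_all_intervals_equal_gives_zero(self):
        table = exact_cell_difference_table()
        est = estimate_post_twin_interval(table)
        assert est.coefficient == pytest.approx(0.0, abs=1e-10)

    def test_exact_shift_recovered(self):
        table = exact_cell_difference_table()
        table.loc[table["dtwin"] == 1, "next_interval_months"] += 6.0
        est = estimate_post_twin_interval(table)
        assert est.coefficient == pytest.approx(6.0, abs=1e-9)

    def test_only_rows_with_successor_used(self, small_table):
        est = estimate_post_twin_interval(small_table)
        assert est.n_obs == int(small_table["next_interval_months"].notna().sum())


class TestParityProfile:
    def test_exact_gap_at_every_parity(self):
        table = exact_cell_difference_table()
        prof = parity_profile(table, "births")
        assert (prof["gap"].round(9) == 1.0).all()
        assert prof["n_twin"].tolist() == [2] * len(prof)

    def test_only_parities_with_twins_reported(self, small_table):
        prof = parity_profile(small_table, "births")
        twin_parities = set(small_table.loc[small_table["dtwin"] == 1, "parity"])
        assert set(prof["parity"]) == twin_parities

    def test_natural_gaps_flat_control_gaps_rise(self, natural_table_50k, control_table_50k):
        nat = parity_profile(natural_table_50k, "births")
        nat = nat[nat["n_twin"] >= 30]
        ctl = parity_profile(control_table_50k, "births")
        ctl = ctl[ctl["n_twin"] >= 30]
        slope_nat = np.polyfit(nat["parity"], nat["gap"], 1, w=np.sqrt(nat["n_twin"]))[0]
        slope_ctl = np.polyfit(ctl["parity"], ctl["gap"], 1, w=np.sqrt(ctl["n_twin"]))[0]
        assert abs(slope_nat) < 0.1
        assert slope_ctl > slope_nat + 0.02
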