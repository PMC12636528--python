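"""Matching stage: distances, optimal calls, proportion tests, GLMs."""

import numpy as np
import pandas as pd
import pytest

from perchmatch.glmtools import emm_and_contrasts, fit_factorial_glm
from perchmatch.matching import (
    distance_table,
    find_optimal,
    fit_matching_glm,
    microhabitat_distances,
    optimal_calls,
    proportion_test_by_clade,
)


class TestDistances:
    def test_hand_euclidean(self):
        d = microhabitat_distances([0.0, 0.0], [[3.0, 4.0]])
        assert d[0] == pytest.approx(5.0)

    def test_identical_zero(self):
        assert microhabitat_distances([1.0, 2.0, 3.0], [[1.0, 2.0, 3.0]])[0] == 0.0

    def test_coordinate_permutation_invariance(self, rng):
        L = rng.normal(size=3)
        B = rng.normal(size=(4, 3))
        perm = [2, 0, 1]
        np.testing.assert_allclose(
            microhabitat_distances(L, B), microhabitat_distances(L[perm], B[:, perm])
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            microhabitat_distances([0.0, 0.0], [[1.0, 2.0, 3.0]])

    def test_distance_table_covers_usable_backgrounds(self, small_components):
        dt = distance_table(small_components, "cluster")
        n_usable = len(
            small_components[
                (small_components["roi_type"] == "background")
                & ~small_components["corrupted"]
            ]
        )
        assert len(dt) == n_usable
        assert (dt["d"] >= 0).all()
        assert dt.groupby("lizard_id")["is_perch"].sum().eq(1).all()


def _planted_comp(perch_xy, options):
    """Tiny 2D component table in edge space for one lizard at the origin."""
    rows = [
        {"roi_id": "L_d", "roi_type": "lizard", "background_id": "", "is_perch": False,
         "corrupted": False, "lizard_id": "L", "edge_color": 0.0, "edge_lum": 0.0}
    ]
    for i, (x, y) in enumerate([perch_xy] + options):
        rows.append(
            {"roi_id": f"b{i}", "roi_type": "background", "background_id": f"b{i}",
             "is_perch": i == 0, "corrupted": False, "lizard_id": "L",
             "edge_color": float(x), "edge_lum": float(y)}
        )
    return pd.DataFrame(rows)


class TestFindOptimal:
    def test_on_optimal_when_perch_closest(self):
        comp = _planted_comp((0.1, 0.0), [(0.5, 0.0), (0.9, 0.0)])
        call = find_optimal(distance_table(comp, "edge"), comp, "edge")
        assert call.on_optimal
        assert call.d_perch_to_optimal is None

    def test_perch_to_optimal_distance(self):
        # lizard at origin; perch at (3,4) -> d(L,P)=5; optimal at (1,1)
        comp = _planted_comp((3.0, 4.0), [(1.0, 1.0)])
        call = find_optimal(distance_table(comp, "edge"), comp, "edge")
        assert not call.on_optimal
        assert call.d_lizard_perch == pytest.approx(5.0)
        assert call.d_lizard_optimal == pytest.approx(np.sqrt(2))
        assert call.d_perch_to_optimal == pytest.approx(np.hypot(2.0, 3.0))

    def test_tie_broken_by_lowest_id_and_flagged(self):
        comp = _planted_comp((1.0, 0.0), [(0.0, 1.0)])  # both at distance 1
        call = find_optimal(distance_table(comp, "edge"), comp, "edge")
        assert call.tied
        assert call.optimal_background_id == "b0"
        assert call.on_optimal

    def test_invariant_optimal_never_farther_than_perch(self, small_components):
        for space in ("cluster", "edge", "visual"):
            oc = optimal_calls(small_components, space)
            assert (oc["d_lo"] <= oc["d_lp"] + 1e-12).all()
            same = oc["on_optimal"]
            np.testing.assert_allclose(oc.loc[same, "d_lo"], oc.loc[same, "d_lp"])


def _pearson_oracle(successes, totals):
    """Hand Pearson chi-square on the 2 x k table, explicit sums."""
    s = np.asarray(successes, float)
    t = np.asarray(totals, float)
    table = np.vstack([s, t - s])
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestProportionTest:
    def test_four_clades_df_three(self):
        chi2, df, p = proportion_test_by_clade([3, 2, 0, 0], [16, 6, 25, 5])
        assert df == 3
        assert chi2 == pytest.approx(8.611, abs=0.001)

    def test_equal_proportions_statistic_zero(self):
        chi2, df, p = proportion_test_by_clade([2, 2, 2], [10, 10, 10])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_pearson_on_small_tables(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 5))
            totals = rng.integers(1, 31, size=k)
            successes = np.array([rng.integers(0, t + 1) for t in totals])
            if successes.sum() == 0 or (totals - successes).sum() == 0:
                continue  # degenerate margin: statistic defined as 0
            chi2, df, _ = proportion_test_by_clade(successes, totals)
            assert chi2 == pytest.approx(_pearson_oracle(successes, totals), rel=1e-10)
            assert df == k - 1

    def test_zero_total_clade_dropped(self):
        with pytest.warns(UserWarning, match="zero total"):
            chi2, df, _ = proportion_test_by_clade([1, 0, 2], [5, 0, 6], ["A", "B", "C"])
        assert df == 1


def _factor_frame(n, rng, y=None):
    df = pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], n),
            "habitat": rng.choice(["coastal heath", "other"], n),
            "clade": rng.choice(list("ABCD"), n),
            "svl": rng.uniform(70, 120, n),
        }
    )
    df["y"] = rng.normal(size=n) if y is None else y
    return df


class TestFactorialGLM:
    def test_exact_svl_signal_dominates(self, rng):
        df = _factor_frame(120, rng)
        df["y"] = 2.0 + 0.05 * df["svl"]  # zero noise
        res = fit_factorial_glm(df, "y")
        svl_p = res.term("svl")["p"]
        assert svl_p < 1e-10
        for term in ("sex", "habitat", "clade"):
            assert res.term(term)["p"] > 0.05

    def test_balanced_design_type1_equals_type2(self):
        # fully crossed balanced design -> orthogonal factors, so
        # sequential and partial sums of squares agree for main effects
        import itertools
        rows = []
        rng = np.random.default_rng(8)
        for sex, hab, clade in itertools.product(
            ["F", "M"], ["coastal heath", "other"], list("ABCD")
        ):
            for _ in range(5):
                rows.append({"sex": sex, "habitat": hab, "clade": clade,
                             "svl": 90.0, "y": rng.normal()})
        df = pd.DataFrame(rows)
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        m = smf.ols("y ~ sex + habitat + clade", data=df).fit()
        t1 = anova_lm(m, typ=1)
        t2 = anova_lm(m, typ=2)
        for term in ("sex", "habitat", "clade"):
            assert t1.loc[term, "sum_sq"] == pytest.approx(
                t2.loc[term, "sum_sq"], rel=1e-10
            )

    def test_term_table_covers_all_terms(self, rng):
        res = fit_factorial_glm(_factor_frame(150, rng), "y")
        assert set(res.table["term"]) == {
            "sex", "habitat", "clade", "svl", "sex:habitat", "sex:clade"
        }

    def test_log10_requires_positive_response(self, rng):
        df = _factor_frame(80, rng)
        df["y"] = df["y"] - df["y"].max() - 1  # all negative
        with pytest.raises(ValueError, match="positive"):
            fit_factorial_glm(df, "y", transform="log10")

    def test_type3_branch_on_planted_interaction(self, rng):
        df = _factor_frame(300, rng)
        shift = ((df["sex"] == "M") & (df["clade"] == "D")).astype(float)
        df["y"] = rng.normal(size=len(df)) + 4.0 * shift
        res = fit_factorial_glm(df, "y")
        assert res.interaction_trail["sex:clade"]["significant"]
        assert (res.table.loc[res.table["term"] == "clade", "ss_type"] == "III").all()


class TestEMMs:
    def test_null_emms_near_grand_mean(self, rng):
        df = _factor_frame(400, rng)
        res = fit_factorial_glm(df, "y")
        emm, contrasts = emm_and_contrasts(res, ("clade",))
        grand = df["y"].mean()
        for _, row in emm.iterrows():
            assert row["ci_lower"] - 0.3 < grand < row["ci_upper"] + 0.3
        assert (contrasts["p_adj"] >= contrasts["p_raw"] - 1e-12).all()

    def test_planted_within_sex_contrast_recovered(self, rng):
        df = _factor_frame(600, rng)
        shift = ((df["sex"] == "M") & (df["clade"] == "D")).astype(float)
        df["y"] = rng.normal(size=len(df)) - 2.0 * shift
        res = fit_factorial_glm(df, "y")
        emm, contrasts = emm_and_contrasts(res, ("clade", "sex"))
        males_d = contrasts[
            (contrasts["within"] == "M") & contrasts["contrast"].str.contains("D")
        ]
        females_d = contrasts[
            (contrasts["within"] == "F") & contrasts["contrast"].str.contains("D")
        ]
        assert (males_d["p_adj"] < 0.05).all()
        assert (females_d["p_adj"] > 0.05).all()
        # clade-D males sit below every other male group
        d_emm = emm[(emm["clade"] == "D") & (emm["sex"] == "M")]["emmean"].iloc[0]
        others = emm[(emm["clade"] != "D") & (emm["sex"] == "M")]["emmean"]
        assert (d_emm < others).all()


def test_matching_glm_excludes_on_optimal_for_dpo(small_components):
    oc = optimal_calls(small_components, "cluster")
    factors = small_components[small_components["roi_type"] == "lizard"][
        ["lizard_id", "sex", "habitat", "clade", "svl"]
    ]
    oc = oc.merge(factors, on="lizard_id")
    res = fit_matching_glm(oc, "d_po", "cluster")
    assert res.n_obs == int((~oc["on_optimal"]).sum())
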