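"""Shared factorial-GLM machinery for the matching and diversity stages.

All response variables in the pipeline are analyzed with the same recipe:
a Gaussian linear model of sex, habitat, clade and snout-vent length (SVL)
with sex x habitat and sex x clade interactions.  The interactions are
tested first by sequential (Type I) deviance tests; if at least one is
significant at alpha, non-significant interactions are removed and main
effects are tested by Type III sums of squares under sum-to-zero
contrasts, otherwise all interactions are removed and main effects are
tested by Type II sums of squares.  Type I rows report the deviance drop
(with an F-based p-value under the estimated dispersion); Type II/III rows
report a deviance-based chi-square statistic (SS / dispersion) with a
chi-square p-value, matching the conventional R `anova`/`car::Anova`
output for Gaussian GLMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

FACTORS = ["sex", "habitat", "clade"]
MAIN_TERMS = ["sex", "habitat", "clade", "svl"]
INTERACTIONS = ["sex:habitat", "sex:clade"]
ALL_TERMS = MAIN_TERMS + INTERACTIONS


@dataclass
class GLMResult:
    """Term table plus the decision trail of one factorial GLM."""

    response: str
    transform: str | None
    table: pd.DataFrame  # term, ss_type, df, statistic, stat_kind, p
    interaction_trail: dict = field(default_factory=dict)
    residual_df: int = 0
    residual_deviance: float = 0.0
    n_obs: int = 0
    n_excluded: int = 0
    flags: list[str] = field(default_factory=list)
    model: object = None  # fitted statsmodels results used for EMMs
    data: pd.DataFrame | None = None

    def term(self, name: str) -> pd.Series:
        rows = self.table[self.table["term"] == name]
        if rows.empty:
            raise KeyError(name)
        return rows.iloc[0]


def apply_transform(y: np.ndarray, transform: str | None) -> np.ndarray:
    if transform is None or transform == "none":
        return np.asarray(y, dtype=float)
    if transform == "log10":
        y = np.asarray(y, dtype=float)
        if (y <= 0).any():
            raise ValueError("log10 transform requires a positive response")
        return np.log10(y)
    if transform == "sqrt":
        y = np.asarray(y, dtype=float)
        if (y < 0).any():
            raise ValueError("sqrt transform requires a non-negative response")
        return np.sqrt(y)
    raise ValueError(f"unknown transform {transform!r}")


def _term_formula(term: str, sum_contrasts: bool) -> str:
    def enc(f: str) -> str:
        return f"C({f}, Sum)" if sum_contrasts and f != "svl" else f

    if ":" in term:
        a, b = term.split(":")
        return f"{enc(a)}:{enc(b)}"
    return enc(term)


def _formula(terms: list[str], sum_contrasts: bool = False) -> str:
    rhs = " + ".join(_term_formula(t, sum_contrasts) for t in terms)
    return f"_y ~ {rhs}"


def _anova_term_name(term: str, sum_contrasts: bool) -> str:
    return _term_formula(term, sum_contrasts)


def fit_factorial_glm(
    data: pd.DataFrame,
    response: str,
    transform: str | None = None,
    alpha: float = 0.05,
) -> GLMResult:
    """Fit the factorial model for one response and build the term table.

    ``data`` must carry ``sex``, ``habitat``, ``clade``, ``svl`` and the
    response column; rows with missing response are dropped.  See the
    module docstring for the Type I / II / III decision rule.
    """
    need = MAIN_TERMS + [response]
    missing = [c for c in need if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing columns: {missing}")
    df = data.dropna(subset=[response]).copy()
    n_excluded = len(data) - len(df)
    if len(df) < len(ALL_TERMS) + 2:
        raise ValueError("too few observations for the factorial model")
    df["_y"] = apply_transform(df[response].to_numpy(), transform)

    flags: list[str] = []
    # empty factor-combination cells make some interaction contrasts aliased
    for a, b in (("sex", "habitat"), ("sex", "clade")):
        cells = pd.crosstab(df[a], df[b])
        if (cells == 0).any().any():
            flags.append(f"empty cells in {a} x {b}; related contrasts aliased")

    full = smf.ols(_formula(ALL_TERMS), data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        type1 = anova_lm(full, typ=1)

    rows = []
    trail = {}
    sig_inter = []
    for term in INTERACTIONS:
        key = _anova_term_name(term, False)
        r = type1.loc[key]
        p = float(r["PR(>F)"])
        trail[term] = {"type1_p": p, "significant": p < alpha}
        if p < alpha:
            sig_inter.append(term)
        rows.append(
            {
                "term": term,
                "ss_type": "I",
                "df": int(r["df"]),
                "statistic": float(r["sum_sq"]),
                "stat_kind": "deviance",
                "p": p,
            }
        )

    if sig_inter:
        kept = MAIN_TERMS + sig_inter
        model = smf.ols(_formula(kept, sum_contrasts=True), data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = anova_lm(model, typ=3)
        ss_type = "III"
        terms_to_report = kept
        sum_contrasts = True
    else:
        kept = list(MAIN_TERMS)
        model = smf.ols(_formula(kept), data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = anova_lm(model, typ=2)
        ss_type = "II"
        terms_to_report = kept
        sum_contrasts = False

    scale = model.mse_resid  # estimated Gaussian dispersion
    main_rows = []
    for term in terms_to_report:
        key = _anova_term_name(term, sum_contrasts)
        r = tab.loc[key]
        dfree = int(r["df"])
        chisq = float(r["sum_sq"]) / scale
        main_rows.append(
            {
                "term": term,
                "ss_type": ss_type,
                "df": dfree,
                "statistic": chisq,
                "stat_kind": "chisq",
                "p": float(stats.chi2.sf(chisq, dfree)),
            }
        )
    # report mains first (in canonical order), then interactions: the
    # Type III rows for retained interactions replace their Type I rows
    reported = {r["term"] for r in main_rows}
    table = pd.DataFrame(
        [r for r in main_rows if r["term"] in MAIN_TERMS]
        + [r for r in main_rows if r["term"] in INTERACTIONS]
        + [r for r in rows if r["term"] not in reported]
    )

    return GLMResult(
        response=response,
        transform=transform,
        table=table.reset_index(drop=True),
        interaction_trail=trail,
        residual_df=int(full.df_resid),
        residual_deviance=float(full.ssr),
        n_obs=len(df),
        n_excluded=n_excluded,
        flags=flags,
        model=model,
        data=df,
    )


# ---------------------------------------------------------------------------
# estimated marginal means and contrasts
# ---------------------------------------------------------------------------

def emm_and_contrasts(
    result: GLMResult,
    factors: tuple[str, str] | tuple[str],
    adjust: str = "holm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means and pairwise contrasts.

    EMMs are model predictions at every combination of the requested
    factors, averaged with equal weight over the levels of the remaining
    factors, with SVL held at its sample mean; 95% CIs use the model's
    residual t distribution.  When two factors are given, pairwise
    contrasts of the first factor's levels are computed *within* each
    level of the second (the conditioning factor), with p-values adjusted
    by ``adjust`` (Holm by default) within each conditioning level's
    family.
    """
    model = result.model
    df = result.data
    design_info = model.model.data.design_info
    from patsy import build_design_matrices

    levels = {f: sorted(df[f].unique()) for f in FACTORS}
    svl_mean = float(df["svl"].mean())

    target = list(factors)
    nuisance = [f for f in FACTORS if f not in target]

    def emm_vector(combo: dict[str, str]) -> np.ndarray:
        grid = [dict(combo)]
        for f in nuisance:
            grid = [dict(g, **{f: lv}) for g in grid for lv in levels[f]]
        for g in grid:
            g["svl"] = svl_mean
        gdf = pd.DataFrame(grid)
        (X,) = build_design_matrices([design_info], gdf)
        return np.asarray(X).mean(axis=0)

    combos = [{target[0]: lv} for lv in levels[target[0]]]
    for f in target[1:]:
        combos = [dict(c, **{f: lv}) for c in combos for lv in levels[f]]

    cov = model.cov_params().to_numpy()
    params = model.params.to_numpy()
    dof = model.df_resid
    tcrit = stats.t.ppf(0.975, dof)

    emm_rows = []
    lvecs = {}
    for combo in combos:
        L = emm_vector(combo)
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        lvecs[tuple(combo[f] for f in target)] = L
        emm_rows.append(
            {
                **combo,
                "emmean": est,
                "se": se,
                "ci_lower": est - tcrit * se,
                "ci_upper": est + tcrit * se,
            }
        )
    emm_df = pd.DataFrame(emm_rows)

    contrast_rows = []
    lv_main = levels[target[0]]
    cond_levels = levels[target[1]] if len(target) == 2 else [None]
    for cond in cond_levels:
        fam = []
        for i in range(len(lv_main)):
            for j in range(i + 1, len(lv_main)):
                key_i = (lv_main[i],) + ((cond,) if cond is not None else ())
                key_j = (lv_main[j],) + ((cond,) if cond is not None else ())
                L = lvecs[key_i] - lvecs[key_j]
                est = float(L @ params)
                se = float(np.sqrt(L @ cov @ L))
                tval = est / se if se > 0 else 0.0
                p = float(2 * stats.t.sf(abs(tval), dof))
                fam.append(
                    {
                        "contrast": f"{lv_main[i]} - {lv_main[j]}",
                        "within": cond if cond is not None else "",
                        "estimate": est,
                        "se": se,
                        "t": tval,
                        "p_raw": p,
                    }
                )
        if fam:
            praw = [r["p_raw"] for r in fam]
            _, padj, _, _ = multipletests(praw, method=adjust)
            for r, pa in zip(fam, padj):
                r["p_adj"] = float(pa)
            contrast_rows.extend(fam)
    return emm_df, pd.DataFrame(contrast_rows)
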