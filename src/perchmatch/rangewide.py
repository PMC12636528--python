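"""Species-wide matching of all lizards to all backgrounds.

Stage 4 of the analysis: the full lizard x background Euclidean distance
matrix in each component space (with the study design, 52 x 309 = 16,068
distances per space), per-lizard per-location mean distances (+/- SE;
52 x 7 = 364 points), Hotelling's T^2 comparisons of those mean points
between clades, habitats and locations in 3D or 2D, and a per-location
within-vs-outside distance summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .spaces import SPACES, space_columns

__all__ = [
    "all_pairs_distances",
    "location_means",
    "location_mean_points",
    "hotelling_t2",
    "pairwise_hotelling",
    "within_vs_between",
    "HotellingResult",
]


def all_pairs_distances(comp: pd.DataFrame, space: str) -> pd.DataFrame:
    """Full lizard x background distance matrix for one space.

    Rows are lizard ids, columns background ids; a lizard's own
    backgrounds are included in the crossing.  Only usable (non-corrupted)
    backgrounds enter.
    """
    cols = space_columns(space)
    liz = comp[comp["roi_type"] == "lizard"]
    bgs = comp[comp["roi_type"] == "background"]
    if "corrupted" in bgs.columns:
        bgs = bgs[~bgs["corrupted"]]
    if bgs.empty:
        raise ValueError("no usable backgrounds")
    D = cdist(liz[cols].to_numpy(dtype=float), bgs[cols].to_numpy(dtype=float))
    return pd.DataFrame(D, index=liz["lizard_id"].to_numpy(), columns=bgs["background_id"].to_numpy())


def location_means(matrix: pd.DataFrame, background_locations: pd.Series) -> pd.DataFrame:
    """Per lizard x location mean and SE of lizard-background distance.

    ``background_locations`` maps background id -> location; every column
    of ``matrix`` must be assigned to exactly one location (locations with
    zero backgrounds are dropped with a warning).  SE is SD/sqrt(n) over
    that location's backgrounds and is NaN for n < 2.
    """
    locs = background_locations.reindex(matrix.columns)
    if locs.isna().any():
        missing = list(matrix.columns[locs.isna()])
        raise ValueError(f"backgrounds without a location: {missing[:5]}...")
    rows = []
    for loc, cols in locs.groupby(locs).groups.items():
        sub = matrix[list(cols)]
        n = sub.shape[1]
        mean = sub.mean(axis=1)
        se = sub.std(axis=1, ddof=1) / np.sqrt(n) if n >= 2 else pd.Series(np.nan, index=sub.index)
        for lid in matrix.index:
            rows.append(
                {
                    "lizard_id": lid,
                    "location": loc,
                    "mean": float(mean.loc[lid]),
                    "se": float(se.loc[lid]),
                    "n_backgrounds": n,
                }
            )
    return pd.DataFrame(rows)


def location_mean_points(
    comp: pd.DataFrame,
    spaces: tuple[str, ...] = SPACES,
) -> pd.DataFrame:
    """The N = n_lizards x n_locations mean points across all spaces.

    Each row is one lizard x background-location pair with one mean (and
    SE) distance per space, plus the lizard's clade/sex and the habitat of
    the background location — the dataset for the Hotelling stage.
    """
    bgs = comp[comp["roi_type"] == "background"]
    if "corrupted" in bgs.columns:
        bgs = bgs[~bgs["corrupted"]]
    bg_loc = bgs.set_index("background_id")["location"]
    loc_habitat = bgs.groupby("location")["habitat"].first()
    liz = comp[comp["roi_type"] == "lizard"].set_index("lizard_id")

    merged: pd.DataFrame | None = None
    for space in spaces:
        D = all_pairs_distances(comp, space)
        lm = location_means(D, bg_loc).rename(
            columns={"mean": f"mean_{space}", "se": f"se_{space}"}
        )
        lm = lm.drop(columns=["n_backgrounds"]) if merged is not None else lm
        merged = lm if merged is None else merged.merge(lm, on=["lizard_id", "location"])
    merged["lizard_clade"] = merged["lizard_id"].map(liz["clade"]).to_numpy()
    merged["background_habitat"] = merged["location"].map(loc_habitat).to_numpy()
    return merged


@dataclass(frozen=True)
class HotellingResult:
    """Two-sample Hotelling T^2 with its large-sample chi-square form.

    ``chi2`` equals T^2 with ``df = p`` degrees of freedom (the form used
    for the heat maps); the exact-F version is carried alongside.
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    p_dims: int
    t2: float
    chi2: float
    df: int
    p_chi2: float
    f_stat: float
    f_df: tuple[int, int]
    p_f: float
    p_adjusted: float | None = None


def hotelling_t2(points_a, points_b, names: tuple[str, str] = ("A", "B")) -> HotellingResult:
    """Two-sample Hotelling T^2 test.

    ``T^2 = (n1 n2 / (n1 + n2)) * dxbar' S_pooled^-1 dxbar`` with the
    chi-square statistic equal to T^2 on p degrees of freedom
    (large-sample form).  Raises when the pooled covariance is singular.
    """
    A = np.atleast_2d(np.asarray(points_a, dtype=float))
    B = np.atleast_2d(np.asarray(points_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share dimensionality")
    n1, n2, p = A.shape[0], B.shape[0], A.shape[1]
    if n1 + n2 <= p + 1:
        raise ValueError(f"need n1 + n2 > p + 1 (got {n1}+{n2} with p={p})")
    d = A.mean(axis=0) - B.mean(axis=0)
    S1 = np.cov(A, rowvar=False, ddof=1) if n1 > 1 else np.zeros((p, p))
    S2 = np.cov(B, rowvar=False, ddof=1) if n2 > 1 else np.zeros((p, p))
    S1, S2 = np.atleast_2d(S1), np.atleast_2d(S2)
    Sp = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(Sp, d)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; reduce the dimensionality"
        ) from err
    if not np.isfinite(sol).all() or np.linalg.cond(Sp) > 1e12:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; reduce the dimensionality"
        )
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    df1, df2 = p, n1 + n2 - 1 - p
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    return HotellingResult(
        group_a=names[0],
        group_b=names[1],
        n_a=n1,
        n_b=n2,
        p_dims=p,
        t2=t2,
        chi2=t2,
        df=p,
        p_chi2=float(stats.chi2.sf(t2, p)),
        f_stat=float(f_stat),
        f_df=(df1, df2),
        p_f=float(stats.f.sf(f_stat, df1, df2)),
    )


def pairwise_hotelling(
    points: pd.DataFrame,
    group_by: str,
    dims: tuple[str, ...],
    adjust: str = "bonferroni",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hotelling T^2 for every unordered pair of groups.

    ``points`` holds one row per observation with the coordinate columns
    ``dims`` and a grouping column; all C(k, 2) pairs are tested, p-values
    are Bonferroni-adjusted by default, and the chi-square statistics are
    returned as a symmetric heat-map matrix (zero diagonal).  Pairs whose
    pooled size is too small for the dimensionality are flagged untestable
    (NaN in the matrix).
    """
    groups = sorted(points[group_by].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    p = len(dims)
    results = []
    heat = pd.DataFrame(0.0, index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        A = points.loc[points[group_by] == a, list(dims)].to_numpy(dtype=float)
        B = points.loc[points[group_by] == b, list(dims)].to_numpy(dtype=float)
        if len(A) < p + 2 or len(B) < p + 2:
            results.append(
                {"group_a": a, "group_b": b, "testable": False, "chi2": np.nan,
                 "df": p, "p_raw": np.nan, "p_adj": np.nan}
            )
            heat.loc[a, b] = heat.loc[b, a] = np.nan
            continue
        r = hotelling_t2(A, B, names=(str(a), str(b)))
        results.append(
            {"group_a": a, "group_b": b, "testable": True, "chi2": r.chi2,
             "df": r.df, "p_raw": r.p_chi2, "p_adj": np.nan}
        )
        heat.loc[a, b] = heat.loc[b, a] = r.chi2
    res = pd.DataFrame(results)
    testable = res["testable"]
    n_tests = int(testable.sum())
    if n_tests:
        if adjust == "bonferroni":
            res.loc[testable, "p_adj"] = np.minimum(res.loc[testable, "p_raw"] * n_tests, 1.0)
        elif adjust in ("none", None):
            res.loc[testable, "p_adj"] = res.loc[testable, "p_raw"]
        else:
            from statsmodels.stats.multitest import multipletests

            _, padj, _, _ = multipletests(res.loc[testable, "p_raw"], method=adjust)
            res.loc[testable, "p_adj"] = padj
    return res, heat


def within_vs_between(
    matrix: pd.DataFrame,
    lizard_locations: pd.Series,
    background_locations: pd.Series,
) -> pd.DataFrame:
    """Per-location comparison of within- vs outside-location matching.

    For each location: the mean distance between that location's lizards
    and its own backgrounds (within) versus all backgrounds elsewhere
    (outside), flagging locations where outside < within (the signature of
    a locally mismatched background pool).  With a single location the
    outside mean is undefined and flagged.  Locations with no lizards are
    dropped.
    """
    liz_loc = lizard_locations.reindex(matrix.index)
    bg_loc = background_locations.reindex(matrix.columns)
    if liz_loc.isna().any() or bg_loc.isna().any():
        raise ValueError("every lizard and background must have a location")
    rows = []
    for loc in sorted(liz_loc.unique()):
        lrows = matrix.index[liz_loc == loc]
        if len(lrows) == 0:
            continue
        inside_cols = matrix.columns[bg_loc == loc]
        outside_cols = matrix.columns[bg_loc != loc]
        within = float(matrix.loc[lrows, inside_cols].to_numpy().mean()) if len(inside_cols) else np.nan
        outside = (
            float(matrix.loc[lrows, outside_cols].to_numpy().mean())
            if len(outside_cols)
            else np.nan
        )
        rows.append(
            {
                "location": loc,
                "n_lizards": int(len(lrows)),
                "n_backgrounds_within": int(len(inside_cols)),
                "mean_within": within,
                "mean_outside": outside,
                "outside_lt_within": bool(outside < within) if np.isfinite(outside) and np.isfinite(within) else False,
                "outside_defined": bool(len(outside_cols) > 0),
            }
        )
    return pd.DataFrame(rows)
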