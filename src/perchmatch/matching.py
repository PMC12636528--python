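"""Microhabitat-level background matching.

Stage 1–2 of the analysis: Euclidean distances between each lizard's
pattern and its own background options in each component space,
identification of the optimal (closest) background, proportion tests of
optimal-background use across clades, and factorial GLMs of the
lizard-to-perch distance d(L,P) and — for lizards not already on the
optimal background — of the perch-to-optimal distance d(P,O*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmtools import GLMResult, emm_and_contrasts, fit_factorial_glm
from .spaces import space_columns

__all__ = [
    "microhabitat_distances",
    "distance_table",
    "find_optimal",
    "optimal_calls",
    "proportion_test_by_clade",
    "fit_matching_glm",
    "emm_and_contrasts",
    "OptimalCall",
]

#: default response transforms, following the analysis protocol:
#: d(L,P) — log10 for edge and visual, none for cluster;
#: d(P,O*) — log10 for edge and visual, square root for cluster.
DEFAULT_TRANSFORMS = {
    ("d_lp", "cluster"): None,
    ("d_lp", "edge"): "log10",
    ("d_lp", "visual"): "log10",
    ("d_po", "cluster"): "sqrt",
    ("d_po", "edge"): "log10",
    ("d_po", "visual"): "log10",
}


def microhabitat_distances(lizard_vec, background_vecs) -> np.ndarray:
    """Euclidean distances from one lizard to each background option."""
    L = np.asarray(lizard_vec, dtype=float)
    B = np.atleast_2d(np.asarray(background_vecs, dtype=float))
    if B.shape[0] == 0:
        raise ValueError("need at least one background")
    if B.shape[1] != L.size:
        raise ValueError(f"dimension mismatch: lizard {L.size}D vs backgrounds {B.shape[1]}D")
    return np.linalg.norm(B - L, axis=1)


def distance_table(comp: pd.DataFrame, space: str) -> pd.DataFrame:
    """One distance record per lizard x own usable background.

    ``comp`` is a component table (lizards plus usable backgrounds);
    returns columns lizard_id, background_id, space, d, is_perch.
    """
    cols = space_columns(space)
    records = []
    liz = comp[comp["roi_type"] == "lizard"]
    bgs = comp[comp["roi_type"] == "background"]
    if "corrupted" in bgs.columns:
        bgs = bgs[~bgs["corrupted"]]
    for _, lrow in liz.iterrows():
        mine = bgs[bgs["lizard_id"] == lrow["lizard_id"]]
        d = microhabitat_distances(
            lrow[cols].to_numpy(dtype=float), mine[cols].to_numpy(dtype=float)
        )
        for (_, brow), dist in zip(mine.iterrows(), d):
            records.append(
                {
                    "lizard_id": lrow["lizard_id"],
                    "background_id": brow["background_id"],
                    "space": space,
                    "d": float(dist),
                    "is_perch": bool(brow["is_perch"]),
                }
            )
    return pd.DataFrame(records)


@dataclass(frozen=True)
class OptimalCall:
    """Per-lizard verdict: which background is the closest match, whether
    the lizard was perched on it, and if not, the distance between the
    perch and that optimal background."""

    lizard_id: str
    space: str
    optimal_background_id: str
    on_optimal: bool
    d_lizard_perch: float
    d_lizard_optimal: float
    d_perch_to_optimal: float | None  # defined only when not on the optimal
    tied: bool = False


def find_optimal(records: pd.DataFrame, comp: pd.DataFrame, space: str) -> OptimalCall:
    """Optimal-background call for one lizard's distance records.

    Ties on the minimum distance are broken by lowest background id and
    flagged.  ``comp`` supplies the background vectors needed for the
    perch-to-optimal distance.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 backgrounds to call an optimal")
    recs = records.sort_values(["d", "background_id"], kind="stable").reset_index(drop=True)
    best = recs.iloc[0]
    tied = bool(np.isclose(recs["d"].iloc[1], best["d"], rtol=0, atol=0))
    perch = records[records["is_perch"]]
    if len(perch) != 1:
        raise ValueError("records must contain exactly one perch")
    perch = perch.iloc[0]
    on_optimal = bool(best["background_id"] == perch["background_id"])

    d_po = None
    if not on_optimal:
        cols = space_columns(space)
        bg = comp[comp["roi_type"] == "background"].set_index("background_id")
        pvec = bg.loc[perch["background_id"], cols].to_numpy(dtype=float)
        ovec = bg.loc[best["background_id"], cols].to_numpy(dtype=float)
        d_po = float(np.linalg.norm(pvec - ovec))
    return OptimalCall(
        lizard_id=str(best["lizard_id"]),
        space=space,
        optimal_background_id=str(best["background_id"]),
        on_optimal=on_optimal,
        d_lizard_perch=float(perch["d"]),
        d_lizard_optimal=float(best["d"]),
        d_perch_to_optimal=d_po,
        tied=tied,
    )


def optimal_calls(comp: pd.DataFrame, space: str) -> pd.DataFrame:
    """Optimal-background calls for every lizard in the component table."""
    dist = distance_table(comp, space)
    rows = []
    for lid, grp in dist.groupby("lizard_id", sort=True):
        call = find_optimal(grp, comp, space)
        rows.append(
            {
                "lizard_id": lid,
                "space": space,
                "optimal_background_id": call.optimal_background_id,
                "on_optimal": call.on_optimal,
                "d_lp": call.d_lizard_perch,
                "d_lo": call.d_lizard_optimal,
                "d_po": call.d_perch_to_optimal,
                "tied": call.tied,
            }
        )
    return pd.DataFrame(rows)


def proportion_test_by_clade(successes, totals, clades=None):
    """Pearson k-sample test of equal proportions (no continuity correction).

    ``successes[i]`` lizards out of ``totals[i]`` in clade *i* were found
    on their optimal background.  Clades with zero total are dropped with
    a warning.  Returns ``(chi2, df, p)``.
    """
    s = np.asarray(successes, dtype=float)
    t = np.asarray(totals, dtype=float)
    if s.shape != t.shape:
        raise ValueError("successes and totals must align")
    if (s > t).any() or (s < 0).any():
        raise ValueError("need 0 <= successes <= totals")
    keep = t > 0
    if not keep.all():
        dropped = (
            [c for c, k in zip(clades, keep) if not k] if clades is not None else int((~keep).sum())
        )
        warnings.warn(f"dropping clades with zero total: {dropped}", stacklevel=2)
        s, t = s[keep], t[keep]
    if s.size < 2:
        raise ValueError("need at least 2 clades with observations")
    table = np.vstack([s, t - s])
    if table.sum(axis=0).min() == 0:
        raise ValueError("a clade has zero total after filtering")
    # Degenerate margins (all successes or none) give statistic 0 by convention
    if table[0].sum() == 0 or table[1].sum() == 0:
        return 0.0, s.size - 1, 1.0
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def fit_matching_glm(
    data: pd.DataFrame,
    response: str,
    space: str,
    transform: str | None | str = "default",
    alpha: float = 0.05,
) -> GLMResult:
    """Factorial GLM of a matching response (``d_lp`` or ``d_po``).

    ``data`` is an optimal-calls table merged with lizard factors.  For
    ``d_po`` the subset of lizards already on their optimal background is
    excluded (their perch-to-optimal distance is undefined).  The default
    transform follows the per-space protocol in
    :data:`DEFAULT_TRANSFORMS`.
    """
    if transform == "default":
        transform = DEFAULT_TRANSFORMS.get((response, space))
    df = data
    if response == "d_po":
        df = df[~df["on_optimal"].astype(bool)]
    result = fit_factorial_glm(df, response, transform=transform, alpha=alpha)
    result.response = f"{response}[{space}]"
    return result
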