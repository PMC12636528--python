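"""Microhabitat background diversity as convex-hull measure.

Stage 3 of the analysis: the diversity of the background options available
to one lizard is the area (edge space, 2D) or volume (cluster and visual
spaces, 3D) of the convex hull spanned by its background vectors — the
perch counts as one of the options.  Hull measures are then analyzed with
the same factorial GLM machinery as the matching stage, after a log10
transform (degenerate hulls are excluded with their count reported).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .glmtools import GLMResult, fit_factorial_glm
from .spaces import space_columns

__all__ = ["hull_measure", "microhabitat_hulls", "fit_diversity_glm"]


def hull_measure(points: np.ndarray, d: int | None = None) -> tuple[float, bool]:
    """Convex-hull area (2D) or volume (3D) of a point set.

    Returns ``(measure, degenerate)``.  Fewer than ``d + 1`` points, or
    affinely dependent points (all on a line/plane), are degenerate with
    measure 0.  Non-finite coordinates raise ``ValueError``.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(P).all():
        raise ValueError("non-finite coordinates")
    if d is None:
        d = P.shape[1]
    if P.shape[1] != d or d not in (2, 3):
        raise ValueError(f"expected {d}-dimensional points in 2 or 3 dimensions")
    if P.shape[0] < d + 1:
        return 0.0, True
    centered = P - P.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(centered).max()))
    if rank < d:
        return 0.0, True
    try:
        hull = ConvexHull(P)
    except QhullError:
        return 0.0, True
    return float(hull.volume), False  # scipy's 'volume' is area in 2D


def microhabitat_hulls(comp: pd.DataFrame, space: str) -> pd.DataFrame:
    """One hull record per lizard: measure over its usable backgrounds.

    Columns: lizard_id, space, n_points, measure, degenerate.
    """
    cols = space_columns(space)
    d = len(cols)
    bgs = comp[comp["roi_type"] == "background"]
    if "corrupted" in bgs.columns:
        bgs = bgs[~bgs["corrupted"]]
    rows = []
    for lid, grp in bgs.groupby("lizard_id", sort=True):
        pts = grp[cols].to_numpy(dtype=float)
        measure, degenerate = hull_measure(pts, d)
        rows.append(
            {
                "lizard_id": lid,
                "space": space,
                "n_points": len(pts),
                "measure": measure,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def fit_diversity_glm(
    hull_table: pd.DataFrame,
    transform: str | None = "log10",
    alpha: float = 0.05,
) -> GLMResult:
    """Factorial GLM of hull measure against sex, habitat, clade and SVL.

    ``hull_table`` must carry the factor columns (merge the hull records
    with the lizard rows first).  Degenerate hulls are excluded — log10 of
    a zero measure is undefined — and their count is reported on the
    result.  Raises if every hull is degenerate.
    """
    usable = hull_table[~hull_table["degenerate"].astype(bool)]
    n_excluded = len(hull_table) - len(usable)
    if usable.empty:
        raise ValueError("all hulls are degenerate; nothing to analyze")
    result = fit_factorial_glm(usable, "measure", transform=transform, alpha=alpha)
    result.n_excluded += n_excluded
    space = hull_table["space"].iloc[0] if "space" in hull_table.columns else "?"
    result.response = f"hull[{space}]"
    return result
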