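"""Component spaces for lizard/background pattern comparison.

Three low-dimensional spaces summarize every ROI:

* **cluster** (3D) — number of clusters, total patch count, largest-cluster
  area;
* **edge** (2D) — mean maximal chromatic and luminance edge contrast;
* **visual** (3D) — the first three principal components of the twelve
  secondary color-pattern statistics, fitted on lizards and backgrounds
  jointly so that both live in one space.

Component support for the PCA is assessed by a permutation test: each
variable is independently permuted and the observed eigenvalues compared
with the 95th percentile of the permutation null.  Three components are
always retained for the downstream pipeline regardless of support, with
the support flags reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CLUSTER_COLS, EDGE_COLS, SECONDARY_COLS

SPACES = ("cluster", "edge", "visual")

VISUAL_COLS = ["pc1", "pc2", "pc3"]


def space_columns(space: str) -> list[str]:
    """Column names of one component space in the component table."""
    if space == "cluster":
        return list(CLUSTER_COLS)
    if space == "edge":
        return list(EDGE_COLS)
    if space == "visual":
        return list(VISUAL_COLS)
    raise ValueError(f"unknown space {space!r}")


# ---------------------------------------------------------------------------
# PCA with permutation support
# ---------------------------------------------------------------------------

@dataclass
class PCAFit:
    """A fitted, serializable PCA on centered and unit-scaled variables."""

    columns: list[str]
    centers: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (p, p), columns are components
    eigenvalues: np.ndarray  # (p,), non-increasing
    n_retained: int = 3
    null_q95: np.ndarray | None = None
    supported: np.ndarray | None = None
    n_perm: int = 0
    seed: int | None = None
    dropped_columns: list[str] = field(default_factory=list)
    reliable: bool = True

    def to_json(self, path) -> None:
        obj = {
            "columns": self.columns,
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_retained": self.n_retained,
            "null_q95": None if self.null_q95 is None else self.null_q95.tolist(),
            "supported": None if self.supported is None else self.supported.tolist(),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "dropped_columns": self.dropped_columns,
            "reliable": self.reliable,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PCAFit":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            columns=obj["columns"],
            centers=np.asarray(obj["centers"]),
            scales=np.asarray(obj["scales"]),
            loadings=np.asarray(obj["loadings"]),
            eigenvalues=np.asarray(obj["eigenvalues"]),
            n_retained=obj["n_retained"],
            null_q95=None if obj["null_q95"] is None else np.asarray(obj["null_q95"]),
            supported=None if obj["supported"] is None else np.asarray(obj["supported"], dtype=bool),
            n_perm=obj["n_perm"],
            seed=obj["seed"],
            dropped_columns=obj["dropped_columns"],
            reliable=obj["reliable"],
        )


def _scaled(X: np.ndarray, centers: np.ndarray, scales: np.ndarray) -> np.ndarray:
    return (X - centers) / scales


def _eigvals(Xs: np.ndarray) -> np.ndarray:
    s = np.linalg.svd(Xs, compute_uv=False)
    return s**2 / (Xs.shape[0] - 1)


def fit_visual_space(
    stats: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    n_retained: int = 3,
) -> PCAFit:
    """PCA of the secondary-statistics matrix with permutation support.

    Variables are centered and scaled to unit SD (sample SD, ddof=1);
    constant columns are dropped with a warning.  The permutation null
    permutes each column independently ``n_perm`` times (operating on the
    column-sorted values with per-column seed streams, so the null is
    invariant to the row order of the input) and flags component *k* as
    supported when its observed eigenvalue exceeds the null 95th
    percentile.
    """
    if isinstance(stats, pd.DataFrame):
        columns = list(stats.columns)
        X = stats.to_numpy(dtype=float)
    else:
        X = np.asarray(stats, dtype=float)
        columns = [f"v{i + 1}" for i in range(X.shape[1])]
    if not np.isfinite(X).all():
        raise ValueError("secondary statistics contain non-finite values")
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows to fit a {p}-variable PCA")
    if 0 < n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is low; support flags will be coarse", stacklevel=2)

    sds = X.std(axis=0, ddof=1)
    dropped = [columns[i] for i in np.flatnonzero(sds == 0)]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=2)
        keep = sds > 0
        X = X[:, keep]
        columns = [c for c, k in zip(columns, keep) if k]
        sds = sds[keep]
        p = X.shape[1]

    centers = X.mean(axis=0)
    Xs = _scaled(X, centers, sds)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = s**2 / (n - 1)
    loadings = Vt.T
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]

    rank = int(np.linalg.matrix_rank(Xs))
    reliable = rank >= min(n - 1, p)
    if not reliable:
        warnings.warn("rank-deficient input; support flags unreliable", stacklevel=2)

    null_q95 = supported = None
    if n_perm > 0:
        col_sorted = np.sort(Xs, axis=0)
        col_rngs = [
            np.random.default_rng(ss)
            for ss in np.random.SeedSequence(seed).spawn(p)
        ]
        null = np.empty((n_perm, p))
        Xp = np.empty_like(Xs)
        for b in range(n_perm):
            for j in range(p):
                Xp[:, j] = col_sorted[col_rngs[j].permutation(n), j]
            Xp -= Xp.mean(axis=0)
            null[b] = _eigvals(Xp)
        null_q95 = np.quantile(null, 0.95, axis=0)
        supported = eig > null_q95

    return PCAFit(
        columns=columns,
        centers=centers,
        scales=sds,
        loadings=loadings,
        eigenvalues=eig,
        n_retained=n_retained,
        null_q95=null_q95,
        supported=supported,
        n_perm=n_perm,
        seed=seed,
        dropped_columns=dropped,
        reliable=reliable,
    )


def project_visual(rows: pd.DataFrame | np.ndarray, fit: PCAFit) -> np.ndarray:
    """Project rows of secondary statistics onto the retained components."""
    if isinstance(rows, pd.DataFrame):
        X = rows[fit.columns].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(rows, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("cannot project rows with missing values")
    Xs = _scaled(X, fit.centers, fit.scales)
    return Xs @ fit.loadings[:, : fit.n_retained]


# ---------------------------------------------------------------------------
# standardization and component-table assembly
# ---------------------------------------------------------------------------

def standardize_space(vectors: np.ndarray, mode: str = "zscore") -> np.ndarray:
    """Standardize the coordinates of one space over all rows jointly.

    ``zscore`` centers each coordinate and scales it to unit sample SD;
    zero-variance coordinates are centered with scale 1 and a warning.
    ``raw`` returns the input unchanged.
    """
    X = np.asarray(vectors, dtype=float)
    if mode == "raw":
        return X.copy()
    if mode != "zscore":
        raise ValueError(f"unknown standardization mode {mode!r}")
    if X.shape[0] < 2:
        raise ValueError("zscore standardization needs at least 2 rows")
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any():
        warnings.warn("zero-variance coordinate left centered with scale 1", stacklevel=2)
        sds = np.where(sds == 0, 1.0, sds)
    return (X - X.mean(axis=0)) / sds


def build_component_table(
    metric_table: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    standardize: str = "zscore",
) -> tuple[pd.DataFrame, PCAFit]:
    """Assemble the three component spaces from a metric table.

    The input must hold lizard and usable background rows together; the
    PCA of the secondary statistics is fitted on all rows jointly so
    lizard and background visual vectors share one space, and
    standardization (default zscore) is likewise computed over all rows.
    Returns ``(component table, PCA fit)`` where the component table keeps
    the id/factor columns and adds the standardized space columns.
    """
    fit = fit_visual_space(metric_table[SECONDARY_COLS], n_perm=n_perm, seed=seed)
    pcs = project_visual(metric_table[SECONDARY_COLS][fit.columns], fit)

    keep = [
        c
        for c in (
            "roi_id", "roi_type", "background_id", "is_perch", "corrupted",
            "lizard_id", "location", "clade", "habitat", "sex", "svl",
        )
        if c in metric_table.columns
    ]
    comp = metric_table[keep].copy().reset_index(drop=True)
    comp[CLUSTER_COLS] = standardize_space(
        metric_table[CLUSTER_COLS].to_numpy(dtype=float), standardize
    )
    comp[EDGE_COLS] = standardize_space(
        metric_table[EDGE_COLS].to_numpy(dtype=float), standardize
    )
    comp[VISUAL_COLS] = standardize_space(pcs, standardize)
    return comp, fit


def space_matrix(comp: pd.DataFrame, space: str) -> np.ndarray:
    return comp[space_columns(space)].to_numpy(dtype=float)
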