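"""Core tabular containers shared across the pipeline.

A study dataset is one row per region of interest (ROI): either a lizard
dorsal pattern or one of the background options photographed in that
lizard's microhabitat.  Rows carry the pattern metrics extracted by the
visual-model chain (or emulated by the synthetic generator) together with
the study factors used by the statistical stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: cluster-component metrics: number of color clusters, total patch count
#: summed over clusters, and area of the largest cluster (mm^2)
CLUSTER_COLS = ["n_clusters", "counts_within", "area_largest"]

#: local edge-intensity metrics (mean maximal directional contrast, JND)
EDGE_COLS = ["edge_color", "edge_lum"]

#: twelve secondary color-pattern statistics (color adjacency, visual
#: contrast and boundary strength families)
SECONDARY_COLS = [
    "caa_area_diversity",
    "caa_area_evenness",
    "caa_transition_diversity",
    "caa_hv_ratio",
    "vca_chromatic_mean",
    "vca_chromatic_cv",
    "vca_luminance_mean",
    "vca_luminance_cv",
    "bsa_chromatic_mean",
    "bsa_chromatic_cv",
    "bsa_luminance_mean",
    "bsa_luminance_cv",
]

METRIC_COLS = CLUSTER_COLS + EDGE_COLS + SECONDARY_COLS

#: study factors attached to every ROI row
FACTOR_COLS = ["lizard_id", "location", "clade", "habitat", "sex", "svl"]

#: structural columns
ID_COLS = ["roi_id", "roi_type", "background_id", "is_perch", "corrupted"]

ALL_COLS = ID_COLS + FACTOR_COLS + METRIC_COLS

#: hard lower bounds applied to generated/extracted metrics
METRIC_FLOORS = {
    "n_clusters": 1.0,
    "counts_within": 1.0,
    "area_largest": 1.0,
    "edge_color": 0.0,
    "edge_lum": 0.0,
    **{c: 0.0 for c in SECONDARY_COLS},
}


@dataclass
class StudyDataset:
    """All microhabitats of a study, one ROI per row.

    Attributes
    ----------
    table:
        DataFrame with the columns in :data:`ALL_COLS` (extra columns are
        allowed and preserved).  ``roi_type`` is ``"lizard"`` or
        ``"background"``; corrupted background rows stay in the table with
        ``corrupted=True`` and are excluded from analysis.
    design:
        The :class:`~perchmatch.synthgen.StudyDesign` that produced the
        table, or ``None`` for data read from disk.
    seed:
        Seed used by the generator, or ``None``.
    """

    table: pd.DataFrame
    design: Any = None
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def lizards(self) -> pd.DataFrame:
        return self.table[self.table["roi_type"] == "lizard"].reset_index(drop=True)

    def backgrounds(self, include_corrupted: bool = False) -> pd.DataFrame:
        bg = self.table[self.table["roi_type"] == "background"]
        if not include_corrupted:
            bg = bg[~bg["corrupted"]]
        return bg.reset_index(drop=True)

    def usable(self) -> pd.DataFrame:
        """Lizard rows plus non-corrupted background rows."""
        t = self.table
        keep = (t["roi_type"] == "lizard") | (~t["corrupted"])
        return t[keep].reset_index(drop=True)

    @property
    def n_lizards(self) -> int:
        return int((self.table["roi_type"] == "lizard").sum())

    @property
    def n_usable_backgrounds(self) -> int:
        return len(self.backgrounds())

    def validate(self) -> None:
        missing = [c for c in ALL_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset table is missing columns: {missing}")
        bad = self.table[FACTOR_COLS].isna().any(axis=1)
        if bad.any():
            rows = list(self.table.index[bad])
            raise ValueError(f"missing factor values in rows {rows}")
        liz = self.lizards()
        bg = self.table[self.table["roi_type"] == "background"]
        per_perch = bg[bg["is_perch"]].groupby("lizard_id").size()
        for lid in liz["lizard_id"]:
            if per_perch.get(lid, 0) != 1:
                raise ValueError(f"lizard {lid} does not have exactly one perch")
        if (bg[bg["is_perch"]]["corrupted"]).any():
            raise ValueError("a perch background is marked corrupted")

    def copy(self) -> "StudyDataset":
        return StudyDataset(
            table=self.table.copy(),
            design=self.design,
            seed=self.seed,
            provenance=dict(self.provenance),
        )


def metric_matrix(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Float matrix of the requested metric columns, in order."""
    return df[cols].to_numpy(dtype=float)
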