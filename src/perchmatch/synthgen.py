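"""Synthetic study generator.

Emulates the field design of a background-matching survey of *Amphibolurus
muricatus* (Jacky dragon): 52 lizards across 7 locations spanning 4 genetic
clades and 2 habitat classes, each lizard photographed with 6 background
options (one of which is its perch), with 3 background images lost to file
corruption.  Pattern metrics for lizards and backgrounds are drawn from
multivariate normals with controllable group structure so that every
downstream statistical stage can be exercised — and its effect-recovery
behavior tested — without the field data.

Two kinds of output are supported:

* metric tables (:func:`generate_study`) — the common path, feeding the
  component-space and statistics stages directly;
* planted-pattern cone-catch images (:func:`generate_scene`) — small
  5-channel images with known cluster ground truth, used to validate the
  image-metric chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import (
    CLUSTER_COLS,
    EDGE_COLS,
    METRIC_COLS,
    METRIC_FLOORS,
    SECONDARY_COLS,
    StudyDataset,
)

# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

#: location -> (clade, habitat, n_lizards); totals match the sampled design
#: (clade A: 16, B: 6, C: 25, D: 5 lizards; 52 total over 7 locations).
DEFAULT_LOCATIONS: dict[str, tuple[str, str, int]] = {
    "Werrikimbe": ("A", "other", 8),
    "GibraltarRanges": ("A", "other", 8),
    "Wyrrabalong": ("B", "coastal heath", 6),
    "Warrumbungle": ("C", "other", 8),
    "Murramarang": ("C", "coastal heath", 9),
    "Croajingalong": ("C", "coastal heath", 8),
    "YouYangs": ("D", "other", 5),
}


@dataclass(frozen=True)
class StudyDesign:
    """Structural description of the sampling design.

    Defaults reproduce the survey layout: 52 lizards, 7 locations, clades
    A–D, coastal-heath vs other habitat, 6 backgrounds per lizard and 3
    corrupted background images.
    """

    n_lizards: int = 52
    backgrounds_per_lizard: int = 6
    n_corrupted: int = 3
    locations: dict[str, tuple[str, str, int]] = field(
        default_factory=lambda: dict(DEFAULT_LOCATIONS)
    )
    svl_range: tuple[float, float] = (70.0, 120.0)  # snout-vent length, mm
    seed: int | None = None

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def clades(self) -> list[str]:
        return sorted({c for c, _, _ in self.locations.values()})

    @property
    def habitats(self) -> list[str]:
        return sorted({h for _, h, _ in self.locations.values()})

    def clade_of_location(self) -> dict[str, str]:
        return {loc: c for loc, (c, _, _) in self.locations.items()}

    def habitat_of_location(self) -> dict[str, str]:
        return {loc: h for loc, (_, h, _) in self.locations.items()}

    def lizards_per_location(self) -> dict[str, int]:
        counts = {loc: n for loc, (_, _, n) in self.locations.items()}
        total = sum(counts.values())
        if total == self.n_lizards:
            return counts
        # re-distribute round-robin when n_lizards deviates from the map
        locs = list(self.locations)
        counts = {loc: 0 for loc in locs}
        for i in range(self.n_lizards):
            counts[locs[i % len(locs)]] += 1
        return counts

    def validate(self) -> None:
        if self.backgrounds_per_lizard < 2:
            raise ValueError("backgrounds_per_lizard must be >= 2")
        total_bg = self.n_lizards * self.backgrounds_per_lizard
        if self.n_corrupted >= total_bg:
            raise ValueError(
                f"n_corrupted ({self.n_corrupted}) must be below the total "
                f"number of backgrounds ({total_bg})"
            )
        removable = self.n_lizards * (self.backgrounds_per_lizard - 1)
        if self.n_corrupted > removable:
            raise ValueError(
                "n_corrupted exceeds the number of non-perch backgrounds"
            )
        if self.n_lizards < 1 or self.n_locations < 1:
            raise ValueError("need at least one lizard and one location")
        if self.svl_range[0] >= self.svl_range[1]:
            raise ValueError("svl_range must be an increasing interval")


# ---------------------------------------------------------------------------
# effect specification
# ---------------------------------------------------------------------------

DEFAULT_MEANS = {
    "n_clusters": 6.0,
    "counts_within": 14.0,
    "area_largest": 300.0,
    "edge_color": 3.0,
    "edge_lum": 4.0,
    "caa_area_diversity": 1.2,
    "caa_area_evenness": 0.7,
    "caa_transition_diversity": 1.0,
    "caa_hv_ratio": 1.0,
    "vca_chromatic_mean": 4.0,
    "vca_chromatic_cv": 0.5,
    "vca_luminance_mean": 5.0,
    "vca_luminance_cv": 0.5,
    "bsa_chromatic_mean": 4.5,
    "bsa_chromatic_cv": 0.5,
    "bsa_luminance_mean": 5.5,
    "bsa_luminance_cv": 0.5,
}

DEFAULT_SDS = {
    "n_clusters": 1.5,
    "counts_within": 4.0,
    "area_largest": 70.0,
    "edge_color": 0.7,
    "edge_lum": 0.9,
    "caa_area_diversity": 0.25,
    "caa_area_evenness": 0.12,
    "caa_transition_diversity": 0.25,
    "caa_hv_ratio": 0.2,
    "vca_chromatic_mean": 0.8,
    "vca_chromatic_cv": 0.12,
    "vca_luminance_mean": 1.0,
    "vca_luminance_cv": 0.12,
    "bsa_chromatic_mean": 0.9,
    "bsa_chromatic_cv": 0.12,
    "bsa_luminance_mean": 1.1,
    "bsa_luminance_cv": 0.12,
}


@dataclass(frozen=True)
class EffectSpec:
    """Generative effect structure for a synthetic study.

    The model is hierarchical: every metric ``m`` has a species-level mean
    ``mu_m`` and scale ``sd_m``; each location receives a random offset with
    standard deviation ``location_scatter * sd_m`` (shared by its lizards
    and backgrounds, which is what produces location-level clustering in
    the range-wide stage); each lizard is drawn around its location mean
    with scale ``lizard_sd_frac * sd_m``; each background is drawn around
    its *lizard's* vector with scale ``spread * sd_m``, where the
    microhabitat spread is

    ``spread = background_spread * exp(svl_spread_slope * z(SVL) + sum of
    matching spread_offsets)``.

    The spread is the single dial for planted group effects: it scales
    lizard-background distances, perch-to-optimal distances and convex-hull
    diversity together, so a negative log-offset for e.g. clade-D males
    lowers that group's mismatch and microhabitat diversity with the
    correct sign in every response.

    ``mismatched_location`` shifts every background (not the lizards) of
    one location away from the local pattern by ``mismatch_size`` species
    SDs on all metrics, producing a location whose lizards sit closer to
    outside backgrounds than to their own.
    """

    means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SDS))
    lizard_sd_frac: float = 0.5
    location_scatter: float = 0.6
    background_spread: float = 1.0
    #: sequence of (factor-selector, log-spread offset); a selector such as
    #: ``{"sex": "M", "clade": "D"}`` matches lizards with all those levels
    spread_offsets: tuple[tuple[tuple[tuple[str, str], ...], float], ...] = ()
    svl_spread_slope: float = 0.0
    mismatched_location: str | None = None
    mismatch_size: float = 4.0
    perch_rule: str = "random"  # random | optimal | kth_closest
    perch_k: int = 2

    def validate(self, design: StudyDesign) -> None:
        if set(self.means) != set(METRIC_COLS) or set(self.sds) != set(METRIC_COLS):
            raise ValueError("means/sds must cover exactly the metric columns")
        if any(s <= 0 for s in self.sds.values()):
            raise ValueError("metric SDs must be positive")
        if self.perch_rule not in ("random", "optimal", "kth_closest"):
            raise ValueError(f"unknown perch_rule {self.perch_rule!r}")
        if self.perch_rule == "kth_closest" and not (
            1 <= self.perch_k <= design.backgrounds_per_lizard
        ):
            raise ValueError("perch_k out of range")
        if (
            self.mismatched_location is not None
            and self.mismatched_location not in design.locations
        ):
            raise ValueError(
                f"mismatched_location {self.mismatched_location!r} not in design"
            )

    def with_offset(self, selector: dict[str, str], offset: float) -> "EffectSpec":
        """Return a copy with one more planted log-spread offset."""
        key = tuple(sorted(selector.items()))
        return replace(self, spread_offsets=self.spread_offsets + ((key, offset),))


def _matches(selector: tuple[tuple[str, str], ...], row: dict) -> bool:
    return all(row.get(k) == v for k, v in selector)


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def generate_study(
    design: StudyDesign | None = None,
    effects: EffectSpec | None = None,
    seed: int | None = None,
) -> StudyDataset:
    """Generate a complete synthetic study dataset.

    Returns a :class:`StudyDataset` with ``n_lizards`` lizard rows and
    ``n_lizards * backgrounds_per_lizard`` background rows of which exactly
    ``n_corrupted`` non-perch rows are flagged corrupted.  Identical
    ``(design, effects, seed)`` yield identical tables.
    """
    design = design or StudyDesign()
    effects = effects or EffectSpec()
    design.validate()
    effects.validate(design)
    if seed is None:
        seed = design.seed if design.seed is not None else 0

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mu = np.array([effects.means[c] for c in METRIC_COLS])
    sd = np.array([effects.sds[c] for c in METRIC_COLS])
    p = len(METRIC_COLS)

    loc_names = list(design.locations)
    loc_offsets = {
        loc: rng.normal(0.0, effects.location_scatter, size=p) * sd
        for loc in loc_names
    }
    clade_of = design.clade_of_location()
    habitat_of = design.habitat_of_location()
    per_loc = design.lizards_per_location()

    svl_lo, svl_hi = design.svl_range
    svl_mid = 0.5 * (svl_lo + svl_hi)
    svl_halfspan = 0.5 * (svl_hi - svl_lo)

    rows: list[dict] = []
    lid_counter = 0
    for loc in loc_names:
        for _ in range(per_loc[loc]):
            lid_counter += 1
            lid = f"L{lid_counter:03d}"
            sex = rng.choice(["F", "M"])
            svl = rng.uniform(svl_lo, svl_hi)
            factors = {
                "lizard_id": lid,
                "location": loc,
                "clade": clade_of[loc],
                "habitat": habitat_of[loc],
                "sex": sex,
                "svl": svl,
            }
            lizard_vec = (
                mu + loc_offsets[loc] + rng.normal(0.0, effects.lizard_sd_frac, p) * sd
            )

            log_spread = np.log(effects.background_spread)
            log_spread += effects.svl_spread_slope * (svl - svl_mid) / svl_halfspan
            for selector, off in effects.spread_offsets:
                if _matches(selector, factors):
                    log_spread += off
            spread = float(np.exp(log_spread))

            bg_vecs = lizard_vec + rng.normal(0.0, spread, (design.backgrounds_per_lizard, p)) * sd
            if loc == effects.mismatched_location:
                bg_vecs = bg_vecs + effects.mismatch_size * sd

            perch_idx = _choose_perch(effects, rng, lizard_vec, bg_vecs, sd)
            if effects.perch_rule == "optimal":
                # the perch is a near-copy of the lizard's own pattern, which
                # makes it the distance minimizer in every component space
                bg_vecs[perch_idx] = lizard_vec + 1e-6 * sd * rng.normal(0.0, 1.0, p)

            rows.append(
                {
                    "roi_id": f"{lid}_dorsal",
                    "roi_type": "lizard",
                    "background_id": "",
                    "is_perch": False,
                    "corrupted": False,
                    **factors,
                    **dict(zip(METRIC_COLS, lizard_vec)),
                }
            )
            for j in range(design.backgrounds_per_lizard):
                bid = f"{lid}_bg{j + 1}"
                rows.append(
                    {
                        "roi_id": bid,
                        "roi_type": "background",
                        "background_id": bid,
                        "is_perch": j == perch_idx,
                        "corrupted": False,
                        **factors,
                        **dict(zip(METRIC_COLS, bg_vecs[j])),
                    }
                )

    table = pd.DataFrame(rows)
    for c, floor in METRIC_FLOORS.items():
        table[c] = table[c].clip(lower=floor)

    ds = StudyDataset(
        table=table,
        design=design,
        seed=seed,
        provenance={"generator": "perchmatch.synthgen.generate_study", "seed": seed},
    )
    if design.n_corrupted:
        ds = corrupt_backgrounds(ds, design.n_corrupted, seed=int(rng.integers(2**31)))
    ds.validate()
    return ds


def _choose_perch(
    effects: EffectSpec,
    rng: np.random.Generator,
    lizard_vec: np.ndarray,
    bg_vecs: np.ndarray,
    sd: np.ndarray,
) -> int:
    if effects.perch_rule == "random":
        return int(rng.integers(len(bg_vecs)))
    # rank backgrounds by generator-scale distance to the lizard
    d = np.linalg.norm((bg_vecs - lizard_vec) / sd, axis=1)
    order = np.argsort(d, kind="stable")
    if effects.perch_rule == "optimal":
        return int(order[0])
    return int(order[effects.perch_k - 1])


def corrupt_backgrounds(dataset: StudyDataset, n: int, seed: int | None = None) -> StudyDataset:
    """Flag ``n`` non-perch background rows as corrupted (file loss).

    Perches are never removed — every microhabitat keeps its perch and at
    least one alternative.  With a fixed seed the same rows are removed on
    rerun.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    out = dataset.copy()
    if n == 0:
        return out
    t = out.table
    candidates = t.index[
        (t["roi_type"] == "background") & ~t["is_perch"] & ~t["corrupted"]
    ]
    # keep at least one usable non-perch alternative per lizard
    usable_alt = (
        t.loc[candidates].groupby("lizard_id").size().to_dict()
    )
    if n > len(candidates):
        raise ValueError(
            f"cannot corrupt {n} backgrounds: only {len(candidates)} removable rows"
        )
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    remaining = {lid: cnt for lid, cnt in usable_alt.items()}
    pool = list(candidates)
    rng.shuffle(pool)
    for idx in pool:
        if len(chosen) == n:
            break
        lid = t.at[idx, "lizard_id"]
        if remaining[lid] <= 1:
            continue  # would leave the lizard without an alternative
        chosen.append(idx)
        remaining[lid] -= 1
    if len(chosen) < n:
        raise ValueError("cannot corrupt that many rows without emptying a microhabitat")
    out.table.loc[chosen, "corrupted"] = True
    return out


# ---------------------------------------------------------------------------
# planted-pattern cone-catch scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchSpec:
    """One planted color: a 5-channel cone-catch value, target patch area
    in pixels, and the number of disjoint patches of that color."""

    catch: tuple[float, float, float, float, float]
    area_px: int
    count: int = 1


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int] = (64, 64)
    mm_per_px: float = 0.5
    background_catch: tuple[float, float, float, float, float] = (
        0.2, 0.2, 0.2, 0.2, 0.2,
    )
    patches: tuple[PatchSpec, ...] = ()

    def validate(self) -> None:
        if min(self.shape) < 4:
            raise ValueError("scene must be at least 4x4")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if any(v <= 0 for v in self.background_catch):
            raise ValueError("background catches must be positive")
        for pspec in self.patches:
            if any(v <= 0 for v in pspec.catch):
                raise ValueError("patch catches must be positive")
            if pspec.area_px < 1 or pspec.count < 1:
                raise ValueError("patch area and count must be >= 1")


def _patch_footprint(area: int) -> np.ndarray:
    """Boolean footprint of exactly ``area`` pixels: a near-square rectangle
    plus a partial final row, keeping the patch 4-connected."""
    h = max(1, int(round(np.sqrt(area))))
    w = area // h
    rem = area - h * w
    if w == 0:
        h, w, rem = 1, area, 0
    fp = np.zeros((h + (1 if rem else 0), w), dtype=bool)
    fp[:h, :w] = True
    if rem:
        fp[h, :rem] = True
    return fp


def generate_scene(spec: SceneSpec, seed: int | None = None, max_tries: int = 500):
    """Render a planted-pattern cone-catch image with ground truth.

    Patches are placed uniformly at random without overlap, separated by at
    least one background pixel so that patches of the same color remain
    distinct connected components.  Returns ``(image, roi_mask, truth)``
    where ``truth`` records the planted label map, per-color patch counts,
    exact areas and catch vectors.

    Raises ``RuntimeError`` if a patch cannot be placed within
    ``max_tries`` attempts.
    """
    from .visionmetrics import ConeCatchImage  # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(seed)
    H, W = spec.shape
    img = np.empty((H, W, 5), dtype=float)
    img[:] = np.asarray(spec.background_catch)
    labels = np.zeros((H, W), dtype=int)  # 0 = background
    blocked = np.zeros((H, W), dtype=bool)  # footprint + 1 px margin

    truth_colors = [{"catch": list(spec.background_catch), "patch_areas": []}]
    for ci, pspec in enumerate(spec.patches, start=1):
        color_rec = {"catch": list(pspec.catch), "patch_areas": []}
        fp = _patch_footprint(pspec.area_px)
        fh, fw = fp.shape
        if fh > H or fw > W:
            raise RuntimeError("patch footprint does not fit in the scene")
        for _ in range(pspec.count):
            placed = False
            for _try in range(max_tries):
                r = int(rng.integers(0, H - fh + 1))
                c = int(rng.integers(0, W - fw + 1))
                if blocked[r : r + fh, c : c + fw][fp].any():
                    continue
                img[r : r + fh, c : c + fw][fp] = np.asarray(pspec.catch)
                labels[r : r + fh, c : c + fw][fp] = ci
                r0, r1 = max(0, r - 1), min(H, r + fh + 1)
                c0, c1 = max(0, c - 1), min(W, c + fw + 1)
                blocked[r0:r1, c0:c1] = True
                color_rec["patch_areas"].append(int(fp.sum()))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    "could not place all patches without overlap; "
                    "reduce patch area/count or enlarge the scene"
                )
        truth_colors.append(color_rec)

    roi = np.ones((H, W), dtype=bool)
    from scipy import ndimage

    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    bg_cc, n_bg_patches = ndimage.label(labels == 0, structure=four)
    truth_colors[0]["patch_areas"] = [
        int((bg_cc == i).sum()) for i in range(1, n_bg_patches + 1)
    ]
    truth = {
        "label_map": labels,
        "colors": truth_colors,
        "n_colors": 1 + len(spec.patches),
        "patch_counts": [n_bg_patches]
        + [len(c["patch_areas"]) for c in truth_colors[1:]],
        "areas_px": [
            (labels == i).sum() for i in range(1 + len(spec.patches))
        ],
        "mm_per_px": spec.mm_per_px,
    }
    image = ConeCatchImage(data=img, mm_per_px=spec.mm_per_px)
    return image, roi, truth
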