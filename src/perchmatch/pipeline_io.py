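"""Configuration, table I/O and end-to-end pipeline orchestration."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import ALL_COLS, FACTOR_COLS, METRIC_COLS, StudyDataset
from .diversity import fit_diversity_glm, microhabitat_hulls
from .matching import fit_matching_glm, optimal_calls, proportion_test_by_clade
from .rangewide import (
    all_pairs_distances,
    location_mean_points,
    pairwise_hotelling,
    within_vs_between,
)
from .spaces import SPACES, build_component_table
from .synthgen import EffectSpec, StudyDesign, generate_study

_TABLE_HEADER = (
    "# perchmatch metric table: one row per ROI (lizard dorsal or background).\n"
    "# Units: area_largest mm^2; edge_* and *_mean JND; svl mm; diversities nats.\n"
)


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    mode: str = "synthetic"  # synthetic | metric-table
    metric_table: str | None = None  # input path for metric-table mode
    design: dict = field(default_factory=dict)  # StudyDesign overrides
    effects: dict = field(default_factory=dict)  # EffectSpec overrides
    standardize: str = "zscore"
    n_perm: int = 999
    alpha: float = 0.05
    adjust_emm: str = "holm"
    adjust_hotelling: str = "bonferroni"
    seed: int = 0
    outdir: str = "perchmatch_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_dict(self) -> dict:
        return asdict(self)


def write_metric_table(dataset: StudyDataset, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_TABLE_HEADER)
        dataset.table.to_csv(fh, sep="\t", index=False)


def read_metric_table(path) -> StudyDataset:
    """Read and validate a metric table written by :func:`write_metric_table`.

    Unknown columns are preserved; missing required columns or missing
    factor values are rejected with the offending rows named.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ALL_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"metric table {path} is missing columns: {missing}")
    bad = table[FACTOR_COLS + METRIC_COLS].isna().any(axis=1)
    if bad.any():
        rows = [int(i) for i in table.index[bad]]
        raise ValueError(f"malformed rows (missing values) at index {rows}")
    table["is_perch"] = table["is_perch"].astype(bool)
    table["corrupted"] = table["corrupted"].astype(bool)
    table["background_id"] = table["background_id"].fillna("")
    ds = StudyDataset(table=table, provenance={"source": str(path)})
    ds.validate()
    return ds


def build_design(config: RunConfig) -> StudyDesign:
    return replace(StudyDesign(), **config.design) if config.design else StudyDesign()


def build_effects(config: RunConfig) -> EffectSpec:
    eff = config.effects
    if not eff:
        return EffectSpec()
    eff = dict(eff)
    if "spread_offsets" in eff:
        eff["spread_offsets"] = tuple(
            (tuple(sorted(dict(sel).items())), float(off))
            for sel, off in eff["spread_offsets"]
        )
    return replace(EffectSpec(), **eff)


def _glm_table_tsv(result, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# response: {result.response}  transform: {result.transform}\n")
        fh.write(
            f"# n_obs: {result.n_obs}  excluded: {result.n_excluded}  "
            f"residual_df: {result.residual_df}  residual_dev: {result.residual_deviance:.6g}\n"
        )
        result.table.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute every stage and (optionally) write all outputs.

    Stages: dataset acquisition (synthetic generation or metric-table
    load) -> component spaces -> matching (optimal calls, proportion
    tests, GLMs) -> diversity (hulls, GLMs) -> range-wide (distance
    matrices, location means, Hotelling comparisons, within-vs-outside
    summaries).  Returns the result bundle as a dict; identical configs
    produce identical outputs.
    """
    log: list[str] = []
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage: dataset -------------------------------------------------
    if config.mode == "synthetic":
        design = build_design(config)
        effects = build_effects(config)
        dataset = generate_study(design, effects, seed=config.seed)
        log.append(f"generated synthetic study: {dataset.n_lizards} lizards, "
                   f"{dataset.n_usable_backgrounds} usable backgrounds")
    elif config.mode == "metric-table":
        if not config.metric_table:
            raise ValueError("metric-table mode requires metric_table path")
        dataset = read_metric_table(config.metric_table)
        log.append(f"loaded metric table {config.metric_table}")
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    if write:
        write_metric_table(dataset, outdir / "dataset.tsv")

    # ---- stage: spaces --------------------------------------------------
    comp, fit = build_component_table(
        dataset.usable(), n_perm=config.n_perm, seed=config.seed,
        standardize=config.standardize,
    )
    log.append(
        "fitted visual space: eigenvalues "
        + ", ".join(f"{v:.3f}" for v in fit.eigenvalues[:3])
        + f"; supported components: {int(fit.supported.sum()) if fit.supported is not None else 'n/a'}"
    )
    if write:
        comp.to_csv(outdir / "components.tsv", sep="\t", index=False)
        fit.to_json(outdir / "pca_fit.json")

    liz = comp[comp["roi_type"] == "lizard"]
    factors = liz[["lizard_id", "location", "clade", "habitat", "sex", "svl"]]

    # ---- stage: matching ------------------------------------------------
    calls = {}
    prop_tests = []
    matching_glms = {}
    clades = sorted(liz["clade"].unique())
    for space in SPACES:
        oc = optimal_calls(comp, space).merge(factors, on="lizard_id")
        calls[space] = oc
        succ = [int(oc[(oc["clade"] == c) & oc["on_optimal"]].shape[0]) for c in clades]
        tot = [int(oc[oc["clade"] == c].shape[0]) for c in clades]
        chi2, dfree, p = proportion_test_by_clade(succ, tot, clades)
        prop_tests.append(
            {"space": space, "chi2": chi2, "df": dfree, "p": p,
             **{f"n_optimal_{c}": s for c, s in zip(clades, succ)},
             **{f"n_total_{c}": t for c, t in zip(clades, tot)}}
        )
        for response in ("d_lp", "d_po"):
            try:
                res = fit_matching_glm(oc, response, space, alpha=config.alpha)
            except ValueError as err:
                log.append(f"matching GLM {response}[{space}] skipped: {err}")
                continue
            matching_glms[(response, space)] = res
            used = res.table.set_index("term")["ss_type"].to_dict()
            log.append(f"matching GLM {response}[{space}]: SS types {used}")
            if write:
                _glm_table_tsv(res, outdir / f"glm_{response}_{space}.tsv")
        if write:
            oc.to_csv(outdir / f"optimal_calls_{space}.tsv", sep="\t", index=False)
    prop_df = pd.DataFrame(prop_tests)
    if write:
        prop_df.to_csv(outdir / "proportion_tests.tsv", sep="\t", index=False)

    # ---- stage: diversity -----------------------------------------------
    hulls = {}
    diversity_glms = {}
    for space in SPACES:
        ht = microhabitat_hulls(comp, space).merge(factors, on="lizard_id")
        hulls[space] = ht
        try:
            res = fit_diversity_glm(ht, alpha=config.alpha)
            diversity_glms[space] = res
            log.append(
                f"diversity GLM hull[{space}]: degenerate excluded {res.n_excluded}"
            )
            if write:
                _glm_table_tsv(res, outdir / f"glm_hull_{space}.tsv")
        except ValueError as err:
            log.append(f"diversity GLM hull[{space}] skipped: {err}")
        if write:
            ht.to_csv(outdir / f"hulls_{space}.tsv", sep="\t", index=False)

    # ---- stage: range-wide ----------------------------------------------
    matrices = {space: all_pairs_distances(comp, space) for space in SPACES}
    points = location_mean_points(comp)
    log.append(
        f"species-wide: {matrices['cluster'].size} distances per space, "
        f"{len(points)} location mean points"
    )
    dims3 = [f"mean_{s}" for s in SPACES]
    hotelling = {}
    for group_col, label in (
        ("lizard_clade", "clade"),
        ("background_habitat", "habitat"),
        ("location", "location"),
    ):
        res, heat = pairwise_hotelling(
            points, group_col, tuple(dims3), adjust=config.adjust_hotelling
        )
        hotelling[(label, "3d")] = (res, heat)
        if write:
            res.to_csv(outdir / f"hotelling_{label}_3d.tsv", sep="\t", index=False)
            heat.to_csv(outdir / f"heatmap_{label}_3d.tsv", sep="\t")
        for da, db in (("cluster", "edge"), ("cluster", "visual"), ("edge", "visual")):
            res2, heat2 = pairwise_hotelling(
                points, group_col, (f"mean_{da}", f"mean_{db}"),
                adjust=config.adjust_hotelling,
            )
            hotelling[(label, f"{da}-{db}")] = (res2, heat2)
            if write:
                res2.to_csv(outdir / f"hotelling_{label}_{da}_{db}.tsv", sep="\t", index=False)

    liz_loc = liz.set_index("lizard_id")["location"]
    bgs = comp[(comp["roi_type"] == "background")]
    bg_loc = bgs.set_index("background_id")["location"]
    wvb = {}
    for space in SPACES:
        wvb[space] = within_vs_between(matrices[space], liz_loc, bg_loc)
        if write:
            wvb[space].to_csv(outdir / f"within_vs_between_{space}.tsv", sep="\t", index=False)
            matrices[space].to_csv(outdir / f"species_matrix_{space}.tsv", sep="\t")
    if write:
        points.to_csv(outdir / "location_means.tsv", sep="\t", index=False)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "perchmatch_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "log": log,
    }
    if write:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    return {
        "dataset": dataset,
        "components": comp,
        "pca_fit": fit,
        "optimal_calls": calls,
        "proportion_tests": prop_df,
        "matching_glms": matching_glms,
        "hulls": hulls,
        "diversity_glms": diversity_glms,
        "matrices": matrices,
        "location_points": points,
        "hotelling": hotelling,
        "within_vs_between": wvb,
        "manifest": manifest,
    }


def heatmap_figure(heat: pd.DataFrame, path, title: str = "") -> None:
    """Render a chi-square heat-map matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(heat.to_numpy(dtype=float), cmap="viridis")
    ax.set_xticks(range(len(heat.columns)), heat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(heat.index)), heat.index)
    fig.colorbar(im, ax=ax, label="chi-square")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
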