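"""Pipeline orchestration: synth -> assemble -> metrics -> nulls -> stats.

Every stage reads its inputs from, and writes its outputs to, a single run
directory, so stages can be run one at a time or end to end.  A manifest
records the config, seeds, per-stage timings, filter accounting
(species_in = retained + excluded at every filter) and output hashes.
Rerunning with the same config and seed reproduces all numeric outputs
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, metrics, nullmodels, spatial, synth
from .grid import Grid
from .traits import TraitTable


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the study's stated constants
    (999 null replicates, +/-1.96 dispersion thresholds, |r| < 0.7 and
    VIF < 5 collinearity thresholds)."""

    landscape: synth.LandscapeConfig = field(default_factory=synth.LandscapeConfig)
    n_reps: int = 999
    trades_per_rep: int | None = None
    ses_threshold: float = 1.96
    r_max: float = 0.7
    vif_max: float = 5.0
    gls_method: str = "REML"
    fd_max_dim: int = 9
    fd_log_transform: bool = True
    predictors: list[str] = field(
        default_factory=lambda: list(synth.DEFAULT_PREDICTORS)
    )
    apply_suitability: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.landscape, dict):
            self.landscape = synth.LandscapeConfig.from_dict(self.landscape)
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        # one seed to rule the run: the landscape inherits it
        self.landscape = synth.LandscapeConfig(
            **{**asdict(self.landscape), "seed": self.seed}
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stages


def stage_synth(config: RunConfig, out: Path) -> dict:
    study = synth.generate_study(config.landscape)
    synth.write_study(study, out / "synth")
    return {"n_species": config.landscape.n_species,
            "n_cells": study.grid.n_cells}


def _load_synth(out: Path):
    sdir = out / "synth"
    if not sdir.exists():
        raise FileNotFoundError(f"missing synth stage outputs: {sdir}")
    grid = Grid.from_dict(json.load(open(sdir / "grid.json")))
    elevation = np.loadtxt(sdir / "elevation.csv", delimiter=",").ravel()
    habitat = np.loadtxt(sdir / "habitat.csv", delimiter=",").astype(int).ravel()
    ranges = assembly.ranges_from_geojson(sdir / "ranges.geojson")
    traits_path = sdir / "traits.csv"
    if not traits_path.exists():
        raise FileNotFoundError(f"missing trait file: {traits_path}")
    traits = TraitTable.from_csv(traits_path)
    tree = synth.read_newick(sdir / "tree.nwk")
    predictors = pd.read_csv(sdir / "predictors.csv")
    suitability = np.loadtxt(sdir / "suitability.csv", delimiter=",").astype(bool)
    regions = pd.read_csv(sdir / "regions.csv")["region"].to_numpy()
    return grid, elevation, habitat, ranges, traits, tree, predictors, suitability, regions


def stage_assemble(config: RunConfig, out: Path) -> dict:
    grid, elevation, habitat, ranges, traits, _, _, suitability, _ = _load_synth(out)
    adir = out / "assemble"
    adir.mkdir(parents=True, exist_ok=True)

    raw = assembly.build_presence(ranges, grid)
    refined, removed = assembly.refine_occurrences(raw, ranges, elevation, habitat)
    if config.apply_suitability:
        refined = synth.apply_suitability(refined, suitability)
    final, excluded = assembly.filter_trait_complete(refined, traits)

    raw.to_csv(adir / "presence_raw.csv")
    refined.to_csv(adir / "presence_refined.csv")
    final.to_csv(adir / "presence.csv")
    final.to_triplets(adir / "presence_triplets.tsv")
    log = {
        "species_in": len(raw.species),
        "species_retained": len(final.species),
        "species_excluded_incomplete_traits": len(excluded),
        "excluded_species": excluded,
        "cells_removed_by_refinement": removed,
        "low_richness_cells": int((final.richness < 2).sum()),
    }
    with open(adir / "assembly_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return log


def stage_metrics(config: RunConfig, out: Path) -> dict:
    _, _, _, _, traits, tree, _, _, regions = _load_synth(out)
    presence = assembly.PresenceMatrix.from_csv(out / "assemble" / "presence.csv")
    mdir = out / "metrics"
    mdir.mkdir(parents=True, exist_ok=True)
    profile = metrics.diversity_profile(
        presence, traits, tree,
        log_transform=config.fd_log_transform, max_dim=config.fd_max_dim,
    )
    profile.to_csv(mdir / "diversity.csv", index=False, float_format="%.10g")
    summary = metrics.profile_summary(profile, groups=pd.Series(regions))
    summary.to_csv(mdir / "diversity_summary.csv", index=False,
                   float_format="%.10g")
    return {
        "cells_fd_defined": int(profile["FD"].notna().sum()),
        "cells_pd_defined": int(profile["PD"].notna().sum()),
        "cells_low_richness": int((profile["richness"] < 2).sum()),
    }


def stage_nulls(config: RunConfig, out: Path) -> dict:
    _, _, _, _, traits, tree, _, _, _ = _load_synth(out)
    presence = assembly.PresenceMatrix.from_csv(out / "assemble" / "presence.csv")
    profile = pd.read_csv(out / "metrics" / "diversity.csv")
    ndir = out / "nulls"
    ndir.mkdir(parents=True, exist_ok=True)

    space = metrics.TraitSpace(
        traits.subset(presence.species),
        log_transform=config.fd_log_transform, max_dim=config.fd_max_dim,
    )
    lengths, A = metrics.branch_incidence(tree, presence.species)

    def fd_metric(data: np.ndarray) -> np.ndarray:
        m = assembly.PresenceMatrix(presence.species, presence.cells, data)
        return metrics.fric_cells(space, m)[0]

    def pd_metric(data: np.ndarray) -> np.ndarray:
        covered = A.T.astype(np.int32) @ data.astype(np.int32) > 0
        vals = (lengths @ covered).astype(float)
        vals[data.sum(axis=0) < 2] = np.nan
        return vals

    ensemble = nullmodels.generate_nulls(
        presence,
        metrics={"FD": fd_metric, "PD": pd_metric},
        n_reps=config.n_reps,
        trades_per_rep=config.trades_per_rep,
        seed=config.seed,
        checkpoint=ndir / "checkpoint.npz",
    )
    results = {}
    for name in ("FD", "PD"):
        ses = nullmodels.compute_ses(
            profile[name].to_numpy(), ensemble.metrics[name],
            cells=presence.cells, threshold=config.ses_threshold,
        )
        ses.to_csv(ndir / f"ses_{name.lower()}.csv")
        results[name] = {"counts": {k: int(v) for k, v in ses.counts.items()}}
    with open(ndir / "ensemble.json", "w") as fh:
        json.dump(ensemble.to_json_meta(), fh, indent=1)
    (ndir / "checkpoint.npz").unlink(missing_ok=True)
    return results


def stage_stats(config: RunConfig, out: Path) -> dict:
    grid, _, _, _, _, _, predictors, _, regions = _load_synth(out)
    profile = pd.read_csv(out / "metrics" / "diversity.csv")
    sdir = out / "stats"
    sdir.mkdir(parents=True, exist_ok=True)

    coords = grid.centroids()
    screen_retained, screen_log = spatial.collinearity_screen(
        predictors[synth.CANDIDATE_PREDICTORS], r_max=config.r_max,
        vif_max=config.vif_max,
    )
    X_std, std_params = spatial.standardize(predictors[config.predictors])
    std_params.to_csv(sdir / "standardization.csv", float_format="%.10g")

    responses = {"richness": profile["richness"].to_numpy(dtype=float)}
    for name in ("fd", "pd"):
        path = out / "nulls" / f"ses_{name}.csv"
        if path.exists():
            responses[f"ses_{name}"] = pd.read_csv(path)["ses"].to_numpy()

    gls_meta = {}
    for resp_name, y in responses.items():
        ok = np.isfinite(y)
        if ok.sum() <= len(config.predictors) + 3:
            gls_meta[resp_name] = {"skipped": "too few defined cells",
                                   "n": int(ok.sum())}
            continue
        model = spatial.ExponentialGLS(
            y[ok], X_std[ok], coords[ok], method=config.gls_method
        )
        res = model.fit()
        res.to_frame().to_csv(sdir / f"gls_{resp_name}.csv",
                              index_label="variable", float_format="%.10g")
        gls_meta[resp_name] = {
            "rho": res.rho, "loglik": res.loglik, "n": res.nobs,
            "converged": res.converged,
        }

    # spatial correlations of FD/PD with richness (modified t-test)
    corr_rows = []
    for name in ("FD", "PD"):
        vals = profile[name].to_numpy()
        ok = np.isfinite(vals)
        if ok.sum() >= 10:
            mc = spatial.modified_ttest(
                profile["richness"].to_numpy(dtype=float)[ok], vals[ok], coords[ok]
            )
            corr_rows.append(
                {"pair": f"richness_vs_{name}", "r": mc.r, "n": mc.n,
                 "n_eff": mc.n_eff, "t": mc.t, "p": mc.p}
            )
    pd.DataFrame(corr_rows).to_csv(sdir / "correlations.csv", index=False,
                                   float_format="%.10g")

    # group comparisons among synthetic regions
    group_rows = []
    for name in ("richness", "FD", "PD"):
        vals = profile[name].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        # keep only regions with enough defined cells to compare
        labels, counts = np.unique(regions[ok], return_counts=True)
        usable = set(labels[counts >= 2])
        if len(usable) < 2:
            group_rows.append({"metric": name, "H": np.nan, "p": np.nan,
                               "letters": "{}"})
            continue
        ok &= np.isin(regions, list(usable))
        gc = spatial.group_compare(vals[ok], regions[ok])
        group_rows.append(
            {"metric": name, "H": gc.h, "p": gc.p,
             "letters": json.dumps(gc.letters, sort_keys=True)}
        )
        gc.dunn.to_csv(sdir / f"dunn_{name.lower()}.csv", index=False,
                       float_format="%.10g")
    pd.DataFrame(group_rows).to_csv(sdir / "group_tests.csv", index=False,
                                    float_format="%.10g")

    with open(sdir / "fit_meta.json", "w") as fh:
        json.dump(
            {"gls": gls_meta, "screen_retained": screen_retained,
             "screen_log": screen_log, "gls_predictors": config.predictors},
            fh, indent=1, default=float,
        )
    return {"screen_retained": screen_retained, "gls": gls_meta}


STAGES = {
    "synth": stage_synth,
    "assemble": stage_assemble,
    "metrics": stage_metrics,
    "nulls": stage_nulls,
    "stats": stage_stats,
}


def run_pipeline(config: RunConfig, out_dir, stages: list[str] | None = None) -> dict:
    """Run the full pipeline (or selected stages) into ``out_dir``.

    Returns the manifest, which is also written to ``manifest.json``.
    On stage failure the manifest records partial completion and the error
    is re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    manifest: dict = {"seed": config.seed, "stages": {}, "complete": False}
    try:
        for name in stages or list(STAGES):
            t0 = time.perf_counter()
            info = STAGES[name](config, out)
            manifest["stages"][name] = {
                "info": info, "seconds": round(time.perf_counter() - t0, 3),
            }
        manifest["complete"] = True
    finally:
        manifest["output_hashes"] = {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*.csv"))
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)
    return manifest


def summarize(out_dir) -> str:
    """Text report of a completed run: facet means +/- SD over defined
    cells, per-region summaries and dispersion-class counts/fractions."""
    out = Path(out_dir)
    profile = pd.read_csv(out / "metrics" / "diversity.csv")
    lines = ["divfacets run summary", "====================="]
    for m in ("richness", "FD", "PD"):
        vals = profile[m].dropna()
        lines.append(
            f"{m}: mean {vals.mean():.2f} +/- {vals.std(ddof=1):.2f} "
            f"over {len(vals)} cells"
        )
    for name in ("fd", "pd"):
        path = out / "nulls" / f"ses_{name}.csv"
        if not path.exists():
            continue
        ses = pd.read_csv(path)
        defined = ses[ses["dispersion"] != "undefined"]
        n_def = len(defined)
        for cls in ("overdispersed", "underdispersed"):
            k = int((defined["dispersion"] == cls).sum())
            frac = 100.0 * k / n_def if n_def else 0.0
            lines.append(f"SES {name.upper()}: {k} cells {cls} ({frac:.2f}%)")
    gpath = out / "stats" / "group_tests.csv"
    if gpath.exists():
        for _, row in pd.read_csv(gpath).iterrows():
            lines.append(
                f"Kruskal-Wallis {row['metric']}: H = {row['H']:.2f}, "
                f"p = {row['p']:.3g}, letters = {row['letters']}"
            )
    return "\n".join(lines)
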