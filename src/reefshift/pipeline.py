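"""Orchestration of the full analysis: reconstruction, isolation sweep,
per-species SDMs, trait analysis, and assemblage mapping.

``run_all`` sequences the stages for a synthetic world (or inputs loaded
from disk), sweeping the thermal threshold over the configured list,
selecting the threshold whose historical-only models explain the most
deviance, and running the trait and assemblage analyses there.  Every
stage draws its randomness from a seed derived from the master seed by
stable hashing, and a manifest records config, seeds, and per-output
checksums so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .assemblage import RegressionSummary, cell_means, size_history_regression
from .grids import aggregate_to_analysis_grid
from .isolation import compute_isolation
from .paleo import ReconstructionConfig, build_suitability_stack, traversability_masks
from .sdm import run_sdms
from .synthetic import ScenarioConfig, SyntheticWorld, generate_world
from .traits import ModelSet, PglsResult, all_subsets_averaging, pgls_fit, quantile_slopes, trait_design

log = logging.getLogger("reefshift")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed below 2^31 by stable hashing of the stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """End-to-end options; ``scenario`` drives the synthetic world."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    min_presences: int = 10
    n_auc_repeats: int = 100
    train_frac: float = 0.7
    quantiles: tuple[float, ...] = (0.75, 0.9)
    size_transform: str = "cm"
    averaging: str = "conditional"
    selected_threshold_C: float | None = None  # None: pick the sweep peak


@dataclass
class SweepEntry:
    threshold_C: float
    mean_d2_historical: float
    mean_auc_historical: float
    n_converged: int
    sdm_results: pd.DataFrame = field(repr=False)


@dataclass
class PipelineResult:
    world: SyntheticWorld
    sweep: list[SweepEntry]
    selected_threshold_C: float
    sdm_results: pd.DataFrame
    model_set: ModelSet
    pgls: PglsResult
    quantile_fits: pd.DataFrame
    assemblage: pd.DataFrame
    assemblage_regression: RegressionSummary
    manifest: dict


def isolation_sweep(
    world: SyntheticWorld, thresholds: tuple[float, ...] | None = None
) -> dict[float, pd.Series]:
    """Aggregated IREF per analysis cell for each thermal threshold.

    Traversability (sea under the contemporaneous stand) is shared across
    thresholds; only the suitable set changes.
    """
    recon = world.recon_config
    thresholds = thresholds or recon.thresholds
    trav = traversability_masks(world.bathymetry, world.anomalies)
    out: dict[float, pd.Series] = {}
    rows = world.predictors["row"].to_numpy()
    cols = world.predictors["col"].to_numpy()
    from .synthetic import analysis_iref

    for th in thresholds:
        stack = build_suitability_stack(
            world.bathymetry, world.baseline_sst, world.anomalies, recon, th
        )
        iso = compute_isolation(stack, trav)
        coarse = analysis_iref(stack, iso, world.config.aggregation_factor)
        vals = coarse[rows, cols]
        # cells with no habitat at this threshold: maximal isolation proxy
        # (finite so the sweep can still compare thresholds on one cell set)
        fill = np.nanmax(vals) if np.isfinite(vals).any() else iso.unreachable_cap_km
        out[th] = pd.Series(np.where(np.isfinite(vals), vals, fill), index=world.predictors.index)
    return out


def sweep_historical_metrics(
    world: SyntheticWorld,
    irefs: dict[float, pd.Series] | None = None,
    n_auc_repeats: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean historical-only D^2 and AUC across species per threshold.

    The lean sweep experiment: per threshold, each species gets a
    quadratic logit fit on isolation alone, plus repeated split-sample
    AUC.  A threshold so permissive that isolation is constant over the
    analysis cells carries no information and scores D^2 = 0, AUC = 0.5.
    """
    from .sdm import auc_repeated_split, fit_glm_logit

    if irefs is None:
        irefs = isolation_sweep(world)
    rng = np.random.default_rng(seed)
    rows = []
    for th, ir in irefs.items():
        if np.ptp(ir.to_numpy()) == 0.0:
            rows.append({"threshold_C": th, "mean_d2_historical": 0.0,
                         "mean_auc_historical": 0.5, "n_converged": 0})
            continue
        X = pd.DataFrame({"IREF": ir})
        d2s, aucs = [], []
        for sp in world.occurrences.index:
            y = world.occurrences.loc[sp].to_numpy(float)
            fit = fit_glm_logit(y, X, str(sp), "historical")
            if not fit.converged:
                continue
            d2s.append(fit.d2)
            try:
                auc, _ = auc_repeated_split(y, X, n_repeats=n_auc_repeats, seed=rng)
                aucs.append(auc)
            except ValueError:
                pass
        rows.append(
            {
                "threshold_C": th,
                "mean_d2_historical": float(np.mean(d2s)) if d2s else 0.0,
                "mean_auc_historical": float(np.mean(aucs)) if aucs else 0.5,
                "n_converged": len(d2s),
            }
        )
    return pd.DataFrame(rows).set_index("threshold_C")


def run_sdm_stage(
    world: SyntheticWorld,
    iref: pd.Series | None = None,
    min_presences: int = 10,
    n_auc_repeats: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    auc_predictor_set: str = "full",
) -> pd.DataFrame:
    """SDMs over the analysis cells, optionally swapping in an alternative
    IREF column (threshold sweep)."""
    predictors = world.predictors.copy()
    if iref is not None:
        predictors["IREF"] = iref
    return run_sdms(
        world.occurrences,
        predictors,
        cellsize=world.analysis_spec.cellsize,
        min_presences=min_presences,
        n_auc_repeats=n_auc_repeats,
        train_frac=train_frac,
        seed=seed,
        auc_predictor_set=auc_predictor_set,
    )


def run_all(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the five stages and (optionally) write outputs + manifest."""
    master = config.scenario.seed
    log.info("generating world (seed=%d)", master)
    world = generate_world(config.scenario)
    world.recon_config = config.reconstruction

    log.info("threshold sweep over %s", config.reconstruction.thresholds)
    iref_by_threshold = isolation_sweep(world)
    sweep: list[SweepEntry] = []
    for th, iref in iref_by_threshold.items():
        res = run_sdm_stage(
            world,
            iref=iref,
            min_presences=config.min_presences,
            n_auc_repeats=config.n_auc_repeats,
            train_frac=config.train_frac,
            seed=stage_seed(master, f"sdm:{th}"),
            auc_predictor_set="historical",
        )
        ok = res[res["converged"]]
        sweep.append(
            SweepEntry(
                threshold_C=th,
                mean_d2_historical=float(ok["d2_historical"].mean()),
                mean_auc_historical=float(ok["auc_mean"].mean()),
                n_converged=len(ok),
                sdm_results=res,
            )
        )

    if config.selected_threshold_C is None:
        selected = max(sweep, key=lambda e: e.mean_d2_historical).threshold_C
    else:
        selected = config.selected_threshold_C
    log.info("selected threshold %.1f C", selected)

    sdm_results = run_sdm_stage(
        world,
        iref=iref_by_threshold[selected],
        min_presences=config.min_presences,
        n_auc_repeats=config.n_auc_repeats,
        train_frac=config.train_frac,
        seed=stage_seed(master, "sdm:final"),
        auc_predictor_set="full",
    )
    converged = sdm_results[sdm_results["converged"]]
    response = converged["pure_historical"].dropna()

    traits = world.traits.loc[response.index]
    model_set = all_subsets_averaging(
        response, traits, size_transform=config.size_transform, averaging=config.averaging
    )
    design = trait_design(traits, size_transform=config.size_transform)
    pgls = pgls_fit(response, design[["size"]], world.phylogeny)
    qfits = quantile_slopes(response, traits["size_cm"], quantiles=config.quantiles)

    per_species = pd.DataFrame(
        {"pure_historical": response, "size_cm": traits["size_cm"]}
    )
    summary = cell_means(world.occurrences, per_species)
    summary = summary.join(world.predictors[["lon", "lat"]])
    regression = size_history_regression(summary)

    manifest = {
        "master_seed": master,
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "stage_seeds": {f"sdm:{th}": stage_seed(master, f"sdm:{th}") for th in iref_by_threshold}
        | {"sdm:final": stage_seed(master, "sdm:final")},
        "selected_threshold_C": selected,
        "n_species_retained": int(len(converged)),
        "n_cells": int(len(world.predictors)),
    }

    result = PipelineResult(
        world=world,
        sweep=sweep,
        selected_threshold_C=selected,
        sdm_results=sdm_results,
        model_set=model_set,
        pgls=pgls,
        quantile_fits=qfits,
        assemblage=summary,
        assemblage_regression=regression,
        manifest=manifest,
    )
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(result: PipelineResult, out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.sdm_results.to_csv(out / "sdm_results.csv")
    result.model_set.table.to_csv(out / "trait_model_set.csv", index=False)
    result.model_set.averaged.to_csv(out / "trait_averaged_coefficients.csv")
    result.quantile_fits.to_csv(out / "quantile_slopes.csv")
    result.assemblage.to_csv(out / "assemblage.csv")
    pd.DataFrame(
        [
            {
                "threshold_C": e.threshold_C,
                "mean_d2_historical": e.mean_d2_historical,
                "mean_auc_historical": e.mean_auc_historical,
                "n_converged": e.n_converged,
            }
            for e in result.sweep
        ]
    ).to_csv(out / "threshold_sweep.csv", index=False)
    with open(out / "pgls.json", "w") as fh:
        json.dump(
            {
                "lambda": result.pgls.lam,
                "coefficients": result.pgls.params.to_dict(),
                "p_values": result.pgls.pvalues.to_dict(),
                "n": result.pgls.n,
            },
            fh,
            indent=2,
        )
    with open(out / "assemblage_regression.json", "w") as fh:
        json.dump(asdict(result.assemblage_regression), fh, indent=2)
    manifest = dict(result.manifest)
    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
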