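"""Synthetic Indo-Pacific world with known ground truth.

The generator builds every input the analysis pipeline consumes — sediment
cores, bathymetry, a pre-warming SST baseline, contemporary predictor
fields, species occurrences, traits, and a phylogeny — from a single seed,
together with the ground truth (true suitability stack, true isolation map,
true per-species GLM coefficients) needed for parameter-recovery tests.

Statistical structure emulated:

* paleo series are a shared glacial-interglacial sinusoid plus independent
  AR(1) noise per core, on a regular 1,000-yr age grid;
* bathymetry is a smooth random field with land patches (dispersal
  barriers), a shallow shelf, and deep ocean; the baseline SST has a
  meridional gradient so thermal thresholds carve latitude bands;
* species presence/absence is Bernoulli per analysis cell with
  logit-linear-quadratic dependence on the (z-scored) predictors; the
  isolation coefficient magnitude is drawn to increase, stochastically,
  with decreasing body size and mobility, scaled by ``lag_strength`` —
  which produces the triangular size-history pattern rather than a line;
* the phylogeny is a birth-death tree; log body size is rank-matched to a
  Brownian-motion trait evolved on the tree, so size (and hence the
  historical effect) carries phylogenetic signal.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import (
    ClimateGrid,
    ElevationGrid,
    GridSpec,
    aggregate_fraction,
    aggregate_to_analysis_grid,
)
from .isolation import IsolationMap, compute_isolation
from .paleo import (
    AnomalyTable,
    PaleoSeries,
    ReconstructionConfig,
    SuitabilityStack,
    build_suitability_stack,
    compute_anomalies,
    traversability_masks,
)

CONTEMPORARY_PREDICTORS = ("SST", "CHL", "O2", "NI", "SSS")

_MOBILITY_FACTOR = {"sedentary": 1.0, "mobile_within_reef": 0.7, "mobile_between_reefs": 0.45}


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic world.

    The defaults are the study conditions of the package's own experiments:
    25 cores on a 1,000-yr age grid; a 40-slice window with a 20-slice
    glacial cycle (two full cycles); a 72 x 320 one-degree fine grid
    aggregated 4x to the analysis grid; a 60 m sea-level amplitude (the
    lower end of observed glacial low stands) and a 3 deg C tropical SST
    amplitude; 200 species with log-uniform sizes between 4 and 200 cm.
    """

    seed: int = 0
    n_cores: int = 25
    n_timesteps: int = 40
    grid_shape: tuple[int, int] = (72, 320)
    cell_size_deg: float = 1.0
    n_species: int = 200
    true_threshold_C: float = 27.0
    glacial_cycle_period: int = 20  # timesteps per glacial-interglacial cycle
    # interglacial-to-glacial sea-level drop; the lower end of the observed
    # 60-100+ m range so that the deepest reef band (60-100 m at present)
    # stays within the habitat window through a full cycle and true refugia
    # exist, as they did in the Indo-Australian archipelago
    sl_amplitude_m: float = 60.0
    sst_amplitude_C: float = 3.0  # glacial tropical SST cooling
    size_range_cm: tuple[float, float] = (4.0, 200.0)
    lag_strength: float = 1.0  # scales the size/mobility-dependent IREF effect
    sst_noise_sd_C: float = 0.3
    sl_noise_sd_m: float = 3.0
    ar1_phi: float = 0.5
    aggregation_factor: int = 4
    lon0: float = 110.0
    equator_sst_C: float = 29.5
    meridional_range_C: float = 8.0
    # western warm pool (the Indo-Australian archipelago analog): the only
    # region that stays above coral thresholds through glacial cooling, so
    # refugia concentrate there and isolation grows smoothly eastward
    warm_pool_amplitude_C: float = 1.5
    warm_pool_lon_offset_deg: float = 15.0
    warm_pool_sigma_deg: float = 28.0
    prevalence_range: tuple[float, float] = (0.35, 0.7)

    def __post_init__(self) -> None:
        if self.n_timesteps < 2:
            raise ValueError("n_timesteps must be >= 2")
        if self.grid_shape[0] < 4 or self.grid_shape[1] < 4:
            raise ValueError("grid must be at least 4x4")
        if self.sl_amplitude_m <= 0 or self.sst_amplitude_C < 0:
            raise ValueError("sea-level amplitude must be > 0 and SST amplitude >= 0")
        if self.n_species < 1 or self.n_cores < 1:
            raise ValueError("need at least one species and one core")
        if self.lag_strength < 0:
            raise ValueError("lag_strength must be >= 0")

    @property
    def fine_spec(self) -> GridSpec:
        nr, nc = self.grid_shape
        lat0 = (nr - 1) / 2.0 * self.cell_size_deg
        return GridSpec(nrows=nr, ncols=nc, cellsize=self.cell_size_deg, lon0=self.lon0, lat0=lat0)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    coefficients: pd.DataFrame  # per species: intercept + linear/quad betas (z scale)
    historical_effect: pd.Series  # |beta_IREF,1| per species
    suitability_stack: SuitabilityStack
    isolation: IsolationMap


@dataclass
class SyntheticWorld:
    config: ScenarioConfig
    cores: list[PaleoSeries]
    bathymetry: ElevationGrid
    baseline_sst: ClimateGrid
    anomalies: AnomalyTable
    predictors: pd.DataFrame  # analysis cells x (SST..SSS, IREF, lon, lat, row, col)
    occurrences: pd.DataFrame  # species x cells, 0/1
    traits: pd.DataFrame
    phylogeny: dendropy.Tree
    genus_of: dict[str, str]
    truth: GroundTruth
    recon_config: ReconstructionConfig
    analysis_spec: GridSpec = field(default=None)


# ---------------------------------------------------------------------------
# paleo series


def _glacial_anomaly(ages: np.ndarray, amplitude: float, period: float) -> np.ndarray:
    """Anomaly 0 at present, -amplitude at the glacial maximum."""
    return -(amplitude / 2.0) * (1.0 - np.cos(2.0 * np.pi * ages / period))


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0.0, innov_sd)
    return x


def generate_paleo_series(
    config: ScenarioConfig, core_locations: list[tuple[float, float, float]] | None = None
) -> list[PaleoSeries]:
    """Sinusoidal glacial-interglacial core series plus AR(1) noise.

    Returns ``n_cores`` SST series and one sea-level series on the regular
    1,000-yr age grid.  ``core_locations`` optionally fixes (lon, lat,
    present-day SST) per core; otherwise locations and present values are
    drawn from broad tropical ranges.  The noise-free SST components are a
    common curve shifted per core, so their pairwise correlation is 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    ages = np.arange(config.n_timesteps, dtype=float)
    sst_anom = _glacial_anomaly(ages, config.sst_amplitude_C, config.glacial_cycle_period)
    sl = _glacial_anomaly(ages, config.sl_amplitude_m, config.glacial_cycle_period)

    series: list[PaleoSeries] = []
    for k in range(config.n_cores):
        if core_locations is not None:
            lon, lat, present = core_locations[k]
        else:
            lon = float(rng.uniform(config.lon0, config.lon0 + 60))
            lat = float(rng.uniform(-20, 20))
            present = float(rng.normal(27.0, 1.5))
        noise = _ar1(rng, ages.size, config.sst_noise_sd_C, config.ar1_phi)
        series.append(
            PaleoSeries(
                core_id=f"core{k:02d}",
                lon=lon,
                lat=lat,
                kind="sst",
                ages=ages.copy(),
                values=present + sst_anom + noise,
            )
        )
    sl_noise = _ar1(rng, ages.size, config.sl_noise_sd_m, config.ar1_phi)
    series.append(
        PaleoSeries(
            core_id="sealevel",
            lon=config.lon0,
            lat=0.0,
            kind="sea_level",
            ages=ages.copy(),
            values=sl + sl_noise,
        )
    )
    return series


# ---------------------------------------------------------------------------
# geography


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def generate_geography(config: ScenarioConfig) -> tuple[ElevationGrid, ClimateGrid]:
    """Bathymetry (land patches, shelf, deep ocean) and baseline SST."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    spec = config.fine_spec
    g = _smooth_field(rng, spec.shape, sigma=3.0)
    thresh = float(np.quantile(g, 0.70))  # ~30% land
    gmin = float(g.min())
    u = np.clip((thresh - g) / (thresh - gmin), 0.0, 1.0)
    # hypsometry: ~20% of the sea is continental shelf whose cell-mean
    # depths spread over 20-100 m (a one-degree cell averages its reef
    # flats with deeper water, so cell means below ~20 m do not occur),
    # the rest ramps steeply to abyssal depths.  Deep shelf — the part
    # that stays immersed through glacial low stands — clusters in
    # regional provinces (an independent smooth field), so isolation from
    # refugia varies within as well as across thermal bands.
    province = _smooth_field(rng, spec.shape, sigma=6.0)
    province = (province - province.min()) / (province.max() - province.min())
    shelf_u = 0.2
    shelf_pos = np.clip(0.45 * u / shelf_u + 0.55 * province**2, 0.0, 1.0)
    depth = np.where(
        u < shelf_u,
        20.0 + 80.0 * shelf_pos,
        100.0 + 3900.0 * (np.maximum(u - shelf_u, 0.0) / (1.0 - shelf_u)) ** 1.5,
    )
    elev_vals = np.where(g >= thresh, (g - thresh) * 500.0 + 1.0, -np.maximum(depth, 1.0))
    if not np.any(elev_vals < 0):
        raise ValueError("degenerate geography: no sea cells generated")
    # a single connected ocean: enclosed random seas would sit permanently
    # at the unreachable-distance cap, which no real basin does
    from scipy.ndimage import label

    comp, n_comp = label(elev_vals < 0, structure=np.ones((3, 3)))
    if n_comp > 1:
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        main = int(sizes.argmax())
        elev_vals = np.where((elev_vals < 0) & (comp != main), 5.0, elev_vals)
    elev = ElevationGrid(spec=spec, values=elev_vals)

    lon, lat = spec.cell_centers()
    lat_max = abs(spec.lat0) + spec.cellsize
    sst = config.equator_sst_C - config.meridional_range_C * (lat / lat_max) ** 2
    sst = sst + config.warm_pool_amplitude_C * np.exp(
        -(((lon - config.lon0 - config.warm_pool_lon_offset_deg) / config.warm_pool_sigma_deg) ** 2)
    )
    sst = sst + 0.4 * _smooth_field(rng, spec.shape, sigma=4.0)
    sst_vals = np.where(elev.sea_mask, sst, np.nan)
    return elev, ClimateGrid(spec=spec, values=sst_vals)


# ---------------------------------------------------------------------------
# species, traits, phylogeny


def _rank01(x: np.ndarray) -> np.ndarray:
    order = np.argsort(np.argsort(x))
    return order / max(len(x) - 1, 1)


def _draw_species_truth(
    rng: np.random.Generator, config: ScenarioConfig, predictor_names: tuple[str, ...]
) -> pd.DataFrame:
    """Trait values and true GLM coefficients (z-scored predictor scale)."""
    n = config.n_species
    lo, hi = config.size_range_cm
    size = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    size_rank = _rank01(np.log(size))

    # mobility ordered with size (bigger fish range farther), with noise
    mob_score = size_rank + rng.normal(0.0, 0.25, n)
    q1, q2 = np.quantile(mob_score, [1 / 3, 2 / 3])
    mobility = np.where(
        mob_score < q1, "sedentary", np.where(mob_score < q2, "mobile_within_reef", "mobile_between_reefs")
    )
    # habitat specialization mostly independent, smaller fish slightly more
    # coral-specialized
    sp_score = -0.3 * size_rank + rng.normal(0.0, 1.0, n)
    qs1, qs2 = np.quantile(sp_score, [0.45, 0.75])
    specialization = np.where(
        sp_score < qs1, "not_specialized", np.where(sp_score < qs2, "other_specialized", "coral_specialized")
    )

    rows = []
    mob_factor = np.vectorize(_MOBILITY_FACTOR.get)(mobility)
    size_score = 1.0 - size_rank  # small fish -> 1
    envelope = config.lag_strength * (1.2 + 3.0 * size_score * mob_factor)
    u = rng.uniform(0.3, 1.0, n)
    b_iref = envelope * u  # triangular: small/sedentary CAN be high, large cannot
    # niche amplitudes sized so full-model explained deviance sits around
    # one half, with SST the dominant contemporary driver
    importance = {"SST": 0.7, "CHL": 0.45, "O2": 0.45, "NI": 0.45, "SSS": 0.45}
    for i in range(n):
        row: dict[str, float | str] = {
            "size_cm": size[i],
            "mobility": mobility[i],
            "habitat_specialization": specialization[i],
            "b_iref": b_iref[i],
        }
        for name in predictor_names:
            if name == "IREF":
                row["beta_IREF_1"] = -b_iref[i]
                row["beta_IREF_2"] = 0.0
                continue
            opt = rng.uniform(-1.2, 1.2)
            width = rng.uniform(1.2, 2.2)
            gamma = rng.uniform(3.0, 5.0) * importance[name]
            row[f"beta_{name}_1"] = gamma * opt / width**2
            row[f"beta_{name}_2"] = -gamma / (2.0 * width**2)
        rows.append(row)
    return pd.DataFrame(rows)


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept making the mean Bernoulli probability hit ``target``."""
    lo, hi = -15.0, 15.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        p = 1.0 / (1.0 + np.exp(-(mid + eta)))
        if p.mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _simulate_tree(config: ScenarioConfig, sizes: np.ndarray) -> tuple[dendropy.Tree, list[int], dict[int, str]]:
    """Birth-death tree whose tip order is rank-matched to log size via a
    Brownian trait; returns (tree, species index per tip order, genus per
    species index)."""
    pyrng = random.Random(config.seed + 77)
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.3,
        num_extant_tips=config.n_species,
        rng=pyrng,
        repeat_until_success=True,
    )
    # normalize depth to 1 time unit for numerical comfort
    depth = max(l.distance_from_root() for l in tree.leaf_node_iter())
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= depth

    # Brownian log-size on the tree
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    bm: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_val = bm[id(node.parent_node)]
        bm[id(node)] = parent_val + rng.normal(0.0, np.sqrt(max(node.edge.length or 0.0, 1e-12)))

    leaves = list(tree.leaf_node_iter())
    bm_vals = np.array([bm[id(l)] for l in leaves])
    # tips sorted by BM value receive species sorted by size
    tip_order = np.argsort(bm_vals, kind="stable")
    species_order = np.argsort(np.log(sizes), kind="stable")
    species_at_tip = np.empty(len(leaves), dtype=int)
    species_at_tip[tip_order] = species_order

    # genera: clades crossing 60% of the root-to-tip depth
    cutoff = 0.6
    genus_counter = 0
    genus_of_leaf: dict[int, int] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        start = node.parent_node.distance_from_root()
        end = node.distance_from_root()
        if start < cutoff <= end:
            for l in node.leaf_iter():
                genus_of_leaf[id(l)] = genus_counter
            genus_counter += 1
    genus_of_species: dict[int, str] = {}
    for k, leaf in enumerate(leaves):
        genus_of_species[int(species_at_tip[k])] = f"g{genus_of_leaf.get(id(leaf), genus_counter):03d}"

    # label tips with final species ids
    tree.taxon_namespace = dendropy.TaxonNamespace()
    for k, leaf in enumerate(leaves):
        i = int(species_at_tip[k])
        label = f"{genus_of_species[i]}_s{i:03d}"
        leaf.taxon = tree.taxon_namespace.require_taxon(label=label)
    return tree, [int(i) for i in species_at_tip], genus_of_species


# ---------------------------------------------------------------------------
# the world


def analysis_iref(stack: SuitabilityStack, iso: IsolationMap, factor: int) -> np.ndarray:
    """Block-average isolation over established present-day reef cells.

    A fine cell counts as established reef when it is suitable at present
    AND was suitable for at least a third of the window: occurrence data
    come from reefs, reef frameworks need sustained accretion to exist,
    and cells suitable only during brief excursions would enter the block
    mean with near-unconstrained isolation values.  Blocks without any
    established cell are NaN.
    """
    k_min = max(1, int(np.ceil(stack.n_timesteps / 3)))
    established = stack.masks[0] & (stack.occupancy() >= k_min)
    return aggregate_to_analysis_grid(np.where(established, iso.iref, np.nan), factor)


def generate_world(config: ScenarioConfig) -> SyntheticWorld:
    """Build the full synthetic world; deterministic in ``config.seed``."""
    elev, baseline = generate_geography(config)
    spec = elev.spec

    # cores anchored to the baseline at sea cells
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    sea_rows, sea_cols = np.nonzero(elev.sea_mask & np.isfinite(baseline.values))
    pick = rng.choice(sea_rows.size, size=config.n_cores, replace=False)
    lon, lat = spec.cell_centers()
    locations = [
        (float(lon[sea_rows[i], sea_cols[i]]), float(lat[sea_rows[i], sea_cols[i]]),
         float(baseline.values[sea_rows[i], sea_cols[i]]))
        for i in pick
    ]
    cores = generate_paleo_series(config, core_locations=locations)
    anomalies = compute_anomalies(cores, baseline)

    recon = ReconstructionConfig(aggregation_factor=config.aggregation_factor)
    stack = build_suitability_stack(elev, baseline, anomalies, recon, config.true_threshold_C)
    trav = traversability_masks(elev, anomalies)
    iso = compute_isolation(stack, trav)

    # analysis grid
    f = config.aggregation_factor
    coarse_spec = spec.coarsen(f)
    land_frac = aggregate_fraction(~elev.sea_mask, f)
    iref_coarse = analysis_iref(stack, iso, f)
    sst_coarse = aggregate_to_analysis_grid(baseline.values, f)

    rng_env = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
    sst_z_fine = np.where(
        elev.sea_mask, (baseline.values - np.nanmean(baseline.values)) / np.nanstd(baseline.values), np.nan
    )
    mixes = {"CHL": (-0.4, 0.25, 0.10), "O2": (-0.6, 4.7, 0.30), "NI": (-0.3, 2.0, 1.00), "SSS": (0.2, 34.5, 0.50)}
    coarse_fields = {"SST": sst_coarse}
    for name, (w_sst, mean, sd) in mixes.items():
        indep = _smooth_field(rng_env, spec.shape, sigma=4.0)
        fine = w_sst * sst_z_fine + np.sqrt(max(1 - w_sst**2, 0.0)) * indep
        fine = np.where(elev.sea_mask, mean + sd * fine, np.nan)
        coarse_fields[name] = aggregate_to_analysis_grid(fine, f)

    clon, clat = coarse_spec.cell_centers()
    # analysis cells must hold established present-day reef habitat:
    # occurrence data only exist where reefs exist now
    keep = (land_frac < recon.land_fraction_cutoff) & np.isfinite(iref_coarse)
    for name in CONTEMPORARY_PREDICTORS:
        keep &= np.isfinite(coarse_fields[name])
    if keep.sum() < 10:
        raise ValueError("degenerate geography: fewer than 10 analysis cells retained")
    rows_k, cols_k = np.nonzero(keep)
    cell_ids = [f"c{r:02d}_{c:02d}" for r, c in zip(rows_k, cols_k)]
    predictors = pd.DataFrame(
        {name: coarse_fields[name][rows_k, cols_k] for name in CONTEMPORARY_PREDICTORS}
        | {
            "IREF": iref_coarse[rows_k, cols_k],
            "lon": clon[rows_k, cols_k],
            "lat": clat[rows_k, cols_k],
            "row": rows_k,
            "col": cols_k,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )

    # species truth and occurrences
    rng_sp = np.random.default_rng(np.random.SeedSequence([config.seed, 606]))
    truth_df = _draw_species_truth(rng_sp, config, CONTEMPORARY_PREDICTORS + ("IREF",))
    tree, _, genus_of_idx = _simulate_tree(config, truth_df["size_cm"].to_numpy())
    species_ids = [f"{genus_of_idx[i]}_s{i:03d}" for i in range(config.n_species)]
    truth_df.index = pd.Index(species_ids, name="species_id")

    pred_cols = list(CONTEMPORARY_PREDICTORS) + ["IREF"]
    Z = predictors[pred_cols].copy()
    Z = (Z - Z.mean()) / Z.std(ddof=0)
    eta_base = np.zeros((config.n_species, len(predictors)))
    for k, name in enumerate(pred_cols):
        z = Z[name].to_numpy()
        b1 = truth_df[f"beta_{name}_1"].to_numpy()[:, None]
        b2 = truth_df[f"beta_{name}_2"].to_numpy()[:, None]
        eta_base += b1 * z[None, :] + b2 * (z**2)[None, :]

    targets = rng_sp.uniform(*config.prevalence_range, config.n_species)
    intercepts = np.array([_solve_intercept(eta_base[i], targets[i]) for i in range(config.n_species)])
    probs = 1.0 / (1.0 + np.exp(-(intercepts[:, None] + eta_base)))
    occ_vals = (rng_sp.uniform(size=probs.shape) < probs).astype(int)
    occurrences = pd.DataFrame(occ_vals, index=truth_df.index, columns=predictors.index)

    truth_df["intercept"] = intercepts
    truth_df["target_prevalence"] = targets
    traits = truth_df[["size_cm", "mobility", "habitat_specialization"]].copy()
    genus_of = {species_ids[i]: genus_of_idx[i] for i in range(config.n_species)}

    coef_cols = [c for c in truth_df.columns if c.startswith("beta_")] + ["intercept"]
    truth = GroundTruth(
        coefficients=truth_df[coef_cols + ["target_prevalence"]].copy(),
        historical_effect=truth_df["b_iref"].rename("historical_effect"),
        suitability_stack=stack,
        isolation=iso,
    )
    return SyntheticWorld(
        config=config,
        cores=cores,
        bathymetry=elev,
        baseline_sst=baseline,
        anomalies=anomalies,
        predictors=predictors,
        occurrences=occurrences,
        traits=traits,
        phylogeny=tree,
        genus_of=genus_of,
        truth=truth,
        recon_config=recon,
        analysis_spec=coarse_spec,
    )


# ---------------------------------------------------------------------------
# serialization


def occurrences_to_long(occ: pd.DataFrame) -> pd.DataFrame:
    long = occ.stack().rename("presence").reset_index()
    long.columns = ["species_id", "cell_id", "presence"]
    return long


def occurrences_from_long(long: pd.DataFrame) -> pd.DataFrame:
    return long.pivot(index="species_id", columns="cell_id", values="presence").astype(int)


def write_world(world: SyntheticWorld, out_dir) -> None:
    """Serialize the world: tables as CSV, grids as NetCDF, tree as Newick,
    config and truth scalars as JSON."""
    import pathlib

    import xarray as xr

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    from .paleo import cores_to_frame

    cores_to_frame(world.cores).to_csv(out / "cores.csv", index=False)
    world.predictors.to_csv(out / "predictors.csv")
    occurrences_to_long(world.occurrences).to_csv(out / "occurrences.csv", index=False)
    world.traits.to_csv(out / "traits.csv")
    world.anomalies.to_frame().to_csv(out / "anomalies.csv", index=False)
    world.phylogeny.write(path=str(out / "phylogeny.nwk"), schema="newick")

    spec = world.bathymetry.spec
    coords = {"lat": spec.lats(), "lon": spec.lons()}
    ds = xr.Dataset(
        {
            "elevation": (("lat", "lon"), world.bathymetry.values),
            "baseline_sst": (("lat", "lon"), world.baseline_sst.values),
            "suitability": (("age_ka", "lat", "lon"), world.truth.suitability_stack.masks.astype("i1")),
            "iref": (("lat", "lon"), world.truth.isolation.iref),
        },
        coords=coords | {"age_ka": world.truth.suitability_stack.ages},
    )
    ds.to_netcdf(out / "grids.nc", engine="scipy")

    world.truth.coefficients.assign(historical_effect=world.truth.historical_effect).to_csv(
        out / "truth_coefficients.csv"
    )
    cfg = asdict(world.config)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=list)
    with open(out / "genus_map.json", "w") as fh:
        json.dump(world.genus_of, fh, indent=2)
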