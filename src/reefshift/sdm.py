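"""Per-species distribution models and deviance partitioning.

Each species' presence/absence over the analysis cells is modelled with a
binomial GLM (logit link) containing linear and quadratic terms for every
predictor:

    logit(P) = a + sum_k (b_k1 * x_k + b_k2 * x_k^2)

Predictors are z-scored before the quadratic expansion.  Explained deviance
is D^2 = 1 - residual/null deviance.  Fitting the model on three predictor
sets — full, contemporary-only, historical-only — partitions total deviance
into four fractions:

    pure contemporary  a = D2_full - D2_hist
    shared             b = D2_contemp + D2_hist - D2_full
    pure historical    c = D2_full - D2_contemp
    unexplained        d = 1 - D2_full

Model validation uses repeated stratified 70/30 split-sample AUC (rank /
Mann-Whitney formulation with tie correction) and Moran's I of the
full-model response residuals under queen adjacency on the analysis grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

CONTEMPORARY_PREDICTORS = ("SST", "CHL", "O2", "NI", "SSS")
HISTORICAL_PREDICTOR = "IREF"
ALL_PREDICTORS = CONTEMPORARY_PREDICTORS + (HISTORICAL_PREDICTOR,)

# |coefficient| beyond this on the standardized scale indicates
# quasi-separation; the fit is flagged non-converged
_SEPARATION_COEF_LIMIT = 15.0


@dataclass
class SdmFit:
    species_id: str
    predictor_set: str  # full | contemporary | historical | null
    params: pd.Series
    bse: pd.Series
    residual_deviance: float
    null_deviance: float
    d2: float
    converged: bool
    fitted: np.ndarray = field(repr=False, default=None)


@dataclass
class VariancePartition:
    species_id: str
    pure_contemporary: float
    shared: float
    pure_historical: float
    unexplained: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.pure_contemporary, self.shared, self.pure_historical, self.unexplained)


@dataclass
class ValidationSummary:
    species_id: str
    auc_mean: float
    auc_sd: float
    morans_i: float
    morans_i_expected: float
    n_presence: int
    n_absence: int


# ---------------------------------------------------------------------------
# occurrence filtering


def filter_species(
    occ: pd.DataFrame, min_presences: int = 10, min_absences: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop species with too few presence (or absence) cells.

    ``occ`` is a species x cell 0/1 matrix (species on rows).  Species need
    at least ``min_presences`` presence cells and, for identifiability, at
    least ``min_absences`` absence cells (defaults to the presence floor).
    Returns the retained matrix and a table of removals with reasons.
    """
    if min_absences is None:
        min_absences = min_presences
    pres = occ.sum(axis=1)
    abs_ = (1 - occ).sum(axis=1)
    removed = []
    for sp in occ.index:
        if pres[sp] < min_presences:
            removed.append((sp, "too_few_presences", int(pres[sp])))
        elif abs_[sp] < min_absences:
            removed.append((sp, "too_few_absences", int(abs_[sp])))
    removed_df = pd.DataFrame(removed, columns=["species_id", "reason", "count"])
    keep = occ.index.difference(removed_df["species_id"], sort=False)
    kept = occ.loc[keep]
    if kept.empty:
        raise ValueError(
            f"no species retained: {len(removed_df)} removed "
            f"({(removed_df['reason'] == 'too_few_presences').sum()} presence-poor, "
            f"{(removed_df['reason'] == 'too_few_absences').sum()} absence-poor)"
        )
    return kept, removed_df


# ---------------------------------------------------------------------------
# design construction and GLM fitting


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Z-score each predictor column (population SD)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        zero = list(X.columns[sd == 0])
        raise ValueError(f"constant predictor column(s): {zero}")
    return (X - mu) / sd


def quadratic_design(X: pd.DataFrame, standardized: bool = False) -> pd.DataFrame:
    """Linear + quadratic expansion of (optionally pre-standardized) predictors."""
    Z = X if standardized else standardize(X)
    out = {}
    for c in Z.columns:
        out[c] = Z[c].to_numpy()
        out[f"{c}^2"] = Z[c].to_numpy() ** 2
    return pd.DataFrame(out, index=X.index)


def fit_glm_logit(
    y: np.ndarray, X: pd.DataFrame, species_id: str = "", predictor_set: str = "full"
) -> SdmFit:
    """Maximum-likelihood logistic fit with linear + quadratic terms.

    ``X`` holds the raw predictor columns; standardization and quadratic
    expansion happen here.  An empty ``X`` fits the intercept-only (null)
    model.  Fits with non-finite or quasi-separated coefficients are
    flagged ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("response must be binary 0/1")
    if classes.size < 2:
        raise ValueError("response has a single class; model unidentifiable")

    if X.shape[1] > 0:
        design = sm.add_constant(quadratic_design(X), has_constant="add")
    else:
        design = pd.DataFrame({"const": np.ones_like(y)}, index=X.index)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100)
            params = res.params
            converged = bool(getattr(res, "converged", True))
        except Exception:
            res = None
            params = pd.Series(np.nan, index=design.columns)
            converged = False

    if res is not None:
        finite = bool(np.all(np.isfinite(params.to_numpy())))
        sep = bool(np.any(np.abs(params.drop("const").to_numpy()) > _SEPARATION_COEF_LIMIT)) if X.shape[1] else False
        converged = converged and finite and not sep
        resid_dev = float(res.deviance)
        null_dev = float(res.null_deviance)
        fitted = np.asarray(res.fittedvalues)
        bse = res.bse
    else:
        resid_dev = null_dev = np.nan
        fitted = np.full_like(y, np.nan)
        bse = pd.Series(np.nan, index=design.columns)

    d2 = 0.0 if X.shape[1] == 0 else 1.0 - resid_dev / null_dev
    return SdmFit(
        species_id=species_id,
        predictor_set=predictor_set,
        params=params,
        bse=bse,
        residual_deviance=resid_dev,
        null_deviance=null_dev,
        d2=float(d2),
        converged=converged,
        fitted=fitted,
    )


def fit_predictor_sets(
    y: np.ndarray, predictors: pd.DataFrame, species_id: str = ""
) -> dict[str, SdmFit]:
    """Fit the full, contemporary-only, historical-only, and null models."""
    contemp = [c for c in CONTEMPORARY_PREDICTORS if c in predictors.columns]
    hist = [HISTORICAL_PREDICTOR] if HISTORICAL_PREDICTOR in predictors.columns else []
    if not contemp or not hist:
        raise ValueError("predictor table must contain contemporary columns and IREF")
    return {
        "full": fit_glm_logit(y, predictors[contemp + hist], species_id, "full"),
        "contemporary": fit_glm_logit(y, predictors[contemp], species_id, "contemporary"),
        "historical": fit_glm_logit(y, predictors[hist], species_id, "historical"),
        "null": fit_glm_logit(y, predictors[[]], species_id, "null"),
    }


def partition_deviance(fits: dict[str, SdmFit], clamp_tol: float = 1e-6) -> VariancePartition:
    """Four-fraction deviance partition from the three nested-set fits.

    Tiny negative fractions (> -clamp_tol) are numerical noise and clamped
    to zero; larger negatives are reported as-is, since suppression is a
    real phenomenon in GLMs.
    """
    for k in ("full", "contemporary", "historical"):
        if k not in fits:
            raise ValueError(f"missing {k!r} fit")
        if not fits[k].converged:
            raise ValueError(f"{k!r} fit did not converge")
    nulls = {fits[k].null_deviance for k in ("full", "contemporary", "historical")}
    if max(nulls) - min(nulls) > 1e-6 * max(max(nulls), 1.0):
        raise ValueError("fits were not computed on identical data (null deviances differ)")

    d2f = fits["full"].d2
    d2c = fits["contemporary"].d2
    d2h = fits["historical"].d2
    a = d2f - d2h
    b = d2c + d2h - d2f
    c = d2f - d2c
    d = 1.0 - d2f

    def clamp(x: float) -> float:
        return 0.0 if -clamp_tol < x < 0.0 else x

    return VariancePartition(
        species_id=fits["full"].species_id,
        pure_contemporary=clamp(a),
        shared=clamp(b),
        pure_historical=clamp(c),
        unexplained=clamp(d),
    )


# ---------------------------------------------------------------------------
# validation


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation with midrank ties."""
    y_true = np.asarray(y_true, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n1 = int(y_true.sum())
    n0 = y_true.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_repeated_split(
    y: np.ndarray,
    X: pd.DataFrame,
    n_repeats: int = 100,
    train_frac: float = 0.7,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mean and SD of test AUC over repeated stratified 70/30 splits.

    Each repeat refits the quadratic logit model on the training partition
    and scores the held-out partition.  Splits are stratified so both
    partitions keep at least one cell of each class.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    pres = np.flatnonzero(y == 1)
    absn = np.flatnonzero(y == 0)
    n_tr_p = int(round(train_frac * pres.size))
    n_tr_a = int(round(train_frac * absn.size))
    if min(n_tr_p, pres.size - n_tr_p, n_tr_a, absn.size - n_tr_a) < 1:
        raise ValueError("too few cells of one class to stratify the split")

    # standardize once on the full data so train/test share the scale
    design = sm.add_constant(quadratic_design(X), has_constant="add")
    aucs = []
    for _ in range(n_repeats):
        p = rng.permutation(pres)
        a = rng.permutation(absn)
        train = np.concatenate([p[:n_tr_p], a[:n_tr_a]])
        test = np.concatenate([p[n_tr_p:], a[n_tr_a:]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y[train], design.iloc[train], family=sm.families.Binomial()).fit(
                    maxiter=100
                )
                scores = res.predict(design.iloc[test])
            except Exception:
                continue
        if not np.all(np.isfinite(scores)):
            continue
        aucs.append(auc_score(y[test], scores))
    if not aucs:
        raise ValueError("no successful split-sample fits")
    aucs = np.asarray(aucs)
    return float(aucs.mean()), float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0


def queen_weights(coords: pd.DataFrame, cellsize: float) -> np.ndarray:
    """Row-standardized queen-adjacency weights on the analysis grid.

    Two cells are neighbors when they touch in any of the 8 directions,
    i.e. both centroid offsets are at most one cell step.
    """
    lon = coords["lon"].to_numpy()
    lat = coords["lat"].to_numpy()
    tol = 1.5 * cellsize
    dlon = np.abs(lon[:, None] - lon[None, :])
    dlat = np.abs(lat[:, None] - lat[None, :])
    W = ((dlon <= tol) & (dlat <= tol)).astype(float)
    np.fill_diagonal(W, 0.0)
    rs = W.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return W / rs


def morans_i(residuals: np.ndarray, coords: pd.DataFrame, cellsize: float) -> tuple[float, float]:
    """Moran's I of model residuals under queen adjacency.

    I = (n / S0) * (z' W z) / (z' z) with row-standardized weights (S0 = n).
    Returns (I, expected value under no autocorrelation = -1/(n-1)).
    """
    z = np.asarray(residuals, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 cells")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero-variance residuals")
    W = queen_weights(coords, cellsize)
    s0 = W.sum()
    i_stat = (n / s0) * float(z @ (W @ z)) / denom
    return i_stat, -1.0 / (n - 1)


# ---------------------------------------------------------------------------
# per-species driver


def run_sdms(
    occ: pd.DataFrame,
    predictors: pd.DataFrame,
    cellsize: float,
    min_presences: int = 10,
    n_auc_repeats: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    auc_predictor_set: str = "full",
) -> pd.DataFrame:
    """Fit and summarize SDMs for every retained species.

    ``occ`` is a species x cell matrix whose columns match the index of
    ``predictors``; ``predictors`` holds the five contemporary columns,
    IREF, and cell centroid lon/lat.  Returns one row per species with
    D^2 per predictor set, the four deviance fractions, AUC mean/SD,
    Moran's I, and a convergence flag.  Non-converged species are reported
    with NaN summaries (and excluded from downstream analyses).
    """
    if not occ.columns.equals(predictors.index):
        occ = occ.loc[:, predictors.index]
    kept, removed = filter_species(occ, min_presences=min_presences)
    coords = predictors[["lon", "lat"]]
    pred_cols = predictors[list(ALL_PREDICTORS)]
    rng = np.random.default_rng(seed)

    rows = []
    for sp in kept.index:
        y = kept.loc[sp].to_numpy(dtype=float)
        fits = fit_predictor_sets(y, pred_cols, species_id=str(sp))
        ok = all(fits[k].converged for k in ("full", "contemporary", "historical"))
        row: dict[str, object] = {
            "species_id": sp,
            "n_presence": int(y.sum()),
            "n_absence": int((1 - y).sum()),
            "converged": ok,
            "d2_full": fits["full"].d2 if ok else np.nan,
            "d2_contemporary": fits["contemporary"].d2 if ok else np.nan,
            "d2_historical": fits["historical"].d2 if ok else np.nan,
        }
        if ok:
            part = partition_deviance(fits)
            row.update(
                pure_contemporary=part.pure_contemporary,
                shared=part.shared,
                pure_historical=part.pure_historical,
                unexplained=part.unexplained,
            )
            auc_X = {
                "full": pred_cols,
                "contemporary": pred_cols[list(CONTEMPORARY_PREDICTORS)],
                "historical": pred_cols[[HISTORICAL_PREDICTOR]],
            }[auc_predictor_set]
            try:
                auc_mean, auc_sd = auc_repeated_split(
                    y, auc_X, n_repeats=n_auc_repeats, train_frac=train_frac, seed=rng
                )
            except ValueError:
                auc_mean = auc_sd = np.nan
            resid = y - fits["full"].fitted
            try:
                mi, mi_exp = morans_i(resid, coords, cellsize)
            except ValueError:
                mi, mi_exp = np.nan, np.nan
            row.update(auc_mean=auc_mean, auc_sd=auc_sd, morans_i=mi, morans_i_expected=mi_exp)
            for name, val in fits["full"].params.items():
                row[f"coef_{name}"] = val
        else:
            row.update(
                pure_contemporary=np.nan,
                shared=np.nan,
                pure_historical=np.nan,
                unexplained=np.nan,
                auc_mean=np.nan,
                auc_sd=np.nan,
                morans_i=np.nan,
                morans_i_expected=np.nan,
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("species_id")
    out.attrs["removed"] = removed
    return out
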