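"""Trait correlates of the historical signal in the distribution models.

The response is the pure-historical deviance fraction per species; the
candidate traits are maximum body size, a three-level ordered mobility
category, and a three-level habitat-specialization category.  Inference
proceeds by all-subsets ordinary least squares with AIC-based model
averaging (Akaike weights, summed per-trait importance, conditionally
averaged slopes with unconditional standard errors), a phylogenetic GLS
with Pagel's lambda estimated by maximum likelihood, and linear quantile
regressions of the fraction on body size at the upper quantiles, which
summarize the triangular size-history pattern.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

MOBILITY_LEVELS = ("sedentary", "mobile_within_reef", "mobile_between_reefs")
SPECIALIZATION_LEVELS = ("coral_specialized", "other_specialized", "not_specialized")

# dummy coding references: mobility relative to mobile-within-reef (so the
# reported contrasts are "sedentary" and "very mobile"), specialization
# relative to coral-specialized
_MOBILITY_REF = "mobile_within_reef"
_SPECIALIZATION_REF = "coral_specialized"

TRAITS = ("size", "mobility", "specialization")


def validate_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Check category levels and size positivity; returns the table."""
    required = {"size_cm", "mobility", "habitat_specialization"}
    missing = required - set(traits.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(traits["size_cm"])) or (traits["size_cm"] <= 0).any():
        raise ValueError("sizes must be positive and finite")
    bad_mob = set(traits["mobility"]) - set(MOBILITY_LEVELS)
    if bad_mob:
        raise ValueError(f"unknown mobility levels: {sorted(bad_mob)}")
    bad_sp = set(traits["habitat_specialization"]) - set(SPECIALIZATION_LEVELS)
    if bad_sp:
        raise ValueError(f"unknown specialization levels: {sorted(bad_sp)}")
    return traits


def trait_design(traits: pd.DataFrame, size_transform: str = "cm") -> pd.DataFrame:
    """Design columns for the trait models (no intercept).

    size enters in cm by default (``size_transform="log10"`` for log size);
    the categorical traits are dummy-coded against their reference levels.
    """
    validate_trait_table(traits)
    size = traits["size_cm"].astype(float)
    if size_transform == "log10":
        size = np.log10(size)
    elif size_transform != "cm":
        raise ValueError("size_transform must be 'cm' or 'log10'")
    cols = {"size": size}
    for lev, name in (("sedentary", "mobility_sedentary"), ("mobile_between_reefs", "mobility_very_mobile")):
        cols[name] = (traits["mobility"] == lev).astype(float)
    for lev, name in (
        ("not_specialized", "specialization_not"),
        ("other_specialized", "specialization_other"),
    ):
        cols[name] = (traits["habitat_specialization"] == lev).astype(float)
    return pd.DataFrame(cols, index=traits.index)


_TRAIT_COLUMNS = {
    "size": ("size",),
    "mobility": ("mobility_sedentary", "mobility_very_mobile"),
    "specialization": ("specialization_not", "specialization_other"),
}


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """Akaike weights w_m = exp(-dAIC_m/2) / sum over the candidate set.

    Invariant to adding a constant to every AIC.
    """
    aics = np.asarray(aics, dtype=float)
    w = np.exp(-(aics - aics.min()) / 2.0)
    return w / w.sum()


@dataclass
class ModelSet:
    """All-subsets OLS fits with Akaike weights and averaged coefficients."""

    table: pd.DataFrame  # one row per candidate model
    importance: pd.Series  # summed weight per trait
    averaged: pd.DataFrame  # per coefficient: estimate, unconditional SE, Z, p
    best_model: tuple[str, ...]
    averaging: str = "conditional"


def all_subsets_averaging(
    response: pd.Series,
    traits: pd.DataFrame,
    size_transform: str = "cm",
    averaging: str = "conditional",
) -> ModelSet:
    """All-subsets OLS over the three traits with AIC model averaging.

    Fits the 2^3 linear models over {size, mobility, specialization};
    per-model Akaike weight w = exp(-dAIC/2) normalized over the set;
    per-trait importance = sum of weights of models containing the trait.
    Averaged slopes are the weight-weighted means over the models
    containing each term (``averaging="conditional"``, the default) or over
    all models with absent terms counted as zero (``"full"``).  Standard
    errors are unconditional (they include between-model variance), and
    Z = |slope| / SE with a two-sided normal p-value.
    """
    if averaging not in ("conditional", "full"):
        raise ValueError("averaging must be 'conditional' or 'full'")
    design = trait_design(traits.loc[response.index], size_transform=size_transform)
    for tr, cols in _TRAIT_COLUMNS.items():
        sub = design[list(cols)]
        # factor levels with < 2 species make the contrast unidentifiable
        for c in cols:
            if c != "size" and sub[c].sum() < 2 and sub[c].sum() > 0:
                raise ValueError(f"factor level behind {c} has fewer than 2 species")

    y = response.to_numpy(dtype=float)
    rows = []
    fits = {}
    for r in range(len(TRAITS) + 1):
        for subset in itertools.combinations(TRAITS, r):
            cols = [c for tr in subset for c in _TRAIT_COLUMNS[tr]]
            X = sm.add_constant(design[cols], has_constant="add")
            rank = np.linalg.matrix_rank(X.to_numpy())
            if rank < X.shape[1]:
                raise ValueError(f"rank-deficient design for subset {subset}: columns {cols}")
            res = sm.OLS(y, X).fit()
            fits[subset] = res
            rows.append(
                {
                    "model": "+".join(subset) if subset else "(intercept)",
                    "subset": subset,
                    "k": int(res.df_model + 1),
                    "loglik": float(res.llf),
                    "aic": float(res.aic),
                }
            )
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["weight"] = akaike_weights(table["aic"].to_numpy())

    importance = pd.Series(
        {tr: float(table.loc[[tr in s for s in table["subset"]], "weight"].sum()) for tr in TRAITS}
    )

    coef_names = list(design.columns)
    avg_rows = []
    for name in coef_names:
        tr = next(t for t, cols in _TRAIT_COLUMNS.items() if name in cols)
        contains = [tr in s for s in table["subset"]]
        w_in = table.loc[contains, "weight"].to_numpy()
        betas = np.array([fits[s].params[name] for s in table.loc[contains, "subset"]])
        ses = np.array([fits[s].bse[name] for s in table.loc[contains, "subset"]])
        if averaging == "conditional":
            wn = w_in / w_in.sum()
            beta_bar = float(wn @ betas)
            se_u = float(wn @ np.sqrt(ses**2 + (betas - beta_bar) ** 2))
        else:
            beta_bar = float(w_in @ betas)  # absent models contribute 0
            # unconditional SE over the full set, zero-variance where absent
            w_all = table["weight"].to_numpy()
            b_all = np.array(
                [fits[s].params.get(name, 0.0) for s in table["subset"]]
            )
            se_all = np.array([fits[s].bse.get(name, 0.0) for s in table["subset"]])
            se_u = float(w_all @ np.sqrt(se_all**2 + (b_all - beta_bar) ** 2))
        z = abs(beta_bar) / se_u if se_u > 0 else np.inf
        p = 2.0 * (1.0 - stats.norm.cdf(z))
        avg_rows.append({"coefficient": name, "estimate": beta_bar, "se": se_u, "z": z, "p": p})
    averaged = pd.DataFrame(avg_rows).set_index("coefficient")

    best = table.loc[table["aic"].idxmin(), "subset"]
    return ModelSet(
        table=table.drop(columns="subset").assign(model=table["model"]),
        importance=importance,
        averaged=averaged,
        best_model=tuple(best),
        averaging=averaging,
    )


# ---------------------------------------------------------------------------
# phylogeny handling


def _terminal_edge(tree: dendropy.Tree, label: str) -> dendropy.Edge:
    leaf = next((l for l in tree.leaf_node_iter() if l.taxon and l.taxon.label == label), None)
    if leaf is None:
        raise KeyError(label)
    return leaf.edge


def graft_missing_tips(
    tree: dendropy.Tree,
    species: list[str],
    genus_of: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[dendropy.Tree, list[str]]:
    """Attach species absent from the tree next to a congeneric tip.

    Each missing species is grafted at the midpoint of the terminal branch
    of a randomly chosen (seeded) congeneric tip: the tip's branch of length
    L becomes a stem of L/2 carrying a cherry with two branches of L/2,
    which preserves ultrametricity.  ``genus_of`` maps species labels to
    genus names; when omitted the genus is the label up to the first
    underscore or space.  Species with no congeneric tip are returned as
    unplaceable and left out.
    """
    tree = tree.clone(depth=1)
    rng = np.random.default_rng(seed)

    def genus(label: str) -> str:
        if genus_of is not None and label in genus_of:
            return genus_of[label]
        return label.replace(" ", "_").split("_")[0]

    present = {l.taxon.label for l in tree.leaf_node_iter() if l.taxon}
    unplaceable: list[str] = []
    for sp in species:
        if sp in present:
            continue
        congeners = sorted(l for l in present if genus(l) == genus(sp))
        if not congeners:
            unplaceable.append(sp)
            continue
        host_label = congeners[int(rng.integers(len(congeners)))]
        host_leaf = next(
            l for l in tree.leaf_node_iter() if l.taxon and l.taxon.label == host_label
        )
        length = host_leaf.edge.length or 0.0
        parent = host_leaf.parent_node
        new_inner = parent.new_child(edge_length=length / 2.0)
        parent.remove_child(host_leaf)
        new_inner.add_child(host_leaf)
        host_leaf.edge.length = length / 2.0
        taxon = tree.taxon_namespace.require_taxon(label=sp)
        new_inner.new_child(taxon=taxon, edge_length=length / 2.0)
        present.add(sp)
    return tree, unplaceable


def phylo_covariance(tree: dendropy.Tree, species: list[str]) -> np.ndarray:
    """Brownian-motion covariance matrix over the requested tips.

    C[i, j] is the shared root-to-MRCA path length; on an ultrametric tree
    C[i, j] = depth - d_ij / 2 with d the patristic distance.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in species if s not in taxa]
    if missing:
        raise KeyError(f"species not in tree: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    depth = {}
    for leaf in tree.leaf_node_iter():
        depth[leaf.taxon.label] = leaf.distance_from_root()
    n = len(species)
    C = np.zeros((n, n))
    for i, si in enumerate(species):
        C[i, i] = depth[si]
        for j in range(i + 1, n):
            sj = species[j]
            d = pdm.patristic_distance(taxa[si], taxa[sj])
            C[i, j] = C[j, i] = (depth[si] + depth[sj] - d) / 2.0
    return C


def check_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> None:
    depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
    span = max(depths) - min(depths)
    if span > rel_tol * max(depths):
        raise ValueError(f"tree is not ultrametric (tip-depth span {span:.3g})")


@dataclass
class PglsResult:
    lam: float
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    sigma2: float
    n: int


def _gls_profile(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Profile ML for GLS: beta-hat, sigma2-hat, log-likelihood, cov(beta)."""
    n = y.size
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    sigma2 = float(resid @ resid) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    cov = sigma2 * n / max(n - X.shape[1], 1) * xtx_inv  # small-sample scale
    return beta, sigma2, ll, cov


def pgls_fit(
    response: pd.Series,
    design: pd.DataFrame,
    tree: dendropy.Tree,
    lam: float | None = None,
    ultrametric_tol: float = 1e-6,
) -> PglsResult:
    """Phylogenetic GLS with Pagel's lambda.

    The residual covariance is V(lambda) = lambda * C + (1 - lambda) *
    diag(C), with C the Brownian-motion covariance implied by the tree.
    lambda is estimated by bounded maximum likelihood on [0, 1] (multiple
    restarts) unless fixed via ``lam``.  At lambda = 0 the fit reduces to
    ordinary least squares.
    """
    species = list(response.index)
    if list(design.index) != species:
        design = design.loc[species]
    check_ultrametric(tree, rel_tol=max(ultrametric_tol, 1e-9))
    C = phylo_covariance(tree, species)
    y = response.to_numpy(dtype=float)
    X = sm.add_constant(design, has_constant="add")
    Xm = X.to_numpy(dtype=float)
    D = np.diag(np.diag(C))

    def vmat(l: float) -> np.ndarray:
        return l * C + (1.0 - l) * D

    def nll(l: float) -> float:
        try:
            return -_gls_profile(y, Xm, vmat(l))[2]
        except np.linalg.LinAlgError:
            return np.inf

    if lam is None:
        # bounded 1-D ML with a coarse grid of restarts
        best = None
        for x0 in np.linspace(0.0, 1.0, 10):
            r = optimize.minimize_scalar(
                nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
            )
            cand = (r.fun, float(r.x))
            grid = (nll(x0), x0)
            for f, l in (cand, grid):
                if best is None or f < best[0]:
                    best = (f, l)
        lam = best[1]

    beta, sigma2, ll, cov = _gls_profile(y, Xm, vmat(float(lam)))
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    df = y.size - Xm.shape[1]
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    names = list(X.columns)
    return PglsResult(
        lam=float(lam),
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        loglik=float(ll),
        sigma2=float(sigma2),
        n=y.size,
    )


# ---------------------------------------------------------------------------
# quantile regression


def quantile_slopes(
    response: pd.Series, size_cm: pd.Series, quantiles: tuple[float, ...] = (0.75, 0.9)
) -> pd.DataFrame:
    """Linear quantile regressions of the historical fraction on body size.

    Returns one row per quantile with slope, intercept, and the slope's
    p-value from the quantile-regression asymptotic covariance.  Upper
    quantiles track the declining envelope of the triangular size-history
    cloud that an ordinary mean regression understates.
    """
    if response.size < 20:
        raise ValueError("quantile regression needs at least 20 species")
    x = size_cm.loc[response.index].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("degenerate size variance")
    y = response.to_numpy(dtype=float)
    X = sm.add_constant(pd.DataFrame({"size": x}))
    rows = []
    import warnings

    for q in quantiles:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.QuantReg(y, X).fit(q=q)
        rows.append(
            {
                "q": q,
                "slope": float(res.params["size"]),
                "intercept": float(res.params["const"]),
                "p": float(res.pvalues["size"]),
            }
        )
    return pd.DataFrame(rows).set_index("q")
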