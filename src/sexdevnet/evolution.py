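"""Cluster-topology multivariate analysis and phylostratigraphic models.

Three pieces:

* PCA of the eight per-cluster topology statistics (centred and scaled) to
  extract independent axes of network architecture;
* all-subsets binomial model averaging: cluster bias flags are regressed on
  PCA scores in every predictor subset, models are ranked by AICc, and each
  predictor's relative importance (RI) is the sum of the Akaike weights of
  the models containing it;
* gene-age analyses: fold enrichment of phylostrata within bias classes, and
  gamma/logit GLMs of node connection density and hub score on
  ClusterSize + Stratum + DE + DC + Stratum:DE + Stratum:DC, averaged over
  all marginality-respecting submodels with AICc weights.

Stratum is an unordered factor with the oldest level (Metazoa) as reference,
so stratum coefficients read as contrasts against ancient genes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import gamma_logit_irls, guard_unit_interval
from .simulate import STRATA

TOPOLOGY_VARS = [
    "size", "density", "centralization", "heterogeneity", "median_cc",
    "diameter", "prop_splicing", "prop_duplicated",
]

#: RI above this is treated as a significant association
RI_THRESHOLD = 0.70


@dataclass
class PCAResult:
    loadings: pd.DataFrame   # variable x PC
    scores: pd.DataFrame     # cluster x PC
    variance_fraction: np.ndarray


def pca_cluster_topology(
    topology: pd.DataFrame, variables: list[str] | None = None
) -> PCAResult:
    """Centred-and-scaled PCA of cluster topology statistics.

    Zero-variance variables are dropped with a warning; the sign of each PC
    is fixed so its largest-magnitude loading is positive.
    """
    variables = variables or [v for v in TOPOLOGY_VARS if v in topology.columns]
    x = topology[variables].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 clusters for PCA")
    keep = []
    for j, v in enumerate(variables):
        if np.nanstd(x[:, j]) > 0:
            keep.append(j)
        else:
            warnings.warn(f"variable {v} has zero variance; dropped from PCA")
    x = x[:, keep]
    variables = [variables[j] for j in keep]
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # deterministic sign: largest |loading| positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    var_frac = s**2 / (s**2).sum()
    pcs = [f"PC{i+1}" for i in range(len(s))]
    return PCAResult(
        loadings=pd.DataFrame(vt.T, index=variables, columns=pcs),
        scores=pd.DataFrame(scores, index=topology.index, columns=pcs),
        variance_fraction=var_frac,
    )


# ---------------------------------------------------------------------------
# AICc model averaging
# ---------------------------------------------------------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: np.ndarray) -> np.ndarray:
    delta = aiccs - np.nanmin(aiccs)
    w = np.exp(-0.5 * delta)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


def _logistic_loglik(y, X, beta) -> float:
    eta = X @ beta
    return float((y * eta - np.log1p(np.exp(eta))).sum())


def _fit_logistic(y, X, ridge: float = 0.0, max_iter: int = 100):
    """Plain Newton logistic fit; optional Jeffreys-style penalty (Firth)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(X.shape[1])
        score = X.T @ (y - mu)
        if ridge > 0:
            # Firth adjustment: add h_i (1/2 - mu_i) to the working response
            try:
                Hi = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                break
            h = np.einsum("ij,jk,ik->i", X * w[:, None], Hi, X)
            score = X.T @ (y - mu + h * (0.5 - mu))
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            return beta, True
    return beta, False


@dataclass
class ModelAveragingResult:
    ri: pd.Series                 # relative importance per predictor
    averaged_coef: pd.Series      # full model-averaged coefficients
    model_table: pd.DataFrame     # one row per model: terms, k, AICc, weight


def model_average_binomial(
    response: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
    forced: list[str] | None = None,
) -> ModelAveragingResult:
    """All-subsets binomial GLMs ranked by AICc.

    Fits every subset of the predictor columns (forced columns appear in all
    models, hence RI exactly 1), computes Akaike weights, each predictor's
    relative importance (sum of weights of models containing it) and
    full-model-averaged coefficients (absent terms contribute 0).  Complete
    separation triggers a Firth-penalised refit with a warning.
    """
    y = np.asarray(response, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("binary response needs both classes present")
    forced = forced or []
    free = [c for c in predictors.columns if c not in forced]
    n = len(y)
    rows = []
    coef_store = []
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            terms = forced + list(combo)
            X = np.column_stack(
                [np.ones(n)] + [predictors[t].to_numpy(float) for t in terms]
            )
            beta, ok = _fit_logistic(y, X)
            if not ok or np.abs(beta).max() > 15:
                warnings.warn(
                    "possible complete separation; Firth-penalised refit used"
                )
                beta, ok = _fit_logistic(y, X, ridge=1e-4)
            ll = _logistic_loglik(y, X, beta)
            k = X.shape[1]
            rows.append({"terms": tuple(terms), "k": k,
                         "loglik": ll, "aicc": aicc(ll, k, n)})
            coef_store.append(dict(zip(["intercept"] + terms, beta)))
    tbl = pd.DataFrame(rows)
    tbl["weight"] = akaike_weights(tbl["aicc"].to_numpy())
    ri = {}
    for t in predictors.columns:
        ri[t] = float(tbl.loc[[t in tt for tt in tbl["terms"]], "weight"].sum())
    avg = {}
    for name in ["intercept"] + list(predictors.columns):
        avg[name] = float(
            sum(w * c.get(name, 0.0) for w, c in zip(tbl["weight"], coef_store))
        )
    return ModelAveragingResult(
        ri=pd.Series(ri), averaged_coef=pd.Series(avg), model_table=tbl
    )


# ---------------------------------------------------------------------------
# phylostratigraphy
# ---------------------------------------------------------------------------


def stratum_fold_enrichment(
    gene_strata: pd.Series, gene_class: pd.Series
) -> pd.DataFrame:
    """Per-class stratum proportion divided by the genome-wide proportion.

    ``gene_class`` holds a bias class per gene (e.g. none / DE / DE+DC).
    A fold of 1.5 means the class contains 50% more genes of that age than
    the genome-wide average; strata absent genome-wide yield NaN.
    """
    strata = [s for s in STRATA if (gene_strata == s).any()]
    overall = gene_strata.value_counts(normalize=True)
    rows = {}
    for cls in gene_class.unique():
        sub = gene_strata[gene_class == cls]
        prop = sub.value_counts(normalize=True)
        rows[cls] = {
            s: (prop.get(s, 0.0) / overall[s]) if overall.get(s, 0) > 0 else np.nan
            for s in strata
        }
    out = pd.DataFrame(rows).T
    out.index.name = "class"
    return out[strata]


def merge_rare_strata(
    strata: pd.Series, min_count: int = 5, order: tuple = STRATA
) -> pd.Series:
    """Merge stratum levels with < min_count members into the adjacent older
    level (warning issued per merge)."""
    out = strata.copy()
    counts = out.value_counts()
    levels = [s for s in order if s in counts.index]
    for i in range(len(levels) - 1, 0, -1):
        s = levels[i]
        if out.value_counts().get(s, 0) < min_count:
            older = levels[i - 1]
            warnings.warn(f"stratum {s} has <{min_count} nodes; merged into {older}")
            out[out == s] = older
    return out


def _strata_design(
    strata: pd.Series,
    de: np.ndarray,
    dc: np.ndarray,
    cluster_size: np.ndarray,
    terms: list[str],
    levels: list[str],
) -> tuple[np.ndarray, list[str]]:
    n = len(strata)
    cols = [np.ones(n)]
    names = ["intercept"]
    dummies = {
        s: (strata == s).to_numpy(float) for s in levels[1:]
    }  # reference = oldest level
    if "ClusterSize" in terms:
        z = (cluster_size - cluster_size.mean()) / max(cluster_size.std(), 1e-12)
        cols.append(z)
        names.append("ClusterSize")
    if "Stratum" in terms:
        for s in levels[1:]:
            cols.append(dummies[s])
            names.append(f"Stratum[{s}]")
    if "DE" in terms:
        cols.append(de.astype(float))
        names.append("DE")
    if "DC" in terms:
        cols.append(dc.astype(float))
        names.append("DC")
    if "Stratum:DE" in terms:
        for s in levels[1:]:
            cols.append(dummies[s] * de)
            names.append(f"Stratum[{s}]:DE")
    if "Stratum:DC" in terms:
        for s in levels[1:]:
            cols.append(dummies[s] * dc)
            names.append(f"Stratum[{s}]:DC")
    return np.column_stack(cols), names


def _marginality_subsets(optional: list[str]) -> list[list[str]]:
    subsets = []
    for r in range(len(optional) + 1):
        for combo in itertools.combinations(optional, r):
            terms = set(combo)
            if "Stratum:DE" in terms and not {"Stratum", "DE"} <= terms:
                continue
            if "Stratum:DC" in terms and not {"Stratum", "DC"} <= terms:
                continue
            subsets.append(sorted(terms))
    return subsets


def fit_strata_models(
    node_stats: pd.DataFrame,
    strata: pd.Series,
    de_flags: pd.Series,
    dc_flags: pd.Series,
    cluster_sizes: pd.Series,
    responses: tuple[str, ...] = ("Kd", "Hub"),
    forced: tuple[str, ...] = ("ClusterSize",),
    min_stratum: int = 5,
    stratum_order: tuple = STRATA,
) -> dict[str, dict]:
    """Gamma/logit model averaging of node topology on gene age and sex-bias.

    ``node_stats`` holds per-node Kd and Hub (guarded into (0,1));
    ``de_flags``/``dc_flags`` are cluster-level bias flags propagated to
    member nodes; ``cluster_sizes`` is the node's cluster size.  All
    marginality-respecting subsets of {Stratum, DE, DC, Stratum:DE,
    Stratum:DC} are fit (ClusterSize forced), ranked by AICc with k counting
    every coefficient plus the dispersion, and averaged.  Returns per
    response: ri (per term), averaged_coef (per design column), model_table.
    """
    idx = node_stats.index
    strata = merge_rare_strata(strata.loc[idx], min_count=min_stratum,
                               order=stratum_order)
    levels = [s for s in stratum_order if (strata == s).any()]
    de = de_flags.loc[idx].to_numpy(float)
    dc = dc_flags.loc[idx].to_numpy(float)
    size = cluster_sizes.loc[idx].to_numpy(float)
    optional = ["Stratum", "DE", "DC", "Stratum:DE", "Stratum:DC"]
    subsets = _marginality_subsets(optional)
    out: dict[str, dict] = {}
    n = len(idx)
    for resp in responses:
        y = guard_unit_interval(node_stats[resp].to_numpy(float))
        rows, coef_store = [], []
        for terms in subsets:
            full_terms = list(forced) + terms
            X, names = _strata_design(strata, de, dc, size, full_terms, levels)
            fit = gamma_logit_irls(X, y[None, :])
            k = X.shape[1] + 1  # + dispersion
            rows.append(
                {
                    "terms": tuple(terms),
                    "k": k,
                    "loglik": float(fit.loglik[0]),
                    "aicc": aicc(float(fit.loglik[0]), k, n),
                    "converged": bool(fit.converged[0]),
                }
            )
            coef_store.append(dict(zip(names, fit.coef[0])))
        tbl = pd.DataFrame(rows)
        tbl["weight"] = akaike_weights(tbl["aicc"].to_numpy())
        ri = {t: 1.0 for t in forced}
        for t in optional:
            ri[t] = float(tbl.loc[[t in tt for tt in tbl["terms"]], "weight"].sum())
        all_names = sorted({nm for c in coef_store for nm in c})
        avg = {
            nm: float(sum(w * c.get(nm, 0.0)
                          for w, c in zip(tbl["weight"], coef_store)))
            for nm in all_names
        }
        out[resp] = {
            "ri": pd.Series(ri),
            "averaged_coef": pd.Series(avg),
            "model_table": tbl,
            "stratum_levels": levels,
        }
    return out
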