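"""Targeted differential-correlation testing between sexes.

Design: for each developmental stage, every combination of three of its six
whole-body samples is removed in turn (C(6,3) = 20 subnetworks per stage, one
stage perturbed at a time), so every subnetwork keeps the same total sample
count while the sex composition of the perturbed stage varies.  The sex
composition of the three retained focal-stage samples is summarised by the
signed balance b = (#M - #F)/3 in {-1, -1/3, +1/3, +1}.

For every subnetwork the adjacency is rebuilt with the main network's power
and correlation method (never re-estimated), and each cluster's within-
cluster density is recorded together with the whole-subnetwork density.
Density is then modelled per cluster with a gamma/logit GLM
Density ~ Stage + Stage:Balance + NetworkDensity, and the stage-specific
balance interaction is the differential-correlation statistic: a positive
coefficient means density rises as more males are retained (male-biased
co-expression).

Significance is calibrated in two stages against a within-stage sex-label
permutation null: observed interaction p-values are first referred to the
pooled permutation p distribution (stage-1 lfdr), and the stage-1 scores are
then corrected across all clusters (stage-2 lfdr; calls below 0.10).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .glm import gamma_logit_irls, guard_unit_interval
from .lfdr import compute_lfdr
from .network import biweight_midcorrelation, pearson_correlation, _abs_power
from .simulate import STAGES

BALANCE_LEVELS = (-1.0, -1 / 3, 1 / 3, 1.0)


def enumerate_subsamples(design: pd.DataFrame) -> pd.DataFrame:
    """All leave-3-out subnetworks, one perturbed stage at a time.

    Requires 3 male + 3 female whole-body samples per stage.  Returns one row
    per subnetwork: subnet (id), stage (perturbed), removed (comma-joined
    sample ids) and balance (of the three retained focal-stage samples).
    """
    whole = design[design["tissue"] == "whole"]
    rows = []
    sn = 0
    for stage in STAGES:
        cell = whole[whole["stage"] == stage].sort_values("sample_id")
        sexes = cell["sex"].value_counts()
        if len(cell) != 6 or sexes.get("M", 0) != 3 or sexes.get("F", 0) != 3:
            raise ValueError(
                f"stage {stage} must have exactly 3 male + 3 female whole-body "
                f"samples (found {dict(sexes)})"
            )
        ids = cell["sample_id"].tolist()
        sex_of = dict(zip(cell["sample_id"], cell["sex"]))
        for removed in combinations(ids, 3):
            retained = [s for s in ids if s not in removed]
            n_m = sum(sex_of[s] == "M" for s in retained)
            b = (n_m - (3 - n_m)) / 3.0
            rows.append((f"sn{sn:03d}", stage, ",".join(removed), b))
            sn += 1
    return pd.DataFrame(rows, columns=["subnet", "stage", "removed", "balance"])


def subnetwork_densities(
    values: pd.DataFrame,
    clusters: pd.Series,
    scheme: pd.DataFrame,
    beta: int,
    method: str = "bicor",
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Within-cluster and whole-network density for every subnetwork.

    The adjacency of each subnetwork is recomputed on its retained samples
    with the fixed power ``beta`` and the main network's node-to-cluster
    assignment.  Densities are guarded into (eps, 1 - eps) for the logit
    link.  Clusters of size < 3 are excluded with a warning.
    """
    whole_cols = [c for c in values.columns]
    lab = clusters.loc[values.index].to_numpy()
    keep_clusters = []
    for c in pd.unique(lab):
        if (lab == c).sum() >= 3:
            keep_clusters.append(c)
        else:
            warnings.warn(f"cluster {c} has <3 nodes; excluded from DC")
    idx_of = {c: np.flatnonzero(lab == c) for c in keep_clusters}
    # densities are pair averages; single precision is ample for them and
    # halves the cost of the 100 correlation matrices
    mat = values.to_numpy(dtype=np.float32)
    col_pos = {c: i for i, c in enumerate(values.columns)}
    rows = []
    for _, sub in scheme.iterrows():
        removed = set(sub["removed"].split(","))
        cols = [col_pos[c] for c in whole_cols if c not in removed]
        x = mat[:, cols]
        corr = (
            biweight_midcorrelation(x) if method == "bicor" else pearson_correlation(x)
        )
        a = _abs_power(corr, beta)
        # the diagonal is exactly 1^beta; subtract it instead of zeroing
        n = a.shape[0]
        net_density = (float(a.sum()) - n) / (n * (n - 1))
        for c in keep_clusters:
            idx = idx_of[c]
            m = len(idx)
            dens = (float(a[np.ix_(idx, idx)].sum()) - m) / (m * (m - 1))
            rows.append((c, sub["subnet"], sub["stage"], sub["balance"],
                         dens, net_density))
    out = pd.DataFrame(
        rows,
        columns=["cluster", "subnet", "stage", "balance", "density", "net_density"],
    )
    out["density"] = guard_unit_interval(out["density"].to_numpy(), eps)
    out["net_density"] = guard_unit_interval(out["net_density"].to_numpy(), eps)
    return out


def dc_design_matrix(
    stages: np.ndarray, balances: np.ndarray, net_density: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Model matrix for Density ~ Stage + Stage:Balance + NetworkDensity.

    Stage enters as treatment-coded dummies (first stage is reference); the
    balance covariate is stage-specific: for a row whose perturbed stage is
    s, the balance appears in column ``bal[s]`` and every other balance
    column is exactly 0 (non-perturbed stages always retain 3 + 3 samples).
    """
    cols = [np.ones(len(stages))]
    names = ["intercept"]
    for s in STAGES[1:]:
        cols.append((stages == s).astype(float))
        names.append(f"stage[{s}]")
    for s in STAGES:
        cols.append(np.where(stages == s, balances, 0.0))
        names.append(f"bal[{s}]")
    # whole-subnetwork density enters on the link (log-odds) scale so a
    # network-wide connectivity shift is a near-linear confounder
    nd = np.clip(net_density, 1e-9, 1 - 1e-9)
    cols.append(np.log(nd / (1 - nd)))
    names.append("net_density")
    return np.column_stack(cols), names


def fit_dc_glm(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster stage:balance coefficients and Wald p-values.

    Fits one gamma/logit GLM per cluster (batched IRLS, shared design).
    Non-converged clusters are flagged with NaN p-values.
    """
    clusters = table["cluster"].unique()
    first = table[table["cluster"] == clusters[0]].sort_values("subnet")
    X, names = dc_design_matrix(
        first["stage"].to_numpy(),
        first["balance"].to_numpy(),
        first["net_density"].to_numpy(),
    )
    Y = np.vstack(
        [
            table[table["cluster"] == c].sort_values("subnet")["density"].to_numpy()
            for c in clusters
        ]
    )
    fit = gamma_logit_irls(X, Y, squeeze_dispersion=True)
    rows = []
    for ci, c in enumerate(clusters):
        for s in STAGES:
            j = names.index(f"bal[{s}]")
            rows.append(
                (c, s, fit.coef[ci, j], fit.pvalues[ci, j], bool(fit.converged[ci]))
            )
    return pd.DataFrame(rows, columns=["cluster", "stage", "coef", "p", "converged"])


def permutation_null(
    table: pd.DataFrame,
    scheme: pd.DataFrame,
    design: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Stage:balance p-values under within-stage sex-label permutations.

    Sex labels are shuffled within each stage (preserving the stage design),
    balances are recomputed for every subnetwork, and the per-cluster GLMs
    are refit; densities do not change because the removal sets are fixed.
    Returns an array of shape (n_perm, n_clusters, n_stages).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    whole = design[design["tissue"] == "whole"]
    stage_samples = {
        s: sorted(whole.loc[whole["stage"] == s, "sample_id"]) for s in STAGES
    }
    true_sex = dict(zip(whole["sample_id"], whole["sex"]))
    clusters = table["cluster"].unique()
    order = {c: table[table["cluster"] == c].sort_values("subnet") for c in clusters}
    Y = np.vstack([order[c]["density"].to_numpy() for c in clusters])
    first = order[clusters[0]]
    stages_arr = first["stage"].to_numpy()
    net = first["net_density"].to_numpy()
    sub_scheme = scheme.set_index("subnet").loc[first["subnet"]].reset_index()

    # precompute retained focal-sample positions per subnetwork so balances
    # under a permutation reduce to one gather + mean
    all_ids = sorted(whole["sample_id"])
    pos = {s: i for i, s in enumerate(all_ids)}
    retained_pos = np.array(
        [
            [pos[s] for s in stage_samples[row["stage"]]
             if s not in set(row["removed"].split(","))]
            for _, row in sub_scheme.iterrows()
        ]
    )
    stage_pos = {s: np.array([pos[i] for i in stage_samples[s]]) for s in STAGES}
    true_signs = {
        s: np.array([1.0 if true_sex[i] == "M" else -1.0
                     for i in stage_samples[s]])
        for s in STAGES
    }

    out = np.empty((n_perm, len(clusters), len(STAGES)))
    sex_vec = np.empty(len(all_ids))
    for it in range(n_perm):
        for s in STAGES:
            sex_vec[stage_pos[s]] = rng.permutation(true_signs[s])
        balances = sex_vec[retained_pos].mean(axis=1)
        X, names = dc_design_matrix(stages_arr, balances, net)
        fit = gamma_logit_irls(X, Y, squeeze_dispersion=True)
        cols = [names.index(f"bal[{s}]") for s in STAGES]
        out[it] = fit.pvalues[:, cols]
    return out


def calibrate_dc_lfdr(
    observed: pd.DataFrame,
    perm_pvalues: np.ndarray,
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Two-stage lfdr calibration of DC interaction p-values.

    Stage 1: each observed p-value is referred to the pooled permutation
    p-value distribution of all *other* clusters (a cluster's own permuted
    fits are excluded because partially sex-aligned permutations leak real
    signal into the null's left tail), giving a calibrated exceedance q;
    the stage-1 lfdr is the two-component lfdr of the q's at raw Grenander
    resolution, the external permutation null standing in for f0.

    Stage 2 corrects each contrast against all other clusters' stage-1
    scores: the reported stage-2 lfdr is the larger of the stage-1 score and
    its empirical exceedance fraction among all contrasts, so a contrast is
    called only when its score is both small in absolute terms and extreme
    relative to the other clusters.  Direction comes from the interaction
    coefficient sign (positive = male-biased co-expression).

    ``perm_pvalues`` has shape (n_perm, n_clusters, n_stages) with the
    cluster axis ordered as in ``observed`` (the fit_dc_glm row order).
    """
    obs = observed.copy()
    clusters = obs["cluster"].unique()
    if perm_pvalues.ndim != 3 or perm_pvalues.shape[1] != len(clusters):
        raise ValueError("perm_pvalues shape does not match observed clusters")
    finite_pool = np.sort(perm_pvalues[np.isfinite(perm_pvalues)].ravel())
    if len(finite_pool) == 0:
        raise ValueError("permutation p-value set is empty")
    own_sorted = {}
    for ci, c in enumerate(clusters):
        vals = perm_pvalues[:, ci, :]
        own_sorted[c] = np.sort(vals[np.isfinite(vals)].ravel())
    p = obs["p"].to_numpy()
    ok = np.isfinite(p)
    q = np.ones(len(p))
    for i in np.flatnonzero(ok):
        own = own_sorted[obs["cluster"].iat[i]]
        below = np.searchsorted(finite_pool, p[i], side="right") - np.searchsorted(
            own, p[i], side="right"
        )
        size = len(finite_pool) - len(own)
        q[i] = (below + 1) / (size + 1)
    q = np.minimum(q, 1.0)
    if np.ptp(q[ok]) < 1e-12:
        warnings.warn("degenerate p-value distribution; lfdr set to 1")
        obs["p_calibrated"] = q
        obs["lfdr_stage1"] = 1.0
        obs["lfdr_stage2"] = 1.0
        obs["direction"] = "none"
        obs["significant"] = False
        return obs
    lf1, _ = compute_lfdr(q, threshold=threshold, block=1)
    exceed = stats.rankdata(lf1, method="max") / len(lf1)
    lf2 = np.maximum(lf1, exceed)
    calls = (lf2 < threshold) & ok
    obs["p_calibrated"] = q
    obs["lfdr_stage1"] = lf1
    obs["lfdr_stage2"] = lf2
    obs["significant"] = calls
    obs["direction"] = np.where(
        calls, np.where(obs["coef"] > 0, "M", "F"), "none"
    )
    return obs


def run_dc(
    values: pd.DataFrame,
    clusters: pd.Series,
    design: pd.DataFrame,
    beta: int,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = 0.10,
    method: str = "bicor",
) -> pd.DataFrame:
    """Full differential-correlation pipeline on a node matrix."""
    scheme = enumerate_subsamples(design)
    whole_cols = design.loc[design["tissue"] == "whole", "sample_id"].tolist()
    table = subnetwork_densities(
        values[whole_cols], clusters, scheme, beta=beta, method=method
    )
    observed = fit_dc_glm(table)
    perms = permutation_null(table, scheme, design, n_perm=n_perm, seed=seed)
    return calibrate_dc_lfdr(observed, perms, threshold=threshold)
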