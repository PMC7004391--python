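"""Differential expression of nodes and clusters, bias classification and
enrichment tests.

The core model is value ~ Stage + Stage:Sex fit per node by least squares:
the Stage factor absorbs stage-specific expression and sex enters only as a
stage-specific contrast, so each node yields one male-minus-female
coefficient per developmental stage.  Inference uses empirical-Bayes
moderated t statistics by default, and p-values are converted to local false
discovery rates jointly across all node x stage contrasts.  Splicing nodes
are tested on their ratio scale.

Gene-level bias is the any-node rule: a gene is sex-biased at a stage if at
least one of its transcription or splicing nodes is.  Genes that are ever
male- and ever female-biased count as switch genes and are excluded from
linkage-group enrichment.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm import moderated_ols
from .lfdr import compute_lfdr
from .simulate import STAGES

DIR_M, DIR_F, DIR_NONE, DIR_BOTH = "M", "F", "none", "both"


def stage_sex_design(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Cell-means design for value ~ Stage + Stage:Sex on whole-body samples.

    One column per stage (the female baseline at that stage) plus one column
    per stage x male indicator, whose coefficient is mean(M) - mean(F) at
    that stage.
    """
    whole = design[design["tissue"] == "whole"]
    cols, names = [], []
    for stage in STAGES:
        cols.append((whole["stage"] == stage).to_numpy(float))
        names.append(f"stage[{stage}]")
    for stage in STAGES:
        cols.append(
            ((whole["stage"] == stage) & (whole["sex"] == "M")).to_numpy(float)
        )
        names.append(f"stage[{stage}]:sexM")
    X = np.column_stack(cols)
    counts = whole.groupby(["stage", "sex"])["sample_id"].count()
    if (counts < 2).any() or len(counts) < 2 * len(STAGES):
        missing = [
            f"{s}/{x}" for s in STAGES for x in ("M", "F")
            if counts.get((s, x), 0) < 2
        ]
        raise ValueError(f"need >=2 replicates per (stage, sex) cell; short: {missing}")
    return X, names


def fit_node_de(
    values: pd.DataFrame,
    design: pd.DataFrame,
    moderation: bool = True,
    kinds: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-node stage-specific sex contrasts (long table).

    Returns one row per (node, stage) with the male-minus-female coefficient,
    (moderated) t and p-value.  ``kinds`` (node kind per node id) keeps the
    variance moderation within scale-compatible groups: splicing ratios are
    not squeezed toward log2-expression variances.  Call :func:`add_lfdr` to
    append local FDRs and direction calls across the whole table.
    """
    whole_cols = design.loc[design["tissue"] == "whole", "sample_id"].tolist()
    X, names = stage_sex_design(design)
    Y = values[whole_cols].to_numpy()
    groups = None
    if kinds is not None:
        groups = (
            kinds.reindex(values.index)
            .map({"splicing": 1})
            .fillna(0)
            .to_numpy(int)
        )
    fit = moderated_ols(Y, X, moderation=moderation, groups=groups)
    rows = []
    for si, stage in enumerate(STAGES):
        j = len(STAGES) + si
        rows.append(
            pd.DataFrame(
                {
                    "unit": values.index,
                    "stage": stage,
                    "coef": fit.coef[:, j],
                    "t": fit.t[:, j],
                    "p": fit.pvalues[:, j],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def add_lfdr(
    table: pd.DataFrame, threshold: float = 0.05, block: int | None = None
) -> pd.DataFrame:
    """Append lfdr and direction columns (jointly across all contrasts).

    ``block=1`` evaluates the density at raw resolution; appropriate for
    small families (cluster-level tests) where discoveries are isolated.
    """
    out = table.copy()
    lfdr, calls = compute_lfdr(out["p"].to_numpy(), threshold=threshold, block=block)
    out["lfdr"] = lfdr
    out["direction"] = np.where(
        calls, np.where(out["coef"] > 0, DIR_M, DIR_F), DIR_NONE
    )
    return out


def cluster_eigengene(
    values: pd.DataFrame, clusters: pd.Series, skip_unassigned: bool = True
) -> pd.DataFrame:
    """First principal component of each cluster's standardised node values.

    The eigengene sign is oriented to correlate positively with the cluster's
    mean expression profile; constant clusters yield a zero eigengene (with a
    warning).  The unassigned ("grey") pool is not a module and is skipped by
    default.
    """
    rows, idx = [], []
    for c in clusters.unique():
        if skip_unassigned and c == "grey":
            continue
        members = clusters.index[clusters == c]
        sub = values.loc[values.index.intersection(members)].to_numpy()
        if sub.shape[0] < 2:
            continue
        sd = sub.std(axis=1, keepdims=True)
        mean_profile = sub.mean(axis=0)
        ok = sd.ravel() > 0
        if not ok.any():
            warnings.warn(f"cluster {c} is constant; eigengene set to zeros")
            rows.append(np.zeros(sub.shape[1]))
            idx.append(c)
            continue
        z = (sub[ok] - sub[ok].mean(axis=1, keepdims=True)) / sd[ok]
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        if np.corrcoef(eig, mean_profile)[0, 1] < 0:
            eig = -eig
        rows.append(eig)
        idx.append(c)
    return pd.DataFrame(rows, index=pd.Index(idx, name="cluster"), columns=values.columns)


def fit_cluster_de(
    eigengenes: pd.DataFrame, design: pd.DataFrame, moderation: bool = True
) -> pd.DataFrame:
    """Stage-specific sex contrasts on module eigengenes (same model)."""
    return fit_node_de(eigengenes, design, moderation=moderation)


def _gene_list(gene_field: str) -> list[str]:
    return [g for g in str(gene_field).split(",") if g]


def classify_gene_bias(
    node_de: pd.DataFrame,
    node_meta: pd.DataFrame,
    gonad_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Roll node-level direction calls up to genes (any-node rule).

    ``node_de`` must carry lfdr/direction columns.  CCRE nodes attribute
    their bias to every member gene.  Output: one row per gene with per-stage
    bias in {M, F, both, none}, ever_M / ever_F / switch flags and gonad
    status (from ``gonad_flags``, a gene -> {testis, ovary} map; default
    soma).
    """
    gene_of = dict(zip(node_meta["node_id"], node_meta["gene_id"]))
    per_gene: dict[str, dict[str, set]] = {}
    for gs in node_meta["gene_id"]:
        for g in _gene_list(gs):
            per_gene.setdefault(g, {s: set() for s in STAGES})
    sig = node_de[node_de["direction"].isin([DIR_M, DIR_F])]
    for _, row in sig.iterrows():
        for g in _gene_list(gene_of.get(row["unit"], row["unit"])):
            per_gene.setdefault(g, {s: set() for s in STAGES})
            per_gene[g][row["stage"]].add(row["direction"])
    rows = []
    for g, stage_dirs in per_gene.items():
        rec: dict = {"gene_id": g}
        ever = set()
        for s in STAGES:
            d = stage_dirs[s]
            rec[s] = DIR_BOTH if len(d) == 2 else (next(iter(d)) if d else DIR_NONE)
            ever |= d
        rec["ever_M"] = DIR_M in ever
        rec["ever_F"] = DIR_F in ever
        rec["switch"] = rec["ever_M"] and rec["ever_F"]
        rec["gonad"] = (
            gonad_flags.get(g, "soma") if gonad_flags is not None else "soma"
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id").sort_index()


def fisher_one_tailed(
    a: int, b: int, c: int, d: int, alternative: str = "greater"
) -> tuple[float, float]:
    """Odds ratio and one-tailed Fisher p for the 2x2 table [[a, b], [c, d]]."""
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return odds, p


def test_switch_depletion(gene_table: pd.DataFrame) -> dict:
    """Is joint ever-M and ever-F membership rarer than independence predicts?

    2x2 of ever-M x ever-F over all genes in the table, one-tailed Fisher for
    depletion of the joint (switch) cell.  A degenerate margin returns p = 1
    with a warning.
    """
    em = gene_table["ever_M"]
    ef = gene_table["ever_F"]
    a = int((em & ef).sum())
    b = int((em & ~ef).sum())
    c = int((~em & ef).sum())
    d = int((~em & ~ef).sum())
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate margin in switch table; p set to 1")
        return {"table": (a, b, c, d), "odds_ratio": np.nan, "p": 1.0}
    odds, p = fisher_one_tailed(a, b, c, d, alternative="less")
    return {"table": (a, b, c, d), "odds_ratio": odds, "p": p}


# ---------------------------------------------------------------------------
# gonad bias
# ---------------------------------------------------------------------------


def gonad_design(design: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Sub-design and model matrix for the gonad contrast.

    Uses pupal male whole bodies vs testes and adult female whole bodies vs
    ovaries.  Columns: a separate baseline per sex and a separate gonad
    contrast per sex (the value ~ sex + sex:gonad, no-intercept model, so
    each sex is contrasted with its own gonad).
    """
    male = design[(design["stage"] == "pupa") & (design["sex"] == "M")]
    female = design[(design["stage"] == "adult") & (design["sex"] == "F")]
    missing = []
    if not (male["tissue"] == "testis").any():
        missing.append("pupa/M/testis")
    if not (female["tissue"] == "ovary").any():
        missing.append("adult/F/ovary")
    if missing:
        raise ValueError(f"gonad samples absent for: {missing}")
    sub = pd.concat([male, female]).reset_index(drop=True)
    X = np.column_stack(
        [
            (sub["sex"] == "M").to_numpy(float),
            (sub["sex"] == "F").to_numpy(float),
            ((sub["sex"] == "M") & (sub["tissue"] == "testis")).to_numpy(float),
            ((sub["sex"] == "F") & (sub["tissue"] == "ovary")).to_numpy(float),
        ]
    )
    return sub, X, ["baseline_M", "baseline_F", "gonad_M", "gonad_F"]


def fit_gonad_bias(
    values: pd.DataFrame,
    design: pd.DataFrame,
    node_meta: pd.DataFrame,
    threshold: float = 0.05,
    moderation: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag testis-/ovary-enriched nodes and roll up to genes.

    A node is gonad-enriched when the overall gonad contrast (the mean of
    the two sex-specific gonad effects) is significant at the lfdr
    threshold; among gonad-enriched nodes, the testis-vs-ovary contrast
    decides the tissue, and both must be significant for a flag (the tissue
    being the sign of the difference).  Returns (node table, gene -> tissue
    flags).
    """
    sub, X, names = gonad_design(design)
    Y = values[sub["sample_id"].tolist()].to_numpy()
    groups = (
        node_meta.set_index("node_id")["kind"]
        .reindex(values.index)
        .map({"splicing": 1})
        .fillna(0)
        .to_numpy(int)
    )
    fit = moderated_ols(Y, X, moderation=moderation, groups=groups)
    # contrasts: overall gonad effect; testis-vs-ovary difference
    L = np.array([[0, 0, 0.5, 0.5], [0, 0, 1.0, -1.0]])
    xtx_inv = np.linalg.inv(X.T @ X)
    res = {}
    for name, l in zip(["gonad", "tissue_diff"], L):
        c = fit.coef @ l
        var_scale = float(l @ xtx_inv @ l)
        se = np.sqrt(fit.s2 * var_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, c / se, 0.0)
        p = np.where(
            np.isinf(fit.df_total),
            2 * stats.norm.sf(np.abs(t)),
            2 * stats.t.sf(np.abs(t), np.where(np.isinf(fit.df_total), 1, fit.df_total)),
        )
        p = np.where((se == 0) & (np.abs(c) < 1e-12), 1.0, p)
        res[name] = (c, p)
    pooled = np.concatenate([res[k][1] for k in res])
    lfdr, _ = compute_lfdr(pooled, threshold=threshold)
    lf = {k: lfdr[i * len(values): (i + 1) * len(values)] for i, k in enumerate(res)}
    both = (lf["gonad"] < threshold) & (lf["tissue_diff"] < threshold)
    testis = both & (res["tissue_diff"][0] > 0)
    ovary = both & (res["tissue_diff"][0] < 0)
    node_table = pd.DataFrame(
        {
            "coef_gonad": res["gonad"][0],
            "coef_tissue_diff": res["tissue_diff"][0],
            "lfdr_gonad": lf["gonad"],
            "lfdr_tissue_diff": lf["tissue_diff"],
            "testis_enriched": testis,
            "ovary_enriched": ovary,
        },
        index=values.index,
    )
    gene_of = dict(zip(node_meta["node_id"], node_meta["gene_id"]))
    flags: dict[str, str] = {}
    for node_id, row in node_table.iterrows():
        tissue = (
            "testis" if row["testis_enriched"] else
            "ovary" if row["ovary_enriched"] else None
        )
        if tissue:
            for g in _gene_list(gene_of.get(node_id, node_id)):
                flags[g] = tissue
    return node_table, pd.Series(flags, dtype=object)


def enrich_clusters_gonad(
    clusters: pd.Series,
    node_flags: pd.DataFrame,
    min_count: int = 5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of gonad-biased isoforms per cluster (BH-FDR).

    Only clusters with at least ``min_count`` flagged isoforms of a tissue
    are tested, against the counts in the rest of the transcriptome.
    """
    rows = []
    for tissue in ("testis", "ovary"):
        flagged = node_flags[f"{tissue}_enriched"].reindex(clusters.index).fillna(False)
        total_flagged = int(flagged.sum())
        total = len(clusters)
        for c in clusters.unique():
            inside = clusters == c
            a = int((flagged & inside).sum())
            if a < min_count:
                continue
            b = int(inside.sum()) - a
            cc = total_flagged - a
            d = total - int(inside.sum()) - cc
            odds, p = fisher_one_tailed(a, b, cc, d, alternative="greater")
            rows.append((c, tissue, a, b, cc, d, odds, p))
    out = pd.DataFrame(
        rows, columns=["cluster", "tissue", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["enriched"] = out["fdr"] < fdr_threshold
    return out


def enrich_linkage_groups(
    gene_table: pd.DataFrame,
    linkage: pd.Series,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """One-tailed Fisher enrichment of sex-biased genes per linkage group.

    Switch genes (ever-M and ever-F) are excluded first.  Each group is
    tested for male- and for female-bias enrichment against all other groups
    pooled; p-values are corrected jointly by lfdr and calls reported at
    ``threshold``.
    """
    tbl = gene_table[~gene_table["switch"]]
    lg = linkage.reindex(tbl.index)
    rows = []
    for group in sorted(lg.dropna().unique()):
        inside = lg == group
        if inside.sum() == 0:
            warnings.warn(f"linkage group {group} has no genes; skipped")
            continue
        for sex, col in (("M", "ever_M"), ("F", "ever_F")):
            a = int((tbl[col] & inside).sum())
            b = int(inside.sum()) - a
            c = int((tbl[col] & ~inside).sum())
            d = int((~inside).sum()) - c
            odds, p = fisher_one_tailed(a, b, c, d, alternative="greater")
            rows.append((group, sex, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows, columns=["group", "sex", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    if len(out):
        # small family of tests with isolated discoveries: raw-resolution
        # density estimate
        lfdr, calls = compute_lfdr(out["p"].to_numpy(), threshold=threshold,
                                   block=1)
        out["lfdr"] = lfdr
        out["enriched"] = calls
    return out
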