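"""Exon-matrix preprocessing: expression floor, detection filter, node
decomposition and CCRE collapsing.

The raw input is an exon x sample matrix of log2 intensities (already
normalised against a noise quantile).  Preprocessing proceeds in four steps:

1. floor: values below an experiment-wide expression percentile collapse to 0,
2. filter: keep exons detected (>0) in >= min_reps replicates of >= 1
   biological condition, dropping genes with no surviving exon,
3. decompose: one transcription node per gene (constitutive-exon signal) plus
   one splicing node per facultative exon-group, holding splicing ratios in
   [0, 1],
4. collapse: groups of nodes with reciprocal correlation above a threshold
   become single Constitutively Correlated Regulatory Events (CCREs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KIND_TRANSCRIPTION = "transcription"
KIND_SPLICING = "splicing"
KIND_CCRE = "ccre"


@dataclass
class NodeMatrix:
    """Node x sample values plus per-node metadata.

    ``values`` is indexed by node_id with one column per sample.  ``meta`` has
    one row per node: node_id, kind (transcription / splicing / ccre),
    gene_id, and the member exon (or node) ids as a comma-joined string.
    Splicing-node rows hold ratios in [0, 1]; transcription rows hold log2
    expression.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def kinds(self) -> pd.Series:
        return self.meta.set_index("node_id")["kind"]

    def genes_of(self, node_id: str) -> list[str]:
        row = self.meta.loc[self.meta["node_id"] == node_id].iloc[0]
        return str(row["gene_id"]).split(",")


def composition_summary(meta: pd.DataFrame) -> pd.DataFrame:
    """Feature-count roll-up: counts and integer-rounded percentages by kind."""
    counts = meta["kind"].value_counts()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "count": counts,
            "percent": [round(100 * c / total) for c in counts],
        }
    )


def apply_expression_floor(matrix: pd.DataFrame, percentile: float = 66) -> pd.DataFrame:
    """Collapse values below the experiment-wide percentile to exactly 0.

    The percentile is taken over every value in the matrix, with the linear
    interpolation quantile definition; values strictly below the cut become 0,
    values at or above it are unchanged.
    """
    if matrix.size == 0:
        raise ValueError("empty matrix")
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    cut = np.percentile(matrix.to_numpy(), percentile)
    out = matrix.copy()
    out[out < cut] = 0.0
    return out


def filter_detected(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    exon_gene: pd.Series,
    min_reps: int = 2,
) -> pd.DataFrame:
    """Retain exons detected in >= ``min_reps`` replicates of some condition.

    A condition is a (stage, sex, tissue) cell of the design; detection means
    a strictly positive (un-floored) value.  Genes whose exons all fail are
    dropped entirely (their surviving siblings would be un-interpretable).
    """
    reps_per_cell = design.groupby(["stage", "sex", "tissue"])["sample_id"].count()
    if min_reps > reps_per_cell.max():
        raise ValueError(
            f"min_reps={min_reps} exceeds available replication "
            f"({reps_per_cell.max()})"
        )
    keep = pd.Series(False, index=matrix.index)
    for _, cell in design.groupby(["stage", "sex", "tissue"]):
        cols = cell["sample_id"].tolist()
        keep |= (matrix[cols] > 0).sum(axis=1) >= min_reps
    return matrix.loc[keep]


def _linear(x: np.ndarray) -> np.ndarray:
    """Floored log2 -> linear scale; exact zeros mean 'not expressed'."""
    return np.where(x > 0, np.exp2(x), 0.0)


def decompose_nodes(
    matrix: pd.DataFrame,
    models: pd.DataFrame,
) -> NodeMatrix:
    """Split each gene into a transcription node and splicing-ratio nodes.

    The transcription node is the mean of the gene's constitutive-exon log2
    values.  Each facultative exon-group yields one splicing node whose value
    is the group's linear-scale signal divided by the summed linear-scale
    constitutive signal, clamped to [0, 1]; samples with zero gene total get
    ratio 0.  A gene left without constitutive exons falls back to the
    all-exon mean as its gene signal (with a warning).
    """
    models = models[models["exon_id"].isin(matrix.index)].reset_index(drop=True)
    mat = matrix.to_numpy()
    row_of = pd.Series(np.arange(len(matrix)), index=matrix.index)
    exon_rows = row_of.loc[models["exon_id"]].to_numpy()
    rows, metas = [], []
    for gid, idx in models.groupby("gene_id", sort=False).indices.items():
        is_const = models["constitutive"].to_numpy()[idx]
        const_idx = idx[is_const]
        if len(const_idx) == 0:
            warnings.warn(
                f"gene {gid} has no constitutive exon after filtering; "
                "using all-exon mean as gene signal"
            )
            const_idx = idx
        cvals = mat[exon_rows[const_idx]]
        rows.append(cvals.mean(axis=0))
        const_names = models["exon_id"].to_numpy()[const_idx]
        metas.append((f"{gid}_T", KIND_TRANSCRIPTION, gid, ",".join(const_names)))
        gene_total = _linear(cvals).sum(axis=0)
        fac_idx = idx[~is_const]
        if len(fac_idx) == 0:
            continue
        groups = models["exon_group"].to_numpy()[fac_idx]
        for grp in pd.unique(groups):
            gi = fac_idx[groups == grp]
            fac_signal = _linear(mat[exon_rows[gi]]).mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(gene_total > 0, fac_signal / gene_total, 0.0)
            rows.append(np.clip(ratio, 0.0, 1.0))
            ex = models["exon_id"].to_numpy()[gi]
            metas.append((f"{gid}_S_{grp}", KIND_SPLICING, gid, ",".join(ex)))
    meta = pd.DataFrame(metas, columns=["node_id", "kind", "gene_id", "members"])
    values = pd.DataFrame(
        np.vstack(rows), index=pd.Index(meta["node_id"], name="node_id"),
        columns=matrix.columns,
    )
    return NodeMatrix(values=values, meta=meta)


def _correlation_groups(
    corr: np.ndarray, threshold: float, all_pairs: bool
) -> list[list[int]]:
    """Groups of node indices under the chosen collapse rule.

    Default: connected components of the >threshold correlation graph
    (single-linkage).  ``all_pairs`` instead requires every pair within a
    group to exceed the threshold (greedy maximal cliques, deterministic).
    """
    n = corr.shape[0]
    above = corr > threshold
    np.fill_diagonal(above, False)
    if not all_pairs:
        # union-find over the thresholded graph
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in zip(*np.nonzero(np.triu(above))):
            ri, rj = find(int(i)), find(int(j))
            if ri != rj:
                parent[rj] = ri
        comps: dict[int, list[int]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        return [c for c in comps.values() if len(c) > 1]
    groups = []
    unused = np.ones(n, dtype=bool)
    for i in range(n):
        if not unused[i]:
            continue
        members = [i]
        for j in range(i + 1, n):
            if unused[j] and all(above[j, m] for m in members):
                members.append(j)
        if len(members) > 1:
            for m in members:
                unused[m] = False
            groups.append(members)
    return groups


def collapse_ccres(
    nodes: NodeMatrix,
    threshold: float = 0.95,
    all_pairs: bool = False,
) -> tuple[NodeMatrix, pd.DataFrame]:
    """Collapse near-identical nodes into CCREs.

    Nodes with reciprocal Pearson correlation above ``threshold`` (on their
    analysed scale: log2 for transcription, ratio for splicing) are grouped
    and replaced by one CCRE node carrying the representative member's
    values.  The representative is the member with the most within-group
    correlations exceeding the threshold; two-member groups use the member
    with the higher mean value.  Returns the collapsed NodeMatrix and a CCRE
    map (ccre_id, representative, members).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    vals = nodes.values.to_numpy()
    if vals.shape[1] < 3:
        raise ValueError("need >= 3 samples to collapse on correlation")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(vals)
    corr = np.nan_to_num(corr, nan=0.0)
    groups = _correlation_groups(corr, threshold, all_pairs)

    node_ids = nodes.values.index.to_list()
    drop = set()
    ccre_rows = []
    new_vals, new_meta = [], []
    gene_of = nodes.meta.set_index("node_id")["gene_id"]
    for k, grp in enumerate(sorted(groups, key=lambda g: g[0])):
        ids = [node_ids[i] for i in grp]
        if len(grp) == 2:
            means = vals[grp].mean(axis=1)
            rep = grp[int(np.argmax(means))]
        else:
            links = [
                sum(corr[i, j] > threshold for j in grp if j != i) for i in grp
            ]
            rep = grp[int(np.argmax(links))]
        rep_id = node_ids[rep]
        ccre_id = f"ccre{k:04d}"
        drop.update(grp)
        member_genes = sorted({gene_of[i] for i in ids})
        new_vals.append(vals[rep])
        new_meta.append((ccre_id, KIND_CCRE, ",".join(member_genes), ",".join(ids)))
        ccre_rows.append((ccre_id, rep_id, ",".join(ids)))

    keep_idx = [i for i in range(len(node_ids)) if i not in drop]
    out_vals = np.vstack([vals[keep_idx]] + ([np.vstack(new_vals)] if new_vals else []))
    kept_meta = nodes.meta.iloc[keep_idx][["node_id", "kind", "gene_id", "members"]]
    meta = pd.concat(
        [
            kept_meta,
            pd.DataFrame(new_meta, columns=["node_id", "kind", "gene_id", "members"]),
        ],
        ignore_index=True,
    )
    values = pd.DataFrame(
        out_vals, index=pd.Index(meta["node_id"], name="node_id"),
        columns=nodes.values.columns,
    )
    ccre_map = pd.DataFrame(ccre_rows, columns=["ccre_id", "representative", "members"])
    return NodeMatrix(values=values, meta=meta), ccre_map


def preprocess_pipeline(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    models: pd.DataFrame,
    floor_percentile: float | None = 66,
    min_reps: int = 2,
    ccre_threshold: float = 0.95,
) -> tuple[NodeMatrix, pd.DataFrame]:
    """Floor, filter, decompose and collapse in one call."""
    m = matrix
    if floor_percentile is not None:
        m = apply_expression_floor(m, floor_percentile)
        exon_gene = models.set_index("exon_id")["gene_id"]
        m = filter_detected(m, design, exon_gene, min_reps=min_reps)
    nodes = decompose_nodes(m, models)
    return collapse_ccres(nodes, threshold=ccre_threshold)
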