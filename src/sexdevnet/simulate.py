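"""Synthetic developmental transcriptome generator.

Emulates the statistical structure of a two-sex, five-stage whole-body
expression experiment on a haplodiploid insect: exon-level log2 expression
with planted stage-specific sex-biased expression (DE), sex-specific
within-cluster correlation (DC), gonad-enriched genes, an enriched linkage
group, and stratum-dependent network topology.  Every planted effect is
recorded in a truth table so the downstream pipeline can be validated
end-to-end without external data.

The noise model is additive Gaussian on the log2 scale (microarray-like
log-ratio intensities), not count-based.  The cluster-correlated baseline is
a shared latent factor per co-expression cluster plus independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

STAGES = ("early_embryo", "late_embryo", "larva", "pupa", "adult")
SEXES = ("M", "F")
STRATA = ("Metazoa", "Arthropoda", "Insecta", "Hymenoptera", "Chalcid", "Nasonia")

#: default marginal stratum proportions (oldest to youngest); configurable.
DEFAULT_STRATUM_PROBS = (0.34, 0.10, 0.16, 0.12, 0.17, 0.11)

#: node roles used when planting stratum-dependent topology
ROLE_LEAF = "leaf"
ROLE_HUB = "hub"
ROLE_INTERACTOR = "interactor"


def generate_design(n_reps: int = 3, with_gonads: bool = True) -> pd.DataFrame:
    """Balanced whole-body sample design: 5 stages x 2 sexes x ``n_reps``.

    Gonad samples (testis for pupal males, ovary for adult females) are
    appended when ``with_gonads`` is set; their whole-body references are the
    matching (stage, sex) cells already present in the design.

    Returns a DataFrame with columns sample_id, stage, sex, replicate, tissue,
    in deterministic order.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2: DE/DC fits need replication")
    rows = []
    for stage in STAGES:
        for sex in SEXES:
            for rep in range(1, n_reps + 1):
                rows.append((f"{stage}_{sex}{rep}", stage, sex, rep, "whole"))
    if with_gonads:
        for rep in range(1, n_reps + 1):
            rows.append((f"pupa_M{rep}_testis", "pupa", "M", rep, "testis"))
        for rep in range(1, n_reps + 1):
            rows.append((f"adult_F{rep}_ovary", "adult", "F", rep, "ovary"))
    return pd.DataFrame(
        rows, columns=["sample_id", "stage", "sex", "replicate", "tissue"]
    )


def generate_gene_models(
    n_genes: int,
    isoform_rate: float = 0.58,
    rng_seed: int = 0,
    n_clusters: int = 10,
    n_linkage_groups: int = 8,
    exons_per_gene: tuple[int, int] = (3, 8),
    paralog_rate: float = 0.3,
    stratum_probs: Sequence[float] = DEFAULT_STRATUM_PROBS,
) -> pd.DataFrame:
    """Generate a per-exon gene-model table with annotations.

    Each gene receives an ordered set of exons; with probability
    ``isoform_rate`` a gene is multi-isoform and one or two of its exons are
    facultative (grouped into exon groups with identical isoform membership).
    Genes are assigned to co-expression clusters, paralog families, linkage
    groups and phylogenetic strata from configurable categorical
    distributions.  The same seed yields an identical table.

    Columns: gene_id, exon_id, constitutive, exon_group, cluster,
    paralog_family, linkage_group, stratum.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= isoform_rate <= 1.0:
        raise ValueError("isoform_rate must be in [0, 1]")
    probs = np.asarray(stratum_probs, dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(rng_seed)

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    clusters = [f"c{i % n_clusters:03d}" for i in range(n_genes)]
    strata = rng.choice(len(STRATA), size=n_genes, p=probs)
    linkage = rng.integers(0, n_linkage_groups, size=n_genes)
    multi = rng.random(n_genes) < isoform_rate

    # paralog families: a fraction of genes fall into families of size >= 2
    fam = np.full(n_genes, -1)
    n_dup = int(round(paralog_rate * n_genes))
    dup_idx = rng.choice(n_genes, size=n_dup, replace=False)
    fam_id = 0
    i = 0
    while i < n_dup:
        size = min(int(rng.integers(2, 5)), n_dup - i)
        if size < 2:
            break
        for j in range(size):
            fam[dup_idx[i + j]] = fam_id
        fam_id += 1
        i += size

    rows = []
    for g in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        n_fac = 0
        if multi[g]:
            n_fac = min(int(rng.integers(1, 3)), n_ex - 1)
        fac_positions = set(
            rng.choice(n_ex, size=n_fac, replace=False).tolist() if n_fac else []
        )
        for e in range(n_ex):
            is_const = e not in fac_positions
            group = "" if is_const else f"{gene_ids[g]}_grp{sorted(fac_positions).index(e)}"
            rows.append(
                (
                    gene_ids[g],
                    f"{gene_ids[g]}_e{e}",
                    is_const,
                    group,
                    clusters[g],
                    f"fam{fam[g]:04d}" if fam[g] >= 0 else "",
                    f"lg{linkage[g]:02d}",
                    STRATA[strata[g]],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "exon_id",
            "constitutive",
            "exon_group",
            "cluster",
            "paralog_family",
            "linkage_group",
            "stratum",
        ],
    )


@dataclass
class DEEffect:
    cluster: str
    stage: str
    sex: str  # which sex is up-regulated
    log2fc: float


@dataclass
class DCEffect:
    cluster: str
    stage: str
    r_male: float
    r_female: float


@dataclass
class GonadEffect:
    genes: list[str]
    tissue: str  # "testis" or "ovary"
    log2fc: float


@dataclass
class LinkageEffect:
    linkage_group: str
    sex: str
    fraction_biased: float
    stage: str = "adult"
    log2fc: float = 2.0


@dataclass
class StratumTopologyEffect:
    """Planted association between gene age and within-cluster topology.

    ``hub_strata``/``interactor_strata`` name strata whose genes take hub-like
    (star centre: moderate connectivity to mutually unconnected partners) or
    interactor-like (dense mutual block: high connectivity, high clustering)
    positions inside the clusters listed in ``clusters``; other genes are
    leaves on the cluster backbone.  Loadings are on the shared-factor scale.
    """

    clusters: list[str]
    hub_strata: list[str] = field(default_factory=list)
    interactor_strata: list[str] = field(default_factory=list)
    #: dense-core structure: interactor genes split over n_cores independent
    #: core factors at core_loading; hub genes load bridge_loading on every
    #: core with random signs, so their neighbours span unconnected cores
    n_cores: int = 3
    core_loading: float = 0.95
    bridge_loading: float = 0.55


@dataclass
class EffectSpec:
    """Full description of the planted structure of one simulated experiment."""

    de_clusters: list[DEEffect] = field(default_factory=list)
    dc_clusters: list[DCEffect] = field(default_factory=list)
    gonad_enriched: list[GonadEffect] = field(default_factory=list)
    linkage_enriched: list[LinkageEffect] = field(default_factory=list)
    stratum_topology: list[StratumTopologyEffect] = field(default_factory=list)
    noise_sd: float = 0.2
    baseline_rho: float = 0.3
    signal_sd: float = 0.4
    baseline_mean: float = 7.0
    stage_profile_sd: float = 0.0  # shared per-(cluster, stage) amplitude
    #: cluster co-regulation program: "two_state" draws the shared factor as
    #: an on/off state (+1/-1) so planted correlations are realised exactly
    #: per sample; "uniform" draws a bounded continuous activity level
    #: U(-sqrt(3), sqrt(3)); "gaussian" draws it N(0, 1)
    factor_kind: str = "two_state"
    female_contamination: float = 0.0  # optional male admixture in pre-pupal F
    seed: int = 0

    def validate(self, models: pd.DataFrame) -> None:
        known_clusters = set(models["cluster"])
        known_genes = set(models["gene_id"])
        for eff in self.de_clusters + self.dc_clusters:
            if eff.cluster not in known_clusters:
                raise ValueError(f"effect references unknown cluster {eff.cluster!r}")
        for eff in self.dc_clusters:
            for r in (eff.r_male, eff.r_female):
                if not -1.0 <= r <= 1.0:
                    raise ValueError("DC correlations must lie in [-1, 1]")
        for eff in self.gonad_enriched:
            unknown = set(eff.genes) - known_genes
            if unknown:
                raise ValueError(f"gonad effect references unknown genes {unknown}")


def _gene_loadings(
    models: pd.DataFrame, effects: EffectSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, str], dict[str, "StratumTopologyEffect"]]:
    """Assign each gene a latent-factor role for its cluster signal.

    Genes in clusters without a planted topology effect are leaves on the
    cluster backbone at the baseline loading sqrt(rho).
    """
    genes = models.drop_duplicates("gene_id")[["gene_id", "cluster", "stratum"]]
    roles = {g: ROLE_LEAF for g in genes["gene_id"]}
    effect_of: dict[str, StratumTopologyEffect] = {}
    for eff in effects.stratum_topology:
        sub = genes[genes["cluster"].isin(eff.clusters)]
        for _, row in sub.iterrows():
            g = row["gene_id"]
            if row["stratum"] in eff.hub_strata:
                roles[g] = ROLE_HUB
                effect_of[g] = eff
            elif row["stratum"] in eff.interactor_strata:
                roles[g] = ROLE_INTERACTOR
                effect_of[g] = eff
    return genes, roles, effect_of


def generate_expression(
    design: pd.DataFrame,
    models: pd.DataFrame,
    effects: EffectSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an exon x sample log2 expression matrix plus a truth table.

    Gene-level signal is a cluster-correlated Gaussian: within a cluster,
    sample-wise values share a latent factor (loading sqrt(rho)), so the mean
    pairwise gene-gene correlation is ``baseline_rho``.  DE effects shift the
    stated (stage, sex) cells; DC effects replace the within-cluster
    correlation at the stated stage with the stated per-sex values.
    Facultative exon groups carry the gene signal times a latent logit-normal
    splicing fraction.  Gonad samples are the matched whole-body profile plus
    gene-specific enrichment shifts.

    Returns (exon_matrix, truth_table); the exon matrix is indexed by exon_id
    with one column per sample_id.
    """
    effects.validate(models)
    rng = np.random.default_rng(effects.seed)

    whole = design[design["tissue"] == "whole"].reset_index(drop=True)
    genes, roles, effect_of = _gene_loadings(models, effects, rng)
    gene_ids = genes["gene_id"].to_numpy()
    gene_cluster = genes["cluster"].to_numpy()
    n_genes = len(gene_ids)
    n_whole = len(whole)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    clusters = pd.unique(gene_cluster)
    # optional per-cluster per-stage profile (developmental amplitude); the
    # default 0 keeps the baseline a pure factor model so planted
    # correlations are exactly the stated ones
    stage_profile = {
        (c, st): rng.normal(0.0, effects.stage_profile_sd)
        for c in clusters
        for st in STAGES
    }
    mu_gene = rng.normal(effects.baseline_mean, 1.5, size=n_genes)

    dc_lookup = {(e.cluster, e.stage): e for e in effects.dc_clusters}

    rho0 = effects.baseline_rho
    sig = effects.signal_sd
    z = np.empty((n_genes, n_whole))
    # cluster latent factors per sample; interactor sub-block factors per cluster
    for ci, c in enumerate(clusters):
        gmask = gene_cluster == c
        idx = np.flatnonzero(gmask)
        role_arr = np.array([roles[g] for g in gene_ids[idx]])
        topo_eff = next(
            (effect_of[g] for g in gene_ids[idx] if g in effect_of), None
        )

        def draw_factor(size):
            if effects.factor_kind == "two_state":
                return rng.choice([-1.0, 1.0], size=size)
            if effects.factor_kind == "uniform":
                return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=size)
            return rng.normal(size=size)

        f = draw_factor(n_whole)  # cluster backbone factor
        eps = rng.normal(size=(len(idx), n_whole))
        is_core = role_arr == ROLE_INTERACTOR
        is_bridge = role_arr == ROLE_HUB
        if topo_eff is not None:
            n_cores = topo_eff.n_cores
            cores = draw_factor((n_cores, n_whole))
            core_of = np.flatnonzero(is_core) % n_cores  # round-robin
            signs = rng.choice([-1.0, 1.0], size=(int(is_bridge.sum()), n_cores))
            cl_ = topo_eff.core_loading
            bl = topo_eff.bridge_loading
            bridge_noise = np.sqrt(max(1.0 - n_cores * bl**2, 0.0))
        for s in range(n_whole):
            stage = whole.loc[s, "stage"]
            sex = whole.loc[s, "sex"]
            eff = dc_lookup.get((c, stage))
            if eff is not None:
                r = eff.r_male if sex == "M" else eff.r_female
                r = max(r, 0.0)
                load = np.sqrt(r)
            else:
                load = np.sqrt(rho0)
            col = load * f[s] + np.sqrt(1 - load**2) * eps[:, s]
            if topo_eff is not None and (is_core.any() or is_bridge.any()):
                # dense independent cores (interactors) and cross-core
                # bridges (hubs) replace the backbone signal for role genes
                ci_rows = np.flatnonzero(is_core)
                col[ci_rows] = (
                    cl_ * cores[core_of, s]
                    + np.sqrt(1 - cl_**2) * eps[ci_rows, s]
                )
                bi_rows = np.flatnonzero(is_bridge)
                col[bi_rows] = (
                    bl * (signs @ cores[:, s])
                    + bridge_noise * eps[bi_rows, s]
                )
            z[idx, s] = col
    gene_log2 = mu_gene[:, None] + sig * z
    for s in range(n_whole):
        stage = whole.loc[s, "stage"]
        for ci, c in enumerate(clusters):
            gene_log2[gene_cluster == c, s] += stage_profile[(c, stage)]

    truth_rows = []
    # planted cluster-level DE shifts
    for eff in effects.de_clusters:
        gmask = gene_cluster == eff.cluster
        smask = (
            (whole["stage"] == eff.stage) & (whole["sex"] == eff.sex)
        ).to_numpy()
        gene_log2[np.ix_(gmask, smask)] += eff.log2fc
        truth_rows.append(
            ("de_cluster", eff.cluster, "", eff.stage, eff.sex, eff.log2fc)
        )
    for eff in effects.dc_clusters:
        direction = "M" if eff.r_male > eff.r_female else "F"
        truth_rows.append(
            ("dc_cluster", eff.cluster, "", eff.stage, direction,
             eff.r_male - eff.r_female)
        )
    # planted gene-level linkage-group bias
    gene_lg = models.drop_duplicates("gene_id").set_index("gene_id")["linkage_group"]
    for eff in effects.linkage_enriched:
        members = [g for g in gene_ids if gene_lg[g] == eff.linkage_group]
        n_biased = int(round(eff.fraction_biased * len(members)))
        chosen = rng.choice(members, size=n_biased, replace=False)
        smask = (
            (whole["stage"] == eff.stage) & (whole["sex"] == eff.sex)
        ).to_numpy()
        for g in chosen:
            gene_log2[gene_pos[g], smask] += eff.log2fc
            truth_rows.append(
                ("de_gene", "", g, eff.stage, eff.sex, eff.log2fc)
            )

    # optional male admixture in pre-pupal "female" pools
    if effects.female_contamination > 0:
        c = effects.female_contamination
        pre = whole["stage"].isin(["early_embryo", "late_embryo", "larva"])
        for s in np.flatnonzero((pre & (whole["sex"] == "F")).to_numpy()):
            # find matching male replicate sample at the same stage
            m = whole[
                (whole["stage"] == whole.loc[s, "stage"])
                & (whole["sex"] == "M")
                & (whole["replicate"] == whole.loc[s, "replicate"])
            ].index[0]
            mix = (1 - c) * 2 ** gene_log2[:, s] + c * 2 ** gene_log2[:, m]
            gene_log2[:, s] = np.log2(mix)

    # ---- exon-level matrix -------------------------------------------------
    n_samples = len(design)
    sample_ids = design["sample_id"].tolist()
    whole_col = {whole.loc[s, "sample_id"]: s for s in range(n_whole)}

    # gonad columns start from the matched whole-body profile
    gonad_shift = np.zeros((n_genes, n_samples))
    gene_col = np.empty((n_genes, n_samples))
    for j, (_, row) in enumerate(design.iterrows()):
        if row["tissue"] == "whole":
            gene_col[:, j] = gene_log2[:, whole_col[row["sample_id"]]]
        else:
            ref = whole[
                (whole["stage"] == row["stage"])
                & (whole["sex"] == row["sex"])
                & (whole["replicate"] == row["replicate"])
            ].index[0]
            gene_col[:, j] = gene_log2[:, ref]
    gonad_genes: dict[str, str] = {}
    for eff in effects.gonad_enriched:
        jmask = (design["tissue"] == eff.tissue).to_numpy()
        for g in eff.genes:
            gonad_shift[gene_pos[g], jmask] += eff.log2fc
            gonad_genes[g] = eff.tissue
            truth_rows.append(("gonad_gene", "", g, "", eff.tissue, eff.log2fc))
    gene_col = gene_col + gonad_shift

    exon_rows = []
    exon_index = []
    exon_gene = []
    frac_truth = []
    for gid, sub in models.groupby("gene_id", sort=False):
        gi = gene_pos[gid]
        base = gene_col[gi]
        groups = [g for g in pd.unique(sub["exon_group"]) if g]
        group_frac = {}
        for grp in groups:
            base_logit = rng.normal(0.0, 1.0)
            lat = base_logit + rng.normal(0.0, 0.8, size=n_samples)
            frac = 1.0 / (1.0 + np.exp(-lat))
            group_frac[grp] = frac
            frac_truth.append((grp, gid, frac))
        for _, ex in sub.iterrows():
            if ex["constitutive"]:
                vals = base + rng.normal(0.0, effects.noise_sd, size=n_samples)
            else:
                frac = group_frac[ex["exon_group"]]
                vals = (
                    base
                    + np.log2(frac)
                    + rng.normal(0.0, effects.noise_sd, size=n_samples)
                )
            exon_rows.append(vals)
            exon_index.append(ex["exon_id"])
            exon_gene.append(gid)

    matrix = pd.DataFrame(
        np.vstack(exon_rows), index=pd.Index(exon_index, name="exon_id"),
        columns=sample_ids,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "cluster", "gene", "stage", "direction", "value"],
    )
    # latent splicing fractions, for recoverability checks
    frac_df = pd.DataFrame(
        {
            "exon_group": [t[0] for t in frac_truth],
            "gene_id": [t[1] for t in frac_truth],
        }
    )
    frac_mat = pd.DataFrame(
        np.vstack([t[2] for t in frac_truth]) if frac_truth else
        np.empty((0, n_samples)),
        columns=sample_ids,
    )
    truth.attrs["splicing_fractions"] = pd.concat([frac_df, frac_mat], axis=1)
    truth.attrs["gonad_genes"] = gonad_genes
    return matrix, truth


def write_dataset(
    out_dir,
    design: pd.DataFrame,
    models: pd.DataFrame,
    matrix: pd.DataFrame,
    truth: pd.DataFrame,
) -> None:
    """Write the simulated dataset as tab-delimited text files."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "exon_matrix.tsv", sep="\t")
    design.to_csv(out / "samples.tsv", sep="\t", index=False)
    models.to_csv(out / "gene_models.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
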