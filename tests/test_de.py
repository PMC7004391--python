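"""Stage-specific sex-bias models, eigengenes, gene-level classification and
enrichment tests (Fisher results checked against an exact hypergeometric
oracle)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sexdevnet import de, simulate
from sexdevnet.simulate import DEEffect, EffectSpec, GonadEffect, STAGES
from tests.conftest import simulate_nodes


def hypergeom_one_tailed(a, b, c, d, alternative="greater"):
    """Exact one-tailed Fisher p by summing hypergeometric probabilities."""
    n1, n2, m1 = a + b, c + d, a + c
    total = n1 + n2
    lo, hi = max(0, m1 - n2), min(n1, m1)
    probs = {
        k: stats.hypergeom.pmf(k, total, n1, m1) for k in range(lo, hi + 1)
    }
    if alternative == "greater":
        return sum(p for k, p in probs.items() if k >= a)
    return sum(p for k, p in probs.items() if k <= a)


class TestNodeDe:
    def test_identical_sexes_zero_interaction(self):
        design = simulate.generate_design(3, False)
        whole = design[design["tissue"] == "whole"]
        base = whole["stage"].map({s: float(i) for i, s in enumerate(STAGES)})
        vals = pd.DataFrame([base.to_numpy()], index=["n0"],
                            columns=whole["sample_id"])
        tab = de.fit_node_de(vals, design, moderation=False)
        assert np.allclose(tab["coef"], 0.0)
        assert (tab["p"] == 1.0).all()

    def test_planted_adult_bias_recovered(self):
        # average recovered coefficient over simulations within +/- 0.2
        coefs = {s: [] for s in STAGES}
        for seed in range(40):
            design, models, nodes, _, labels = simulate_nodes(
                seed=seed, n_genes=40, n_clusters=4,
                de_clusters=[DEEffect("c001", "adult", "F", 2.0)],
            )
            tab = de.fit_node_de(nodes.values, design)
            tab["cluster"] = labels.loc[tab["unit"]].to_numpy()
            planted = tab[tab["cluster"] == "c001"]
            for s in STAGES:
                coefs[s].append(planted.loc[planted["stage"] == s, "coef"].mean())
        assert abs(np.mean(coefs["adult"]) - (-2.0)) < 0.2
        for s in STAGES[:-1]:
            assert abs(np.mean(coefs[s])) < 0.2

    def test_stage_shift_invariance(self):
        # adding a constant to all samples of one stage is absorbed by Stage
        design = simulate.generate_design(3, False)
        whole = design[design["tissue"] == "whole"]
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(20, 30)),
                            index=[f"n{i}" for i in range(20)],
                            columns=whole["sample_id"])
        shifted = vals.copy()
        cols = whole.loc[whole["stage"] == "pupa", "sample_id"]
        shifted[cols] += 7.0
        a = de.fit_node_de(vals, design, moderation=False)
        b = de.fit_node_de(shifted, design, moderation=False)
        assert np.allclose(a["coef"], b["coef"], atol=1e-10)
        assert np.allclose(a["t"], b["t"], atol=1e-8)

    def test_rank_deficient_cell_named(self):
        design = simulate.generate_design(3, False)
        design = design[~((design["stage"] == "larva") & (design["sex"] == "M"))]
        vals = pd.DataFrame(np.zeros((1, len(design))), index=["n"],
                            columns=design["sample_id"])
        with pytest.raises(ValueError, match="larva"):
            de.fit_node_de(vals, design)


class TestLfdrCalls:
    def test_null_table_no_calls(self):
        design, _, nodes, _, _ = simulate_nodes(seed=60, n_genes=60, n_clusters=6)
        tab = de.add_lfdr(de.fit_node_de(nodes.values, design))
        assert (tab["direction"] == "none").mean() > 0.99


class TestEigengene:
    def test_identical_nodes_full_variance(self):
        profile = np.sin(np.linspace(0, 3, 12))
        vals = pd.DataFrame([profile + 5] * 4, index=[f"n{i}" for i in range(4)],
                            columns=[f"s{j}" for j in range(12)])
        labels = pd.Series("c", index=vals.index)
        eig = de.cluster_eigengene(vals, labels)
        r = np.corrcoef(eig.loc["c"], profile)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert r > 0  # oriented along the mean profile

    def test_two_node_closed_form(self):
        # eigenvector of a hand-computable 2x2 correlation matrix is (1,1)/sqrt(2)
        rng = np.random.default_rng(1)
        shared = rng.normal(size=200)
        x1 = shared + rng.normal(0, 0.5, 200)
        x2 = shared + rng.normal(0, 0.5, 200)
        vals = pd.DataFrame([x1, x2], index=["a", "b"],
                            columns=[f"s{j}" for j in range(200)])
        eig = de.cluster_eigengene(vals, pd.Series("c", index=["a", "b"]))
        z = (vals - vals.mean(axis=1).values[:, None]).div(
            vals.std(axis=1, ddof=0), axis=0
        )
        expected = (z.iloc[0] + z.iloc[1]) / np.sqrt(2)
        r = np.corrcoef(eig.loc["c"], expected)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_orientation_invariant_to_global_flip(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.normal(size=(5, 20)),
                            index=[f"n{i}" for i in range(5)],
                            columns=[f"s{j}" for j in range(20)])
        labels = pd.Series("c", index=vals.index)
        e1 = de.cluster_eigengene(vals, labels)
        e2 = de.cluster_eigengene(-vals, labels)
        r = np.corrcoef(e1.loc["c"], e2.loc["c"])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10


class TestClusterDe:
    def test_planted_cluster_called_at_right_stage(self):
        hits, wrong = 0, 0
        n_seeds = 15
        for seed in range(n_seeds):
            design, models, nodes, _, labels = simulate_nodes(
                seed=seed + 100, n_genes=200, n_clusters=10,
                de_clusters=[DEEffect("c003", "adult", "F", 3.0)],
            )
            whole = design.loc[design["tissue"] == "whole", "sample_id"].tolist()
            eig = de.cluster_eigengene(nodes.values[whole], labels)
            tab = de.add_lfdr(de.fit_cluster_de(eig, design), block=1)
            called = tab[tab["direction"] != "none"]
            if (
                ((called["unit"] == "c003") & (called["stage"] == "adult")).any()
            ):
                hits += 1
            wrong += len(called[
                (called["unit"] == "c003") & (called["stage"] != "adult")
            ])
        assert hits >= 0.9 * n_seeds
        assert wrong <= n_seeds  # pre-adult stages essentially never called

    def test_duplicated_node_cluster_matches_node_test(self):
        design, _, nodes, _, _ = simulate_nodes(seed=130, n_genes=30)
        whole = design.loc[design["tissue"] == "whole", "sample_id"].tolist()
        node = nodes.values.iloc[[0]]
        dup = pd.concat([node, node.set_axis(["copy"], axis=0)])
        labels = pd.Series("c", index=dup.index)
        eig = de.cluster_eigengene(dup[whole], labels)
        cl_tab = de.fit_cluster_de(eig, design, moderation=False)
        nd_tab = de.fit_node_de(node[whole], design, moderation=False)
        # identical nodes: eigengene is the standardised profile, so the
        # t statistics agree up to sign/scale of the response
        assert np.allclose(
            np.abs(cl_tab["t"].to_numpy()), np.abs(nd_tab["t"].to_numpy()),
            rtol=1e-6,
        )


class TestGeneBias:
    def _node_de(self, rows):
        return pd.DataFrame(rows, columns=["unit", "stage", "coef", "direction"])

    def _meta(self, mapping):
        return pd.DataFrame(
            {"node_id": list(mapping), "gene_id": list(mapping.values()),
             "kind": "transcription", "members": ""}
        )

    def test_single_stage_splicing_bias(self):
        tab = self._node_de([("n1", "larva", -1.0, "F")])
        meta = self._meta({"n1": "g1"})
        out = de.classify_gene_bias(tab, meta)
        assert out.loc["g1", "larva"] == "F"
        assert out.loc["g1", "adult"] == "none"
        assert not out.loc["g1", "switch"]

    def test_switch_gene(self):
        tab = self._node_de(
            [("n1", "pupa", 1.0, "M"), ("n2", "adult", -1.0, "F")]
        )
        meta = self._meta({"n1": "g1", "n2": "g1"})
        out = de.classify_gene_bias(tab, meta)
        assert out.loc["g1", "switch"]
        assert out.loc["g1", "ever_M"] and out.loc["g1", "ever_F"]

    def test_fixture_matches_enumeration(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(20)]
        rows, meta_map = [], {}
        expected = {g: {s: set() for s in STAGES} for g in genes}
        for i, g in enumerate(genes):
            for j in range(rng.integers(1, 4)):
                node = f"{g}_n{j}"
                meta_map[node] = g
                if rng.random() < 0.5:
                    s = STAGES[rng.integers(0, 5)]
                    d = "M" if rng.random() < 0.5 else "F"
                    rows.append((node, s, 1.0 if d == "M" else -1.0, d))
                    expected[g][s].add(d)
        out = de.classify_gene_bias(self._node_de(rows), self._meta(meta_map))
        for g in genes:
            for s in STAGES:
                exp = expected[g][s]
                want = "both" if len(exp) == 2 else (exp.pop() if exp else "none")
                assert out.loc[g, s] == want

    def test_monotone_adding_bias_never_removes(self):
        tab = self._node_de([("n1", "pupa", 1.0, "M")])
        meta = self._meta({"n1": "g1", "n2": "g1"})
        before = de.classify_gene_bias(tab, meta)
        tab2 = self._node_de(
            [("n1", "pupa", 1.0, "M"), ("n2", "larva", 1.0, "M")]
        )
        after = de.classify_gene_bias(tab2, meta)
        assert before.loc["g1", "ever_M"] and after.loc["g1", "ever_M"]
        assert after.loc["g1", "larva"] == "M"


class TestSwitchDepletion:
    def test_exact_table(self):
        gt = pd.DataFrame(
            {
                "ever_M": [True] * 100 + [False] * 900,
                "ever_F": [True] * 10 + [False] * 90 + [True] * 90 + [False] * 810,
            }
        )
        gt["switch"] = gt["ever_M"] & gt["ever_F"]
        res = de.test_switch_depletion(gt)
        assert res["table"] == (10, 90, 90, 810)
        assert res["p"] == pytest.approx(
            hypergeom_one_tailed(10, 90, 90, 810, "less"), rel=1e-9
        )

    def test_zero_overlap_depleted(self):
        gt = pd.DataFrame(
            {
                "ever_M": [True] * 200 + [False] * 800,
                "ever_F": [False] * 200 + [True] * 200 + [False] * 600,
            }
        )
        res = de.test_switch_depletion(gt)
        assert res["p"] < 1e-10

    def test_degenerate_margin_warns(self):
        gt = pd.DataFrame({"ever_M": [True, True], "ever_F": [True, False]})
        with pytest.warns(UserWarning, match="degenerate"):
            res = de.test_switch_depletion(gt)
        assert res["p"] == 1.0

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            em = rng.random(300) < 0.3
            ef = rng.random(300) < 0.3
            gt = pd.DataFrame({"ever_M": em, "ever_F": ef})
            ps.append(de.test_switch_depletion(gt)["p"])
        # one-tailed exact p under independence is stochastically >= uniform
        assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.01


class TestGonad:
    def test_identical_profiles_no_flags(self):
        design, _, nodes, _, _ = simulate_nodes(
            seed=140, n_genes=80, with_gonads=True
        )
        node_tab, flags = de.fit_gonad_bias(nodes.values, design, nodes.meta)
        assert len(flags) == 0

    def test_planted_testis_enrichment_flagged(self):
        tps = []
        for seed in range(5):
            design = simulate.generate_design(3, True)
            models = simulate.generate_gene_models(300, 0.3, rng_seed=seed)
            genes = models.drop_duplicates("gene_id")["gene_id"].tolist()
            planted = genes[:50]
            eff = EffectSpec(
                seed=seed + 1,
                gonad_enriched=[GonadEffect(planted, "testis", 3.0),
                                GonadEffect(genes[50:70], "ovary", 3.0)],
            )
            from sexdevnet import preprocess

            matrix, _ = simulate.generate_expression(design, models, eff)
            nodes, _ = preprocess.preprocess_pipeline(
                matrix, design, models, floor_percentile=None
            )
            _, flags = de.fit_gonad_bias(nodes.values, design, nodes.meta)
            tps.append(sum(1 for g in planted if flags.get(g) == "testis"))
        assert np.mean(tps) >= 45

    def test_missing_gonad_samples_rejected(self):
        design = simulate.generate_design(3, False)
        vals = pd.DataFrame(np.zeros((1, len(design))), index=["n"],
                            columns=design["sample_id"])
        with pytest.raises(ValueError, match="testis"):
            de.fit_gonad_bias(vals, design, pd.DataFrame(
                {"node_id": ["n"], "gene_id": ["g"], "kind": ["transcription"]}
            ))


class TestEnrichment:
    def test_cluster_gonad_counts_exact(self):
        ids = [f"n{i}" for i in range(2100)]
        clusters = pd.Series(["a"] * 100 + ["b"] * 2000, index=ids)
        flags = pd.DataFrame(
            {"testis_enriched": [True] * 20 + [False] * 80 + [True] * 100
             + [False] * 1900,
             "ovary_enriched": False},
            index=ids,
        )
        out = de.enrich_clusters_gonad(clusters, flags, min_count=5)
        row = out[(out["cluster"] == "a") & (out["tissue"] == "testis")].iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (20, 80, 100, 1900)
        assert row["p"] == pytest.approx(
            hypergeom_one_tailed(20, 80, 100, 1900, "greater"), rel=1e-9
        )

    def test_below_min_count_skipped(self):
        ids = [f"n{i}" for i in range(100)]
        clusters = pd.Series(["a"] * 10 + ["b"] * 90, index=ids)
        flags = pd.DataFrame(
            {"testis_enriched": [True] * 4 + [False] * 96,
             "ovary_enriched": False},
            index=ids,
        )
        out = de.enrich_clusters_gonad(clusters, flags, min_count=5)
        assert not (out["cluster"] == "a").any() if len(out) else True

    def test_linkage_enrichment_table3_like_group(self):
        # a group with 49 male-biased of 109 genes against ~17% background
        rng = np.random.default_rng(5)
        genes, lgs, em, ef = [], [], [], []
        for i in range(109):
            genes.append(f"a{i}")
            lgs.append("lg_hot")
            em.append(i < 49)
            ef.append(49 <= i < 61)
        for i in range(2000):
            genes.append(f"b{i}")
            lgs.append(f"lg{i % 8}")
            em.append(rng.random() < 0.17)
            ef.append(rng.random() < 0.17)
        gt = pd.DataFrame({"ever_M": em, "ever_F": ef}, index=genes)
        gt["switch"] = gt["ever_M"] & gt["ever_F"]
        out = de.enrich_linkage_groups(gt, pd.Series(lgs, index=genes))
        hot = out[(out["group"] == "lg_hot") & (out["sex"] == "M")].iloc[0]
        assert hot["enriched"]
        # every reported p equals the exact hypergeometric sum
        for _, r in out.iterrows():
            assert r["p"] == pytest.approx(
                hypergeom_one_tailed(r["a"], r["b"], r["c"], r["d"], "greater"),
                rel=1e-9, abs=1e-12,
            )

    def test_switch_genes_excluded(self):
        gt = pd.DataFrame(
            {"ever_M": [True, True], "ever_F": [True, False],
             "switch": [True, False]},
            index=["s1", "g1"],
        )
        out = de.enrich_linkage_groups(gt, pd.Series({"s1": "x", "g1": "x"}))
        assert (out[["a", "b"]].sum(axis=1) == 1).all()


class TestFisherOracleProperty:
    """Property: every one-tailed Fisher p equals the hypergeometric tail sum."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
        alt=st.sampled_from(["greater", "less"]),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_hypergeometric(self, a, b, c, d, alt):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        _, p = de.fisher_one_tailed(a, b, c, d, alternative=alt)
        assert p == pytest.approx(
            hypergeom_one_tailed(a, b, c, d, alt), rel=1e-9, abs=1e-12
        )
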