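import warnings

import numpy as np
import pandas as pd
import pytest

from sexdevnet import preprocess, simulate

warnings.filterwarnings("ignore", category=UserWarning)


def node_cluster_labels(nodes: preprocess.NodeMatrix, models: pd.DataFrame) -> pd.Series:
    """Ground-truth cluster label per node (CCREs take their first gene's)."""
    gene_cluster = (
        models.drop_duplicates("gene_id").set_index("gene_id")["cluster"]
    )
    meta = nodes.meta.set_index("node_id")
    return pd.Series(
        [
            gene_cluster[str(meta.loc[n, "gene_id"]).split(",")[0]]
            for n in nodes.values.index
        ],
        index=nodes.values.index,
    )


def simulate_nodes(
    seed: int,
    n_genes: int = 300,
    n_clusters: int = 10,
    isoform_rate: float = 0.0,
    with_gonads: bool = False,
    effects: simulate.EffectSpec | None = None,
    **effect_kwargs,
):
    """One-stop synthetic dataset -> (design, models, nodes, truth, labels)."""
    design = simulate.generate_design(3, with_gonads)
    models = simulate.generate_gene_models(
        n_genes, isoform_rate, rng_seed=seed, n_clusters=n_clusters
    )
    eff = effects or simulate.EffectSpec(seed=seed + 10_000, **effect_kwargs)
    matrix, truth = simulate.generate_expression(design, models, eff)
    nodes, _ = preprocess.preprocess_pipeline(
        matrix, design, models, floor_percentile=None
    )
    return design, models, nodes, truth, node_cluster_labels(nodes, models)


@pytest.fixture(scope="session")
def small_dataset():
    """A small null dataset reused by several structural tests."""
    return simulate_nodes(seed=11, n_genes=120, n_clusters=6, isoform_rate=0.4)
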