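import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mircircuitnet.io_formats import ExpressionMatrix, SampleSheet
from mircircuitnet.synthetic_data import (
    CohortConfig,
    generate_cohort,
    generate_target_predictions,
    generate_tf_layer,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Default synthetic cohort shared across tests (seeded, read-only)."""
    cfg = CohortConfig(seed=11)
    mirna, genes, sheet, truth = generate_cohort(cfg)
    interactions, genes = generate_tf_layer(truth, cfg, mirna, genes)
    predictions = generate_target_predictions(truth, cfg)
    return {
        "config": cfg,
        "mirna": mirna,
        "genes": genes,
        "sheet": sheet,
        "truth": truth,
        "interactions": interactions,
        "predictions": predictions,
    }


@pytest.fixture()
def tiny_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        index=["f1", "f2"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(data, "gene")


@pytest.fixture()
def tiny_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "patient_id": ["p1", "p1", "p1"],
                "tissue": ["N", "T", "M"],
            }
        )
    )


def two_class_sheet(n_a: int, n_b: int, class_a: str = "T", class_b: str = "N") -> SampleSheet:
    rows = []
    for i in range(n_a):
        rows.append({"sample_id": f"a{i}", "patient_id": f"pa{i}", "tissue": class_a})
    for i in range(n_b):
        rows.append({"sample_id": f"b{i}", "patient_id": f"pb{i}", "tissue": class_b})
    return SampleSheet(pd.DataFrame(rows))


def random_matrix(
    n_features: int, n_samples: int, seed: int, kind: str = "miRNA",
    loc: float = 6.0, scale: float = 1.0, prefix: str = "f", columns=None
) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    cols = columns if columns is not None else [f"s{i}" for i in range(n_samples)]
    data = pd.DataFrame(
        rng.normal(loc, scale, (n_features, n_samples)),
        index=[f"{prefix}{i}" for i in range(n_features)],
        columns=cols,
    )
    return ExpressionMatrix(data, kind)


def random_mixed_graph(rng, max_nodes=30):
    """Random typed graph with all three edge classes and p attributes."""
    n_tf = int(rng.integers(1, 5))
    n_m = int(rng.integers(1, 8))
    n_g = int(rng.integers(1, max(2, max_nodes - n_tf - n_m)))
    g = nx.DiGraph()
    tfs = [f"TF{i}" for i in range(n_tf)]
    mirnas = [f"m{i}" for i in range(n_m)]
    genes = [f"g{i}" for i in range(n_g)]
    for n in tfs:
        g.add_node(n, kind="TF")
    for n in mirnas:
        g.add_node(n, kind="miRNA")
    for n in genes:
        g.add_node(n, kind="gene")
    for tf in tfs:
        for m in mirnas:
            if rng.random() < 0.35:
                g.add_edge(tf, m, etype="tf_mirna", p=float(rng.uniform(1e-6, 0.05)))
        for gene in genes:
            if rng.random() < 0.35:
                g.add_edge(tf, gene, etype="tf_gene", p=float(rng.uniform(1e-6, 0.05)))
    for m in mirnas:
        for target in genes + tfs:
            if rng.random() < 0.3:
                g.add_edge(m, target, etype="repression", p=float(rng.uniform(1e-6, 0.05)))
    return g


def brute_force_circuits(g):
    """All-triples scan over (TF, miRNA, gene) with hand-rolled Fisher combination."""
    kinds = nx.get_node_attributes(g, "kind")
    tfs = [n for n, k in kinds.items() if k == "TF"]
    mirnas = [n for n, k in kinds.items() if k == "miRNA"]
    genes = [n for n, k in kinds.items() if k == "gene"]

    def edge(u, v, etype):
        d = g.get_edge_data(u, v)
        return d if d is not None and d.get("etype") == etype else None

    def fisher(ps):
        chi2 = -2.0 * sum(np.log(p) for p in ps)
        return float(stats.chi2.sf(chi2, df=2 * len(ps)))

    found = set()
    for tf, m, gene in itertools.product(tfs, mirnas, genes):
        e1, e2, e3 = (edge(tf, m, "tf_mirna"), edge(tf, gene, "tf_gene"),
                      edge(m, gene, "repression"))
        if e1 and e2 and e3:
            found.add(("TF_driven", tf, m, gene,
                       round(fisher([e1["p"], e2["p"], e3["p"]]), 12)))
        e1, e2, e3 = (edge(m, tf, "repression"), edge(m, gene, "repression"),
                      edge(tf, gene, "tf_gene"))
        if e1 and e2 and e3:
            found.add(("miRNA_driven", tf, m, gene,
                       round(fisher([e1["p"], e2["p"], e3["p"]]), 12)))
    return found
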