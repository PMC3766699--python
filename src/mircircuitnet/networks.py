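"""Regulatory-network induction and mixed miRNA-TF circuit enumeration.

Two network layers are built on top of the supported miRNA->target relations:

* the *post-transcriptional* network induced by differentially expressed
  miRNAs (DEMs) and their supported targets, annotated with DEG flags and
  decomposed into connected components (up- and down-modulated DEMs reported
  separately);
* the *mixed* network adding transcription-factor edges (TF->gene and
  TF->miRNA), scored by Pearson correlation of the two members' expression
  profiles over matched samples — miRNA edges must be anti-correlated, TF
  edges may carry either sign — and kept at a BH FDR threshold within each
  edge class.

Triangular feed-forward circuits of the two canonical types are enumerated
exhaustively on the mixed network:

* **TF-driven**: TF->miRNA, TF->gene and miRNA-|gene;
* **miRNA-driven**: miRNA-|TF, miRNA-|gene and TF->gene.

Each circuit's three edge p-values are combined with Fisher's method.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SampleSheet
from .preprocess import class_mean_log2fc
from .target_support import bh_adjust, match_samples, _rowwise_standardize

REPRESSION = "repression"   # miRNA -| target (gene or TF)
TF_GENE = "tf_gene"
TF_MIRNA = "tf_mirna"


def induce_dem_network(
    relations: pd.DataFrame,
    dems: pd.DataFrame,
    degs: pd.DataFrame | None = None,
) -> nx.DiGraph:
    """Bipartite network of selected DEMs and their supported target genes.

    Nodes are the DEMs present in ``dems`` (already screened by the
    fold-change/background rule) plus every gene they are supported to
    repress; gene nodes are flagged ``deg=True`` when listed in ``degs``.
    DEM nodes carry ``direction`` ('up'/'down') from the sign of their fold
    change so that up- and down-modulated components can be reported apart.
    """
    graph = nx.DiGraph()
    if dems.empty:
        return graph
    dem_dir = {
        row["feature_id"]: ("up" if row["log2fc"] > 0 else "down")
        for _, row in dems.iterrows()
    }
    deg_set = set() if degs is None or degs.empty else set(degs["feature_id"])
    for _, rel in relations.iterrows():
        mirna = rel["mirna_id"]
        if mirna not in dem_dir:
            continue
        gene = rel["gene_id"]
        graph.add_node(mirna, kind="miRNA", dem=True, direction=dem_dir[mirna])
        graph.add_node(gene, kind="gene", deg=bool(gene in deg_set))
        graph.add_edge(
            mirna, gene, etype=REPRESSION,
            r=float(rel["r"]), p=float(rel["p"]), q=float(rel["q"]),
        )
    # isolated DEMs (no supported target) are still part of the analysis view
    for mirna, direction in dem_dir.items():
        if mirna not in graph:
            graph.add_node(mirna, kind="miRNA", dem=True, direction=direction)
    return graph


def connected_components(network: nx.Graph) -> list[set]:
    """Node sets of the undirected connected components, largest first."""
    comps = [set(c) for c in nx.connected_components(network.to_undirected())]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def split_by_dem_direction(network: nx.DiGraph) -> dict[str, nx.DiGraph]:
    """Sub-networks induced by up- vs down-modulated DEMs and their targets."""
    out = {}
    for direction in ("up", "down"):
        dems = [n for n, d in network.nodes(data=True)
                if d.get("dem") and d.get("direction") == direction]
        targets = {t for m in dems for t in network.successors(m)}
        out[direction] = network.subgraph(set(dems) | targets).copy()
    return out


def build_mixed_network(
    mirna_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    sheet: SampleSheet,
    mirna_relations: pd.DataFrame,
    tf_interactions: pd.DataFrame,
    top_gene_fraction: float = 0.75,
    q_max: float = 0.05,
    contrasts: tuple[tuple[str, str], ...] = (("T", "N"), ("M", "T")),
) -> tuple[nx.DiGraph, dict]:
    """Mixed miRNA-TF network over the most differential genes.

    Genes are ranked by the maximum |log2 fold change| across the analysis
    contrasts and the top ``top_gene_fraction`` kept.  Candidate TF edges come
    from the validated interaction table; each is scored by the Pearson
    correlation of the two expression profiles over the matched samples and
    kept at BH ``q <= q_max`` within its edge class (TF->gene, TF->miRNA).
    miRNA-|target edges are the supported relations restricted to retained
    genes (TF targets always retained).  Returns the network and a report of
    dropped candidates.
    """
    if not 0 < top_gene_fraction <= 1:
        raise ValueError("top_gene_fraction must lie in (0, 1]")
    report = {"n_tf_candidates": int(len(tf_interactions)),
              "n_tf_edges_kept": 0, "n_tf_no_expression": 0,
              "n_relations_kept": 0}

    tf_ids = sorted(set(tf_interactions["regulator_id"])) if len(tf_interactions) else []
    tf_with_expr = [t for t in tf_ids if t in set(gene_matrix.feature_ids)]

    # rank genes by the largest class-mean shift across contrasts
    fcs = []
    for class_a, class_b in contrasts:
        try:
            fcs.append(class_mean_log2fc(gene_matrix, sheet, class_a, class_b).abs())
        except ValueError:
            continue
    max_fc = pd.concat(fcs, axis=1).max(axis=1) if fcs else pd.Series(
        0.0, index=gene_matrix.data.index
    )
    n_keep = int(np.floor(top_gene_fraction * len(max_fc)))
    order = np.argsort(-max_fc.to_numpy(), kind="stable")
    kept_genes = set(max_fc.index[order[:n_keep]]) | set(tf_with_expr)

    matched = match_samples(mirna_matrix, gene_matrix, sheet)
    n = len(matched)
    graph = nx.DiGraph()

    # --- miRNA -| target edges from the supported relations ---
    for _, rel in mirna_relations.iterrows():
        gene = rel["gene_id"]
        if gene not in kept_genes:
            continue
        kind = "TF" if gene in set(tf_with_expr) else "gene"
        graph.add_node(rel["mirna_id"], kind="miRNA")
        graph.add_node(gene, kind=kind)
        graph.add_edge(rel["mirna_id"], gene, etype=REPRESSION,
                       r=float(rel["r"]), p=float(rel["p"]), q=float(rel["q"]))
        report["n_relations_kept"] += 1

    if not tf_with_expr or tf_interactions.empty:
        report["n_tf_no_expression"] = len(tf_ids) - len(tf_with_expr)
        return graph, report

    # --- score candidate TF edges by expression correlation ---
    Gz = pd.DataFrame(
        _rowwise_standardize(gene_matrix.data.loc[:, matched].to_numpy()),
        index=gene_matrix.data.index, columns=matched,
    )
    Mz = pd.DataFrame(
        _rowwise_standardize(mirna_matrix.data.loc[:, matched].to_numpy()),
        index=mirna_matrix.data.index, columns=matched,
    )
    candidates = {TF_GENE: [], TF_MIRNA: []}
    for _, row in tf_interactions.iterrows():
        tf, target, kind = row["regulator_id"], row["target_id"], row["target_kind"]
        if tf not in Gz.index:
            report["n_tf_no_expression"] += 1
            continue
        if kind == "gene":
            if target in Gz.index and target in kept_genes and target != tf:
                candidates[TF_GENE].append((tf, target))
        else:
            if target in Mz.index:
                candidates[TF_MIRNA].append((tf, target))

    for etype, pairs in candidates.items():
        if not pairs:
            continue
        rs, ps = [], []
        for tf, target in pairs:
            other = Gz.loc[target] if etype == TF_GENE else Mz.loc[target]
            r = float(np.dot(Gz.loc[tf], other) / (n - 1))
            r = max(-1.0, min(1.0, r))
            with np.errstate(divide="ignore"):
                t = r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r**2, 1e-300))
            ps.append(2.0 * stats.t.sf(abs(t), df=n - 2))
            rs.append(r)
        qs = bh_adjust(ps)
        ranked = sorted(
            zip(pairs, rs, ps, qs), key=lambda item: -abs(item[1])
        )
        for (tf, target), r, p, q in ranked:
            if q > q_max:
                continue
            graph.add_node(tf, kind="TF")
            if etype == TF_GENE:
                graph.add_node(target, kind=graph.nodes.get(target, {}).get("kind", "gene"))
            else:
                graph.add_node(target, kind="miRNA")
            graph.add_edge(tf, target, etype=etype, r=float(r), p=float(p), q=float(q))
            report["n_tf_edges_kept"] += 1
    return graph, report


@dataclass(frozen=True)
class MixedCircuit:
    circuit_type: str      # "TF_driven" or "miRNA_driven"
    tf: str
    mirna: str
    gene: str
    combined_p: float
    edge_p: tuple[float, float, float]


def _edge(network: nx.DiGraph, u, v, etype):
    data = network.get_edge_data(u, v)
    if data is not None and data.get("etype") == etype:
        return data
    return None


def enumerate_circuits(network: nx.DiGraph) -> list[MixedCircuit]:
    """Exhaustively enumerate both triangular feed-forward circuit types.

    TF-driven: TF->miRNA, TF->gene, miRNA-|gene.  miRNA-driven: miRNA-|TF,
    miRNA-|gene, TF->gene.  Output is deduplicated on (type, TF, miRNA, gene)
    and sorted by Fisher-combined p ascending.
    """
    kinds = nx.get_node_attributes(network, "kind")
    tfs = [node for node, k in kinds.items() if k == "TF"]
    circuits: dict[tuple, MixedCircuit] = {}

    def add(ctype, tf, mirna, gene, edges):
        key = (ctype, tf, mirna, gene)
        if key in circuits:
            return
        ps = tuple(float(e.get("p", 1.0)) for e in edges)
        safe = [min(max(p, 1e-300), 1.0) for p in ps]
        _, combined = stats.combine_pvalues(safe, method="fisher")
        circuits[key] = MixedCircuit(ctype, tf, mirna, gene, float(combined), ps)

    for tf in tfs:
        succ = list(network.successors(tf))
        mirna_edges = [(v, d) for v in succ
                       if (d := _edge(network, tf, v, TF_MIRNA)) is not None]
        gene_edges = [(v, d) for v in succ
                      if (d := _edge(network, tf, v, TF_GENE)) is not None
                      and kinds.get(v) == "gene"]
        # TF-driven: the TF regulates both the miRNA and the miRNA's target
        for mirna, e_tm in mirna_edges:
            for gene in network.successors(mirna):
                e_mg = _edge(network, mirna, gene, REPRESSION)
                if e_mg is None or kinds.get(gene) != "gene":
                    continue
                e_tg = _edge(network, tf, gene, TF_GENE)
                if e_tg is not None:
                    add("TF_driven", tf, mirna, gene, (e_tm, e_tg, e_mg))
        # miRNA-driven: a miRNA represses both the TF and one of its targets
        for mirna in network.predecessors(tf):
            e_mt = _edge(network, mirna, tf, REPRESSION)
            if e_mt is None or kinds.get(mirna) != "miRNA":
                continue
            for gene, e_tg in gene_edges:
                e_mg = _edge(network, mirna, gene, REPRESSION)
                if e_mg is not None:
                    add("miRNA_driven", tf, mirna, gene, (e_mt, e_mg, e_tg))

    return sorted(
        circuits.values(), key=lambda c: (c.combined_p, c.circuit_type, c.tf, c.mirna, c.gene)
    )


def circuits_to_frame(circuits: list[MixedCircuit]) -> pd.DataFrame:
    rows = [
        {
            "circuit_type": c.circuit_type, "tf": c.tf, "mirna": c.mirna,
            "gene": c.gene, "combined_p": c.combined_p,
            "p_edge1": c.edge_p[0], "p_edge2": c.edge_p[1], "p_edge3": c.edge_p[2],
        }
        for c in circuits
    ]
    return pd.DataFrame(
        rows, columns=["circuit_type", "tf", "mirna", "gene", "combined_p",
                       "p_edge1", "p_edge2", "p_edge3"],
    )
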