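"""Protein-sharing network and genome grouping.

The pangenome matrix is exported as a bipartite genome/protein-cluster
network, and genomes are partitioned into groups and singletons by
connected components of a thresholded shared-protein-content similarity:

    sim(i, j) = |clusters shared| / min(|clusters of i|, |clusters of j|)

Min-normalisation (rather than Jaccard) keeps a gene-poor, degenerated
prophage grouped with its intact relatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .orthology import PangenomeMatrix


@dataclass
class GenomeGroup:
    group_id: int
    member_genome_ids: list[str]

    @property
    def is_singleton(self) -> bool:
        return len(self.member_genome_ids) == 1


def build_bipartite_graph(matrix: PangenomeMatrix) -> nx.Graph:
    graph = nx.Graph()
    for g in matrix.genome_ids:
        graph.add_node(g, kind="genome")
    for c in matrix.cluster_ids:
        graph.add_node(f"cluster_{c}", kind="cluster")
    for i, g in enumerate(matrix.genome_ids):
        for j, c in enumerate(matrix.cluster_ids):
            if matrix.presence[i, j]:
                graph.add_edge(g, f"cluster_{c}")
    return graph


def export_bipartite_network(matrix: PangenomeMatrix, graphml_path,
                             edgelist_path=None) -> nx.Graph:
    """Write the bipartite network as GraphML (plus an optional edge TSV)."""
    graph = build_bipartite_graph(matrix)
    nx.write_graphml(graph, graphml_path)
    if edgelist_path is not None:
        with open(edgelist_path, "w") as fh:
            fh.write("genome_id\tcluster_id\n")
            for i, g in enumerate(matrix.genome_ids):
                for j, c in enumerate(matrix.cluster_ids):
                    if matrix.presence[i, j]:
                        fh.write(f"{g}\tcluster_{c}\n")
    return graph


def matrix_from_graph(graph: nx.Graph) -> PangenomeMatrix:
    """Rebuild a pangenome matrix from a bipartite network (round-trip)."""
    import numpy as np

    genomes = sorted(n for n, d in graph.nodes(data=True) if d.get("kind") == "genome")
    clusters = sorted(
        (int(str(n).split("_", 1)[1]) for n, d in graph.nodes(data=True)
         if d.get("kind") == "cluster"))
    presence = np.zeros((len(genomes), len(clusters)), dtype=bool)
    cindex = {c: j for j, c in enumerate(clusters)}
    for i, g in enumerate(genomes):
        for nb in graph.neighbors(g):
            presence[i, cindex[int(str(nb).split("_", 1)[1])]] = True
    return PangenomeMatrix(genome_ids=genomes, cluster_ids=clusters,
                           presence=presence)


def genome_similarity(matrix: PangenomeMatrix, i: str, j: str) -> float:
    """Shared clusters over the smaller cluster repertoire; 0 if either is empty."""
    if i == j:
        raise ValueError("similarity is defined for distinct genomes")
    for g in (i, j):
        if g not in matrix.genome_ids:
            raise ValueError(f"unknown genome {g!r}")
    ci = matrix.clusters_of(i)
    cj = matrix.clusters_of(j)
    if not ci or not cj:
        return 0.0
    return len(ci & cj) / min(len(ci), len(cj))


def make_groups(matrix: PangenomeMatrix, threshold: float = 0.5) -> list[GenomeGroup]:
    """Connected components of the similarity graph at ``threshold``.

    Groups are ordered by size descending, then by smallest member id;
    singletons are size-1 components.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    graph = nx.Graph()
    graph.add_nodes_from(matrix.genome_ids)
    ids = sorted(matrix.genome_ids)
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            if genome_similarity(matrix, ids[a_idx], ids[b_idx]) >= threshold:
                graph.add_edge(ids[a_idx], ids[b_idx])
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return [GenomeGroup(group_id=i, member_genome_ids=c)
            for i, c in enumerate(components, start=1)]


def write_groups_tsv(groups: list[GenomeGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tgenome_id\tis_singleton\n")
        for grp in groups:
            for g in grp.member_genome_ids:
                fh.write(f"{grp.group_id}\t{g}\t{int(grp.is_singleton)}\n")
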