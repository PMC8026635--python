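"""Ortholog clustering across selected genomes.

All-vs-all local protein alignment (E-value and query-coverage thresholded),
bidirectional best hits, and COGtriangles: clusters are seeded by triangles
of pairwise-BBH proteins from three distinct genomes and merged when they
share a BBH edge.  Proteins in no triangle become singleton clusters, which
still participate in the pangenome presence/absence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from . import align
from .align import ScoringScheme
from .records import ProteinRecord
from .screen import ScreenConfig


@dataclass
class HomologyHit:
    query_id: str
    query_genome: str
    target_id: str
    target_genome: str
    bit_score: float
    evalue: float
    query_coverage: float
    identity: float


@dataclass
class OrthologCluster:
    cluster_id: int
    members: list[tuple[str, str]]  # (genome_id, protein_id)


@dataclass
class PangenomeMatrix:
    genome_ids: list[str]
    cluster_ids: list[int]
    presence: np.ndarray  # bool, genomes x clusters

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence.astype(int), index=self.genome_ids,
                            columns=[f"cluster_{c}" for c in self.cluster_ids])

    def clusters_of(self, genome_id: str) -> set[int]:
        i = self.genome_ids.index(genome_id)
        return {c for c, present in zip(self.cluster_ids, self.presence[i]) if present}


def _kmer_set(seq: str, k: int = 4) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def all_vs_all(proteomes: dict[str, list[ProteinRecord]],
               cfg: Optional[ScreenConfig] = None,
               scheme: Optional[ScoringScheme] = None,
               prefilter: bool = True) -> list[HomologyHit]:
    """Local alignment of every inter-genome protein pair.

    Each unordered pair is aligned once; both orderings are emitted as hits
    (coverage is direction-specific) and hits failing
    ``evalue <= ortho_evalue`` or ``query_coverage >= ortho_query_coverage``
    are discarded.  The optional k-mer prefilter skips pairs sharing fewer
    than ``max(3, 2% of the shorter length)`` 4-mers; it cannot reject
    homologs at the divergences the thresholds accept.
    """
    if len(proteomes) < 2:
        raise ValueError("all-vs-all needs at least 2 genomes")
    cfg = cfg or ScreenConfig()
    scheme = scheme or align.protein_scheme()

    entries = [(g, p) for g in sorted(proteomes) for p in proteomes[g]]
    kmers = {p.id: _kmer_set(p.sequence) for _, p in entries} if prefilter else {}

    hits: list[HomologyHit] = []
    for (ga, pa), (gb, pb) in combinations(entries, 2):
        if ga == gb:
            continue
        if prefilter:
            need = max(3, int(0.02 * min(len(pa.sequence), len(pb.sequence))))
            if len(kmers[pa.id] & kmers[pb.id]) < need:
                continue
        aln = align.align_local(pa.sequence, pb.sequence, scheme,
                                query_id=pa.id, target_id=pb.id)
        if aln.evalue > cfg.ortho_evalue:
            continue
        for (q, qg, t, tg, qcov) in (
                (pa, ga, pb, gb, aln.query_coverage),
                (pb, gb, pa, ga, aln.target_coverage)):
            if qcov < cfg.ortho_query_coverage:
                continue
            hits.append(HomologyHit(
                query_id=q.id, query_genome=qg, target_id=t.id,
                target_genome=tg, bit_score=aln.bit_score, evalue=aln.evalue,
                query_coverage=qcov, identity=aln.identity))
    hits.sort(key=lambda h: (h.query_id, h.target_id))
    return hits


def _better(h: HomologyHit, cur: Optional[HomologyHit]) -> bool:
    """Higher bit score wins; ties by higher coverage, then smaller id."""
    if cur is None:
        return True
    if h.bit_score != cur.bit_score:
        return h.bit_score > cur.bit_score
    if h.query_coverage != cur.query_coverage:
        return h.query_coverage > cur.query_coverage
    return h.target_id < cur.target_id


def bbh_pairs(hits: list[HomologyHit]) -> list[tuple[str, str]]:
    """Bidirectional best hits: each is the other's best hit in its genome."""
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        key = (h.query_id, h.target_genome)
        if _better(h, best.get(key)):
            best[key] = h
    pairs = set()
    for (q, _), h in best.items():
        back = best.get((h.target_id, h.query_genome))
        if back is not None and back.target_id == q:
            pairs.add(tuple(sorted((q, h.target_id))))
    return sorted(pairs)


def cog_triangles(bbhs: list[tuple[str, str]],
                  all_proteins: list[tuple[str, str]]) -> list[OrthologCluster]:
    """COGtriangles clustering.

    ``all_proteins`` is a list of (genome_id, protein_id).  A triangle is
    three proteins from three distinct genomes that are pairwise BBH;
    triangles sharing a BBH edge merge into one cluster.  Remaining proteins
    become singletons.  Cluster ids follow the order of the smallest member
    protein id.
    """
    genome_of = {pid: gid for gid, pid in all_proteins}
    adj: dict[str, set[str]] = {}
    for a, b in bbhs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    # enumerate each triangle once: edge (a, b) with a < b, third vertex c > b
    triangles: list[tuple[str, str, str]] = []
    for a, b in bbhs:
        a, b = min(a, b), max(a, b)
        for c in sorted(adj.get(a, ()) & adj.get(b, ())):
            if c <= b:
                continue
            if len({genome_of[a], genome_of[b], genome_of[c]}) == 3:
                triangles.append((a, b, c))

    # union-find over triangles keyed by shared edges
    parent: dict[int, int] = {i: i for i in range(len(triangles))}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    edge_to_tris: dict[tuple[str, str], list[int]] = {}
    for idx, tri in enumerate(triangles):
        for e in combinations(tri, 2):
            edge_to_tris.setdefault(e, []).append(idx)
    for tris in edge_to_tris.values():
        for other in tris[1:]:
            union(tris[0], other)

    groups: dict[int, set[str]] = {}
    for idx, tri in enumerate(triangles):
        groups.setdefault(find(idx), set()).update(tri)

    clustered = set().union(*groups.values()) if groups else set()
    member_sets = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
    for gid, pid in sorted(all_proteins, key=lambda gp: gp[1]):
        if pid not in clustered:
            member_sets.append([pid])
    member_sets.sort(key=lambda g: g[0])

    clusters = []
    for cid, mset in enumerate(member_sets, start=1):
        clusters.append(OrthologCluster(
            cluster_id=cid,
            members=sorted((genome_of[p], p) for p in mset)))
    return clusters


def build_pangenome(clusters: list[OrthologCluster],
                    genome_ids: list[str]) -> PangenomeMatrix:
    """Boolean genome x cluster presence matrix."""
    cluster_ids = [c.cluster_id for c in clusters]
    index = {g: i for i, g in enumerate(genome_ids)}
    presence = np.zeros((len(genome_ids), len(clusters)), dtype=bool)
    for j, cl in enumerate(clusters):
        for genome_id, _ in cl.members:
            if genome_id in index:
                presence[index[genome_id], j] = True
    return PangenomeMatrix(genome_ids=list(genome_ids),
                           cluster_ids=cluster_ids, presence=presence)


def write_clusters_tsv(clusters: list[OrthologCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tgenome_id\tprotein_id\n")
        for cl in clusters:
            for genome_id, protein_id in cl.members:
                fh.write(f"{cl.cluster_id}\t{genome_id}\t{protein_id}\n")


def write_pangenome_tsv(matrix: PangenomeMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="genome_id")
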