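"""All-vs-all homology, BBH, COGtriangles and the pangenome matrix."""

import numpy as np
import pytest

from plasphage import orthology
from plasphage.orthology import (HomologyHit, all_vs_all, bbh_pairs,
                                 build_pangenome, cog_triangles)
from plasphage.records import ProteinRecord
from plasphage.screen import ScreenConfig

from oracles import bbh_oracle, cog_partition_oracle


def _protein(gid, pid, seq):
    return ProteinRecord(id=pid, genome_id=gid, start=1, end=3 * len(seq) + 3,
                         strand="+", sequence=seq)


def _hit(q, qg, t, tg, bits, cov=0.9):
    return HomologyHit(query_id=q, query_genome=qg, target_id=t,
                       target_genome=tg, bit_score=bits, evalue=1e-20,
                       query_coverage=cov, identity=0.9)


def _random_instance(rng, n_genomes=None, n_proteins=None):
    """Random synthetic hit lists over <=30 proteins / <=6 genomes."""
    n_genomes = n_genomes or int(rng.integers(3, 7))
    n_proteins = n_proteins or int(rng.integers(n_genomes, 31))
    proteins = []
    for i in range(n_proteins):
        proteins.append((f"g{i % n_genomes}", f"p{i:02d}"))
    hits = []
    for i in range(n_proteins):
        for j in range(n_proteins):
            gi, pi = proteins[i]
            gj, pj = proteins[j]
            if i == j or gi == gj:
                continue
            if rng.random() < 0.35:
                hits.append(_hit(pi, gi, pj, gj,
                                 bits=float(rng.integers(20, 200)),
                                 cov=float(rng.uniform(0.75, 1.0))))
    return proteins, hits


class TestAllVsAll:
    def test_coverage_threshold_discards_partial_hits(self):
        rng = np.random.default_rng(1)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        core = "".join(rng.choice(list(aa), size=60))
        long = core + "".join(rng.choice(list(aa), size=40))  # 60% covered
        proteomes = {"g1": [_protein("g1", "a", core)],
                     "g2": [_protein("g2", "b", long)]}
        hits = all_vs_all(proteomes, ScreenConfig())
        # the short protein is fully covered; the long one is not
        assert {h.query_id for h in hits} == {"a"}

    def test_identical_proteins_reciprocal(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        proteomes = {"g1": [_protein("g1", "a", seq)],
                     "g2": [_protein("g2", "b", seq)]}
        hits = all_vs_all(proteomes, ScreenConfig())
        assert {(h.query_id, h.target_id) for h in hits} == {("a", "b"), ("b", "a")}
        assert all(h.identity == 1.0 for h in hits)

    def test_needs_two_genomes(self):
        with pytest.raises(ValueError):
            all_vs_all({"g1": []}, ScreenConfig())

    def test_prefilter_neutral_on_homologous_families(self):
        rng = np.random.default_rng(3)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        anc = "".join(rng.choice(aa, size=90))
        proteomes = {}
        for g in range(3):
            seq = "".join(c if rng.random() > 0.2 else str(rng.choice(aa))
                          for c in anc)
            proteomes[f"g{g}"] = [_protein(f"g{g}", f"p{g}", seq)]
        with_f = all_vs_all(proteomes, ScreenConfig(), prefilter=True)
        without = all_vs_all(proteomes, ScreenConfig(), prefilter=False)
        key = lambda h: (h.query_id, h.target_id)
        assert sorted(map(key, with_f)) == sorted(map(key, without))


class TestBBH:
    def test_single_pair_is_bbh(self):
        hits = [_hit("a", "g1", "b", "g2", 100), _hit("b", "g2", "a", "g1", 100)]
        assert bbh_pairs(hits) == [("a", "b")]

    def test_asymmetric_best_is_not_bbh(self):
        hits = [
            _hit("p", "g1", "q", "g2", 100), _hit("q", "g2", "p", "g1", 50),
            _hit("q", "g2", "r", "g1", 120), _hit("r", "g1", "q", "g2", 120),
        ]
        assert ("p", "q") not in bbh_pairs(hits)
        assert ("q", "r") in bbh_pairs(hits)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        _, hits = _random_instance(rng, n_genomes=3)
        assert set(bbh_pairs(hits)) == bbh_oracle(hits)


class TestCogTriangles:
    def test_single_triangle(self):
        proteins = [("g1", "a"), ("g2", "b"), ("g3", "c")]
        bbhs = [("a", "b"), ("b", "c"), ("a", "c")]
        clusters = cog_triangles(bbhs, proteins)
        assert [sorted(p for _, p in c.members) for c in clusters] == \
            [["a", "b", "c"]]

    def test_triangles_sharing_edge_merge(self):
        proteins = [("g1", "a"), ("g2", "b"), ("g3", "c"), ("g4", "d")]
        bbhs = [("a", "b"), ("b", "c"), ("a", "c"), ("a", "d"), ("b", "d")]
        clusters = cog_triangles(bbhs, proteins)
        assert [sorted(p for _, p in c.members) for c in clusters] == \
            [["a", "b", "c", "d"]]

    def test_bbh_pair_without_triangle_stays_singleton(self):
        proteins = [("g1", "a"), ("g2", "b"), ("g3", "c")]
        clusters = cog_triangles([("a", "b")], proteins)
        assert sorted(sorted(p for _, p in c.members) for c in clusters) == \
            [["a"], ["b"], ["c"]]

    @pytest.mark.parametrize("seed", range(25))
    def test_partition_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        proteins, hits = _random_instance(rng)
        bbhs = bbh_pairs(hits)
        clusters = cog_triangles(bbhs, proteins)
        got = {frozenset(p for _, p in c.members) for c in clusters}
        want = cog_partition_oracle(bbhs, proteins)
        assert got == want
        # exact partition: each protein in exactly one cluster
        flat = [p for c in clusters for _, p in c.members]
        assert sorted(flat) == sorted(p for _, p in proteins)


class TestPangenome:
    def test_matrix_counts(self):
        proteins = [("g1", "a"), ("g2", "b"), ("g3", "c"), ("g1", "d")]
        bbhs = [("a", "b"), ("b", "c"), ("a", "c")]
        clusters = cog_triangles(bbhs, proteins)
        matrix = build_pangenome(clusters, ["g1", "g2", "g3", "g4"])
        # row sums count distinct clusters per genome
        assert matrix.presence.sum(axis=1).tolist() == [2, 1, 1, 0]
        # true cells recount from the cluster lists
        want = sum(len({g for g, _ in c.members}) for c in clusters)
        assert matrix.presence.sum() == want

    def test_genome_without_proteins_all_false(self):
        clusters = cog_triangles([], [("g1", "a")])
        matrix = build_pangenome(clusters, ["g1", "gX"])
        assert matrix.presence[1].sum() == 0


def test_planted_families_recovered_as_single_clusters(default_run):
    """Each marker family spans exactly the selected genomes carrying it."""
    res = default_run
    ds = res.dataset
    marker_of = {p.id: p.marker for gid in res.screen_result.selected
                 for p in ds.proteins[gid]}
    selected = set(res.screen_result.selected)
    # terminase: every selected genome carries one; intact copies must sit in
    # one cluster spanning every genome with an intact (non-truncated) copy
    truth = ds.truth.set_index("genome_id")
    for marker in ("major_capsid_protein", "terminase"):
        carriers = {g for g in selected if truth.loc[g, f"{marker}_present"]
                    and truth.loc[g, f"{marker}_intact"]}
        spanning = [c for c in res.ortholog_clusters
                    if {marker_of.get(p) for _, p in c.members} == {marker}
                    and len(c.members) >= 3]
        big = max(spanning, key=lambda c: len(c.members))
        assert {g for g, _ in big.members} >= carriers
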