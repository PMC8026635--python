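"""Synthetic data generator: determinism, planted structure, corruption."""

import numpy as np
import pytest

from plasphage import io as pio
from plasphage import synth
from plasphage.align import protein_scheme
from plasphage.classify import ACTIVE, DEGENERATED, NON_PHAGE, VIRULENT

from oracles import expected_family_identity


@pytest.fixture(scope="module")
def spec():
    return synth.GeneratorSpec(seed=1)


class TestFamilies:
    def test_same_seed_identical(self, spec):
        f1 = synth.make_marker_families(spec)
        f2 = synth.make_marker_families(spec)
        assert f1 == f2

    def test_mean_pairwise_identity_matches_model(self, spec):
        """Gapless column identity of family members matches the closed-form
        expectation for independent substitution from a shared ancestor."""
        fams = synth.make_marker_families(spec)
        want = expected_family_identity(spec.family_divergence)
        for name in ("terminase", "tape_measure_protein", "adapter"):
            members = fams[name]
            idents = []
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    a, b = members[i], members[j]
                    idents.append(np.mean([x == y for x, y in zip(a, b)]))
            assert np.mean(idents) == pytest.approx(want, abs=0.05)

    def test_serine_recombinase_members_below_class_boundary(self, spec):
        fams = synth.make_marker_families(spec)
        assert all(len(m) <= 250 for m in fams["serine_recombinase"])

    def test_member_count(self, spec):
        fams = synth.make_marker_families(spec)
        assert all(len(m) >= 12 for m in fams.values())


class TestGenerate:
    def test_determinism_byte_identical(self, spec, tmp_path):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        synth.generate(spec).write(d1)
        synth.generate(spec).write(d2)
        for f1 in sorted(d1.rglob("*")):
            if f1.is_file():
                f2 = d2 / f1.relative_to(d1)
                assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_state_counts_match_spec(self, default_dataset):
        truth = default_dataset.truth
        base = truth[truth.is_duplicate == 0]
        counts = base.planted_state.value_counts().to_dict()
        assert counts == default_dataset.spec.state_mix

    def test_genome_lengths_inside_screen_window(self, default_dataset):
        lo, hi = default_dataset.spec.genome_length_range
        for g in default_dataset.genomes:
            assert lo <= g.length_bp <= max(hi, lo)
            assert 15_000 <= g.length_bp <= 500_000

    def test_gff_translations_equal_protein_fasta(self, default_dataset, tmp_path):
        default_dataset.write(tmp_path)
        genomes = {g.id: g.sequence for g in
                   pio.read_genomes_fasta(tmp_path / "genomes.fna")}
        from_gff = pio.read_gff3(tmp_path / "annotations.gff3", genomes)
        from_faa = pio.read_proteins_fasta(tmp_path / "proteins.faa")
        assert len(from_gff) == len(from_faa)
        faa_by_id = {p.id: p for p in from_faa}
        for p in from_gff:
            assert faa_by_id[p.id].sequence == p.sequence

    def test_marker_architecture_by_state(self, default_dataset):
        truth = default_dataset.truth
        base = truth[truth.is_duplicate == 0].set_index("genome_id")
        for gid, row in base.iterrows():
            if row.planted_state in (ACTIVE, DEGENERATED, VIRULENT):
                assert row.terminase_present and row.major_capsid_protein_present
            if row.planted_state == VIRULENT:
                assert not (row.parA_present or row.parM_present or
                            row.tubZ_present)
                assert not (row.tyrosine_recombinase_present or
                            row.serine_recombinase_present)
            if row.planted_state == NON_PHAGE:
                assert not row.terminase_present
                assert not row.major_capsid_protein_present

    def test_adapter_immediately_downstream_of_motor(self, default_dataset):
        base = default_dataset.truth[default_dataset.truth.is_duplicate == 0]
        for _, row in base.iterrows():
            if not row.adapter_present:
                continue
            prots = default_dataset.proteins[row.genome_id]
            by_start = sorted(prots, key=lambda p: p.start)
            idx = {p.id: i for i, p in enumerate(by_start)}
            motor = next(p for p in prots if p.marker in ("parA", "parM", "tubZ"))
            adapter = next(p for p in prots if p.marker == "adapter")
            assert idx[adapter.id] == idx[motor.id] + 1
            assert adapter.strand == motor.strand

    def test_invalid_state_mix_rejected(self):
        with pytest.raises(ValueError):
            synth.GeneratorSpec(n_genomes=10, state_mix={ACTIVE: 5})


class TestCorruptGene:
    def _active_genome(self, ds):
        base = ds.truth[(ds.truth.is_duplicate == 0) &
                        (ds.truth.planted_state == ACTIVE)]
        return base.genome_id.iloc[0]

    def test_split_fragment_lengths_sum(self, default_dataset):
        gid = self._active_genome(default_dataset)
        original = next(p for p in default_dataset.proteins[gid]
                        if p.marker == "tape_measure_protein")
        ds = synth.corrupt_gene(default_dataset, gid, "tape_measure_protein",
                                "split", seed=3)
        frags = [p for p in ds.proteins[gid]
                 if p.marker == "tape_measure_protein"]
        assert len(frags) == 2
        total = sum(p.length_aa for p in frags)
        assert abs(total - original.length_aa) <= 1
        # genome sequence still translates to the fragment proteins
        genome = next(g for g in ds.genomes if g.id == gid)
        for p in frags:
            assert pio.translate_cds(genome.sequence, p.start, p.end,
                                     p.strand) == p.sequence

    def test_truth_flips_to_degenerated(self, default_dataset):
        gid = self._active_genome(default_dataset)
        ds = synth.corrupt_gene(default_dataset, gid, "tape_measure_protein",
                                "split", seed=3)
        row = ds.truth.set_index("genome_id").loc[gid]
        assert row.planted_state == DEGENERATED
        assert row.tape_measure_protein_intact == 0

    def test_truncate_removes_three_prime_third(self, default_dataset):
        gid = self._active_genome(default_dataset)
        original = next(p for p in default_dataset.proteins[gid]
                        if p.marker == "terminase")
        ds = synth.corrupt_gene(default_dataset, gid, "terminase",
                                "truncate", seed=3)
        trunc = next(p for p in ds.proteins[gid] if p.marker == "terminase")
        assert trunc.length_aa == int(original.length_aa * 0.70)
        assert trunc.sequence == original.sequence[:trunc.length_aa]

    def test_absent_marker_rejected(self, default_dataset):
        base = default_dataset.truth[(default_dataset.truth.is_duplicate == 0) &
                                     (default_dataset.truth.planted_state ==
                                      NON_PHAGE)]
        with pytest.raises(ValueError):
            synth.corrupt_gene(default_dataset, base.genome_id.iloc[0],
                               "terminase", "split", seed=0)
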