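"""Synthetic plasmid datasets with planted prophage truth.

Generates desk-scale collections of plasmid genomes that emulate the real
survey inputs: circular plasmids of 15-120 kbp carrying ordered gene
cassettes drawn from diverged marker families (terminase, major capsid
protein, tape measure protein, recombinases, ParA/ParM/TubZ partitioning
motors with their adapters, tail sheath, cargo genes), with planted
duplicates, near-duplicates, split/truncated genes, group structure, and a
machine-readable truth table.

The stated world: 40 genomes (12 active / 6 degenerated / 2 virulent-like /
20 non-phage), 3 planted groups of 5, family divergence 0.2, 3 duplicate
pairs (one exact, the rest at 99.5% identity) and 2 decoy pairs at 98%
identity that deduplication must keep apart.  All randomness flows from a
single seed; outputs are byte-identical across reruns.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as pio
from .classify import ACTIVE, DEGENERATED, MYO, NON_PHAGE, SIPHO, UNDETERMINED, VIRULENT
from .hmm import AA, ALL_MARKERS
from .records import PlasmidRecord, ProteinRecord
from .screen import CODON_TABLE_11, STOP_CODONS, revcomp

#: typical lengths (aa) of the marker family ancestors
FAMILY_LENGTHS = {
    "terminase": 420,
    "major_capsid_protein": 350,
    "tape_measure_protein": 1200,
    "tyrosine_recombinase": 300,
    "parA": 260,
    "parM": 330,
    "tubZ": 420,
    "adapter": 90,
    "sheath": 480,
    "serine_recombinase": 195,
}

_CODONS_FOR = {}
for codon, aa in CODON_TABLE_11.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()


@dataclass
class GeneratorSpec:
    seed: int = 0
    n_genomes: int = 40
    state_mix: dict[str, int] = field(default_factory=lambda: {
        ACTIVE: 12, DEGENERATED: 6, VIRULENT: 2, NON_PHAGE: 20})
    n_groups: int = 3
    group_size: int = 5
    family_divergence: float = 0.2
    duplicate_pairs: int = 3
    near_duplicate_identity: float = 0.995
    decoy_pairs: int = 2
    decoy_identity: float = 0.98
    genome_length_range: tuple[int, int] = (15_000, 120_000)
    intergenic_mean: int = 120
    members_per_family: int = 12
    cargo_per_group: int = 10
    cargo_per_singleton: int = 10
    cargo_per_nonphage: int = 8
    sheath_in_last_group: bool = True
    intra_genome_paralogs: bool = False

    def __post_init__(self) -> None:
        if sum(self.state_mix.values()) != self.n_genomes:
            raise ValueError("state_mix counts must sum to n_genomes")
        if not (0.0 <= self.family_divergence <= 0.6):
            raise ValueError("family_divergence must be in [0, 0.6]")
        grouped = self.n_groups * self.group_size
        phage = self.state_mix.get(ACTIVE, 0) + self.state_mix.get(DEGENERATED, 0)
        if grouped > phage:
            raise ValueError("groups cannot hold more genomes than active+degenerated")
        if self.group_size and self.group_size < 3:
            raise ValueError("planted groups need >= 3 members for ortholog triangles")


@dataclass
class SyntheticDataset:
    spec: GeneratorSpec
    genomes: list[PlasmidRecord]
    proteins: dict[str, list[ProteinRecord]]
    truth: pd.DataFrame
    families: dict[str, list[str]]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_genomes_fasta(self.genomes, outdir / "genomes.fna")
        all_proteins = [p for g in self.genomes for p in self.proteins[g.id]]
        pio.write_proteins_fasta(all_proteins, outdir / "proteins.faa")
        pio.write_gff3(all_proteins, outdir / "annotations.gff3")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        famdir = outdir / "families"
        famdir.mkdir(exist_ok=True)
        for name in ALL_MARKERS:
            entries = [(f"{name}_m{i + 1}", seq)
                       for i, seq in enumerate(self.families[name])]
            pio.write_fasta(entries, famdir / f"{name}.faa")


# ---------------------------------------------------------------------------
# Protein-level helpers
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _diverge(rng: np.random.Generator, ancestor: str, rate: float) -> str:
    """i.i.d. substitutions at ``rate``; replacements never equal the original."""
    out = []
    for ch in ancestor:
        if rng.random() < rate:
            alt = AA[int(rng.integers(20))]
            while alt == ch:
                alt = AA[int(rng.integers(20))]
            out.append(alt)
        else:
            out.append(ch)
    return "".join(out)


def reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """Uniform synonymous-codon choice under translation table 11."""
    return "".join(_CODONS_FOR[aa][int(rng.integers(len(_CODONS_FOR[aa])))]
                   for aa in protein)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_marker_families(spec: GeneratorSpec) -> dict[str, list[str]]:
    """Diverged member sets for every marker family (deterministic per seed)."""
    _, families = _ancestors_and_families(spec)
    return families


def _ancestors_and_families(spec: GeneratorSpec):
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    ancestors: dict[str, str] = {}
    families: dict[str, list[str]] = {}
    for name in sorted(FAMILY_LENGTHS):
        ancestors[name] = _random_protein(rng, FAMILY_LENGTHS[name])
        families[name] = [_diverge(rng, ancestors[name], spec.family_divergence)
                          for _ in range(max(spec.members_per_family, 12))]
    return ancestors, families


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    marker: str          # family label, or "cargo"/"" for unlabelled genes
    protein: str
    strand: str = "+"
    split_after: Optional[int] = None   # codon index of a planted in-frame stop
    intact: bool = True


def _genome_plan(spec: GeneratorSpec):
    """Assign states, groups, motors and recombinases to genome slots."""
    ids_by_state: dict[str, list[str]] = {s: [] for s in
                                          (ACTIVE, DEGENERATED, VIRULENT, NON_PHAGE)}
    counter = 1
    for state in (ACTIVE, DEGENERATED, VIRULENT, NON_PHAGE):
        for _ in range(spec.state_mix.get(state, 0)):
            ids_by_state[state].append(f"PL{counter:03d}")
            counter += 1

    group_of: dict[str, int] = {}
    actives = list(ids_by_state[ACTIVE])
    degens = list(ids_by_state[DEGENERATED])
    for g in range(1, spec.n_groups + 1):
        members: list[str] = []
        while len(members) < spec.group_size:
            # favour actives but give every group some degenerated members
            take_degen = (len(members) >= spec.group_size - 2) and degens
            pool = degens if take_degen else (actives or degens)
            members.append(pool.pop(0))
        for m in members:
            group_of[m] = g
    return ids_by_state, group_of


MOTOR_BY_GROUP = ["parA", "parM", "tubZ"]
RECOMBINASE_BY_GROUP = ["tyrosine_recombinase", "serine_recombinase",
                        "tyrosine_recombinase"]


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Build the full dataset: genomes, proteomes, truth table, families."""
    ancestors, families = _ancestors_and_families(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    ids_by_state, group_of = _genome_plan(spec)

    # per-group cargo ancestors
    cargo_groups: dict[int, list[str]] = {}
    for g in range(1, spec.n_groups + 1):
        cargo_groups[g] = [
            _random_protein(rng, int(rng.integers(150, 601)))
            for _ in range(spec.cargo_per_group)]

    d = spec.family_divergence

    def marker_gene(name: str, strand: str = "+") -> _Gene:
        return _Gene(marker=name, strand=strand,
                     protein=_diverge(rng, ancestors[name], d))

    def cargo_genes(n: int, group: Optional[int]) -> list[_Gene]:
        genes = []
        for i in range(n):
            if group is not None:
                prot = _diverge(rng, cargo_groups[group][i], d)
            else:
                prot = _random_protein(rng, int(rng.integers(150, 601)))
            strand = "+" if i % 2 == 0 else "-"
            genes.append(_Gene(marker="cargo", protein=prot, strand=strand))
        return genes

    genomes: list[PlasmidRecord] = []
    proteins: dict[str, list[ProteinRecord]] = {}
    truth_rows: list[dict] = []
    singleton_cycle = 0
    degen_mode: dict[str, str] = {}
    for i, gid in enumerate(ids_by_state[DEGENERATED]):
        degen_mode[gid] = "split_tmp" if i % 2 == 0 else "truncate_terminase"

    for state in (ACTIVE, DEGENERATED, VIRULENT, NON_PHAGE):
        for gid in ids_by_state[state]:
            group = group_of.get(gid)
            genes: list[_Gene] = []
            if state in (ACTIVE, DEGENERATED, VIRULENT):
                genes.append(marker_gene("terminase"))
                genes.append(marker_gene("major_capsid_protein"))
                genes.append(marker_gene("tape_measure_protein"))
            if state in (ACTIVE, DEGENERATED) or state == NON_PHAGE:
                if group is not None:
                    motor = MOTOR_BY_GROUP[(group - 1) % 3]
                    recomb = RECOMBINASE_BY_GROUP[(group - 1) % 3]
                else:
                    motor = MOTOR_BY_GROUP[singleton_cycle % 3]
                    recomb = RECOMBINASE_BY_GROUP[singleton_cycle % 3]
                    singleton_cycle += 1
                genes.append(marker_gene(motor))
                genes.append(marker_gene("adapter"))  # immediately downstream
                genes.append(marker_gene(recomb))
            has_sheath = (state in (ACTIVE, DEGENERATED) and group == spec.n_groups
                          and spec.sheath_in_last_group and spec.n_groups > 0)
            if has_sheath:
                genes.append(marker_gene("sheath"))
            if state in (ACTIVE, DEGENERATED, VIRULENT):
                n_cargo = spec.cargo_per_group if group else spec.cargo_per_singleton
                genes.extend(cargo_genes(n_cargo, group))
            else:
                genes.extend(cargo_genes(spec.cargo_per_nonphage, None))
            if spec.intra_genome_paralogs and state == ACTIVE:
                genes.append(_Gene(marker="cargo", protein=genes[-1].protein,
                                   strand="+"))

            if state == DEGENERATED:
                _degrade(genes, degen_mode[gid], rng)

            genome, prots = _assemble(gid, genes, spec, rng)
            genomes.append(genome)
            proteins[gid] = prots
            truth_rows.append(_truth_row(gid, state, group, genes, prots,
                                         has_sheath))

    _plant_decoys(spec, rng, genomes, proteins, truth_rows, ids_by_state)
    _plant_duplicates(spec, rng, genomes, proteins, truth_rows, ids_by_state)

    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(spec=spec, genomes=genomes, proteins=proteins,
                            truth=truth, families=families)


def _degrade(genes: list[_Gene], mode: str, rng: np.random.Generator) -> None:
    if mode == "split_tmp":
        for g in genes:
            if g.marker == "tape_measure_protein":
                frac = 0.4 + 0.2 * rng.random()
                g.split_after = int(len(g.protein) * frac)
                g.intact = False
                return
    else:  # truncate_terminase
        for g in genes:
            if g.marker == "terminase":
                keep = int(len(g.protein) * 0.70)
                g.protein = g.protein[:keep]
                g.intact = False
                return


def _assemble(gid: str, genes: list[_Gene], spec: GeneratorSpec,
              rng: np.random.Generator):
    """Lay genes on the genome with intergenic spacers and random padding."""
    target = int(rng.integers(spec.genome_length_range[0],
                              spec.genome_length_range[1] + 1))
    parts: list[str] = []
    pos = 0
    prots: list[ProteinRecord] = []
    pidx = 0

    def add_cds(protein: str, strand: str, marker: str,
                include_stop: bool = True) -> None:
        nonlocal pos, pidx
        nt = reverse_translate(rng, protein) + ("TAA" if include_stop else "")
        if strand == "-":
            nt = revcomp(nt)
        start = pos + 1
        end = pos + len(nt)
        pidx += 1
        prots.append(ProteinRecord(id=f"{gid}_p{pidx:03d}", genome_id=gid,
                                   start=start, end=end, strand=strand,
                                   sequence=protein, marker=marker))
        parts.append(nt)
        pos = end

    for gene in genes:
        spacer = max(20, int(rng.poisson(spec.intergenic_mean)))
        parts.append(_random_dna(rng, spacer))
        pos += spacer
        if gene.split_after is not None:
            c = gene.split_after
            frag1, frag2 = gene.protein[:c], gene.protein[c + 1:]
            add_cds(frag1, gene.strand, gene.marker)
            add_cds(frag2, gene.strand, gene.marker)
        else:
            add_cds(gene.protein, gene.strand, gene.marker)

    if pos < target:
        parts.append(_random_dna(rng, target - pos))
        pos = target
    sequence = "".join(parts)
    genome = PlasmidRecord(id=gid, sequence=sequence, circular=True)
    for p in prots:  # planted coordinates must translate back to the protein
        assert pio.translate_cds(sequence, p.start, p.end, p.strand) == p.sequence
    return genome, prots


def _truth_row(gid: str, state: str, group: Optional[int], genes: list[_Gene],
               prots: list[ProteinRecord], has_sheath: bool) -> dict:
    if has_sheath:
        morphotype = MYO
    elif any(g.marker == "tape_measure_protein" for g in genes):
        morphotype = SIPHO
    else:
        morphotype = UNDETERMINED
    row = {
        "genome_id": gid,
        "planted_state": state,
        "planted_group_id": group if group is not None else "",
        "duplicate_of": "",
        "mutated_from": "",
        "is_duplicate": 0,
        "planted_morphotype": morphotype,
    }
    by_marker: dict[str, list[ProteinRecord]] = {}
    for p in prots:
        if p.marker and p.marker != "cargo":
            by_marker.setdefault(p.marker, []).append(p)
    gene_intact = {g.marker: g.intact for g in genes if g.marker != "cargo"}
    for name in sorted(FAMILY_LENGTHS):
        recs = by_marker.get(name, [])
        row[f"{name}_present"] = int(bool(recs))
        row[f"{name}_intact"] = int(bool(recs) and gene_intact.get(name, True))
        row[f"{name}_coords"] = ";".join(f"{p.start}-{p.end}" for p in recs)
    return row


# ---------------------------------------------------------------------------
# Duplicates, near-duplicates and decoys
# ---------------------------------------------------------------------------

def _mutate_genome(rng: np.random.Generator, sequence: str,
                   proteins: list[ProteinRecord], identity: float):
    """Point-mutate a genome to an exact identity without breaking any CDS.

    Mutations never touch start/stop codons and never create an in-frame
    stop, so every CDS still translates cleanly; changed proteins are
    re-translated afterwards.
    """
    n = len(sequence)
    n_mut = round((1.0 - identity) * n)
    seq = list(sequence)
    cds_at: dict[int, ProteinRecord] = {}
    forbidden: set[int] = set()
    for p in proteins:
        for off in range(p.start - 1, p.end):
            cds_at[off] = p
        for off in list(range(p.start - 1, p.start + 2)) + \
                list(range(p.end - 3, p.end)):
            forbidden.add(off)

    mutated: set[int] = set()
    attempts = 0
    while len(mutated) < n_mut:
        attempts += 1
        if attempts > 100 * n_mut + 1000:
            raise RuntimeError("could not place all mutations")
        pos = int(rng.integers(n))
        if pos in mutated or pos in forbidden:
            continue
        old = seq[pos]
        new = "ACGT"[int(rng.integers(4))]
        while new == old:
            new = "ACGT"[int(rng.integers(4))]
        p = cds_at.get(pos)
        if p is not None:
            # check the affected codon in gene orientation
            if p.strand == "+":
                codon_start = p.start - 1 + ((pos - (p.start - 1)) // 3) * 3
                codon = seq[codon_start:codon_start + 3]
                codon[pos - codon_start] = new
                codon_str = "".join(codon)
            else:
                rel = (p.end - 1 - pos)  # offset from gene 5' end on '-'
                codon_start = p.end - 1 - (rel // 3) * 3 - 2
                codon = seq[codon_start:codon_start + 3]
                codon[pos - codon_start] = new
                codon_str = revcomp("".join(codon))
            if codon_str in STOP_CODONS:
                continue
        seq[pos] = new
        mutated.add(pos)

    new_seq = "".join(seq)
    new_prots = [replace(p, sequence=pio.translate_cds(new_seq, p.start, p.end,
                                                       p.strand))
                 for p in proteins]
    return new_seq, new_prots


def _copy_truth(truth_rows: list[dict], src: str) -> dict:
    return copy.deepcopy(next(r for r in truth_rows if r["genome_id"] == src))


def _plant_decoys(spec, rng, genomes, proteins, truth_rows, ids_by_state) -> None:
    """Rewrite the last ``decoy_pairs`` non-phage genomes as 98%-identity
    mutants of earlier non-phage genomes (near-threshold dedup pairs)."""
    nonphage = ids_by_state[NON_PHAGE]
    if spec.decoy_pairs == 0 or len(nonphage) < 2 * spec.decoy_pairs:
        return
    by_id = {g.id: g for g in genomes}
    for k in range(spec.decoy_pairs):
        src = nonphage[k]
        dst = nonphage[-(k + 1)]
        new_seq, new_prots = _mutate_genome(rng, by_id[src].sequence,
                                            proteins[src], spec.decoy_identity)
        idx = next(i for i, g in enumerate(genomes) if g.id == dst)
        genomes[idx] = PlasmidRecord(id=dst, sequence=new_seq, circular=True)
        proteins[dst] = [replace(p, id=p.id.replace(src, dst), genome_id=dst)
                         for p in new_prots]
        row = _copy_truth(truth_rows, src)
        row["genome_id"] = dst
        row["mutated_from"] = src
        for i, r in enumerate(truth_rows):
            if r["genome_id"] == dst:
                truth_rows[i] = row
                break


def _plant_duplicates(spec, rng, genomes, proteins, truth_rows, ids_by_state) -> None:
    """Append ``duplicate_pairs`` extra genomes: one exact copy, the rest at
    ``near_duplicate_identity`` (intergenic-safe point substitutions)."""
    sources = []
    for state in (ACTIVE, NON_PHAGE, DEGENERATED, VIRULENT):
        sources.extend(ids_by_state[state])
    by_id = {g.id: g for g in genomes}
    for k in range(spec.duplicate_pairs):
        src = sources[k % len(sources)]
        dup_id = f"{src}x{k + 1}"
        if k == 0:
            new_seq = by_id[src].sequence
            new_prots = [replace(p) for p in proteins[src]]
        else:
            new_seq, new_prots = _mutate_genome(
                rng, by_id[src].sequence, proteins[src],
                spec.near_duplicate_identity)
        genomes.append(PlasmidRecord(id=dup_id, sequence=new_seq, circular=True))
        proteins[dup_id] = [replace(p, id=p.id.replace(src, dup_id),
                                    genome_id=dup_id) for p in new_prots]
        row = _copy_truth(truth_rows, src)
        row["genome_id"] = dup_id
        row["duplicate_of"] = src
        row["is_duplicate"] = 1
        row["planted_group_id"] = ""
        truth_rows.append(row)


# ---------------------------------------------------------------------------
# Post-hoc corruption (perturbation experiments)
# ---------------------------------------------------------------------------

def corrupt_gene(dataset: SyntheticDataset, genome_id: str, marker: str,
                 mode: str, seed: int = 0) -> SyntheticDataset:
    """Split or truncate a planted marker gene and update the truth table.

    ``split`` plants one in-frame stop near the midpoint (the CDS becomes
    two); ``truncate`` removes the 3' 30% of the CDS.  The genome's planted
    state becomes degenerated.
    """
    if mode not in ("split", "truncate"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    rng = np.random.default_rng(seed)
    ds = copy.deepcopy(dataset)
    targets = [p for p in ds.proteins[genome_id] if p.marker == marker]
    if len(targets) != 1:
        raise ValueError(
            f"genome {genome_id} does not carry a single intact {marker!r} gene")
    p = targets[0]
    genome = next(g for g in ds.genomes if g.id == genome_id)
    seq = list(genome.sequence)
    n_codons = p.length_aa

    if mode == "split":
        c = n_codons // 2 + int(rng.integers(-n_codons // 10, n_codons // 10 + 1))
        if p.strand == "+":
            cs = p.start - 1 + 3 * c
            seq[cs:cs + 3] = list("TAA")
            cds1 = (p.start, p.start + 3 * (c + 1) - 1)
            cds2 = (p.start + 3 * (c + 1), p.end)
        else:
            cs = p.end - 3 * (c + 1)
            seq[cs:cs + 3] = list(revcomp("TAA"))
            cds1 = (p.end - 3 * (c + 1) + 1, p.end)
            cds2 = (p.start, p.end - 3 * (c + 1))
        new_seq = "".join(seq)
        frag1 = pio.translate_cds(new_seq, cds1[0], cds1[1], p.strand)
        frag2 = pio.translate_cds(new_seq, cds2[0], cds2[1], p.strand)
        new_records = [
            replace(p, id=f"{p.id}a", start=cds1[0], end=cds1[1], sequence=frag1),
            replace(p, id=f"{p.id}b", start=cds2[0], end=cds2[1], sequence=frag2),
        ]
        coords = f"{cds1[0]}-{cds1[1]};{cds2[0]}-{cds2[1]}"
    else:
        keep = int(n_codons * 0.70)
        if p.strand == "+":
            cds1 = (p.start, p.start + 3 * keep - 1)
        else:
            cds1 = (p.end - 3 * keep + 1, p.end)
        new_seq = "".join(seq)
        trunc = pio.translate_cds(new_seq, cds1[0], cds1[1], p.strand)
        new_records = [replace(p, start=cds1[0], end=cds1[1], sequence=trunc)]
        coords = f"{cds1[0]}-{cds1[1]}"

    idx = next(i for i, g in enumerate(ds.genomes) if g.id == genome_id)
    ds.genomes[idx] = PlasmidRecord(id=genome_id, sequence=new_seq, circular=True)
    plist = ds.proteins[genome_id]
    pi = next(i for i, q in enumerate(plist) if q.id == p.id)
    ds.proteins[genome_id] = plist[:pi] + new_records + plist[pi + 1:]

    t = ds.truth
    mask = t["genome_id"] == genome_id
    t.loc[mask, "planted_state"] = DEGENERATED
    t.loc[mask, f"{marker}_intact"] = 0
    t.loc[mask, f"{marker}_coords"] = coords
    return ds
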