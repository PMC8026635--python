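"""Genome-level marker screen.

Plasmids are size-filtered (15-500 kbp inclusive), every protein is searched
against every marker profile, and a genome is selected only if it carries
qualifying hits for *all* required markers — by default the terminase and the
major capsid protein, the minimal phage signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .hmm import HmmHit, ProfileHMM, search_profile
from .records import PlasmidRecord, ProteinRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}

CODON_TABLE_11 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ScreenConfig:
    """Every numeric threshold of the screening stage, with field defaults."""

    min_len_bp: int = 15_000
    max_len_bp: int = 500_000
    required_markers: tuple[str, ...] = ("terminase", "major_capsid_protein")
    bit_threshold: float = 25.0
    evalue_cutoff: Optional[float] = None  # used instead of bits if profiles calibrated
    family_min_size: int = 10
    dedup_min_identity: float = 0.99
    dedup_min_coverage: float = 0.99
    family_min_identity: float = 0.20
    family_min_coverage: float = 0.80
    ortho_query_coverage: float = 0.75
    ortho_evalue: float = 1e-5
    group_similarity_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_len_bp >= self.max_len_bp:
            raise ValueError("min_len_bp must be below max_len_bp")
        if not self.required_markers:
            raise ValueError("at least one required marker")


#: genome_id -> marker -> best HmmHit (or absent)
MarkerTable = dict[str, dict[str, HmmHit]]


@dataclass
class ScreenResult:
    marker_table: MarkerTable
    selected: list[str]
    hits_by_protein: dict[str, list[HmmHit]] = field(default_factory=dict)


def size_filter(genomes: list[PlasmidRecord], cfg: ScreenConfig) -> list[PlasmidRecord]:
    """Keep genomes whose length is inside [min_len_bp, max_len_bp]."""
    return [g for g in genomes if cfg.min_len_bp <= g.length_bp <= cfg.max_len_bp]


def screen_genomes(proteomes: dict[str, list[ProteinRecord]],
                   profiles: list[ProfileHMM],
                   cfg: ScreenConfig) -> ScreenResult:
    """Search every protein against every profile and select genomes.

    A genome is selected iff it has a qualifying hit for every required
    marker; the marker table keeps the best hit per genome per marker for
    all profiles, required or not.
    """
    profile_names = {p.name for p in profiles}
    missing = set(cfg.required_markers) - profile_names
    if missing:
        raise ValueError(f"required marker profiles missing: {sorted(missing)}")

    db_size = sum(len(ps) for ps in proteomes.values())
    table: MarkerTable = {}
    hits_by_protein: dict[str, list[HmmHit]] = {}
    for genome_id in proteomes:
        table[genome_id] = {}
        for protein in proteomes[genome_id]:
            for profile in profiles:
                hit = search_profile(
                    profile, protein.id, genome_id, protein.sequence,
                    bit_threshold=cfg.bit_threshold,
                    evalue_cutoff=cfg.evalue_cutoff,
                    db_size=db_size)
                if hit is None:
                    continue
                hits_by_protein.setdefault(protein.id, []).append(hit)
                best = table[genome_id].get(profile.name)
                if best is None or hit.bit_score > best.bit_score:
                    table[genome_id][profile.name] = hit
    selected = [g for g in proteomes
                if all(m in table[g] for m in cfg.required_markers)]
    return ScreenResult(marker_table=table, selected=selected,
                        hits_by_protein=hits_by_protein)


def orf_scan(genome: PlasmidRecord, min_aa: int = 50,
             alt_starts: bool = False) -> list[ProteinRecord]:
    """Six-frame ORF scan: ATG-initiated ORFs between stops, both strands.

    Coordinates are 1-based inclusive on the forward strand with a strand
    sign; ``alt_starts`` additionally accepts the GTG/TTG starts of
    translation table 11.  This is a fallback for genomes supplied without
    annotation; annotated CDSs always take precedence.
    """
    if min_aa < 20:
        raise ValueError("min_aa must be >= 20")
    starts = {"ATG"} | ({"GTG", "TTG"} if alt_starts else set())
    n = genome.length_bp
    orfs: list[ProteinRecord] = []
    counter = 0

    for strand, seq in (("+", genome.sequence), ("-", revcomp(genome.sequence))):
        for frame in range(3):
            i = frame
            pending_start: Optional[int] = None  # first start codon since last stop
            while i + 3 <= n:
                codon = seq[i:i + 3]
                if codon in STOP_CODONS:
                    if pending_start is not None:
                        orf = _make_orf(seq, pending_start, i, strand, n,
                                        min_aa, genome.id, counter)
                        if orf is not None:
                            orfs.append(orf)
                            counter += 1
                    pending_start = None
                elif pending_start is None and codon in starts:
                    pending_start = i
                i += 3
    orfs.sort(key=lambda p: (p.start, p.end, p.strand))
    for idx, p in enumerate(orfs, start=1):
        p.id = f"{genome.id}_orf{idx}"
    return orfs


def _make_orf(seq: str, start: int, stop: int, strand: str, n: int,
              min_aa: int, genome_id: str, counter: int) -> Optional[ProteinRecord]:
    aa = []
    for j in range(start, stop, 3):
        codon = seq[j:j + 3]
        res = CODON_TABLE_11.get(codon)
        if res is None:
            return None  # ambiguous codon: skip this ORF
        aa.append(res)
    if len(aa) < min_aa:
        return None
    # convert to forward-strand 1-based inclusive coords, including the stop codon
    if strand == "+":
        fwd_start, fwd_end = start + 1, stop + 3
    else:
        fwd_start, fwd_end = n - (stop + 3) + 1, n - start
    return ProteinRecord(id=f"orf{counter}", genome_id=genome_id, start=fwd_start,
                         end=fwd_end, strand=strand, sequence="".join(aa))
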