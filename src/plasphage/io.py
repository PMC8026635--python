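"""File formats owned by the pipeline: FASTA, GFF3 (CDS subset), MSA, TSV.

Protein FASTA headers follow ``genome_id|protein_id|start|end|strand``; all
coordinates are 1-based inclusive on the forward strand.  FASTA is wrapped
at 60 columns.  Everything round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .msa import MultipleAlignment
from .records import PlasmidRecord, ProteinRecord

WRAP = 60


# -- FASTA ------------------------------------------------------------------

def write_fasta(entries: Iterable[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=WRAP)
        writer.write_file(records)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_genomes_fasta(genomes: Iterable[PlasmidRecord], path) -> None:
    write_fasta(((g.id, g.sequence) for g in genomes), path)


def read_genomes_fasta(path) -> list[PlasmidRecord]:
    return [PlasmidRecord(id=name, sequence=seq)
            for name, seq in read_fasta(path).items()]


def protein_header(p: ProteinRecord) -> str:
    return f"{p.genome_id}|{p.id}|{p.start}|{p.end}|{p.strand}"


def write_proteins_fasta(proteins: Iterable[ProteinRecord], path) -> None:
    write_fasta(((protein_header(p), p.sequence) for p in proteins), path)


def read_proteins_fasta(path) -> list[ProteinRecord]:
    proteins = []
    for header, seq in read_fasta(path).items():
        parts = header.split("|")
        if len(parts) != 5:
            raise ValueError(
                f"protein header {header!r} is not genome|protein|start|end|strand")
        genome_id, protein_id, start, end, strand = parts
        proteins.append(ProteinRecord(id=protein_id, genome_id=genome_id,
                                      start=int(start), end=int(end),
                                      strand=strand, sequence=seq))
    return proteins


# -- GFF3 (CDS subset) ------------------------------------------------------

def write_gff3(proteins: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in proteins:
            attrs = f"ID={p.id}"
            if p.marker:
                attrs += f";marker={p.marker}"
            fh.write("\t".join([
                p.genome_id, "plasphage", "CDS", str(p.start), str(p.end),
                ".", p.strand, "0", attrs,
            ]) + "\n")


def read_gff3(path, genomes: dict[str, str] | None = None) -> list[ProteinRecord]:
    """Parse CDS features; translate them when genome sequences are given."""
    proteins: list[ProteinRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "CDS":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: CDS end {end_i} < start {start_i}")
            attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            pid = attr_map.get("ID", f"cds{lineno}")
            seq = ""
            if genomes is not None:
                if seqid not in genomes:
                    raise ValueError(f"{path}:{lineno}: unknown genome {seqid!r}")
                seq = translate_cds(genomes[seqid], start_i, end_i, strand)
            proteins.append(ProteinRecord(
                id=pid, genome_id=seqid, start=start_i, end=end_i,
                strand=strand, sequence=seq, marker=attr_map.get("marker", "")))
    return proteins


def translate_cds(genome: str, start: int, end: int, strand: str) -> str:
    """Translate a CDS span (1-based inclusive), dropping a trailing stop."""
    sub = Seq(genome[start - 1:end])
    if strand == "-":
        sub = sub.reverse_complement()
    aa = str(sub.translate(table=11))
    return aa[:-1] if aa.endswith("*") else aa


# -- MSA --------------------------------------------------------------------

def write_msa_fasta(msa: MultipleAlignment, path) -> None:
    write_fasta(msa.rows.items(), path)


def read_msa(path, fmt: str = "fasta") -> MultipleAlignment:
    """Read an externally produced MSA (aligned FASTA or Stockholm)."""
    aln = AlignIO.read(str(path), fmt)
    rows = {rec.id: str(rec.seq).replace(".", "-").upper() for rec in aln}
    return MultipleAlignment(rows=rows, n_columns=aln.get_alignment_length())
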