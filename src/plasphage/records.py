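"""Core record types: plasmid genomes and their translated CDS proteins."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PlasmidRecord:
    id: str
    sequence: str
    organism: str = ""
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: non-nucleotide symbols {sorted(bad)}")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """A translated CDS with 1-based inclusive forward-strand coordinates."""

    id: str
    genome_id: str
    start: int
    end: int
    strand: str
    sequence: str
    marker: str = ""  # planted/annotated family label, informational only

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CDS {self.id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.id}: bad strand {self.strand!r}")
        if (self.end - self.start + 1) < 3 * len(self.sequence):
            raise ValueError(f"CDS {self.id}: span too short for {len(self.sequence)} aa")

    @property
    def length_aa(self) -> int:
        return len(self.sequence)
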