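"""Center-star multiple sequence alignment.

A small exact-pairwise MSA builder for marker families: the center sequence
maximises the summed pairwise local alignment score to all other members;
every member is then globally aligned to the center and the pairwise
alignments are merged under the once-a-gap-always-a-gap rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import align
from .align import ScoringScheme

GAP = "-"


@dataclass
class MultipleAlignment:
    rows: dict[str, str]  # id -> gapped sequence, all the same length
    n_columns: int

    def __post_init__(self) -> None:
        for rid, row in self.rows.items():
            if len(row) != self.n_columns:
                raise ValueError(f"row {rid!r} has length {len(row)} != {self.n_columns}")


def _member_profile(center: str, member: str, scheme: ScoringScheme):
    """Global-align member to center; return (insertions per slot, residue per center pos).

    ``inserts[c]`` is the run of member residues falling before center
    position c (slot len(center) collects the tail); ``aligned[c]`` is the
    member residue aligned to center position c or None for a deletion.
    """
    aln = align.align_global(center, member, scheme)
    inserts: list[str] = ["" for _ in range(len(center) + 1)]
    aligned: list[Optional[str]] = [None] * len(center)
    prev_m = 0
    for c_pos, m_pos in aln.aligned_pairs:
        # member residues between prev_m and m_pos are insertions before c_pos
        inserts[c_pos] += member[prev_m:m_pos]
        aligned[c_pos] = member[m_pos]
        prev_m = m_pos + 1
    inserts[len(center)] += member[prev_m:]
    return inserts, aligned


def center_star_msa(members: dict[str, str],
                    scheme: Optional[ScoringScheme] = None) -> MultipleAlignment:
    """Build a center-star MSA of two or more sequences."""
    if len(members) < 2:
        raise ValueError("center-star MSA needs at least 2 sequences")
    scheme = scheme or align.protein_scheme()

    ids = sorted(members)
    sums = {i: 0.0 for i in ids}
    for ix, i in enumerate(ids):
        for j in ids[ix + 1:]:
            s = align.align_local(members[i], members[j], scheme).raw_score
            sums[i] += s
            sums[j] += s
    # deterministic tie-break: highest summed score, then lexicographically first
    best = max(sums.values())
    center_id = min(i for i in ids if sums[i] == best)

    center = members[center_id]
    others = [i for i in ids if i != center_id]

    profiles = {i: _member_profile(center, members[i], scheme) for i in others}
    master_ins = [0] * (len(center) + 1)
    for inserts, _ in profiles.values():
        for c, run in enumerate(inserts):
            master_ins[c] = max(master_ins[c], len(run))

    def build_row(inserts, aligned) -> str:
        parts = []
        for c in range(len(center)):
            run = inserts[c]
            parts.append(run + GAP * (master_ins[c] - len(run)))
            parts.append(aligned[c] if aligned[c] is not None else GAP)
        run = inserts[len(center)]
        parts.append(run + GAP * (master_ins[len(center)] - len(run)))
        return "".join(parts)

    rows = {}
    center_ins = ["" for _ in range(len(center) + 1)]
    center_aligned = list(center)
    rows[center_id] = build_row(center_ins, center_aligned)
    for i in others:
        rows[i] = build_row(*profiles[i])

    n_cols = len(rows[center_id])
    return MultipleAlignment(rows={i: rows[i] for i in ids}, n_columns=n_cols)
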