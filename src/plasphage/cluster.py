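"""Greedy incremental identity/coverage sequence clustering.

Used at two points of the pipeline: plasmid-genome deduplication (global
mode, 99% identity / 99% coverage) and marker protein-family clustering
(local mode, 20% identity / 80% coverage).  Each sequence, visited longest
first, joins the first existing cluster whose *representative* it matches at
the thresholds, otherwise it founds a new cluster; coverage is enforced on
both sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from . import align
from .align import PairwiseAlignment, ScoringScheme


@dataclass(frozen=True)
class ClusterParams:
    min_identity: float
    min_coverage: float
    mode: str = "global"  # "global" | "local"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 1.0 and 0.0 <= self.min_coverage <= 1.0):
            raise ValueError("thresholds must be fractions in [0, 1]")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SequenceCluster:
    representative_id: str
    member_ids: list[str]
    params: ClusterParams


# genome-scale sequences switch to the banded global aligner
BANDED_MIN_LEN = 2000
GENOME_K = 16  # 4^16 >> genome length, so chance sharing is negligible


def _kmer_set(seq: str, k: int) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}


def _kmer_ints(seq: str, k: int = GENOME_K) -> np.ndarray:
    """Sorted unique k-mers of a nucleotide sequence as base-4 integers."""
    codes = np.fromiter((_NT_CODE.get(c, 0) for c in seq), dtype=np.uint64,
                        count=len(seq))
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64)
    kmers = np.zeros(len(codes) - k + 1, dtype=np.uint64)
    for off in range(k):
        kmers = (kmers << np.uint64(2)) | codes[off:off + len(kmers)]
    return np.unique(kmers)


def _containment(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return 0.0
    return len(np.intersect1d(a, b, assume_unique=True)) / min(len(a), len(b))


def _passes(aln: PairwiseAlignment, params: ClusterParams) -> bool:
    return (aln.identity >= params.min_identity
            and aln.query_coverage >= params.min_coverage
            and aln.target_coverage >= params.min_coverage)


def greedy_cluster(sequences: dict[str, str], params: ClusterParams,
                   scheme: Optional[ScoringScheme] = None,
                   prefilter: bool = True) -> list[SequenceCluster]:
    """Cluster sequences greedily against cluster representatives.

    Sequences are visited by decreasing length (ties broken by identifier);
    output clusters are in founding order.  ``prefilter`` enables a shared
    k-mer screen (k=8 nucleotide / k=4 protein) plus, in global mode, an
    exact length-ratio bound (identity can never exceed the shorter length
    over the longer); neither filter changes results on point-substitution
    divergence.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if len(set(sequences)) != len(sequences):  # dict keys are unique already
        raise ValueError("duplicate identifiers")

    first_seq = next(iter(sequences.values()))
    scheme = scheme or align.infer_scheme(first_seq)
    is_nt = set(first_seq.upper()) <= set(align.NUCLEOTIDE_ALPHABET)
    k = 8 if is_nt else 4

    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    genome_scale = is_nt and params.mode == "global" and any(
        len(sequences[sid]) > BANDED_MIN_LEN for sid in order)
    # a pair at identity >= t is guaranteed a shared k-mer only when the
    # longest exact-match run t/(1-t) reaches k; below that the k-mer screens
    # could change results, so they disengage
    kmer_safe = params.min_identity >= k / (k + 1)
    kmers: dict = {}
    big_kmers: dict = {}
    if prefilter and kmer_safe:
        if genome_scale:
            big_kmers = {sid: _kmer_ints(sequences[sid]) for sid in order}
        else:
            kmers = {sid: _kmer_set(sequences[sid], k) for sid in order}
    # containment of long near-identical sequences concentrates around
    # identity**k; anything this far below cannot reach min_identity
    containment_floor = max(0.25, params.min_identity ** GENOME_K - 0.25)

    clusters: list[SequenceCluster] = []
    for sid in order:
        seq = sequences[sid]
        placed = False
        for cl in clusters:
            rep = sequences[cl.representative_id]
            if prefilter:
                if params.mode == "global":
                    # identity <= min(m, n) / max(m, n); exact bound
                    if min(len(seq), len(rep)) < params.min_identity * max(len(seq), len(rep)):
                        continue
                if kmer_safe and genome_scale:
                    if _containment(big_kmers[sid],
                                    big_kmers[cl.representative_id]) < containment_floor:
                        continue
                elif kmer_safe and kmers[sid].isdisjoint(kmers[cl.representative_id]):
                    continue
            aln = _compare(seq, rep, params, scheme)
            if _passes(aln, params):
                cl.member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(sid, [sid], params))
    return clusters


def _compare(seq: str, rep: str, params: ClusterParams,
             scheme: ScoringScheme) -> PairwiseAlignment:
    if params.mode == "local":
        return align.align_local(seq, rep, scheme)
    if max(len(seq), len(rep)) > BANDED_MIN_LEN:
        return align.align_global_banded(seq, rep, scheme)
    return align.align_global(seq, rep, scheme)


def select_family_clusters(clusters: Iterable[SequenceCluster],
                           min_size: int = 10) -> list[SequenceCluster]:
    """Keep clusters with at least ``min_size`` members, preserving order."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [cl for cl in clusters if len(cl.member_ids) >= min_size]


def write_cluster_tsv(clusters: Iterable[SequenceCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\trepresentative_id\n")
        for cl in clusters:
            for member in cl.member_ids:
                fh.write(f"{member}\t{cl.representative_id}\n")
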