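"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: recursive enumeration of alignments,
explicit enumeration of HMM state paths, double-loop best-hit scans and
fixpoint triangle merging.  None of it shares code with the package's DP or
graph implementations.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np

MATCH_STATE, GAP_A, GAP_B = "M", "GA", "GB"


def enum_global_score(a: str, b: str, scheme) -> float:
    """Optimal global affine-gap score by memoised recursion over alignments.

    Gap convention matches the implementation: the first gap column costs
    gap_open, each further column of the same gap costs gap_extend.
    """
    S = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        cands = []
        if i < len(a) and j < len(b):
            cands.append(S[a[i], b[j]] + best(i + 1, j + 1, MATCH_STATE))
        if j < len(b):
            cands.append((ge if prev == GAP_A else go) + best(i, j + 1, GAP_A))
        if i < len(a):
            cands.append((ge if prev == GAP_B else go) + best(i + 1, j, GAP_B))
        return max(cands)

    return best(0, 0, MATCH_STATE)


def enum_local_score(a: str, b: str, scheme) -> float:
    """Optimal local score: best global score over all substring pairs, or 0.

    Alignments that begin or end with a gap column score no better than the
    trimmed alignment, so taking the maximum over substrings is exhaustive.
    """
    best = 0.0
    for i0 in range(len(a) + 1):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b) + 1):
                for j1 in range(j0 + 1, len(b) + 1):
                    s = enum_global_score(a[i0:i1], b[j0:j1], scheme)
                    best = max(best, s)
    return best


# ---------------------------------------------------------------------------
# Profile HMM path enumeration
# ---------------------------------------------------------------------------

def enum_joint_scores(profile, seq: str):
    """(viterbi_log2, forward_log2) by explicit enumeration of state paths."""
    t = profile.transitions
    M = profile.M
    em = profile.match_emissions
    bg = profile.background
    from plasphage.hmm import encode
    x = encode(seq)
    L = len(seq)
    best = [-np.inf]
    total = [0.0]

    def rec(state: str, node: int, i: int, logp: float) -> None:
        if node == M:
            tend = {"M": t["mm"][M], "I": t["im"][M], "D": t["dm"][M]}[state]
            if i == L and tend > 0:
                lp = logp + np.log2(tend)
                best[0] = max(best[0], lp)
                total[0] += 2.0 ** lp
        if state == "M":
            moves = [("M", node + 1, t["mm"][node]), ("I", node, t["mi"][node]),
                     ("D", node + 1, t["md"][node])]
        elif state == "I":
            moves = [("M", node + 1, t["im"][node]), ("I", node, t["ii"][node])]
        else:
            moves = [("M", node + 1, t["dm"][node]), ("D", node + 1, t["dd"][node])]
        for ns, nn, tp in moves:
            if tp <= 0 or nn > M:
                continue
            if ns == "M":
                if i < L:
                    rec("M", nn, i + 1, logp + np.log2(tp) + np.log2(em[nn - 1][x[i]]))
            elif ns == "I":
                if i < L:
                    rec("I", nn, i + 1, logp + np.log2(tp) + np.log2(bg[x[i]]))
            else:
                rec("D", nn, i, logp + np.log2(tp))

    rec("M", 0, 0, 0.0)
    return best[0], np.log2(total[0]) if total[0] > 0 else -np.inf


def enum_local_search_bits(profile, seq: str) -> float:
    """Best local log-odds path by enumerating every entry/exit and path."""
    t = {k: np.log2(np.maximum(v, 1e-300)) for k, v in profile.transitions.items()}
    lo = np.log2(profile.match_emissions / profile.background)
    M = profile.M
    from plasphage.hmm import encode
    x = encode(seq)
    L = len(x)
    best = [0.0]

    def rec(state: str, node: int, i: int, score: float) -> None:
        if state == "M":
            best[0] = max(best[0], score)  # free exit from any match state
        if state == "M":
            moves = [("M", node + 1, t["mm"][node]), ("I", node, t["mi"][node]),
                     ("D", node + 1, t["md"][node])]
        elif state == "I":
            moves = [("M", node + 1, t["im"][node]), ("I", node, t["ii"][node])]
        else:
            moves = [("M", node + 1, t["dm"][node]), ("D", node + 1, t["dd"][node])]
        for ns, nn, tp in moves:
            if nn > M:
                continue
            if ns == "M":
                if i < L:
                    rec("M", nn, i + 1, score + tp + lo[nn - 1, x[i]])
            elif ns == "I":
                if i < L:
                    rec("I", nn, i + 1, score + tp)
            else:
                rec("D", nn, i, score + tp)

    for j in range(1, M + 1):
        for i0 in range(1, L + 1):
            rec("M", j, i0, lo[j - 1, x[i0 - 1]])
    return best[0]


# ---------------------------------------------------------------------------
# Greedy clustering oracle
# ---------------------------------------------------------------------------

def greedy_cluster_oracle(sequences: dict[str, str], params, pairwise) -> list[list[str]]:
    """Apply the greedy rule using independently supplied pairwise stats.

    ``pairwise(a, b)`` must return (identity, coverage_a, coverage_b).
    """
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    clusters: list[list[str]] = []
    for sid in order:
        for members in clusters:
            rep = members[0]
            ident, cov_a, cov_b = pairwise(sequences[sid], sequences[rep])
            if (ident >= params.min_identity and cov_a >= params.min_coverage
                    and cov_b >= params.min_coverage):
                members.append(sid)
                break
        else:
            clusters.append([sid])
    return clusters


# ---------------------------------------------------------------------------
# BBH + COGtriangles oracle
# ---------------------------------------------------------------------------

def bbh_oracle(hits) -> set[tuple[str, str]]:
    """Double-loop best-hit scan with the documented tie-breaks."""
    by_query: dict[tuple[str, str], list] = {}
    for h in hits:
        by_query.setdefault((h.query_id, h.target_genome), []).append(h)
    best = {}
    for key, hs in by_query.items():
        hs = sorted(hs, key=lambda h: (-h.bit_score, -h.query_coverage, h.target_id))
        best[key] = hs[0].target_id
    out = set()
    for (q, tg), t in best.items():
        for (q2, tg2), t2 in best.items():
            if q2 == t and t2 == q:
                out.add(tuple(sorted((q, t))))
    return out


def cog_partition_oracle(bbhs, all_proteins) -> set[frozenset]:
    """All-triples triangle test plus fixpoint shared-edge merging."""
    genome_of = dict((pid, gid) for gid, pid in [(g, p) for g, p in all_proteins])
    bbh_set = {tuple(sorted(e)) for e in bbhs}
    proteins = [p for _, p in all_proteins]
    triangles = []
    for trio in combinations(sorted(proteins), 3):
        a, b, c = trio
        if len({genome_of[a], genome_of[b], genome_of[c]}) != 3:
            continue
        edges = [tuple(sorted(e)) for e in combinations(trio, 2)]
        if all(e in bbh_set for e in edges):
            triangles.append((set(trio), set(edges)))

    merged = [(set(t[0]), set(t[1])) for t in triangles]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if merged[i][1] & merged[j][1]:
                    merged[i] = (merged[i][0] | merged[j][0],
                                 merged[i][1] | merged[j][1])
                    del merged[j]
                    changed = True
                    break
            if changed:
                break

    partition = {frozenset(m[0]) for m in merged}
    clustered = set().union(*(m[0] for m in merged)) if merged else set()
    for p in proteins:
        if p not in clustered:
            partition.add(frozenset([p]))
    return partition


def expected_family_identity(divergence: float, n_alpha: int = 19) -> float:
    """Expected pairwise identity of two sequences independently mutated at
    rate d from a common ancestor (replacement uniform over the other 19)."""
    d = divergence
    return (1 - d) ** 2 + d * d / n_alpha
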