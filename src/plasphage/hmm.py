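"""Profile hidden Markov models for marker-gene screening.

Krogh-style profile HMMs are built from multiple alignments of marker
families (terminase, major capsid protein, tape measure protein, tyrosine
and serine recombinases, ParA/ParM/TubZ partitioning motors, tail sheath)
and searched against plasmid proteomes, standing in for hmmbuild/hmmsearch.

Architecture: match states M_1..M_M with 20-letter emissions, insert states
I_0..I_M emitting the background distribution, delete states D_1..D_M.
Transition groups are M->{M,I,D}, I->{M,I}, D->{M,D}.  Searching uses a
local Viterbi over log-odds scores (bits) with free entry into and exit from
any match state and free (background-scoring) flanking insertions, so the
flanks contribute nothing to the score.  E-values are optional and come from
a Gumbel fit to shuffled-decoy scores.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .msa import GAP, MultipleAlignment

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
LOG2E = math.log2(math.e)
NEG = -1.0e30

#: the seven markers screened in the pipeline plus auxiliary profiles
CORE_MARKERS = ("terminase", "major_capsid_protein", "tape_measure_protein",
                "tyrosine_recombinase", "parM", "parA", "tubZ")
AUX_MARKERS = ("sheath", "serine_recombinase")
ALL_MARKERS = CORE_MARKERS + AUX_MARKERS
MOTOR_MARKERS = ("parA", "parM", "tubZ")


@dataclass(frozen=True)
class GumbelCalibration:
    mu: float
    beta: float
    n_decoys: int

    def pvalue(self, bits: float) -> float:
        """P(S >= bits) under the fitted Gumbel null."""
        z = (bits - self.mu) / self.beta
        # survival function 1 - exp(-exp(-z)), stable for large z
        if z > 30:
            return math.exp(-z)
        return -math.expm1(-math.exp(-z))


@dataclass
class ProfileHMM:
    name: str
    M: int
    match_emissions: np.ndarray       # (M, 20)
    insert_emissions: np.ndarray      # (20,) == background by construction
    transitions: dict[str, np.ndarray]  # keys mm, mi, md, im, ii, dm, dd; len M+1
    background: np.ndarray            # (20,)
    calibration: Optional[GumbelCalibration] = None
    training_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("profile needs at least one match state")
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=tol):
            raise ValueError("match emission rows must sum to 1")
        for arr in (self.insert_emissions, self.background):
            if abs(arr.sum() - 1.0) > tol:
                raise ValueError("emission distribution must sum to 1")
        t = self.transitions
        for k in range(self.M + 1):
            m_group = t["mm"][k] + t["mi"][k] + t["md"][k]
            i_group = t["im"][k] + t["ii"][k]
            if abs(m_group - 1.0) > tol or abs(i_group - 1.0) > tol:
                raise ValueError(f"transition group at node {k} does not sum to 1")
            if k >= 1:
                d_group = t["dm"][k] + t["dd"][k]
                if abs(d_group - 1.0) > tol:
                    raise ValueError(f"delete group at node {k} does not sum to 1")


@dataclass
class HmmHit:
    protein_id: str
    genome_id: str
    profile_name: str
    bit_score: float
    evalue: Optional[float]
    match_state_coverage: float
    region: tuple[int, int]  # 1-based inclusive on the protein


def encode(seq: str) -> np.ndarray:
    """Map a protein sequence to alphabet indices; unknown residues get -1."""
    return np.fromiter((AA_INDEX.get(c, -1) for c in seq), dtype=np.int64,
                       count=len(seq))


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

def build_profile(msa: MultipleAlignment, name: str,
                  background: Optional[Sequence[float]] = None) -> ProfileHMM:
    """Estimate a profile HMM from an MSA with Laplace(+1) smoothing.

    Match columns are those with more than 50% non-gap residues.  Insert
    states emit the background distribution.
    """
    bg = np.full(20, 1.0 / 20) if background is None else np.asarray(background, float)
    rows = list(msa.rows.values())
    n_rows = len(rows)
    cols = msa.n_columns

    col_is_match = []
    for c in range(cols):
        non_gap = sum(1 for r in rows if r[c] != GAP)
        col_is_match.append(non_gap > n_rows / 2)
    M = sum(col_is_match)
    if M == 0:
        raise ValueError("alignment has no match column (>50% residues)")

    match_counts = np.zeros((M, 20))
    # transition counts per node 0..M
    c_mm = np.zeros(M + 1)
    c_mi = np.zeros(M + 1)
    c_md = np.zeros(M + 1)
    c_im = np.zeros(M + 1)
    c_ii = np.zeros(M + 1)
    c_dm = np.zeros(M + 1)
    c_dd = np.zeros(M + 1)

    match_index = np.cumsum(col_is_match)  # node number at each column

    for row in rows:
        state = "M"  # begin is treated as M_0
        node = 0
        for c in range(cols):
            ch = row[c]
            if col_is_match[c]:
                nxt = "M" if ch != GAP else "D"
                k = match_index[c]
                if nxt == "M" and ch in AA_INDEX:
                    match_counts[k - 1, AA_INDEX[ch]] += 1
                if state == "M":
                    (c_mm if nxt == "M" else c_md)[node] += 1
                elif state == "I":
                    c_im[node] += 1
                    if nxt == "D":
                        # I->D is unmodelled; route the count through M->D
                        c_md[node] += 1
                else:  # D
                    (c_dm if nxt == "M" else c_dd)[node] += 1
                state, node = nxt, k
            else:
                if ch == GAP:
                    continue
                if state == "M":
                    c_mi[node] += 1
                elif state == "I":
                    c_ii[node] += 1
                else:  # D -> I unmodelled: close the deletion first
                    c_dm[node] += 1
                    c_mi[node] += 1
                state = "I"
        # end transition: to M_{M+1}
        if state == "M":
            c_mm[node] += 1
        elif state == "I":
            c_im[node] += 1
        else:
            c_dm[node] += 1

    match_emissions = (match_counts + 1.0) / (match_counts.sum(axis=1, keepdims=True) + 20.0)

    def norm3(a, b, c):
        tot = a + b + c + 3.0
        return (a + 1.0) / tot, (b + 1.0) / tot, (c + 1.0) / tot

    def norm2(a, b):
        tot = a + b + 2.0
        return (a + 1.0) / tot, (b + 1.0) / tot

    t = {k: np.zeros(M + 1) for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    for k in range(M + 1):
        if k < M:
            t["mm"][k], t["mi"][k], t["md"][k] = norm3(c_mm[k], c_mi[k], c_md[k])
            if k >= 1:
                t["dm"][k], t["dd"][k] = norm2(c_dm[k], c_dd[k])
        else:
            # final node: no delete successor exists
            t["mm"][k], t["mi"][k] = norm2(c_mm[k], c_mi[k])
            t["md"][k] = 0.0
            t["dm"][k], t["dd"][k] = 1.0, 0.0
        t["im"][k], t["ii"][k] = norm2(c_im[k], c_ii[k])

    lengths = tuple(sorted(len(r.replace(GAP, "")) for r in rows))
    return ProfileHMM(name=name, M=M, match_emissions=match_emissions,
                      insert_emissions=bg.copy(), transitions=t, background=bg,
                      training_lengths=lengths)


# ---------------------------------------------------------------------------
# Joint (global) Viterbi / Forward, used for correctness checks
# ---------------------------------------------------------------------------

def _log2(x: float) -> float:
    return math.log2(x) if x > 0 else NEG


def _joint_dp(profile: ProfileHMM, seq: str, viterbi: bool) -> float:
    """log2 P(seq, best path) (Viterbi) or log2 P(seq) (Forward).

    The full sequence is generated begin -> ... -> end through the profile;
    ambiguous residues emit the background probability.
    """
    L = len(seq)
    M = profile.M
    x = encode(seq)
    t = {k: np.log2(np.maximum(v, 1e-300)) for k, v in profile.transitions.items()}
    em = np.log2(profile.match_emissions)
    bg = np.log2(profile.background)

    def emit_m(k: int, i: int) -> float:
        a = x[i]
        return em[k - 1, a] if a >= 0 else bg.mean()

    def emit_i(i: int) -> float:
        a = x[i]
        return bg[a] if a >= 0 else bg.mean()

    def comb(vals):
        vals = [v for v in vals if v > NEG / 2]
        if not vals:
            return NEG
        if viterbi:
            return max(vals)
        mx = max(vals)
        return mx + math.log2(sum(2.0 ** (v - mx) for v in vals))

    # vm[i][k]: log prob of consuming first i residues, last state M_k (k=0 begin)
    vm = [[NEG] * (M + 2) for _ in range(L + 1)]
    vi = [[NEG] * (M + 1) for _ in range(L + 1)]
    vd = [[NEG] * (M + 1) for _ in range(L + 1)]
    vm[0][0] = 0.0
    for k in range(1, M + 1):
        vd[0][k] = comb([vm[0][k - 1] + t["md"][k - 1], vd[0][k - 1] + t["dd"][k - 1]]) \
            if k > 1 else vm[0][0] + t["md"][0]
    for i in range(0, L + 1):
        for k in range(0, M + 1):
            if i > 0 and k > 0:
                vm[i][k] = emit_m(k, i - 1) + comb([
                    vm[i - 1][k - 1] + t["mm"][k - 1],
                    vi[i - 1][k - 1] + t["im"][k - 1],
                    vd[i - 1][k - 1] + t["dm"][k - 1] if k - 1 >= 1 else NEG,
                ])
            if i > 0:
                vi[i][k] = emit_i(i - 1) + comb([
                    vm[i - 1][k] + t["mi"][k],
                    vi[i - 1][k] + t["ii"][k],
                ])
            if k > 0 and i > 0:
                vd[i][k] = comb([
                    vm[i][k - 1] + t["md"][k - 1],
                    vd[i][k - 1] + t["dd"][k - 1] if k - 1 >= 1 else NEG,
                ])
    # end: from M_M, I_M or D_M
    return comb([
        vm[L][M] + t["mm"][M],
        vi[L][M] + t["im"][M],
        vd[L][M] + t["dm"][M],
    ])


def viterbi_log2(profile: ProfileHMM, seq: str) -> float:
    """log2 joint probability of the best full-length state path."""
    return _joint_dp(profile, seq, viterbi=True)


def forward_log2(profile: ProfileHMM, seq: str) -> float:
    """log2 total probability of the sequence under the profile."""
    return _joint_dp(profile, seq, viterbi=False)


# ---------------------------------------------------------------------------
# Local log-odds search
# ---------------------------------------------------------------------------

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard runtime dependency
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not args else args[0]


@njit(cache=True)
def _search_kernel(x, lo, lo_mean, tmm, tmi, tmd, tim, tii, tdm, tdd):  # pragma: no cover
    L = x.shape[0]
    M = lo.shape[0]
    neg = -1.0e30
    vm = np.full(M + 1, neg)
    vi = np.full(M + 1, neg)
    vd = np.full(M + 1, neg)
    # start coordinates (i, k) carried along the best path per state
    smi = np.zeros(M + 1, dtype=np.int64)
    smk = np.zeros(M + 1, dtype=np.int64)
    sii = np.zeros(M + 1, dtype=np.int64)
    sik = np.zeros(M + 1, dtype=np.int64)
    sdi = np.zeros(M + 1, dtype=np.int64)
    sdk = np.zeros(M + 1, dtype=np.int64)
    vm_new = np.empty(M + 1)
    smi_new = np.empty(M + 1, dtype=np.int64)
    smk_new = np.empty(M + 1, dtype=np.int64)

    best = 0.0
    bi0 = bi1 = bk0 = bk1 = 0
    for i in range(1, L + 1):
        a = x[i - 1]
        vm_new[0] = neg
        smi_new[0] = 0
        smk_new[0] = 0
        for k in range(1, M + 1):
            e = lo[k - 1, a] if a >= 0 else lo_mean
            b = 0.0
            src = 0
            c1 = vm[k - 1] + tmm[k - 1]
            if c1 > b:
                b = c1
                src = 1
            c2 = vi[k - 1] + tim[k - 1]
            if c2 > b:
                b = c2
                src = 2
            c3 = vd[k - 1] + tdm[k - 1]
            if c3 > b:
                b = c3
                src = 3
            vm_new[k] = e + b
            if src == 0:
                smi_new[k] = i
                smk_new[k] = k
            elif src == 1:
                smi_new[k] = smi[k - 1]
                smk_new[k] = smk[k - 1]
            elif src == 2:
                smi_new[k] = sii[k - 1]
                smk_new[k] = sik[k - 1]
            else:
                smi_new[k] = sdi[k - 1]
                smk_new[k] = sdk[k - 1]
        # inserts: consume the residue, stay at node (prev-row values)
        for k in range(M + 1):
            io_ = vm[k] + tmi[k]
            ie = vi[k] + tii[k]
            if ie > io_:
                vi[k] = ie
            else:
                vi[k] = io_
                sii[k] = smi[k]
                sik[k] = smk[k]
        # commit the match row
        for k in range(M + 1):
            vm[k] = vm_new[k]
            smi[k] = smi_new[k]
            smk[k] = smk_new[k]
        # deletes within this row (sequential scan over nodes)
        vd[0] = neg
        for k in range(1, M + 1):
            do = vm[k - 1] + tmd[k - 1]
            de = vd[k - 1] + tdd[k - 1]
            if de > do:
                vd[k] = de
                sdi[k] = sdi[k - 1]
                sdk[k] = sdk[k - 1]
            else:
                vd[k] = do
                sdi[k] = smi[k - 1]
                sdk[k] = smk[k - 1]
        for k in range(1, M + 1):
            if vm[k] > best:
                best = vm[k]
                bi1 = i
                bk1 = k
                bi0 = smi[k]
                bk0 = smk[k]
    return best, bi0, bi1, bk0, bk1


def _search_dp(profile: ProfileHMM, seq: str):
    """Best local log-odds path; returns (bits, (i0, i1), (k0, k1)) 1-based."""
    x = encode(seq)
    t = _log_odds_tables(profile)
    best, i0, i1, k0, k1 = _search_kernel(x, *t)
    if best <= 0.0:
        return 0.0, (0, 0), (0, 0)
    return float(best), (i0, i1), (k0, k1)


def _log_odds_tables(profile: ProfileHMM):
    cached = getattr(profile, "_lo_cache", None)
    if cached is not None:
        return cached
    t = {k: np.log2(np.maximum(v, 1e-300)) for k, v in profile.transitions.items()}
    lo = np.log2(profile.match_emissions / profile.background)
    lo_mean = float(np.mean(np.log2(profile.match_emissions)) -
                    np.mean(np.log2(profile.background)))
    tables = (lo, lo_mean, t["mm"], t["mi"], t["md"], t["im"], t["ii"],
              t["dm"], t["dd"])
    object.__setattr__(profile, "_lo_cache", tables)
    return tables


def search_profile(profile: ProfileHMM, protein_id: str, genome_id: str,
                   sequence: str, *, bit_threshold: float = 25.0,
                   evalue_cutoff: Optional[float] = None,
                   db_size: int = 1) -> Optional[HmmHit]:
    """Search one protein with one profile; return a hit or ``None``.

    Acceptance is by bit score (default 25 bits) or, when the profile is
    calibrated and ``evalue_cutoff`` given, by E-value with
    ``E = db_size * P_gumbel(S >= s)``.
    """
    if not sequence:
        return None
    bits, (i0, i1), (k0, k1) = _search_dp(profile, sequence)
    ev = None
    if profile.calibration is not None:
        ev = db_size * profile.calibration.pvalue(bits)
    if evalue_cutoff is not None:
        if ev is None:
            raise ValueError("E-value cutoff requested but profile is uncalibrated")
        if ev > evalue_cutoff:
            return None
    elif bits < bit_threshold:
        return None
    coverage = (k1 - k0 + 1) / profile.M if k1 >= k0 >= 1 else 0.0
    return HmmHit(protein_id=protein_id, genome_id=genome_id,
                  profile_name=profile.name, bit_score=bits, evalue=ev,
                  match_state_coverage=coverage, region=(i0, i1))


def score_sequence(profile: ProfileHMM, sequence: str) -> float:
    """Local log-odds bit score of a sequence against the profile."""
    bits, _, _ = _search_dp(profile, sequence)
    return bits


# ---------------------------------------------------------------------------
# Decoy calibration
# ---------------------------------------------------------------------------

EULER_GAMMA = 0.5772156649015329


def calibrate_evalues(profile: ProfileHMM, decoys: int = 500,
                      seed: int = 0) -> ProfileHMM:
    """Fit Gumbel (mu, beta) to bit scores of background-shuffled decoys.

    Decoy lengths are resampled from the profile's training lengths and
    residues drawn i.i.d. from the background distribution; the fit is by
    the method of moments.
    """
    if decoys < 100:
        raise ValueError("need at least 100 decoys for a stable fit")
    if not profile.training_lengths:
        raise ValueError("profile has no recorded training lengths")
    rng = np.random.default_rng(seed)
    lengths = rng.choice(profile.training_lengths, size=decoys)
    probs = profile.background / profile.background.sum()
    scores = np.empty(decoys)
    for d in range(decoys):
        seq = "".join(rng.choice(list(AA), size=int(lengths[d]), p=probs))
        scores[d] = score_sequence(profile, seq)
    beta = float(scores.std(ddof=1) * math.sqrt(6.0) / math.pi)
    beta = max(beta, 1e-9)
    mu = float(scores.mean() - EULER_GAMMA * beta)
    return replace(profile, calibration=GumbelCalibration(mu, beta, decoys))


# ---------------------------------------------------------------------------
# Serialization (documented JSON text format)
# ---------------------------------------------------------------------------

def profile_to_json(profile: ProfileHMM) -> str:
    doc = {
        "format": "plasphage-profile-1",
        "name": profile.name,
        "M": profile.M,
        "alphabet": AA,
        "match_emissions": profile.match_emissions.tolist(),
        "insert_emissions": profile.insert_emissions.tolist(),
        "transitions": {k: v.tolist() for k, v in profile.transitions.items()},
        "background": profile.background.tolist(),
        "training_lengths": list(profile.training_lengths),
        "calibration": None if profile.calibration is None else {
            "mu": profile.calibration.mu,
            "beta": profile.calibration.beta,
            "n_decoys": profile.calibration.n_decoys,
        },
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def profile_from_json(text: str) -> ProfileHMM:
    doc = json.loads(text)
    if doc.get("format") != "plasphage-profile-1":
        raise ValueError("not a plasphage profile document")
    cal = doc.get("calibration")
    return ProfileHMM(
        name=doc["name"],
        M=doc["M"],
        match_emissions=np.asarray(doc["match_emissions"], float),
        insert_emissions=np.asarray(doc["insert_emissions"], float),
        transitions={k: np.asarray(v, float) for k, v in doc["transitions"].items()},
        background=np.asarray(doc["background"], float),
        calibration=None if cal is None else GumbelCalibration(
            cal["mu"], cal["beta"], cal["n_decoys"]),
        training_lengths=tuple(doc.get("training_lengths", ())),
    )
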