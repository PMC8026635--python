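"""Rule-based prophage-state classification.

The manual expert calls of plasmid-prophage surveys are formalised into a
deterministic cascade over per-genome gene features:

  R1  no terminase or no major capsid protein       -> non-phage plasmid
  R2  phage signature but no partitioning motor and
      no recombinase of either family               -> putative virulent phage
  R3  truncated terminase or split tape measure     -> putative degenerated
                                                       plasmid prophage
  R4  otherwise                                     -> putative active
                                                       plasmid prophage

Morphotype: myovirus-like iff a tail sheath protein is found, else
siphovirus-like iff a tail marker (TMP) is present, else undetermined.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .hmm import HmmHit, MOTOR_MARKERS
from .records import PlasmidRecord, ProteinRecord

ACTIVE = "putative_active_plasmid_prophage"
DEGENERATED = "putative_degenerated_plasmid_prophage"
VIRULENT = "putative_virulent_phage"
NON_PHAGE = "non_phage_plasmid"
STATES = (ACTIVE, DEGENERATED, VIRULENT, NON_PHAGE)

SIPHO = "siphovirus_like"
MYO = "myovirus_like"
UNDETERMINED = "undetermined"


@dataclass
class FeatureConfig:
    """Thresholds that formalise the expert judgments; all configurable."""

    tmp_min_aa: int = 900          # intact tape measure proteins are long
    tmp_window_genes: int = 3      # fragments must be near-adjacent CDSs
    terminase_min_profile_cov: float = 0.80
    adapter_max_aa: int = 150
    adapter_window_genes: int = 2
    serine_small_max_aa: int = 250  # resolvase/invertase-sized
    serine_large_min_aa: int = 400  # integrase-sized


@dataclass
class GeneFeatureSet:
    has_terminase: bool = False
    has_mcp: bool = False
    has_tmp: bool = False
    tmp_intact: bool = False
    tmp_fragment_count: int = 0
    terminase_truncated: bool = False
    motor_type: str = "none"  # none | parA | parM | tubZ
    has_adapter_downstream: bool = False
    has_tyrosine_recombinase: bool = False
    has_serine_recombinase: bool = False
    serine_recombinase_class: str = "none"
    has_sheath: bool = False

    def __post_init__(self) -> None:
        if self.tmp_intact and not self.has_tmp:
            raise ValueError("tmp_intact requires has_tmp")
        if self.has_adapter_downstream and self.motor_type == "none":
            raise ValueError("adapter position is defined relative to a motor")


@dataclass
class ProphageCall:
    genome_id: str
    state: str
    morphotype: str
    features: GeneFeatureSet
    rules: list[str] = field(default_factory=list)


def _best_hit(hits: list[HmmHit], marker: str) -> Optional[HmmHit]:
    marker_hits = [h for h in hits if h.profile_name == marker]
    if not marker_hits:
        return None
    return max(marker_hits, key=lambda h: h.bit_score)


def extract_features(genome: PlasmidRecord,
                     proteins: list[ProteinRecord],
                     hits_by_protein: dict[str, list[HmmHit]],
                     cfg: Optional[FeatureConfig] = None) -> GeneFeatureSet:
    """Derive the classifier's feature flags from marker hits and gene layout."""
    cfg = cfg or FeatureConfig()
    for p in proteins:
        if p.end > genome.length_bp:
            raise ValueError(
                f"CDS {p.id} ends at {p.end} beyond genome length {genome.length_bp}")

    ordered = sorted(proteins, key=lambda p: (p.start, p.end))
    index_of = {p.id: i for i, p in enumerate(ordered)}
    all_hits = [h for p in ordered for h in hits_by_protein.get(p.id, [])]

    def hit_protein(h: HmmHit) -> ProteinRecord:
        return ordered[index_of[h.protein_id]]

    term = _best_hit(all_hits, "terminase")
    mcp = _best_hit(all_hits, "major_capsid_protein")
    tmp = _best_hit(all_hits, "tape_measure_protein")
    sheath = _best_hit(all_hits, "sheath")
    tyr = _best_hit(all_hits, "tyrosine_recombinase")
    ser = _best_hit(all_hits, "serine_recombinase")

    features = GeneFeatureSet()
    features.has_terminase = term is not None
    features.has_mcp = mcp is not None
    features.has_tmp = tmp is not None
    features.has_sheath = sheath is not None
    features.has_tyrosine_recombinase = tyr is not None
    features.has_serine_recombinase = ser is not None

    if term is not None:
        features.terminase_truncated = (
            term.match_state_coverage < cfg.terminase_min_profile_cov)

    if tmp is not None:
        features.tmp_intact = hit_protein(tmp).length_aa >= cfg.tmp_min_aa
        tmp_indices = sorted({index_of[h.protein_id] for h in all_hits
                              if h.profile_name == "tape_measure_protein"})
        # largest run of TMP-hit CDSs within a window of consecutive genes
        best_run = 1
        run = 1
        for a, b in zip(tmp_indices, tmp_indices[1:]):
            if b - a < cfg.tmp_window_genes:
                run += 1
                best_run = max(best_run, run)
            else:
                run = 1
        features.tmp_fragment_count = best_run

    motor_hits = [h for h in all_hits if h.profile_name in MOTOR_MARKERS]
    if motor_hits:
        motor = max(motor_hits, key=lambda h: h.bit_score)
        features.motor_type = motor.profile_name
        mp = hit_protein(motor)
        mi = index_of[motor.protein_id]
        step = 1 if mp.strand == "+" else -1
        for off in range(1, cfg.adapter_window_genes + 1):
            ni = mi + step * off
            if not (0 <= ni < len(ordered)):
                break
            cand = ordered[ni]
            if cand.strand == mp.strand and cand.length_aa <= cfg.adapter_max_aa:
                features.has_adapter_downstream = True
                break

    if ser is not None:
        length = hit_protein(ser).length_aa
        if length <= cfg.serine_small_max_aa:
            features.serine_recombinase_class = "small_resolvase_invertase"
        elif length >= cfg.serine_large_min_aa:
            features.serine_recombinase_class = "large_integrase_like"

    return features


def classify(genome_id: str, features: GeneFeatureSet) -> ProphageCall:
    """Pure rule cascade mapping features to a prophage state; first match wins."""
    rules: list[str] = []
    if not (features.has_terminase and features.has_mcp):
        rules.append("R1")
        state = NON_PHAGE
    elif (features.motor_type == "none"
          and not features.has_tyrosine_recombinase
          and not features.has_serine_recombinase):
        rules.append("R2")
        state = VIRULENT
    elif features.terminase_truncated or (features.has_tmp and not features.tmp_intact):
        rules.append("R3")
        state = DEGENERATED
    else:
        rules.append("R4")
        state = ACTIVE

    if features.has_sheath:
        morphotype = MYO
    elif features.has_tmp:
        morphotype = SIPHO
    else:
        morphotype = UNDETERMINED

    return ProphageCall(genome_id=genome_id, state=state, morphotype=morphotype,
                        features=features, rules=rules)


def report_calls(calls: list[ProphageCall],
                 groups: Optional[list] = None,
                 calls_path=None, counts_path=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome call table plus per-state counts and percentages."""
    group_of: dict[str, int] = {}
    singleton: dict[str, bool] = {}
    for grp in groups or []:
        for g in grp.member_genome_ids:
            group_of[g] = grp.group_id
            singleton[g] = grp.is_singleton

    rows = []
    for call in sorted(calls, key=lambda c: c.genome_id):
        f = call.features
        rows.append({
            "genome_id": call.genome_id,
            "state": call.state,
            "morphotype": call.morphotype,
            "group_id": group_of.get(call.genome_id, ""),
            "is_singleton": int(singleton.get(call.genome_id, True)),
            "rules": ",".join(call.rules),
            "has_terminase": int(f.has_terminase),
            "has_mcp": int(f.has_mcp),
            "has_tmp": int(f.has_tmp),
            "tmp_intact": int(f.tmp_intact),
            "tmp_fragment_count": f.tmp_fragment_count,
            "terminase_truncated": int(f.terminase_truncated),
            "motor_type": f.motor_type,
            "has_adapter_downstream": int(f.has_adapter_downstream),
            "has_tyrosine_recombinase": int(f.has_tyrosine_recombinase),
            "has_serine_recombinase": int(f.has_serine_recombinase),
            "serine_recombinase_class": f.serine_recombinase_class,
            "has_sheath": int(f.has_sheath),
        })
    calls_df = pd.DataFrame(rows)

    tallies = Counter(c.state for c in calls)
    n = max(len(calls), 1)
    counts_df = pd.DataFrame([
        {"state": s, "count": tallies.get(s, 0),
         "percent": round(100.0 * tallies.get(s, 0) / n, 2)}
        for s in STATES
    ])
    if calls_path is not None:
        calls_df.to_csv(calls_path, sep="\t", index=False)
    if counts_path is not None:
        counts_df.to_csv(counts_path, sep="\t", index=False)
    return calls_df, counts_df
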