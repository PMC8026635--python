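"""Feature extraction and the prophage-state rule cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasphage import classify as clf
from plasphage.classify import (ACTIVE, DEGENERATED, MYO, NON_PHAGE, SIPHO,
                                UNDETERMINED, VIRULENT, FeatureConfig,
                                GeneFeatureSet, classify, extract_features,
                                report_calls)
from plasphage.hmm import HmmHit
from plasphage.records import PlasmidRecord, ProteinRecord


def _features(**kw):
    return GeneFeatureSet(**kw)


class TestRuleCascade:
    def test_intact_prophage_with_partitioning_system(self):
        call = classify("g", _features(
            has_terminase=True, has_mcp=True, has_tmp=True, tmp_intact=True,
            motor_type="parM", has_adapter_downstream=True,
            has_tyrosine_recombinase=True))
        assert call.state == ACTIVE
        assert call.morphotype == SIPHO
        assert call.rules == ["R4"]

    def test_no_partitioning_no_recombinase_is_virulent(self):
        call = classify("g", _features(has_terminase=True, has_mcp=True,
                                       has_tmp=True, tmp_intact=True))
        assert call.state == VIRULENT

    def test_split_tmp_is_degenerated(self):
        call = classify("g", _features(
            has_terminase=True, has_mcp=True, has_tmp=True, tmp_intact=False,
            tmp_fragment_count=2, motor_type="parA"))
        assert call.state == DEGENERATED
        assert call.rules == ["R3"]

    def test_truncated_terminase_is_degenerated(self):
        call = classify("g", _features(
            has_terminase=True, has_mcp=True, has_tmp=True, tmp_intact=True,
            terminase_truncated=True, has_serine_recombinase=True,
            serine_recombinase_class="small_resolvase_invertase"))
        assert call.state == DEGENERATED

    def test_missing_signature_is_non_phage(self):
        assert classify("g", _features(motor_type="parA")).state == NON_PHAGE
        assert classify("g", _features(has_terminase=True)).state == NON_PHAGE

    def test_sheath_forces_myovirus(self):
        call = classify("g", _features(
            has_terminase=True, has_mcp=True, has_tmp=True, tmp_intact=True,
            motor_type="tubZ", has_sheath=True))
        assert call.morphotype == MYO

    def test_no_tail_markers_undetermined(self):
        call = classify("g", _features(has_terminase=True, has_mcp=True,
                                       motor_type="parA"))
        assert call.morphotype == UNDETERMINED


@st.composite
def feature_sets(draw):
    has_tmp = draw(st.booleans())
    motor = draw(st.sampled_from(["none", "parA", "parM", "tubZ"]))
    return GeneFeatureSet(
        has_terminase=draw(st.booleans()),
        has_mcp=draw(st.booleans()),
        has_tmp=has_tmp,
        tmp_intact=draw(st.booleans()) if has_tmp else False,
        tmp_fragment_count=draw(st.integers(0, 4)),
        terminase_truncated=draw(st.booleans()),
        motor_type=motor,
        has_adapter_downstream=(draw(st.booleans()) if motor != "none" else False),
        has_tyrosine_recombinase=draw(st.booleans()),
        has_serine_recombinase=draw(st.booleans()),
        serine_recombinase_class=draw(st.sampled_from(
            ["none", "small_resolvase_invertase", "large_integrase_like"])),
        has_sheath=draw(st.booleans()),
    )


@settings(max_examples=300, derandomize=True, deadline=None)
@given(feature_sets())
def test_classify_is_pure_and_total(features):
    """Every feature set maps to exactly one state, deterministically."""
    c1 = classify("g", features)
    c2 = classify("g", features)
    assert c1.state in (ACTIVE, DEGENERATED, VIRULENT, NON_PHAGE)
    assert c1.state == c2.state and c1.morphotype == c2.morphotype
    assert len(c1.rules) == 1


def _hit(pid, profile, cov=0.95):
    return HmmHit(protein_id=pid, genome_id="g", profile_name=profile,
                  bit_score=100.0, evalue=None, match_state_coverage=cov,
                  region=(1, 10))


def _prot(pid, start, length_aa, strand="+"):
    return ProteinRecord(id=pid, genome_id="g", start=start,
                         end=start + 3 * length_aa + 2, strand=strand,
                         sequence="A" * length_aa)


class TestExtractFeatures:
    GENOME = PlasmidRecord(id="g", sequence="A" * 50_000)

    def test_split_tmp_fragments(self):
        proteins = [_prot("p1", 100, 313), _prot("p2", 1100, 669)]
        hits = {"p1": [_hit("p1", "tape_measure_protein")],
                "p2": [_hit("p2", "tape_measure_protein")]}
        f = extract_features(self.GENOME, proteins, hits)
        assert f.has_tmp and not f.tmp_intact
        assert f.tmp_fragment_count == 2

    def test_small_serine_recombinase_class(self):
        proteins = [_prot("p1", 100, 195)]
        hits = {"p1": [_hit("p1", "serine_recombinase")]}
        f = extract_features(self.GENOME, proteins, hits)
        assert f.serine_recombinase_class == "small_resolvase_invertase"

    def test_large_serine_recombinase_class(self):
        proteins = [_prot("p1", 100, 450)]
        hits = {"p1": [_hit("p1", "serine_recombinase")]}
        f = extract_features(self.GENOME, proteins, hits)
        assert f.serine_recombinase_class == "large_integrase_like"

    def test_no_motor_means_no_adapter(self):
        proteins = [_prot("p1", 100, 90)]
        f = extract_features(self.GENOME, proteins, {})
        assert f.motor_type == "none"
        assert not f.has_adapter_downstream

    def test_adapter_downstream_same_strand(self):
        proteins = [_prot("m", 100, 330), _prot("adp", 1200, 90)]
        hits = {"m": [_hit("m", "parM")]}
        f = extract_features(self.GENOME, proteins, hits)
        assert f.motor_type == "parM"
        assert f.has_adapter_downstream

    def test_adapter_on_other_strand_ignored(self):
        proteins = [_prot("m", 100, 330), _prot("adp", 1200, 90, strand="-")]
        hits = {"m": [_hit("m", "parM")]}
        f = extract_features(self.GENOME, proteins, hits)
        assert not f.has_adapter_downstream

    def test_truncated_terminase_flag(self):
        proteins = [_prot("p1", 100, 294)]
        hits = {"p1": [_hit("p1", "terminase", cov=0.70)]}
        f = extract_features(self.GENOME, proteins, hits)
        assert f.terminase_truncated

    def test_cds_outside_genome_rejected(self):
        proteins = [_prot("p1", 49_990, 100)]
        with pytest.raises(ValueError):
            extract_features(self.GENOME, proteins, {})


class TestReport:
    def test_counts_match_rows_and_percentages(self, tmp_path):
        calls = [classify(f"g{i}", _features(has_terminase=True, has_mcp=True,
                                             motor_type="parA"))
                 for i in range(3)]
        calls += [classify("g9", _features())]
        calls_df, counts_df = report_calls(
            calls, None, tmp_path / "calls.tsv", tmp_path / "counts.tsv")
        assert len(calls_df) == 4
        assert counts_df["count"].sum() == 4
        assert counts_df["percent"].sum() == pytest.approx(100.0)
        by_state = dict(zip(counts_df.state, counts_df["count"]))
        assert by_state[ACTIVE] == 3 and by_state[NON_PHAGE] == 1


def test_calls_match_planted_states(default_run):
    """Per-genome state and morphotype equal the planted truth exactly."""
    truth = default_run.dataset.truth
    base = truth[truth.is_duplicate == 0].set_index("genome_id")
    calls = {c.genome_id: c for c in default_run.calls}
    assert set(calls) == set(base.index)
    for gid, row in base.iterrows():
        assert calls[gid].state == row.planted_state, gid
        assert calls[gid].morphotype == row.planted_morphotype, gid
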