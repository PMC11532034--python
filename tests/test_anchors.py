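"""Membrane-anchor detection: scores, scans and MAD calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alpscan import ProteinRecord
from alpscan.anchors import (
    FAUCHERE_PLISKA,
    KYTE_DOOLITTLE,
    HelixCandidate,
    HelixKind,
    HydrophobicityScale,
    MotifClass,
    MotifSide,
    Terminal,
    call_mads,
    detect_amphipathic,
    detect_short_hydrophobic,
    detect_tm_segments,
    hydrophobic_moment,
    mean_hydrophobicity,
    resolve_overlaps,
    scan_dibasic_motifs,
)

from conftest import interval_coverage

AA = "ACDEFGHIKLMNPQRSTVWY"


def moment_oracle(segment: str, scale=FAUCHERE_PLISKA, delta_deg=100.0) -> float:
    """Independent trigonometric route: sqrt((Σh·cos)² + (Σh·sin)²)/N."""
    d = math.radians(delta_deg)
    cos_sum = sum(scale[r] * math.cos(k * d) for k, r in enumerate(segment))
    sin_sum = sum(scale[r] * math.sin(k * d) for k, r in enumerate(segment))
    return math.hypot(cos_sum, sin_sum) / len(segment)


class TestScores:
    def test_glycine_homopolymer_scores_zero(self):
        # Fauchère-Pliška is transfer free energy relative to Gly
        assert mean_hydrophobicity("G" * 18, FAUCHERE_PLISKA) == 0.0

    @pytest.mark.parametrize("residue", list(AA))
    def test_homopolymer_mean_equals_scale_value(self, residue):
        assert mean_hydrophobicity(residue * 7, FAUCHERE_PLISKA) == pytest.approx(
            FAUCHERE_PLISKA[residue]
        )

    def test_hand_summed_mean(self):
        seg = "LILFLILFLI"
        expected = sum(FAUCHERE_PLISKA[r] for r in seg) / 10
        assert mean_hydrophobicity(seg) == pytest.approx(expected)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            mean_hydrophobicity("")
        with pytest.raises(ValueError):
            hydrophobic_moment("")

    @pytest.mark.parametrize("residue", list(AA))
    def test_homopolymer_18mer_moment_is_zero(self, residue):
        # 18 × 100° = 1800° ≡ 0 (mod 360°): unit vectors cancel exactly
        assert hydrophobic_moment(residue * 18) == pytest.approx(0.0, abs=1e-12)

    def test_single_residue_moment_is_scale_magnitude(self):
        assert hydrophobic_moment("W") == pytest.approx(abs(FAUCHERE_PLISKA["W"]))
        assert hydrophobic_moment("R") == pytest.approx(abs(FAUCHERE_PLISKA["R"]))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.text(alphabet=AA, min_size=1, max_size=30))
    def test_moment_matches_brute_force_oracle(self, segment):
        assert hydrophobic_moment(segment) == pytest.approx(
            moment_oracle(segment), abs=1e-12
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.text(alphabet=AA, min_size=2, max_size=24))
    def test_moment_invariant_under_reversal_with_angle_negation(self, segment):
        assert hydrophobic_moment(segment, delta_deg=100.0) == pytest.approx(
            hydrophobic_moment(segment[::-1], delta_deg=-100.0), abs=1e-12
        )

    def test_mean_is_translation_covariant_and_moment_translation_free(self):
        # adding a constant c to every scale value shifts the mean by c and
        # leaves any homopolymer-window moment unchanged
        c = 1.37
        shifted = HydrophobicityScale(
            "shifted", {aa: FAUCHERE_PLISKA[aa] + c for aa in AA}
        )
        seg = "LILFSTNQ"
        assert mean_hydrophobicity(seg, shifted) == pytest.approx(
            mean_hydrophobicity(seg, FAUCHERE_PLISKA) + c
        )
        assert hydrophobic_moment("A" * 18, shifted) == pytest.approx(0.0, abs=1e-12)


class TestTMDetection:
    def test_polyserine_has_no_tm(self):
        assert detect_tm_segments(ProteinRecord(id="p", sequence="S" * 100)) == []

    def test_sequence_shorter_than_window_yields_empty(self):
        assert detect_tm_segments(ProteinRecord(id="p", sequence="L" * 10)) == []

    def test_planted_n_terminal_helix_recovered(self):
        # 23-mer poly-Leu at 5-27 in a polar context
        seq = "S" * 4 + "L" * 23 + "S" * 73
        cands = detect_tm_segments(ProteinRecord(id="p", sequence=seq))
        assert len(cands) == 1
        cand = cands[0]
        assert cand.terminal is Terminal.N
        assert interval_coverage((5, 27), [(cand.start, cand.end)]) >= 0.9

    def test_anchors_at_both_termini(self):
        seq = "L" * 23 + "S" * 200 + "L" * 23
        cands = detect_tm_segments(ProteinRecord(id="p", sequence=seq))
        assert [c.terminal for c in cands] == [Terminal.N, Terminal.C]


class TestShortHydrophobic:
    def test_n_terminal_short_helix(self):
        seq = "SS" + "LLFILLIVLLFI" + "S" * 80
        cands = detect_short_hydrophobic(ProteinRecord(id="p", sequence=seq), tm=[])
        assert len(cands) >= 1
        assert cands[0].kind is HelixKind.SHORT_HYDROPHOBIC
        assert cands[0].mean_hydrophobicity > 1.0

    def test_polyglycine_yields_nothing(self):
        rec = ProteinRecord(id="p", sequence="G" * 80)
        assert detect_short_hydrophobic(rec, tm=[]) == []

    def test_segment_inside_tm_not_reported_twice(self):
        seq = "S" * 4 + "L" * 23 + "S" * 73
        rec = ProteinRecord(id="p", sequence=seq)
        tm = detect_tm_segments(rec)
        assert tm
        shorts = detect_short_hydrophobic(rec, tm=tm)
        assert all(
            not (t.start <= c.start and c.end <= t.end) for c in shorts for t in tm
        )


class TestAmphipathic:
    def test_homopolymer_terminus_yields_nothing(self):
        rec = ProteinRecord(id="p", sequence="L" * 18 + "G" * 50)
        cands = detect_amphipathic(rec)
        assert all(c.start != 1 for c in cands)

    def test_planted_ideal_amphipathic_18mer(self):
        helix = "".join("L" if (i * 100) % 360 < 180 else "S" for i in range(18))
        rec = ProteinRecord(id="p", sequence=helix + "G" * 60)
        cands = detect_amphipathic(rec)
        assert len(cands) >= 1
        assert cands[0].hydrophobic_moment >= 0.5
        assert interval_coverage((1, 18), [(c.start, c.end) for c in cands]) >= 0.5

    def test_amphipathic_only_anchor_without_tm(self):
        # a protein whose sole anchor is an amphipathic helix still gets a MAD
        helix = "".join("L" if (i * 100) % 360 < 180 else "S" for i in range(18))
        rec = ProteinRecord(id="p", sequence=helix + "G" * 100)
        tm = detect_tm_segments(rec)
        assert tm == []
        mads = call_mads(rec, tm, detect_short_hydrophobic(rec, tm=tm), detect_amphipathic(rec))
        assert len(mads) >= 1


class TestDiBasic:
    def _tm_at(self, record, start, end):
        return HelixCandidate(
            protein_id=record.id, start=start, end=end, kind=HelixKind.TM,
            mean_hydrophobicity=3.0, hydrophobic_moment=0.1,
            terminal=Terminal.N if start <= 40 else Terminal.C,
        )

    def test_di_lysine_upstream_of_n_helix(self):
        rec = ProteinRecord(id="p", sequence="MKK" + "L" * 20 + "S" * 40)
        motifs = scan_dibasic_motifs(rec, [self._tm_at(rec, 4, 23)])
        assert len(motifs) == 1
        m = motifs[0]
        assert m.motif_class is MotifClass.DI_LYSINE
        assert m.position == 2 and m.pair == "KK"
        assert m.side is MotifSide.UPSTREAM_OF_N_HELIX

    def test_lys_asn_substitution_variant(self):
        rec = ProteinRecord(id="p", sequence="MKN" + "L" * 20 + "S" * 40)
        motifs = scan_dibasic_motifs(rec, [self._tm_at(rec, 4, 23)])
        assert motifs[0].motif_class is MotifClass.LYS_ASN

    def test_other_variant_pairs(self):
        rec = ProteinRecord(id="p", sequence="MRD" + "L" * 20 + "S" * 40)
        motifs = scan_dibasic_motifs(rec, [self._tm_at(rec, 4, 23)])
        assert motifs[0].motif_class is MotifClass.OTHER_VARIANT

    def test_no_basic_residues_in_flank(self):
        rec = ProteinRecord(id="p", sequence="MST" + "L" * 20 + "S" * 40)
        assert scan_dibasic_motifs(rec, [self._tm_at(rec, 4, 23)]) == []

    def test_downstream_of_c_terminal_helix(self):
        seq = "S" * 40 + "L" * 20 + "KK" + "S"
        rec = ProteinRecord(id="p", sequence=seq)
        motifs = scan_dibasic_motifs(rec, [self._tm_at(rec, 41, 60)])
        assert motifs and motifs[0].side is MotifSide.DOWNSTREAM_OF_C_HELIX


class TestCallMads:
    def test_union_of_candidate_kinds(self):
        # one short N-terminal helix plus one internal TM -> two MADs
        seq = "SS" + "LLFLLFLLFLL" + "S" * 30 + "L" * 23 + "S" * 30
        rec = ProteinRecord(id="p", sequence=seq)
        tm = detect_tm_segments(rec)
        short = detect_short_hydrophobic(rec, tm=tm)
        mads = call_mads(rec, tm, short, [])
        assert len(mads) == 2
        assert interval_coverage((3, 13), [(m.start, m.end) for m in mads]) >= 0.8
        assert interval_coverage((44, 66), [(m.start, m.end) for m in mads]) >= 0.8

    def test_zero_candidates_zero_mads(self):
        rec = ProteinRecord(id="p", sequence="S" * 150)
        assert call_mads(rec, [], [], []) == []

    def test_duplicated_n_terminal_helix_gives_two_mads(self):
        seq = "L" * 23 + "SSDDNNDDNNSS" + "L" * 23 + "S" * 100
        rec = ProteinRecord(id="p", sequence=seq)
        tm = detect_tm_segments(rec)
        mads = call_mads(rec, tm, [], [])
        assert len(mads) == 2
        assert all(m.start <= 60 for m in mads)

    def test_priority_suppresses_overlapping_lower_kind(self):
        tm = HelixCandidate("p", 1, 23, HelixKind.TM, 3.8, 0.1, Terminal.N)
        amph = HelixCandidate("p", 5, 22, HelixKind.AMPHIPATHIC, 0.9, 0.7, Terminal.N)
        kept = resolve_overlaps([tm, amph])
        assert [c.kind for c in kept] == [HelixKind.TM]


class TestPlantedRecovery:
    def test_planted_tm_sensitivity_on_synthetic_proteome(self, proteome):
        """≥95% of planted TM anchors recovered at ≥80% boundary coverage."""
        planted = recovered = 0
        for truth in proteome["truths"]:
            record = proteome["records_by_id"][truth.protein_id]
            detected = [
                (c.start, c.end) for c in detect_tm_segments(record)
            ]
            for s, e, kind in truth.anchors:
                if kind != "TM":
                    continue
                planted += 1
                if interval_coverage((s, e), detected) >= 0.8:
                    recovered += 1
        assert planted > 50
        assert recovered / planted >= 0.95
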