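"""Motif scanning and conservation-profile behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ahltools.motifs import (
    LOG2_20,
    build_profile,
    mismatches,
    scan_at_hooks,
    scan_ppc,
    score_window,
)
from ahltools.records import AMINO_ACIDS, MotifClass, ProteinRecord

from conftest import protein


# Constructed PPC fixtures: 4-mer prefix + 40 filler + upstream
# tripeptide + GRFEIL anchor + 77 filler = 130 residues.
PPC_A_SEQ = "LRSH" + "A" * 40 + "TKH" + "GRFEIL" + "A" * 77
PPC_B_SEQ = "FTPH" + "A" * 40 + "TYE" + "GRFEIL" + "A" * 77


class TestScanAtHooks:
    def test_type_i_hit_with_gsknk_context(self):
        hits = scan_at_hooks(protein("MKKRPRGRPAGSKNKPKA"))
        assert len(hits) == 1
        (hit,) = hits
        assert hit.motif_class is MotifClass.AT_HOOK_I
        assert hit.anchor_pos == 5
        assert hit.start == 5 and hit.end == 15
        assert hit.matched == "RGRPAGSKNK"

    def test_type_ii_hit_with_rky_context(self):
        hits = scan_at_hooks(protein("MAAARGRPKRKYQQA"))
        assert len(hits) == 1
        (hit,) = hits
        assert hit.motif_class is MotifClass.AT_HOOK_II
        assert hit.anchor_pos == 4

    def test_no_core_no_hit(self):
        assert scan_at_hooks(protein("MAAAAAAAAAA")) == []

    def test_core_without_typed_context_yields_nothing(self):
        assert scan_at_hooks(protein("MRGRAAAAAAAAAAAAAAAA")) == []

    def test_gsknk_one_mismatch_still_type_i(self):
        hits = scan_at_hooks(protein("MKKRPRGRPAGSKNRPKA"))
        assert [h.motif_class for h in hits] == [MotifClass.AT_HOOK_I]

    def test_rky_must_be_exact(self):
        # RKF is one mismatch from RKY: no Type-II hit.
        assert scan_at_hooks(protein("MAAARGRPKRKFQQA")) == []

    def test_context_outside_window_not_counted(self):
        seq = "MKKRPRGR" + "A" * 11 + "GSKNK"
        assert scan_at_hooks(protein(seq), window=10) == []
        assert len(scan_at_hooks(protein(seq), window=12)) == 1

    def test_window_below_minimum_rejected(self):
        with pytest.raises(ValueError, match="window"):
            scan_at_hooks(protein("MKKRPRGRPAGSKNKPKA"), window=4)

    def test_invalid_residue_error_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            ProteinRecord(id="bad", species="At", sequence="MKKZRGR")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ProteinRecord(id="bad", species="At", sequence="")

    def test_x_never_matches_a_signature_position(self):
        # X inside the core or consuming the full context budget kills the hit.
        assert scan_at_hooks(protein("MKKRPRGXPAGSKNKPKA")) == []
        # X in the context uses the single mismatch; a second difference kills it.
        assert len(scan_at_hooks(protein("MKKRPRGRPAGSKNXPKA"))) == 1
        assert scan_at_hooks(protein("MKKRPRGRPAGSRNXPKA")) == []


class TestScanPpc:
    @pytest.mark.parametrize(
        "seq,expected",
        [(PPC_A_SEQ, MotifClass.PPC_A), (PPC_B_SEQ, MotifClass.PPC_B)],
    )
    def test_typed_domains(self, seq, expected):
        hits = scan_ppc(protein(seq))
        assert len(hits) == 1
        (hit,) = hits
        assert hit.motif_class is expected
        assert hit.anchor_pos == 47
        assert hit.start == 0 and hit.end == min(len(seq), 47 + 6 + 60)

    def test_anchor_without_typing_evidence_is_untyped(self):
        seq = "A" * 70 + "GRFEIL" + "A" * 70
        hits = scan_ppc(protein(seq))
        assert [h.motif_class for h in hits] == [MotifClass.PPC_UNTYPED]

    def test_conflicting_evidence_is_untyped_not_tiebroken(self):
        # Upstream TKE is one mismatch from both TKH and TYE.
        seq = "A" * 70 + "TKE" + "GRFEIL" + "A" * 70
        hits = scan_ppc(protein(seq))
        assert [h.motif_class for h in hits] == [MotifClass.PPC_UNTYPED]

    def test_no_anchor_no_hit(self):
        assert scan_ppc(protein("A" * 130)) == []

    def test_anchor_tolerates_one_mismatch(self):
        seq = "LRSH" + "A" * 40 + "TKH" + "GRFEIV" + "A" * 77
        hits = scan_ppc(protein(seq))
        assert [h.motif_class for h in hits] == [MotifClass.PPC_A]

    def test_span_below_minimum_rejected(self):
        with pytest.raises(ValueError, match="span"):
            scan_ppc(protein(PPC_A_SEQ), span=30)


class TestScanProperties:
    def test_hits_are_position_faithful_and_sorted(self):
        seq = "MKKRPRGRPAGSKNKPKA" + "A" * 30 + PPC_A_SEQ
        rec = protein(seq)
        hits = scan_at_hooks(rec) + scan_ppc(rec)
        for hit in hits:
            assert hit.matched == seq[hit.start:hit.end]
            assert hit.start <= hit.anchor_pos < hit.end

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(k=st.integers(min_value=0, max_value=80))
    def test_shift_equivariance_under_prepended_filler(self, k):
        # Interior hits with >= span margin shift rigidly with padding.
        base = "MKKRPRGRPAGSKNKPKA" + "A" * 62 + "TKH" + "GRFEIL" + "A" * 70
        rec0, reck = protein(base), protein("A" * k + base)
        for scan in (scan_at_hooks, scan_ppc):
            h0, hk = scan(rec0), scan(reck)
            assert len(h0) == len(hk) > 0
            for a, b in zip(h0, hk):
                assert (b.start, b.end, b.anchor_pos) == (
                    a.start + k, a.end + k, a.anchor_pos + k
                )
                assert (b.motif_class, b.score, b.matched) == (
                    a.motif_class, a.score, a.matched
                )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=160))
    def test_random_sequences_scan_cleanly(self, seq):
        rec = ProteinRecord(id="r", species="At", sequence=seq)
        for scan in (scan_at_hooks, scan_ppc):
            hits = scan(rec)
            assert hits == scan(rec)  # deterministic
            for i in range(len(hits) - 1):
                assert hits[i].end <= hits[i + 1].start  # sorted, non-overlapping
            for hit in hits:
                assert hit.matched == seq[hit.start:hit.end]

    def test_overlapping_cores_resolved_to_single_hit(self):
        # RGRGR holds two RGR cores sharing one GSKNK context.
        hits = scan_at_hooks(protein("MRGRGRPAGSKNKAA"))
        assert len(hits) == 1


class TestProfiles:
    def test_point_mass_columns_fully_conserved(self):
        prof = build_profile(["RGR", "RGR", "RGR"])
        assert prof.n_sequences == 3
        assert np.allclose(prof.conservation, LOG2_20, atol=1e-12)
        r_idx = AMINO_ACIDS.index("R")
        assert prof.freqs[0, r_idx] == 1.0

    def test_four_way_uniform_column(self):
        prof = build_profile(["A", "C", "G", "Y"])
        for aa in "ACGY":
            assert prof.freqs[0, AMINO_ACIDS.index(aa)] == pytest.approx(0.25)
        assert prof.conservation[0] == pytest.approx(LOG2_20 - 2.0, abs=1e-12)

    def test_single_instance_degenerate_profile(self):
        prof = build_profile(["GSKNK"])
        assert prof.n_sequences == 1
        assert np.allclose(prof.conservation, LOG2_20)

    def test_ragged_and_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["RGR", "RG"])
        with pytest.raises(ValueError):
            build_profile([])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet=AMINO_ACIDS, min_size=4, max_size=4),
                    min_size=1, max_size=12))
    def test_profile_invariants(self, instances):
        prof = build_profile(instances)
        assert np.allclose(prof.freqs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(prof.conservation >= -1e-12)
        assert np.all(prof.conservation <= LOG2_20 + 1e-12)
        for j in range(prof.n_columns):
            single = np.count_nonzero(prof.freqs[j]) == 1
            maximal = prof.conservation[j] == pytest.approx(LOG2_20, abs=1e-9)
            assert single == maximal


class TestScoreWindow:
    def test_perfect_match_against_point_mass(self):
        prof = build_profile(["RGR"])
        score = score_window("RGR", prof, pseudocount=0.0)
        assert score == pytest.approx(3 * LOG2_20)

    def test_uniform_profile_scores_zero(self):
        uniform = np.full((4, 20), 0.05)
        from ahltools.motifs import MotifProfile

        prof = MotifProfile(freqs=uniform, n_sequences=1)
        assert score_window("ACDE", prof, pseudocount=0.0) == pytest.approx(0.0)

    def test_mismatch_with_pseudocount_matches_direct_formula(self):
        prof = build_profile(["RGR"])
        score = score_window("AAA", prof, pseudocount=0.01)
        # Independent computation: f' = (0 + 0.01) / (1 + 20 * 0.01).
        expected = 3 * math.log2((0.01 / 1.2) / 0.05)
        assert score == pytest.approx(expected, abs=1e-12)
        assert score < 0 and math.isfinite(score)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            score_window("AAAA", build_profile(["RGR"]))

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            score_window("AXA", build_profile(["RGR"]))


def test_mismatch_counter_requires_equal_lengths():
    with pytest.raises(ValueError):
        mismatches("AA", "AAA")
    assert mismatches("GSKNK", "GSKNK") == 0
    assert mismatches("XSKNK", "GSKNK") == 1
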