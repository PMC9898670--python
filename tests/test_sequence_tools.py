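"""Sequence parsing and the physical quantities derived from composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hyp_st

from helixfit import sequence_tools as st
from helixfit.sequence_tools import (BufferConditions, PeptideChain,
                                     PeptideParseError, SedCoefficient)
from conftest import TABLE_SEQUENCES


class TestParsing:
    def test_repeat_expansion_and_blocking(self):
        c = st.parse_peptide("Ac-(POG)10-NH2")
        assert len(c) == 30
        assert c.n_block == "acetyl" and c.c_block == "amide"
        assert "".join(c.residues) == "POG" * 10

    def test_unblocked_peptide(self):
        c = st.parse_peptide("(PPG)10")
        assert len(c) == 30
        assert c.n_block == "free" and c.c_block == "free"

    def test_mixed_literal_and_repeat_segments(self):
        c = st.parse_peptide("Ac-(POG)4-QG-(POG)5-NH2")
        assert len(c) == 29
        assert c.residues[12:14] == ("Q", "G")

    @pytest.mark.parametrize("bad", [
        "Ac-(POG)0-NH2",          # degenerate repeat -> empty
        "",                       # empty spec
        "Ac-(POG)x-NH2",          # malformed repeat count
        "Ac-(POG)4-QZ-(POG)5-NH2",  # Z is not a residue
    ])
    def test_malformed_specs_raise(self, bad):
        with pytest.raises(PeptideParseError):
            st.parse_peptide(bad)

    def test_error_names_offending_token(self):
        with pytest.raises(PeptideParseError, match="Z"):
            st.parse_peptide("Ac-POZ-POG-POG-NH2")

    @pytest.mark.parametrize("spec", list(TABLE_SEQUENCES.values()))
    def test_render_roundtrip(self, spec):
        c = st.parse_peptide(spec)
        assert st.parse_peptide(st.render_peptide(c)) == c


class TestMass:
    def test_trivial_single_gly_chain(self):
        c = PeptideChain(("G",) * 6)
        # per chain: 6 residues + one water
        expected = 3 * (6 * 57.0519 + 18.0153)
        assert st.trimer_mass(c) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("name,expected", [
        ("(POG)10", 8194.0), ("MBL-C", 7949.0), ("G>A", 8236.0),
        ("MBL-N", 8179.0), ("MBL-E", 9019.0), ("MBL-12", 10574.0),
    ])
    def test_printed_trimer_masses(self, name, expected):
        c = st.parse_peptide(TABLE_SEQUENCES[name])
        assert st.trimer_mass(c) == pytest.approx(expected, rel=1e-3)

    def test_mass_additivity_on_concatenation(self):
        a = st.parse_peptide("(POG)4")
        b = st.parse_peptide("(PQG)3")
        ab = PeptideChain(a.residues + b.residues)
        # joining unblocked chains releases one water per chain
        assert st.trimer_mass(ab) == pytest.approx(
            st.trimer_mass(a) + st.trimer_mass(b) - 3 * 18.0153, abs=1e-6)


class TestPartialSpecificVolume:
    @pytest.mark.parametrize("name,expected", [
        ("(POG)10", 0.735), ("(PPG)10", 0.735), ("T3-785", 0.741),
        ("MBL-C", 0.730), ("MBL-N", 0.729), ("G>A", 0.738),
    ])
    def test_printed_vbar_values(self, name, expected):
        c = st.parse_peptide(TABLE_SEQUENCES[name])
        assert st.partial_specific_volume(c) == pytest.approx(expected,
                                                              abs=0.003)

    def test_pog_and_ppg_identical_under_pro_substitution(self):
        pog = st.parse_peptide("Ac-(POG)10-NH2")
        ppg = st.parse_peptide("Ac-(PPG)10-NH2")
        assert st.partial_specific_volume(pog) == pytest.approx(
            st.partial_specific_volume(ppg), abs=1e-12)

    def test_homopolymer_recovers_tabulated_volume(self):
        from helixfit.residues import (RESIDUE_MASS, RESIDUE_VOLUME,
                                       A3_TO_ML_PER_MOL)
        c = PeptideChain(("A",) * 12)
        expected = RESIDUE_VOLUME["A"] * A3_TO_ML_PER_MOL / RESIDUE_MASS["A"]
        got = st.partial_specific_volume(c, include_chain_ends=False)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_vbar_invariant_under_permutation(self):
        c1 = st.parse_peptide("(POG)3-QERLIT")
        c2 = PeptideChain(tuple(sorted(c1.residues)))
        assert st.partial_specific_volume(c1) == pytest.approx(
            st.partial_specific_volume(c2), abs=1e-12)

    @pytest.mark.parametrize("spec", list(TABLE_SEQUENCES.values()))
    def test_vbar_in_physical_range(self, spec):
        v = st.partial_specific_volume(st.parse_peptide(spec))
        assert 0.59 <= v <= 0.78


class TestExtinction:
    def test_tyr_free_helix_at_280(self):
        assert st.extinction_coefficient(
            st.parse_peptide("Ac-(POG)10-NH2"), 280) == 0.0

    def test_single_tyr_at_280(self):
        c = PeptideChain(("P", "O", "G", "Y", "P", "G"))
        assert st.extinction_coefficient(c, 280) == 3 * 1280

    def test_unblocked_ppg10_at_214(self):
        # 29 bonds per chain, three chains
        c = st.parse_peptide("(PPG)10")
        assert st.extinction_coefficient(c, 214) == 2200 * 29 * 3

    def test_blocked_termini_add_amide_bonds(self):
        c = st.parse_peptide("Ac-(POG)10-NH2")
        assert st.extinction_coefficient(c, 214) == 2200 * 31 * 3

    def test_unsupported_wavelength(self):
        with pytest.raises(ValueError):
            st.extinction_coefficient(st.parse_peptide("(PPG)10"), 260)


class TestSedimentationCorrection:
    def test_water_at_20C_is_identity(self):
        buf = BufferConditions(density=st.RHO_20W, viscosity=st.ETA_20W)
        out = st.correct_s_to_standard(SedCoefficient(1.23), buf, 0.73)
        assert out.s == pytest.approx(1.23, rel=1e-12)

    def test_heavy_water_buffer_hand_substitution(self):
        # hand evaluation of the correction with the printed heavy-water
        # buffer constants (rho = 1.11100 g/ml, eta = 0.01384 P), vbar 0.735
        buf = BufferConditions(density=1.11100, viscosity=0.01384)
        vbar = 0.735
        expected = 1.00 * (0.01384 / 0.010020) * \
            (1 - vbar * 0.99823) / (1 - vbar * 1.11100)
        out = st.correct_s_to_standard(SedCoefficient(1.00), buf, vbar)
        assert out.s == pytest.approx(expected, rel=1e-12)

    def test_neutral_buoyancy_raises(self):
        buf = BufferConditions(density=1.0 / 0.735, viscosity=0.01)
        with pytest.raises(ZeroDivisionError):
            st.correct_s_to_standard(SedCoefficient(1.0), buf, 0.735)

    def test_sign_flip_raises(self):
        buf = BufferConditions(density=1.40, viscosity=0.01)
        with pytest.raises(ValueError):
            st.correct_s_to_standard(SedCoefficient(1.0), buf, 0.735)

    @settings(deadline=None, max_examples=30)
    @given(s=hyp_st.floats(0.1, 20.0),
           rho=hyp_st.floats(0.99, 1.12),
           eta=hyp_st.floats(0.009, 0.018),
           vbar=hyp_st.floats(0.60, 0.78))
    def test_correction_is_invertible(self, s, rho, eta, vbar):
        buf = BufferConditions(density=rho, viscosity=eta)
        std_buf = BufferConditions(density=st.RHO_20W, viscosity=st.ETA_20W)
        fwd = st.correct_s_to_standard(SedCoefficient(s), buf, vbar)
        # applying the inverse multiplicative factor recovers the input
        back = fwd.s * (st.ETA_20W / eta) * \
            (1 - vbar * rho) / (1 - vbar * st.RHO_20W)
        assert back == pytest.approx(s, rel=1e-9)
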