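"""Peptide mass arithmetic, digestion and fragment-ladder behaviour."""

import pytest
from hypothesis import given, settings, strategies as st

from nestmark.chem import (
    DEAMIDATION,
    DEFAULT_TABLE,
    OXIDATION,
    PROTON,
    WATER,
    PeptideSequence,
    ResidueTable,
    UnknownResidueError,
    fragment_ladder,
    modification_hypotheses,
    monoisotopic_mass,
    ppm_error,
    precursor_mz,
    tryptic_digest,
)

AMINO = "ACDEFGHIKLMNPQRSTVWY"
peptides = st.text(alphabet=AMINO, min_size=2, max_size=12)


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "sequence,expected",
        [
            ("G", 75.03203),  # single residue + water
            ("VSAPGPVLTR", 995.57636),  # hand-summed 10 residues + water
        ],
    )
    def test_known_masses(self, sequence, expected):
        assert monoisotopic_mass(sequence) == pytest.approx(expected, abs=5e-5)

    def test_oxidized_tryptophan_adds_delta(self):
        plain = monoisotopic_mass("SDDSLWR")
        modified = PeptideSequence("SDDSLWR", ((5, OXIDATION),))
        assert plain == pytest.approx(877.39299, abs=5e-5)
        assert monoisotopic_mass(modified) == pytest.approx(893.38790, abs=5e-5)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(UnknownResidueError, match="'B'"):
            monoisotopic_mass("AAB")

    def test_agrees_with_pyteomics(self):
        # independent oracle: pyteomics' own monoisotopic mass computation
        from pyteomics import mass as pmass

        for seq in ("AMESINSR", "VSAPGPVLTR", "SDDSLWR", "GAVLIK"):
            assert monoisotopic_mass(seq) == pytest.approx(
                pmass.calculate_mass(sequence=seq), abs=2e-3
            )

    @settings(max_examples=50, deadline=None)
    @given(p=peptides, q=peptides)
    def test_mass_additivity(self, p, q):
        # concatenation shares one water
        assert monoisotopic_mass(p + q) == pytest.approx(
            monoisotopic_mass(p) + monoisotopic_mass(q) - WATER, abs=1e-9
        )


class TestPrecursorMz:
    def test_e7_two_plus_matches_observed_within_3ppm(self):
        mz = precursor_mz("VSAPGPVLTR", 2)
        assert mz == pytest.approx(498.7954, abs=5e-4)
        assert abs(ppm_error(498.7967, mz)) < 3.5

    def test_oxidized_g1_two_plus(self):
        pep = PeptideSequence("SDDSLWR", ((5, OXIDATION),))
        mz = precursor_mz(pep, 2)
        assert mz == pytest.approx(447.7012, abs=5e-4)
        assert abs(ppm_error(447.6996, mz)) < 5

    @settings(max_examples=30, deadline=None)
    @given(p=peptides)
    def test_singly_charged_is_mass_plus_proton(self, p):
        assert precursor_mz(p, 1) == pytest.approx(monoisotopic_mass(p) + PROTON)

    @settings(max_examples=30, deadline=None)
    @given(p=peptides, z=st.integers(min_value=1, max_value=5))
    def test_strictly_decreasing_in_charge(self, p, z):
        assert precursor_mz(p, z + 1) < precursor_mz(p, z)

    def test_rejects_nonpositive_charge(self):
        with pytest.raises(ValueError):
            precursor_mz("GAVLIK", 0)


class TestPpmError:
    @pytest.mark.parametrize(
        "observed,theoretical,expected",
        [(500.0, 500.0, 0.0), (500.005, 500.0, 10.0), (498.7967, 498.7954, 2.6)],
    )
    def test_definition(self, observed, theoretical, expected):
        assert ppm_error(observed, theoretical) == pytest.approx(expected, abs=0.05)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            ppm_error(500.0, 0.0)


class TestTrypticDigest:
    def test_cleaves_after_k_and_r(self):
        frags = [str(p) for p in tryptic_digest("AMESINSRVSAPGPVLTR")]
        assert frags == ["AMESINSR", "VSAPGPVLTR"]

    def test_proline_suppresses_cleavage(self):
        assert [str(p) for p in tryptic_digest("AKPR")] == ["AKPR"]

    def test_rejects_unknown_residue(self):
        with pytest.raises(UnknownResidueError):
            tryptic_digest("AAAKBB")

    def test_missed_cleavages_extend_the_set(self):
        zero = {str(p) for p in tryptic_digest("AKGKLR", 0)}
        one = {str(p) for p in tryptic_digest("AKGKLR", 1)}
        assert zero == {"AK", "GK", "LR"}
        assert one == zero | {"AKGK", "GKLR"}

    @settings(max_examples=50, deadline=None)
    @given(protein=st.text(alphabet=AMINO, min_size=1, max_size=60))
    def test_zero_missed_partitions_protein(self, protein):
        frags = tryptic_digest(protein, 0)
        assert "".join(str(p) for p in frags) == protein


class TestFragmentLadder:
    def test_known_y1_and_b2(self):
        ions = {i.label: i.mz for i in fragment_ladder("SDDSLWR")}
        assert ions["y1"] == pytest.approx(175.1190, abs=5e-4)  # R + water + proton
        assert ions["b2"] == pytest.approx(203.0662, abs=5e-4)  # S + D + proton

    @settings(max_examples=40, deadline=None)
    @given(p=peptides)
    def test_singly_charged_count_is_2n_minus_2(self, p):
        assert len(fragment_ladder(p, max_charge=1)) == 2 * (len(p) - 1)

    @settings(max_examples=40, deadline=None)
    @given(p=peptides)
    def test_b_y_complementarity(self, p):
        # b_i + y_{n-i} at 1+ reconstruct the precursor plus two protons
        ions = {(i.series, i.ordinal): i.mz for i in fragment_ladder(p, max_charge=1)}
        total = monoisotopic_mass(p) + 2 * PROTON
        n = len(p)
        for i in range(1, n):
            assert ions[("b", i)] + ions[("y", n - i)] == pytest.approx(total, abs=1e-9)

    def test_modification_shifts_only_its_side(self):
        plain = {i.label: i.mz for i in fragment_ladder("SDDSLWR")}
        mod = {i.label: i.mz
               for i in fragment_ladder(PeptideSequence("SDDSLWR", ((5, OXIDATION),)))}
        assert mod["b2"] == pytest.approx(plain["b2"])  # W is position 5; b2 untouched
        assert mod["y2"] == pytest.approx(plain["y2"] + OXIDATION.delta)

    def test_rejects_single_residue(self):
        with pytest.raises(ValueError):
            fragment_ladder("G")


class TestResidueTableAndMods:
    def test_constants_to_six_decimals(self):
        assert DEFAULT_TABLE.water == pytest.approx(18.010565, abs=1e-6)
        assert DEFAULT_TABLE.proton == pytest.approx(1.0072765, abs=1e-7)

    def test_builtin_modification_deltas(self):
        assert OXIDATION.delta == pytest.approx(15.994915)
        assert DEAMIDATION.delta == pytest.approx(0.984016)
        assert OXIDATION.residues == frozenset("MW")
        assert DEAMIDATION.residues == frozenset("NQ")

    def test_table_roundtrip_through_plain_text_config(self, tmp_path):
        path = tmp_path / "residues.txt"
        path.write_text("# test table\nG 57.02146\nA 71.03711\nwater 18.010565\n")
        table = ResidueTable.from_config(path)
        assert table.masses == {"G": 57.02146, "A": 71.03711}

    def test_modification_must_sit_on_compatible_residue(self):
        with pytest.raises(ValueError, match="not allowed"):
            PeptideSequence("GAVLIK", ((0, OXIDATION),))

    def test_hypotheses_cover_combined_deltas(self):
        labels = {label for label, _ in modification_hypotheses("AMESINSR")}
        assert labels == {"none", "oxidation", "deamidation", "oxidation+deamidation"}
        labels_g1 = {label for label, _ in modification_hypotheses("SDDSLWR")}
        assert labels_g1 == {"none", "oxidation"}  # no N/Q present
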