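"""Backbone fragment chemistry, enumeration, m/z and isotope patterns."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pyteomics import mass as ptmass

import rnacleave as rc
from rnacleave.chem import RESIDUES, Composition, parse_sequence
from rnacleave.fragments import (
    ION_TYPES,
    enumerate_fragments,
    fragment_composition,
    fragment_neutral_mass,
    mz_negative,
    precursor_ion,
)
from rnacleave.isotopes import (
    ISOTOPE_SPACING,
    aggregated_pattern,
    averagine_composition,
    isotope_pattern,
)


class TestFragmentMasses:
    def test_cyclic_phosphate_c4(self, rna1):
        # ACCC>p: A + 3C nucleosides + 3 linkages + cyclic phosphate
        assert fragment_neutral_mass(rna1, "c", 4) == pytest.approx(
            1244.176, abs=1e-3
        )

    def test_complementary_y14(self, rna1):
        assert fragment_neutral_mass(rna1, "y", 14) == pytest.approx(
            5764.869 - 1244.176, abs=1e-3
        )

    @pytest.mark.parametrize("number", [1, 5, 6, 9, 10, 12])
    def test_pair_conservation_all_sites(self, number):
        seq = rc.reference_rna(number)
        parent = rc.sequence_mass(seq)
        for k in range(1, len(seq)):
            for t5, t3 in (("a", "w"), ("b", "x"), ("c", "y"), ("d", "z")):
                total = fragment_neutral_mass(seq, t5, k) + fragment_neutral_mass(
                    seq, t3, len(seq) - k
                )
                assert total == pytest.approx(parent, abs=1e-6)

    def test_c_is_d_minus_water_and_z_is_y_minus_water(self, rna10):
        for k in range(1, len(rna10)):
            assert fragment_neutral_mass(rna10, "d", k) - fragment_neutral_mass(
                rna10, "c", k
            ) == pytest.approx(18.0105646, abs=1e-6)
            assert fragment_neutral_mass(rna10, "y", k) - fragment_neutral_mass(
                rna10, "z", k
            ) == pytest.approx(18.0105646, abs=1e-6)

    def test_index_out_of_range(self, rna10):
        with pytest.raises(ValueError, match="outside"):
            fragment_neutral_mass(rna10, "c", 8)


class TestEnumeration:
    def test_cy_singly_charged_count(self, rna1):
        ions = enumerate_fragments(rna1, "cy", max_charge=1)
        assert len(ions) == 34  # 17 sites x 2 types

    def test_all_types_count_octamer(self, rna10):
        ions = enumerate_fragments(rna10, "abcdwxyz", max_charge=1)
        assert len(ions) == 56  # 8 types x 7 sites

    def test_sorted_by_mz(self, rna1):
        ions = enumerate_fragments(rna1, "cy", max_charge=3)
        mz = [ion.mz for ion in ions]
        assert mz == sorted(mz)

    def test_charge_capped_by_phosphate_count(self, rna1):
        ions = enumerate_fragments(rna1, "y", max_charge=7)
        y1 = [ion for ion in ions if ion.index == 1]
        assert {ion.charge for ion in y1} == {1}  # y1 has no phosphate

    def test_single_residue_fragment_base_loss(self):
        seq = parse_sequence("GGC")
        ions = enumerate_fragments(seq, "c", max_charge=1, with_base_loss=True)
        c1 = [ion for ion in ions if ion.index == 1]
        assert len(c1) == 2  # plain + exactly one base-loss variant
        assert {ion.base_loss for ion in c1} == {None, "G"}

    def test_base_loss_deduplicated_per_base(self, rna1):
        ions = enumerate_fragments(rna1, "c", max_charge=1, with_base_loss=True)
        c4 = [ion.base_loss for ion in ions if ion.index == 4]
        # ACCC covers two distinct bases only
        assert sorted(x for x in c4 if x) == ["A", "C"]

    def test_base_loss_mass_identity(self, rna1):
        ions = enumerate_fragments(rna1, "c", max_charge=1, with_base_loss=True)
        by_key = {(ion.index, ion.base_loss): ion for ion in ions}
        parent = by_key[(4, None)]
        lost = by_key[(4, "A")]
        assert lost.neutral_mass + RESIDUES["A"].base.mass == pytest.approx(
            parent.neutral_mass, abs=1e-9
        )

    def test_empty_ion_types_rejected(self, rna1):
        with pytest.raises(ValueError, match="empty"):
            enumerate_fragments(rna1, set())

    def test_precursor_ion(self, rna1):
        ion = precursor_ion(rna1, 7)
        assert ion.mz == pytest.approx(822.545, abs=1e-3)


class TestMz:
    @pytest.mark.parametrize(
        "mass,z,expected",
        [(5764.869, 7, 822.545), (2523.388, 1, 2522.381)],
    )
    def test_negative_mode_mz(self, mass, z, expected):
        assert mz_negative(mass, z) == pytest.approx(expected, abs=1e-3)

    @given(st.floats(100.0, 10000.0), st.integers(1, 15))
    def test_round_trip(self, m, z):
        assert mz_negative(m, z) * z + z * 1.00727646 == pytest.approx(m, rel=1e-12)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            mz_negative(1000.0, 0)


class TestIsotopePatterns:
    def test_monoisotopic_element_single_peak(self):
        pat = isotope_pattern(Composition(P=1))
        assert len(pat) == 1
        assert pat.relative[0] == 1.0

    def test_apex_beyond_monoisotopic_for_kilodalton_rna(self, rna1):
        pat = isotope_pattern(rc.composition_of(rna1))
        assert pat.apex > 0  # ~5.8 kDa: +1/+2 isotopologues dominate

    def test_coverage_band(self, rna6):
        pat = isotope_pattern(rc.composition_of(rna6))
        assert 0.999 <= pat.coverage <= 1.0

    def test_offsets_are_neutron_multiples(self, rna10):
        pat = isotope_pattern(rc.composition_of(rna10))
        assert np.allclose(pat.offsets, np.arange(len(pat)) * ISOTOPE_SPACING)

    def test_averagine_tracks_exact_pattern(self, rna10):
        comp = rc.composition_of(rna10)
        exact = isotope_pattern(comp, mode="exact")
        approx = isotope_pattern(comp.mass, mode="averagine")
        n = min(len(exact), len(approx))
        assert np.allclose(
            exact.fractions[:n], approx.fractions[:n], atol=0.05
        )

    def test_averagine_composition_mass(self):
        comp = averagine_composition(2523.39)
        assert comp.mass == pytest.approx(2523.39, abs=1.1)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            isotope_pattern(-5.0, mode="averagine")

    def test_exact_mode_requires_composition(self):
        with pytest.raises(ValueError, match="composition"):
            isotope_pattern(1500.0, mode="exact")

    def test_agrees_with_pyteomics_isotopologues(self):
        """Independent check of the convolution against full isotopologue
        expansion for guanosine."""
        comp = Composition("C10H13N5O5")
        ours = aggregated_pattern(comp)
        agg: dict[int, float] = {}
        for isot, ab in ptmass.isotopologues(
            formula="C10H13N5O5",
            report_abundance=True,
            overall_threshold=1e-10,
            isotope_threshold=1e-10,
        ):
            k = 0
            for el, n in isot.items():
                if "[" in el:
                    sym = el.split("[")[0]
                    iso = int(el.strip("]").split("[")[1])
                    base = min(
                        i
                        for i in ptmass.nist_mass[sym]
                        if i != 0 and ptmass.nist_mass[sym][i][1] > 0
                    )
                    k += (iso - base) * n
            agg[k] = agg.get(k, 0.0) + ab
        for k in range(min(len(ours), 4)):
            assert ours.fractions[k] == pytest.approx(agg.get(k, 0.0), abs=1e-6)
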