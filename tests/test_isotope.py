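"""Isotope forward model: compositions, envelopes, M0 decay curve."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from d2okinetics.isotope import (
    ISOTOPE_ABUNDANCES,
    ElementalComposition,
    ExchangeableHydrogenTable,
    composition_of_peptide,
    expected_M0,
    labeled_envelope,
    natural_envelope,
)


def sympy_envelope_oracle(comp: ElementalComposition, n_peaks: int,
                          h_dist=None) -> np.ndarray:
    """Exhaustive polynomial-expansion envelope, independent of the
    convolution implementation: expands prod_e (sum_i a_ei x^i)^N_e with exact
    symbolic arithmetic, truncates, renormalizes."""
    x = sympy.symbols("x")
    poly = sympy.Integer(1)
    for el in ("C", "H", "N", "O", "S"):
        count = getattr(comp, el)
        if not count:
            continue
        dist = h_dist if (el == "H" and h_dist is not None) \
            else ISOTOPE_ABUNDANCES[el]
        base = sum(sympy.Rational(str(a)) * x**i for i, a in enumerate(dist))
        poly *= base**count
    coeffs = sympy.Poly(sympy.expand(poly), x).all_coeffs()[::-1]
    vals = np.array([float(c) for c in coeffs[:n_peaks]])
    if len(vals) < n_peaks:
        vals = np.pad(vals, (0, n_peaks - len(vals)))
    return vals / vals.sum()


class TestComposition:
    def test_two_glycines_plus_water(self):
        assert composition_of_peptide("GG") == ElementalComposition(
            C=4, H=8, N=2, O=3)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            composition_of_peptide("")

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="'B' at position 3"):
            composition_of_peptide("GGBG")

    def test_dcn_peptide_monoisotopic_mass(self):
        # independent check: residue-mass summation for ASYSAVSLYGNPVR
        residue_masses = {
            "A": 71.03711, "S": 87.03203, "Y": 163.06333, "V": 99.06841,
            "L": 113.08406, "G": 57.02146, "N": 114.04293, "P": 97.05276,
            "R": 156.10111,
        }
        seq = "ASYSAVSLYGNPVR"
        expected = sum(residue_masses[r] for r in seq) + 18.010565
        comp = composition_of_peptide(seq)
        assert comp.monoisotopic_mass == pytest.approx(expected, abs=1e-3)
        assert comp.monoisotopic_mass == pytest.approx(1482.74, abs=1e-2)

    def test_concatenation_is_sum_plus_one_water(self):
        a, b = composition_of_peptide("ASY"), composition_of_peptide("GNPVR")
        joint = composition_of_peptide("ASYGNPVR")
        water = ElementalComposition(H=2, O=1)
        assert a + b == joint + water


class TestNaturalEnvelope:
    def test_single_carbon_is_c13_abundance(self):
        env = natural_envelope(ElementalComposition(C=1), n_peaks=2)
        assert env == pytest.approx([0.9893, 0.0107])

    def test_single_peak_renormalizes_to_one(self):
        env = natural_envelope(composition_of_peptide("GG"), n_peaks=1)
        assert env == pytest.approx([1.0])

    def test_all_zero_composition_rejected(self):
        with pytest.raises(ValueError):
            natural_envelope(ElementalComposition())

    @pytest.mark.parametrize("comp", [
        composition_of_peptide("GG"),                  # C4 H8 N2 O3
        ElementalComposition(C=3, H=5, N=1, O=1, S=1),  # cysteine residue
        ElementalComposition(C=2, H=6, O=2),
    ], ids=["GG", "Cys-residue", "small-CHO"])
    def test_matches_exhaustive_expansion_oracle(self, comp):
        assert comp.total_atoms <= 20
        got = natural_envelope(comp, n_peaks=5)
        want = sympy_envelope_oracle(comp, n_peaks=5)
        assert got == pytest.approx(want, abs=1e-9)

    @given(c=st.integers(0, 6), h=st.integers(0, 10), n=st.integers(0, 3),
           o=st.integers(0, 3), peaks=st.integers(1, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_envelope_sums_to_one(self, c, h, n, o, peaks):
        comp = ElementalComposition(C=c, H=h, N=n, O=o)
        if comp.total_atoms == 0:
            return
        env = natural_envelope(comp, n_peaks=peaks)
        assert env.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((env >= 0) & (env <= 1))


class TestLabeledEnvelope:
    comp = composition_of_peptide("ASYSAVSLYGNPVR")
    sites = ExchangeableHydrogenTable().peptide_sites("ASYSAVSLYGNPVR")

    def test_zero_enrichment_is_natural(self):
        np.testing.assert_allclose(
            labeled_envelope(self.comp, self.sites, 0.0),
            natural_envelope(self.comp), atol=1e-12)

    def test_zero_sites_is_natural(self):
        np.testing.assert_allclose(
            labeled_envelope(self.comp, 0.0, 0.055),
            natural_envelope(self.comp), atol=1e-12)

    def test_enrichment_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            labeled_envelope(self.comp, self.sites, 0.25)

    def test_integer_sites_match_expansion_oracle(self):
        # enriched-channel oracle: H split into 8 enriched + rest natural,
        # expanded symbolically
        comp = composition_of_peptide("GG")  # 8 H total
        p = 0.055
        h_nat = ISOTOPE_ABUNDANCES["H"][1]
        got = labeled_envelope(comp, 8.0, p, n_peaks=5)
        want = sympy_envelope_oracle(comp, 5, h_dist=(1 - (h_nat + p),
                                                      h_nat + p))
        assert got == pytest.approx(want, abs=1e-9)

    def test_m0_below_natural_and_monotone_in_p(self):
        m0_nat = natural_envelope(self.comp)[0]
        m0s = [labeled_envelope(self.comp, self.sites, p)[0]
               for p in (0.01, 0.03, 0.055, 0.08)]
        assert all(m < m0_nat for m in m0s)
        assert np.all(np.diff(m0s) < 0)

    def test_m0_monotone_in_site_count(self):
        m0s = [labeled_envelope(self.comp, n, 0.055)[0]
               for n in (5.0, 15.0, 28.36, 40.0)]
        assert np.all(np.diff(m0s) < 0)


class TestExpectedM0:
    def test_time_zero_is_natural(self):
        assert expected_M0(0.0, 0.02, 0.43, 0.10) == pytest.approx(0.43)

    def test_asymptote_is_plateau(self):
        assert expected_M0(1e6, 0.02, 0.43, 0.10) == pytest.approx(0.10,
                                                                   abs=1e-12)

    def test_half_life_is_exact_midpoint(self):
        # PRG4's reported 32.8-day half-life: at t = ln2/k the decline is
        # exactly halfway between natural and plateau M0
        k = np.log(2) / 32.8
        nat, plat = 0.433, 0.097
        assert expected_M0(32.8, k, nat, plat) == (nat + plat) / 2

    def test_monotone_non_increasing(self):
        t = np.linspace(0, 120, 50)
        y = expected_M0(t, 0.021, 0.43, 0.10)
        assert np.all(np.diff(y) <= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            expected_M0(-1.0, 0.02, 0.43, 0.10)


def test_exchangeable_table_rejects_unknown_residue():
    with pytest.raises(ValueError, match="'X'"):
        ExchangeableHydrogenTable().peptide_sites("GXG")
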