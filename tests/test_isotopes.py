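"""Natural-abundance envelope, convolution and cluster correction."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom, multinomial

from lipotrace import (
    ElementalComposition,
    IsotopeTable,
    MassIsotopomerDistribution as MID,
    RawCluster,
    convolve,
    correct_mid,
    correction_matrix,
    natural_mid,
)

C13, H2 = 0.0107, 0.000115
O17, O18 = 0.00038, 0.00205

SINGLE_ISOTOPE = IsotopeTable({"X": [(0, 1.0)], "C": [(0, 1.0)], "H": [(0, 1.0)], "O": [(0, 1.0)]})

FRAGMENTS = ["C17H34O2", "C19H38O2", "C18H32O"]


def enumeration_envelope(formula: str, k_max: int) -> np.ndarray:
    """Oracle: exact isotopologue fractions by enumerating heavy-atom counts."""
    counts = ElementalComposition.parse(formula).as_dict()
    n_c, n_h, n_o = counts.get("C", 0), counts.get("H", 0), counts.get("O", 0)
    out = np.zeros(k_max + 1)
    for i_c in range(min(n_c, k_max) + 1):
        p_c = binom.pmf(i_c, n_c, C13)
        for i_h in range(min(n_h, k_max - i_c) + 1):
            p_h = binom.pmf(i_h, n_h, H2)
            for i_17, i_18 in itertools.product(range(n_o + 1), repeat=2):
                if i_17 + i_18 > n_o:
                    continue
                shift = i_c + i_h + i_17 + 2 * i_18
                if shift > k_max:
                    continue
                p_o = multinomial.pmf(
                    [n_o - i_17 - i_18, i_17, i_18], n_o, [1 - O17 - O18, O17, O18]
                )
                out[shift] += p_c * p_h * p_o
    return out / out.sum()


def random_mid(rng: np.random.Generator, k_max: int) -> MID:
    f = rng.dirichlet(np.ones(k_max + 1))
    return MID(f)


class TestElementalComposition:
    def test_parse_and_roundtrip(self):
        comp = ElementalComposition.parse("C17H34O2")
        assert comp.as_dict() == {"C": 17, "H": 34, "O": 2}
        assert str(comp) == "C17H34O2"

    @pytest.mark.parametrize("bad", ["", "17C", "C-1", "c17"])
    def test_rejects_malformed_formulas(self, bad):
        with pytest.raises(ValueError):
            ElementalComposition.parse(bad)


class TestNaturalMid:
    def test_single_stable_isotope_gives_delta(self):
        mid = natural_mid(ElementalComposition.parse("X"), 4, SINGLE_ISOTOPE)
        np.testing.assert_allclose(mid.fractions, [1, 0, 0, 0, 0], atol=1e-15)

    def test_c2_first_isotopologue_ratio(self, iso_table):
        """(0.9893 + 0.0107 x)^2 expanded by hand: f1/f0 = 2 * 0.0107/0.9893."""
        table = IsotopeTable({"C": [(0, 1 - C13), (1, C13)]})
        mid = natural_mid(ElementalComposition.parse("C2"), 3, table)
        assert mid.fractions[1] / mid.fractions[0] == pytest.approx(
            2 * C13 / (1 - C13), rel=1e-12
        )

    @pytest.mark.parametrize("formula", FRAGMENTS)
    def test_matches_enumeration_oracle(self, formula, iso_table):
        """Full fragment envelopes agree with brute-force isotope enumeration."""
        k_max = 4
        mid = natural_mid(ElementalComposition.parse(formula), k_max, iso_table)
        np.testing.assert_allclose(mid.fractions, enumeration_envelope(formula, k_max), atol=1e-12)

    def test_unknown_element_is_configuration_error(self, iso_table):
        with pytest.raises(KeyError):
            natural_mid(ElementalComposition.parse("Si2"), 3, iso_table)


class TestConvolve:
    def test_delta_is_identity(self, rng):
        x = random_mid(rng, 5)
        out = convolve(MID.delta(0, 2), x)
        np.testing.assert_allclose(out.fractions[:6], x.fractions, atol=1e-15)

    def test_deltas_add_shifts(self):
        out = convolve(MID.delta(1, 2), MID.delta(2, 2))
        assert np.argmax(out.fractions) == 3
        assert out.fractions[3] == pytest.approx(1.0)

    def test_natural_envelopes_compose(self, iso_table):
        """C2 * C3 = C5: convolution equals the larger molecule's envelope."""
        k = 4
        c2 = natural_mid(ElementalComposition.parse("C2"), k, iso_table)
        c3 = natural_mid(ElementalComposition.parse("C3"), k, iso_table)
        c5 = natural_mid(ElementalComposition.parse("C5"), k, iso_table)
        np.testing.assert_allclose(convolve(c2, c3, k_max=k).fractions, c5.fractions, atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_commutative_and_associative(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (random_mid(rng, rng.integers(2, 7)) for _ in range(3))
        ab = convolve(a, b)
        ba = convolve(b, a)
        np.testing.assert_allclose(ab.fractions, ba.fractions, atol=1e-12)
        np.testing.assert_allclose(
            convolve(ab, c).fractions, convolve(a, convolve(b, c)).fractions, atol=1e-12
        )

    @given(seed=st.integers(0, 10_000))
    def test_output_is_valid_mid(self, seed):
        rng = np.random.default_rng(seed)
        out = convolve(random_mid(rng, 5), random_mid(rng, 5), k_max=6)
        assert out.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(out.fractions >= 0)


class TestCorrection:
    def test_identity_isotope_table_gives_identity_matrix(self):
        m = correction_matrix(ElementalComposition.parse("C5H10O2"), 4, SINGLE_ISOTOPE)
        np.testing.assert_allclose(m, np.eye(5), atol=1e-15)

    def test_first_column_is_natural_envelope(self, iso_table):
        comp = ElementalComposition.parse("C17H34O2")
        m = correction_matrix(comp, 5, iso_table)
        np.testing.assert_allclose(m[:, 0], natural_mid(comp, 5, iso_table).fractions)
        assert np.allclose(m, np.tril(m))

    def test_matrix_shifts_delta(self, iso_table):
        comp = ElementalComposition.parse("C17H34O2")
        k = 6
        m = correction_matrix(comp, k, iso_table)
        nat = natural_mid(comp, k, iso_table).fractions
        shifted = m @ MID.delta(2, k).fractions
        np.testing.assert_allclose(shifted[2:], nat[: k - 1], atol=1e-15)
        np.testing.assert_allclose(shifted[:2], 0, atol=1e-15)

    def test_unlabeled_sample_returns_delta(self, iso_table):
        comp = ElementalComposition.parse("C19H38O2")
        nat = natural_mid(comp, 5, iso_table)
        raw = RawCluster("stearate", 298, nat.fractions * 2.5e5)
        out = correct_mid(raw, comp, iso_table)
        np.testing.assert_allclose(out.fractions, MID.delta(0, 5).fractions, atol=1e-9)

    @given(seed=st.integers(0, 10_000))
    def test_round_trip_recovers_tracer_mid(self, seed, iso_table):
        """correct(natural * X) = X for arbitrary tracer distributions X."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 11))
        comp = ElementalComposition.parse(FRAGMENTS[int(rng.integers(3))])
        x = random_mid(rng, k)
        observed = convolve(natural_mid(comp, k, iso_table), x, k_max=k)
        raw = RawCluster("x", 0, observed.fractions * 1e6)
        recovered = correct_mid(raw, comp, iso_table)
        assert np.max(np.abs(recovered.fractions - x.fractions)) <= 1e-9

    def test_all_zero_cluster_rejected(self):
        with pytest.raises(ValueError):
            RawCluster("x", 270, np.zeros(6))
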