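"""Deuterium-water fractional-synthesis estimators."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import deuterium_mixture, grid_fit_deuterium_p
from lipotrace import (
    DeuteriumParams,
    MassIsotopomerDistribution as MID,
    correct_mid,
    estimate_deuterium,
    fns_deuterium,
    molar_enrichment,
    simulate_cluster,
    synthesis_rate,
    water_enrichment_from_ratio,
)
from lipotrace.definitions import FattyAcidDefinition


def full_chain_estimate(f, p, n_sites, rng):
    """simulate -> correct -> estimate, with the cluster spanning the envelope."""
    defn = FattyAcidDefinition("palmitate", "C17H34O2", 270, n_sites, 8, n_sites)
    raw = simulate_cluster(f, p, defn, "deuterium", rng, count_depth=None)
    mid = correct_mid(raw, defn.composition)
    return estimate_deuterium(mid, DeuteriumParams(n_sites))


class TestMolarEnrichment:
    @pytest.mark.parametrize(
        "fractions, expected",
        [([1, 0, 0], 0.0), ([0, 0, 1], 2.0), ([0.25, 0.5, 0.25], 1.0)],
    )
    def test_weighted_mean_shift(self, fractions, expected):
        assert molar_enrichment(MID(np.array(fractions))) == pytest.approx(expected)

    def test_binomial_mixture_mean(self):
        """40% of molecules labeled Binomial(21, 0.03): ME = 0.4 * 21 * 0.03."""
        mid = deuterium_mixture(0.4, 21, 0.03, 21)
        assert molar_enrichment(mid) == pytest.approx(0.252, abs=1e-9)


class TestWaterEnrichment:
    @pytest.mark.parametrize("n_sites, p", [(21, 0.03), (11, 0.05)])
    def test_recovers_p_from_binomial_mixture(self, n_sites, p):
        mid = deuterium_mixture(0.35, n_sites, p, n_sites)
        assert water_enrichment_from_ratio(mid, n_sites) == pytest.approx(p, abs=1e-9)

    def test_consecutive_ratio_value(self):
        """For Binomial(21, 0.03) the m2/m1 ratio is 10 * 0.03/0.97."""
        mid = deuterium_mixture(1.0, 21, 0.03, 21)
        r = mid[2] / mid[1]
        assert r == pytest.approx(10 * 0.03 / 0.97, rel=1e-12)

    def test_zero_ratio_gives_zero(self):
        mid = MID(np.array([0.9, 0.1, 0.0, 0.0]))
        assert water_enrichment_from_ratio(mid, 21) == 0.0

    def test_unlabeled_pool_size_does_not_matter(self):
        sparse = deuterium_mixture(0.02, 21, 0.03, 21)
        dense = deuterium_mixture(0.95, 21, 0.03, 21)
        assert water_enrichment_from_ratio(sparse, 21) == pytest.approx(
            water_enrichment_from_ratio(dense, 21), abs=1e-12
        )

    def test_no_m1_signal_raises(self):
        with pytest.raises(ValueError):
            water_enrichment_from_ratio(MID(np.array([1.0, 0, 0])), 21)


class TestFns:
    def test_printed_formula_arithmetic(self):
        """ME 0.252 at p = 0.03, N = 21 gives FNS = 0.400."""
        mid = deuterium_mixture(0.4, 21, 0.03, 21)
        assert fns_deuterium(mid, 0.03, DeuteriumParams(21)) == pytest.approx(0.400, abs=1e-9)

    def test_unlabeled_gives_zero(self):
        assert fns_deuterium(MID(np.array([1.0, 0, 0])), 0.03, DeuteriumParams(21)) == 0.0

    def test_round_trip_at_study_operating_point(self, rng):
        """Noiseless chain recovers the FR-scale FNS of 0.435 exactly."""
        res = full_chain_estimate(0.435, 0.03, 21, rng)
        assert res.fns == pytest.approx(0.435, abs=1e-9)
        assert res.p == pytest.approx(0.03, abs=1e-9)

    def test_zero_p_raises(self):
        with pytest.raises(ValueError):
            fns_deuterium(deuterium_mixture(0.4, 21, 0.03, 21), 0.0, DeuteriumParams(21))

    def test_monotone_in_molar_enrichment(self):
        """At fixed p and N, FNS strictly increases with the labeled fraction."""
        params = DeuteriumParams(21)
        values = [
            fns_deuterium(deuterium_mixture(f, 21, 0.03, 21), 0.03, params)
            for f in np.linspace(0.05, 0.95, 10)
        ]
        assert np.all(np.diff(values) > 0)

    def test_noise_above_unity_is_clipped_with_diagnostics(self):
        mid = deuterium_mixture(1.0, 21, 0.03, 21)
        res = estimate_deuterium(mid, DeuteriumParams(21), p=0.028)
        assert res.fns == 1.0
        assert res.diagnostics["fns_unclipped"] > 1.0


class TestSynthesisRate:
    @pytest.mark.parametrize(
        "amount, fns, days, expected",
        [(1.0, 0.5, 14, 0.5 / 14), (1.0, 0.0, 14, 0.0), (112.0, 0.40, 14, 3.2)],
    )
    def test_rate_arithmetic(self, amount, fns, days, expected):
        assert synthesis_rate(amount, fns, days) == pytest.approx(expected)

    def test_zero_labeling_window_raises(self):
        with pytest.raises(ValueError):
            synthesis_rate(1.0, 0.5, 0.0)


class TestRecovery:
    @pytest.mark.parametrize("p", [0.01, 0.03, 0.05])
    @pytest.mark.parametrize("n_sites", [11, 21, 27])
    @pytest.mark.parametrize("f", [0.05, 0.4, 0.9])
    def test_noiseless_grid(self, p, n_sites, f, rng):
        res = full_chain_estimate(f, p, n_sites, rng)
        assert res.p == pytest.approx(p, abs=1e-6)
        assert res.fns == pytest.approx(f, abs=1e-6)

    @given(seed=st.integers(0, 5_000))
    def test_ratio_inversion_matches_grid_search(self, seed):
        """The closed-form m2/m1 inversion agrees with an independent LS fit."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.005, 0.08)
        n_sites = int(rng.integers(11, 28))
        f = rng.uniform(0.05, 0.95)
        mid = deuterium_mixture(f, n_sites, p, n_sites)
        closed = water_enrichment_from_ratio(mid, n_sites)
        fitted = grid_fit_deuterium_p(mid.fractions, n_sites)
        assert closed == pytest.approx(fitted, abs=1e-6)
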