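"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's estimator code paths:
binomial mixtures are built from scipy pmfs, and precursor enrichments are
re-estimated by least-squares grid search over the binomial forward model,
so ratio-inversion estimators are checked against an independent fit.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import minimize_scalar
from scipy.stats import binom

from lipotrace import IsotopeTable, MassIsotopomerDistribution, default_definitions

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def iso_table() -> IsotopeTable:
    return IsotopeTable.default()


@pytest.fixture(scope="session")
def definitions():
    return default_definitions()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def deuterium_mixture(f: float, n_sites: int, p: float, k_max: int) -> MassIsotopomerDistribution:
    """Tracer-only MID of a pool with fraction f labeled Binomial(N, p)."""
    fractions = f * binom.pmf(np.arange(k_max + 1), n_sites, p)
    fractions[0] += 1.0 - f
    return MassIsotopomerDistribution(fractions / fractions.sum())


def grid_fit_deuterium_p(fractions: np.ndarray, n_sites: int) -> float:
    """Least-squares fit of p over the labeled-peak shape, independent of m0.

    Normalizes observed shifts >= 1 and matches them to the conditional
    Binomial(N, p) pmf; coarse grid then bounded scalar refinement.
    """
    obs = np.asarray(fractions, dtype=float)[1:]
    obs = obs / obs.sum()
    shifts = np.arange(1, obs.size + 1)

    def loss(p: float) -> float:
        model = binom.pmf(shifts, n_sites, p)
        model = model / model.sum()
        return float(((model - obs) ** 2).sum())

    grid = np.linspace(1e-4, 0.45, 800)
    best = grid[np.argmin([loss(p) for p in grid])]
    lo, hi = max(1e-6, best - 2e-3), min(0.49, best + 2e-3)
    res = minimize_scalar(loss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
    return float(res.x)


def grid_fit_mida_g(fractions: np.ndarray, n_units: int) -> float:
    """Least-squares fit of g over the labeled even-peak shape."""
    obs_all = np.asarray(fractions, dtype=float)
    ks = np.arange(1, min(n_units, (obs_all.size - 1) // 2) + 1)
    obs = obs_all[2 * ks]
    obs = obs / obs.sum()

    def loss(g: float) -> float:
        model = binom.pmf(ks, n_units, g)
        model = model / model.sum()
        return float(((model - obs) ** 2).sum())

    grid = np.linspace(1e-4, 0.6, 800)
    best = grid[np.argmin([loss(g) for g in grid])]
    lo, hi = max(1e-6, best - 2e-3), min(0.8, best + 2e-3)
    res = minimize_scalar(loss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
    return float(res.x)
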