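"""Natural-abundance isotope arithmetic for GC/MS selected-ion-monitoring clusters.

A monitored fragment ion (e.g. the methyl-palmitate molecular ion at m/z 270)
produces a cluster of peaks at integer mass shifts above the monoisotopic
peak. Two processes populate those peaks: natural heavy-isotope abundance
(¹³C, ²H, ¹⁷O, ¹⁸O) in every atom of the fragment, and tracer incorporation.
This module provides the forward model (convolution of a tracer mass-isotopomer
distribution with the fragment's natural-abundance envelope) and its inverse
(deconvolution of observed intensities into a tracer-only distribution by
solving a lower-triangular linear system).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular, toeplitz

__all__ = [
    "IsotopeTable",
    "ElementalComposition",
    "MassIsotopomerDistribution",
    "RawCluster",
    "natural_mid",
    "convolve",
    "correction_matrix",
    "correct_mid",
]

# IUPAC representative isotopic abundances; shift is the integer mass excess
# over the lightest isotope.
_DEFAULT_ABUNDANCES: dict[str, list[tuple[int, float]]] = {
    "C": [(0, 0.9893), (1, 0.0107)],
    "H": [(0, 0.999885), (1, 0.000115)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
}

_SUM_TOL = 1e-9


class IsotopeTable:
    """Per-element natural isotope abundances as (mass shift, fraction) pairs.

    The default table carries ¹³C, ²H, ¹⁷O and ¹⁸O at IUPAC values; users can
    supply their own table (e.g. to drop oxygen isotopes, or to model an
    element-free control) from a CSV with columns element, mass_shift,
    abundance.
    """

    def __init__(self, abundances: Mapping[str, Sequence[tuple[int, float]]]):
        table: dict[str, list[tuple[int, float]]] = {}
        for element, pairs in abundances.items():
            pairs = [(int(s), float(a)) for s, a in pairs]
            if any(s < 0 for s, _ in pairs):
                raise ValueError(f"negative mass shift for element {element!r}")
            if any(a < 0 for _, a in pairs):
                raise ValueError(f"negative abundance for element {element!r}")
            total = sum(a for _, a in pairs)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"abundances for element {element!r} sum to {total}, not 1"
                )
            table[element] = sorted(pairs)
        self._table = table

    @classmethod
    def default(cls) -> "IsotopeTable":
        return cls(_DEFAULT_ABUNDANCES)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IsotopeTable":
        df = pd.read_csv(path)
        grouped: dict[str, list[tuple[int, float]]] = {}
        for row in df.itertuples(index=False):
            grouped.setdefault(str(row.element), []).append(
                (int(row.mass_shift), float(row.abundance))
            )
        return cls(grouped)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"element": el, "mass_shift": s, "abundance": a}
            for el, pairs in sorted(self._table.items())
            for s, a in pairs
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def elements(self) -> list[str]:
        return sorted(self._table)

    def __contains__(self, element: str) -> bool:
        return element in self._table

    def __getitem__(self, element: str) -> list[tuple[int, float]]:
        try:
            return self._table[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} has no configured isotope abundances"
            ) from None

    def atom_distribution(self, element: str, max_shift: int) -> np.ndarray:
        """Single-atom mass-shift distribution truncated at max_shift."""
        v = np.zeros(max_shift + 1)
        for shift, abundance in self[element]:
            if shift <= max_shift:
                v[shift] += abundance
        return v


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a monitored fragment, e.g. C17H34O2 for methyl palmitate."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("composition must contain at least one atom")
        for element, n in self.counts:
            if n < 0 or int(n) != n:
                raise ValueError(f"atom count for {element!r} must be a non-negative integer")
        if sum(n for _, n in self.counts) < 1:
            raise ValueError("composition must contain at least one atom")

    @classmethod
    def parse(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula such as ``C17H34O2``."""
        pos = 0
        counts: dict[str, int] = {}
        for match in _FORMULA_RE.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(tuple(sorted(counts.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        return "".join(f"{el}{n if n != 1 else ''}" for el, n in self.counts if n)


@dataclass
class MassIsotopomerDistribution:
    """Molar fractions m0, m1, m2, ... of an ion cluster per 1-Da mass shift.

    ``origin`` records the shift of index 0 relative to the monitored base
    m/z (0 for a full cluster starting at the monoisotopic peak).
    """

    fractions: np.ndarray
    origin: int = 0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 1 or self.fractions.size < 3:
            raise ValueError("a MID needs fractions for shifts 0..K with K >= 2")
        if np.any(self.fractions < -_SUM_TOL):
            raise ValueError("MID fractions must be non-negative")
        self.fractions = np.clip(self.fractions, 0.0, None)
        total = self.fractions.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"MID fractions sum to {total}, not 1")

    @classmethod
    def delta(cls, shift: int, k_max: int) -> "MassIsotopomerDistribution":
        """Point mass at one shift: a molecule with exactly `shift` labels."""
        if not 0 <= shift <= k_max:
            raise ValueError("delta shift must lie within 0..k_max")
        f = np.zeros(k_max + 1)
        f[shift] = 1.0
        return cls(f)

    @property
    def k_max(self) -> int:
        return self.fractions.size - 1

    def __getitem__(self, shift: int) -> float:
        return float(self.fractions[shift]) if shift < self.fractions.size else 0.0


# Short alias used throughout the package.
MID = MassIsotopomerDistribution


@dataclass
class RawCluster:
    """Integrated SIM intensities at contiguous shifts 0..K above base m/z."""

    fatty_acid: str
    base_mz: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 3:
            raise ValueError("cluster needs intensities at shifts 0..K with K >= 2")
        if np.any(self.intensities < 0):
            raise ValueError("cluster intensities must be non-negative")
        if self.intensities.sum() <= 0:
            raise ValueError("cluster total intensity must be positive")

    @property
    def k_max(self) -> int:
        return self.intensities.size - 1


def natural_mid(
    comp: ElementalComposition,
    k_max: int,
    table: IsotopeTable | None = None,
) -> MID:
    """Theoretical isotopologue distribution of the unlabeled fragment.

    Convolves single-atom shift distributions over all atoms of ``comp``,
    truncates at ``k_max`` and renormalizes. Powers per element are computed
    by repeated truncated convolution, which is exact for shifts <= k_max.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    table = table or IsotopeTable.default()
    out = np.zeros(k_max + 1)
    out[0] = 1.0
    for element, n_atoms in comp.counts:
        if n_atoms == 0:
            continue
        atom = table.atom_distribution(element, k_max)
        # binary exponentiation of the atom polynomial, truncated at k_max
        power = np.zeros(k_max + 1)
        power[0] = 1.0
        base = atom
        n = n_atoms
        while n:
            if n & 1:
                power = np.convolve(power, base)[: k_max + 1]
            n >>= 1
            if n:
                base = np.convolve(base, base)[: k_max + 1]
        out = np.convolve(out, power)[: k_max + 1]
    return MID(out / out.sum())


def convolve(a: MID, b: MID, k_max: int | None = None) -> MID:
    """Convolution of two MIDs: the cluster of a molecule combining both labels.

    Truncates to ``k_max`` (default: untruncated) and renormalizes;
    commutative and, away from truncation, associative.
    """
    full = np.convolve(a.fractions, b.fractions)
    if k_max is not None:
        full = full[: k_max + 1]
    return MID(full / full.sum(), origin=a.origin + b.origin)


def correction_matrix(
    comp: ElementalComposition,
    k_max: int,
    table: IsotopeTable | None = None,
) -> np.ndarray:
    """Lower-triangular natural-abundance mixing matrix, (K+1) x (K+1).

    Column j holds the natural envelope of ``comp`` shifted up by j mass
    units: multiplying by a tracer-only MID gives the observed cluster.
    """
    nat = natural_mid(comp, k_max, table).fractions
    return toeplitz(nat, np.zeros_like(nat))


def correct_mid(
    raw: RawCluster,
    comp: ElementalComposition,
    table: IsotopeTable | None = None,
) -> MID:
    """Remove natural-abundance contributions from an observed ion cluster.

    Normalizes the intensities, solves the triangular system against
    :func:`correction_matrix`, clips small negative components (noise) to
    zero and renormalizes. An unlabeled sample returns the delta at m0.
    """
    k_max = raw.k_max
    observed = raw.intensities / raw.intensities.sum()
    matrix = correction_matrix(comp, k_max, table)
    if matrix[0, 0] <= 1e-12:
        raise np.linalg.LinAlgError(
            "natural envelope has no monoisotopic component; system is singular"
        )
    tracer = solve_triangular(matrix, observed, lower=True)
    tracer = np.clip(tracer, 0.0, None)
    total = tracer.sum()
    if total <= 0:
        raise np.linalg.LinAlgError("correction produced an all-zero distribution")
    return MID(tracer / total)
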