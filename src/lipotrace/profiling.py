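"""Fatty-acid profiles, desaturation indices, quantification, and qPCR folds.

Profiles are expressed relative to palmitate (set at 100%) within the same
tissue; desaturation indices are monounsaturated/saturated peak-area ratios
(a proxy for stearoyl-CoA desaturase activity); absolute amounts come from
the known quantity of the tri-deuterated heptadecanoate internal standard;
relative gene expression uses the 2^(-ddCt) method.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

__all__ = [
    "INTERNAL_STANDARD",
    "profile_percent",
    "desaturation_indices",
    "quantify",
    "ddct_fold_change",
]

INTERNAL_STANDARD = "heptadecanoate_d3"

# (index name, numerator analyte, denominator analyte); the first three are
# desaturation indices proper, the last tracks stearate production/turnover.
INDEX_DEFINITIONS = (
    ("palmitoleate_palmitate", "palmitoleate", "palmitate"),
    ("oleate_stearate", "oleate", "stearate"),
    ("vaccenate_stearate", "vaccenate", "stearate"),
    ("stearate_palmitate", "stearate", "palmitate"),
)


def profile_percent(
    areas: Mapping[str, float], reference: str = "palmitate"
) -> dict[str, float]:
    """Peak areas as percent of the reference analyte (palmitate = 100%)."""
    if reference not in areas:
        raise KeyError(f"reference analyte {reference!r} missing from areas")
    ref = areas[reference]
    if ref <= 0:
        raise ValueError(f"reference analyte {reference!r} has non-positive area")
    return {name: 100.0 * area / ref for name, area in areas.items()}


def desaturation_indices(areas: Mapping[str, float]) -> dict[str, float]:
    """Monounsaturated/saturated area ratios plus stearate/palmitate.

    A zero denominator yields NaN for that ratio with a warning rather than
    an error, so one failed peak does not abort a profile; ratios whose
    analytes were not monitored at all are NaN without comment.
    """
    out: dict[str, float] = {}
    for name, numerator, denominator in INDEX_DEFINITIONS:
        num = areas.get(numerator)
        den = areas.get(denominator)
        if num is None or den is None:
            out[name] = math.nan
        elif den <= 0:
            warnings.warn(f"cannot compute {name}: zero denominator peak")
            out[name] = math.nan
        else:
            out[name] = num / den
    return out


def quantify(
    areas: Mapping[str, float],
    is_area: float,
    is_quantity_ug: float,
    tissue_mass_mg: float,
    response_factors: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Micrograms of each analyte per mg tissue via the internal standard.

    quantity_i = IS_quantity * (area_i / area_IS) / tissue_mass, with a
    per-analyte detector response factor (default 1.0 for all FAMEs).
    """
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    if is_quantity_ug <= 0:
        raise ValueError("internal-standard quantity must be positive")
    if tissue_mass_mg <= 0:
        raise ValueError("tissue mass must be positive")
    rf = response_factors or {}
    return {
        name: is_quantity_ug * (area / is_area) / rf.get(name, 1.0) / tissue_mass_mg
        for name, area in areas.items()
        if name != INTERNAL_STANDARD
    }


def ddct_fold_change(
    ct_target_a: float,
    ct_ref_a: float,
    ct_target_b: float,
    ct_ref_b: float,
) -> float:
    """Fold change of group b relative to group a by the 2^(-ddCt) method.

    ddCt = (Ct_target_b - Ct_ref_b) - (Ct_target_a - Ct_ref_a); amplification
    efficiency is taken as exactly 2 per cycle.
    """
    for ct in (ct_target_a, ct_ref_a, ct_target_b, ct_ref_b):
        if ct <= 0:
            raise ValueError("Ct values must be positive cycle numbers")
    ddct = (ct_target_b - ct_ref_b) - (ct_target_a - ct_ref_a)
    return 2.0 ** (-ddct)
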