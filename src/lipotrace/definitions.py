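"""Analyte definitions: chemistry and tracer constants per fatty acid.

Each monitored fatty acid carries the elemental composition of its SIM
fragment (as the methyl ester), the monitored base m/z, the number N of
hydrogen positions that acquire deuterium from body water during de novo
synthesis, and the number n of acetyl units polymerized into the chain
(used by the ¹³C mass-isotopomer analysis). Only palmitate's N is an
established literature constant here (N = 21); the stearate and oleate
values ship as editable assumptions in the same table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .isotopes import ElementalComposition

__all__ = ["FattyAcidDefinition", "default_definitions", "load_definitions", "save_definitions"]


@dataclass(frozen=True)
class FattyAcidDefinition:
    """Constants for one analyte's monitored ion cluster."""

    name: str
    formula: str
    base_mz: int
    n_deuterium_sites: int
    n_acetyl_units: int
    cluster_length: int  # default max mass shift K monitored above base m/z

    def __post_init__(self) -> None:
        if self.n_deuterium_sites < 2:
            raise ValueError("n_deuterium_sites must be >= 2")
        if self.n_acetyl_units < 2:
            raise ValueError("n_acetyl_units must be >= 2")
        if self.cluster_length < 2:
            raise ValueError("cluster_length must be >= 2")

    @property
    def composition(self) -> ElementalComposition:
        return ElementalComposition.parse(self.formula)

    def k_for_tracer(self, tracer: str) -> int:
        """Monitored window for a tracer type.

        ``cluster_length`` is the deuterium SIM window; ¹³C acquisition must
        reach at least m8 so the m2/m4/m6 light peaks survive correction.
        """
        if tracer == "c13":
            return max(self.cluster_length, 8)
        return self.cluster_length


def default_definitions() -> dict[str, FattyAcidDefinition]:
    """Built-in analyte table.

    Palmitate and stearate use the methyl-ester molecular ions (m/z 270 and
    298); oleate uses the methanol-loss fragment at m/z 264. Deuterium
    clusters default to shifts m0-m5; ¹³C clusters to m0-m8 (covering m6,
    the heaviest peak entering the light-fraction analysis).
    """
    defs = [
        FattyAcidDefinition("palmitate", "C17H34O2", 270, 21, 8, 5),
        FattyAcidDefinition("stearate", "C19H38O2", 298, 24, 9, 5),
        FattyAcidDefinition("oleate", "C18H32O", 264, 24, 9, 5),
    ]
    return {d.name: d for d in defs}


def load_definitions(path: str | Path) -> dict[str, FattyAcidDefinition]:
    df = pd.read_csv(path)
    required = {"name", "formula", "base_mz", "n_deuterium_sites", "n_acetyl_units", "cluster_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"definitions file missing columns: {sorted(missing)}")
    out: dict[str, FattyAcidDefinition] = {}
    for row in df.itertuples(index=False):
        d = FattyAcidDefinition(
            name=str(row.name),
            formula=str(row.formula),
            base_mz=int(row.base_mz),
            n_deuterium_sites=int(row.n_deuterium_sites),
            n_acetyl_units=int(row.n_acetyl_units),
            cluster_length=int(row.cluster_length),
        )
        out[d.name] = d
    return out


def save_definitions(defs: dict[str, FattyAcidDefinition], path: str | Path) -> None:
    pd.DataFrame([vars(d) for d in defs.values()]).to_csv(path, index=False)
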