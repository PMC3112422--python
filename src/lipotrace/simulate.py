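"""Synthetic GC/MS studies with known ground truth.

Generates complete two-group study bundles — raw SIM ion-cluster
intensities, integrated peak areas, a sample manifest, qPCR Ct values, and
a per-sample truth table — mimicking the design of a maternal
food-restriction programming experiment: Control vs FR offspring, nursing
pups labeled for 14 days at ~3% body-water deuterium enrichment, or primary
adipocyte cultures labeled with [U-¹³C]glucose giving ~12-13% doubly
labeled acetyl-CoA.

Noise model: Poisson counting noise on ion-cluster intensities at a
configurable total count depth (None = noiseless expected fractions), plus
multiplicative log-normal noise on integrated peak areas. Between-animal
variation is Gaussian on the fraction of new synthesis and log-normal on
tissue composition; group dispersion is parameterized as SE * sqrt(n) so a
published mean ± SE row translates directly into a per-animal spread.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binom

from .definitions import FattyAcidDefinition, default_definitions
from .isotopes import MID, IsotopeTable, RawCluster, convolve, natural_mid
from .mida import MidaParams, mida_forward
from .profiling import INTERNAL_STANDARD

__all__ = [
    "AnalyteTruth",
    "TissueDesign",
    "ExpressionTruth",
    "StudyDesign",
    "StudyBundle",
    "simulate_cluster",
    "simulate_study",
    "nursing_pup_design",
    "adipocyte_c13_design",
]

# Analytes whose ion clusters are monitored; the remaining profile analytes
# (palmitoleate, vaccenate) contribute peak areas only.
CLUSTER_ANALYTES = ("palmitate", "stearate", "oleate")


@dataclass
class AnalyteTruth:
    """Ground truth for one analyte in one (group, tissue) cell."""

    fns: float
    fns_se: float = 0.0
    amount_ug_per_mg: float = 0.0
    amount_cv: float = 0.15  # per-animal log-scale SD of composition

    def __post_init__(self) -> None:
        if not 0 <= self.fns <= 1:
            raise ValueError("fns must lie in [0, 1]")
        if self.fns_se < 0 or self.amount_ug_per_mg < 0 or self.amount_cv < 0:
            raise ValueError("dispersion and amounts must be non-negative")


@dataclass
class ExpressionTruth:
    """qPCR ground truth: mean target/reference Ct per group."""

    ct_target: dict[str, float]
    ct_reference: dict[str, float]
    ct_sd: float = 0.05
    target: str = "SCD1"
    reference: str = "18S"


@dataclass
class TissueDesign:
    tissue_mass_mg: float = 30.0
    # analyte -> group -> truth
    analytes: dict[str, dict[str, AnalyteTruth]] = field(default_factory=dict)
    expression: ExpressionTruth | None = None


@dataclass
class StudyDesign:
    """Full specification of a synthetic two-group study."""

    groups: tuple[str, str] = ("Control", "FR")
    n_per_group: int = 6
    tracer: str = "deuterium"  # deuterium | c13 | none
    labeling_days: float = 14.0
    # precursor enrichment per group: body-water p (deuterium) or acetyl g (c13)
    precursor: dict[str, float] = field(default_factory=dict)
    precursor_sd: float = 0.0015
    tissues: dict[str, TissueDesign] = field(default_factory=dict)
    count_depth: float | None = 1e6
    area_cv: float = 0.05
    is_quantity_ug: float = 10.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per group")
        if self.tracer not in ("deuterium", "c13", "none"):
            raise ValueError(f"unknown tracer {self.tracer!r}")
        for g, v in self.precursor.items():
            if not 0 < v < 1:
                raise ValueError(f"precursor enrichment for {g!r} must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_to_builtin(dataclasses.asdict(self)), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyDesign":
        raw = yaml.safe_load(Path(path).read_text())
        tissues = {}
        for tname, t in raw.pop("tissues", {}).items():
            expr = t.pop("expression", None)
            analytes = {
                a: {g: AnalyteTruth(**tr) for g, tr in per_group.items()}
                for a, per_group in t.pop("analytes", {}).items()
            }
            tissues[tname] = TissueDesign(
                analytes=analytes,
                expression=ExpressionTruth(**expr) if expr else None,
                **t,
            )
        raw["groups"] = tuple(raw.get("groups", ("Control", "FR")))
        return cls(tissues=tissues, **raw)


def _to_builtin(obj):
    """Recursively convert numpy scalars/containers for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class StudyBundle:
    """In-memory study: the frames the pipeline consumes, plus ground truth."""

    manifest: pd.DataFrame
    clusters: pd.DataFrame
    areas: pd.DataFrame
    ct: pd.DataFrame
    truth: pd.DataFrame
    design: StudyDesign
    seed: int

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        self.clusters.to_csv(out / "clusters.csv", index=False)
        self.areas.to_csv(out / "areas.csv", index=False)
        self.ct.to_csv(out / "ct.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.design.to_yaml(out / "design.yaml")
        (out / "seed.txt").write_text(f"{self.seed}\n")
        return out


def _tracer_mid(
    fns: float,
    precursor: float,
    defn: FattyAcidDefinition,
    tracer: str,
    k_max: int,
) -> MID:
    """Tracer-only MID of a pool with fraction `fns` newly synthesized."""
    fractions = np.zeros(k_max + 1)
    if tracer == "deuterium":
        shifts = np.arange(k_max + 1)
        fractions = fns * binom.pmf(shifts, defn.n_deuterium_sites, precursor)
        fractions[0] += 1.0 - fns
    elif tracer == "c13":
        params = MidaParams(n_units=defn.n_acetyl_units)
        return mida_forward(fns, precursor, params, k_max=k_max)
    else:
        fractions[0] = 1.0
    return MID(fractions / fractions.sum())


def simulate_cluster(
    fns: float,
    precursor: float,
    defn: FattyAcidDefinition,
    tracer: str,
    rng: np.random.Generator,
    count_depth: float | None = 1e6,
    k_max: int | None = None,
    table: IsotopeTable | None = None,
) -> RawCluster:
    """One observed SIM cluster: tracer MID ⊛ natural envelope, Poisson-sampled.

    ``count_depth`` is the expected total ion count of the cluster; None
    returns the exact expected fractions (noiseless limit) scaled to 1e6.
    """
    if k_max is None:
        k_max = defn.k_for_tracer(tracer)
    tracer_mid = _tracer_mid(fns, precursor, defn, tracer, k_max)
    nat = natural_mid(defn.composition, k_max, table)
    expected = convolve(nat, tracer_mid, k_max=k_max).fractions
    if count_depth is None:
        intensities = expected * 1e6
    else:
        intensities = rng.poisson(expected * count_depth).astype(float)
        if intensities.sum() <= 0:  # pathological depth; keep cluster valid
            intensities = expected * count_depth
    return RawCluster(defn.name, defn.base_mz, intensities)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def simulate_study(
    design: StudyDesign,
    seed: int,
    definitions: dict[str, FattyAcidDefinition] | None = None,
    table: IsotopeTable | None = None,
) -> StudyBundle:
    """Draw a full study bundle from the design under one seed.

    Per-animal truth: FNS ~ Normal(group mean, SE * sqrt(n)) truncated to
    [0, 1]; composition ~ log-normal around the group mean; precursor
    enrichment ~ Normal(group value, precursor_sd) truncated to (0, 0.5).
    All randomness flows from ``seed``; identical seeds give identical
    bundles.
    """
    definitions = definitions or default_definitions()
    rng = np.random.default_rng(seed)
    manifest_rows, cluster_rows, area_rows, ct_rows, truth_rows = [], [], [], [], []

    for group in design.groups:
        group_precursor = design.precursor.get(group, 0.0)
        for i in range(design.n_per_group):
            sample_id = f"{group}_{i + 1:02d}"
            p_animal = (
                _truncated_normal(rng, group_precursor, design.precursor_sd, 1e-4, 0.499)
                if design.tracer != "none"
                else 0.0
            )
            for tissue_name in sorted(design.tissues):
                tissue = design.tissues[tissue_name]
                manifest_rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "tissue": tissue_name,
                        "tracer": design.tracer,
                        "labeling_days": design.labeling_days,
                        "tissue_mass_mg": tissue.tissue_mass_mg,
                        "is_quantity_ug": design.is_quantity_ug,
                    }
                )
                # detector scale shared by all peaks of this specimen run;
                # cancels under internal-standard normalization
                run_scale = 1000.0 * rng.lognormal(0.0, 0.2)
                is_area = (
                    design.is_quantity_ug
                    * run_scale
                    * rng.lognormal(0.0, design.area_cv)
                )
                area_rows.append(
                    {
                        "sample_id": sample_id,
                        "tissue": tissue_name,
                        "fatty_acid": INTERNAL_STANDARD,
                        "area": is_area,
                    }
                )
                for analyte in sorted(tissue.analytes):
                    truth = tissue.analytes[analyte].get(group)
                    if truth is None:
                        continue
                    sd = truth.fns_se * np.sqrt(design.n_per_group)
                    f_animal = _truncated_normal(rng, truth.fns, sd, 0.0, 1.0)
                    amount = truth.amount_ug_per_mg * rng.lognormal(
                        0.0, truth.amount_cv
                    )
                    # same per-ug detector response as the internal standard
                    area = amount * tissue.tissue_mass_mg * run_scale
                    area_rows.append(
                        {
                            "sample_id": sample_id,
                            "tissue": tissue_name,
                            "fatty_acid": analyte,
                            "area": area * rng.lognormal(0.0, design.area_cv),
                        }
                    )
                    if design.tracer != "none" and analyte in definitions:
                        defn = definitions[analyte]
                        cluster = simulate_cluster(
                            f_animal,
                            p_animal,
                            defn,
                            design.tracer,
                            rng,
                            count_depth=design.count_depth,
                            table=table,
                        )
                        for shift, intensity in enumerate(cluster.intensities):
                            cluster_rows.append(
                                {
                                    "sample_id": sample_id,
                                    "tissue": tissue_name,
                                    "fatty_acid": analyte,
                                    "base_mz": defn.base_mz,
                                    "mass_shift": shift,
                                    "intensity": intensity,
                                }
                            )
                    truth_rows.append(
                        {
                            "sample_id": sample_id,
                            "group": group,
                            "tissue": tissue_name,
                            "fatty_acid": analyte,
                            "true_fns": f_animal,
                            "true_precursor": p_animal,
                            "true_amount_ug_per_mg": amount,
                        }
                    )
                if tissue.expression is not None:
                    expr = tissue.expression
                    ct_rows.append(
                        {
                            "sample_id": sample_id,
                            "tissue": tissue_name,
                            "target": expr.target,
                            "reference": expr.reference,
                            "ct_target": rng.normal(expr.ct_target[group], expr.ct_sd),
                            "ct_reference": rng.normal(
                                expr.ct_reference[group], expr.ct_sd
                            ),
                        }
                    )

    return StudyBundle(
        manifest=pd.DataFrame(manifest_rows),
        clusters=pd.DataFrame(cluster_rows),
        areas=pd.DataFrame(area_rows),
        ct=pd.DataFrame(ct_rows),
        truth=pd.DataFrame(truth_rows),
        design=design,
        seed=seed,
    )


def nursing_pup_design(
    n_per_group: int = 6,
    count_depth: float | None = 1e6,
    fns_shift: float = 0.0,
) -> StudyDesign:
    """Deuterium nursing-pup study: Control vs FR subcutaneous fat at weaning.

    Defaults encode the study conditions of the in-vivo experiment this
    package targets: 14 labeling days at ~3% body-water enrichment, SC-fat
    palmitate FNS 0.400 (Control) vs 0.435 (FR), stearate 0.225/0.241,
    oleate 0.178/0.176, composition chosen so palmitate synthesis is
    ~3.2 ug/mg/day and the Control desaturation indices sit at
    palmitoleate/palmitate 0.041, oleate/stearate 3.23, vaccenate/stearate
    0.29, stearate/palmitate 0.27 (FR: 0.046, 3.51, 0.31, 0.25). SCD1
    expression folds (FR vs Control) are 1.65 in SC fat and 0.28 in liver.

    ``fns_shift`` is added to every FR FNS mean; passing the negative of the
    configured group difference yields a null (no-difference) design for
    calibration studies.
    """

    def truths(control, fr):
        return {"Control": control, "FR": fr}

    sc_fat = TissueDesign(
        tissue_mass_mg=30.0,
        analytes={
            "palmitate": truths(
                AnalyteTruth(0.400, 0.014, 112.0),
                AnalyteTruth(min(1.0, 0.435 + fns_shift), 0.011, 124.0),
            ),
            "stearate": truths(
                AnalyteTruth(0.225, 0.011, 30.2),
                AnalyteTruth(min(1.0, 0.241 + fns_shift), 0.010, 31.0),
            ),
            "oleate": truths(
                AnalyteTruth(0.178, 0.010, 97.6),
                AnalyteTruth(min(1.0, 0.176 + fns_shift), 0.012, 108.8),
            ),
            "palmitoleate": truths(
                AnalyteTruth(0.0, 0.0, 4.6), AnalyteTruth(0.0, 0.0, 5.7)
            ),
            "vaccenate": truths(
                AnalyteTruth(0.0, 0.0, 8.8), AnalyteTruth(0.0, 0.0, 9.6)
            ),
        },
        expression=ExpressionTruth(
            ct_target={"Control": 22.0, "FR": 22.0 - np.log2(1.65)},
            ct_reference={"Control": 12.0, "FR": 12.0},
        ),
    )
    liver = TissueDesign(
        tissue_mass_mg=50.0,
        analytes={},
        expression=ExpressionTruth(
            ct_target={"Control": 20.0, "FR": 20.0 - np.log2(0.28)},
            ct_reference={"Control": 12.0, "FR": 12.0},
        ),
    )
    return StudyDesign(
        groups=("Control", "FR"),
        n_per_group=n_per_group,
        tracer="deuterium",
        labeling_days=14.0,
        precursor={"Control": 0.03, "FR": 0.03},
        tissues={"sc_fat": sc_fat, "liver": liver},
        count_depth=count_depth,
    )


def adipocyte_c13_design(
    n_per_group: int = 6,
    count_depth: float | None = 1e6,
) -> StudyDesign:
    """[U-¹³C]glucose primary-adipocyte study: Control vs FR cultures.

    Acetyl-CoA doubly-labeled enrichment g = 0.118 (Control) vs 0.133 (FR);
    FNS palmitate 0.254/0.310, stearate 0.079/0.092, oleate 0.015/0.017.
    """

    def truths(control, fr):
        return {"Control": control, "FR": fr}

    cells = TissueDesign(
        tissue_mass_mg=10.0,
        analytes={
            "palmitate": truths(
                AnalyteTruth(0.254, 0.004, 50.0), AnalyteTruth(0.310, 0.001, 55.0)
            ),
            "stearate": truths(
                AnalyteTruth(0.079, 0.002, 12.0), AnalyteTruth(0.092, 0.001, 12.5)
            ),
            "oleate": truths(
                AnalyteTruth(0.015, 0.001, 30.0), AnalyteTruth(0.017, 0.001, 31.0)
            ),
        },
    )
    return StudyDesign(
        groups=("Control", "FR"),
        n_per_group=n_per_group,
        tracer="c13",
        labeling_days=4.0,
        precursor={"Control": 0.118, "FR": 0.133},
        precursor_sd=0.001,
        tissues={"adipocytes": cells},
        count_depth=count_depth,
    )
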