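"""End-to-end orchestration: validate, correct, estimate, profile, summarize.

The pipeline consumes a study bundle (directory of CSVs or an in-memory
:class:`~lipotrace.simulate.StudyBundle`), runs natural-abundance correction
on every monitored ion cluster, applies the tracer-appropriate synthesis
estimators, computes profiles and internal-standard quantities, performs
per-metric two-group comparisons, and writes stage outputs plus a Markdown
report. The report formatter only reformats stage outputs; it computes
nothing new, so a rerun on the same inputs is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .definitions import FattyAcidDefinition, default_definitions
from .deuterium import DeuteriumParams, estimate_deuterium, synthesis_rate
from .isotopes import MID, IsotopeTable, RawCluster, correct_mid
from .mida import MidaParams, estimate_mida
from .profiling import INTERNAL_STANDARD, desaturation_indices, profile_percent, quantify
from .simulate import StudyBundle, StudyDesign
from .stats import bh_adjust, summarize_groups

__all__ = [
    "ValidationError",
    "load_bundle",
    "validate_bundle",
    "correct_clusters",
    "analyze_tracer",
    "analyze_profile",
    "analyze_expression",
    "summarize",
    "run_pipeline",
]

logger = logging.getLogger("lipotrace")

# which consecutive even-peak ratio estimates acetyl enrichment per analyte
MIDA_RATIO_PAIRS = {"palmitate": (4, 2), "stearate": (6, 4), "oleate": (4, 2)}


class ValidationError(ValueError):
    """Input-schema violation, reported with row/column context."""


def load_bundle(input_dir: str | Path) -> StudyBundle:
    """Read a study bundle directory written by the simulator (or hand-built)."""
    d = Path(input_dir)
    if not d.is_dir():
        raise ValidationError(f"input directory {d} does not exist")

    def read(name: str, required: bool) -> pd.DataFrame:
        path = d / name
        if not path.exists():
            if required:
                raise ValidationError(f"missing required input file {path}")
            return pd.DataFrame()
        return pd.read_csv(path)

    design = None
    if (d / "design.yaml").exists():
        try:
            design = StudyDesign.from_yaml(d / "design.yaml")
        except Exception:  # design echo is informational; analysis runs without it
            logger.warning("could not parse design.yaml; continuing without it")
    seed_file = d / "seed.txt"
    seed = int(seed_file.read_text()) if seed_file.exists() else -1
    return StudyBundle(
        manifest=read("manifest.csv", required=True),
        clusters=read("clusters.csv", required=False),
        areas=read("areas.csv", required=False),
        ct=read("ct.csv", required=False),
        truth=read("truth.csv", required=False),
        design=design,
        seed=seed,
    )


def validate_bundle(bundle: StudyBundle) -> None:
    """Schema checks before any computation; raises ValidationError with context."""
    manifest = bundle.manifest
    if manifest.empty:
        raise ValidationError("manifest is empty: no samples to analyze")
    required = {"sample_id", "group", "tissue", "tracer"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if manifest["group"].nunique() < 1:
        raise ValidationError("manifest contains no groups")
    if not bundle.clusters.empty:
        needed = {"sample_id", "fatty_acid", "mass_shift", "intensity"}
        missing = needed - set(bundle.clusters.columns)
        if missing:
            raise ValidationError(f"clusters missing columns: {sorted(missing)}")
        bad = bundle.clusters[bundle.clusters["intensity"] < 0]
        if not bad.empty:
            raise ValidationError(
                f"negative cluster intensity at rows {bad.index[:5].tolist()}"
            )
        for keys, grp in bundle.clusters.groupby(["sample_id", "fatty_acid"]):
            shifts = np.sort(grp["mass_shift"].to_numpy())
            if shifts[0] != 0 or np.any(np.diff(shifts) != 1):
                raise ValidationError(
                    f"cluster shifts not contiguous from 0 for {keys}"
                )
    if not bundle.areas.empty:
        needed = {"sample_id", "fatty_acid", "area"}
        missing = needed - set(bundle.areas.columns)
        if missing:
            raise ValidationError(f"areas missing columns: {sorted(missing)}")


def correct_clusters(
    clusters: pd.DataFrame,
    definitions: dict[str, FattyAcidDefinition] | None = None,
    table: IsotopeTable | None = None,
) -> pd.DataFrame:
    """Natural-abundance-correct every (sample, tissue, analyte) cluster."""
    definitions = definitions or default_definitions()
    rows = []
    group_cols = [c for c in ("sample_id", "tissue", "fatty_acid") if c in clusters.columns]
    for keys, grp in clusters.groupby(group_cols, sort=True):
        keyd = dict(zip(group_cols, keys))
        name = keyd["fatty_acid"]
        if name not in definitions:
            logger.warning("no definition for analyte %r; cluster skipped", name)
            continue
        defn = definitions[name]
        grp = grp.sort_values("mass_shift")
        raw = RawCluster(name, defn.base_mz, grp["intensity"].to_numpy())
        mid = correct_mid(raw, defn.composition, table)
        for shift, fraction in enumerate(mid.fractions):
            rows.append(keyd | {"mass_shift": shift, "fraction": fraction})
    return pd.DataFrame(rows)


def _mid_from_rows(grp: pd.DataFrame) -> MID:
    return MID(grp.sort_values("mass_shift")["fraction"].to_numpy())


def analyze_tracer(
    bundle: StudyBundle,
    corrected: pd.DataFrame,
    definitions: dict[str, FattyAcidDefinition] | None = None,
    amounts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample, per-analyte enrichment estimates.

    Deuterium: body-water p is estimated per sample from palmitate (the
    strongest signal) and applied to that sample's other analytes; FNS and,
    when amounts are available, the synthesis rate (ug/mg/day) follow.
    ¹³C: acetyl-CoA enrichment g is estimated per analyte from its
    consecutive even-peak ratio (M+4/M+2 for palmitate and oleate,
    M+6/M+4 for stearate), then MIDA FNS from the light peaks m2/m4/m6.
    """
    definitions = definitions or default_definitions()
    if corrected.empty:
        return pd.DataFrame()
    manifest = bundle.manifest.drop_duplicates(["sample_id", "tissue"]).set_index(
        ["sample_id", "tissue"]
    )
    amount_lookup = {}
    if amounts is not None and not amounts.empty:
        amount_lookup = {
            (r.sample_id, r.tissue, r.fatty_acid): r.amount_ug_per_mg
            for r in amounts.itertuples(index=False)
        }
    rows = []
    for (sample_id, tissue), per_sample in corrected.groupby(["sample_id", "tissue"]):
        meta = manifest.loc[(sample_id, tissue)]
        tracer = meta["tracer"]
        labeling_days = float(meta.get("labeling_days", np.nan))
        mids = {
            name: _mid_from_rows(grp)
            for name, grp in per_sample.groupby("fatty_acid")
        }
        p_sample = None
        if tracer == "deuterium" and "palmitate" in mids:
            p_sample = estimate_deuterium(
                mids["palmitate"],
                DeuteriumParams(definitions["palmitate"].n_deuterium_sites),
            ).p
        for name in sorted(mids):
            mid = mids[name]
            defn = definitions[name]
            row = {
                "sample_id": sample_id,
                "group": meta["group"],
                "tissue": tissue,
                "fatty_acid": name,
                "tracer": tracer,
            }
            if tracer == "deuterium":
                params = DeuteriumParams(
                    defn.n_deuterium_sites,
                    labeling_days if np.isfinite(labeling_days) else 14.0,
                )
                res = estimate_deuterium(mid, params, p=p_sample)
                row |= {
                    "precursor_enrichment": res.p,
                    "molar_enrichment": res.molar_enrichment,
                    "fns": res.fns,
                }
                amount = amount_lookup.get((sample_id, tissue, name))
                if amount is not None and np.isfinite(labeling_days):
                    row["amount_ug_per_mg"] = amount
                    row["rate_ug_per_mg_per_day"] = synthesis_rate(
                        amount, res.fns, labeling_days
                    )
            elif tracer == "c13":
                params = MidaParams(
                    defn.n_acetyl_units,
                    ratio_pair=MIDA_RATIO_PAIRS.get(name, (4, 2)),
                )
                res = estimate_mida(mid, params)
                row |= {"precursor_enrichment": res.g, "fns": res.fns}
            else:
                continue
            rows.append(row)
    return pd.DataFrame(rows)


def analyze_profile(bundle: StudyBundle) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample fatty-acid profile and internal-standard quantification.

    Returns (profile frame with percents and indices, amounts frame with
    ug analyte per mg tissue).
    """
    if bundle.areas.empty:
        return pd.DataFrame(), pd.DataFrame()
    manifest = bundle.manifest.drop_duplicates(["sample_id", "tissue"]).set_index(
        ["sample_id", "tissue"]
    )
    profile_rows, amount_rows = [], []
    for (sample_id, tissue), grp in bundle.areas.groupby(["sample_id", "tissue"]):
        meta = manifest.loc[(sample_id, tissue)]
        areas = dict(zip(grp["fatty_acid"], grp["area"]))
        is_area = areas.pop(INTERNAL_STANDARD, None)
        base = {
            "sample_id": sample_id,
            "group": meta["group"],
            "tissue": tissue,
        }
        if "palmitate" in areas and areas["palmitate"] > 0:
            percents = profile_percent(areas)
            indices = desaturation_indices(areas)
            profile_rows.append(
                base
                | {f"percent_{k}": v for k, v in sorted(percents.items())}
                | indices
            )
        if (
            is_area
            and is_area > 0
            and "is_quantity_ug" in meta
            and "tissue_mass_mg" in meta
        ):
            quantities = quantify(
                areas,
                is_area=float(is_area),
                is_quantity_ug=float(meta["is_quantity_ug"]),
                tissue_mass_mg=float(meta["tissue_mass_mg"]),
            )
            for name, q in sorted(quantities.items()):
                amount_rows.append(
                    base | {"fatty_acid": name, "amount_ug_per_mg": q}
                )
    return pd.DataFrame(profile_rows), pd.DataFrame(amount_rows)


def analyze_expression(bundle: StudyBundle) -> pd.DataFrame:
    """Per-sample relative expression 2^(-dCt), target normalized to reference."""
    if bundle.ct.empty:
        return pd.DataFrame()
    manifest = bundle.manifest.drop_duplicates(["sample_id", "tissue"]).set_index(
        ["sample_id", "tissue"]
    )
    rows = []
    for r in bundle.ct.itertuples(index=False):
        meta = manifest.loc[(r.sample_id, r.tissue)]
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": meta["group"],
                "tissue": r.tissue,
                "target": r.target,
                "relative_expression": 2.0 ** -(r.ct_target - r.ct_reference),
            }
        )
    return pd.DataFrame(rows)


def _metrics_long(
    tracer_df: pd.DataFrame,
    profile_df: pd.DataFrame,
    expression_df: pd.DataFrame,
) -> pd.DataFrame:
    """Stack all per-sample results into (sample_id, group, tissue, metric, value)."""
    pieces = []
    if not tracer_df.empty:
        value_cols = [
            c
            for c in (
                "precursor_enrichment",
                "fns",
                "amount_ug_per_mg",
                "rate_ug_per_mg_per_day",
            )
            if c in tracer_df.columns
        ]
        long = tracer_df.melt(
            id_vars=["sample_id", "group", "tissue", "fatty_acid"],
            value_vars=value_cols,
            var_name="quantity",
        ).dropna(subset=["value"])
        long["metric"] = long["quantity"] + "_" + long["fatty_acid"]
        pieces.append(long[["sample_id", "group", "tissue", "metric", "value"]])
    if not profile_df.empty:
        value_cols = [
            c
            for c in profile_df.columns
            if c not in ("sample_id", "group", "tissue")
        ]
        long = profile_df.melt(
            id_vars=["sample_id", "group", "tissue"],
            value_vars=value_cols,
            var_name="metric",
        ).dropna(subset=["value"])
        pieces.append(long[["sample_id", "group", "tissue", "metric", "value"]])
    if not expression_df.empty:
        long = expression_df.rename(columns={"relative_expression": "value"}).copy()
        long["metric"] = "relative_expression_" + long["target"]
        pieces.append(long[["sample_id", "group", "tissue", "metric", "value"]])
    if not pieces:
        return pd.DataFrame(columns=["sample_id", "group", "tissue", "metric", "value"])
    return pd.concat(pieces, ignore_index=True)


def summarize(
    metrics: pd.DataFrame,
    groups: tuple[str, str] | None = None,
    welch: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Two-group mean ± SE and unpaired t-test per (tissue, metric)."""
    if metrics.empty:
        return pd.DataFrame()
    if groups is None:
        found = list(dict.fromkeys(metrics["group"]))
        if len(found) != 2:
            raise ValidationError(
                f"expected two groups for summary, found {found}"
            )
        groups = (found[0], found[1])
    rows = []
    for (tissue, metric), grp in metrics.groupby(["tissue", "metric"], sort=True):
        values = {
            g: grp.loc[grp["group"] == g, "value"].to_numpy() for g in groups
        }
        if any(v.size == 0 for v in values.values()):
            continue
        summary = summarize_groups(values, metric=metric, welch=welch)
        rows.append({"tissue": tissue} | summary.as_row())
    df = pd.DataFrame(rows)
    if bh and not df.empty and df["p"].notna().any():
        mask = df["p"].notna()
        df.loc[mask, "p_adjusted"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    return df


def _report_markdown(summary: pd.DataFrame, bundle: StudyBundle) -> str:
    lines = [
        "# Study report",
        "",
        f"lipotrace {__version__}; seed {bundle.seed}; "
        f"{bundle.manifest['sample_id'].nunique()} samples, "
        f"groups: {', '.join(sorted(bundle.manifest['group'].unique()))}",
        "",
        "Values are mean ± SE; unpaired t-test. "
        "Markers: `**` p<0.01, `*` p<0.05, `¥` 0.05≤p<0.10 (strong trend).",
        "",
    ]
    if summary.empty:
        lines.append("_No metrics computed._")
        return "\n".join(lines) + "\n"
    for tissue, grp in summary.groupby("tissue", sort=True):
        g1, g2 = grp.iloc[0][["group_1", "group_2"]]
        lines += [f"## {tissue}", "", f"| metric | {g1} | {g2} | p | |", "|---|---|---|---|---|"]
        for r in grp.itertuples(index=False):
            p_txt = f"{r.p:.4g}" if r.p is not None and np.isfinite(r.p) else "-"
            lines.append(
                f"| {r.metric} | {r.mean_1:.4g} ± {r.se_1:.2g} "
                f"| {r.mean_2:.4g} ± {r.se_2:.2g} | {p_txt} | {r.significance} |"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


def run_pipeline(
    bundle: StudyBundle | str | Path,
    out_dir: str | Path | None = None,
    definitions: dict[str, FattyAcidDefinition] | None = None,
    table: IsotopeTable | None = None,
    welch: bool = False,
    bh: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run every stage on a bundle; optionally write stage CSVs and report.md.

    Returns the stage outputs keyed by name: corrected, tracer, profile,
    amounts, expression, metrics, summary.
    """
    if not isinstance(bundle, StudyBundle):
        bundle = load_bundle(bundle)
    validate_bundle(bundle)
    definitions = definitions or default_definitions()

    corrected = correct_clusters(bundle.clusters, definitions, table) if not bundle.clusters.empty else pd.DataFrame()
    profile_df, amounts_df = analyze_profile(bundle)
    tracer_df = analyze_tracer(bundle, corrected, definitions, amounts=amounts_df)
    expression_df = analyze_expression(bundle)
    metrics = _metrics_long(tracer_df, profile_df, expression_df)
    summary = summarize(metrics, welch=welch, bh=bh)

    results = {
        "corrected": corrected,
        "tracer": tracer_df,
        "profile": profile_df,
        "amounts": amounts_df,
        "expression": expression_df,
        "metrics": metrics,
        "summary": summary,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "report.md").write_text(_report_markdown(summary, bundle))
        (out / "run.yaml").write_text(
            yaml.safe_dump(
                {
                    "lipotrace_version": __version__,
                    "seed": bundle.seed,
                    "n_samples": int(bundle.manifest["sample_id"].nunique()),
                    "welch": welch,
                    "benjamini_hochberg": bh,
                }
            )
        )
        logger.info("pipeline outputs written to %s", out)
    return results
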