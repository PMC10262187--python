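"""End-to-end orchestration: score -> filter -> normalize -> features ->
univariate -> discriminant -> mixed-model suite -> longitudinal.

Every run writes tidy result tables plus a manifest that reconciles row
counts at each stage (analyzed = input - excluded), mirroring the
flowchart-style accounting used when reporting survey cohorts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features, inference, mixed, normalize
from .mctq import apply_sigma_filter, score_frame
from .simulate import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)

#: Columns a raw cohort CSV must provide.
REQUIRED_COLUMNS = (
    "participant_id",
    "household_id",
    "age",
    "sex",
    "sleep_onset_work",
    "sleep_end_work",
    "sleep_onset_free",
    "sleep_end_free",
)


class SchemaError(ValueError):
    """Raised when an input table does not match the documented schema."""


def read_cohort(path, sep: str = ",") -> pd.DataFrame:
    """Read a cohort CSV with the documented column names (UTF-8)."""
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table {path} is missing required columns: {missing}")
    return df


@dataclass
class RunManifest:
    """Row-count ledger and provenance for one pipeline run."""

    seed: int | None = None
    config_hash: str = ""
    started: str = ""
    finished: str = ""
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, n_input: int, n_excluded: int, **extra):
        entry = {"input": int(n_input), "excluded": int(n_excluded),
                 "analyzed": int(n_input - n_excluded)}
        entry.update(extra)
        self.stages[stage] = entry

    def reconciles(self) -> bool:
        return all(
            s["analyzed"] == s["input"] - s["excluded"] for s in self.stages.values()
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config_hash": self.config_hash,
                "started": self.started,
                "finished": self.finished,
                "stages": self.stages,
            },
            indent=2,
        )


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    manifest: RunManifest
    univariate: pd.DataFrame | None = None
    discriminant: inference.DiscriminantResult | None = None
    suite_table: pd.DataFrame | None = None
    suite_lr: dict | None = None
    longitudinal: pd.DataFrame | None = None
    chronotype_model: normalize.AgeSexCubic | None = None
    sjl_split: features.BinaryCategorization | None = None


def run_pipeline(
    data: pd.DataFrame | None = None,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    simulate: bool = False,
    followup: pd.DataFrame | None = None,
    out_dir=None,
) -> PipelineResult:
    """Execute all analysis stages on ``data`` (or a simulated cohort).

    With ``simulate=True`` a synthetic dataset (including a follow-up wave)
    is generated from ``config`` and ``seed``. Stages degrade gracefully:
    without biomarker columns the discriminant and model-suite stages are
    skipped with a notice; without a follow-up wave the longitudinal stage
    is skipped.
    """
    manifest = RunManifest(seed=seed)
    manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")
    if simulate:
        config = config or GeneratorConfig()
        ds = generate_dataset(config, seed=seed, followup=True)
        data = ds.cohort
        followup = ds.followup
        manifest.config_hash = hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]
    if data is None:
        raise ValueError("run_pipeline needs data or simulate=True")

    # -- scoring ----------------------------------------------------------
    n0 = len(data)
    scored = score_frame(data)
    cohort = data.join(scored.drop(columns=["participant_id"]))
    invalid = (~scored["valid_sjl"]).sum()
    manifest.record("score", n0, invalid)

    # -- outlier filter ----------------------------------------------------
    profiles, exclusion_log = apply_sigma_filter(cohort)
    cohort = profiles
    manifest.record(
        "sigma_filter",
        int(n0 - invalid),
        int((cohort["exclusion_reason"] == "outlier").sum()),
    )

    # -- normalization -----------------------------------------------------
    chrono_model = None
    usable = cohort["valid_msfsc"].astype(bool) & (cohort["age"] >= 18)
    if usable.sum() >= 20:
        cohort, chrono_model = normalize.add_normalized_columns(cohort)
        manifest.record("normalize", int(n0), int(n0 - usable.sum()))

    # -- features ----------------------------------------------------------
    if {"height_m", "weight_kg"} <= set(cohort.columns):
        bmi, bmi_ok = features.compute_bmi(cohort["height_m"], cohort["weight_kg"])
        cohort["BMI"] = bmi
    for spec in (features.TIME_STRESS_SPEC, features.DISEASES_SPEC):
        if set(spec.items) <= set(cohort.columns):
            cohort[spec.name] = features.composite_index(cohort, spec)
    has_panel = set(features.BIOMARKER_COLUMNS) <= set(cohort.columns)
    if has_panel and "lab_id" in cohort.columns:
        for marker in list(features.BIOMARKER_COLUMNS) + (
            ["AIP"] if "AIP" in cohort.columns else []
        ):
            cohort[f"{marker}_centered"] = features.batch_center(
                cohort[marker].to_numpy(), cohort["lab_id"].to_numpy()
            )
        if "AIP" not in cohort.columns:
            cohort["AIP"] = features.compute_aip(cohort["TAG"], cohort["HDL"])
    cohort["sex_male"] = (cohort["sex"] == "male").astype(float)

    sjl_split = None
    valid_sjl = cohort.loc[cohort["valid_sjl"].astype(bool), "SJL"]
    if valid_sjl.notna().sum() >= 10:
        sjl_split = features.quantile_binarize(cohort["SJL"].to_numpy(), variable="SJL")
        cohort["sjl_group"] = sjl_split.apply(cohort["SJL"].to_numpy())
        cohort.loc[~cohort["valid_sjl"].astype(bool), "sjl_group"] = None
    if "age" in cohort.columns:
        cohort["age_group"] = np.where(
            cohort["age"] <= features.AGE_SPLIT_THRESHOLD, "younger", "older"
        )

    # -- univariate --------------------------------------------------------
    uni_rows = []
    if has_panel and sjl_split is not None:
        mask = cohort["sjl_group"].notna()
        for marker in ("CHL", "LDL", "HDL", "TAG"):
            lo = cohort.loc[mask & (cohort["sjl_group"] == "low"), f"{marker}_centered"]
            hi = cohort.loc[mask & (cohort["sjl_group"] == "high"), f"{marker}_centered"]
            if len(lo.dropna()) and len(hi.dropna()):
                t = inference.mann_whitney(hi, lo)
                uni_rows.append({"analysis": f"{marker}_by_sjl_group", "method": t.method,
                                 "statistic": t.statistic, "p_value": t.p_value,
                                 "effect": t.effect})
    if has_panel and "chronotype_category" in cohort.columns:
        groups = [
            cohort.loc[cohort["chronotype_category"] == c, "cortisol_centered"].dropna()
            for c in (normalize.CATEGORY_EARLY, normalize.CATEGORY_MID, normalize.CATEGORY_LATE)
        ]
        if all(len(g) > 1 for g in groups):
            omnibus, dunn = inference.kruskal_dunn(groups)
            uni_rows.append({"analysis": "cortisol_by_chronotype_category",
                             "method": omnibus.method, "statistic": omnibus.statistic,
                             "p_value": omnibus.p_value, "effect": float("nan")})
    if chrono_model is not None:
        sub = cohort.dropna(subset=["SJL", "MSF_sc", "age"])
        if len(sub) >= 10:
            t = inference.partial_spearman(
                sub["SJL"], sub["MSF_sc"], [sub["age"], sub["sex_male"]]
            )
            uni_rows.append({"analysis": "sjl_vs_chronotype_partial", "method": t.method,
                             "statistic": t.statistic, "p_value": t.p_value,
                             "effect": t.effect})
    univariate = pd.DataFrame(uni_rows) if uni_rows else None

    # -- discriminant ------------------------------------------------------
    discriminant = None
    if has_panel and sjl_split is not None:
        feat_cols = [f"{m}_centered" for m in features.BIOMARKER_COLUMNS]
        sub = cohort.dropna(subset=feat_cols + ["sjl_group"])
        if len(sub) >= 40:
            discriminant = inference.lda_two_class(
                sub[feat_cols].to_numpy(), sub["sjl_group"].to_numpy(), seed=seed
            )

    # -- mixed-model suite -------------------------------------------------
    suite_table, suite_lr = None, None
    if has_panel and chrono_model is not None:
        model_cols = {m: f"{m}_centered" for m in ("CHL", "LDL", "HDL", "TAG")}
        model_cols["AIP"] = "AIP_centered" if "AIP_centered" in cohort.columns else "AIP"
        suite_input = cohort.copy()
        for outcome, col in model_cols.items():
            suite_input[outcome] = cohort[col]
        try:
            suite_table, _, suite_lr = mixed.run_biomarker_suite(suite_input)
            manifest.record(
                "mixed_models",
                int(len(suite_input)),
                int(len(suite_input)) - int(suite_table["n"].max()),
            )
        except (KeyError, ValueError) as err:
            logger.warning("mixed-model suite skipped: %s", err)
    elif not has_panel:
        logger.info("no biomarker panel found: discriminant and model suite skipped")

    # -- longitudinal ------------------------------------------------------
    longitudinal = None
    if followup is not None:
        rows = []
        for group, mask in (
            ("home_office", followup["home_office"]),
            ("same_schedule", ~followup["home_office"]),
        ):
            sub = followup[mask]
            for var in ("MSF_sc", "SJL", "SD_week"):
                t, summary = inference.wilcoxon_paired(sub[f"{var}_w1"], sub[f"{var}_w2"])
                rows.append({
                    "group": group, "variable": var, "n_pairs": summary["n_pairs"],
                    "mean_diff_h": summary["mean_diff"],
                    "mean_diff_min": summary["mean_diff"] * 60.0,
                    "median_diff_h": summary["median_diff"],
                    "statistic": t.statistic, "p_value": t.p_value,
                })
        longitudinal = pd.DataFrame(rows)
        manifest.record("longitudinal", int(len(followup)), 0)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    result = PipelineResult(
        cohort=cohort,
        manifest=manifest,
        univariate=univariate,
        discriminant=discriminant,
        suite_table=suite_table,
        suite_lr=suite_lr,
        longitudinal=longitudinal,
        chronotype_model=chrono_model,
        sjl_split=sjl_split,
    )
    if out_dir is not None:
        write_results(result, out_dir, exclusion_log=exclusion_log)
    return result


def write_results(result: PipelineResult, out_dir, exclusion_log=None, force: bool = True):
    """Write all result tables, models, and the manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _target(name):
        path = out / name
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
        return path

    result.cohort.to_csv(_target("cohort_scored.csv"), index=False)
    if exclusion_log is not None:
        exclusion_log.to_csv(_target("exclusions.csv"), index=False)
    if result.univariate is not None:
        result.univariate.to_csv(_target("univariate.csv"), index=False)
    if result.suite_table is not None:
        result.suite_table.to_csv(_target("mixed_models.csv"), index=False)
    if result.suite_lr:
        lr_payload = {
            k: {"statistic": v.statistic, "df": v.df, "p_value": v.p_value}
            for k, v in result.suite_lr.items()
        }
        _target("mixed_models_lr.json").write_text(json.dumps(lr_payload, indent=2))
    if result.longitudinal is not None:
        result.longitudinal.to_csv(_target("longitudinal.csv"), index=False)
    if result.chronotype_model is not None:
        _target("chronotype_model.json").write_text(result.chronotype_model.to_json())
    if result.sjl_split is not None:
        _target("thresholds.json").write_text(
            json.dumps({"SJL": result.sjl_split.threshold}, indent=2)
        )
    if result.discriminant is not None:
        d = result.discriminant
        _target("discriminant.json").write_text(json.dumps({
            "accuracy_mean": d.accuracy_mean,
            "accuracy_sd": d.accuracy_sd,
            "confusion": d.confusion.tolist(),
            "separation_p": d.separation.p_value,
            "classes": list(d.classes),
        }, indent=2))
    _target("manifest.json").write_text(result.manifest.to_json())
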