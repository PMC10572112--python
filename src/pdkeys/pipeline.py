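"""End-to-end orchestration: data in, report tables out.

A run — real keystroke logs or a synthetic cohort — produces the full set
of report artifacts:

* ``features.csv`` — per-subject feature table;
* ``outlier_report.csv`` / ``outlier_by_subject.csv`` — removal counts per
  latency kind and pooled per subject;
* ``group_comparison.csv`` — per-feature group means ± SD, Kruskal-Wallis
  omnibus and rank post hoc p-values;
* ``screening_<case>.csv`` + ``delong_<case>.csv`` per contrast — AUC with
  exact binomial CI, Youden operating point, pairwise DeLong p-values;
* ``correlations_<group>.csv`` — Spearman vs UPDRS-III within each patient
  group;
* ``resolved_config.yaml`` and ``run_manifest.json`` — the frozen
  configuration and per-stage counts of the run.

Contrasts are explicit and never pooled: newly diagnosed (de novo) and
treated early-PD patients are screened against controls separately, since
treatment visibly changes which markers discriminate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import comparison_table, correlation_table
from .fluctuation import build_feature_record
from .io import (
    FEATURE_TABLE_COLUMNS,
    SubjectMetadata,
    read_metadata,
    read_sessions,
    select_first_visit,
    write_feature_table,
)
from .outliers import OutlierPolicy, OutlierReport
from .screening import DEFAULT_ORIENTATIONS, delong_matrix, screen_features
from .simulate import CohortSpec, default_cohort_spec, generate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "build_feature_table"]

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = [
    "hl_sd", "il_sd", "pl_sd", "rl_sd", "sd_restricted",
    "typing_speed", "word_count", "nqi", "stap", "aftap",
]
DEFAULT_CONTRASTS = [("de_novo_pd", "control"), ("early_pd", "control")]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "real"
    keystrokes_path: str | None = None
    metadata_path: str | None = None
    cohort_spec: CohortSpec | None = None
    policy: OutlierPolicy = field(default_factory=OutlierPolicy)
    features: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURES))
    contrasts: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_CONTRASTS))
    orientations: dict[str, str] = field(default_factory=dict)
    outdir: str = "pdkeys_run"
    seed: int = 0
    word_convention: str = "space_plus_one"
    pair_policy: str = "compact"
    posthoc: str = "nemenyi"
    log_level: str = "INFO"

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["policy"] = dataclasses.asdict(self.policy)
        if self.cohort_spec is not None:
            d["cohort_spec"] = {
                "seed": self.cohort_spec.seed,
                "groups": [dataclasses.asdict(g) for g in self.cohort_spec.groups],
            }
        d["version"] = __version__
        return d


def build_feature_table(
    sessions,
    metadata: list[SubjectMetadata],
    policy: OutlierPolicy = OutlierPolicy(),
    word_convention: str = "space_plus_one",
    pair_policy: str = "compact",
) -> tuple[pd.DataFrame, OutlierReport]:
    """Per-subject feature records for a list of sessions + metadata."""
    meta_by_id = {m.subject_id: m for m in metadata}
    report = OutlierReport()
    rows = []
    for session in sessions:
        meta = meta_by_id.get(session.subject_id)
        record, out_records = build_feature_record(
            session, meta, policy, word_convention=word_convention, pair_policy=pair_policy
        )
        for r in out_records:
            report.add(r)
        rows.append(record.__dict__)
    df = pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)
    return df, report


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run and return the output directory.

    Any stage error aborts with a stage-named :class:`PipelineError`; in
    that case the manifest written next to the partial outputs is marked
    incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pdkeys")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {"version": __version__, "seed": config.seed, "complete": False}
    try:
        _run(config, outdir, manifest)
        manifest["complete"] = True
    finally:
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        root.removeHandler(handler)
        handler.close()
    return outdir


def _run(config: RunConfig, outdir: Path, manifest: dict) -> None:
    # ---- input stage -----------------------------------------------------
    if config.mode == "synthetic":
        spec = config.cohort_spec or default_cohort_spec()
        cohort = _stage("simulate")(generate_cohort, spec, config.seed)
        sessions, metadata = cohort.sessions, cohort.metadata
        cohort.truth.to_csv(outdir / "ground_truth.csv", index=False)
    elif config.mode == "real":
        if not config.keystrokes_path or not config.metadata_path:
            raise PipelineError("stage 'read' failed: real mode needs keystrokes and metadata paths")
        sessions = _stage("read")(read_sessions, config.keystrokes_path)
        sessions = _stage("read")(select_first_visit, sessions)
        metadata = _stage("read")(read_metadata, config.metadata_path)
    else:
        raise PipelineError(f"stage 'config' failed: unknown mode {config.mode!r}")
    manifest["n_sessions"] = len(sessions)
    manifest["n_events"] = int(sum(len(s) for s in sessions))
    manifest["n_events_rejected"] = int(
        sum(s.read_report.n_rejected_negative_hold for s in sessions)
    )
    logger.info("input: %d sessions, %d events", len(sessions), manifest["n_events"])

    # ---- features --------------------------------------------------------
    features_df, outlier_report = _stage("features")(
        build_feature_table, sessions, metadata, config.policy,
        config.word_convention, config.pair_policy,
    )
    _validated_write(features_df, FEATURE_TABLE_COLUMNS, outdir / "features.csv")
    out_df = outlier_report.to_frame()
    out_df.to_csv(outdir / "outlier_report.csv", index=False)
    outlier_report.pooled_by_subject().to_csv(outdir / "outlier_by_subject.csv", index=False)
    manifest["n_outliers_removed"] = int(
        (out_df["n_negative_removed"] + out_df["n_iqr_removed"]).sum()
    )
    manifest["n_subjects_missing_per_feature"] = {
        f: int(features_df[f].isna().sum()) for f in config.features
    }

    # ---- group comparison ------------------------------------------------
    comp = _stage("group_comparison")(
        comparison_table, features_df, config.features + ["updrs3"], posthoc=config.posthoc
    )
    comp.to_csv(outdir / "group_comparison.csv", index=False)

    # ---- screening per contrast ------------------------------------------
    orientations = {**DEFAULT_ORIENTATIONS, **config.orientations}
    for case_group, control_group in config.contrasts:
        results = _stage("screening")(
            screen_features, features_df, config.features, case_group, control_group,
            orientations,
        )
        rows = [
            {
                "feature": r.feature_name,
                "orientation": r.orientation,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "auc": r.auc,
                "ci_low": r.auc_ci95[0],
                "ci_high": r.auc_ci95[1],
                "cutoff": r.cutoff,
                "sensitivity": r.sensitivity_at_cutoff,
                "specificity": r.specificity_at_cutoff,
            }
            for r in results
        ]
        sdf = pd.DataFrame(rows)
        _validated_write(
            sdf,
            ["feature", "orientation", "n_cases", "n_controls", "auc",
             "ci_low", "ci_high", "cutoff", "sensitivity", "specificity"],
            outdir / f"screening_{case_group}.csv",
        )
        dmat = _stage("delong")(
            delong_matrix, features_df, config.features, case_group, control_group,
            orientations,
        )
        dmat.to_csv(outdir / f"delong_{case_group}.csv")

    # ---- severity correlations -------------------------------------------
    for group in ("de_novo_pd", "early_pd"):
        if not (features_df["group"] == group).any():
            continue
        corrs = _stage("correlations")(
            correlation_table, features_df, config.features, group
        )
        cdf = pd.DataFrame(
            [{"feature": c.feature_name, "group": c.group, "rho": c.rho,
              "p_value": c.p_value, "n": c.n, "reason": c.reason} for c in corrs]
        )
        cdf.to_csv(outdir / f"correlations_{group}.csv", index=False)

    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=False)


def _validated_write(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    """Schema check before write; missing stays missing (empty field)."""
    missing = set(columns) - set(df.columns)
    if missing:
        raise PipelineError(f"stage 'write' failed: {path.name} missing columns {sorted(missing)}")
    df[columns].to_csv(path, index=False, na_rep="")
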