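"""End-to-end pipeline: file I/O, configuration and the two study arms.

The study design has two arms:

* a **within-group** arm — the same participants perform timed functional
  tasks with both prosthetic hands; completion times are compared by paired
  t tests and the kinematic metrics (RoM, KV, KR) by a 2 x 7
  repeated-measures ANOVA (prosthetic hand x joint angle) per task, with the
  shoulder coordination pattern tabulated as JC_SIM / JC_DIFF;
* a **between-group** arm — two independent user groups complete
  questionnaires; continuous measures are routed by Shapiro-Wilk normality
  to a Levene-routed unpaired t test or a Mann-Whitney test, nominal
  characteristics to chi-squared with Cramer's V.

Tables are exchanged as UTF-8 CSV. Joint-angle recordings use a long format
(participant_id, condition, task, trial, time_s, joint, angle_deg). Reports
are written twice: full precision, and rounded to the reporting convention
(statistic 1 dp, p 2 dp, effect size 1 dp).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import group_stats as gs
from . import kinematics as km
from .kinematics import (
    JOINTS,
    CONDITIONS,
    JointAngleTrial,
    KinematicSummary,
    NormalizedTrial,
    ProcessingConfig,
)

logger = logging.getLogger("prokin")

JOINT_ANGLE_COLUMNS = (
    "participant_id", "condition", "task", "trial", "time_s", "joint", "angle_deg",
)


class SchemaError(ValueError):
    """A CSV is missing required columns or malformed."""


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Run-level configuration for the analysis pipeline."""

    input_path: str | None = None
    output_dir: str = "prokin_out"
    onset_velocity_threshold_deg_s: float = km.DEFAULT_ONSET_VELOCITY_DEG_S
    sustain_ms: float = km.DEFAULT_SUSTAIN_MS
    return_tolerance_deg: float = km.DEFAULT_RETURN_TOLERANCE_DEG
    baseline_window_s: float = km.DEFAULT_BASELINE_WINDOW_S
    max_step_deg: float = km.DEFAULT_MAX_STEP_DEG
    angle_bounds_deg: tuple[float, float] = km.DEFAULT_ANGLE_BOUNDS_DEG
    variance_policy: str = "auto"
    alpha: float = 0.01
    round_reports: bool = True
    seed: int = 0
    instrument_tables: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.variance_policy not in ("auto", "pooled", "welch"):
            raise ConfigError(f"unknown variance_policy: {self.variance_policy}")
        for name in (
            "onset_velocity_threshold_deg_s", "sustain_ms",
            "return_tolerance_deg", "baseline_window_s", "max_step_deg",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def processing(self) -> ProcessingConfig:
        return ProcessingConfig(
            onset_velocity_threshold_deg_s=self.onset_velocity_threshold_deg_s,
            sustain_ms=self.sustain_ms,
            return_tolerance_deg=self.return_tolerance_deg,
            baseline_window_s=self.baseline_window_s,
            max_step_deg=self.max_step_deg,
            angle_bounds_deg=tuple(self.angle_bounds_deg),
        )


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"unknown config field: {exc}") from exc


# ---------------------------------------------------------------------------
# Joint-angle CSV dialect
# ---------------------------------------------------------------------------

def write_joint_angle_csv(trials: Sequence[JointAngleTrial], path) -> None:
    """Write trials in the long joint-angle CSV dialect."""
    frames = []
    for t in trials:
        n = t.n_samples
        time_s = np.arange(n) / t.sample_rate_hz
        for j in JOINTS:
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": t.participant_id,
                        "condition": t.condition,
                        "task": t.task,
                        "trial": t.trial_index,
                        "time_s": time_s,
                        "joint": j,
                        "angle_deg": t.angles[j],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_joint_angle_csv(path) -> list[JointAngleTrial]:
    """Read the long joint-angle CSV dialect back into trials."""
    df = pd.read_csv(path)
    missing = set(JOINT_ANGLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"joint-angle CSV missing columns: {sorted(missing)}")
    trials = []
    for (pid, cond, task, k), g in df.groupby(
        ["participant_id", "condition", "task", "trial"], sort=True
    ):
        angles = {}
        fs = None
        for joint, gj in g.groupby("joint"):
            gj = gj.sort_values("time_s")
            angles[joint] = gj["angle_deg"].to_numpy()
            times = gj["time_s"].to_numpy()
            if len(times) >= 2:
                fs = 1.0 / float(np.median(np.diff(times)))
        if fs is None:
            raise SchemaError(f"trial {pid}/{cond}/{task}/{k} has fewer than 2 samples")
        trials.append(
            JointAngleTrial(
                participant_id=str(pid), condition=str(cond), task=str(task),
                trial_index=int(k), sample_rate_hz=fs, angles=angles,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Kinematic analysis over a dataset
# ---------------------------------------------------------------------------

@dataclass
class DatasetAnalysis:
    """Kinematic summaries, QC reports and coordination labels for a dataset."""

    summaries: list[KinematicSummary]
    qc: list[km.ArtifactReport]
    normalized: dict[tuple[str, str], list[NormalizedTrial]]  # (pid, cond) -> trials
    coordination: list[km.CoordinationAssessment]
    skipped_sets: list[str]


def analyze_dataset(
    trials: Sequence[JointAngleTrial], config: RunConfig = RunConfig()
) -> DatasetAnalysis:
    """Run the per-set kinematic chain over every participant/condition/task."""
    proc = config.processing()
    by_set: dict[tuple[str, str, str], list[JointAngleTrial]] = {}
    for t in trials:
        by_set.setdefault((t.participant_id, t.condition, t.task), []).append(t)

    summaries: list[KinematicSummary] = []
    qc: list[km.ArtifactReport] = []
    normalized: dict[tuple[str, str], list[NormalizedTrial]] = {}
    skipped: list[str] = []
    for key in sorted(by_set):
        pid, cond, task = key
        try:
            summary, reports, norm = km.summarize_participant(by_set[key], proc)
        except km.NoAnalyzableTrialsError as exc:
            logger.warning("skipping %s/%s/%s: %s", pid, cond, task, exc)
            qc.extend(exc.reports)
            skipped.append(f"{pid}/{cond}/{task}")
            continue
        summaries.append(summary)
        qc.extend(reports)
        normalized.setdefault((pid, cond), []).extend(norm)

    coordination = []
    pids = sorted({pid for pid, _ in normalized})
    for pid in pids:
        by_cond = {c: normalized.get((pid, c), []) for c in CONDITIONS}
        try:
            coordination.append(km.classify_coordination(by_cond, pid))
        except km.KinematicsError as exc:
            logger.warning("coordination: %s", exc)
    return DatasetAnalysis(summaries, qc, normalized, coordination, skipped)


def summaries_to_frame(summaries: Sequence[KinematicSummary]) -> pd.DataFrame:
    """One row per participant x condition x task x joint."""
    rows = []
    for s in summaries:
        for j in JOINTS:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "condition": s.condition,
                    "task": s.task,
                    "joint": j,
                    "rom_mean_deg": s.rom_mean_deg[j],
                    "kv_deg": s.kv_deg[j] if s.kv_deg else np.nan,
                    "kr": s.kr[j] if s.kr else np.nan,
                    "n_trials_included": s.n_trials_included,
                    "n_trials_excluded": s.n_trials_excluded,
                    "completion_time_mean_s": s.completion_time_mean_s,
                    "completion_time_sd_s": s.completion_time_sd_s,
                }
            )
    return pd.DataFrame(rows)


def qc_to_frame(reports: Sequence[km.ArtifactReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": r.participant_id,
            "condition": r.condition,
            "task": r.task,
            "trial": r.trial_index,
            "excluded": r.excluded,
            "reasons": "; ".join(r.reasons),
        }
        for r in reports
    )


# ---------------------------------------------------------------------------
# Within-group comparison (paired: both conditions in the same participants)
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Full-precision comparison table plus a rounded presentation twin."""

    table: pd.DataFrame
    alpha: float = 0.01
    notes: list[str] = field(default_factory=list)

    def rounded(self) -> pd.DataFrame:
        out = self.table.copy()
        for col, nd in (("statistic", 1), ("df", 1), ("df2", 1),
                        ("p_value", 2), ("effect_size", 1)):
            if col in out.columns:
                out[col] = pd.to_numeric(out[col], errors="coerce").round(nd)
        return out

    def write(self, outdir, stem: str) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / f"{stem}_full.csv", index=False)
        self.rounded().to_csv(outdir / f"{stem}.csv", index=False)


def _result_row(res: gs.StatTestResult, **labels) -> dict:
    row = dict(labels)
    row.update(
        test=res.method, statistic=res.statistic, df=res.df, df2=res.df2,
        p_value=res.p_value, effect_size=res.effect_size,
        effect_metric=res.effect_metric, effect_label=res.effect_label,
        significant=res.significant,
    )
    for k, v in res.extras.items():
        row[k] = v
    return row


def run_within_comparison(
    trials: Sequence[JointAngleTrial], config: RunConfig = RunConfig()
) -> tuple[ComparisonReport, DatasetAnalysis]:
    """Paired MHP-vs-SHP comparison of completion times and kinematics.

    Completion-time means and SDs are compared per task by paired t tests;
    RoM, KV and KR each by the 2 x 7 repeated-measures ANOVA per task.
    Participants missing a condition are excluded with a logged reason.
    """
    analysis = analyze_dataset(trials, config)
    sm = summaries_to_frame(analysis.summaries)
    rows: list[dict] = []
    notes: list[str] = list(analysis.skipped_sets)

    per_set = sm.drop_duplicates(["participant_id", "condition", "task"])[
        ["participant_id", "condition", "task",
         "completion_time_mean_s", "completion_time_sd_s"]
    ]
    for task in km.TASKS:
        tdf = per_set[per_set["task"] == task].pivot(
            index="participant_id", columns="condition",
            values=["completion_time_mean_s", "completion_time_sd_s"],
        )
        if tdf.empty:
            continue
        complete = tdf.dropna()
        dropped = sorted(set(tdf.index) - set(complete.index))
        for pid in dropped:
            msg = f"{pid} lacks a condition for task {task}; excluded from pairing"
            logger.warning(msg)
            notes.append(msg)
        for measure, col in (
            ("completion_time_mean", "completion_time_mean_s"),
            ("completion_time_sd", "completion_time_sd_s"),
        ):
            x = complete[(col, "MHP")].to_numpy()
            y = complete[(col, "SHP")].to_numpy()
            if len(x) < 2:
                continue
            try:
                res = gs.paired_t(x, y)
            except gs.StatError as exc:
                notes.append(f"{task}/{measure}: degenerate ({exc})")
                continue
            res.alpha = config.alpha
            rows.append(
                _result_row(
                    res, task=task, measure=measure,
                    mhp_mean=float(np.mean(x)), mhp_sd=float(np.std(x, ddof=1)),
                    shp_mean=float(np.mean(y)), shp_sd=float(np.std(y, ddof=1)),
                )
            )

    for metric in ("rom_mean_deg", "kv_deg", "kr"):
        for task in km.TASKS:
            tdf = sm[sm["task"] == task][
                ["participant_id", "condition", "joint", metric]
            ].rename(
                columns={"participant_id": "subject", "condition": "hand",
                         metric: "value"}
            )
            if tdf.empty:
                continue
            # keep subjects with a complete 2 x 7 design
            counts = tdf.dropna().groupby("subject")["value"].count()
            keep = counts[counts == 2 * len(JOINTS)].index
            tdf = tdf[tdf["subject"].isin(keep)].dropna()
            if tdf["subject"].nunique() < 3:
                notes.append(f"{task}/{metric}: fewer than 3 complete subjects")
                continue
            try:
                anova = gs.rm_anova_hand_by_joint(tdf)
            except gs.StatError as exc:
                notes.append(f"{task}/{metric}: ANOVA failed ({exc})")
                continue
            for t in anova.tables:
                rows.append(
                    {
                        "task": task, "measure": f"{metric}:{t.effect}",
                        "test": "rm_anova", "statistic": t.F,
                        "df": t.df_num, "df2": t.df_den, "p_value": t.p_value,
                        "effect_size": t.eta_g_sq, "effect_metric": "eta_g_sq",
                        "effect_label": gs.classify_effect(t.eta_g_sq, "eta_g_sq"),
                        "significant": t.p_value < config.alpha,
                        "epsilon_gg": t.epsilon_gg, "mauchly_w": t.mauchly_w,
                        "mauchly_p": t.mauchly_p,
                    }
                )

    labels = pd.Series([c.label for c in analysis.coordination])
    for label, count in labels.value_counts().items():
        rows.append(
            {"task": "RCRT", "measure": f"coordination:{label}", "test": "count",
             "statistic": float(count)}
        )
    report = ComparisonReport(pd.DataFrame(rows), alpha=config.alpha, notes=notes)
    return report, analysis


# ---------------------------------------------------------------------------
# Between-group comparison (two independent groups of questionnaire scores)
# ---------------------------------------------------------------------------

def run_between_comparison(
    scores: pd.DataFrame, config: RunConfig = RunConfig(),
    group_col: str = "group",
) -> ComparisonReport:
    """Two-group comparison per measure with SPSS-style routing.

    Numeric measures: Shapiro-Wilk on each group (alpha = 0.05); both normal
    -> Levene-routed unpaired t; otherwise Mann-Whitney (median/IQR
    reported). Non-numeric measures: chi-squared with Cramer's V.
    """
    if group_col not in scores.columns:
        raise SchemaError(f"score table missing column: {group_col}")
    groups = sorted(scores[group_col].unique())
    if len(groups) != 2:
        raise SchemaError(f"expected exactly 2 groups, found {groups}")
    g1, g2 = groups
    rows: list[dict] = []
    notes: list[str] = []
    measures = [
        c for c in scores.columns if c not in (group_col, "participant_id")
    ]
    for measure in measures:
        col = scores[measure]
        x = col[scores[group_col] == g1].dropna()
        y = col[scores[group_col] == g2].dropna()
        if x.empty or y.empty:
            notes.append(f"{measure}: present in one group only; skipped")
            continue
        if pd.api.types.is_numeric_dtype(col):
            xv, yv = x.to_numpy(float), y.to_numpy(float)
            if np.ptp(xv) == 0 and np.ptp(yv) == 0:
                notes.append(f"{measure}: constant in both groups; degenerate")
                rows.append({"measure": measure, "test": "degenerate"})
                continue
            try:
                _, _, x_norm = gs.check_normality(xv)
                _, _, y_norm = gs.check_normality(yv)
                parametric = x_norm and y_norm
            except gs.StatError:
                parametric = False
            try:
                if parametric:
                    res = gs.independent_t(xv, yv, config.variance_policy)
                else:
                    res = gs.mann_whitney(xv, yv)
            except gs.StatError as exc:
                notes.append(f"{measure}: degenerate ({exc})")
                rows.append({"measure": measure, "test": "degenerate"})
                continue
            res.alpha = config.alpha
            row = _result_row(
                res, measure=measure,
                mhp_mean=float(np.mean(xv)), mhp_sd=float(np.std(xv, ddof=1)),
                shp_mean=float(np.mean(yv)), shp_sd=float(np.std(yv, ddof=1)),
            )
            if not parametric:
                row.update(
                    mhp_median=float(np.median(xv)),
                    mhp_iqr=float(np.percentile(xv, 75) - np.percentile(xv, 25)),
                    shp_median=float(np.median(yv)),
                    shp_iqr=float(np.percentile(yv, 75) - np.percentile(yv, 25)),
                )
            rows.append(row)
        else:
            table = pd.crosstab(scores[group_col], col)
            try:
                res = gs.chi_squared(table.to_numpy())
            except gs.StatError as exc:
                notes.append(f"{measure}: degenerate table ({exc})")
                rows.append({"measure": measure, "test": "degenerate"})
                continue
            res.alpha = config.alpha
            rows.append(_result_row(res, measure=measure))
    return ComparisonReport(pd.DataFrame(rows), alpha=config.alpha, notes=notes)


# ---------------------------------------------------------------------------
# Condition-order metadata (blocked randomization, recorded but not analyzed)
# ---------------------------------------------------------------------------

def blocked_condition_order(participant_ids: Sequence[str], seed: int) -> pd.DataFrame:
    """Blocked randomization of condition order (blocks of 2), as metadata."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    orders = []
    block = []
    for pid in participant_ids:
        if not block:
            block = [("MHP", "SHP"), ("SHP", "MHP")]
            rng.shuffle(block)
        orders.append(block.pop())
    return pd.DataFrame(
        {
            "participant_id": list(participant_ids),
            "first_condition": [o[0] for o in orders],
            "second_condition": [o[1] for o in orders],
        }
    )
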