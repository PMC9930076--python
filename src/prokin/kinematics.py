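"""Body-function kinematic analysis for upper-limb prosthesis trials.

Implements the per-trial and per-participant processing chain used to compare
a multi-grip myoelectric hand prosthesis (MHP) with a standard myoelectric
hand prosthesis (SHP) on upper-body kinematics:

1. movement segmentation (velocity-threshold onset, return-to-baseline offset),
2. artifact screening (gimbal-lock-like spikes, out-of-range angles),
3. time normalization of the movement segment to 500 samples (cubic spline),
4. per-trial range of motion (RoM) on the raw segment,
5. kinematic variability (KV): time-averaged across-trial SD of the
   normalized waveforms,
6. kinematic repeatability (KR): the adjusted coefficient of multiple
   determination across normalized trials,
7. classification of the shoulder rotation/abduction coordination pattern as
   similar (JC_SIM) or different (JC_DIFF) between the two prosthesis
   conditions.

Angles are Euler joint angles in degrees, sampled at a fixed rate (60 Hz in
the motivating protocol). Seven joint angles are tracked: three trunk, three
shoulder, one elbow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

# The seven tracked joint angles, in canonical order.
JOINTS: tuple[str, ...] = (
    "trunk_flexion_extension",
    "trunk_axial_bending",
    "trunk_lateral_bending",
    "shoulder_flexion_extension",
    "shoulder_internal_external_rotation",
    "shoulder_abduction_adduction",
    "elbow_flexion_extension",
)

#: Shoulder angles used for onset/offset detection (humeral elevation drives
#: all three tasks).
SEGMENTATION_JOINTS: tuple[str, str] = (
    "shoulder_flexion_extension",
    "shoulder_abduction_adduction",
)

#: Shoulder angles whose signed excursions define the coordination pattern.
COORDINATION_JOINTS: tuple[str, str] = (
    "shoulder_internal_external_rotation",
    "shoulder_abduction_adduction",
)

CONDITIONS: tuple[str, str] = ("MHP", "SHP")
TASKS: tuple[str, str, str] = ("RCRT_up", "RCRT_down", "TRAY")
RCRT_TASKS: tuple[str, str] = ("RCRT_up", "RCRT_down")

N_NORMALIZED_STEPS = 500

# Default processing thresholds (see docs/methods.md for rationale).
DEFAULT_ONSET_VELOCITY_DEG_S = 5.0
DEFAULT_SUSTAIN_MS = 100.0
DEFAULT_RETURN_TOLERANCE_DEG = 2.0
DEFAULT_BASELINE_WINDOW_S = 0.5
DEFAULT_MAX_STEP_DEG = 30.0
DEFAULT_ANGLE_BOUNDS_DEG = (-180.0, 180.0)
#: Excursions smaller than this are treated as indeterminate when classifying
#: the coordination pattern, and resolved conservatively toward JC_SIM.
DEFAULT_EXCURSION_DEADBAND_DEG = 1.0


class KinematicsError(ValueError):
    """Base error for kinematic processing failures."""


class NoMovementError(KinematicsError):
    """No movement onset found in the shoulder angles."""


class EndUndeterminableError(KinematicsError):
    """Offset not detectable and no measured completion time to fall back on."""


class InsufficientTrialsError(KinematicsError):
    """Fewer analyzable trials than the statistic requires."""


class NoAnalyzableTrialsError(KinematicsError):
    """Every trial of a participant-condition-task set was excluded."""

    def __init__(self, message: str, reports: list["ArtifactReport"]):
        super().__init__(message)
        self.reports = reports


@dataclass
class JointAngleTrial:
    """One recorded trial: 7 joint-angle series plus labels.

    ``angles`` maps each joint in :data:`JOINTS` to a 1-D array of degrees.
    ``measured_completion_time_s`` is the stopwatch completion time, used as a
    fallback when the movement offset cannot be detected from the angles.
    """

    participant_id: str
    condition: str
    task: str
    trial_index: int
    sample_rate_hz: float
    angles: dict[str, np.ndarray]
    measured_completion_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise KinematicsError("sample_rate_hz must be positive")
        missing = set(JOINTS) - set(self.angles)
        extra = set(self.angles) - set(JOINTS)
        if missing or extra:
            raise KinematicsError(
                f"trial must contain exactly the 7 tracked joints; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        self.angles = {j: np.asarray(self.angles[j], dtype=float) for j in JOINTS}
        lengths = {len(v) for v in self.angles.values()}
        if len(lengths) != 1 or min(lengths) < 2:
            raise KinematicsError("all joint series must share a length >= 2")

    @property
    def n_samples(self) -> int:
        return len(self.angles[JOINTS[0]])


@dataclass(frozen=True)
class SegmentBounds:
    """Start/end sample indices of the movement within a trial."""

    start_index: int
    end_index: int
    completion_time_s: float
    end_source: str  # "detected" | "fallback_measured_time"

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index):
            raise KinematicsError("require 0 <= start_index < end_index")


@dataclass(frozen=True)
class NormalizedTrial:
    """Joint series resampled to exactly 500 points over the movement segment."""

    participant_id: str
    condition: str
    task: str
    trial_index: int
    angles: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for j, series in self.angles.items():
            if len(series) != N_NORMALIZED_STEPS:
                raise KinematicsError(
                    f"normalized series for {j} has length {len(series)}, "
                    f"expected {N_NORMALIZED_STEPS}"
                )


@dataclass
class ArtifactReport:
    """Outcome of the gimbal-lock/out-of-range screen for one trial."""

    participant_id: str
    condition: str
    task: str
    trial_index: int
    excluded: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class KinematicSummary:
    """Per participant x condition x task summary of the kinematic metrics."""

    participant_id: str
    condition: str
    task: str
    rom_mean_deg: dict[str, float]
    kv_deg: dict[str, float] | None
    kr: dict[str, float] | None
    n_trials_included: int
    n_trials_excluded: int
    completion_time_mean_s: float
    completion_time_sd_s: float


@dataclass
class CoordinationAssessment:
    """JC_SIM/JC_DIFF label plus the signed excursions it was based on."""

    participant_id: str
    label: str  # "JC_SIM" | "JC_DIFF"
    excursions: dict[str, dict[str, float]]  # condition -> joint -> degrees
    rule_version: str = "signed-mean-excursion-v1"


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _angular_velocity(series: np.ndarray, fs: float) -> np.ndarray:
    """Sample-wise angular velocity in deg/s (central differences)."""
    return np.gradient(series) * fs


def detect_trial_bounds(
    trial: JointAngleTrial,
    onset_velocity_threshold_deg_s: float = DEFAULT_ONSET_VELOCITY_DEG_S,
    sustain_ms: float = DEFAULT_SUSTAIN_MS,
    return_tolerance_deg: float = DEFAULT_RETURN_TOLERANCE_DEG,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> SegmentBounds:
    """Detect movement start and end from the shoulder angles.

    Start: first sample at which the absolute angular velocity of shoulder
    flexion/extension OR abduction/adduction exceeds the threshold and stays
    above it for ``sustain_ms``; the start is then backtracked while the
    velocity stays above half the threshold (hysteresis), so brief dips right
    after the true onset do not delay it. End: first sample after the last
    suprathreshold movement at which BOTH shoulder angles are back within
    ``return_tolerance_deg`` of their pre-start baseline (the mean over the
    first ``baseline_window_s`` of the recording). If the angles never return
    to baseline the end is approximated with the measured completion time.
    """
    if onset_velocity_threshold_deg_s <= 0 or sustain_ms <= 0 or return_tolerance_deg <= 0:
        raise KinematicsError("segmentation thresholds must be positive")
    fs = trial.sample_rate_hz
    n = trial.n_samples
    sustain_n = max(1, int(round(sustain_ms / 1000.0 * fs)))

    speeds = np.stack(
        [np.abs(_angular_velocity(trial.angles[j], fs)) for j in SEGMENTATION_JOINTS]
    )
    supra = (speeds > onset_velocity_threshold_deg_s).any(axis=0)

    # first index opening a run of >= sustain_n suprathreshold samples
    start_index: int | None = None
    if supra.any():
        run = 0
        for i, flag in enumerate(supra):
            run = run + 1 if flag else 0
            if run >= sustain_n:
                start_index = i - sustain_n + 1
                break
    if start_index is None:
        raise NoMovementError("no movement detected in the shoulder angles")
    # hysteresis backtrack: extend the onset to the first sample of the
    # contiguous stretch above half the threshold
    supra_low = (speeds > onset_velocity_threshold_deg_s / 2.0).any(axis=0)
    while start_index > 0 and supra_low[start_index - 1]:
        start_index -= 1

    baseline_n = max(1, min(int(round(baseline_window_s * fs)), start_index or 1))
    baselines = {
        j: float(np.mean(trial.angles[j][:baseline_n])) for j in SEGMENTATION_JOINTS
    }

    last_supra = int(np.nonzero(supra)[0][-1])
    returned = np.ones(n, dtype=bool)
    for j in SEGMENTATION_JOINTS:
        returned &= np.abs(trial.angles[j] - baselines[j]) <= return_tolerance_deg
    candidates = np.nonzero(returned[last_supra + 1:])[0]
    if candidates.size:
        end_index = last_supra + 1 + int(candidates[0])
        end_source = "detected"
    else:
        if trial.measured_completion_time_s is None:
            raise EndUndeterminableError(
                "shoulder angles never return to baseline and no measured "
                "completion time is available"
            )
        end_index = start_index + int(round(trial.measured_completion_time_s * fs))
        end_index = min(end_index, n - 1)
        end_source = "fallback_measured_time"
    if end_index <= start_index:
        raise EndUndeterminableError("detected end precedes detected start")
    return SegmentBounds(
        start_index=start_index,
        end_index=end_index,
        completion_time_s=(end_index - start_index) / fs,
        end_source=end_source,
    )


# ---------------------------------------------------------------------------
# Artifact screening
# ---------------------------------------------------------------------------

def screen_artifacts(
    trial: JointAngleTrial,
    max_step_deg: float = DEFAULT_MAX_STEP_DEG,
    angle_bounds_deg: tuple[float, float] = DEFAULT_ANGLE_BOUNDS_DEG,
) -> ArtifactReport:
    """Flag gimbal-lock-like discontinuities and out-of-range samples.

    A trial is excluded when any joint series has a sample-to-sample jump
    exceeding ``max_step_deg`` or a sample outside ``angle_bounds_deg``.
    """
    if max_step_deg <= 0:
        raise KinematicsError("max_step_deg must be positive")
    lo, hi = angle_bounds_deg
    reasons: list[str] = []
    for j in JOINTS:
        series = trial.angles[j]
        steps = np.abs(np.diff(series))
        for idx in np.nonzero(steps > max_step_deg)[0]:
            reasons.append(
                f"spike: {j} step {steps[idx]:.1f} deg at sample {idx + 1}"
            )
        for idx in np.nonzero((series < lo) | (series > hi))[0]:
            reasons.append(
                f"out-of-range: {j} value {series[idx]:.1f} deg at sample {idx}"
            )
    return ArtifactReport(
        participant_id=trial.participant_id,
        condition=trial.condition,
        task=trial.task,
        trial_index=trial.trial_index,
        excluded=bool(reasons),
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# Time normalization and metrics
# ---------------------------------------------------------------------------

def time_normalize(
    trial: JointAngleTrial,
    bounds: SegmentBounds,
    n_steps: int = N_NORMALIZED_STEPS,
) -> NormalizedTrial:
    """Resample the movement segment to ``n_steps`` points via cubic splines.

    Original sample indices within [start, end] are mapped affinely onto
    [0, 1] (both endpoints included); the spline is evaluated at ``n_steps``
    equally spaced normalized times, so the first and last output samples
    equal the original boundary values.
    """
    seg = slice(bounds.start_index, bounds.end_index + 1)
    seg_len = bounds.end_index - bounds.start_index + 1
    if seg_len < 4:
        raise KinematicsError("segment too short for cubic spline (need >= 4 samples)")
    u = np.linspace(0.0, 1.0, seg_len)
    u_out = np.linspace(0.0, 1.0, n_steps)
    normalized = {}
    for j in JOINTS:
        spline = CubicSpline(u, trial.angles[j][seg])
        normalized[j] = spline(u_out)
    return NormalizedTrial(
        participant_id=trial.participant_id,
        condition=trial.condition,
        task=trial.task,
        trial_index=trial.trial_index,
        angles=normalized,
    )


def compute_rom(trial: JointAngleTrial, bounds: SegmentBounds) -> dict[str, float]:
    """Per-joint range of motion: max - min of the RAW segment, in degrees."""
    seg = slice(bounds.start_index, bounds.end_index + 1)
    return {
        j: float(np.max(trial.angles[j][seg]) - np.min(trial.angles[j][seg]))
        for j in JOINTS
    }


def _stack(normalized_trials: Sequence[NormalizedTrial], joint: str) -> np.ndarray:
    return np.stack([np.asarray(t.angles[joint]) for t in normalized_trials])


def compute_kv(normalized_trials: Sequence[NormalizedTrial]) -> dict[str, float]:
    """Kinematic variability per joint, in degrees.

    The across-trial sample SD (denominator M-1) is computed at each
    normalized time point and averaged over all time points.
    """
    if len(normalized_trials) < 2:
        raise InsufficientTrialsError("kinematic variability needs >= 2 trials")
    return {
        j: float(np.mean(np.std(_stack(normalized_trials, j), axis=0, ddof=1)))
        for j in JOINTS
    }


def kv_of_waveforms(waveforms: np.ndarray) -> float:
    """KV of an (M trials x T time points) waveform matrix (helper/oracle form)."""
    if waveforms.shape[0] < 2:
        raise InsufficientTrialsError("kinematic variability needs >= 2 trials")
    return float(np.mean(np.std(waveforms, axis=0, ddof=1)))


def kr_of_waveforms(waveforms: np.ndarray) -> float:
    """Adjusted coefficient of multiple determination of an M x T matrix.

    With Y_mt the angle of trial m at time t, Ybar_t the across-trial mean and
    Ybar the grand mean::

        KR = 1 - [ sum (Y_mt - Ybar_t)^2 / (T (M-1)) ]
               / [ sum (Y_mt - Ybar)^2  / (T M - 1) ]

    KR <= 1; it can be negative and is reported unclamped. If the total
    variance is zero (all samples identical) the waveform is degenerate and
    NaN is returned as the "no repeatability estimate" signal.
    """
    Y = np.asarray(waveforms, dtype=float)
    M, T = Y.shape
    if M < 2:
        raise InsufficientTrialsError("kinematic repeatability needs >= 2 trials")
    time_means = Y.mean(axis=0)
    grand = Y.mean()
    ss_within = float(((Y - time_means) ** 2).sum())
    ss_total = float(((Y - grand) ** 2).sum())
    if ss_total == 0.0:
        return math.nan  # degenerate waveform: no variance to apportion
    ms_within = ss_within / (T * (M - 1))
    ms_total = ss_total / (T * M - 1)
    return 1.0 - ms_within / ms_total


def compute_kr(normalized_trials: Sequence[NormalizedTrial]) -> dict[str, float]:
    """Kinematic repeatability per joint (adjusted CMD; see kr_of_waveforms)."""
    if len(normalized_trials) < 2:
        raise InsufficientTrialsError("kinematic repeatability needs >= 2 trials")
    return {j: kr_of_waveforms(_stack(normalized_trials, j)) for j in JOINTS}


# ---------------------------------------------------------------------------
# Per-participant summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcessingConfig:
    """Thresholds for the segmentation and screening stages."""

    onset_velocity_threshold_deg_s: float = DEFAULT_ONSET_VELOCITY_DEG_S
    sustain_ms: float = DEFAULT_SUSTAIN_MS
    return_tolerance_deg: float = DEFAULT_RETURN_TOLERANCE_DEG
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S
    max_step_deg: float = DEFAULT_MAX_STEP_DEG
    angle_bounds_deg: tuple[float, float] = DEFAULT_ANGLE_BOUNDS_DEG

    def __post_init__(self) -> None:
        for name in (
            "onset_velocity_threshold_deg_s",
            "sustain_ms",
            "return_tolerance_deg",
            "baseline_window_s",
            "max_step_deg",
        ):
            if getattr(self, name) <= 0:
                raise KinematicsError(f"{name} must be positive")
        if self.angle_bounds_deg[0] >= self.angle_bounds_deg[1]:
            raise KinematicsError("angle_bounds_deg must be an increasing interval")


def summarize_participant(
    trials: Sequence[JointAngleTrial],
    config: ProcessingConfig = ProcessingConfig(),
) -> tuple[KinematicSummary, list[ArtifactReport], list[NormalizedTrial]]:
    """Run the full per-set chain: screen, segment, RoM, normalize, KV, KR.

    All trials must belong to one participant x condition x task set. Returns
    the summary, the per-trial artifact reports, and the normalized trials
    (for downstream coordination analysis).
    """
    if not trials:
        raise KinematicsError("no trials given")
    keys = {(t.participant_id, t.condition, t.task) for t in trials}
    if len(keys) != 1:
        raise KinematicsError("trials must share participant, condition and task")
    participant_id, condition, task = keys.pop()

    reports = [
        screen_artifacts(t, config.max_step_deg, config.angle_bounds_deg)
        for t in trials
    ]
    included = [t for t, r in zip(trials, reports) if not r.excluded]
    if not included:
        raise NoAnalyzableTrialsError(
            f"all {len(trials)} trials excluded for "
            f"{participant_id}/{condition}/{task}",
            reports,
        )

    bounds = [
        detect_trial_bounds(
            t,
            config.onset_velocity_threshold_deg_s,
            config.sustain_ms,
            config.return_tolerance_deg,
            config.baseline_window_s,
        )
        for t in included
    ]
    roms = [compute_rom(t, b) for t, b in zip(included, bounds)]
    normalized = [time_normalize(t, b) for t, b in zip(included, bounds)]
    times = np.array([b.completion_time_s for b in bounds])

    rom_mean = {j: float(np.mean([r[j] for r in roms])) for j in JOINTS}
    if len(included) >= 2:
        kv = compute_kv(normalized)
        kr = compute_kr(normalized)
        time_sd = float(np.std(times, ddof=1))
    else:
        kv = None  # KV/KR undefined with a single trial
        kr = None
        time_sd = math.nan

    summary = KinematicSummary(
        participant_id=participant_id,
        condition=condition,
        task=task,
        rom_mean_deg=rom_mean,
        kv_deg=kv,
        kr=kr,
        n_trials_included=len(included),
        n_trials_excluded=len(trials) - len(included),
        completion_time_mean_s=float(np.mean(times)),
        completion_time_sd_s=time_sd,
    )
    return summary, reports, normalized


# ---------------------------------------------------------------------------
# Coordination-pattern classification
# ---------------------------------------------------------------------------

def signed_mean_excursion(normalized_trials: Sequence[NormalizedTrial], joint: str) -> float:
    """Time-averaged deviation from each trial's initial value, trial-averaged."""
    vals = []
    for t in normalized_trials:
        series = np.asarray(t.angles[joint])
        vals.append(float(np.mean(series - series[0])))
    return float(np.mean(vals))


def classify_coordination(
    normalized_by_condition: Mapping[str, Sequence[NormalizedTrial]],
    participant_id: str,
    tasks: Iterable[str] = RCRT_TASKS,
    deadband_deg: float = DEFAULT_EXCURSION_DEADBAND_DEG,
) -> CoordinationAssessment:
    """Label a participant JC_SIM or JC_DIFF from shoulder excursion signs.

    For each condition the signed mean excursions of shoulder internal(+)/
    external(-) rotation and abduction(+)/adduction(-) are computed over the
    clothespin-relocation trials. The participant is JC_DIFF iff BOTH
    excursion signs differ between the MHP and SHP conditions; excursions
    within ``deadband_deg`` of zero are indeterminate and resolve to JC_SIM.
    """
    for cond in CONDITIONS:
        trials = [
            t for t in normalized_by_condition.get(cond, []) if t.task in set(tasks)
        ]
        if not trials:
            raise KinematicsError(
                f"incomparable participant {participant_id}: no analyzable "
                f"trials in condition {cond}"
            )
    excursions: dict[str, dict[str, float]] = {}
    for cond in CONDITIONS:
        trials = [
            t for t in normalized_by_condition[cond] if t.task in set(tasks)
        ]
        excursions[cond] = {
            j: signed_mean_excursion(trials, j) for j in COORDINATION_JOINTS
        }

    def _sign(x: float) -> int:
        if abs(x) <= deadband_deg:
            return 0  # indeterminate
        return 1 if x > 0 else -1

    differs = []
    for j in COORDINATION_JOINTS:
        s_mhp = _sign(excursions["MHP"][j])
        s_shp = _sign(excursions["SHP"][j])
        differs.append(s_mhp != 0 and s_shp != 0 and s_mhp != s_shp)
    label = "JC_DIFF" if all(differs) else "JC_SIM"
    return CoordinationAssessment(
        participant_id=participant_id, label=label, excursions=excursions
    )
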