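"""Synthetic kinematic trials and questionnaire data with known ground truth.

The study protocol this package analyzes records 7 Euler joint angles at
60 Hz while prosthesis users perform the refined clothespin relocation test
(RCRT, 5 trials up + 5 down) and a bimanual tray task (10 trials), once with
a multi-grip hand (MHP) and once with a standard hand (SHP). The raw
recordings are external, so this module generates datasets of the same shape
with controllable ground truth:

* smooth raised-cosine-edged (bell/trapezoid-shaped) joint excursions with
  per-joint amplitudes, bracketed by quiescent baseline padding;
* between-participant completion-time scatter (task duration mean +/- SD per
  condition) and within-participant trial-to-trial duration scatter
  (``time_warp_sd``);
* trial-to-trial amplitude scatter and smooth (low-pass filtered) additive
  angle noise of known SD, so the kinematic-variability estimator can be
  validated by parameter recovery;
* a coordination mode: ``JC_SIM`` participants use the same shoulder
  rotation/abduction strategy with both hands, ``JC_DIFF`` participants flip
  the sign of both shoulder excursions in the MHP condition only;
* optional single-sample gimbal-lock-like spikes of known magnitude;
* two-group questionnaire tables with specified means/SDs or ordinal level
  probabilities, clipped/resampled into declared valid ranges.

All randomness derives from one master seed through per-participant
``numpy`` ``SeedSequence`` substreams, so adding participants never perturbs
earlier ones and identical configs reproduce byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .kinematics import CONDITIONS, JOINTS, JointAngleTrial, TASKS

JC_SIM = "JC_SIM"
JC_DIFF = "JC_DIFF"

#: Signed peak excursion (degrees) of each joint's base profile. Signs follow
#: the convention shoulder internal(+)/external(-) rotation and
#: abduction(+)/adduction(-): the default strategy pairs external rotation
#: with abduction.
DEFAULT_AMPLITUDES_DEG: dict[str, float] = {
    "trunk_flexion_extension": 12.0,
    "trunk_axial_bending": 8.0,
    "trunk_lateral_bending": 6.0,
    "shoulder_flexion_extension": 45.0,
    "shoulder_internal_external_rotation": -20.0,
    "shoulder_abduction_adduction": 25.0,
    "elbow_flexion_extension": 50.0,
}

#: Completion-time mean and SD (seconds) per condition and task, matching the
#: study's observed group statistics.
DEFAULT_TASK_DURATION_S: dict[str, dict[str, tuple[float, float]]] = {
    "MHP": {"RCRT_up": (23.8, 6.8), "RCRT_down": (22.4, 8.8), "TRAY": (15.6, 3.8)},
    "SHP": {"RCRT_up": (16.3, 5.6), "RCRT_down": (17.7, 7.9), "TRAY": (14.5, 4.8)},
}

DEFAULT_TRIALS_PER_TASK: dict[str, int] = {"RCRT_up": 5, "RCRT_down": 5, "TRAY": 10}

#: Joints whose excursion signs flip in the MHP condition under JC_DIFF.
_FLIP_JOINTS = ("shoulder_internal_external_rotation", "shoulder_abduction_adduction")


class SyntheticConfigError(ValueError):
    """A generator configuration field is invalid."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the kinematic trial generator.

    ``task_duration_s`` gives, per condition and task, the mean and SD of the
    between-participant completion time; ``time_warp_sd`` is the relative
    within-participant trial-to-trial duration scatter. ``amp_noise_sd`` is
    the relative trial-to-trial amplitude scatter per joint;
    ``additive_noise_sd`` is the SD in degrees of smooth additive noise on
    each sample of the movement. With all three scatter parameters at zero a
    participant's trials are sample-for-sample identical.
    """

    n_participants: int = 14
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_task: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRIALS_PER_TASK)
    )
    sample_rate_hz: float = 60.0
    task_duration_s: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_TASK_DURATION_S.items()}
    )
    pad_s: float = 1.0
    base_amplitudes_deg: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES_DEG)
    )
    rise_s: float = 1.0  # duration of the raised-cosine onset/offset edges
    amp_noise_sd: float = 0.05
    time_warp_sd: float = 0.15
    additive_noise_sd: float = 1.0
    noise_cutoff_hz: float = 6.0
    coordination_mode: str = JC_SIM
    artifact_prob: float = 0.0
    spike_magnitude_deg: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise SyntheticConfigError("n_participants must be >= 1")
        if self.sample_rate_hz <= 0:
            raise SyntheticConfigError("sample_rate_hz must be positive")
        for task, n in self.trials_per_task.items():
            if task not in TASKS:
                raise SyntheticConfigError(f"unknown task in trials_per_task: {task}")
            if n < 1:
                raise SyntheticConfigError(f"trials_per_task[{task}] must be >= 1")
        for name in ("amp_noise_sd", "time_warp_sd", "additive_noise_sd"):
            if getattr(self, name) < 0:
                raise SyntheticConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise SyntheticConfigError("artifact_prob must be in [0, 1]")
        if self.pad_s < 0:
            raise SyntheticConfigError("pad_s must be >= 0")
        if self.coordination_mode not in (JC_SIM, JC_DIFF):
            raise SyntheticConfigError(
                f"coordination_mode must be {JC_SIM} or {JC_DIFF}"
            )
        for cond in self.conditions:
            if cond not in self.task_duration_s:
                raise SyntheticConfigError(f"task_duration_s missing condition {cond}")
            for task, (m, s) in self.task_duration_s[cond].items():
                if m <= 0 or s < 0:
                    raise SyntheticConfigError(
                        f"task_duration_s[{cond}][{task}] needs mean > 0, SD >= 0"
                    )
        missing = set(JOINTS) - set(self.base_amplitudes_deg)
        if missing:
            raise SyntheticConfigError(f"base_amplitudes_deg missing {sorted(missing)}")


def _trapezoid_profile(n: int, rise_n: int) -> np.ndarray:
    """Smooth 0->1->0 profile: raised-cosine rise/fall around a unit plateau."""
    rise_n = max(2, min(rise_n, n // 2))
    u = np.ones(n)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(rise_n) / rise_n))
    u[:rise_n] = ramp
    u[-rise_n:] = ramp[::-1]
    return u


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float,
                  sd: float) -> np.ndarray:
    """Low-pass filtered white noise rescaled to sample SD ``sd``."""
    if sd == 0.0 or n < 20:
        return np.zeros(n)
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    b, a = butter(4, min(cutoff_hz / nyq, 0.99))
    smooth = filtfilt(b, a, white)
    s = smooth.std()
    if s == 0:
        return np.zeros(n)
    return smooth * (sd / s)


def _participant_amplitudes(config: SyntheticConfig, condition: str) -> dict[str, float]:
    amps = dict(config.base_amplitudes_deg)
    if config.coordination_mode == JC_DIFF and condition == "MHP":
        for j in _FLIP_JOINTS:
            amps[j] = -amps[j]
    return amps


def generate_kinematic_dataset(config: SyntheticConfig) -> list[JointAngleTrial]:
    """Generate all trials for every participant x condition x task.

    Deterministic in ``config.seed``; per-participant substreams ensure the
    first k participants are identical across runs that differ only in
    ``n_participants``.
    """
    fs = config.sample_rate_hz
    pad_n = int(round(config.pad_s * fs))
    trials: list[JointAngleTrial] = []
    substreams = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    for p_idx, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        pid = f"P{p_idx + 1:02d}"
        # shared "speed" trait so completion times correlate across conditions
        speed = rng.standard_normal()
        for condition in config.conditions:
            amps = _participant_amplitudes(config, condition)
            for task in TASKS:
                n_trials = config.trials_per_task.get(task, 0)
                if n_trials == 0:
                    continue
                mean_s, sd_s = config.task_duration_s[condition][task]
                indep = rng.standard_normal()
                # participant-level mean duration; 0.7 shared-trait loading
                dur_mean = mean_s + sd_s * (0.7 * speed + np.sqrt(1 - 0.49) * indep)
                dur_mean = max(dur_mean, 3.0)
                for k in range(n_trials):
                    warp = 1.0 + config.time_warp_sd * rng.standard_normal()
                    duration = max(dur_mean * max(warp, 0.1), 3.0)
                    move_n = max(int(round(duration * fs)), 8)
                    total_n = move_n + 2 * pad_n
                    profile = _trapezoid_profile(move_n, int(round(config.rise_s * fs)))
                    angles: dict[str, np.ndarray] = {}
                    for j in JOINTS:
                        amp = amps[j] * (
                            1.0 + config.amp_noise_sd * rng.standard_normal()
                        )
                        series = np.zeros(total_n)
                        series[pad_n:pad_n + move_n] = amp * profile
                        noise = _smooth_noise(
                            rng, move_n, fs, config.noise_cutoff_hz,
                            config.additive_noise_sd,
                        )
                        # taper noise to zero at the segment edges so padding
                        # stays quiescent and the onset transition is clean;
                        # capped at 5% of the movement so the taper never
                        # depresses the effective noise SD by more than a
                        # few percent even on very short trials
                        taper_n = max(
                            2, min(int(round(0.3 * fs)), move_n // 20)
                        )
                        env = np.ones(move_n)
                        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(taper_n) / taper_n))
                        env[:taper_n] = ramp
                        env[-taper_n:] = ramp[::-1]
                        series[pad_n:pad_n + move_n] += noise * env
                        angles[j] = series
                    # artifact draws happen unconditionally so that varying
                    # artifact_prob never shifts the rest of the stream
                    u_spike = rng.random()
                    j_spike = JOINTS[rng.integers(len(JOINTS))]
                    idx = pad_n + int(rng.integers(move_n))
                    if u_spike < config.artifact_prob:
                        angles[j_spike][idx] += config.spike_magnitude_deg
                    trials.append(
                        JointAngleTrial(
                            participant_id=pid,
                            condition=condition,
                            task=task,
                            trial_index=k,
                            sample_rate_hz=fs,
                            angles=angles,
                            measured_completion_time_s=duration,
                        )
                    )
    return trials


# ---------------------------------------------------------------------------
# Questionnaire / characteristics generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasureSpec:
    """Distribution of one measure in one group.

    ``kind`` is "normal" (``params`` = (mean, sd)) or "ordinal" (``params`` =
    mapping level -> probability). Normal draws outside ``valid_range`` are
    redrawn (up to 100 times) then clipped.
    """

    kind: str
    params: tuple[float, float] | Mapping[object, float]
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "ordinal"):
            raise SyntheticConfigError(f"unknown distribution kind: {self.kind}")
        if self.kind == "normal":
            mean, sd = self.params  # type: ignore[misc]
            if sd < 0:
                raise SyntheticConfigError("normal SD must be >= 0")
        else:
            probs = list(self.params.values())  # type: ignore[union-attr]
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-8:
                raise SyntheticConfigError("ordinal probabilities must sum to 1")


@dataclass(frozen=True)
class GroupScoreSpec:
    """Per-measure, per-group distributions for a two-group score table."""

    measures: Mapping[str, Mapping[str, MeasureSpec]]  # measure -> group -> spec
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"MHP": 14, "SHP": 19}
    )

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise SyntheticConfigError(f"group size for {g} must be >= 1")
        for m, groups in self.measures.items():
            for g in self.group_sizes:
                if g not in groups:
                    raise SyntheticConfigError(f"measure {m} missing group {g}")


def default_group_score_spec() -> GroupScoreSpec:
    """Two-group spec mirroring the study's participant characteristics and
    principal questionnaire scores (means/SDs as observed per group)."""
    n = MeasureSpec
    measures = {
        "age_years": {
            "MHP": n("normal", (48.6, 12.4), (18, 90)),
            "SHP": n("normal", (58.1, 15.7), (18, 90)),
        },
        "experience_current_years": {
            "MHP": n("normal", (3.1, 2.8), (0.5, 70)),
            "SHP": n("normal", (29.4, 19.8), (0.5, 70)),
        },
        "sex": {
            "MHP": n("ordinal", {"male": 9 / 14, "female": 5 / 14}),
            "SHP": n("ordinal", {"male": 13 / 19, "female": 6 / 19}),
        },
        "side_of_limb_absence": {
            "MHP": n("ordinal", {"left": 9 / 14, "right": 5 / 14}),
            "SHP": n("ordinal", {"left": 13 / 19, "right": 6 / 19}),
        },
        "puf_ulp": {
            "MHP": n("normal", (8.9, 2.1), (0.0, 12.1)),
            "SHP": n("normal", (10.6, 1.3), (0.0, 12.1)),
        },
        "dquest_total": {
            "MHP": n("normal", (3.9, 0.5), (1, 5)),
            "SHP": n("normal", (4.1, 0.4), (1, 5)),
        },
        "eq5d_vas": {
            "MHP": n("normal", (83.6, 12.8), (0, 100)),
            "SHP": n("normal", (83.6, 15.6), (0, 100)),
        },
    }
    return GroupScoreSpec(measures=measures)


def generate_group_scores(spec: GroupScoreSpec, seed: int):
    """Generate a tidy two-group score table (one row per participant).

    Returns a pandas DataFrame with columns participant_id, group, and one
    column per measure. Normal measures converge to the spec's mean/SD as n
    grows; ordinal measures are sampled from the level probabilities.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for group, size in spec.group_sizes.items():
        for i in range(size):
            rows.append({"participant_id": f"{group}{i + 1:03d}", "group": group})
    for measure, groups in spec.measures.items():
        values: list[object] = []
        for group, size in spec.group_sizes.items():
            mspec = groups[group]
            if mspec.kind == "normal":
                mean, sd = mspec.params  # type: ignore[misc]
                draws = mean + sd * rng.standard_normal(size)
                if mspec.valid_range is not None:
                    lo, hi = mspec.valid_range
                    for _ in range(100):
                        bad = (draws < lo) | (draws > hi)
                        if not bad.any():
                            break
                        draws[bad] = mean + sd * rng.standard_normal(bad.sum())
                    draws = np.clip(draws, lo, hi)
                values.extend(float(v) for v in draws)
            else:
                levels = list(mspec.params.keys())  # type: ignore[union-attr]
                probs = list(mspec.params.values())  # type: ignore[union-attr]
                idx = rng.choice(len(levels), size=size, p=probs)
                values.extend(levels[i] for i in idx)
        for row, v in zip(rows, values):
            row[measure] = v
    return pd.DataFrame(rows)
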