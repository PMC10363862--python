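"""Synthetic cohorts emulating the self-rotation speech-intelligibility experiment.

Generates the balanced block/trial design (6 blocks x 48 trials, 12 per target
location), head-yaw trajectories with a reaction phase, fast minimum-jerk turns
and condition-dependent undershoot, word timing from the sentence-duration
statistics of the speech material, and Bernoulli word responses driven by a
logistic psychometric function of model-predicted benefit.  A configurable
dynamic-motion deficit (delta, in dB) degrades words spoken while the head is
turning, standing in for motion-induced intelligibility loss (e.g. binaural
sluggishness) that a static spatial-unmasking model cannot capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .trajectory import SAMPLE_RATE_HZ, Trajectory, WordWindows

__all__ = [
    "CohortConfig",
    "TrialRecord",
    "make_design",
    "gen_word_windows",
    "gen_trajectory",
    "gen_responses",
    "gen_cohort",
    "gen_static_scores",
    "cohort_to_frames",
]

CONDITIONS = ("Static", "A-only", "AV")
TARGETS_DEG = (0.0, -90.0, 90.0, 180.0)


@dataclass
class CohortConfig:
    """Study conditions of the synthetic experiment.

    Psychometric truth: logit p = beta0 + beta1 * benefit_dB + u_j with
    beta1/4 = 0.08 proportion/dB by default.  ``static_benefit_db`` holds the
    model-predicted benefit per target location when the listener faces the
    interferer (the Static condition), as computed from the calibrated room
    model; pass explicit benefit maps to gen_cohort to re-derive per-word
    values along each trajectory.
    """

    n_participants: int = 9
    seed: int = 0
    # psychometric truth
    beta0: float = -0.2
    beta1: float = 0.32
    sigma_u: float = 0.5
    # dynamic-motion deficit
    delta_db: float = 1.4
    delta_mode: str = "motion_gated"  # or "constant"
    motion_gate_deg_s: float = 5.0
    # trajectory parameters
    reaction_mean_s: float = 0.25
    reaction_sd_s: float = 0.08
    peak_speed_deg_s: float = 150.0
    undershoot_mean_deg: dict = field(
        default_factory=lambda: {
            ("A-only", 0.0): -11.5, ("AV", 0.0): -0.5,
            ("A-only", 90.0): 29.0, ("AV", 90.0): 27.4,
            ("A-only", 180.0): 74.1, ("AV", 180.0): 49.4,
        }
    )
    undershoot_sd_deg: dict = field(
        default_factory=lambda: {"A-only": 20.0, "AV": 10.0}
    )
    static_jitter_sd_deg: float = 0.8
    static_limit_deg: float = 3.0
    # word timing
    sentence_mean_s: float = 2.19
    sentence_sd_s: float = 0.2
    sentence_min_s: float = 1.78
    sentence_max_s: float = 2.77
    word_dirichlet: float = 8.0
    target_onset_s: float = 1.0
    trial_duration_s: float = 4.5
    sample_rate: float = SAMPLE_RATE_HZ
    # Static-condition predictions per target location (dB), calibrated room
    static_benefit_db: dict = field(
        default_factory=lambda: {0.0: 0.0, -90.0: 4.5, 90.0: 4.4, 180.0: 1.0}
    )

    def __post_init__(self) -> None:
        if self.delta_db < 0:
            raise ValueError("delta must be >= 0")
        if self.peak_speed_deg_s <= 0:
            raise ValueError("peak speed must be positive")
        if any(sd < 0 for sd in self.undershoot_sd_deg.values()):
            raise ValueError("undershoot SDs must be >= 0")
        if self.delta_mode not in ("motion_gated", "constant"):
            raise ValueError("delta_mode must be 'motion_gated' or 'constant'")


@dataclass
class TrialRecord:
    participant: int
    block: int
    condition: str
    target_deg: float
    trajectory: Trajectory
    windows: WordWindows
    correct: np.ndarray  # (5,) bool
    word_benefit_db: np.ndarray  # (5,) model benefit used for generation


def make_design(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Blocked trial list for one participant.

    6 blocks of 48 trials; condition fixed per block, every condition in
    exactly two blocks and all three conditions within the first three blocks;
    each block holds 12 trials per target location in pseudo-random order.
    """
    first = list(rng.permutation(CONDITIONS))
    second = list(rng.permutation(CONDITIONS))
    conditions = first + second
    rows = []
    for block, cond in enumerate(conditions):
        targets = np.repeat(TARGETS_DEG, 12)
        rng.shuffle(targets)
        for t_i, tgt in enumerate(targets):
            rows.append({"block": block, "trial": block * 48 + t_i,
                         "condition": cond, "target_deg": float(tgt)})
    return pd.DataFrame(rows)


def gen_word_windows(config: CohortConfig, rng: np.random.Generator) -> WordWindows:
    """Word timing: truncated-normal sentence duration split by a Dirichlet."""
    a = (config.sentence_min_s - config.sentence_mean_s) / config.sentence_sd_s
    b = (config.sentence_max_s - config.sentence_mean_s) / config.sentence_sd_s
    dur = float(
        sps.truncnorm.rvs(a, b, loc=config.sentence_mean_s,
                          scale=config.sentence_sd_s, random_state=rng)
    )
    props = rng.dirichlet(np.full(5, config.word_dirichlet))
    bounds = config.target_onset_s + dur * np.concatenate([[0.0], np.cumsum(props)])
    bounds[-1] = config.target_onset_s + dur  # exact partition
    words = [(float(bounds[i]), float(bounds[i + 1])) for i in range(5)]
    return WordWindows(words=words)


def _min_jerk(t: np.ndarray, t_start: float, duration: float, goal: float) -> np.ndarray:
    """Minimum-jerk position profile from 0 to goal (peak speed 1.875 goal/T)."""
    s = np.clip((t - t_start) / duration, 0.0, 1.0)
    return goal * (10 * s**3 - 15 * s**4 + 6 * s**5)


def _smooth_noise(n: int, rng: np.random.Generator, sample_rate: float,
                  tau_s: float = 0.4) -> np.ndarray:
    """Slow unit-variance jitter emulating postural sway.

    White noise convolved with a Gaussian kernel (sigma = tau_s), so the
    angular speed of the jitter stays well below the motion-gate threshold
    (sub-deg/s for sub-degree amplitudes)."""
    sigma = tau_s * sample_rate
    half = int(4 * sigma)
    k = np.exp(-0.5 * ((np.arange(-half, half + 1)) / sigma) ** 2)
    k /= k.sum()
    x = np.convolve(rng.standard_normal(n + 2 * half), k, mode="valid")[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_trajectory(
    condition: str,
    target_deg: float,
    config: CohortConfig,
    rng: np.random.Generator,
    participant=None,
    trial=None,
) -> Trajectory:
    """One trial's yaw trajectory (time 0 = interferer onset).

    Static trials jitter within the +/-3 deg tolerance.  Moving trials hold
    until a reaction time after target onset, then rotate with a minimum-jerk
    profile toward the target minus a condition-dependent undershoot; rear
    targets are approached leftward or rightward with equal probability, and
    the peak angular speed equals the configured limit.
    """
    n = int(round(config.trial_duration_s * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    if condition == "Static":
        yaw = config.static_jitter_sd_deg * _smooth_noise(n, rng, config.sample_rate)
        limit = config.static_limit_deg - 0.05
        yaw = np.clip(yaw, -limit, limit)
        return Trajectory(t, yaw, participant=participant, trial=trial)

    mag = abs(float(target_deg))
    undershoot = rng.normal(config.undershoot_mean_deg[(condition, mag)],
                            config.undershoot_sd_deg[condition])
    if mag in (0.0, 180.0):
        direction = rng.choice([-1.0, 1.0])
    else:
        direction = np.sign(target_deg)
    goal = direction * (mag - undershoot)
    reaction = max(0.05, rng.normal(config.reaction_mean_s, config.reaction_sd_s))
    t_start = config.target_onset_s + reaction
    duration = max(1.875 * abs(goal) / config.peak_speed_deg_s, 0.05)
    yaw = _min_jerk(t, t_start, duration, goal)
    yaw = yaw + 0.5 * _smooth_noise(n, rng, config.sample_rate)
    return Trajectory(t, yaw, participant=participant, trial=trial)


def _word_motion_gate(
    traj: Trajectory, windows: WordWindows, threshold_deg_s: float
) -> np.ndarray:
    """True per word when the in-window RMS angular speed exceeds the gate."""
    speed = traj.angular_speed()
    out = np.zeros(5, dtype=bool)
    for wi, (onset, offset) in enumerate(windows.words):
        sel = (traj.timestamps >= onset) & (traj.timestamps < offset)
        if np.any(sel):
            out[wi] = np.sqrt(np.mean(speed[sel] ** 2)) > threshold_deg_s
    return out


def gen_responses(
    condition: str,
    traj: Trajectory,
    windows: WordWindows,
    word_benefit_db: np.ndarray,
    u_j: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Five Bernoulli word-correct flags.

    The effective benefit of a word is reduced by delta when the word's window
    contains motion (RMS angular speed above the gate), or, in "constant"
    mode, on every word of a moving-condition trial.
    """
    benefit = np.asarray(word_benefit_db, float)
    if not np.all(np.isfinite(benefit)):
        raise ValueError("word benefits must be finite")
    if config.delta_mode == "constant":
        penalty = config.delta_db if condition != "Static" else 0.0
        eff = benefit - penalty
    else:
        gate = _word_motion_gate(traj, windows, config.motion_gate_deg_s)
        eff = benefit - config.delta_db * gate
    p = expit(config.beta0 + config.beta1 * eff + u_j)
    return rng.random(5) < p


def gen_cohort(config: CohortConfig, benefit_maps: dict | None = None) -> list[TrialRecord]:
    """Full synthetic cohort, reproducible from the config seed.

    ``benefit_maps`` maps target azimuth to a BenefitMap; per-word benefits are
    then the median map benefit over each word window along the trajectory.
    Without maps, the per-location Static predictions are used for every word
    (adequate for Static-only analyses and fast tests).
    """
    from .intelligibility import trajectory_benefit  # local: avoid cycle

    root = np.random.SeedSequence(config.seed)
    part_seeds = root.spawn(config.n_participants)
    trials: list[TrialRecord] = []
    for j in range(config.n_participants):
        rng = np.random.default_rng(part_seeds[j])
        u_j = rng.normal(0.0, config.sigma_u)
        design = make_design(config, rng)
        for row in design.itertuples():
            windows = gen_word_windows(config, rng)
            traj = gen_trajectory(row.condition, row.target_deg, config, rng,
                                  participant=j, trial=row.trial)
            if benefit_maps is not None and row.condition != "Static":
                benefit = trajectory_benefit(
                    benefit_maps[row.target_deg], traj, windows, scale="unmasking"
                )
            else:
                benefit = np.full(5, config.static_benefit_db[row.target_deg])
            correct = gen_responses(row.condition, traj, windows, benefit, u_j, config, rng)
            trials.append(
                TrialRecord(j, row.block, row.condition, row.target_deg,
                            traj, windows, correct, benefit)
            )
    return trials


def gen_static_scores(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Static-condition score cells only (fast path for psychometric fitting).

    Returns one row per participant x target x word position with binomial
    counts out of 24, generated from the psychometric truth at the per-location
    Static predictions.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for j in range(config.n_participants):
        u_j = rng.normal(0.0, config.sigma_u)
        for tgt in TARGETS_DEG:
            x = config.static_benefit_db[tgt]
            p = expit(config.beta0 + config.beta1 * x + u_j)
            for wp in range(1, 6):
                rows.append({
                    "participant": j, "condition": "Static", "target_deg": tgt,
                    "word_position": wp, "n_correct": int(rng.binomial(24, p)),
                    "n_total": 24, "predicted_db": x,
                })
    return pd.DataFrame(rows)


def cohort_to_frames(trials: list[TrialRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format (trials, trajectory-samples) tables for CSV/TSV export."""
    trial_rows, traj_rows = [], []
    for tr in trials:
        rec = {"participant": tr.participant, "block": tr.block, "trial": tr.trajectory.trial,
               "condition": tr.condition, "target_deg": tr.target_deg}
        for wi in range(5):
            rec[f"word{wi + 1}"] = int(tr.correct[wi])
            rec[f"benefit{wi + 1}_db"] = float(tr.word_benefit_db[wi])
            rec[f"word{wi + 1}_onset_s"] = tr.windows.words[wi][0]
            rec[f"word{wi + 1}_offset_s"] = tr.windows.words[wi][1]
        trial_rows.append(rec)
        traj_rows.append(pd.DataFrame({
            "time_s": tr.trajectory.timestamps, "yaw_deg": tr.trajectory.yaw_deg,
            "participant": tr.participant, "trial": tr.trajectory.trial,
            "condition": tr.condition, "target_deg": tr.target_deg,
        }))
    return pd.DataFrame(trial_rows), pd.concat(traj_rows, ignore_index=True)
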