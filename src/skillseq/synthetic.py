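"""Seeded generator of bimanual tool-motion trials with known skill structure.

Emulates 30-FPS pattern-cutting captures in a 640 x 480 frame: the
scissors trace a smoothed circular cutting arc (radius 100 px around the
frame centre) at a speed set by trial duration, while the grasper holds
traction near a gauze corner with repositioning jumps at struggle events.
A subject's skill in [0, 1] continuously interpolates the trial
parameters between the proficient and struggling regimes: duration range,
motion jitter and the Poisson rate of *struggle windows* — planted
segments of high-frequency jitter and local back-tracking that a correct
saliency method should highlight.

Performance is scored by a transparent surrogate, linear in duration and
struggle-event count with Gaussian noise (this is NOT the proprietary FLS
formula, which is not public); the pass/fail label comes from a declared
cut-off, so trials near the cut-off are intrinsically ambiguous given the
unobservable score noise.  Frames are dropped i.i.d. to emulate detector
misses.  Every draw flows through one ``numpy.random.Generator`` so a
seed fully determines the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .sequences import SequenceDataset, TrialSequence, ValidationError

PASS, FAIL = "pass", "fail"


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic task."""

    n_subjects: int = 12
    trials_per_subject: int = 25
    fps: float = 30.0
    frame_width: int = 640
    frame_height: int = 480
    pass_duration_s: tuple[float, float] = (60.0, 120.0)
    fail_duration_s: tuple[float, float] = (180.0, 300.0)
    pass_struggle_rate: float = 0.5
    fail_struggle_rate: float = 4.0
    struggle_len_s: tuple[float, float] = (5.0, 15.0)
    pass_jitter_px: float = 3.0
    fail_jitter_px: float = 15.0
    jitter_corr_time_s: float = 20.0
    detector_noise_px: float = 1.0
    struggle_jitter_px: float = 25.0
    active_cut_time_s: float = 40.0
    missing_prob: float = 0.01
    score_base: float = 200.0
    score_duration_weight: float = 0.5
    score_event_weight: float = 10.0
    score_noise_sd: float = 5.0
    pass_cutoff: float = 70.0
    # A certification cohort mixes distinctly proficient and distinctly
    # struggling subjects rather than clustering at the pass mark, so the
    # default skill distribution is the U/J-shaped Beta(0.4, 1.0), whose
    # mass sits away from the cut-off skill while keeping the expected
    # pass/fail split near 1:1 under the surrogate score model; skew the
    # parameters to produce imbalanced cohorts.
    skill_beta: tuple[float, float] = (0.4, 1.0)
    within_subject_skill_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pass_struggle_rate", "fail_struggle_rate", "pass_jitter_px",
                     "fail_jitter_px", "struggle_jitter_px", "missing_prob",
                     "score_noise_sd", "within_subject_skill_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("pass_duration_s", "fail_duration_s", "struggle_len_s"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValidationError(f"{name} must be a positive range")
        if not (0 <= self.missing_prob < 1):
            raise ValidationError("missing_prob must lie in [0, 1)")


@dataclass
class TrialTruth:
    trial_id: str
    label: str
    score: float
    struggle_windows_s: list[tuple[float, float]]
    duration_s: float
    n_events: int
    subject_skill: float


@dataclass
class GroundTruth:
    trials: dict[str, TrialTruth] = field(default_factory=dict)

    @property
    def class_ratio(self) -> float:
        """pass : fail count ratio (inf when there are no fails)."""
        n_pass = sum(1 for t in self.trials.values() if t.label == PASS)
        n_fail = len(self.trials) - n_pass
        return np.inf if n_fail == 0 else n_pass / n_fail


def _lerp(a: float, b: float, w: float) -> float:
    return a + (b - a) * w


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = np.concatenate([np.full(width, x[0]), x, np.full(width, x[-1])])
    return np.convolve(pad, kernel, mode="same")[width:-width]


def generate_trial(
    cfg: GeneratorConfig,
    subject_skill: float,
    rng: np.random.Generator,
    trial_id: str = "trial",
    subject_id: str = "subject",
) -> tuple[TrialSequence, TrialTruth]:
    """Draw one trial for a subject of the given skill level."""
    if not (0.0 <= subject_skill <= 1.0):
        raise ValidationError("subject_skill must lie in [0, 1]")
    w = 1.0 - subject_skill  # 0 = proficient, 1 = struggling
    duration = rng.uniform(_lerp(cfg.pass_duration_s[0], cfg.fail_duration_s[0], w),
                           _lerp(cfg.pass_duration_s[1], cfg.fail_duration_s[1], w))
    T = max(2, int(round(duration * cfg.fps)))
    t = np.arange(T) / cfg.fps
    jitter_sd = _lerp(cfg.pass_jitter_px, cfg.fail_jitter_px, w)

    # planted struggle windows
    n_events = int(rng.poisson(_lerp(cfg.pass_struggle_rate, cfg.fail_struggle_rate, w)))
    windows: list[tuple[float, float]] = []
    in_window = np.zeros(T, dtype=bool)
    for _ in range(n_events):
        length = rng.uniform(*cfg.struggle_len_s)
        length = min(length, duration)
        start = rng.uniform(0.0, duration - length)
        windows.append((start, start + length))
        in_window |= (t >= start) & (t < start + length)

    # Scissors: one revolution of the cutting circle, advanced in bursts.
    # Movement speed while cutting is roughly skill-invariant; what skill
    # changes is the duty cycle — unskilled subjects hesitate, pause and
    # re-attempt, so long trials are long because little of their time is
    # productive, not because the hand glides uniformly slower.
    cx, cy = cfg.frame_width / 2.0, cfg.frame_height / 2.0
    radius = 100.0
    active_T = min(T, int(round(cfg.active_cut_time_s * cfg.fps)))
    advancing = np.zeros(T, dtype=bool)
    pos = 0
    need = active_T
    total_pause = T - active_T
    mean_burst = 4.0 * cfg.fps
    mean_pause = max(1.0, total_pause / max(1, active_T / mean_burst)) if total_pause else 0
    while pos < T and need > 0:
        burst = min(int(rng.exponential(mean_burst)) + 1, need, T - pos)
        advancing[pos:pos + burst] = True
        pos += burst
        need -= burst
        if pos >= T or need == 0:
            break
        pos += int(rng.exponential(mean_pause)) + 1 if total_pause else 0
    if need > 0:  # pauses ate the tail; finish the cut at the end
        free = np.flatnonzero(~advancing)[-need:]
        advancing[free] = True
    dtheta = advancing.astype(float)
    if in_window.any():
        # struggling: the cut oscillates forward and back instead of advancing
        dtheta[in_window] = 1.5 * np.cos(2.0 * np.pi * 0.4 * t[in_window])
    total = dtheta.sum()
    if abs(total) < 1e-9:
        dtheta[:] = 1.0
        total = float(T)
    dtheta *= 2.0 * np.pi / total  # exactly one revolution
    theta = np.cumsum(dtheta) - dtheta[0] + rng.uniform(0.0, 2.0 * np.pi)
    scissors = np.stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)], axis=1)

    # grasper: holds near a gauze corner, re-anchoring at each struggle event
    corner = np.array([cx - 150.0, cy - 110.0])
    anchor = np.tile(corner + rng.normal(0.0, 10.0, size=2), (T, 1))
    for start, _end in windows:
        j = min(T - 1, int(start * cfg.fps))
        anchor[j:] = anchor[j] + rng.uniform(-60.0, 60.0, size=2)
    drift = np.stack([_smooth(rng.normal(0.0, 1.0, T), int(2 * cfg.fps) + 1)
                      for _ in range(2)], axis=1) * 5.0
    grasper = anchor + drift

    coords = np.concatenate([grasper, scissors], axis=1)
    # Baseline unsteadiness is a slow bounded wander: an Ornstein-Uhlenbeck
    # process with a seconds-scale correlation time and the class-dependent
    # marginal sd (a hand drifts over seconds; it does not teleport between
    # frames), plus ~1 px white detector noise.  Struggle jitter, by
    # contrast, is white high-frequency tremor — the planted saliency signal.
    phi = float(np.exp(-1.0 / (cfg.jitter_corr_time_s * cfg.fps)))
    innov = rng.normal(0.0, 1.0, size=coords.shape) * np.sqrt(1.0 - phi ** 2)
    innov[0] = rng.normal(0.0, 1.0, size=4)
    wander = lfilter([1.0], [1.0, -phi], innov, axis=0)
    coords += wander * jitter_sd
    coords += rng.normal(0.0, cfg.detector_noise_px, size=coords.shape)
    if in_window.any():
        coords[in_window] += rng.normal(0.0, cfg.struggle_jitter_px,
                                        size=(int(in_window.sum()), 4))
    coords[:, [0, 2]] = np.clip(coords[:, [0, 2]], 0.0, cfg.frame_width - 1.0)
    coords[:, [1, 3]] = np.clip(coords[:, [1, 3]], 0.0, cfg.frame_height - 1.0)

    # detector misses
    missing = rng.random(T) < cfg.missing_prob
    if missing.all():  # pathological; keep at least one observation
        missing[0] = False
    coords = coords.copy()
    coords[missing] = np.nan

    score = (cfg.score_base
             - cfg.score_duration_weight * duration
             - cfg.score_event_weight * n_events
             + rng.normal(0.0, cfg.score_noise_sd))
    label = PASS if score >= cfg.pass_cutoff else FAIL

    seq = TrialSequence(
        trial_id=trial_id, subject_id=subject_id, fps=cfg.fps,
        coords=coords, missing_mask=missing, label=label, score=score,
    )
    truth = TrialTruth(trial_id, label, score, windows, duration, n_events, subject_skill)
    return seq, truth


def generate_dataset(cfg: GeneratorConfig) -> tuple[SequenceDataset, GroundTruth]:
    """Generate the full cohort: per-subject skills, then their trials.

    Subject skills are Beta-distributed so leave-one-user-out folds carry
    real between-subject structure; per-trial skill adds small
    within-subject variation.
    """
    rng = np.random.default_rng(cfg.seed)
    trials: list[TrialSequence] = []
    truth = GroundTruth()
    for s in range(cfg.n_subjects):
        subject_id = f"S{s + 1:02d}"
        skill = float(rng.beta(*cfg.skill_beta))
        for r in range(cfg.trials_per_subject):
            trial_id = f"{subject_id}_T{r + 1:03d}"
            trial_skill = float(np.clip(
                skill + rng.normal(0.0, cfg.within_subject_skill_sd), 0.0, 1.0))
            seq, tt = generate_trial(cfg, trial_skill, rng, trial_id, subject_id)
            trials.append(seq)
            truth.trials[trial_id] = tt
    class_names = [PASS, FAIL]
    return SequenceDataset(trials, class_names), truth
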