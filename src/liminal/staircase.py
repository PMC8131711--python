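"""Bayesian adaptive contrast staircasing (QUEST) with simulated observers.

A QUEST process maintains a posterior over the log10 contrast threshold of a
Weibull psychometric observer, places each trial at the current posterior-mean
threshold, and updates the posterior with the binary recognition report.  The
threshold parameter is defined directly as the contrast at which the observer
says "yes" with probability ``target_p`` (0.55 for the Day-1 calibration,
0.50 for the Day-2 pooled re-staircase), so the posterior mean is itself the
quantity the procedure tracks.

Calibration sessions interleave 20 independent processes (one per real image)
into an 800-trial session; a Day-2 validation block of 80 trials (4 per image)
either passes, or triggers two interleaved 40-trial pooled processes that
re-estimate a single gain applied to all Day-1 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PsychometricObserver",
    "QuestState",
    "StaircaseConfig",
    "SessionResult",
    "ValidationResult",
    "quest_init",
    "quest_update",
    "quest_recommend",
    "simulate_response",
    "run_interleaved_session",
    "validate_and_adjust",
]


def _weibull_k(target_p: float, guess: float, lapse: float) -> float:
    # scaling constant such that P(yes | c = threshold) = target_p
    frac = (target_p - guess) / (1.0 - guess - lapse)
    if not 0.0 < frac < 1.0:
        raise ValueError("target_p must lie strictly between guess and 1 - lapse")
    return -np.log1p(-frac)


@dataclass(frozen=True)
class PsychometricObserver:
    """Weibull observer: P(yes|c) = g + (1-g-l)(1 - exp(-k (c/T)^beta)).

    ``threshold`` is the contrast where P(yes) = ``target_p`` (k is chosen
    accordingly); ``slope`` is the Weibull steepness beta; ``guess_floor`` the
    yes-rate at zero contrast; ``lapse`` one minus the asymptotic yes-rate.
    """

    threshold: float
    slope: float = 3.5
    guess_floor: float = 0.05
    lapse: float = 0.02
    target_p: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.guess_floor < 1.0 - self.lapse <= 1.0):
            raise ValueError("require 0 <= guess_floor < 1 - lapse <= 1")
        if self.slope <= 0 or self.threshold <= 0:
            raise ValueError("slope and threshold must be positive")

    def p_yes(self, contrast: float | np.ndarray) -> np.ndarray:
        c = np.asarray(contrast, dtype=float)
        k = _weibull_k(self.target_p, self.guess_floor, self.lapse)
        f = -np.expm1(-k * (c / self.threshold) ** self.slope)
        return self.guess_floor + (1.0 - self.guess_floor - self.lapse) * f

    def contrast_at(self, p: float) -> float:
        """Invert the psychometric: contrast where P(yes) = p."""
        k = _weibull_k(self.target_p, self.guess_floor, self.lapse)
        kp = _weibull_k(p, self.guess_floor, self.lapse)
        return float(self.threshold * (kp / k) ** (1.0 / self.slope))


@dataclass
class StaircaseConfig:
    n_processes: int = 20
    trials_per_process: int = 40
    target_p: float = 0.55
    prior_mean: float = -1.3  # log10 contrast
    prior_sd: float = 0.7
    grid_lo: float = -4.0
    grid_hi: float = 0.0
    grid_n: int = 200
    slope: float = 3.5
    guess_floor: float = 0.05
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.n_processes < 1 or self.trials_per_process < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.target_p < 1.0:
            raise ValueError("target_p must lie in (0, 1)")


@dataclass
class QuestState:
    """Posterior over log10 threshold on a fixed grid, plus the trial history."""

    log_grid: np.ndarray
    posterior: np.ndarray
    config: StaircaseConfig
    history: list[tuple[float, bool]] = field(default_factory=list)

    def mean_log_threshold(self) -> float:
        return float(np.sum(self.posterior * self.log_grid))


def quest_init(cfg: StaircaseConfig) -> QuestState:
    grid = np.linspace(cfg.grid_lo, cfg.grid_hi, cfg.grid_n)
    prior = np.exp(-0.5 * ((grid - cfg.prior_mean) / cfg.prior_sd) ** 2)
    return QuestState(grid, prior / prior.sum(), cfg)


def _likelihood_yes(cfg: StaircaseConfig, contrast: float, log_grid: np.ndarray) -> np.ndarray:
    thresholds = 10.0**log_grid
    k = _weibull_k(cfg.target_p, cfg.guess_floor, cfg.lapse)
    f = -np.expm1(-k * (contrast / thresholds) ** cfg.slope)
    return cfg.guess_floor + (1.0 - cfg.guess_floor - cfg.lapse) * f


def quest_update(state: QuestState, contrast: float, response: bool) -> QuestState:
    """Bayes update of the threshold posterior with one (contrast, yes/no) trial."""
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    p_yes = _likelihood_yes(state.config, contrast, state.log_grid)
    like = p_yes if response else 1.0 - p_yes
    post = state.posterior * like
    total = post.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError(
            "posterior mass underflowed; widen the threshold grid or prior"
        )
    return QuestState(
        state.log_grid,
        post / total,
        state.config,
        state.history + [(float(contrast), bool(response))],
    )


def quest_recommend(state: QuestState) -> float:
    """Next test contrast: posterior-mean log threshold, clipped to [1e-4, 1]."""
    return float(np.clip(10.0 ** state.mean_log_threshold(), 1e-4, 1.0))


def simulate_response(
    obs: PsychometricObserver, contrast: float, rng: np.random.Generator
) -> bool:
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    return bool(rng.random() < obs.p_yes(contrast))


@dataclass
class SessionResult:
    thresholds: dict[str, float]
    trial_log: pd.DataFrame  # columns: trial, process_id, contrast, response
    states: dict[str, QuestState]


def run_interleaved_session(
    cfg: StaircaseConfig,
    observers: dict[str, PsychometricObserver],
    rng: np.random.Generator,
) -> SessionResult:
    """Interleave one QUEST process per image into a single session.

    Trials are organised in blocks of ``n_processes``: within each block every
    image appears exactly once, in a freshly shuffled order, so no image
    repeats before all others have been shown.  Each process receives exactly
    ``trials_per_process`` trials (800 total at the defaults).
    """
    ids = list(observers)
    if len(ids) != cfg.n_processes:
        raise ValueError(
            f"need one observer per process: got {len(ids)}, expected {cfg.n_processes}"
        )
    states = {i: quest_init(cfg) for i in ids}
    rows = []
    trial = 0
    for _ in range(cfg.trials_per_process):
        order = list(ids)
        rng.shuffle(order)
        for pid in order:
            c = quest_recommend(states[pid])
            resp = simulate_response(observers[pid], c, rng)
            states[pid] = quest_update(states[pid], c, resp)
            rows.append((trial, pid, c, int(resp)))
            trial += 1
    log = pd.DataFrame(rows, columns=["trial", "process_id", "contrast", "response"])
    thresholds = {i: quest_recommend(states[i]) for i in ids}
    return SessionResult(thresholds, log, states)


@dataclass
class ValidationResult:
    passed: bool
    recognition_rate: float
    thresholds: dict[str, float]  # Day-1 thresholds, rescaled if adjusted
    gain: float  # multiplicative adjustment (1.0 when passed)
    validation_log: pd.DataFrame


def validate_and_adjust(
    thresholds: dict[str, float],
    observers: dict[str, PsychometricObserver],
    rng: np.random.Generator,
    *,
    n_per_image: int = 4,
    low: float = 0.30,
    high: float = 0.80,
    adjust_target_p: float = 0.50,
    adjust_processes: int = 2,
    adjust_trials: int = 40,
) -> ValidationResult:
    """Day-2 validation: 80 trials at the Day-1 thresholds, then adjust if needed.

    A recognition rate in (``low``, ``high``] passes.  Otherwise two interleaved
    pooled QUEST processes (40 trials each, all images) re-estimate a single
    gain g applied to every Day-1 threshold, targeting ``adjust_target_p``
    recognition across images — correcting an overall threshold shift but not
    new between-image differences.
    """
    ids = list(thresholds)
    rows = []
    trial = 0
    for _ in range(n_per_image):
        order = list(ids)
        rng.shuffle(order)
        for pid in order:
            c = float(np.clip(thresholds[pid], 1e-4, 1.0))
            resp = simulate_response(observers[pid], c, rng)
            rows.append((trial, pid, c, int(resp)))
            trial += 1
    log = pd.DataFrame(rows, columns=["trial", "process_id", "contrast", "response"])
    rate = float(log["response"].mean())
    if low < rate <= high:
        return ValidationResult(True, rate, dict(thresholds), 1.0, log)

    # Pooled re-staircase over a common gain on the Day-1 thresholds.
    gain_cfg = StaircaseConfig(
        n_processes=adjust_processes,
        trials_per_process=adjust_trials,
        target_p=adjust_target_p,
        prior_mean=0.0,
        prior_sd=0.5,
        grid_lo=-1.5,
        grid_hi=1.5,
    )
    states = [quest_init(gain_cfg) for _ in range(adjust_processes)]
    image_cycle = list(ids)
    idx = 0
    for t in range(adjust_processes * adjust_trials):
        proc = t % adjust_processes
        if idx == 0:
            rng.shuffle(image_cycle)
        pid = image_cycle[idx]
        idx = (idx + 1) % len(image_cycle)
        gain = float(np.clip(10.0 ** states[proc].mean_log_threshold(), 10.0**-1.5, 10.0**1.5))
        c = float(np.clip(gain * thresholds[pid], 1e-4, 1.0))
        resp = simulate_response(observers[pid], c, rng)
        # Update in gain space: the effective contrast relative to this
        # image's Day-1 threshold plays the role of the test contrast.
        states[proc] = quest_update(states[proc], c / thresholds[pid], resp)
    gains = [float(np.clip(10.0 ** s.mean_log_threshold(), 10.0**-1.5, 10.0**1.5)) for s in states]
    gain = float(np.exp(np.mean(np.log(gains))))
    adjusted = {i: float(np.clip(gain * thresholds[i], 1e-4, 1.0)) for i in ids}
    return ValidationResult(False, rate, adjusted, gain, log)
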