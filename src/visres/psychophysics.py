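"""Adaptive 2IFC threshold estimation: QUEST staircase, session logic,
maximum-likelihood psychometric fitting and robust outlier rejection.

The task is two-interval forced choice (2IFC): the observer reports which of
two intervals contained the grating, so chance performance is 0.5.  The
stimulus variable is display resolution in ppd, and — unlike a classical
contrast staircase — *higher* levels are *harder*: a finer grating is
closer to (or beyond) the observer's resolution limit.  The psychometric
function is therefore a Weibull in log10 ppd that falls from a lapse-limited
ceiling towards the 0.5 guessing floor as the level increases:

    p(correct | x) = gamma + (1 - gamma - lapse) * (1 - exp(-ln2 * 10**(beta*(T - x))))

with ``x = log10(level_ppd)`` and ``T = log10(threshold_ppd)``.  The ln2
factor places the threshold parameter exactly at the performance criterion
midway between the guessing floor and the ceiling (p = (gamma + 1 - lapse)/2),
which is also the criterion at which fitted thresholds are reported.

QUEST maintains a discrete posterior over ``T`` on a log10 grid, places each
trial at the posterior mean, and stops a track once the posterior SD drops
to 0.07 log10 units after a minimum of 30 trials, or at 50 trials.  Each
selected level is presented three times consecutively (mirroring an
apparatus whose viewing distance is expensive to change), with every
response fed to the staircase individually by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "QuestConfig",
    "QuestState",
    "SessionConfig",
    "TrialRecord",
    "PsychometricFit",
    "weibull_2ifc",
    "quest_init",
    "quest_update",
    "quest_estimate",
    "quest_next_level",
    "run_2ifc_session",
    "fit_psychometric_mle",
    "threshold_at_criterion",
    "detect_outliers_modz",
    "trials_to_frame",
    "trials_from_frame",
]

LN2 = math.log(2.0)


def weibull_2ifc(level_ppd, threshold_ppd, beta: float, gamma: float = 0.5, lapse: float = 0.0):
    """Probability of a correct 2IFC response at resolution ``level_ppd``.

    Decreasing in the level: levels far below the threshold are seen almost
    always (``1 - lapse``), levels far above are pure guessing (``gamma``).
    At ``level == threshold`` the probability is exactly midway between
    floor and ceiling.  Vectorised over either argument.
    """
    level = np.asarray(level_ppd, dtype=float)
    thresh = np.asarray(threshold_ppd, dtype=float)
    if np.any(level <= 0) or np.any(thresh <= 0):
        raise ValueError("levels and thresholds must be positive")
    excess = beta * (np.log10(thresh) - np.log10(level))
    # exp(-ln2 * 10**excess): 1 at excess -> -inf (guessing), 0 at +inf;
    # overflow of 10**excess to inf yields the correct ceiling limit.
    with np.errstate(over="ignore"):
        p = gamma + (1.0 - gamma - lapse) * (1.0 - np.exp(-LN2 * 10.0 ** excess))
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class QuestConfig:
    """Grid, prior and psychometric shape for a QUEST staircase.

    The grid spans log10 threshold ppd; 0.3–2.3 covers 2–200 ppd.  The
    prior is a broad Gaussian centred near the 60 ppd folk value.
    """

    grid_min: float = 0.3
    grid_max: float = 2.3
    grid_step: float = 0.01
    beta: float = 10.0
    gamma: float = 0.5
    delta: float = 0.01
    prior_mean: float = math.log10(60.0)
    prior_sd: float = 0.6
    placement: str = "mean"  # or "quantile"
    placement_quantile: float = 0.5

    def __post_init__(self) -> None:
        if not self.grid_min < self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not (0 <= self.delta < 0.1):
            raise ValueError("lapse rate delta must be in [0, 0.1)")
        if self.gamma != 0.5:
            raise ValueError("gamma must be 0.5 for 2IFC")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.placement not in ("mean", "quantile"):
            raise ValueError("placement must be 'mean' or 'quantile'")


@dataclass(frozen=True)
class QuestState:
    """Posterior over log10 threshold ppd on a discrete grid."""

    grid: np.ndarray
    posterior: np.ndarray
    config: QuestConfig
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.grid.shape != self.posterior.shape:
            raise ValueError("grid and posterior shapes differ")
        if abs(float(self.posterior.sum()) - 1.0) > 1e-12:
            raise ValueError("posterior must sum to 1")
        if np.any(self.posterior < 0):
            raise ValueError("posterior must be non-negative")


def quest_init(config: QuestConfig | None = None) -> QuestState:
    """Fresh staircase: Gaussian prior over log10 ppd, renormalised on the grid."""
    config = config or QuestConfig()
    n = int(round((config.grid_max - config.grid_min) / config.grid_step)) + 1
    grid = config.grid_min + config.grid_step * np.arange(n)
    prior = np.exp(-0.5 * ((grid - config.prior_mean) / config.prior_sd) ** 2)
    total = prior.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate prior on grid")
    return QuestState(grid=grid, posterior=prior / total, config=config)


def quest_update(state: QuestState, level_ppd: float, correct: bool) -> QuestState:
    """Bayes update of the posterior after one trial.

    The likelihood is the 2IFC Weibull evaluated at every candidate
    threshold on the grid; updates commute over trial order.
    """
    if level_ppd <= 0:
        raise ValueError("level_ppd must be positive")
    cfg = state.config
    p_correct = weibull_2ifc(level_ppd, 10.0 ** state.grid, cfg.beta, cfg.gamma, cfg.delta)
    like = p_correct if correct else 1.0 - p_correct
    post = state.posterior * like
    total = post.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError("posterior mass underflowed to zero")
    return replace(state, posterior=post / total, n_trials=state.n_trials + 1)


def quest_estimate(state: QuestState) -> tuple[float, float]:
    """Posterior mean and SD of log10 threshold ppd."""
    mean = float(np.sum(state.grid * state.posterior))
    var = float(np.sum((state.grid - mean) ** 2 * state.posterior))
    return mean, math.sqrt(max(var, 0.0))


def quest_next_level(state: QuestState) -> float:
    """Test level (ppd) for the next trial: posterior mean by default, or a
    posterior quantile when configured."""
    cfg = state.config
    if cfg.placement == "mean":
        return 10.0 ** quest_estimate(state)[0]
    cum = np.cumsum(state.posterior)
    idx = int(np.searchsorted(cum, cfg.placement_quantile))
    return 10.0 ** float(state.grid[min(idx, state.grid.size - 1)])


@dataclass(frozen=True)
class SessionConfig:
    """Stopping rule and repeat structure of one interleaved 2IFC session."""

    min_trials: int = 30
    max_trials: int = 50
    sd_stop: float = 0.07  # log10 units, QuestSd convention
    repeats: int = 3
    aggregate_repeats: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.min_trials <= self.max_trials):
            raise ValueError("need 1 <= min_trials <= max_trials")
        if self.sd_stop <= 0:
            raise ValueError("sd_stop must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    """One simulated 2IFC response."""

    track_id: str
    channel: str
    eccentricity_deg: float
    trial_index: int
    repeat_index: int
    level_ppd: float
    correct: bool

    def __post_init__(self) -> None:
        if self.level_ppd <= 0:
            raise ValueError("level_ppd must be positive")
        if self.repeat_index < 1:
            raise ValueError("repeat_index starts at 1")


def run_2ifc_session(
    observer,
    channels: Sequence[str],
    eccentricity: float,
    seed: int,
    quest_config: QuestConfig | None = None,
    session_config: SessionConfig | None = None,
) -> tuple[list[TrialRecord], dict[str, QuestState]]:
    """Simulate one interleaved multi-channel QUEST session.

    One staircase per channel; on every step a random still-active channel
    (seeded order) is chosen, its next level presented ``repeats`` times
    consecutively with independently simulated responses, and the track is
    stopped once its posterior SD reaches ``sd_stop`` after at least
    ``min_trials`` responses, or at ``max_trials``.  Returns the trial log
    and the final staircase states.
    """
    from .synthetic import simulate_response  # local import to avoid a cycle

    quest_config = quest_config or QuestConfig()
    session_config = session_config or SessionConfig()
    for c in channels:
        if (c, eccentricity) not in observer.true_thresholds:
            raise KeyError(f"observer {observer.id} has no threshold for ({c}, {eccentricity})")

    rng = np.random.default_rng(seed)
    states = {c: quest_init(quest_config) for c in channels}
    active = list(channels)
    trials: list[TrialRecord] = []
    counters = {c: 0 for c in channels}

    while active:
        chan = active[int(rng.integers(len(active)))]
        state = states[chan]
        level = quest_next_level(state)
        n_rep = min(session_config.repeats, session_config.max_trials - counters[chan])
        responses = [
            bool(simulate_response(observer, chan, eccentricity, level, rng))
            for _ in range(n_rep)
        ]
        for k, corr in enumerate(responses, start=1):
            counters[chan] += 1
            trials.append(
                TrialRecord(
                    track_id=f"{observer.id}:{chan}:e{eccentricity:g}",
                    channel=chan,
                    eccentricity_deg=eccentricity,
                    trial_index=counters[chan],
                    repeat_index=k,
                    level_ppd=level,
                    correct=corr,
                )
            )
        if session_config.aggregate_repeats:
            # Score the triplet as one majority-vote response at its level.
            state = quest_update(state, level, sum(responses) > len(responses) / 2)
        else:
            for corr in responses:
                state = quest_update(state, level, corr)
        states[chan] = state
        _, sd = quest_estimate(state)
        if counters[chan] >= session_config.max_trials or (
            counters[chan] >= session_config.min_trials and sd <= session_config.sd_stop
        ):
            active.remove(chan)
    return trials, states


@dataclass(frozen=True)
class PsychometricFit:
    """MLE fit of the 2IFC Weibull to a track's binary responses."""

    threshold_ppd: float
    slope: float
    lapse: float
    loglik: float
    converged: bool
    boundary_flag: bool
    n_trials: int


_T_BOUNDS = (0.3, 2.3)  # log10 ppd, matches the QUEST grid span
_BETA_BOUNDS = (0.5, 20.0)
_LAPSE_BOUNDS = (0.0, 0.05)


def _neg_loglik(theta: np.ndarray, x: np.ndarray, correct: np.ndarray) -> float:
    t, beta, lapse = theta
    p = weibull_2ifc(10.0 ** x, 10.0 ** t, beta, 0.5, lapse)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(np.where(correct, np.log(p), np.log1p(-p))))


def fit_psychometric_mle(
    trials: Iterable[TrialRecord] | pd.DataFrame,
    beta_init: float = 10.0,
) -> PsychometricFit:
    """Maximum-likelihood 2IFC Weibull fit in log10 ppd.

    The guess rate is fixed at 0.5; the lapse rate is bounded to [0, 0.05].
    The reported threshold is the level at the midway performance criterion
    (the Weibull location parameter under this parameterisation).  When the
    responses carry no gradient information (e.g. all correct), the
    optimum sits on a box bound and ``boundary_flag`` is set instead of
    raising.
    """
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    levels = df["level_ppd"].to_numpy(float)
    correct = df["correct"].to_numpy(bool)
    if levels.size < 10:
        raise ValueError(f"need >= 10 trials, got {levels.size}")
    if np.unique(np.round(np.log10(levels), 6)).size < 3:
        raise ValueError("need >= 3 distinct levels")
    x = np.log10(levels)

    t_inits = [float(np.median(x)), float(np.percentile(x, 25)), float(np.percentile(x, 75))]
    best = None
    for t0 in t_inits:
        for b0 in (beta_init, 3.5, 16.0):
            sol = optimize.minimize(
                _neg_loglik,
                x0=[np.clip(t0, *_T_BOUNDS), b0, 0.01],
                args=(x, correct),
                method="L-BFGS-B",
                bounds=[_T_BOUNDS, _BETA_BOUNDS, _LAPSE_BOUNDS],
            )
            if best is None or sol.fun < best.fun:
                best = sol
    t_hat, beta_hat, lapse_hat = best.x
    eps = 1e-6
    boundary = bool(
        t_hat <= _T_BOUNDS[0] + eps
        or t_hat >= _T_BOUNDS[1] - eps
        or beta_hat >= _BETA_BOUNDS[1] - eps
    )
    return PsychometricFit(
        threshold_ppd=float(10.0 ** t_hat),
        slope=float(beta_hat),
        lapse=float(lapse_hat),
        loglik=-float(best.fun),
        converged=bool(best.success),
        boundary_flag=boundary,
        n_trials=int(levels.size),
    )


def threshold_at_criterion(fit: PsychometricFit, p_criterion: float) -> float:
    """Level (ppd) at which the fitted curve crosses ``p_criterion``.

    The stored threshold is the midway criterion; this converts it to any
    other attainable proportion-correct criterion.
    """
    gamma, lapse = 0.5, fit.lapse
    if not (gamma < p_criterion < 1.0 - lapse):
        raise ValueError(f"criterion must be in ({gamma}, {1 - lapse})")
    q = (p_criterion - gamma) / (1.0 - gamma - lapse)
    # Solve 1 - exp(-ln2 * 10**(beta*(T-x))) = q for x: levels above the
    # threshold (x > T) give sub-midway performance.
    excess = math.log10(-math.log1p(-q) / LN2) / fit.slope
    return float(10.0 ** (math.log10(fit.threshold_ppd) - excess))


def detect_outliers_modz(values: Sequence[float], cutoff: float = 3.5) -> np.ndarray:
    """Flag outliers by the modified Z-score, ``0.6745 (x - median) / MAD``.

    ``MAD`` is the median absolute deviation from the median.  When the MAD
    is zero but the data are not constant (more than half the values tied),
    the scale falls back to ``1.253314 * mean absolute deviation``
    (Iglewicz–Hoaglin); constant data yield no outliers.  Default cutoff
    3.5.  The flags are invariant to affine rescaling of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 values")
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad > 0:
        z = 0.6745 * dev / mad
    else:
        mean_ad = np.mean(np.abs(dev))
        if mean_ad == 0:
            return np.zeros(x.shape, dtype=bool)
        z = dev / (1.253314 * mean_ad)
    return np.abs(z) > cutoff


TRIAL_COLUMNS = [
    "track_id",
    "channel",
    "eccentricity_deg",
    "trial_index",
    "repeat_index",
    "level_ppd",
    "correct",
]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "track_id": t.track_id,
            "channel": t.channel,
            "eccentricity_deg": t.eccentricity_deg,
            "trial_index": t.trial_index,
            "repeat_index": t.repeat_index,
            "level_ppd": t.level_ppd,
            "correct": int(t.correct),
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            track_id=str(r.track_id),
            channel=str(r.channel),
            eccentricity_deg=float(r.eccentricity_deg),
            trial_index=int(r.trial_index),
            repeat_index=int(r.repeat_index),
            level_ppd=float(r.level_ppd),
            correct=bool(r.correct),
        )
        for r in df.itertuples(index=False)
    ]
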