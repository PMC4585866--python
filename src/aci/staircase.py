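"""Adaptive 3-down-1-up SNR staircase and experiment simulation.

The experiment adapts the signal-to-noise ratio from trial to trial:
SNR rises by one step after every incorrect response and falls by one
step after three consecutive correct responses since the last change.
Each session starts with a 2 dB step that shrinks by 10% at every SNR
change down to a 0.2 dB floor; the first session starts at -11 dB and
each later session resumes at the previous session's final SNR.  The
3-down-1-up rule converges to the SNR where P(correct) = 0.5**(1/3),
about 79.4% — the task's target performance level.

Two simulation drivers are provided: :func:`run_staircase` drives the
staircase with any correctness-level observer (no audio involved; this
is how full 10,000-trial runs are simulated cheaply), while
:func:`simulate_experiment` runs the complete audio pipeline — target
draw, noise draw, SNR mixing, cochleogram, linear-observer response —
and returns a trial table ready for template estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .cochleogram import CochleogramConfig, compute_cochleogram, make_filterbank
from .stimuli import generate_noise, mix_at_snr

#: performance level targeted by a 3-down-1-up rule (transformed up-down
#: fixed point): P(correct) such that p**3 = 1/2.
CONVERGENCE_PCORRECT = 0.5 ** (1.0 / 3.0)


@dataclass(frozen=True)
class StaircaseConfig:
    initial_snr_db: float = -11.0
    initial_step_db: float = 2.0
    step_decay: float = 0.9
    step_floor_db: float = 0.2
    n_down: int = 3
    snr_min_db: float = -40.0  # safety bounds, unreachable for realistic
    snr_max_db: float = 10.0   # observers


@dataclass(frozen=True)
class StaircaseState:
    snr_db: float
    step_db: float
    consecutive_correct: int
    trial_index: int
    session_index: int


def init_session(previous_state: StaircaseState | None = None,
                 config: StaircaseConfig | None = None) -> StaircaseState:
    """Start a session: resume the previous final SNR, reset the step to 2 dB."""
    cfg = config or StaircaseConfig()
    if previous_state is None:
        return StaircaseState(cfg.initial_snr_db, cfg.initial_step_db, 0, 0, 0)
    return StaircaseState(previous_state.snr_db, cfg.initial_step_db, 0,
                          previous_state.trial_index,
                          previous_state.session_index + 1)


def update(state: StaircaseState, correct: bool,
           config: StaircaseConfig | None = None) -> StaircaseState:
    """One staircase transition; the step decays at every SNR change."""
    cfg = config or StaircaseConfig()
    snr, step, streak = state.snr_db, state.step_db, state.consecutive_correct
    if not correct:
        snr += step
        streak = 0
        step = max(cfg.step_floor_db, step * cfg.step_decay)
    else:
        streak += 1
        if streak >= cfg.n_down:
            snr -= step
            streak = 0
            step = max(cfg.step_floor_db, step * cfg.step_decay)
    snr = min(cfg.snr_max_db, max(cfg.snr_min_db, snr))
    return StaircaseState(snr, step, streak, state.trial_index + 1,
                          state.session_index)


@dataclass(frozen=True)
class PsychometricObserver:
    """Correctness-level observer: P(correct | SNR) is a scaled logistic.

    ``p = guess + (1 - guess) / (1 + exp(-(snr - threshold)/slope_scale))``
    with a 0.5 guessing floor for the two-alternative task.  Under the
    3-down-1-up rule the staircase settles where p = 0.794, i.e. at
    ``threshold + slope_scale * logit((0.794 - guess)/(1 - guess))``.
    """

    threshold_db: float = -13.0
    slope_scale_db: float = 1.0
    guess_rate: float = 0.5

    def p_correct(self, snr_db: float) -> float:
        z = (snr_db - self.threshold_db) / self.slope_scale_db
        return self.guess_rate + (1.0 - self.guess_rate) / (1.0 + np.exp(-z))


def run_staircase(observer, n_sessions: int = 20,
                  trials_per_session: int = 500, seed: int = 0,
                  config: StaircaseConfig | None = None) -> pd.DataFrame:
    """Drive the staircase with a correctness-level observer (no audio).

    ``observer`` must expose ``p_correct(snr_db)``.  Returns one row per
    trial: session, trial, snr_db, step_db, correct.
    """
    cfg = config or StaircaseConfig()
    rng = np.random.default_rng(seed)
    state = None
    rows = np.empty((n_sessions * trials_per_session, 4))
    correct_col = np.empty(n_sessions * trials_per_session, dtype=bool)
    i = 0
    for _ in range(n_sessions):
        state = init_session(state, cfg)
        for _ in range(trials_per_session):
            correct = rng.random() < observer.p_correct(state.snr_db)
            rows[i] = (state.session_index, state.trial_index,
                       state.snr_db, state.step_db)
            correct_col[i] = correct
            state = update(state, correct, cfg)
            i += 1
    df = pd.DataFrame(rows, columns=["session", "trial", "snr_db", "step_db"])
    df[["session", "trial"]] = df[["session", "trial"]].astype(int)
    df["correct"] = correct_col
    return df


@dataclass
class ExperimentLog:
    """A full simulated run: per-trial log plus the cochleogram design matrix."""

    trials: pd.DataFrame       # session, trial, target_id, noise_seed,
                               # noise_index, snr_db, step_db, response, correct
    design: np.ndarray         # n_trials x n_pixels cochleogram vectors
    grid_shape: tuple[int, int]
    master_seed: int
    config: dict


def simulate_experiment(observer, targets, noise_seed: int,
                        n_sessions: int = 20, trials_per_session: int = 500,
                        staircase_config: StaircaseConfig | None = None,
                        cochleogram_config: CochleogramConfig | None = None,
                        seed: int = 0) -> ExperimentLog:
    """Simulate the full audio experiment with a template observer.

    Per trial: draw one of the four targets uniformly, draw a fresh noise
    masker, mix at the staircase SNR, compute its cochleogram, query the
    observer (``respond(cochleogram_values, rng) -> 0/1``), score it, and
    update the staircase.  Fully reproducible from the seeds.
    """
    cfg = staircase_config or StaircaseConfig()
    ccfg = cochleogram_config or CochleogramConfig(
        sample_rate=targets[0].sample_rate)
    fb = make_filterbank(ccfg)
    target_coch = [compute_cochleogram(t.samples, fb, ccfg) for t in targets]
    grid = target_coch[0].values.shape

    rng = np.random.default_rng(seed)
    n_total = n_sessions * trials_per_session
    X = np.empty((n_total, grid[0] * grid[1]))
    recs = []
    state = None
    i = 0
    for _ in range(n_sessions):
        state = init_session(state, cfg)
        for _ in range(trials_per_session):
            k = int(rng.integers(len(targets)))
            target = targets[k]
            noise = generate_noise(len(target.samples), noise_seed, index=i)
            mix = mix_at_snr(target, noise, state.snr_db)
            coch = compute_cochleogram(mix.samples, fb, ccfg)
            resp = observer.respond(coch.values, rng)
            correct = int(resp) == target.response_class
            X[i] = coch.values.ravel()
            recs.append((state.session_index, state.trial_index,
                         target.target_id, target.response_class,
                         noise_seed, i, state.snr_db, state.step_db,
                         int(resp), correct))
            state = update(state, correct, cfg)
            i += 1
    trials = pd.DataFrame(recs, columns=[
        "session", "trial", "target_id", "target_class", "noise_seed",
        "noise_index", "snr_db", "step_db", "response", "correct"])
    return ExperimentLog(trials=trials, design=X, grid_shape=grid,
                         master_seed=seed,
                         config={"n_sessions": n_sessions,
                                 "trials_per_session": trials_per_session,
                                 "noise_seed": noise_seed,
                                 "staircase": {f.name: getattr(cfg, f.name)
                                               for f in fields(cfg)},
                                 "cochleogram": {f.name: getattr(ccfg, f.name)
                                                 for f in fields(ccfg)}})
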