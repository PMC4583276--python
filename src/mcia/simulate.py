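"""Synthetic experiment generator driven by the McIA random walk.

This module plays two roles. First, the step-level walk simulator is the
Monte-Carlo oracle against which the closed-form choice/RT solutions in
:mod:`mcia.model` are validated. Second, :func:`simulate_experiment` emulates
the full experiment — per-participant staircase calibration, 56-face block
construction, choice/RT generation from the walk, and planted contaminant
trials (fast guesses, slow outliers, guess-confidence ratings) — so every
downstream pipeline stage can be exercised end to end with known ground
truth.

Confidence ratings are a placeholder: the walk model does not define
confidence, so ratings are drawn from a noisy map that decreases with the
number of steps taken, which is enough to exercise the confidence-50 filter
and the I/O schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import analysis as ba
from .design import (
    FAMILIES,
    LOCATIONS,
    CalibrationLevels,
    block_seed,
    build_block,
    correct_family,
    enumerate_test_faces,
)
from .model import DEFAULT_PARAMS, VARIANTS, McIAParams, ModelVariant, step_probability
from .staircase import PsychometricObserver, run_calibration

STEP_CAP = 10**6


@dataclass(frozen=True)
class WalkOutcome:
    """Result of one random walk: which boundary absorbed it, and when."""

    correct: bool
    n_steps: int


def simulate_walk(p: float, theta: float, rng: np.random.Generator) -> WalkOutcome:
    """Run one +-1 random walk from 0 to the +-theta absorbing boundaries."""
    if not 0.0 < p < 1.0:
        raise ValueError("step probability must lie strictly in (0, 1)")
    if theta <= 0:
        raise ValueError("theta must be positive")
    pos = 0.0
    n = 0
    chunk = 128
    while n < STEP_CAP:
        steps = np.where(rng.random(chunk) < p, 1.0, -1.0)
        path = pos + np.cumsum(steps)
        hit = np.nonzero(np.abs(path) >= theta)[0]
        if hit.size:
            i = int(hit[0])
            return WalkOutcome(correct=bool(path[i] >= theta), n_steps=n + i + 1)
        pos = float(path[-1])
        n += chunk
    raise RuntimeError(f"walk not absorbed within {STEP_CAP} steps (p={p}, theta={theta})")


def simulate_walks(
    p: float, theta: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized batch of walks; returns (correct flags, step counts)."""
    if not 0.0 < p < 1.0:
        raise ValueError("step probability must lie strictly in (0, 1)")
    if theta <= 0:
        raise ValueError("theta must be positive")
    pos = np.zeros(n)
    n_steps = np.zeros(n, dtype=np.int64)
    correct = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    t = 0
    while active.any():
        t += 1
        if t > STEP_CAP:
            raise RuntimeError("walks not absorbed within the step cap")
        m = int(active.sum())
        pos[active] += np.where(rng.random(m) < p, 1.0, -1.0)
        hit = active & (np.abs(pos) >= theta)
        if hit.any():
            n_steps[hit] = t
            correct[hit] = pos[hit] > 0
            active &= ~hit
    return correct, n_steps


def _confidence_from_steps(
    n_steps: int, theta: float, rng: np.random.Generator
) -> int:
    """Placeholder confidence: noisy, decreasing in decision steps, in 60..100."""
    z = float(np.exp(-n_steps / (2.0 * theta**2)))
    c = z + 0.15 * rng.standard_normal()
    idx = int(np.clip(np.digitize(c, [0.2, 0.4, 0.6, 0.8]), 0, 4))
    return (60, 70, 80, 90, 100)[idx]


def simulate_trial(
    face,
    params: McIAParams,
    variant: ModelVariant = VARIANTS["full"],
    rng: np.random.Generator | None = None,
) -> dict:
    """Simulate one trial: choice from the walk, RT = tau + (h)k*N.

    Returns a dict with response family, rt_ms, confidence, and the walk
    bookkeeping (correct flag, n_steps).
    """
    rng = np.random.default_rng() if rng is None else rng
    p = step_probability(face, params, variant)
    outcome = simulate_walk(p, params.theta, rng)
    target = correct_family(face)
    other = "B" if target == "A" else "A"
    step_ms = params.k * (params.h if face.is_half else 1.0)
    return {
        "response": target if outcome.correct else other,
        "rt_ms": params.tau + step_ms * outcome.n_steps,
        "confidence": _confidence_from_steps(outcome.n_steps, params.theta, rng),
        "correct_walk": outcome.correct,
        "n_steps": outcome.n_steps,
    }


@dataclass(frozen=True)
class SimConfig:
    """Study-design configuration for the synthetic experiment.

    Defaults mirror the experiment being emulated: 19 participants, 4
    integration blocks of 68 trials, generating parameters from
    :data:`mcia.model.DEFAULT_PARAMS` under the full variant (whole-face
    sampling for together faces only), small between-participant parameter
    jitter, and ~13% planted contaminant trials split between fast guesses
    (4.0%), slow outliers (6.4%) and guess-confidence ratings (2.6%, near the
    ~2.5% of confidence-50 responses seen in this paradigm).
    """

    n_participants: int = 19
    n_blocks: int = 4
    seed: int = 0
    params: McIAParams = field(default_factory=lambda: DEFAULT_PARAMS)
    variant_id: str = "full"
    # between-participant jitter scales (lognormal for theta/k, logit-normal
    # for alpha/deltas); zero disables jitter
    theta_jitter: float = 0.10
    k_jitter: float = 0.10
    alpha_jitter: float = 0.20
    delta_jitter: float = 0.10
    # contamination rates; must sum below 1
    rate_fast_guess: float = 0.040
    rate_slow_outlier: float = 0.064
    rate_confidence_50: float = 0.026
    # synthetic-observer population for calibration
    observer_midpoint_mean: float = 80.0
    observer_midpoint_sd: float = 4.0
    observer_slope: float = 0.08
    observer_lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_blocks < 1:
            raise ValueError("n_participants and n_blocks must be >= 1")
        rates = (self.rate_fast_guess, self.rate_slow_outlier, self.rate_confidence_50)
        if any(not 0.0 <= r <= 1.0 for r in rates) or sum(rates) >= 1.0:
            raise ValueError("contamination rates must lie in [0, 1] and sum below 1")
        if self.variant_id not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant_id!r}")

    @property
    def variant(self) -> ModelVariant:
        return VARIANTS[self.variant_id]

    def to_yaml(self) -> str:
        payload = asdict(self)
        payload["params"] = {k: v for k, v in payload["params"].items() if v is not None}
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        payload = yaml.safe_load(text)
        if "params" in payload:
            payload["params"] = McIAParams(**payload["params"])
        return cls(**payload)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _jitter_params(params: McIAParams, cfg: SimConfig, rng) -> McIAParams:
    """Draw one participant's parameters around the population values."""
    kw = {}
    if cfg.theta_jitter > 0:
        kw["theta"] = params.theta * np.exp(cfg.theta_jitter * rng.standard_normal())
    if cfg.k_jitter > 0:
        kw["k"] = params.k * np.exp(cfg.k_jitter * rng.standard_normal())
    if cfg.alpha_jitter > 0 and 0.0 < params.alpha < 1.0:
        kw["alpha"] = _expit(_logit(params.alpha) + cfg.alpha_jitter * rng.standard_normal())
    if cfg.delta_jitter > 0:
        for name in ("delta_weak", "delta_medium", "delta_strong"):
            kw[name] = _expit(
                _logit(getattr(params, name)) + cfg.delta_jitter * rng.standard_normal()
            )
    return params.replace(**kw)


def _calibrate_participant(cfg: SimConfig, rng) -> tuple[CalibrationLevels, dict]:
    """Run the four independent staircases for one participant."""
    medium = {}
    observers = {}
    for loc in LOCATIONS:
        for fam in FAMILIES:
            midpoint = float(
                np.clip(
                    rng.normal(cfg.observer_midpoint_mean, cfg.observer_midpoint_sd),
                    70.0,
                    90.0,
                )
            )
            obs = PsychometricObserver(
                midpoint=midpoint, slope=cfg.observer_slope, lapse=cfg.observer_lapse
            )
            run = run_calibration(
                obs, rng_seed=int(rng.integers(0, 2**31))
            )
            medium[(loc, fam)] = run.medium_level
            observers[f"{loc}_{fam}"] = midpoint
    return CalibrationLevels(medium=medium), observers


def simulate_experiment(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the whole experiment; returns (trials, truth).

    Per participant: staircase calibration fixes the morph levels recorded in
    the trial table; every block is a shuffled 68-trial schedule over the 56
    test faces; choices and RTs come from the participant's jittered
    parameters under the configured variant. Contaminants then overwrite the
    RT (uniform in (0,150) or (5000,8000) ms) or the confidence (set to 50)
    of randomly chosen trials. ``truth`` records each participant's
    parameters, calibration, and the contaminant labels, keyed for the
    parameter-recovery studies.
    """
    rows = []
    truth: dict = {
        "config": json.loads(json.dumps(asdict(config), default=float)),
        "participants": {},
        "contaminants": [],
    }
    faces = enumerate_test_faces()
    for pid in range(1, config.n_participants + 1):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, pid]))
        levels, observers = _calibrate_participant(config, rng)
        p_params = _jitter_params(config.params, config, rng)
        truth["participants"][str(pid)] = {
            "params": {k: v for k, v in p_params.__dict__.items() if v is not None},
            "observer_midpoints": observers,
            "medium_levels": {f"{l}_{f}": levels.medium[(l, f)] for l, f in levels.medium},
        }
        for block in range(1, config.n_blocks + 1):
            schedule = build_block(faces, block_seed(config.seed, pid, block))
            for idx, trial in enumerate(schedule):
                face = trial.face
                sim = simulate_trial(face, p_params, config.variant, rng)
                rows.append(
                    {
                        "participant": pid,
                        "block": block,
                        "trial_index": idx,
                        "format": face.format,
                        "top_family": face.top.family if face.top else None,
                        "top_strength": face.top.strength if face.top else None,
                        "top_morph": levels.level(face.top) if face.top else None,
                        "bottom_family": face.bottom.family if face.bottom else None,
                        "bottom_strength": face.bottom.strength if face.bottom else None,
                        "bottom_morph": levels.level(face.bottom) if face.bottom else None,
                        "screen_x": trial.screen_x,
                        "screen_y": trial.screen_y,
                        "response": sim["response"],
                        "rt_ms": sim["rt_ms"],
                        "confidence": sim["confidence"],
                    }
                )
    trials = pd.DataFrame(rows, columns=ba.TRIAL_COLUMNS)

    # plant contaminants with an experiment-level stream
    crng = np.random.default_rng(np.random.SeedSequence([config.seed, 982451653]))
    probs = [
        1.0 - config.rate_fast_guess - config.rate_slow_outlier - config.rate_confidence_50,
        config.rate_fast_guess,
        config.rate_slow_outlier,
        config.rate_confidence_50,
    ]
    kinds = crng.choice(4, size=len(trials), p=probs)
    for i in np.nonzero(kinds)[0]:
        kind = kinds[i]
        if kind == 1:
            trials.loc[i, "rt_ms"] = crng.uniform(1.0, 150.0 - 1e-9)
            label = "fast_guess"
        elif kind == 2:
            trials.loc[i, "rt_ms"] = crng.uniform(5000.0 + 1e-9, 8000.0)
            label = "slow_outlier"
        else:
            trials.loc[i, "confidence"] = 50
            label = "confidence_50"
        truth["contaminants"].append({"row": int(i), "kind": label})
    return trials, truth


def make_observed_summary(config: SimConfig):
    """Simulate, filter, and summarize in one step.

    Returns (summary, trials, truth); the single entry point for
    parameter-recovery studies and fitting demos.
    """
    trials, truth = simulate_experiment(config)
    coded = ba.code_accuracy(trials)
    kept, report = ba.filter_trials(coded)
    truth["filter_report"] = report
    summary = ba.summarize_conditions(kept)
    return summary, kept, truth
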