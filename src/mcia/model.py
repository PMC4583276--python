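"""The multi-component information accumulation (McIA) model.

Choice and response time arise from a biased random walk between two
absorbing response thresholds at +-theta, starting midway. On every step one
of three evidence sources is sampled: the top half face, the bottom half
face, or the automatically integrated whole face. The whole-face source is
sampled with probability alpha (the attention parameter); the two halves
with probability (1 - alpha)/2 each. A sampled source moves the walk toward
the correct threshold with its step probability delta; the whole-face source
combines the two half probabilities optimally by multiplying their odds.

Because the source is redrawn independently on every step, the walk is a
simple random walk at the marginal step probability, and the classical
gambler's-ruin closed forms give choice probability and expected decision
steps exactly. Decision steps map to milliseconds as RT = tau + k*N for
whole faces and RT = tau + h*k*N for half faces (comparing a lone half face
against whole-face targets carries an extra per-step cost h).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .design import (
    FORMATS,
    STRENGTH_CODE,
    TestFaceSpec,
    correct_family,
)

#: Canonical collapsed conditions: 6 same-family whole + opposite, per format,
#: plus the 3 half-face strengths. 17 cells in all; the 14 whole/opposite
#: cells also carry a deviation score.
WHOLE_CONDITIONS = ("ww", "wm", "ws", "mm", "ms", "ss")
CONDITION_ORDER: tuple[tuple[str, str], ...] = tuple(
    [(c, fmt) for fmt in ("together", "split") for c in WHOLE_CONDITIONS + ("wom",)]
    + [(c, "half") for c in ("w", "m", "s")]
)

_CODE_TO_STRENGTH = {v: k for k, v in STRENGTH_CODE.items()}


@dataclass(frozen=True)
class McIAParams:
    """The eight McIA parameters, plus optional variant extras.

    theta : response threshold in steps (> 0; non-integer values allowed).
    alpha : probability of sampling the whole-face source, in [0, 1].
    delta_weak/medium/strong : per-source step probabilities toward the
        correct threshold, in (0, 1).
    tau : non-decision time, ms (>= 0).
    k : time per step, ms (> 0).
    h : half-face multiplier on the step time (> 0).
    alpha_split : whole-face sampling probability for split faces; used only
        by the variant with a free split alpha.
    gamma : attenuation in [0, 1] applied to the split-face deltas; used only
        by the rate-attenuation variant.
    """

    theta: float = 6.76
    alpha: float = 0.30
    delta_weak: float = 0.54
    delta_medium: float = 0.56
    delta_strong: float = 0.64
    tau: float = 359.0
    k: float = 20.0
    h: float = 1.24
    alpha_split: Optional[float] = None
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.k <= 0 or self.h <= 0:
            raise ValueError("theta, k and h must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        for name in ("delta_weak", "delta_medium", "delta_strong"):
            d = getattr(self, name)
            if not 0.0 < d < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.alpha_split is not None and not 0.0 <= self.alpha_split <= 1.0:
            raise ValueError("alpha_split must lie in [0, 1]")
        if self.gamma is not None and not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")

    def delta(self, strength: str) -> float:
        return {
            "weak": self.delta_weak,
            "medium": self.delta_medium,
            "strong": self.delta_strong,
        }[strength]

    def to_json(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if v is not None}
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "McIAParams":
        return cls(**json.loads(text))

    def replace(self, **kwargs) -> "McIAParams":
        return replace(self, **kwargs)


#: Default parameter configuration for the face task: threshold ~6.8 steps,
#: modest whole-face sampling (alpha = .30) for together faces, calibrated
#: step probabilities just above chance, ~360 ms non-decision time, 20 ms
#: per step and a 24% per-step surcharge for half faces.
DEFAULT_PARAMS = McIAParams()


@dataclass(frozen=True)
class ModelVariant:
    """A structural variant of the McIA: how alpha and delta depend on format.

    Variants:
      full             alpha free for together faces, fixed at 0 for split
                       faces (splitting abolishes automatic integration).
      alpha_one        optimal integration everywhere (alpha = 1).
      alpha_zero       pure half-face averaging everywhere (alpha = 0).
      alpha_split_free separate free alphas for together and split faces.
      rate_attenuation alpha = 1 everywhere, but split-face deltas are
                       attenuated by a free factor gamma in (0, 1].
    """

    id: str
    free_params: tuple[str, ...]

    def alpha_for(self, fmt: str, params: McIAParams) -> float:
        if fmt not in FORMATS:
            raise ValueError(f"unknown format {fmt!r}")
        if self.id == "full":
            return params.alpha if fmt == "together" else 0.0
        if self.id == "alpha_one":
            return 1.0
        if self.id == "alpha_zero":
            return 0.0
        if self.id == "alpha_split_free":
            if fmt == "together":
                return params.alpha
            if params.alpha_split is None:
                raise ValueError("alpha_split_free variant requires params.alpha_split")
            return params.alpha_split
        if self.id == "rate_attenuation":
            return 1.0
        raise ValueError(f"unknown variant {self.id!r}")

    def delta_scale(self, fmt: str, params: McIAParams) -> float:
        if self.id == "rate_attenuation" and fmt == "split":
            if params.gamma is None:
                raise ValueError("rate_attenuation variant requires params.gamma")
            return params.gamma
        return 1.0


_CORE = ("theta", "delta_weak", "delta_medium", "delta_strong", "tau", "k", "h")

VARIANTS: dict[str, ModelVariant] = {
    "full": ModelVariant("full", ("theta", "alpha") + _CORE[1:]),
    "alpha_one": ModelVariant("alpha_one", _CORE),
    "alpha_zero": ModelVariant("alpha_zero", _CORE),
    "alpha_split_free": ModelVariant(
        "alpha_split_free", ("theta", "alpha", "alpha_split") + _CORE[1:]
    ),
    "rate_attenuation": ModelVariant("rate_attenuation", _CORE + ("gamma",)),
}


def combine_optimal(d_top: float, d_bottom: float) -> float:
    """Optimal (odds-product) combination of two evidence probabilities.

    odds(combined) = odds(d_top) * odds(d_bottom); symmetric and associative.
    Neutral evidence (.5) leaves the other source unchanged; two sources both
    above .5 combine to something above either alone.
    """
    for d in (d_top, d_bottom):
        if not 0.0 < d < 1.0:
            raise ValueError(f"evidence probabilities must lie strictly in (0, 1), got {d}")
    odds = (d_top / (1.0 - d_top)) * (d_bottom / (1.0 - d_bottom))
    return odds / (1.0 + odds)


def effective_deltas(
    face: TestFaceSpec, params: McIAParams, scale: float = 1.0
) -> tuple[float, float]:
    """Per-half step probabilities toward the face's correct response.

    A half whose family matches the correct response contributes its strength
    delta; a half favoring the other family (opposite faces) contributes
    1 - delta, by the symmetry of binary evidence. ``scale`` multiplies the
    raw deltas before the opposite-family reflection (rate attenuation).
    """
    if face.is_half:
        raise ValueError("effective_deltas is defined for whole/opposite faces only")
    target = correct_family(face)
    out = []
    for half in (face.top, face.bottom):
        d = scale * params.delta(half.strength)
        out.append(d if half.family == target else 1.0 - d)
    return tuple(out)


def step_probability(
    face: TestFaceSpec, params: McIAParams, variant: ModelVariant = VARIANTS["full"]
) -> float:
    """Marginal probability of a step toward the correct threshold.

    Half faces have a single source: their strength delta. Whole/opposite
    faces mix the optimally combined whole-face source (weight alpha) with
    the two halves (weight (1 - alpha)/2 each), alpha and any delta scaling
    chosen per format by the variant.
    """
    if face.is_half:
        return params.delta(face.sole_half.strength)
    scale = variant.delta_scale(face.format, params)
    d_top, d_bottom = effective_deltas(face, params, scale=scale)
    alpha = variant.alpha_for(face.format, params)
    whole = combine_optimal(d_top, d_bottom) if alpha > 0 else 0.0
    return alpha * whole + (1.0 - alpha) / 2.0 * (d_top + d_bottom)


def walk_choice_probability(p: float, theta: float) -> float:
    """Probability of absorption at the correct threshold.

    Gambler's ruin for a walk starting midway between boundaries theta steps
    away on each side: with r = (1-p)/p, P(correct) = 1 / (1 + r**theta);
    .5 at p = .5. Real-valued theta is evaluated directly.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("step probability must lie strictly in (0, 1)")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if abs(p - 0.5) < 1e-12:
        return 0.5
    r = (1.0 - p) / p
    return 1.0 / (1.0 + r**theta)


def walk_expected_steps(p: float, theta: float) -> float:
    """Expected number of steps to absorption, unconditional on the outcome.

    From the midpoint of boundaries 2*theta apart: for p != .5,
    E[N] = (theta - 2*theta*P(correct)) / (q - p) with q = 1 - p; theta**2 in
    the symmetric limit.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("step probability must lie strictly in (0, 1)")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if abs(p - 0.5) < 1e-9:
        return float(theta) ** 2
    q = 1.0 - p
    p_correct = walk_choice_probability(p, theta)
    return (theta - 2.0 * theta * p_correct) / (q - p)


@dataclass(frozen=True)
class ConditionPrediction:
    """Model prediction for one collapsed condition."""

    condition: str
    format: str
    p_correct: float
    expected_steps: float
    mean_rt: float


def predict_condition(
    face: TestFaceSpec,
    params: McIAParams,
    variant: ModelVariant = VARIANTS["full"],
) -> ConditionPrediction:
    """Closed-form accuracy and mean RT for the condition a face belongs to."""
    p = step_probability(face, params, variant)
    p_correct = walk_choice_probability(p, params.theta)
    n_steps = walk_expected_steps(p, params.theta)
    step_ms = params.h * params.k if face.is_half else params.k
    return ConditionPrediction(
        condition=face.condition,
        format=face.format,
        p_correct=p_correct,
        expected_steps=n_steps,
        mean_rt=params.tau + step_ms * n_steps,
    )


def _representative_face(condition: str, fmt: str) -> TestFaceSpec:
    """One face from each collapsed cell (predictions are collapse-invariant)."""
    from .design import HalfSpec

    if fmt == "half":
        strength = _CODE_TO_STRENGTH[condition]
        return TestFaceSpec(top=HalfSpec("top", "A", strength), format="half")
    if condition == "wom":
        return TestFaceSpec(
            top=HalfSpec("top", "A", "medium"),
            bottom=HalfSpec("bottom", "B", "weak"),
            format=fmt,
        )
    ts, bs = _CODE_TO_STRENGTH[condition[0]], _CODE_TO_STRENGTH[condition[1]]
    return TestFaceSpec(
        top=HalfSpec("top", "A", ts), bottom=HalfSpec("bottom", "A", bs), format=fmt
    )


def _stronger_half_delta(face: TestFaceSpec, params: McIAParams) -> float:
    """Delta of the model's stronger half: the larger effective (unscaled) delta.

    For opposite faces this is the medium half (the weak half's effective
    contribution 1 - delta_weak is below .5); for same-family faces it is the
    larger strength delta. Half faces are never split, so no attenuation
    applies here.
    """
    d_top, d_bottom = effective_deltas(face, params, scale=1.0)
    halves = list(face.halves())
    idx = 0 if d_top >= d_bottom else 1
    return params.delta(halves[idx].strength)


def predict_vectors(
    params: McIAParams, variant: ModelVariant = VARIANTS["full"]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predictions in canonical condition order as plain arrays.

    Returns (p_correct[17], mean_rt[17], deviation[14]); deviations cover the
    whole/opposite cells (the first 14 entries of CONDITION_ORDER). This is
    the hot path for the fitting objective.
    """
    acc = np.empty(len(CONDITION_ORDER))
    rt = np.empty(len(CONDITION_ORDER))
    dev = np.empty(14)
    for i, (cond, fmt) in enumerate(CONDITION_ORDER):
        face = _representative_face(cond, fmt)
        pred = predict_condition(face, params, variant)
        acc[i] = pred.p_correct
        rt[i] = pred.mean_rt
        if fmt != "half":
            d_strong = _stronger_half_delta(face, params)
            dev[i] = pred.p_correct - walk_choice_probability(d_strong, params.theta)
    return acc, rt, dev


def predict_all(
    params: McIAParams, variant: ModelVariant = VARIANTS["full"]
) -> pd.DataFrame:
    """Tidy table of the 17 condition predictions plus predicted deviations.

    The predicted deviation score for each whole/opposite cell is the
    predicted whole-face accuracy minus the predicted accuracy of its
    stronger half presented alone.
    """
    acc, rt, dev = predict_vectors(params, variant)
    rows = []
    for i, (cond, fmt) in enumerate(CONDITION_ORDER):
        rows.append(
            {
                "condition": cond,
                "format": fmt,
                "p_correct": acc[i],
                "expected_steps": (rt[i] - params.tau)
                / (params.k * (params.h if fmt == "half" else 1.0)),
                "mean_rt_ms": rt[i],
                "deviation_pred": dev[i] if fmt != "half" else np.nan,
            }
        )
    return pd.DataFrame(rows)
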