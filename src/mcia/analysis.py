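"""Trial-level behavioral pipeline: filtering, accuracy, deviation scores,
condition summaries, strength-difference coding, and the fast/slow split.

Trials live in a tidy DataFrame, one row per response, with the columns
produced by :mod:`mcia.simulate` (or an equivalent recording):

    participant, block, trial_index, format, top_family, top_strength,
    top_morph, bottom_family, bottom_strength, bottom_morph, screen_x,
    screen_y, response, rt_ms, confidence

Half faces leave the absent half's columns empty/NaN. The deviation score of
a whole-face trial is its 0/1 accuracy minus that participant's mean
accuracy on the stronger of the face's two halves presented alone; negative
deviations are dilution, positive ones additive integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import HalfSpec, TestFaceSpec, correct_family
from .model import CONDITION_ORDER

RT_MIN_MS = 150.0
RT_MAX_MS = 5000.0
CONFIDENCE_SCALE = (50, 60, 70, 80, 90, 100)

TRIAL_COLUMNS = [
    "participant", "block", "trial_index", "format",
    "top_family", "top_strength", "top_morph",
    "bottom_family", "bottom_strength", "bottom_morph",
    "screen_x", "screen_y", "response", "rt_ms", "confidence",
]

_STRENGTH_RANK = {"weak": 0, "medium": 1, "strong": 2}


def face_from_row(row) -> TestFaceSpec:
    """Rebuild the TestFaceSpec encoded in one trial row."""
    def half(loc):
        fam = row[f"{loc}_family"]
        if fam is None or pd.isna(fam) or fam == "":
            return None
        return HalfSpec(loc, str(fam), row[f"{loc}_strength"])

    return TestFaceSpec(top=half("top"), bottom=half("bottom"), format=row["format"])


def _ensure_condition_columns(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach condition / correct_family / correct columns (idempotent)."""
    out = trials.copy()
    if "condition" not in out.columns or "correct" not in out.columns:
        faces = [face_from_row(row) for _, row in out.iterrows()]
        out["condition"] = [f.condition for f in faces]
        out["correct_family"] = [correct_family(f) for f in faces]
        out["correct"] = (out["response"] == out["correct_family"]).astype(int)
    return out


def code_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a 0/1 ``correct`` column: response matches the face's correct family.

    For opposite faces the correct response is the one supported by the
    stronger (medium) evidence.
    """
    return _ensure_condition_columns(trials)


def filter_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove guess-confidence and out-of-range-RT trials.

    A trial is removed if its confidence rating is 50, its RT is below 150 ms,
    or its RT exceeds 5 s (both RT bounds strict, so 150 and 5000 ms survive).
    Returns the kept trials and a report with counts and fractions by reason
    and by format.
    """
    conf50 = trials["confidence"] == 50
    fast = trials["rt_ms"] < RT_MIN_MS
    slow = trials["rt_ms"] > RT_MAX_MS
    removed = conf50 | fast | slow
    kept = trials.loc[~removed].copy()

    def frac(mask, base=None):
        denom = len(trials) if base is None else int(base.sum())
        return float(mask.sum()) / denom if denom else 0.0

    by_format = {}
    for fmt in trials["format"].unique():
        in_fmt = trials["format"] == fmt
        by_format[str(fmt)] = {
            "n": int(in_fmt.sum()),
            "fraction_removed": frac(removed & in_fmt, in_fmt),
            "fraction_confidence_50": frac(conf50 & in_fmt, in_fmt),
        }
    report = {
        "n_input": int(len(trials)),
        "n_removed": int(removed.sum()),
        "fraction_removed": frac(removed),
        "by_reason": {
            "confidence_50": int(conf50.sum()),
            "rt_below_150ms": int(fast.sum()),
            "rt_above_5s": int(slow.sum()),
        },
        "by_format": by_format,
    }
    return kept, report


def half_face_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean accuracy for each half-face cell.

    Collapsed over family, indexed by (participant, location, strength); this
    is the reference against which whole-face deviations are scored.
    """
    t = _ensure_condition_columns(trials)
    halves = t[t["format"] == "half"].copy()
    halves["location"] = np.where(halves["top_family"].notna(), "top", "bottom")
    halves["strength"] = halves["top_strength"].where(
        halves["top_family"].notna(), halves["bottom_strength"]
    )
    return (
        halves.groupby(["participant", "location", "strength"])["correct"]
        .mean()
        .rename("half_acc")
        .reset_index()
    )


def stronger_half(
    participant_half_means: dict, face: TestFaceSpec
) -> str:
    """Location ('top'/'bottom') of the stronger half of a whole face.

    ``participant_half_means`` maps (location, strength) -> mean half-face
    accuracy for one participant. For same-family faces the stronger half is
    the one with the higher empirical mean (the individual's own performance
    overrides the nominal strength labels); exact ties fall back to the
    calibrated strength label (s > m > w), then to top. For opposite faces
    the stronger half is the medium half by definition of the correct
    response.
    """
    if face.is_half:
        raise ValueError("stronger_half is defined for whole/opposite faces only")
    if face.is_opposite:
        return "top" if face.top.strength == "medium" else "bottom"
    key_top = ("top", face.top.strength)
    key_bot = ("bottom", face.bottom.strength)
    for key in (key_top, key_bot):
        if key not in participant_half_means:
            raise KeyError(f"missing half-face mean for cell {key}")
    acc_top, acc_bot = participant_half_means[key_top], participant_half_means[key_bot]
    if acc_top > acc_bot:
        return "top"
    if acc_bot > acc_top:
        return "bottom"
    rank_top = _STRENGTH_RANK[face.top.strength]
    rank_bot = _STRENGTH_RANK[face.bottom.strength]
    if rank_top != rank_bot:
        return "top" if rank_top > rank_bot else "bottom"
    return "top"


def deviation_scores(
    trials: pd.DataFrame, half_means: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-trial deviation records for whole/opposite trials.

    deviation = accuracy(0/1) - participant's mean accuracy on the stronger
    half alone. ``half_means`` defaults to :func:`half_face_means` over the
    same (already filtered) trials.
    """
    t = _ensure_condition_columns(trials)
    if half_means is None:
        half_means = half_face_means(t)
    lookup: dict = {}
    for _, r in half_means.iterrows():
        lookup.setdefault(r["participant"], {})[(r["location"], r["strength"])] = r[
            "half_acc"
        ]

    whole = t[t["format"] != "half"].copy()
    devs = []
    for _, row in whole.iterrows():
        face = face_from_row(row)
        means = lookup.get(row["participant"], {})
        loc = stronger_half(means, face)
        strength = face.top.strength if loc == "top" else face.bottom.strength
        key = (loc, strength)
        if key not in means:
            raise KeyError(
                f"participant {row['participant']} lacks half-face data for {key}"
            )
        devs.append(row["correct"] - means[key])
    whole["deviation"] = devs
    return whole


@dataclass
class ObservedSummary:
    """Condition-level summary of an experiment, the input to model fitting.

    ``table`` holds one row per collapsed condition with columns: condition,
    format, acc_mean, acc_sem, rt_mean, rt_sem, dev_mean, dev_sem (deviations
    NaN for half-face rows); ``n_participants`` is the number of participants
    entering the between-subject SEMs.
    """

    table: pd.DataFrame
    n_participants: int

    def __post_init__(self) -> None:
        required = {
            "condition", "format", "acc_mean", "acc_sem",
            "rt_mean", "rt_sem", "dev_mean", "dev_sem",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"summary table missing columns: {sorted(missing)}")

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["n_participants"] = self.n_participants
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservedSummary":
        table = pd.read_csv(path)
        n = int(table["n_participants"].iloc[0])
        return cls(table=table.drop(columns=["n_participants"]), n_participants=n)


def _between_subject(values: pd.Series) -> tuple[float, float]:
    """Grand mean and between-subject SEM of per-participant means."""
    n = values.notna().sum()
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
    return mean, sem


def summarize_conditions(
    trials: pd.DataFrame, deviations: pd.DataFrame | None = None
) -> ObservedSummary:
    """Collapse filtered trials into the 17-cell condition summary.

    Accuracy and RT are averaged within participant and condition first, then
    across participants; error bars are between-subject SEMs (sd of
    participant means / sqrt(n)). Deviation cells cover the 14 whole/opposite
    conditions. Cells with fewer than two participants get a NaN SEM.
    """
    t = _ensure_condition_columns(trials)
    if deviations is None:
        deviations = deviation_scores(t)

    per_p_acc = t.groupby(["participant", "condition", "format"])["correct"].mean()
    per_p_rt = t.groupby(["participant", "condition", "format"])["rt_ms"].mean()
    per_p_dev = deviations.groupby(["participant", "condition", "format"])[
        "deviation"
    ].mean()

    rows = []
    for cond, fmt in CONDITION_ORDER:
        acc = per_p_acc.xs((cond, fmt), level=("condition", "format"))
        rt = per_p_rt.xs((cond, fmt), level=("condition", "format"))
        acc_mean, acc_sem = _between_subject(acc)
        rt_mean, rt_sem = _between_subject(rt)
        if fmt != "half":
            dev = per_p_dev.xs((cond, fmt), level=("condition", "format"))
            dev_mean, dev_sem = _between_subject(dev)
        else:
            dev_mean = dev_sem = np.nan
        rows.append(
            {
                "condition": cond, "format": fmt,
                "acc_mean": acc_mean, "acc_sem": acc_sem,
                "rt_mean": rt_mean, "rt_sem": rt_sem,
                "dev_mean": dev_mean, "dev_sem": dev_sem,
            }
        )
    n_participants = t["participant"].nunique()
    return ObservedSummary(table=pd.DataFrame(rows), n_participants=n_participants)


#: Strength-difference coding for same-family whole faces: equal strengths
#: -1, one step apart 0, two steps apart (ws) +1.
STRENGTH_DIFF_CODE = {"ww": -1, "mm": -1, "ss": -1, "wm": 0, "ms": 0, "ws": 1}


def strength_difference_table(deviations: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean deviation by |strength difference| and format.

    Opposite (wom) trials are excluded; the coding applies to same-family
    whole faces only. Dilution growing with the strength gap shows up as a
    decreasing trend in this table.
    """
    if len(deviations) == 0:
        return pd.DataFrame(
            columns=["participant", "format", "strength_diff", "deviation"]
        )
    d = deviations[deviations["condition"].isin(STRENGTH_DIFF_CODE)].copy()
    d["strength_diff"] = d["condition"].map(STRENGTH_DIFF_CODE)
    return (
        d.groupby(["participant", "format", "strength_diff"])["deviation"]
        .mean()
        .reset_index()
    )


def median_split(deviations: pd.DataFrame) -> pd.DataFrame:
    """Fast/slow deviation means per participant, overall and by format.

    Each participant's whole-face trials are split at their own median RT
    (computed over all their whole-face trials); trials at the median count
    as slow. Returns tidy rows (participant, format, speed, deviation, n),
    with format 'all' rows for the overall split; empty cells (e.g. no fast
    trials when all RTs are identical) are flagged with n = 0 and NaN means.
    """
    d = deviations.copy()
    out = []
    for pid, grp in d.groupby("participant"):
        med = grp["rt_ms"].median()
        speed = np.where(grp["rt_ms"] < med, "fast", "slow")
        grp = grp.assign(speed=speed)
        for fmt in ["all"] + sorted(grp["format"].unique()):
            sub = grp if fmt == "all" else grp[grp["format"] == fmt]
            for sp in ("fast", "slow"):
                cell = sub[sub["speed"] == sp]
                out.append(
                    {
                        "participant": pid,
                        "format": fmt,
                        "speed": sp,
                        "deviation": cell["deviation"].mean() if len(cell) else np.nan,
                        "n": int(len(cell)),
                    }
                )
    return pd.DataFrame(out)


def read_trials(path) -> pd.DataFrame:
    """Read a tidy trial CSV, keeping family labels as strings."""
    return pd.read_csv(path, dtype={"top_family": "string", "bottom_family": "string"})


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)
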