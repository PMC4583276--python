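"""Weighted-SSE model fitting and variant comparison.

The objective standardizes every condition-level data point — accuracy and
mean RT for the 17 cells, deviation score for the 14 whole/opposite cells —
by its between-subject SEM, squares, and sums. Minimization is Nelder-Mead
on transformed coordinates (logit for probabilities, log for positive scale
parameters) with seeded multi-start to guard against simplex local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .analysis import ObservedSummary
from .model import (
    CONDITION_ORDER,
    McIAParams,
    ModelVariant,
    VARIANTS,
    predict_all,
    predict_vectors,
)

DELTA_LO, DELTA_HI = 0.5, 0.999

#: Generic starting point for the simplex (not tied to any dataset).
DEFAULT_START = {
    "theta": 4.0,
    "alpha": 0.5,
    "alpha_split": 0.5,
    "delta_weak": 0.55,
    "delta_medium": 0.60,
    "delta_strong": 0.70,
    "tau": 250.0,
    "k": 30.0,
    "h": 1.5,
    "gamma": 0.8,
}


def _to_search(name: str, value: float) -> float:
    if name.startswith("delta"):
        return float(logit((value - DELTA_LO) / (DELTA_HI - DELTA_LO)))
    if name in ("alpha", "alpha_split", "gamma"):
        return float(logit(np.clip(value, 1e-9, 1 - 1e-9)))
    if name in ("theta", "k", "h"):
        return float(np.log(value))
    if name == "tau":
        return float(value)
    raise KeyError(name)


def _from_search(name: str, z: float) -> float:
    if name.startswith("delta"):
        return DELTA_LO + (DELTA_HI - DELTA_LO) * float(expit(z))
    if name in ("alpha", "alpha_split", "gamma"):
        return float(expit(z))
    if name in ("theta", "k", "h"):
        return float(np.exp(z))
    if name == "tau":
        return max(float(z), 0.0)
    raise KeyError(name)


def _align_observed(
    observed: ObservedSummary, sem_floor: bool = False
) -> tuple[np.ndarray, ...]:
    """Observed means/SEMs as arrays in canonical condition order.

    With ``sem_floor=True`` a zero or missing SEM (e.g. a ceiling cell where
    every participant scored 100%) is replaced by the smallest positive SEM
    among cells of the same measure, instead of being rejected; the fitter
    uses this so near-ceiling synthetic datasets remain fittable.
    """
    table = observed.table.set_index(["condition", "format"])
    acc = np.empty(len(CONDITION_ORDER))
    acc_sem = np.empty_like(acc)
    rt = np.empty_like(acc)
    rt_sem = np.empty_like(acc)
    dev = np.empty(14)
    dev_sem = np.empty(14)
    for i, key in enumerate(CONDITION_ORDER):
        if key not in table.index:
            raise ValueError(f"observed summary missing condition cell {key}")
        row = table.loc[key]
        acc[i], acc_sem[i] = row["acc_mean"], row["acc_sem"]
        rt[i], rt_sem[i] = row["rt_mean"], row["rt_sem"]
        if key[1] != "half":
            dev[i], dev_sem[i] = row["dev_mean"], row["dev_sem"]
    if sem_floor:
        for arr in (acc_sem, rt_sem, dev_sem):
            bad = ~np.isfinite(arr) | (arr <= 0)
            if bad.any():
                if bad.all():
                    raise ValueError("no positive SEMs available to floor against")
                arr[bad] = arr[~bad].min()
    sems = np.concatenate([acc_sem, rt_sem, dev_sem])
    if np.any(~np.isfinite(sems)) or np.any(sems <= 0):
        bad = [
            key
            for i, key in enumerate(CONDITION_ORDER)
            if not (np.isfinite(acc_sem[i]) and acc_sem[i] > 0)
            or not (np.isfinite(rt_sem[i]) and rt_sem[i] > 0)
            or (key[1] != "half" and not (np.isfinite(dev_sem[i]) and dev_sem[i] > 0))
        ]
        raise ValueError(f"non-positive or missing SEMs for cells: {bad}")
    return acc, acc_sem, rt, rt_sem, dev, dev_sem


def wsse_objective(predictions: pd.DataFrame, observed: ObservedSummary) -> float:
    """Weighted SSE between a prediction table and an observed summary.

    Sum over accuracy and RT (17 cells each) and deviation scores (14 cells)
    of ((observed - predicted) / SEM)**2.
    """
    acc_o, acc_s, rt_o, rt_s, dev_o, dev_s = _align_observed(observed)
    ptab = predictions.set_index(["condition", "format"])
    acc_p = np.empty(len(CONDITION_ORDER))
    rt_p = np.empty_like(acc_p)
    dev_p = np.empty(14)
    for i, key in enumerate(CONDITION_ORDER):
        if key not in ptab.index:
            raise ValueError(f"prediction table missing condition cell {key}")
        row = ptab.loc[key]
        acc_p[i], rt_p[i] = row["p_correct"], row["mean_rt_ms"]
        if key[1] != "half":
            dev_p[i] = row["deviation_pred"]
    return float(
        np.sum(((acc_o - acc_p) / acc_s) ** 2)
        + np.sum(((rt_o - rt_p) / rt_s) ** 2)
        + np.sum(((dev_o - dev_p) / dev_s) ** 2)
    )


@dataclass
class FitResult:
    """Best-of-restarts fit of one model variant."""

    variant_id: str
    params: McIAParams
    wsse: float
    n_function_evals: int
    converged: bool
    n_restarts: int
    seed: int
    restart_wsse: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant_id,
            "params": {k: v for k, v in self.params.__dict__.items() if v is not None},
            "wsse": self.wsse,
            "n_function_evals": self.n_function_evals,
            "converged": self.converged,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "restart_wsse": self.restart_wsse,
        }


def _params_from_vector(names, z, variant: ModelVariant) -> McIAParams:
    kw = {name: _from_search(name, zi) for name, zi in zip(names, z)}
    if variant.id == "alpha_one":
        kw["alpha"] = 1.0
    elif variant.id in ("alpha_zero",):
        kw["alpha"] = 0.0
    elif variant.id == "rate_attenuation":
        kw["alpha"] = 1.0
    return McIAParams(**kw)


def fit_variant(
    observed: ObservedSummary,
    variant: ModelVariant | str = "full",
    seed: int = 0,
    n_restarts: int = 25,
    start: dict | None = None,
    maxfev: int = 4000,
    sem_floor: bool = True,
) -> FitResult:
    """Fit one variant by Nelder-Mead with seeded jittered restarts.

    Restart 0 starts at the (generic) default start; later restarts jitter
    it in the transformed space. Restarts whose search hits a non-finite
    objective are discarded. The best restart wins.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    targets = _align_observed(observed, sem_floor=sem_floor)
    acc_o, acc_s, rt_o, rt_s, dev_o, dev_s = targets
    names = list(variant.free_params)
    start = dict(DEFAULT_START, **(start or {}))
    z0 = np.array([_to_search(n, start[n]) for n in names])
    # give tau a simplex scale comparable to its magnitude
    jitter_scale = np.array([50.0 if n == "tau" else 0.5 for n in names])

    def objective(z):
        try:
            params = _params_from_vector(names, z, variant)
            acc_p, rt_p, dev_p = predict_vectors(params, variant)
        except (ValueError, OverflowError, FloatingPointError):
            return np.inf
        val = (
            np.sum(((acc_o - acc_p) / acc_s) ** 2)
            + np.sum(((rt_o - rt_p) / rt_s) ** 2)
            + np.sum(((dev_o - dev_p) / dev_s) ** 2)
        )
        return val if np.isfinite(val) else np.inf

    rng = np.random.default_rng(seed)
    best = None
    n_fev = 0
    restart_wsse = []
    for r in range(n_restarts):
        z_init = z0 if r == 0 else z0 + jitter_scale * rng.standard_normal(len(names))
        res = minimize(
            objective,
            z_init,
            method="Nelder-Mead",
            options={
                "xatol": 1e-6,
                "fatol": 1e-6,
                "maxfev": maxfev,
                "adaptive": True,
            },
        )
        n_fev += res.nfev
        if not np.isfinite(res.fun):
            continue
        restart_wsse.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all restarts produced non-finite objectives")
    params = _params_from_vector(names, best.x, variant)
    return FitResult(
        variant_id=variant.id,
        params=params,
        wsse=float(best.fun),
        n_function_evals=n_fev,
        converged=bool(best.success),
        n_restarts=n_restarts,
        seed=seed,
        restart_wsse=sorted(restart_wsse),
    )


def residuals(fit: FitResult, observed: ObservedSummary) -> pd.DataFrame:
    """Per-cell standardized residuals (observed - predicted) / SEM."""
    preds = predict_all(fit.params, VARIANTS[fit.variant_id]).set_index(
        ["condition", "format"]
    )
    rows = []
    obs = observed.table.set_index(["condition", "format"])
    for key in CONDITION_ORDER:
        o, p = obs.loc[key], preds.loc[key]
        rows.append(
            {
                "condition": key[0],
                "format": key[1],
                "acc_resid": (o["acc_mean"] - p["p_correct"]) / o["acc_sem"],
                "rt_resid": (o["rt_mean"] - p["mean_rt_ms"]) / o["rt_sem"],
                "dev_resid": (o["dev_mean"] - p["deviation_pred"]) / o["dev_sem"]
                if key[1] != "half"
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_variants(
    observed: ObservedSummary,
    variants=("full", "alpha_one", "alpha_zero", "alpha_split_free", "rate_attenuation"),
    seed: int = 0,
    n_restarts: int = 25,
    maxfev: int = 4000,
) -> tuple[pd.DataFrame, dict]:
    """Fit each variant and rank by wSSE.

    Returns (ranking table, {variant_id: FitResult}); the table includes the
    fitted parameter values, and per-cell residuals are available through
    :func:`residuals`.
    """
    variants = list(variants)
    if len(variants) < 2:
        raise ValueError("compare_variants needs at least two variants")
    fits = {}
    for v in variants:
        vid = v if isinstance(v, str) else v.id
        fits[vid] = fit_variant(
            observed, vid, seed=seed, n_restarts=n_restarts, maxfev=maxfev
        )
    rows = []
    for vid, fit in fits.items():
        row = {"variant": vid, "wsse": fit.wsse, "converged": fit.converged}
        row.update(
            {k: v for k, v in fit.params.__dict__.items() if v is not None}
        )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("wsse").reset_index(drop=True)
    return table, fits
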