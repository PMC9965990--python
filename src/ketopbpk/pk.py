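"""Non-compartmental PK metrics, model-evaluation statistics and fitting.

Implements the evaluation toolkit used throughout the analyses: AUC_last by
the linear trapezoid, C_max/T_max, log-linear terminal half-life, the mean
relative deviation (MRD) of predicted concentrations, the geometric mean
fold error (GMFE) of predicted PK parameters, interaction (DFI/DDI) ratios,
the two-fold criterion and the ratio-dependent Guest et al. acceptance band,
plus least-squares parameter estimation (Levenberg-Marquardt style or seeded
Monte-Carlo search) and local sensitivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ObservedProfile",
    "PKParameters",
    "InteractionRatio",
    "auc_last",
    "cmax_tmax",
    "terminal_half_life",
    "nca",
    "mrd",
    "gmfe",
    "interaction_ratio",
    "guest_limits",
    "within_guest",
    "within_twofold",
    "FitResult",
    "fit_parameters",
    "local_sensitivity",
    "read_profiles",
    "write_profiles",
]


# --------------------------------------------------------------------------
# observed data container
# --------------------------------------------------------------------------

@dataclass
class ObservedProfile:
    """One observed (or synthetic) mean plasma concentration-time profile."""

    study_id: str
    compound: str
    times: np.ndarray          # h
    concentrations: np.ndarray  # ng/mL
    sd: np.ndarray | None = None
    dose_metadata: list = field(default_factory=list)  # DoseEvent list
    prandial_state: str = "unknown"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.study_id}: times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError(f"{self.study_id}: concentrations must be non-negative")


def read_profiles(path) -> list[ObservedProfile]:
    """Read observed profiles from delimited text.

    Columns: study_id, compound, time_h, conc_ng_per_ml, and optionally sd.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for (study, comp), grp in df.groupby(["study_id", "compound"], sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            ObservedProfile(
                study_id=str(study),
                compound=str(comp),
                times=grp["time_h"].to_numpy(),
                concentrations=grp["conc_ng_per_ml"].to_numpy(),
                sd=grp["sd"].to_numpy() if "sd" in grp else None,
            )
        )
    return out


def write_profiles(profiles: Sequence[ObservedProfile], path) -> None:
    rows = []
    for p in profiles:
        for i, (t, c) in enumerate(zip(p.times, p.concentrations)):
            row = {
                "study_id": p.study_id,
                "compound": p.compound,
                "time_h": t,
                "conc_ng_per_ml": c,
            }
            if p.sd is not None:
                row["sd"] = p.sd[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# non-compartmental metrics
# --------------------------------------------------------------------------

@dataclass
class PKParameters:
    AUC_last: float        # ng*h/mL
    C_max: float           # ng/mL
    T_max: float           # h
    t_half: float | None = None  # h


def auc_last(times: np.ndarray, concentrations: np.ndarray) -> float:
    """AUC from dose time to the last measurement (linear trapezoid)."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if times.size < 2:
        raise ValueError("AUC_last requires at least two points")
    return float(np.trapezoid(conc, times))


def cmax_tmax(times: np.ndarray, concentrations: np.ndarray) -> tuple[float, float]:
    """Peak concentration and its time; the first occurrence wins on ties."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if times.size < 1:
        raise ValueError("profile is empty")
    i = int(np.argmax(conc))
    if conc[i] == 0.0:
        warnings.warn("degenerate all-zero profile", stacklevel=2)
        return 0.0, 0.0
    return float(conc[i]), float(times[i])


def terminal_half_life(
    times: np.ndarray,
    concentrations: np.ndarray,
    n_terminal_points: int = 4,
) -> float:
    """ln(2)/lambda_z from a log-linear fit over the terminal points after C_max."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if n_terminal_points < 3:
        raise ValueError("need at least three terminal points")
    i_max = int(np.argmax(conc))
    tail_t = times[i_max:]
    tail_c = conc[i_max:]
    pos = tail_c > 0
    tail_t, tail_c = tail_t[pos], tail_c[pos]
    if tail_t.size < n_terminal_points:
        raise ValueError("not enough positive terminal concentrations")
    t_fit = tail_t[-n_terminal_points:]
    c_fit = tail_c[-n_terminal_points:]
    slope = np.polyfit(t_fit, np.log(c_fit), 1)[0]
    if slope >= 0:
        raise ValueError("terminal phase is not declining; half-life undefined")
    return float(math.log(2.0) / -slope)


def nca(times: np.ndarray, concentrations: np.ndarray, n_terminal_points: int = 4) -> PKParameters:
    """Standard non-compartmental summary of a profile."""
    c_max, t_max = cmax_tmax(times, concentrations)
    try:
        t_half = terminal_half_life(times, concentrations, n_terminal_points)
    except ValueError:
        t_half = None
    return PKParameters(
        AUC_last=auc_last(times, concentrations),
        C_max=c_max,
        T_max=t_max,
        t_half=t_half,
    )


# --------------------------------------------------------------------------
# evaluation statistics
# --------------------------------------------------------------------------

def mrd(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean relative deviation: 10 ** RMS of log10 prediction errors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("observed and predicted must be equal-length and non-empty")
    bad = np.flatnonzero((obs <= 0) | (pred <= 0))
    if bad.size:
        raise ValueError(f"non-positive concentration at index {bad[0]}; drop below-LOQ pairs first")
    x = np.sqrt(np.mean((np.log10(pred) - np.log10(obs)) ** 2))
    return float(10.0 ** x)


def gmfe(pairs: Sequence[tuple[float, float]]) -> float:
    """Geometric mean fold error of (predicted, observed) PK parameter pairs."""
    if len(pairs) == 0:
        raise ValueError("GMFE of an empty comparison is undefined")
    logs = []
    for pred, obs in pairs:
        if pred <= 0 or obs <= 0:
            raise ValueError("PK values must be positive")
        logs.append(abs(math.log10(pred / obs)))
    return float(10.0 ** np.mean(logs))


@dataclass
class InteractionRatio:
    metric: str       # AUC_last | C_max
    effect: float
    reference: float

    @property
    def ratio(self) -> float:
        return self.effect / self.reference


def interaction_ratio(effect_pk: float, reference_pk: float, metric: str = "AUC_last") -> InteractionRatio:
    """DFI/DDI ratio: PK under the effect condition over the reference."""
    if reference_pk <= 0:
        raise ValueError("reference PK value must be positive")
    return InteractionRatio(metric=metric, effect=effect_pk, reference=reference_pk)


def guest_limits(observed_ratio: float, variability: float = 1.25) -> tuple[float, float]:
    """Ratio-dependent acceptance band of Guest et al. for interaction ratios.

    With R the observed ratio folded above 1, the limit factor is
    L = (variability + 2 (R - 1)) / R; the band is (observed / L, observed * L).
    Near R = 1 the band is (1/variability, variability); far from 1 it
    approaches the two-fold criterion.
    """
    if observed_ratio <= 0:
        raise ValueError("observed ratio must be positive")
    r = observed_ratio if observed_ratio >= 1.0 else 1.0 / observed_ratio
    limit = (variability + 2.0 * (r - 1.0)) / r
    return observed_ratio / limit, observed_ratio * limit


def within_guest(predicted_ratio: float, observed_ratio: float, variability: float = 1.25) -> bool:
    lo, hi = guest_limits(observed_ratio, variability)
    return lo <= predicted_ratio <= hi


def within_twofold(predicted: float, observed: float) -> bool:
    """True if the prediction lies within two-fold of the observation (inclusive)."""
    if predicted <= 0 or observed <= 0:
        raise ValueError("values must be positive")
    ratio = predicted / observed
    return 0.5 <= ratio <= 2.0


# --------------------------------------------------------------------------
# parameter estimation
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    estimates: dict[str, float]
    objective: float
    trace: list[tuple[int, float]]
    converged: bool
    message: str = ""


def _pooled_residuals(
    values: np.ndarray,
    names: list[str],
    observed: Sequence[ObservedProfile],
    predict: Callable[[dict[str, float], ObservedProfile], np.ndarray],
    floor: float,
) -> np.ndarray:
    params = dict(zip(names, values))
    res = []
    for prof in observed:
        pred = np.asarray(predict(params, prof), dtype=float)
        obs = prof.concentrations
        keep = obs > 0
        res.append(
            np.log10(np.maximum(pred[keep], floor)) - np.log10(obs[keep])
        )
    return np.concatenate(res)


def fit_parameters(
    free_params: dict[str, tuple[float, float, float]],
    observed: Sequence[ObservedProfile],
    predict: Callable[[dict[str, float], ObservedProfile], np.ndarray],
    method: str = "LevenbergMarquardt",
    seed: int = 0,
    n_samples: int = 2000,
    floor: float = 1e-9,
) -> FitResult:
    """Estimate model parameters from observed profiles.

    ``free_params`` maps a parameter name to (initial, lower, upper).
    ``predict(params, profile)`` returns the predicted concentrations at the
    profile's sampling times. The objective is the pooled sum of squared
    log10-concentration residuals across all profiles (below-LOQ points,
    stored as zeros, are excluded). ``LevenbergMarquardt`` runs a damped
    least-squares descent within bounds; ``MonteCarlo`` draws uniform
    candidates within bounds (seeded, best-of-``n_samples``) and polishes the
    best candidate with the same least-squares step. Deterministic given the
    seed; non-convergence is reported on the result, not raised.
    """
    if method not in ("LevenbergMarquardt", "MonteCarlo"):
        raise ValueError(f"unknown fitting method {method!r}")
    names = list(free_params)
    x0 = np.array([free_params[n][0] for n in names], dtype=float)
    lo = np.array([free_params[n][1] for n in names], dtype=float)
    hi = np.array([free_params[n][2] for n in names], dtype=float)

    trace: list[tuple[int, float]] = []

    def objective(x: np.ndarray) -> float:
        r = _pooled_residuals(x, names, observed, predict, floor)
        return float(np.sum(r**2))

    if method == "MonteCarlo":
        rng = np.random.default_rng(seed)
        candidates = rng.uniform(lo, hi, size=(n_samples, len(names)))
        candidates[0] = x0
        best_val, best_x = math.inf, x0
        for i, cand in enumerate(candidates):
            val = objective(cand)
            if val < best_val:
                best_val, best_x = val, cand
                trace.append((i, val))
        x0 = np.asarray(best_x)

    calls = [len(trace)]

    def residuals(x):
        r = _pooled_residuals(x, names, observed, predict, floor)
        calls[0] += 1
        trace.append((calls[0], float(np.sum(r**2))))
        return r

    try:
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            x_scale=np.maximum(np.abs(x0), 1e-12), xtol=1e-10, ftol=1e-12,
        )
        estimates = dict(zip(names, sol.x))
        return FitResult(
            estimates=estimates,
            objective=float(np.sum(sol.fun**2)),
            trace=trace,
            converged=bool(sol.success),
            message=str(sol.message),
        )
    except Exception as exc:  # non-convergence: report last iterate
        best = min(trace, key=lambda t: t[1]) if trace else (0, math.inf)
        return FitResult(
            estimates=dict(zip(names, x0)),
            objective=best[1],
            trace=trace,
            converged=False,
            message=str(exc),
        )


# --------------------------------------------------------------------------
# local sensitivity
# --------------------------------------------------------------------------

def local_sensitivity(
    run_output: Callable[[float], float],
    value: float,
    relative_perturbation: float = 0.1,
) -> float:
    """Normalized local sensitivity S = (dOutput/Output) / (dp/p).

    Central difference: the output function is evaluated at
    ``value * (1 +/- relative_perturbation)`` and at ``value``.
    """
    if value == 0:
        raise ValueError("cannot perturb a zero-valued parameter relatively")
    base = run_output(value)
    if base == 0:
        return 0.0
    up = run_output(value * (1.0 + relative_perturbation))
    down = run_output(value * (1.0 - relative_perturbation))
    return float((up - down) / (2.0 * relative_perturbation * base))
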