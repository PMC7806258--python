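"""Boltzmann psychometric fits: PSE, difference limen, and shift statistics.

Choice proportions over the 7 walker levels are fitted with a two-parameter
sigmoid.  We parameterize it as the increasing logistic

    F(z; x0, s) = 1 / (1 + exp(-(z - x0) / s)),      s > 0,

so 'proportion male' rises with masculine Z; the classical decreasing
Boltzmann form f(x) = 1/(1+exp((x-x0)/omega)) is the same curve with
omega = -s.  The fitted x0 is the point of subjective equality (PSE): the Z
value judged male 50% of the time.  The difference limen is half the
interquartile range of the fitted curve, which for a logistic has the closed
form s * ln 3.

Fitting is unweighted least squares on the 7 (normalized) proportions; the
baseline normalization destroys the binomial likelihood, so no likelihood is
pretended.  Optional trial-count weights are accepted.  A deterministic
multi-start grid around a moment-based initializer guards against local
minima; boundary-pinned or degenerate solutions are flagged rather than
raised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "PsychometricFit",
    "ShiftResult",
    "logistic",
    "fit_boltzmann",
    "pse",
    "difference_limen",
    "pse_shift",
    "bias_at_neutral",
    "fit_table",
    "shift_table",
]

X0_BOUNDS = (-1.0, 1.0)
S_BOUNDS = (1e-4, 2.0)
_BOUNDARY_TOL = 1e-3


@dataclass(frozen=True)
class PsychometricFit:
    """Least-squares logistic fit to one condition's 7 proportions."""

    pse: float                 # x0, Z units
    slope_scale: float         # s, Z units (omega = -s)
    difference_limen: float    # s * ln 3, Z units
    sse: float
    converged: bool
    n_levels_used: int


@dataclass(frozen=True)
class ShiftResult:
    """Per-participant PSE shift of an odorant condition vs carrier control.

    Positive = feminine bias (curve moved right: more 'female' responses),
    negative = masculine bias.
    """

    participant_id: str
    odor: str
    drug: str
    pse_shift: float
    bias_at_neutral: float
    valid: bool = True


def logistic(z, x0: float, s: float):
    """Increasing standard logistic on the gender axis."""
    return expit((np.asarray(z, dtype=float) - x0) / s)


def _initial_guess(levels: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    # x0 from linear interpolation of the 0.5 crossing of the monotone hull,
    # s from a quarter of the stimulus range.
    p_mono = np.maximum.accumulate(p[np.argsort(levels)])
    z_sorted = np.sort(levels)
    if p_mono[0] >= 0.5:
        x0 = z_sorted[0]
    elif p_mono[-1] <= 0.5:
        x0 = z_sorted[-1]
    else:
        x0 = float(np.interp(0.5, p_mono, z_sorted))
    s0 = (z_sorted[-1] - z_sorted[0]) / 4.0
    return float(np.clip(x0, *X0_BOUNDS)), s0


def fit_boltzmann(levels, p_norm, weights=None) -> PsychometricFit:
    """Fit the two-parameter sigmoid to 7 proportions by least squares.

    Minimizes sum w_i (p_i - F(z_i; x0, s))^2 with a 3x3 deterministic
    multi-start around the moment initializer.  Ties are broken by lowest SSE,
    then smallest s.  Constant response vectors and boundary-pinned solutions
    are returned with ``converged=False`` (never an exception).
    """
    z = np.asarray(levels, dtype=float)
    p = np.asarray(p_norm, dtype=float)
    if z.shape != p.shape or z.ndim != 1:
        raise ValueError("levels and proportions must be 1-D and aligned")
    if len(z) < 7:
        raise ValueError(f"need at least 7 levels, got {len(z)}")
    if not np.all(np.diff(z) > 0):
        raise ValueError("levels must be strictly increasing")
    if not (np.all(np.isfinite(p)) and np.all((p >= 0) & (p <= 1))):
        raise ValueError("proportions must be finite and within [0, 1]")
    w = np.ones_like(p) if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    if p.max() - p.min() < 1e-3:  # constant responses: curve location unidentified
        return PsychometricFit(float("nan"), float("nan"), float("nan"),
                               float(np.sum((w * (p - p.mean())) ** 2)), False, len(z))

    x0_init, s_init = _initial_guess(z, p)
    best = None
    for dx in (-0.1, 0.0, 0.1):
        for fs in (0.5, 1.0, 2.0):
            start = (
                float(np.clip(x0_init + dx, *X0_BOUNDS)),
                float(np.clip(s_init * fs, *S_BOUNDS)),
            )
            res = least_squares(
                lambda th: w * (expit((z - th[0]) / th[1]) - p),
                start,
                bounds=(np.array([X0_BOUNDS[0], S_BOUNDS[0]]),
                        np.array([X0_BOUNDS[1], S_BOUNDS[1]])),
                method="trf",
            )
            sse = 2.0 * res.cost
            if (best is None or sse < best[0] - 1e-12
                    or (abs(sse - best[0]) <= 1e-12 and res.x[1] < best[1][1])):
                best = (sse, res.x, res.success)
    sse, (x0, s), success = best
    pinned = (
        abs(x0 - X0_BOUNDS[0]) < _BOUNDARY_TOL or abs(x0 - X0_BOUNDS[1]) < _BOUNDARY_TOL
        or s < S_BOUNDS[0] * 1.5 or abs(s - S_BOUNDS[1]) < _BOUNDARY_TOL
    )
    return PsychometricFit(
        pse=float(x0),
        slope_scale=float(s),
        difference_limen=float(s) * math.log(3.0),
        sse=float(sse),
        converged=bool(success and not pinned),
        n_levels_used=len(z),
    )


def pse(fit: PsychometricFit) -> float:
    """Point of subjective equality: the Z level at which F = 0.5."""
    if not fit.converged:
        raise ValueError("PSE undefined for a non-converged fit")
    return fit.pse


def difference_limen(fit: PsychometricFit) -> float:
    """Half the interquartile range of the fitted curve: (z(.75) - z(.25))/2 = s ln 3."""
    if not fit.converged:
        raise ValueError("difference limen undefined for a non-converged fit")
    return fit.slope_scale * math.log(3.0)


def pse_shift(
    fit_odor: PsychometricFit,
    fit_control: PsychometricFit,
    *,
    participant_id: str = "",
    odor: str = "",
    drug: str = "",
    bias: float = float("nan"),
) -> ShiftResult:
    """PSE under an odorant minus PSE under the carrier control.

    A positive generative feminine shift lowers 'male'-response probability at
    every z, moving the fitted 50% point rightward, so positive shift =
    feminine bias.  If either fit is flagged the shift is marked invalid and
    should be excluded downstream.
    """
    valid = fit_odor.converged and fit_control.converged
    shift = fit_odor.pse - fit_control.pse if valid else float("nan")
    if not valid:
        logger.info("flagged fit for %s %s/%s: shift excluded", participant_id, drug, odor)
    return ShiftResult(participant_id, odor, drug, shift, bias, valid)


def bias_at_neutral(p_norm_odor_at_zero: float, p_norm_control_at_zero: float) -> float:
    """Difference in 'male'-response proportion at Z = 0, odor minus control.

    Negative = fewer 'male' responses = feminine bias (sign opposite to the
    PSE shift for monotone curves).
    """
    return float(p_norm_odor_at_zero) - float(p_norm_control_at_zero)


def fit_table(proportions: pd.DataFrame, value_col: str = "p_norm") -> pd.DataFrame:
    """Fit one sigmoid per participant x drug x odor from a proportions table.

    Expects the output of :func:`pseshift.preprocessing.aggregate_proportions`.
    Returns one row per condition with the fitted parameters and diagnostics.
    """
    rows = []
    for (pid, drug, odor), g in proportions.groupby(
        ["participant_id", "drug", "odor"], observed=True, sort=True
    ):
        g = g.sort_values("z_level")
        fit = fit_boltzmann(g["z_level"].to_numpy(), g[value_col].to_numpy())
        at_zero = g.loc[np.isclose(g["z_level"], 0.0), value_col]
        rows.append({
            "participant_id": pid, "drug": drug, "odor": odor,
            "pse": fit.pse, "slope_scale": fit.slope_scale,
            "difference_limen": fit.difference_limen,
            "sse": fit.sse, "converged": fit.converged,
            "p_at_zero": float(at_zero.iloc[0]) if len(at_zero) else float("nan"),
        })
    return pd.DataFrame(rows)


def shift_table(fits: pd.DataFrame, control_odor: str = "control") -> pd.DataFrame:
    """PSE shifts (odor minus carrier control) per participant x drug x odor."""
    rows = []
    for (pid, drug), g in fits.groupby(["participant_id", "drug"], observed=True, sort=True):
        g = g.set_index("odor")
        if control_odor not in g.index:
            raise ValueError(f"no carrier-control fit for {pid} under {drug}")
        ctrl = g.loc[control_odor]
        for odor in g.index:
            if odor == control_odor:
                continue
            od = g.loc[odor]
            valid = bool(od["converged"]) and bool(ctrl["converged"])
            rows.append({
                "participant_id": pid, "drug": drug, "odor": odor,
                "pse_shift": od["pse"] - ctrl["pse"] if valid else float("nan"),
                "bias_at_neutral": bias_at_neutral(od["p_at_zero"], ctrl["p_at_zero"]),
                "valid": valid,
            })
    return pd.DataFrame(rows)
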