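"""Generative observer model for the gender-identification task.

Each simulated participant is a lapse-contaminated logistic observer on the
walker gender axis.  The probability of a 'male' response at stimulus level z
is

    P(male | z) = lambda/2 + (1 - lambda) * L((z - mu) / s)

with L the standard logistic, s > 0 the slope scale, lambda a small lapse
rate, and a criterion mu that moves with three ingredients:

* ``true_neutral`` - residual miscalibration of the individually set neutral
  point (the task recenters the axis per participant, imperfectly);
* a per-day criterion drift, N(0, day_drift_sd^2), shared by all blocks of
  that day - exactly the nuisance the baseline normalization removes;
* a condition effect Delta(drug, odor): a positive Delta is a feminine bias -
  it lowers the 'male'-response probability at every level by moving the
  generative 50% point rightward by Delta on the z axis, so the fitted PSE
  shift (odor minus carrier control) recovers +Delta.

The increasing-logistic convention means 'proportion male' rises with
masculine Z; the classical decreasing Boltzmann parameterization is recovered
with omega = -s.

Condition effects follow an inverted-U dose-response in effective oxytocin
tone: endogenous tone falls with AQ score (socially proficient, low-AQ men sit
near the optimum already), nasal oxytocin adds its dose, atosiban blocks the
pathway entirely, and vasopressin leaves tone unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .design import DesignSpec

__all__ = [
    "DoseResponseModel",
    "ObserverSpec",
    "response_probability",
    "build_effect_map",
    "make_observers",
    "calibrate_neutral_point",
    "CalibrationWarning",
]


@dataclass(frozen=True)
class DoseResponseModel:
    """Inverted-U mapping from effective oxytocin tone to effect gain.

    ``gain = max(0, 1 - |tone - optimum_iu| / width_iu)`` where tone is the
    AQ-dependent endogenous offset plus any exogenous oxytocin dose.  The gain
    is maximal (1) at the optimum and 0 beyond the descending limb.
    """

    shape: str = "inverted_U"
    peak_effect: float = 0.05          # Z units at the optimum
    optimum_iu: float = 12.0
    width_iu: float = 12.0
    endo_max_iu: float = 12.0          # endogenous tone of a highly proficient man
    aq_zero_tone: float = 25.0         # AQ at/above which endogenous tone is 0
    aq_full_tone: float = 15.0         # AQ at/below which endogenous tone is maximal

    def endogenous_tone(self, aq: float) -> float:
        frac = (self.aq_zero_tone - aq) / (self.aq_zero_tone - self.aq_full_tone)
        return self.endo_max_iu * float(np.clip(frac, 0.0, 1.0))

    def gain(self, aq: float, drug: str) -> float:
        """Effect gain in [0, 1] for one drug condition."""
        if drug == "atosiban60ug":
            return 0.0
        tone = self.endogenous_tone(aq)
        if drug in ("OT12", "OT24"):
            tone += {"OT12": 12.0, "OT24": 24.0}[drug]
        # vasopressin, saline and no-drug leave oxytocin tone unchanged
        return max(0.0, 1.0 - abs(tone - self.optimum_iu) / self.width_iu)


@dataclass(frozen=True)
class ObserverSpec:
    """Ground-truth generative parameters for one simulated participant."""

    participant_id: str
    true_neutral: float = 0.0        # Z units
    slope_scale: float = 0.15        # Z units, > 0 (omega = -slope_scale)
    lapse_rate: float = 0.02         # in [0, 0.1]
    day_drift_sd: float = 0.05       # Z units, >= 0
    aq_score: int = 20               # 0..50
    kinsey_score: int = 0            # 0..6
    #: (drug, odor) -> true criterion shift Delta in Z units (+ = feminine bias)
    effect_map: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.slope_scale > 0:
            raise ValueError("slope_scale must be > 0")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if self.day_drift_sd < 0:
            raise ValueError("day_drift_sd must be >= 0")
        if not 0 <= self.aq_score <= 50:
            raise ValueError("aq_score must lie in 0..50")
        if not 0 <= self.kinsey_score <= 6:
            raise ValueError("kinsey_score must lie in 0..6")
        for (drug, odor), delta in self.effect_map.items():
            if odor in ("control", "none") and delta != 0.0:
                raise ValueError("carrier-control and no-odor conditions must map to 0")

    def effect(self, drug: str, odor: str) -> float:
        if odor in ("control", "none") or drug == "none" and odor == "none":
            return 0.0
        return self.effect_map.get((drug, odor), 0.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_map"] = {f"{k[0]}|{k[1]}": v for k, v in self.effect_map.items()}
        return d


def response_probability(
    observer: ObserverSpec,
    z,
    drug: str = "none",
    odor: str = "none",
    day_drift: float = 0.0,
):
    """P('male' | z) for one session context; strictly increasing in z, in (0, 1)."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("stimulus level must be finite")
    mu = observer.true_neutral + day_drift + observer.effect(drug, odor)
    lam = observer.lapse_rate
    p = lam / 2.0 + (1.0 - lam) * expit((z - mu) / observer.slope_scale)
    return p if p.ndim else float(p)


def build_effect_map(
    design: DesignSpec,
    *,
    orientation: str,
    aq: float,
    dose_model: DoseResponseModel,
    peak_and: float,
    peak_est: float,
    observer_scale: float = 1.0,
) -> dict[tuple[str, str], float]:
    """True criterion shifts for every (drug, odor) pair in a design.

    ``orientation`` selects which chemosignal carries information for this
    recipient: estratetraenol biases heterosexual men (feminine, Delta > 0),
    androstadienone biases homosexual men (masculine, Delta < 0).
    ``observer_scale`` multiplies the peaks to model between-observer
    heterogeneity in susceptibility.
    """
    if orientation not in ("heterosexual", "homosexual"):
        raise ValueError(f"unknown orientation {orientation!r}")
    drugs = (
        design.group_factors.get("drug")
        or design.within_factors.get("drug")
    )
    odors = design.within_factors["odor"]
    peaks = {"AND": 0.0, "EST": 0.0, "control": 0.0}
    if orientation == "heterosexual":
        peaks["EST"] = peak_est * observer_scale
    else:
        peaks["AND"] = peak_and * observer_scale
    return {
        (drug, odor): (0.0 if odor == "control"
                       else peaks.get(odor, 0.0) * dose_model.gain(aq, drug))
        for drug in drugs
        for odor in odors
    }


#: cohort characteristics per experiment: orientation and AQ stratum
_COHORTS = {
    "E1": ("heterosexual", "mixed"),
    "E2": ("homosexual", "mixed"),
    "E3": ("heterosexual", "high"),
    "E4": ("heterosexual", "high"),
    "E5": ("heterosexual", "low"),
}


def _sample_aq(rng: np.random.Generator, stratum: str) -> int:
    """AQ ~ discretized N(20, 6) clipped to 0..50, truncated by stratum.

    ``high`` keeps scores >= 25 (1 SD above the reported male mean), ``low``
    keeps scores < 25, ``mixed`` keeps everything.
    """
    for _ in range(1000):
        aq = int(np.clip(round(rng.normal(20.0, 6.0)), 0, 50))
        if stratum == "high" and aq >= 25:
            return aq
        if stratum == "low" and aq < 25:
            return aq
        if stratum == "mixed":
            return aq
    raise RuntimeError("AQ rejection sampling failed")


def make_observers(
    design: DesignSpec,
    seed: int | np.random.Generator,
    *,
    neutral_sd: float = 0.05,
    slope_scale: float = 0.15,
    slope_cv: float = 0.2,
    lapse_rate: float = 0.02,
    day_drift_sd: float = 0.05,
    peak_and: float = -0.05,
    peak_est: float = 0.05,
    effect_sd: float = 0.05,
    dose_model: DoseResponseModel | None = None,
    effect_override: dict[tuple[str, str], float] | None = None,
) -> list[ObserverSpec]:
    """Sample a cohort of ground-truth observers matching a design's population.

    Effect magnitudes default to values for which a subgroup of n = 24
    recovers paired effect sizes dz around 0.6-0.9 (see docs/methods.md).
    Individual susceptibility scales the peak effect by ``1 + N(0,
    effect_sd/|peak|)`` so the per-observer shift is ``peak + N(0,
    effect_sd)`` at full gain.

    ``effect_override`` bypasses the dose-response machinery: the given
    (drug, odor) -> Delta map (plus N(0, effect_sd) per-observer
    heterogeneity on nonzero entries) is injected verbatim, every other
    condition getting exactly 0 - the configuration for ground-truth
    injection studies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    orientation, stratum = _COHORTS[design.experiment_id]
    dose_model = dose_model or DoseResponseModel(peak_effect=abs(peak_est))
    kinsey_pool = (0, 0, 0, 0, 0, 1) if orientation == "heterosexual" else (4, 5, 5, 5, 6, 6)
    observers = []
    for i in range(design.n_participants):
        aq = _sample_aq(rng, stratum)
        peak = peak_est if orientation == "heterosexual" else peak_and
        scale = 1.0 + rng.normal(0.0, effect_sd / abs(peak)) if peak else 1.0
        s = float(np.clip(slope_scale * np.exp(rng.normal(0.0, slope_cv)), 0.05, 0.4))
        if effect_override is not None:
            emap = {
                k: (v + rng.normal(0.0, effect_sd) if v else 0.0)
                for k, v in effect_override.items()
            }
        else:
            emap = build_effect_map(
                design,
                orientation=orientation,
                aq=aq,
                dose_model=dose_model,
                peak_and=peak_and,
                peak_est=peak_est,
                observer_scale=scale,
            )
        observers.append(
            ObserverSpec(
                participant_id=f"{design.experiment_id}_P{i + 1:03d}",
                true_neutral=float(rng.normal(0.0, neutral_sd)),
                slope_scale=s,
                lapse_rate=lapse_rate,
                day_drift_sd=day_drift_sd,
                aq_score=aq,
                kinsey_score=int(rng.choice(kinsey_pool)),
                effect_map=emap,
            )
        )
    return observers


class CalibrationWarning(UserWarning):
    """Degenerate calibration data; falling back to a zero offset."""


def calibrate_neutral_point(calibration_trials) -> float:
    """Fitted PSE of a no-drug, no-odor calibration run, as a Z-axis offset.

    Subtracting the returned offset from the stimulus axis recenters the
    observer; downstream levels stay on the canonical 7-point grid.  If the
    calibration data are degenerate (all one response, or the fit fails) a
    :class:`CalibrationWarning` is issued and the offset is 0.
    """
    from .psychometrics import fit_boltzmann

    df = calibration_trials
    grouped = df.groupby("z_level", observed=True)["response"]
    p = grouped.apply(lambda r: float(np.mean(r == "male")))
    levels = p.index.to_numpy(dtype=float)
    props = p.to_numpy(dtype=float)
    if props.min() > 0.99 or props.max() < 0.01:
        warnings.warn("all responses identical; neutral offset set to 0", CalibrationWarning)
        return 0.0
    fit = fit_boltzmann(levels, props)
    if not fit.converged:
        warnings.warn("calibration fit did not converge; offset set to 0", CalibrationWarning)
        return 0.0
    return fit.pse
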