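"""Trial-level simulation of the five experiments from ground-truth observers.

Every (design, observers, seed) triple reproduces the trial table
bit-for-bit.  Each testing day contributes the baseline blocks (no drug, no
odorant, pre-administration) followed by the experimental blocks under that
day's drug x odorant combination; responses are independent Bernoulli draws
from the observer model.  A ground-truth manifest mirroring every observer's
generative parameters is returned alongside the table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DOSE_IU, DesignSpec, session_conditions
from .observers import ObserverSpec, response_probability

__all__ = ["simulate_experiment", "simulate_calibration_block"]


def simulate_experiment(
    design: DesignSpec,
    observers: list[ObserverSpec],
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Simulate every trial of an experiment.

    Returns ``(trials, manifest)`` where ``trials`` follows the canonical CSV
    schema (see :mod:`pseshift.io`) and ``manifest`` records all ground-truth
    observer parameters plus the seed.
    """
    if len(observers) != design.n_participants:
        raise ValueError(
            f"design expects {design.n_participants} observers, got {len(observers)}"
        )
    rng = np.random.default_rng(seed)
    assignments = session_conditions(
        design, rng if design.counterbalancing == "random_permutation" else None
    )
    levels = np.asarray(design.levels, dtype=float)
    reps = design.repetitions_per_level_per_block
    base_z = np.repeat(levels, reps)

    cols: dict[str, list] = {k: [] for k in (
        "participant_id", "experiment", "session_day", "block_index", "block_type",
        "drug", "dose_iu", "odor", "z_level", "response", "aq", "kinsey")}

    for obs, days in zip(observers, assignments):
        drifts = rng.normal(0.0, obs.day_drift_sd, size=design.sessions_per_participant)
        for day_idx, cond in enumerate(days):
            drift = float(drifts[day_idx])
            for block in range(design.blocks_per_session):
                is_base = block < design.baseline_blocks_per_session
                drug = "none" if is_base else cond["drug"]
                odor = "none" if is_base else cond["odor"]
                z = rng.permutation(base_z)
                p = response_probability(obs, z, drug=drug, odor=odor, day_drift=drift)
                male = rng.random(len(z)) < p
                n = len(z)
                cols["participant_id"].extend([obs.participant_id] * n)
                cols["experiment"].extend([design.experiment_id] * n)
                cols["session_day"].extend([day_idx + 1] * n)
                cols["block_index"].extend([block + 1] * n)
                cols["block_type"].extend(
                    ["baseline" if is_base else "experimental"] * n)
                cols["drug"].extend([drug] * n)
                cols["dose_iu"].extend([DOSE_IU[drug]] * n)
                cols["odor"].extend([odor] * n)
                cols["z_level"].extend(np.round(z, 2).tolist())
                cols["response"].extend(np.where(male, "male", "female").tolist())
                cols["aq"].extend([obs.aq_score] * n)
                cols["kinsey"].extend([obs.kinsey_score] * n)

    trials = pd.DataFrame(cols)
    manifest = {
        "experiment": design.experiment_id,
        "seed": int(seed),
        "n_participants": design.n_participants,
        "observers": [o.to_dict() for o in observers],
    }
    return trials, manifest


def simulate_calibration_block(
    observer: ObserverSpec,
    levels,
    repetitions: int,
    seed: int,
) -> pd.DataFrame:
    """Dedicated pre-experiment neutral-point calibration run (no drug, no odor).

    Stands in for the adaptive neutral-setting procedure: the observer judges
    the canonical grid many times and the fitted PSE is taken as their
    neutral-point offset.
    """
    rng = np.random.default_rng(seed)
    z = np.repeat(np.asarray(levels, dtype=float), repetitions)
    p = response_probability(observer, z)
    male = rng.random(len(z)) < p
    return pd.DataFrame({
        "participant_id": observer.participant_id,
        "z_level": np.round(z, 2),
        "response": np.where(male, "male", "female"),
    })
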