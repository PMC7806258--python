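"""Baseline normalization of response proportions.

Day-to-day criterion drift is removed per stimulus level with the mean-shift
correction

    p' = p_exp - p_base + p_base_bar

where p_exp and p_base are the 'male'-response proportions in a day's
experimental and baseline blocks, and p_base_bar is the participant's mean
baseline proportion across all testing days.  Absent clipping, this preserves
the across-day mean of p_exp while canceling any additive day effect common
to both block types.  The formula can leave [0, 1]; values are clipped and
the clipping events counted and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["normalize_baseline", "aggregate_proportions", "MissingBaselineError"]


class MissingBaselineError(ValueError):
    """A testing day has experimental blocks but no baseline blocks."""


def normalize_baseline(p_exp, p_base, p_base_bar):
    """Apply p' = clip(p_exp - p_base + p_base_bar, 0, 1) elementwise.

    Inputs must lie in [0, 1]; the number of clipped entries is logged.
    Scalars in, scalar out.
    """
    arrs = [np.asarray(a, dtype=float) for a in (p_exp, p_base, p_base_bar)]
    for name, a in zip(("p_exp", "p_base", "p_base_bar"), arrs):
        if np.any((a < 0) | (a > 1) | ~np.isfinite(a)):
            raise ValueError(f"{name} outside [0, 1]")
    raw = arrs[0] - arrs[1] + arrs[2]
    clipped = np.clip(raw, 0.0, 1.0)
    n_clipped = int(np.sum(raw != clipped))
    if n_clipped:
        logger.info("baseline normalization clipped %d value(s) into [0, 1]", n_clipped)
    if clipped.ndim == 0:
        return float(clipped)
    return clipped


def aggregate_proportions(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x session x level proportions, raw and normalized.

    For each participant, testing day and stimulus level: ``p_exp`` pools that
    day's experimental blocks, ``p_base`` pools the same day's baseline
    blocks, and ``p_base_bar`` is the mean of ``p_base`` across all of the
    participant's testing days.  The day's experimental drug x odor condition
    is carried along as the condition key.  Normalization is applied per
    level, never on pooled curves.
    """
    t = trials.copy()
    t["male"] = (t["response"] == "male").astype(float)

    exp = t[t["block_type"] == "experimental"]
    base = t[t["block_type"] == "baseline"]

    exp_days = set(map(tuple, exp[["participant_id", "session_day"]].drop_duplicates().values))
    base_days = set(map(tuple, base[["participant_id", "session_day"]].drop_duplicates().values))
    orphans = sorted(exp_days - base_days)
    if orphans:
        pid, day = orphans[0]
        raise MissingBaselineError(
            f"no baseline blocks for participant {pid} on day {day}"
            + (f" (and {len(orphans) - 1} more)" if len(orphans) > 1 else "")
        )

    p_exp = (
        exp.groupby(["participant_id", "session_day", "drug", "odor", "z_level"],
                    observed=True)["male"]
        .agg(p_exp="mean", n_exp="size").reset_index()
    )
    p_base = (
        base.groupby(["participant_id", "session_day", "z_level"], observed=True)["male"]
        .agg(p_base="mean", n_base="size").reset_index()
    )
    p_base_bar = (
        p_base.groupby(["participant_id", "z_level"], observed=True)["p_base"]
        .mean().rename("p_base_bar").reset_index()
    )

    cells = (
        p_exp.merge(p_base, on=["participant_id", "session_day", "z_level"], how="left")
        .merge(p_base_bar, on=["participant_id", "z_level"], how="left")
    )
    cells["p_norm"] = normalize_baseline(
        cells["p_exp"].to_numpy(), cells["p_base"].to_numpy(),
        cells["p_base_bar"].to_numpy(),
    )
    cells["n_trials"] = cells["n_exp"]
    return cells.sort_values(
        ["participant_id", "session_day", "z_level"], ignore_index=True
    )
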