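"""Reading, writing and validating the canonical text formats.

The trial table is a plain UTF-8 CSV, comma-separated, '.' decimal separator,
newline-terminated, with header::

    participant_id,experiment,session_day,block_index,block_type,drug,dose_iu,
    odor,z_level,response,aq,kinsey

``block_type`` is ``baseline`` or ``experimental``; ``response`` is ``male``
or ``female``.  Baseline blocks are pre-administration: their behavioral
context is always drug ``none``, odor ``none``.  Derived tables (proportions,
fits, shifts, test results) round-trip as CSVs with documented headers, and a
JSON sidecar carries provenance (source, seed, config hash).

A fits-level import (:func:`read_fits`) is provided for datasets shipped as
per-participant PSEs rather than raw trials.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DOSE_IU, DRUGS, EXPERIMENT_IDS, ODORS, DesignSpec

__all__ = [
    "SchemaError",
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "validate_trials",
    "validate_design_consistency",
    "read_fits",
    "write_table",
    "write_sidecar",
    "config_hash",
]

TRIAL_COLUMNS = (
    "participant_id", "experiment", "session_day", "block_index", "block_type",
    "drug", "dose_iu", "odor", "z_level", "response", "aq", "kinsey",
)

FIT_COLUMNS = ("participant_id", "drug", "odor", "pse")

_FLOAT_FMT = "%.6g"


class SchemaError(ValueError):
    """A table violates the canonical schema; the message names row and field."""


def _check_enum(df: pd.DataFrame, col: str, allowed: tuple[str, ...]) -> list[str]:
    bad = df.loc[~df[col].isin(allowed)]
    return [
        f"row {i}: field '{col}' has unknown value {v!r}"
        for i, v in bad[col].head(10).items()
    ]


def validate_trials(df: pd.DataFrame, design: DesignSpec | None = None) -> None:
    """Raise :class:`SchemaError` listing offending rows/fields, if any."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {', '.join(missing)}")
    problems: list[str] = []
    problems += _check_enum(df, "experiment", EXPERIMENT_IDS)
    problems += _check_enum(df, "block_type", ("baseline", "experimental"))
    problems += _check_enum(df, "drug", DRUGS)
    problems += _check_enum(df, "odor", ODORS)
    problems += _check_enum(df, "response", ("male", "female"))

    base = df["block_type"] == "baseline"
    off_context = df.loc[base & ((df["drug"] != "none") | (df["odor"] != "none"))]
    for i in off_context.head(10).index:
        problems.append(f"row {i}: baseline block carries a drug/odor context")

    grid = np.asarray(design.levels if design else np.round(np.linspace(-0.45, 0.45, 7), 2))
    z = pd.to_numeric(df["z_level"], errors="coerce")
    off_grid = df.loc[~np.isclose(z.to_numpy()[:, None], grid[None, :], atol=1e-6).any(axis=1)]
    for i, v in off_grid["z_level"].head(10).items():
        problems.append(f"row {i}: field 'z_level' value {v!r} off the 7-level grid")

    if problems:
        raise SchemaError("; ".join(problems))


def read_trials(path: str | Path, design: DesignSpec | None = None) -> pd.DataFrame:
    """Read and validate a trial-level CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    validate_trials(df, design)
    df["z_level"] = df["z_level"].astype(float)
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a trial table in the pinned CSV dialect (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def validate_design_consistency(df: pd.DataFrame, design: DesignSpec) -> list[str]:
    """Check a trial table against its design; an empty report means pass."""
    report: list[str] = []
    pids = df["participant_id"].unique()
    if len(pids) != design.n_participants:
        report.append(
            f"expected {design.n_participants} participants, found {len(pids)}")

    sessions = df.groupby("participant_id", observed=True)["session_day"].nunique()
    for pid, n in sessions.items():
        if n != design.sessions_per_participant:
            report.append(
                f"participant {pid}: {n} sessions, expected "
                f"{design.sessions_per_participant}")

    blocks = df.groupby(
        ["participant_id", "session_day", "block_type"], observed=True
    )["block_index"].nunique()
    for (pid, day, btype), n in blocks.items():
        want = (design.baseline_blocks_per_session if btype == "baseline"
                else design.experimental_blocks_per_session)
        if n != want:
            report.append(
                f"participant {pid} day {day}: {n} {btype} blocks, expected {want}")

    per_block = df.groupby(
        ["participant_id", "session_day", "block_index"], observed=True
    ).size()
    wrong = per_block[per_block != design.trials_per_block]
    for (pid, day, blk), n in wrong.items():
        report.append(
            f"participant {pid} day {day} block {blk}: {n} trials, "
            f"expected {design.trials_per_block}")

    exp = df[df["block_type"] == "experimental"]
    conds = exp.groupby("participant_id", observed=True).apply(
        lambda g: set(zip(g["drug"], g["odor"])), include_groups=False)
    want_conds = None
    if "drug" in design.within_factors:
        want_conds = {
            (d, o)
            for d in design.within_factors["drug"]
            for o in design.within_factors["odor"]
        }
    for pid, got in conds.items():
        if want_conds is not None and got != want_conds:
            report.append(f"participant {pid}: condition set incomplete")
        lv = set(np.round(exp.loc[exp["participant_id"] == pid, "z_level"], 2))
        if lv != set(np.round(design.levels, 2)):
            report.append(f"participant {pid}: stimulus levels incomplete")

    # counterbalancing balance: each within combination equally often per day rank
    if not design.group_factors:
        day_cond = exp.drop_duplicates(["participant_id", "session_day"])
        counts = day_cond.groupby(["session_day", "drug", "odor"], observed=True).size()
        if len(counts) and counts.max() - counts.min() > max(
            1, counts.sum() // design.sessions_per_participant
        ):
            report.append("counterbalancing: condition/day allocation unbalanced")
    return report


def read_fits(path: str | Path) -> pd.DataFrame:
    """Import a per-participant fits-level CSV (for datasets without raw trials).

    Requires at least ``participant_id,drug,odor,pse``; optional columns
    (slope_scale, difference_limen, sse, converged, p_at_zero) are kept.
    Missing ``converged`` defaults to True.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in FIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"fits table missing columns: {', '.join(missing)}")
    if "converged" not in df.columns:
        df["converged"] = True
    if "p_at_zero" not in df.columns:
        df["p_at_zero"] = float("nan")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a derived table (proportions / fits / shifts / results) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path


def _jsonable(obj):
    """Coerce nested mappings to JSON-encodable form (tuple keys -> strings)."""
    if isinstance(obj, dict):
        return {
            "|".join(map(str, k)) if isinstance(k, tuple) else str(k): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance stamps."""
    blob = json.dumps(_jsonable(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sidecar(path: str | Path, *, source: str, seed: int | None,
                  config: dict | None = None, extra: dict | None = None) -> Path:
    """JSON sidecar with provenance for a derived table."""
    meta = {
        "source": source,
        "seed": seed,
        "config_hash": config_hash(config) if config else None,
    }
    meta.update(extra or {})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path
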