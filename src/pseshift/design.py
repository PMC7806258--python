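"""Canonical experimental designs for the five gender-identification studies.

Five experiments share one task: on each testing day a participant first runs
baseline blocks (no drug, no odorant), then experimental blocks under a drug x
odorant combination.  Stimulus gender is parameterized on a normalized Z axis
with seven equally spaced levels from -0.45 (feminine) to +0.45 (masculine).

* E1 / E2 - 72 heterosexual / homosexual men, drug group between subjects
  (60 ug atosiban, 24 IU oxytocin, 24 IU vasopressin), three sessions with
  androstadienone, estratetraenol or carrier control, counterbalanced.
* E3 / E5 - 24 high-AQ / low-AQ heterosexual men, 10 sessions crossing five
  drug conditions (none, 12/24 IU oxytocin, 12/24 IU vasopressin) with two
  odorant conditions (estratetraenol, carrier control), all within subjects.
* E4 - 24 high-AQ heterosexual men, 6 sessions crossing saline and 12/24 IU
  oxytocin with the two odorant conditions, within subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

EXPERIMENT_IDS = ("E1", "E2", "E3", "E4", "E5")

#: The seven stimulus levels on the walker gender axis (Z units).
LEVELS: tuple[float, ...] = tuple(np.round(np.linspace(-0.45, 0.45, 7), 2))

DRUGS = ("none", "saline", "atosiban60ug", "OT12", "OT24", "VP12", "VP24")
ODORS = ("none", "AND", "EST", "control")

#: Nominal dose in IU for drugs where an IU dose is defined.
DOSE_IU = {
    "none": 0, "saline": 0, "atosiban60ug": 0,
    "OT12": 12, "OT24": 24, "VP12": 12, "VP24": 24,
}

COUNTERBALANCING_SCHEMES = ("latin_square", "random_permutation")


class DesignError(ValueError):
    """Raised for unknown experiments or malformed design parameters."""


@dataclass(frozen=True)
class DesignSpec:
    """Complete factorial description of one experiment.

    ``group_factors`` are between-subject (participants split evenly across
    level combinations); ``within_factors`` are crossed within subject, one
    session per combination.
    """

    experiment_id: str
    n_participants: int
    group_factors: dict[str, tuple[str, ...]]
    within_factors: dict[str, tuple[str, ...]]
    sessions_per_participant: int
    baseline_blocks_per_session: int = 5
    experimental_blocks_per_session: int = 7
    levels: tuple[float, ...] = LEVELS
    repetitions_per_level_per_block: int = 10
    counterbalancing: str = "latin_square"

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if len(lv) != 7:
            raise DesignError(f"expected 7 stimulus levels, got {len(lv)}")
        steps = np.diff(lv)
        if not np.all(steps > 0) or not np.allclose(steps, steps[0], atol=1e-9):
            raise DesignError("levels must be strictly increasing and equally spaced")
        if not np.allclose(lv + lv[::-1], 0.0, atol=1e-9):
            raise DesignError("levels must be symmetric about 0")
        n_within = int(np.prod([len(v) for v in self.within_factors.values()]))
        if self.sessions_per_participant != n_within:
            raise DesignError(
                f"{self.experiment_id}: sessions_per_participant "
                f"({self.sessions_per_participant}) must equal the number of "
                f"within-condition combinations ({n_within})"
            )
        n_cells = int(np.prod([len(v) for v in self.group_factors.values()])) or 1
        if self.n_participants % n_cells:
            raise DesignError("participants must divide evenly across between-subject cells")
        if self.counterbalancing not in COUNTERBALANCING_SCHEMES:
            raise DesignError(f"unknown counterbalancing scheme {self.counterbalancing!r}")

    @property
    def trials_per_block(self) -> int:
        return len(self.levels) * self.repetitions_per_level_per_block

    @property
    def blocks_per_session(self) -> int:
        return self.baseline_blocks_per_session + self.experimental_blocks_per_session

    @property
    def n_sessions_total(self) -> int:
        return self.n_participants * self.sessions_per_participant

    @property
    def trials_per_session(self) -> int:
        return self.blocks_per_session * self.trials_per_block

    @property
    def n_trials_total(self) -> int:
        return self.n_sessions_total * self.trials_per_session

    @property
    def between_cells(self) -> list[tuple[str, ...]]:
        """Between-subject cells as tuples of factor levels (one cell if none)."""
        if not self.group_factors:
            return [()]
        return list(itertools.product(*self.group_factors.values()))

    @property
    def within_combinations(self) -> list[tuple[str, ...]]:
        """Within-subject condition combinations, in canonical factor order."""
        return list(itertools.product(*self.within_factors.values()))


_CANONICAL: dict[str, dict] = {
    "E1": dict(
        n_participants=72,
        group_factors={"drug": ("atosiban60ug", "OT24", "VP24")},
        within_factors={"odor": ("AND", "EST", "control")},
        sessions_per_participant=3,
    ),
    "E3": dict(
        n_participants=24,
        group_factors={},
        within_factors={
            "drug": ("none", "OT12", "OT24", "VP12", "VP24"),
            "odor": ("EST", "control"),
        },
        sessions_per_participant=10,
    ),
    "E4": dict(
        n_participants=24,
        group_factors={},
        within_factors={
            "drug": ("saline", "OT12", "OT24"),
            "odor": ("EST", "control"),
        },
        sessions_per_participant=6,
    ),
}
_CANONICAL["E2"] = _CANONICAL["E1"]
_CANONICAL["E5"] = _CANONICAL["E3"]


def build_design(experiment_id: str, counterbalancing: str = "latin_square") -> DesignSpec:
    """Return the canonical :class:`DesignSpec` for one of the five experiments."""
    if experiment_id not in _CANONICAL:
        raise DesignError(
            f"unknown experiment_id {experiment_id!r}; expected one of {EXPERIMENT_IDS}"
        )
    return DesignSpec(
        experiment_id=experiment_id,
        counterbalancing=counterbalancing,
        **_CANONICAL[experiment_id],
    )


def session_conditions(
    design: DesignSpec, rng: np.random.Generator | None = None
) -> list[list[dict[str, str]]]:
    """Assign a (drug, odor) condition to every participant x day.

    Returns ``assignments[participant][day] -> {"drug": ..., "odor": ...}``.
    Under ``latin_square`` the within-subject condition order is rotated
    cyclically across participants so that each condition occupies each day
    rank equally often; for E3-E5 the two sessions of the same drug fall on
    consecutive days with the odorant order alternated across participants,
    mirroring the administration schedule.  ``random_permutation`` shuffles
    the condition order independently per participant (rng required).
    """
    if design.counterbalancing == "random_permutation" and rng is None:
        raise DesignError("random_permutation counterbalancing requires an rng")

    cells = design.between_cells
    per_cell = design.n_participants // len(cells)
    out: list[list[dict[str, str]]] = []
    wnames = list(design.within_factors)

    for i in range(design.n_participants):
        cell = dict(zip(design.group_factors, cells[i // per_cell]))
        if wnames == ["odor"]:  # E1/E2: drug is between-subject
            odors = list(design.within_factors["odor"])
            if design.counterbalancing == "latin_square":
                k = i % len(odors)
                order = odors[k:] + odors[:k]
            else:
                order = list(rng.permutation(odors))
            days = [{"drug": cell["drug"], "odor": o} for o in order]
        else:  # E3-E5: drug and odor both within-subject
            drugs = list(design.within_factors["drug"])
            odors = list(design.within_factors["odor"])
            if design.counterbalancing == "latin_square":
                k = i % len(drugs)
                drug_order = drugs[k:] + drugs[:k]
            else:
                drug_order = list(rng.permutation(drugs))
            days = []
            for j, d in enumerate(drug_order):
                pair = list(odors) if (i + j) % 2 == 0 else list(odors[::-1])
                if design.counterbalancing == "random_permutation":
                    pair = list(rng.permutation(odors))
                days.extend({"drug": d, "odor": o} for o in pair)
        if len(days) != design.sessions_per_participant:
            raise DesignError("internal error: session assignment length mismatch")
        out.append(days)
    return out
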