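"""Adjusting-amount staircase for intertemporal-choice tasks.

The task presents, for each (delayed amount, delay) block, six binary
choices between an immediate amount and the fixed delayed amount.  The
immediate offer starts at half the delayed amount and is titrated up
after a "delayed" choice and down after an "immediate" choice, with the
adjustment halving (rounded to the nearest currency unit) on every
trial.  The hypothetical seventh-trial offer estimates the indifference
point: the immediate amount subjectively equivalent to the delayed
reward.  Dividing by the delayed amount gives a normalized subjective
value (SV) in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

__all__ = [
    "Choice",
    "ChoiceRecord",
    "CorruptDataError",
    "DELAY_DAYS",
    "DELAY_MONTHS",
    "IncompleteBlockError",
    "InvalidDesignError",
    "StaircaseError",
    "StaircaseState",
    "TaskDesign",
    "init_block",
    "replay_block",
    "step",
    "subjective_value",
    "titrate",
]

Choice = Literal["immediate", "delayed"]

#: The seven delays of the study design, in months (1 week = 0.25 month).
DELAY_MONTHS: tuple[float, ...] = (0.25, 1.0, 3.0, 6.0, 12.0, 36.0, 120.0)

#: Day counts used when a delay enters a discounting model (D in days):
#: 1 week = 7 d, months = 30 d each up to half a year, 1 y = 365 d,
#: 3 y = 1095 d, 10 y = 3650 d.
DELAY_DAYS: dict[float, float] = {
    0.25: 7.0,
    1.0: 30.0,
    3.0: 90.0,
    6.0: 180.0,
    12.0: 365.0,
    36.0: 1095.0,
    120.0: 3650.0,
}

CONDITIONS: tuple[str, str] = ("Standard", "EFT")
GROUPS: tuple[str, str] = ("patient", "control")
MAGNITUDES: tuple[str, str] = ("small", "large")


class StaircaseError(RuntimeError):
    """Illegal operation on a staircase (e.g. stepping a finished block)."""


class InvalidDesignError(ValueError):
    """A task design or block parameter violates its invariants."""


class IncompleteBlockError(StaircaseError):
    """Subjective value requested before/after exactly six choices."""


class CorruptDataError(ValueError):
    """Stored choice data disagree with a deterministic replay."""

    def __init__(self, message: str, trial: int | None = None):
        super().__init__(message)
        self.trial = trial


def _round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (x >= 0)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TaskDesign:
    """The factorial layout of the discounting task.

    Defaults reproduce the study design: two delayed amounts (small and
    large magnitude), seven delays from one week to ten years, six
    titration choices per block, and two cueing conditions.
    """

    delayed_amounts: tuple[int, ...] = (100, 2000)
    delays_months: tuple[float, ...] = DELAY_MONTHS
    trials_per_block: int = 6
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.delayed_amounts):
            raise InvalidDesignError("delayed amounts must be positive")
        if list(self.delays_months) != sorted(self.delays_months) or len(
            set(self.delays_months)
        ) != len(self.delays_months):
            raise InvalidDesignError("delays must be strictly increasing")
        if self.trials_per_block < 1:
            raise InvalidDesignError("trials_per_block must be >= 1")

    @property
    def n_blocks(self) -> int:
        return len(self.delayed_amounts) * len(self.delays_months)

    @property
    def choices_per_condition(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class StaircaseState:
    """State of one titration block.

    ``trial_index`` is 1-based; 7 marks a finished block.  ``history``
    holds the (offer, choice) pairs already administered, so
    ``len(history) == trial_index - 1``.
    """

    delayed_amount: int
    delay_months: float
    immediate_offer: int
    adjustment: int
    trial_index: int = 1
    history: tuple[tuple[int, Choice], ...] = ()

    @property
    def finished(self) -> bool:
        return self.trial_index > 6


@dataclass(frozen=True)
class ChoiceRecord:
    """One administered trial, as serialized in long-format choice tables."""

    participant_id: str
    group: str
    condition: str
    magnitude: str
    delayed_amount: int
    delay_months: float
    trial: int
    immediate_offer: int
    choice: Choice


def init_block(delayed_amount: int | float, delay_months: float) -> StaircaseState:
    """Open a titration block: first offer is half the delayed amount.

    The first adjustment is half of the first-trial difference between
    the immediate and delayed amounts, i.e. a quarter of the delayed
    amount (rounded to the nearest currency unit).
    """
    if delayed_amount <= 0:
        raise InvalidDesignError(f"delayed amount must be positive, got {delayed_amount}")
    amount = _round_half_away(float(delayed_amount))
    offer = _round_half_away(amount / 2)
    adjustment = _round_half_away((amount - offer) / 2)
    return StaircaseState(
        delayed_amount=amount,
        delay_months=delay_months,
        immediate_offer=offer,
        adjustment=adjustment,
    )


def step(state: StaircaseState, choice: Choice) -> StaircaseState:
    """Advance the staircase by one recorded choice.

    A "delayed" choice raises the next immediate offer by the current
    adjustment; an "immediate" choice lowers it.  The adjustment then
    halves, rounded to the nearest unit (ties away from zero).  Offers
    are capped to [0, delayed_amount]: the task never offers more
    immediately than the delayed reward itself.
    """
    if state.finished:
        raise StaircaseError("block already has six recorded choices")
    if choice not in ("immediate", "delayed"):
        raise ValueError(f"choice must be 'immediate' or 'delayed', got {choice!r}")
    sign = 1 if choice == "delayed" else -1
    offer = state.immediate_offer + sign * state.adjustment
    offer = max(0, min(state.delayed_amount, offer))
    return StaircaseState(
        delayed_amount=state.delayed_amount,
        delay_months=state.delay_months,
        immediate_offer=offer,
        adjustment=_round_half_away(state.adjustment / 2),
        trial_index=state.trial_index + 1,
        history=state.history + ((state.immediate_offer, choice),),
    )


def subjective_value(state: StaircaseState) -> int:
    """Indifference-point estimate after a complete six-choice block.

    Returns the immediate amount that would have been offered on a
    seventh trial, in currency units.  Divide by ``delayed_amount`` for
    the normalized SV in [0, 1].
    """
    if len(state.history) != 6:
        raise IncompleteBlockError(
            f"subjective value needs exactly 6 choices, block has {len(state.history)}"
        )
    return state.immediate_offer


def titrate(
    delayed_amount: int | float,
    delay_months: float,
    chooser: Callable[[StaircaseState], Choice],
) -> StaircaseState:
    """Run a full six-trial block against a deterministic/stochastic chooser."""
    state = init_block(delayed_amount, delay_months)
    for _ in range(6):
        state = step(state, chooser(state))
    return state


def replay_block(records: Sequence[ChoiceRecord]) -> float:
    """Re-run one stored block and return its normalized subjective value.

    Validates the stored offers against the deterministic staircase:
    any deviation raises :class:`CorruptDataError` naming the trial.
    """
    records = sorted(records, key=lambda r: r.trial)
    if [r.trial for r in records] != list(range(1, 7)):
        raise CorruptDataError(
            f"block must hold trials 1..6, got {[r.trial for r in records]}"
        )
    first = records[0]
    if any(
        (r.delayed_amount, r.delay_months) != (first.delayed_amount, first.delay_months)
        for r in records
    ):
        raise CorruptDataError("records mix different blocks")
    state = init_block(first.delayed_amount, first.delay_months)
    for rec in records:
        if rec.immediate_offer != state.immediate_offer:
            raise CorruptDataError(
                f"trial {rec.trial}: stored offer {rec.immediate_offer} != "
                f"replayed offer {state.immediate_offer}",
                trial=rec.trial,
            )
        state = step(state, rec.choice)
    sv = subjective_value(state) / state.delayed_amount
    return min(1.0, max(0.0, sv))
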