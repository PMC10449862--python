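"""Outcome taxonomy and framing for the two-reel slot-machine task.

Every trial of the task ends with the right reel at a class-defined distance
from the item the player selected:

* ``MATCH`` — the reels align (a win in the gain framing, a loss in the loss
  framing).
* ``NEAR_BEFORE`` — the reel stops one item *before* a match; the selected
  item never reaches the payline.
* ``NEAR_AFTER`` — the reel stops one item *after* a match; the selected item
  crossed the payline and kept going.
* ``FULL_AWAY`` — the reel stops two or three items away from a match.

Time is stop-locked everywhere in this package: 0 s is the instant the reel
stands still, negative times precede it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class OutcomeClass(enum.Enum):
    """The four outcome classes, ordered as they enter every concatenation."""

    MATCH = "match"
    NEAR_BEFORE = "near_before"
    NEAR_AFTER = "near_after"
    FULL_AWAY = "full_away"

    def __str__(self) -> str:  # keeps CSV columns readable
        return self.value


#: Fixed condition order used for condition-curve concatenation and all
#: tabular outputs.  Both sides of the coupling analysis must use this order.
CONDITION_ORDER: tuple[OutcomeClass, ...] = (
    OutcomeClass.MATCH,
    OutcomeClass.NEAR_BEFORE,
    OutcomeClass.NEAR_AFTER,
    OutcomeClass.FULL_AWAY,
)

#: Admissible stop distances (in items) per class.  FULL_AWAY covers 2 and 3.
STOP_DISTANCES: dict[OutcomeClass, tuple[int, ...]] = {
    OutcomeClass.MATCH: (0,),
    OutcomeClass.NEAR_BEFORE: (-1,),
    OutcomeClass.NEAR_AFTER: (1,),
    OutcomeClass.FULL_AWAY: (2, 3),
}


class Framing(enum.Enum):
    """Valence of a match: gain framing (match pays) or loss framing
    (match costs, every miss pays a small amount)."""

    GAIN = "gain"
    LOSS = "loss"


@dataclass(frozen=True)
class DomainFraming:
    """Payoff structure attached to a framing.

    In the gain framing a match pays ``match_payoff`` > 0 and misses pay
    nothing; in the loss framing a match costs money (``match_payoff`` < 0)
    and every miss pays a small positive amount.
    """

    framing: Framing
    match_payoff: float
    nonmatch_payoff: float

    def __post_init__(self) -> None:
        if self.framing is Framing.GAIN:
            if not (self.match_payoff > 0 and self.nonmatch_payoff == 0):
                raise ValueError(
                    "GAIN framing requires match_payoff > 0 and nonmatch_payoff == 0"
                )
        else:
            if not (self.match_payoff < 0 and self.nonmatch_payoff > 0):
                raise ValueError(
                    "LOSS framing requires match_payoff < 0 and nonmatch_payoff > 0"
                )


GAIN_FRAMING = DomainFraming(Framing.GAIN, match_payoff=0.25, nonmatch_payoff=0.0)
LOSS_FRAMING = DomainFraming(Framing.LOSS, match_payoff=-0.25, nonmatch_payoff=0.10)
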