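"""Deterministic rules of the bystander confrontation scenario.

The scenario is a staged argument between a virtual victim and perpetrator,
observed by a participant who may intervene verbally or physically.  An
adaptive agent performs one action per fixed-interval slot; the participant's
distance to the arguing pair defines a three-band proxemic state, and each
action window is scored by whether (and how) the participant intervened.

This module holds the pieces that are pure bookkeeping: the slot timeline,
distance-band classification, the reward rule, and the scripted sequence of
bystander utterances.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Tuple


class ScenarioError(ValueError):
    """Raised for invalid scenario configuration or inputs."""


class BystanderState(enum.IntEnum):
    """Proxemic state of the participant relative to the arguing pair.

    Ordered by distance band: ``Intervention`` (within arm's reach,
    < 0.5 m), ``Active`` (close but keeping a safety distance, 0.5-1 m),
    ``Passive`` (staying away, >= 1 m).
    """

    Intervention = 0
    Active = 1
    Passive = 2


class AgentAction(enum.IntEnum):
    """The three actions the adaptive agent can trigger.

    ``VictimLookAt``: the victim turns his head to the participant for 2 s.
    ``PerpLookAt``: the perpetrator does the same.
    ``BystandersUtter``: a virtual bystander says the next scripted line
    encouraging intervention.
    """

    VictimLookAt = 0
    PerpLookAt = 1
    BystandersUtter = 2


N_STATES = len(BystanderState)
N_ACTIONS = len(AgentAction)


@dataclass(frozen=True)
class InterventionFlags:
    """Binary per-window indicators of verbal and physical intervention."""

    verbal: bool
    physical: bool

    @property
    def any(self) -> bool:
        return self.verbal or self.physical


@dataclass(frozen=True)
class ScenarioConfig:
    """Timing and proxemics constants of one confrontation.

    Defaults reproduce the staged argument: first agent action 4 s after the
    confrontation starts, one action every 10 s, 13 actions in total over a
    130 s confrontation, with proxemic bands at 0.5 m and 1.0 m.
    """

    n_slots: int = 13
    first_action_s: float = 4.0
    interval_s: float = 10.0
    confrontation_s: float = 130.0
    near_threshold_m: float = 0.5
    far_threshold_m: float = 1.0

    def __post_init__(self) -> None:
        if self.n_slots < 1:
            raise ScenarioError(f"n_slots must be >= 1, got {self.n_slots}")
        if not (0.0 < self.near_threshold_m < self.far_threshold_m):
            raise ScenarioError(
                "need 0 < near_threshold_m < far_threshold_m, got "
                f"{self.near_threshold_m}, {self.far_threshold_m}"
            )
        if self.interval_s <= 0 or self.first_action_s < 0:
            raise ScenarioError("non-positive interval or negative first action time")
        last = self.first_action_s + (self.n_slots - 1) * self.interval_s
        if last > self.confrontation_s:
            raise ScenarioError(
                f"last action at {last} s exceeds confrontation length "
                f"{self.confrontation_s} s"
            )

    @classmethod
    def with_auto_slots(
        cls,
        first_action_s: float = 4.0,
        interval_s: float = 10.0,
        confrontation_s: float = 130.0,
        **kwargs,
    ) -> "ScenarioConfig":
        """Derive ``n_slots`` as the number of actions fitting the confrontation."""
        n = int(math.floor((confrontation_s - first_action_s) / interval_s)) + 1
        return cls(
            n_slots=n,
            first_action_s=first_action_s,
            interval_s=interval_s,
            confrontation_s=confrontation_s,
            **kwargs,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_slots": self.n_slots,
                "first_action_s": self.first_action_s,
                "interval_s": self.interval_s,
                "confrontation_s": self.confrontation_s,
                "near_threshold_m": self.near_threshold_m,
                "far_threshold_m": self.far_threshold_m,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        return cls(**json.loads(text))


def classify_state(
    distance_m: float, config: ScenarioConfig | None = None
) -> BystanderState:
    """Map a participant-to-argument distance (metres) onto a proxemic state.

    Bands are half-open, lower-inclusive: [0, near) -> Intervention,
    [near, far) -> Active, [far, inf) -> Passive, so a boundary distance
    falls in the farther band.
    """
    cfg = config or _DEFAULT_CONFIG
    if not isinstance(distance_m, (int, float)) or isinstance(distance_m, bool):
        raise ScenarioError(f"distance must be a real number, got {distance_m!r}")
    if math.isnan(distance_m) or math.isinf(distance_m) or distance_m < 0:
        raise ScenarioError(f"distance must be finite and >= 0, got {distance_m}")
    if distance_m < cfg.near_threshold_m:
        return BystanderState.Intervention
    if distance_m < cfg.far_threshold_m:
        return BystanderState.Active
    return BystanderState.Passive


#: Reward for a window with no intervention of either kind.
NO_RESPONSE_REWARD = -0.1


def compute_reward(flags: InterventionFlags) -> float:
    """Score one action window: +1 per intervention type, -0.1 if none.

    Verbal and physical interventions each contribute 1, so a window with
    both scores 2.  The small negative reward for silence pushes the agent
    to keep exploring untried actions.
    """
    score = int(flags.verbal) + int(flags.physical)
    return float(score) if score > 0 else NO_RESPONSE_REWARD


def action_schedule(config: ScenarioConfig) -> List[float]:
    """Times (seconds from confrontation onset) at which agent actions fire."""
    return [
        config.first_action_s + k * config.interval_s for k in range(config.n_slots)
    ]


def load_utterances() -> List[str]:
    """The 12 scripted bystander lines, in performance order."""
    text = (
        resources.files("bystander_rl").joinpath("data/utterances.txt").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    return lines


@dataclass
class UtteranceCursor:
    """Serves the scripted bystander utterances sequentially.

    The script has 12 entries but a session allows 13 actions, so an
    all-utterance session would exhaust it; the cursor wraps back to the
    first line rather than failing.
    """

    utterances: List[str] = field(default_factory=load_utterances)
    next_index: int = 0

    def __post_init__(self) -> None:
        if len(self.utterances) != 12:
            raise ScenarioError(
                f"utterance script must have 12 lines, got {len(self.utterances)}"
            )
        if self.next_index < 0:
            raise ScenarioError("next_index must be >= 0")


def next_utterance(cursor: UtteranceCursor) -> Tuple[str, UtteranceCursor]:
    """Return the next scripted line and the advanced cursor (wrap at 12)."""
    line = cursor.utterances[cursor.next_index % len(cursor.utterances)]
    return line, UtteranceCursor(cursor.utterances, cursor.next_index + 1)


_DEFAULT_CONFIG = ScenarioConfig()
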