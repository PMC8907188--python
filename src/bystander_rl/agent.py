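"""Tabular Watkins' Q(lambda) with epsilon-greedy selection.

The state-action space is tiny (3 proxemic states x 3 agent actions), so the
Q function and eligibility traces are plain 3x3 arrays.  Watkins' variant
cuts the traces to zero whenever the action actually taken is non-greedy
with respect to the current Q table, so credit only flows back along greedy
trajectories.

Cohorts chain their knowledge: the final Q tables of one group of sessions
are averaged element-wise and used as the initial table of the next group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .scenario import N_ACTIONS, N_STATES, AgentAction, BystanderState


@dataclass(frozen=True)
class RLParams:
    """Learning hyper-parameters.

    alpha: learning rate (0.2); gamma: discount factor (1.0, so every
    intervention counts equally whenever it happens); lam: eligibility-trace
    decay (0.2); epsilon: per-slot probability of choosing the action
    uniformly at random instead of greedily.
    """

    alpha: float = 0.2
    gamma: float = 1.0
    lam: float = 0.2
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        for name in ("gamma", "lam", "epsilon"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


class QTable:
    """Q values, one per (state, action) pair, stored as a 3x3 float array."""

    __slots__ = ("q",)

    def __init__(self, q: Optional[np.ndarray] = None):
        if q is None:
            q = np.zeros((N_STATES, N_ACTIONS))
        q = np.asarray(q, dtype=float)
        if q.shape != (N_STATES, N_ACTIONS):
            raise ValueError(f"Q table must be {N_STATES}x{N_ACTIONS}, got {q.shape}")
        if not np.all(np.isfinite(q)):
            raise ValueError("Q table entries must be finite")
        self.q = q

    def copy(self) -> "QTable":
        return QTable(self.q.copy())

    def __getitem__(self, key) -> float:
        return self.q[key]

    def __eq__(self, other) -> bool:
        return isinstance(other, QTable) and np.array_equal(self.q, other.q)

    def __repr__(self) -> str:
        return f"QTable({self.q!r})"

    def to_json(self, **metadata) -> str:
        return json.dumps(
            {
                "states": [s.name for s in BystanderState],
                "actions": [a.name for a in AgentAction],
                "q": self.q.tolist(),
                "metadata": metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> Tuple["QTable", dict]:
        obj = json.loads(text)
        return cls(np.asarray(obj["q"])), obj.get("metadata", {})


class EligibilityTraces:
    """Per-(state, action) accumulating traces; nonnegative by construction."""

    __slots__ = ("e",)

    def __init__(self, e: Optional[np.ndarray] = None):
        if e is None:
            e = np.zeros((N_STATES, N_ACTIONS))
        e = np.asarray(e, dtype=float)
        if e.shape != (N_STATES, N_ACTIONS):
            raise ValueError(f"traces must be {N_STATES}x{N_ACTIONS}, got {e.shape}")
        if not np.all(np.isfinite(e)) or np.any(e < 0):
            raise ValueError("traces must be finite and >= 0")
        self.e = e

    def copy(self) -> "EligibilityTraces":
        return EligibilityTraces(self.e.copy())


@dataclass(frozen=True)
class Transition:
    """One logged step: state, action, reward, successor (None = terminal)."""

    s: BystanderState
    a: AgentAction
    r: float
    s_next: Optional[BystanderState]


def greedy_actions(q: QTable, s: BystanderState) -> np.ndarray:
    """Indices of all actions maximising q(s, .) (ties included)."""
    row = q.q[int(s)]
    return np.flatnonzero(row == row.max())


def select_action(
    q: QTable, s: BystanderState, params: RLParams, rng: np.random.Generator
) -> Tuple[AgentAction, bool]:
    """Epsilon-greedy choice.

    With probability ``epsilon`` the action is uniform over all three and the
    returned flag is True (this is what the study's `proprandom` counts);
    otherwise an argmax action is taken, ties broken uniformly, flag False.
    """
    if rng.random() < params.epsilon:
        return AgentAction(int(rng.integers(N_ACTIONS))), True
    best = greedy_actions(q, s)
    if len(best) == 1:
        return AgentAction(int(best[0])), False
    return AgentAction(int(rng.choice(best))), False


def q_lambda_update(
    q: QTable, e: EligibilityTraces, t: Transition, params: RLParams
) -> Tuple[QTable, EligibilityTraces]:
    """One Watkins' Q(lambda) backup for transition ``t``.

    delta = r + gamma * max_a' q(s_next, a') - q(s, a)   (no bootstrap when
    s_next is terminal); the trace of (s, a) is incremented by 1
    (accumulating traces), then every cell receives alpha * delta * e.
    Trace decay/cutting is a separate step (`post_choice_trace_step`)
    because it depends on whether the *next* chosen action is greedy.
    """
    qn, en = q.q.copy(), e.e.copy()
    si, ai = int(t.s), int(t.a)
    bootstrap = 0.0 if t.s_next is None else params.gamma * qn[int(t.s_next)].max()
    delta = t.r + bootstrap - qn[si, ai]
    en[si, ai] += 1.0
    qn += params.alpha * delta * en
    return QTable(qn), EligibilityTraces(en)


def post_choice_trace_step(
    e: EligibilityTraces, next_action_greedy: bool, params: RLParams
) -> EligibilityTraces:
    """Decay traces by gamma*lambda if the next action is greedy, else cut to 0.

    Greediness is judged against the current Q table regardless of whether
    the action came from the epsilon branch; a random draw that happens to
    coincide with the argmax does not cut the traces.
    """
    if next_action_greedy:
        return EligibilityTraces(e.e * (params.gamma * params.lam))
    return EligibilityTraces(np.zeros_like(e.e))


def average_q(tables: Sequence[QTable] | Iterable[QTable]) -> QTable:
    """Element-wise mean of Q tables; how one cohort's knowledge seeds the next."""
    tables = list(tables)
    if not tables:
        raise ValueError("cannot average an empty list of Q tables")
    return QTable(np.mean([t.q for t in tables], axis=0))
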