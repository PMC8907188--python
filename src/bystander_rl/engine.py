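"""Orchestration of sessions, groups, and the three-cohort adaptive study.

One *session* is a single participant's confrontation: 13 action slots in
which the agent observes the proxemic state, picks an action
(epsilon-greedy), the participant may intervene during the following 10 s
window, and the agent's Q table is updated with Watkins' Q(lambda).

The *study* runs three cohorts of 15 participants in sequence with the
exploration rate stepped down (epsilon = 1, 0.66, 0.33 for RLLevel None,
Medium, High) and the learned knowledge carried forward: each cohort starts
from the element-wise average of the previous cohort's final Q tables, the
first from all zeros.  The study output is the analysis-ready dataset: one
row per participant (resp, proprandom, RLLevel dummies) and one row per
trial (y and the one-hot action indicators).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agent import (
    EligibilityTraces,
    QTable,
    RLParams,
    Transition,
    average_q,
    greedy_actions,
    post_choice_trace_step,
    q_lambda_update,
    select_action,
)
from .participants import ParticipantModel, sample_population, sample_response, step_distance_state
from .scenario import (
    AgentAction,
    BystanderState,
    InterventionFlags,
    ScenarioConfig,
    UtteranceCursor,
    action_schedule,
    compute_reward,
    next_utterance,
)

#: Exploration rate by cohort label.
EPSILON_BY_LEVEL = {"None": 1.0, "Medium": 0.66, "High": 0.33}
LEVEL_ORDER = ("None", "Medium", "High")


@dataclass(frozen=True)
class TrialRecord:
    """One action slot's outcome."""

    participant_id: int
    slot: int
    time_s: float
    state: BystanderState
    action: AgentAction
    random_flag: bool
    utterance_index: Optional[int]
    verbal: bool
    physical: bool
    reward: float

    @property
    def y(self) -> int:
        return int(self.verbal or self.physical)


@dataclass
class SessionResult:
    """One participant's full episode plus the final learned Q table."""

    participant_id: int
    records: List[TrialRecord]
    q_final: QTable

    @property
    def resp(self) -> int:
        return sum(r.y for r in self.records)

    @property
    def proprandom(self) -> float:
        return sum(r.random_flag for r in self.records) / len(self.records)


@dataclass(frozen=True)
class GroupSpec:
    """A cohort: its RLLevel label, exploration rate, size and starting Q."""

    label: str
    epsilon: float
    n_participants: int = 15
    q_init: QTable = field(default_factory=QTable)

    def __post_init__(self) -> None:
        if self.label not in EPSILON_BY_LEVEL:
            raise ValueError(f"label must be one of {LEVEL_ORDER}, got {self.label!r}")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass
class StudyDataset:
    """Analysis-ready tables from one study run.

    ``participants``: id, resp, proprandom, RLLevel, M, H (one row each);
    ``trials``: id, y, vl, pl, bu (one row per action slot).
    """

    participants: pd.DataFrame
    trials: pd.DataFrame


def run_session(
    model: ParticipantModel,
    spec: GroupSpec,
    config: ScenarioConfig,
    rng: np.random.Generator,
    params: Optional[RLParams] = None,
    initial_state: BystanderState = BystanderState.Passive,
    participant_id: int = 0,
) -> SessionResult:
    """Simulate one participant's confrontation with the learning agent.

    Per slot: observe the proxemic state, choose an action, play the 10 s
    window (one proxemics step; an Intervention-state window forces the
    physical flag — staying within arm's reach counts as physical
    intervention automatically), score the reward, and apply the Q(lambda)
    backup.  Traces are cut or decayed according to whether the *next*
    chosen action is greedy; the final slot is terminal (no bootstrap).
    """
    params = params or RLParams(epsilon=spec.epsilon)
    params = RLParams(params.alpha, params.gamma, params.lam, spec.epsilon)
    q = spec.q_init.copy()
    e = EligibilityTraces()
    cursor = UtteranceCursor()
    times = action_schedule(config)
    state = initial_state
    records: List[TrialRecord] = []
    pending: Optional[Tuple[Transition, bool]] = None  # update deferred one slot

    for slot, t in enumerate(times, start=1):
        action, random_flag = select_action(q, state, params, rng)
        if pending is not None:
            trans, _ = pending
            chosen_greedy = int(action) in greedy_actions(q, state)
            q, e = q_lambda_update(q, e, trans, params)
            e = post_choice_trace_step(e, chosen_greedy, params)

        utt_index: Optional[int] = None
        if action == AgentAction.BystandersUtter:
            utt_index = cursor.next_index % 12
            _, cursor = next_utterance(cursor)

        flags = sample_response(model, action, rng)
        next_state = step_distance_state(model, state, flags.any, rng)
        # within arm's reach during the window counts as physical automatically
        if state == BystanderState.Intervention or next_state == BystanderState.Intervention:
            flags = InterventionFlags(verbal=flags.verbal, physical=True)
        reward = compute_reward(flags)

        records.append(
            TrialRecord(
                participant_id=participant_id,
                slot=slot,
                time_s=t,
                state=state,
                action=action,
                random_flag=random_flag,
                utterance_index=utt_index,
                verbal=flags.verbal,
                physical=flags.physical,
                reward=reward,
            )
        )
        is_last = slot == len(times)
        trans = Transition(state, action, reward, None if is_last else next_state)
        if is_last:
            q, e = q_lambda_update(q, e, trans, params)
        else:
            pending = (trans, random_flag)
        state = next_state

    return SessionResult(participant_id=participant_id, records=records, q_final=q)


def run_group(
    models: Sequence[ParticipantModel],
    spec: GroupSpec,
    config: ScenarioConfig,
    rng: np.random.Generator,
    params: Optional[RLParams] = None,
    first_participant_id: int = 1,
) -> Tuple[List[SessionResult], QTable]:
    """Run every participant of a cohort from the same initial Q table.

    Each session gets its own child generator spawned from ``rng`` so the
    cohort is reproducible as a whole.  Returns the session results and the
    element-wise mean of the final Q tables (the next cohort's knowledge).
    """
    if len(models) != spec.n_participants:
        raise ValueError(
            f"group expects {spec.n_participants} participants, got {len(models)}"
        )
    session_rngs = rng.spawn(len(models))
    results = [
        run_session(m, spec, config, srng, params,
                    participant_id=first_participant_id + i)
        for i, (m, srng) in enumerate(zip(models, session_rngs))
    ]
    return results, average_q([r.q_final for r in results])


def run_study(
    config: Optional[ScenarioConfig] = None,
    master_seed: int = 0,
    n_per_group: int = 15,
    sigma_u: float = 1.0,
    weights=None,
    params: Optional[RLParams] = None,
    population: Optional[Sequence[ParticipantModel]] = None,
) -> Tuple[StudyDataset, Dict[str, List[SessionResult]], Dict[str, QTable]]:
    """Run the full three-cohort adaptive study.

    Cohorts run in order None (epsilon=1, Q all zero), Medium (epsilon=0.66,
    Q seeded from cohort 1's average) and High (epsilon=0.33, seeded from
    cohort 2).  Returns the assembled dataset, per-group session results,
    and the per-group mean Q tables.
    """
    from .participants import DEFAULT_WEIGHTS

    config = config or ScenarioConfig()
    weights = DEFAULT_WEIGHTS if weights is None else weights
    rng = np.random.default_rng(master_seed)
    pop_rng, *group_rngs = rng.spawn(4)
    if population is None:
        population = sample_population(
            3 * n_per_group, sigma_u=sigma_u, weights=weights, rng=pop_rng
        )
    elif len(population) != 3 * n_per_group:
        raise ValueError(f"population must have {3 * n_per_group} participants")

    results: Dict[str, List[SessionResult]] = {}
    q_means: Dict[str, QTable] = {}
    q_init = QTable()
    offset = 0
    for level, grng in zip(LEVEL_ORDER, group_rngs):
        models = population[offset : offset + n_per_group]
        spec = GroupSpec(
            label=level,
            epsilon=EPSILON_BY_LEVEL[level],
            n_participants=n_per_group,
            q_init=q_init,
        )
        group_results, q_mean = run_group(
            models, spec, config, grng, params, first_participant_id=offset + 1
        )
        offset += n_per_group
        results[level] = group_results
        q_means[level] = q_mean
        q_init = q_mean

    return assemble_dataset(results), results, q_means


def assemble_dataset(results: Dict[str, List[SessionResult]]) -> StudyDataset:
    """Flatten per-group session results into the two analysis tables."""
    part_rows, trial_rows = [], []
    for level in LEVEL_ORDER:
        for sess in results.get(level, []):
            part_rows.append(
                {
                    "id": sess.participant_id,
                    "resp": sess.resp,
                    "proprandom": sess.proprandom,
                    "RLLevel": level,
                    "M": int(level == "Medium"),
                    "H": int(level == "High"),
                }
            )
            for rec in sess.records:
                trial_rows.append(
                    {
                        "id": sess.participant_id,
                        "y": rec.y,
                        "vl": int(rec.action == AgentAction.VictimLookAt),
                        "pl": int(rec.action == AgentAction.PerpLookAt),
                        "bu": int(rec.action == AgentAction.BystandersUtter),
                    }
                )
    return StudyDataset(pd.DataFrame(part_rows), pd.DataFrame(trial_rows))


# --------------------------------------------------------------------------
# event logs

EVENT_LOG_HEADER = [
    "participant_id",
    "group",
    "slot",
    "time_s",
    "state",
    "action",
    "random_flag",
    "utterance_index",
    "verbal",
    "physical",
    "reward",
    "y",
]


class EventLogError(ValueError):
    """Raised when an event-log file cannot be parsed."""


def write_event_log(path, records: Sequence[TrialRecord], group: str = "") -> None:
    """Write trial records as a CSV event log (booleans as 0/1)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_LOG_HEADER)
        for r in records:
            w.writerow(
                [
                    r.participant_id,
                    group,
                    r.slot,
                    r.time_s,
                    r.state.name,
                    r.action.name,
                    int(r.random_flag),
                    "" if r.utterance_index is None else r.utterance_index,
                    int(r.verbal),
                    int(r.physical),
                    r.reward,
                    r.y,
                ]
            )


def _parse_bool(text: str, line_no: int, col: str) -> bool:
    if text not in ("0", "1"):
        raise EventLogError(f"line {line_no}: {col} must be 0 or 1, got {text!r}")
    return text == "1"


def read_event_log(path) -> List[TrialRecord]:
    """Read an event-log CSV back into trial records (lossless round-trip)."""
    records: List[TrialRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return []
        if header != EVENT_LOG_HEADER:
            raise EventLogError(f"line 1: unexpected header {header}")
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(EVENT_LOG_HEADER):
                raise EventLogError(f"line {line_no}: expected {len(EVENT_LOG_HEADER)} fields")
            try:
                state = BystanderState[row[4]]
                action = AgentAction[row[5]]
            except KeyError as exc:
                raise EventLogError(f"line {line_no}: unknown enum name {exc}") from None
            try:
                rec = TrialRecord(
                    participant_id=int(row[0]),
                    slot=int(row[2]),
                    time_s=float(row[3]),
                    state=state,
                    action=action,
                    random_flag=_parse_bool(row[6], line_no, "random_flag"),
                    utterance_index=None if row[7] == "" else int(row[7]),
                    verbal=_parse_bool(row[8], line_no, "verbal"),
                    physical=_parse_bool(row[9], line_no, "physical"),
                    reward=float(row[10]),
                )
            except EventLogError:
                raise
            except ValueError as exc:
                raise EventLogError(f"line {line_no}: {exc}") from None
            if rec.y != int(row[11]):
                raise EventLogError(f"line {line_no}: y inconsistent with flags")
            records.append(rec)
    return records
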