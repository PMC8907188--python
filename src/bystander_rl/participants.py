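"""Synthetic participants for desk-scale runs of the adaptive study.

Real sessions put a human bystander in a staged virtual argument; here each
participant is a small stochastic model whose probability of intervening in
an action window follows the same Bernoulli-logistic structure the analysis
models assume:

    P(respond | action) = inv_logit(u + b_vl*[VL] + b_pl*[PL] + b_bu*[BU])

with a per-subject effect ``u ~ Normal(0, sigma_u)`` and action weights
``(b_vl, b_pl, b_bu)`` on the unit simplex.  The default weights
(0.59, 0.29, 0.12) rank the victim's gaze as the strongest cue, the
perpetrator's gaze next, and a bystander's utterance weakest, so recovering
this ordering from simulated sessions is the natural end-to-end smoke test.

Movement is not part of the analysis models; a simple sticky Markov chain
over the three proxemic bands stands in for it, with an "approach bonus"
that shifts probability mass one band nearer after the participant responds
(people who engage tend to close distance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bayes import inv_logit
from .scenario import N_STATES, AgentAction, BystanderState, InterventionFlags

#: Action-weight defaults: victim gaze strongest, bystander utterance weakest.
DEFAULT_WEIGHTS = (0.59, 0.29, 0.12)


def default_move_matrix() -> np.ndarray:
    """Sticky proxemics chain: stay w.p. 0.8, 0.2 split across neighbours."""
    return np.array(
        [
            [0.8, 0.2, 0.0],
            [0.1, 0.8, 0.1],
            [0.0, 0.2, 0.8],
        ]
    )


@dataclass
class ParticipantModel:
    """One synthetic participant.

    u: subject effect on the logit scale; weights: simplex action weights;
    p_verbal_given_response / p_physical_given_response: how a response
    splits into intervention types (redrawn until at least one is set);
    move: row-stochastic transition matrix over the proxemic states, rows
    ordered Intervention, Active, Passive; approach_bonus: fraction of each
    destination's probability shifted one band nearer after a response.
    """

    u: float = 0.0
    weights: Sequence[float] = DEFAULT_WEIGHTS
    p_verbal_given_response: float = 0.8
    p_physical_given_response: float = 0.4
    move: np.ndarray = field(default_factory=default_move_matrix)
    approach_bonus: float = 0.3

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must be 3 nonnegative values summing to 1, got {w}")
        self.weights = w
        for name in ("p_verbal_given_response", "p_physical_given_response"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_verbal_given_response == 0 and self.p_physical_given_response == 0:
            raise ValueError("at least one intervention-type probability must be > 0")
        m = np.asarray(self.move, dtype=float)
        if m.shape != (N_STATES, N_STATES) or np.any(m < 0):
            raise ValueError("move must be a nonnegative 3x3 matrix")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("rows of move must sum to 1")
        self.move = m
        if not (0.0 <= self.approach_bonus <= 1.0):
            raise ValueError("approach_bonus must be in [0, 1]")

    def response_probability(self, a: AgentAction) -> float:
        return float(inv_logit(self.u + self.weights[int(a)]))


def sample_population(
    n: int,
    sigma_u: float = 1.0,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    rng: Optional[np.random.Generator] = None,
    **kwargs,
) -> List[ParticipantModel]:
    """Draw ``n`` participants with subject effects u ~ Normal(0, sigma_u)."""
    rng = np.random.default_rng() if rng is None else rng
    us = rng.normal(0.0, sigma_u, size=n)
    return [ParticipantModel(u=float(u), weights=weights, **kwargs) for u in us]


def sample_response(
    model: ParticipantModel, a: AgentAction, rng: np.random.Generator
) -> InterventionFlags:
    """Simulate one action window: respond or not, and how.

    A response occurs with the model's logistic probability for the action;
    if it does, verbal and physical indicators are drawn independently and
    redrawn until at least one is set (a response must be visible somehow).
    """
    if rng.random() >= model.response_probability(a):
        return InterventionFlags(verbal=False, physical=False)
    while True:
        verbal = rng.random() < model.p_verbal_given_response
        physical = rng.random() < model.p_physical_given_response
        if verbal or physical:
            return InterventionFlags(verbal=verbal, physical=physical)


def _shift_nearer(p: np.ndarray, bonus: float) -> np.ndarray:
    """Move ``bonus`` of each band's probability one band nearer (band 0 stays)."""
    out = p.copy()
    for j in range(1, len(p)):
        moved = bonus * p[j]
        out[j] -= moved
        out[j - 1] += moved
    return out


def step_distance_state(
    model: ParticipantModel,
    s: BystanderState,
    responded: bool,
    rng: np.random.Generator,
) -> BystanderState:
    """Advance the proxemics chain one window.

    The next state is drawn from row ``s`` of the transition matrix; if the
    participant responded during the window, the approach bonus first shifts
    probability mass one band nearer.
    """
    p = model.move[int(s)].copy()
    if responded:
        p = _shift_nearer(p, model.approach_bonus)
    return BystanderState(int(rng.choice(N_STATES, p=p)))


def population_to_json(models: Sequence[ParticipantModel]) -> str:
    """Serialise a participant population (all model fields) as JSON."""
    return json.dumps(
        [
            {
                "u": m.u,
                "weights": list(map(float, m.weights)),
                "p_verbal_given_response": m.p_verbal_given_response,
                "p_physical_given_response": m.p_physical_given_response,
                "move": np.asarray(m.move).tolist(),
                "approach_bonus": m.approach_bonus,
            }
            for m in models
        ],
        indent=2,
    )


def population_from_json(text: str) -> List[ParticipantModel]:
    """Inverse of `population_to_json`."""
    return [
        ParticipantModel(
            u=obj["u"],
            weights=obj["weights"],
            p_verbal_given_response=obj["p_verbal_given_response"],
            p_physical_given_response=obj["p_physical_given_response"],
            move=np.asarray(obj["move"]),
            approach_bonus=obj["approach_bonus"],
        )
        for obj in json.loads(text)
    ]


ActionAssignment = Union[
    None, AgentAction, Sequence[AgentAction], Callable[[int, int], AgentAction]
]


def generate_action_effect_dataset(
    n_participants: int = 45,
    N: int = 13,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    sigma_u: float = 1.0,
    action_assignment: ActionAssignment = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-trial table (id, y, vl, pl, bu) from the Bernoulli-logistic generator.

    ``action_assignment`` chooses the action of each trial: None for uniform
    random, a fixed AgentAction, or a callable (participant_idx, trial_idx)
    -> AgentAction.  Rows are one-hot in (vl, pl, bu) and ids come in blocks
    of ``N``, matching the layout the action-effect model expects.
    """
    rng = np.random.default_rng() if rng is None else rng
    w = np.asarray(weights, dtype=float)
    us = rng.normal(0.0, sigma_u, size=n_participants)
    rows = []
    for pid in range(n_participants):
        for t in range(N):
            if action_assignment is None:
                a = AgentAction(int(rng.integers(3)))
            elif isinstance(action_assignment, AgentAction):
                a = action_assignment
            elif callable(action_assignment):
                a = action_assignment(pid, t)
            else:
                a = action_assignment[pid * N + t]
            p = inv_logit(us[pid] + w[int(a)])
            y = int(rng.random() < p)
            rows.append(
                {
                    "id": pid + 1,
                    "y": y,
                    "vl": int(a == AgentAction.VictimLookAt),
                    "pl": int(a == AgentAction.PerpLookAt),
                    "bu": int(a == AgentAction.BystandersUtter),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BetaBinomGenSpec:
    """Generator settings for overdispersed per-participant response counts.

    Each participant's response probability is Beta-distributed with mean
    inv_logit(beta0 + beta1 * proprandom) and scale phi (shape parameters
    p*phi and (1-p)*phi); the response count is Binomial(N, p).
    """

    n_participants: int = 45
    N: int = 13
    beta0: float = 0.0
    beta1: float = 0.0
    phi: float = 1.0
    proprandom_values: Sequence[float] = ()

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        x = np.asarray(self.proprandom_values, dtype=float)
        if len(x) != self.n_participants:
            raise ValueError(
                f"need {self.n_participants} proprandom values, got {len(x)}"
            )
        if np.any((x < 0) | (x > 1)):
            raise ValueError("proprandom values must lie in [0, 1]")


def generate_beta_binomial_dataset(
    spec: BetaBinomGenSpec, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Per-participant table (id, proprandom, resp) under the Beta-Binomial model."""
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(spec.proprandom_values, dtype=float)
    mean_p = inv_logit(spec.beta0 + spec.beta1 * x)
    p = rng.beta(mean_p * spec.phi, (1.0 - mean_p) * spec.phi)
    resp = rng.binomial(spec.N, p)
    return pd.DataFrame(
        {
            "id": np.arange(1, spec.n_participants + 1),
            "proprandom": x,
            "resp": resp,
        }
    )


def generate_rllevel_dataset(
    gamma0: float,
    gamma1: float,
    gamma2: float,
    phi: float,
    n_per_group: int = 15,
    N: int = 13,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Group-design analogue of `generate_beta_binomial_dataset`.

    Three equal groups (None / Medium / High) with Beta-Binomial counts whose
    mean logits are gamma0, gamma0+gamma1 and gamma0+gamma2; returns columns
    (id, RLLevel, M, H, resp).
    """
    rng = np.random.default_rng() if rng is None else rng
    if phi <= 0:
        raise ValueError(f"phi must be > 0, got {phi}")
    levels = ["None"] * n_per_group + ["Medium"] * n_per_group + ["High"] * n_per_group
    M = np.array([1 if g == "Medium" else 0 for g in levels])
    H = np.array([1 if g == "High" else 0 for g in levels])
    mean_p = inv_logit(gamma0 + gamma1 * M + gamma2 * H)
    p = rng.beta(mean_p * phi, (1.0 - mean_p) * phi)
    resp = rng.binomial(N, p)
    return pd.DataFrame(
        {
            "id": np.arange(1, 3 * n_per_group + 1),
            "RLLevel": levels,
            "M": M,
            "H": H,
            "resp": resp,
        }
    )
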