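"""Two-state, two-action tipping-element Markov decision process.

The environment is either *prosperous* (the only state that yields reward)
or *degraded*.  At each yearly time step the agent exerts a *high* or *low*
pressure.  High pressure at the prosperous state pays ``r_h`` but risks a
collapse with probability ``delta``; low pressure pays the smaller ``r_l``
and is riskless.  From the degraded state only low pressure opens a recovery
channel with probability ``rho``; no reward is ever received there.

Values are normalized discounted sums, ``v = (1-gamma) * E[sum gamma^t r_t]``,
so they live on the reward scale and are directly comparable to the
acceptability threshold ``r_min``.  The closed forms for the risky and
cautious policies, the generic Bellman linear solve, and the undiscounted
(``gamma = 1``) stationary-distribution evaluation are all provided and
cross-validated in the test suite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "State",
    "Action",
    "Policy",
    "RISKY",
    "CAUTIOUS",
    "TRAP_HH",
    "TRAP_LH",
    "POLICIES",
    "TippingModel",
    "TransitionModel",
    "StateValues",
    "MarkovChainSummary",
    "build_transition_model",
    "build_effective_chain",
    "evaluate_policy_linear",
    "value_risky",
    "value_cautious",
    "value_gamma1",
    "state_values",
]


class State(enum.Enum):
    """System state of the tipping element."""

    PROSPEROUS = "prosperous"
    DEGRADED = "degraded"


class Action(enum.Enum):
    """Pressure level the agent exerts on the environment."""

    HIGH = "high"
    LOW = "low"


#: Canonical state ordering used for all vectors/matrices: (prosperous, degraded).
STATE_ORDER: tuple[State, State] = (State.PROSPEROUS, State.DEGRADED)


@dataclass(frozen=True)
class Policy:
    """Deterministic state -> action map.

    Only four instances exist for the two-state, two-action process; the
    named presets :data:`RISKY`, :data:`CAUTIOUS`, :data:`TRAP_HH` and
    :data:`TRAP_LH` cover them all.
    """

    name: str
    action_prosperous: Action
    action_degraded: Action

    def __call__(self, state: State) -> Action:
        if state is State.PROSPEROUS:
            return self.action_prosperous
        return self.action_degraded


RISKY = Policy("risky", Action.HIGH, Action.LOW)
CAUTIOUS = Policy("cautious", Action.LOW, Action.LOW)
#: High pressure everywhere: once degraded, stays degraded forever.
TRAP_HH = Policy("trap_hh", Action.HIGH, Action.HIGH)
#: Low pressure at prosperous, high at degraded: degraded is absorbing.
TRAP_LH = Policy("trap_lh", Action.LOW, Action.HIGH)

POLICIES: dict[str, Policy] = {
    p.name: p for p in (RISKY, CAUTIOUS, TRAP_HH, TRAP_LH)
}


@dataclass(frozen=True)
class TippingModel:
    """Parameter set of the tipping-element MDP.

    Parameters
    ----------
    delta : float
        Collapse probability per time step under high pressure, in [0, 1].
    rho : float
        Recovery probability per time step under low pressure, in [0, 1].
    gamma : float
        Discount factor (farsightedness), in [0, 1]; ``gamma = 1`` is the
        undiscounted long-run-average limit.
    r_h : float
        Reward for surviving a high-pressure step at the prosperous state.
    r_l : float
        Reward for a low-pressure step at the prosperous state.
    r_min : float
        Normative minimum acceptable value; a state is acceptable under a
        policy when its value meets this threshold.

    All rewards are in arbitrary units; policy classification depends on
    them only through the ratios ``r_l / r_h`` and ``r_min / r_h``.  The
    defaults fix ``r_h = 1`` so that ``r_l`` and ``r_min`` are those ratios.
    """

    delta: float
    rho: float
    gamma: float
    r_h: float = 1.0
    r_l: float = 0.5
    r_min: float = 0.3

    def __post_init__(self) -> None:
        for name in ("delta", "rho", "gamma"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("r_h", "r_l", "r_min"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")

    def rescaled(self, c: float) -> "TippingModel":
        """Return a copy with all rewards multiplied by ``c > 0``."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, r_h=c * self.r_h, r_l=c * self.r_l, r_min=c * self.r_min)


@dataclass(frozen=True)
class TransitionModel:
    """Probability and reward tables indexed as ``[state, action, next_state]``.

    Axis order follows :data:`STATE_ORDER` for states and (high, low) for
    actions.  Probability rows sum to one for every (state, action) pair.
    """

    probs: np.ndarray
    rewards: np.ndarray

    def prob(self, s: State, a: Action, s2: State) -> float:
        return float(self.probs[_sidx(s), _aidx(a), _sidx(s2)])

    def reward(self, s: State, a: Action, s2: State) -> float:
        return float(self.rewards[_sidx(s), _aidx(a), _sidx(s2)])


@dataclass(frozen=True)
class StateValues:
    """Pair of state values ``(v_p, v_d)`` for a policy, on the reward scale.

    ``degenerate`` is set when a measure-zero parameter combination made a
    closed-form denominator vanish and the documented continuity limit was
    returned instead of a division result.
    """

    v_p: float
    v_d: float
    degenerate: bool = False

    def value(self, state: State) -> float:
        return self.v_p if state is State.PROSPEROUS else self.v_d

    def as_array(self) -> np.ndarray:
        return np.array([self.v_p, self.v_d])


@dataclass(frozen=True)
class MarkovChainSummary:
    """Effective Markov chain induced by a policy.

    ``P`` is row-stochastic with rows indexed by the *from* state in
    :data:`STATE_ORDER` order (``P[i, j] = p(state_j | state_i)``); ``r_vec``
    holds the expected one-step reward per state and ``sigma`` the stationary
    distribution.  When the chain is reducible the stationary distribution of
    the recurrent class reachable from the prosperous state is reported and
    ``reducible`` is flagged.
    """

    P: np.ndarray
    r_vec: np.ndarray
    sigma: np.ndarray
    reducible: bool = False


def _sidx(s: State) -> int:
    return STATE_ORDER.index(s)


def _aidx(a: Action) -> int:
    return 0 if a is Action.HIGH else 1


def build_transition_model(model: TippingModel) -> TransitionModel:
    """Assemble the fixed transition/reward structure of the tipping element."""
    d, r = model.delta, model.rho
    probs = np.zeros((2, 2, 2))
    rewards = np.zeros((2, 2, 2))
    # prosperous, high: survive w.p. 1-delta (reward r_h), collapse w.p. delta
    probs[0, 0] = (1.0 - d, d)
    rewards[0, 0, 0] = model.r_h
    # prosperous, low: stay w.p. 1 (reward r_l)
    probs[0, 1] = (1.0, 0.0)
    rewards[0, 1, 0] = model.r_l
    # degraded, high: stuck forever, no reward
    probs[1, 0] = (0.0, 1.0)
    # degraded, low: recover w.p. rho, no reward either way
    probs[1, 1] = (r, 1.0 - r)
    return TransitionModel(probs=probs, rewards=rewards)


def _effective_P_r(policy: Policy, model: TippingModel) -> tuple[np.ndarray, np.ndarray]:
    tm = build_transition_model(model)
    P = np.empty((2, 2))
    r_vec = np.empty(2)
    for i, s in enumerate(STATE_ORDER):
        a = _aidx(policy(s))
        P[i] = tm.probs[i, a]
        r_vec[i] = tm.probs[i, a] @ tm.rewards[i, a]
    return P, r_vec


def build_effective_chain(policy: Policy, model: TippingModel) -> MarkovChainSummary:
    """Markov chain obtained by substituting ``a = policy(s)`` into the MDP.

    The stationary distribution is the eigenvector of ``P`` with eigenvalue
    one, normalized to sum to one.  For a reducible chain (one of the
    off-diagonal transition probabilities is zero) it is taken on the
    recurrent class reachable from the prosperous state.
    """
    P, r_vec = _effective_P_r(policy, model)
    a = P[0, 1]  # prosperous -> degraded
    b = P[1, 0]  # degraded -> prosperous
    if a > 0.0 and b > 0.0:
        sigma = np.array([b, a]) / (a + b)
        return MarkovChainSummary(P=P, r_vec=r_vec, sigma=sigma)
    if a == 0.0:
        # prosperous is closed; it is the class reached from a prosperous start
        sigma = np.array([1.0, 0.0])
    else:
        # degraded is the only closed class and is reachable from prosperous
        sigma = np.array([0.0, 1.0])
    return MarkovChainSummary(P=P, r_vec=r_vec, sigma=sigma, reducible=True)


def evaluate_policy_linear(policy: Policy, model: TippingModel) -> StateValues:
    """Exact policy evaluation by solving the 2x2 Bellman system.

    Solves ``(I - gamma P) v = (1 - gamma) r`` for any of the four
    deterministic policies.  Requires ``gamma < 1``; use
    :func:`value_gamma1` for the undiscounted limit.
    """
    if model.gamma >= 1.0:
        raise ValueError("evaluate_policy_linear requires gamma < 1; "
                         "use value_gamma1 for gamma = 1")
    P, r_vec = _effective_P_r(policy, model)
    g = model.gamma
    v = np.linalg.solve(np.eye(2) - g * P, (1.0 - g) * r_vec)
    return StateValues(v_p=float(v[0]), v_d=float(v[1]))


def value_risky(model: TippingModel) -> StateValues:
    """Closed-form values of the risky policy (high at prosperous, low at degraded).

    v_p = r_h (1-delta)(1-(1-rho) gamma) / (1-(1-delta-rho) gamma)
    v_d = r_h (1-delta) rho gamma        / (1-(1-delta-rho) gamma)

    Finite for all gamma <= 1 except the single point gamma = 1 with
    delta = rho = 0, where the delta -> 0 limit (v_p = r_h, v_d = 0) is
    returned with the ``degenerate`` flag set.
    """
    d, r, g = model.delta, model.rho, model.gamma
    denom = 1.0 - (1.0 - d - r) * g
    if denom == 0.0:
        return StateValues(v_p=model.r_h, v_d=0.0, degenerate=True)
    v_p = model.r_h * (1.0 - d) * (1.0 - (1.0 - r) * g) / denom
    v_d = model.r_h * (1.0 - d) * r * g / denom
    return StateValues(v_p=v_p, v_d=v_d)


def value_cautious(model: TippingModel) -> StateValues:
    """Closed-form values of the cautious policy (low pressure in both states).

    v_p = r_l;  v_d = rho gamma r_l / (1-(1-rho) gamma)

    At gamma = 1 with rho = 0 the denominator vanishes; the degraded state
    is then absorbing with zero reward, so the gamma -> 1 limit v_d = 0 is
    returned with the ``degenerate`` flag set.
    """
    r, g = model.rho, model.gamma
    denom = 1.0 - (1.0 - r) * g
    if denom == 0.0:
        return StateValues(v_p=model.r_l, v_d=0.0, degenerate=True)
    return StateValues(v_p=model.r_l, v_d=model.rho * g * model.r_l / denom)


def value_gamma1(policy: Policy, model: TippingModel) -> StateValues:
    """Undiscounted value ``v = sigma . r`` from the stationary distribution.

    For ``gamma = 1`` the normalized value is the long-run average reward,
    which is independent of the initial state; the same scalar is assigned
    to both states.  For reducible chains the stationary distribution of
    the recurrent class reachable from the prosperous state is used.
    """
    chain = build_effective_chain(policy, model)
    v = float(chain.sigma @ chain.r_vec)
    return StateValues(v_p=v, v_d=v, degenerate=chain.reducible)


def state_values(policy: Policy, model: TippingModel) -> StateValues:
    """Values of any deterministic policy, dispatching on policy and gamma.

    The risky and cautious policies use their closed forms (valid for all
    ``gamma <= 1``); the two trap policies use the Bellman linear solve for
    ``gamma < 1`` and the stationary-distribution evaluation at ``gamma = 1``.
    """
    if policy.name == RISKY.name:
        return value_risky(model)
    if policy.name == CAUTIOUS.name:
        return value_cautious(model)
    if model.gamma >= 1.0:
        return value_gamma1(policy, model)
    return evaluate_policy_linear(policy, model)
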