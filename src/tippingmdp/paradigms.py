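"""Classification of policies under three governance paradigms.

A (policy, model) pair is classified as

* **optimal** — its value is at least that of every other deterministic
  policy in every state (economic welfare sense);
* **sustainable** — every state the agent eventually visits under the
  policy is acceptable, i.e. has value >= ``r_min``;
* **safe** — the agent never leaves the safe operating space, which is
  identified with the prosperous state alone (no risk tolerance).

All comparisons are non-strict, so parameter points lying exactly on a
boundary hypersurface classify as optimal/acceptable for both sides.
The analytic boundary surfaces separating the regimes are exposed as
signed residuals (positive on the side where the predicate holds).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mdp import (
    CAUTIOUS,
    RISKY,
    Policy,
    State,
    StateValues,
    TippingModel,
    build_effective_chain,
    state_values,
)

__all__ = [
    "ParadigmLabel",
    "ALL_LABELS",
    "BoundaryKind",
    "is_optimal",
    "is_acceptable",
    "is_sustainable",
    "is_safe",
    "safe_by_reachability",
    "sustainable_by_reachability",
    "classify",
    "classify_many",
    "boundary_residual",
    "find_boundary",
    "sweep_classification",
    "PARAM_NAMES",
]

#: The five ratio-parameters a sweep may vary (r_h is the reward unit).
PARAM_NAMES = ("delta", "rho", "gamma", "r_l", "r_min")


@dataclass(frozen=True, order=True)
class ParadigmLabel:
    """Boolean triple (optimal, sustainable, safe); one of eight categories."""

    optimal: bool
    sustainable: bool
    safe: bool

    @property
    def code(self) -> str:
        """Stable 3-letter code: 'O'/'o', 'S'/'s', 'F'/'f' (upper = true)."""
        return ("O" if self.optimal else "o") + \
               ("S" if self.sustainable else "s") + \
               ("F" if self.safe else "f")

    @classmethod
    def from_code(cls, code: str) -> "ParadigmLabel":
        if len(code) != 3 or code[0] not in "Oo" or code[1] not in "Ss" \
                or code[2] not in "Ff":
            raise ValueError(f"not a paradigm label code: {code!r}")
        return cls(code[0] == "O", code[1] == "S", code[2] == "F")

    @property
    def index(self) -> int:
        """Dense index 0..7 (optimal*4 + sustainable*2 + safe)."""
        return int(self.optimal) * 4 + int(self.sustainable) * 2 + int(self.safe)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


#: All eight labels in dense-index order.
ALL_LABELS: tuple[ParadigmLabel, ...] = tuple(
    ParadigmLabel(bool(i & 4), bool(i & 2), bool(i & 1)) for i in range(8)
)


class BoundaryKind(enum.Enum):
    """The five analytic hypersurfaces separating classification regions."""

    OPTIMALITY = "optimality"
    RISKY_ACCEPTABLE_P = "risky_acceptable_p"
    RISKY_ACCEPTABLE_D = "risky_acceptable_d"
    CAUTIOUS_ACCEPTABLE_P = "cautious_acceptable_p"
    CAUTIOUS_ACCEPTABLE_D = "cautious_acceptable_d"


def _require_main_policy(policy: Policy) -> None:
    if policy.name not in (RISKY.name, CAUTIOUS.name):
        raise ValueError(
            "paradigm classification is defined for the risky and cautious "
            f"policies; got {policy.name!r} (trap policies are dominated)"
        )


def is_optimal(policy: Policy, model: TippingModel) -> bool:
    """Whether the policy's value is >= every other policy's in every state.

    The two trap policies are statewise dominated (tested property), so the
    verdict reduces to comparing the risky and cautious values; that
    comparison is independent of the state, so the prosperous state decides.
    """
    _require_main_policy(policy)
    vr = state_values(RISKY, model)
    vc = state_values(CAUTIOUS, model)
    if policy.name == RISKY.name:
        return vr.v_p >= vc.v_p
    return vc.v_p >= vr.v_p


def is_acceptable(policy: Policy, model: TippingModel, state: State) -> bool:
    """Whether the state's value under the policy meets the threshold r_min."""
    return state_values(policy, model).value(state) >= model.r_min


def is_sustainable(policy: Policy, model: TippingModel) -> bool:
    """Whether every state the agent eventually visits is acceptable.

    The risky policy switches recurrently between both states, so both must
    be acceptable; the cautious policy eventually settles at the prosperous
    state, so only that state matters (equivalently ``r_l >= r_min``).
    """
    _require_main_policy(policy)
    if policy.name == RISKY.name:
        return (is_acceptable(policy, model, State.PROSPEROUS)
                and is_acceptable(policy, model, State.DEGRADED))
    return is_acceptable(policy, model, State.PROSPEROUS)


def is_safe(policy: Policy, model: TippingModel) -> bool:
    """Whether the agent never leaves the safe operating space {prosperous}.

    By convention the cautious policy is safe and the risky policy is unsafe
    for *all* parameter combinations, including the measure-zero boundary
    ``delta = 0`` where the risky policy happens never to collapse; see
    :func:`safe_by_reachability` for the reachability-based cross-check that
    exposes this convention.
    """
    _require_main_policy(policy)
    return policy.name == CAUTIOUS.name


def safe_by_reachability(policy: Policy, model: TippingModel) -> bool:
    """Reachability-based safety: recurrent class from a prosperous start
    is contained in the safe operating space {prosperous}.

    Agrees with :func:`is_safe` whenever ``delta > 0``; at ``delta = 0`` it
    declares the risky policy safe, whereas the blanket convention does not.
    """
    chain = build_effective_chain(policy, model)
    return float(chain.sigma[1]) == 0.0


def sustainable_by_reachability(policy: Policy, model: TippingModel) -> bool:
    """Sustainability via the states actually reachable from a prosperous start.

    Cross-check for :func:`is_sustainable`; agrees whenever ``delta > 0``
    (risky) since both states are then visited.
    """
    v = state_values(policy, model)
    P = build_effective_chain(policy, model).P
    ok = v.v_p >= model.r_min
    if P[0, 1] > 0.0:  # degraded reachable from prosperous
        ok = ok and v.v_d >= model.r_min
    return ok


def classify(policy: Policy, model: TippingModel) -> ParadigmLabel:
    """Full paradigm label (optimal, sustainable, safe) of a policy."""
    return ParadigmLabel(
        optimal=is_optimal(policy, model),
        sustainable=is_sustainable(policy, model),
        safe=is_safe(policy, model),
    )


def boundary_residual(kind: BoundaryKind, model: TippingModel) -> float:
    """Signed residual (LHS - RHS) of a classification hypersurface.

    Positive exactly where the corresponding predicate holds (risky optimal,
    or the given state acceptable under the given policy), zero on the
    surface.  The residuals are polynomial in the parameters — they are the
    value comparisons multiplied through by the positive denominators — so
    they are well defined even at the degenerate denominator points.
    """
    d, r, g = model.delta, model.rho, model.gamma
    rh, rl, rmin = model.r_h, model.r_l, model.r_min
    if kind is BoundaryKind.OPTIMALITY:
        return rh * (1 - d) * (1 - g * (1 - r)) - rl * (1 - g * (1 - d - r))
    if kind is BoundaryKind.RISKY_ACCEPTABLE_P:
        return rh * (1 - d) * (1 - g * (1 - r)) - rmin * (1 - g * (1 - d - r))
    if kind is BoundaryKind.RISKY_ACCEPTABLE_D:
        return rh * (1 - d) * r * g - rmin * (1 - g * (1 - d - r))
    if kind is BoundaryKind.CAUTIOUS_ACCEPTABLE_P:
        return rl - rmin
    if kind is BoundaryKind.CAUTIOUS_ACCEPTABLE_D:
        return rl * r * g - rmin * (1 - g * (1 - r))
    raise ValueError(f"unknown boundary kind: {kind!r}")


def find_boundary(kind: BoundaryKind, model: TippingModel, param: str,
                  lo: float = 0.0, hi: float = 1.0, tol: float = 1e-12) -> float:
    """Locate the boundary crossing along one parameter by bisection.

    The residual must change sign between ``lo`` and ``hi`` with the other
    parameters held at the values in ``model``.  Residuals are continuous
    and monotone in each single parameter on the relevant ranges, so plain
    bisection to ``tol`` suffices.
    """
    if param not in PARAM_NAMES:
        raise ValueError(f"param must be one of {PARAM_NAMES}, got {param!r}")

    def resid(x: float) -> float:
        return boundary_residual(kind, _with_param(model, param, x))

    f_lo, f_hi = resid(lo), resid(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ValueError(f"residual does not change sign on [{lo}, {hi}]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = resid(mid)
        if f_mid == 0.0:
            return mid
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def _with_param(model: TippingModel, name: str, value: float) -> TippingModel:
    from dataclasses import replace
    return replace(model, **{name: value})


def classify_many(delta, rho, gamma, r_l, r_min, r_h=1.0):
    """Vectorized classification of both policies on parameter arrays.

    All inputs broadcast against each other.  Returns a dict
    ``{"risky": (optimal, sustainable, safe), "cautious": (...)}`` of boolean
    arrays.  Degenerate denominator points (``gamma = 1`` with vanishing
    transition probabilities) are resolved by the same continuity limits as
    the scalar closed forms, never dropped.
    """
    delta, rho, gamma, r_l, r_min, r_h = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (delta, rho, gamma, r_l, r_min, r_h))
    )

    denom_r = 1.0 - (1.0 - delta - rho) * gamma
    safe_r = np.where(denom_r > 0.0, denom_r, 1.0)
    v_r_p = np.where(denom_r > 0.0,
                     r_h * (1.0 - delta) * (1.0 - (1.0 - rho) * gamma) / safe_r,
                     r_h)  # gamma=1, delta=rho=0: never collapses
    v_r_d = np.where(denom_r > 0.0,
                     r_h * (1.0 - delta) * rho * gamma / safe_r,
                     0.0)

    denom_c = 1.0 - (1.0 - rho) * gamma
    safe_c = np.where(denom_c > 0.0, denom_c, 1.0)
    v_c_p = r_l
    v_c_d = np.where(denom_c > 0.0, rho * gamma * r_l / safe_c,
                     0.0)  # gamma=1, rho=0: degraded absorbing, no reward

    opt_r = v_r_p >= v_c_p
    opt_c = v_c_p >= v_r_p
    sus_r = (v_r_p >= r_min) & (v_r_d >= r_min)
    sus_c = v_c_p >= r_min

    false = np.zeros_like(opt_r, dtype=bool)
    true = np.ones_like(opt_r, dtype=bool)
    return {
        "risky": (opt_r, sus_r, false),
        "cautious": (opt_c, sus_c, true),
    }


def sweep_classification(policies, axis1: str, axis1_values, axis2: str,
                         axis2_values, fixed: dict | None = None,
                         r_h: float = 1.0) -> pd.DataFrame:
    """Classify policies on a 2-D grid over two ratio-parameters.

    Parameters
    ----------
    policies : iterable of Policy
        Typically ``(RISKY, CAUTIOUS)``.
    axis1, axis2 : str
        Names among ``delta, rho, gamma, r_l, r_min`` (rewards as ratios
        of ``r_h``).
    axis1_values, axis2_values : array-like
        Grid values, each within [0, 1].
    fixed : dict
        Values for the remaining parameters.

    Returns a long-format DataFrame with columns
    (axis1_name, axis1, axis2_name, axis2, policy, optimal, sustainable, safe),
    one row per (grid point, policy) — the data behind the region plots of
    policy classification in the (axis1, axis2) plane.
    """
    fixed = dict(fixed or {})
    if axis1 not in PARAM_NAMES or axis2 not in PARAM_NAMES or axis1 == axis2:
        raise ValueError(f"axes must be two distinct names among {PARAM_NAMES}")
    a1 = np.asarray(axis1_values, dtype=float)
    a2 = np.asarray(axis2_values, dtype=float)
    for name, arr in ((axis1, a1), (axis2, a2)):
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError(f"{name} grid must be a non-empty 1-D array")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(f"{name} grid extends outside [0, 1]")
    missing = set(PARAM_NAMES) - {axis1, axis2} - set(fixed)
    if missing:
        raise ValueError(f"missing fixed values for {sorted(missing)}")

    g1, g2 = np.meshgrid(a1, a2, indexing="ij")
    params = {axis1: g1.ravel(), axis2: g2.ravel()}
    for name in PARAM_NAMES:
        if name not in params:
            params[name] = np.full(g1.size, float(fixed[name]))
    labels = classify_many(params["delta"], params["rho"], params["gamma"],
                           params["r_l"], params["r_min"], r_h=r_h)

    frames = []
    for policy in policies:
        _require_main_policy(policy)
        opt, sus, safe = labels[policy.name]
        frames.append(pd.DataFrame({
            "axis1_name": axis1, "axis1": g1.ravel(),
            "axis2_name": axis2, "axis2": g2.ravel(),
            "policy": policy.name,
            "optimal": opt, "sustainable": sus, "safe": safe,
        }))
    return pd.concat(frames, ignore_index=True)
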