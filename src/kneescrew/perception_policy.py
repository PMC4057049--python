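"""Perception–action control as dynamic programming over screw states.

The control view of stance: at each stage the controller perceives a
screw state ``p`` (an instantaneous axis) and chooses an action screw
``q``; the stage cost is the virtual coefficient magnitude ``|vc(p, q)|``
— the energy a unit wrench on ``q`` expends on a unit twist about ``p`` —
so the optimal policy is *reciprocity-seeking*: it steers toward screws
that exchange no work with the perceived axis.  With the Bellman
recursion

    f(p) = min_q { R(p, q) + γ f(T(p, q)) }

over a finite, deterministic decision process (absorbing terminal states
or discount γ < 1), value iteration converges to the unique fixed point
and the greedy policy with respect to it is optimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .screw_core import Screw, ScrewError, virtual_coefficient

__all__ = [
    "ScrewDecisionProcess",
    "ConvergenceError",
    "value_iteration",
    "stance_policy",
    "default_stage_cost",
]


class ConvergenceError(RuntimeError):
    """Value iteration failed to reach tolerance within the sweep budget."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"value iteration did not converge in {max_iter} sweeps "
            f"(last sup-norm change {residual:.3g})")


def default_stage_cost(p: Screw, q: Screw) -> float:
    """|virtual coefficient| — zero exactly for reciprocal screw pairs."""
    return abs(virtual_coefficient(p, q))


@dataclass
class ScrewDecisionProcess:
    """Finite deterministic decision process over screw states.

    ``states`` are screws; ``actions[i]`` the action screws available in
    state i; ``transition[i][a]`` the successor state index; ``cost[i][a]``
    the stage cost (defaults to |vc(state, action)| when built through
    :meth:`from_screws`).  ``terminal`` marks absorbing zero-cost states;
    ``discount`` γ ∈ (0, 1], with γ = 1 requiring terminal states for the
    fixed point to be unique.
    """

    states: list[Screw]
    actions: list[list[Screw]]
    transition: list[list[int]]
    cost: list[list[float]]
    terminal: list[bool] = field(default=None)
    discount: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.states)
        if self.terminal is None:
            self.terminal = [False] * n
        if not (0.0 < self.discount <= 1.0):
            raise ScrewError("discount must lie in (0, 1]")
        if self.discount == 1.0 and not any(self.terminal):
            raise ScrewError("an undiscounted process needs terminal states")
        for i in range(n):
            if len(self.actions[i]) != len(self.transition[i]) or \
               len(self.actions[i]) != len(self.cost[i]):
                raise ScrewError(f"state {i}: actions/transition/cost lengths differ")
            if not self.terminal[i] and not self.actions[i]:
                raise ScrewError(f"non-terminal state {i} has no actions")
            for j in self.transition[i]:
                if not 0 <= j < n:
                    raise ScrewError(f"state {i}: transition target {j} out of range")
            for c in self.cost[i]:
                if not np.isfinite(c):
                    raise ScrewError(f"state {i}: non-finite stage cost")

    @classmethod
    def from_screws(cls, states: list[Screw], actions: list[list[Screw]],
                    transition: list[list[int]], terminal: list[bool] = None,
                    discount: float = 1.0, stage_cost=default_stage_cost
                    ) -> "ScrewDecisionProcess":
        """Build a process whose costs come from a screw-pair stage cost."""
        cost = [[stage_cost(states[i], q) for q in acts]
                for i, acts in enumerate(actions)]
        return cls(states, actions, transition, cost, terminal, discount)


def value_iteration(mdp: ScrewDecisionProcess, tol: float = 1e-12,
                    max_iter: int = 10_000) -> tuple[np.ndarray, list[int | None]]:
    """Solve the Bellman fixed point by successive sweeps.

    Starts from the all-zero value function (so for nonnegative costs the
    sweeps are monotone non-decreasing) and stops when the sup-norm change
    drops below ``tol``.  Returns the value per state and the greedy policy
    as an action index per state (``None`` for terminal states).  Ties break
    to the lowest action index for reproducibility.
    """
    if tol <= 0:
        raise ScrewError("tolerance must be positive")
    n = len(mdp.states)
    f = np.zeros(n)
    gamma = mdp.discount
    residual = np.inf
    for _ in range(max_iter):
        f_new = np.empty(n)
        for i in range(n):
            if mdp.terminal[i]:
                f_new[i] = 0.0
                continue
            f_new[i] = min(
                mdp.cost[i][a] + gamma * f[mdp.transition[i][a]]
                for a in range(len(mdp.actions[i])))
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(residual, max_iter)

    policy: list[int | None] = []
    for i in range(n):
        if mdp.terminal[i]:
            policy.append(None)
            continue
        q_vals = [mdp.cost[i][a] + gamma * f[mdp.transition[i][a]]
                  for a in range(len(mdp.actions[i]))]
        policy.append(int(np.argmin(q_vals)))  # argmin takes the lowest index on ties
    return f, policy


@dataclass(frozen=True)
class PolicyStep:
    """One frame of a stance policy trace."""

    frame: int
    choice: int
    cost: float
    tie: bool


def stance_policy(iak_track: list[Screw], candidate_screws: list[Screw],
                  tie_tol: float = 0.0) -> list[PolicyStep]:
    """Greedy reciprocity-seeking policy along an IAK track.

    Per frame, chooses the candidate screw minimizing ``|vc(candidate,
    IAK)|`` — the wrench line that can act on the joint while expending the
    least energy against its current freedom.  Ties (within ``tie_tol``)
    break to the lowest candidate index and are recorded in the trace.
    """
    if not candidate_screws:
        raise ScrewError("need at least one candidate screw")
    trace = []
    for k, iak in enumerate(iak_track):
        costs = np.array([default_stage_cost(c, iak) for c in candidate_screws])
        best = int(np.argmin(costs))
        tie = bool(np.sum(costs <= costs[best] + tie_tol) > 1)
        trace.append(PolicyStep(frame=k, choice=best, cost=float(costs[best]), tie=tie))
    return trace
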