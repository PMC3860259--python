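"""Optimal stationary intervention by linear programming (MSSA).

The control action toggles a designated control gene: taking action 1 in
state x replaces the row of x in the transition matrix by the row of the
state with the control bit flipped.  The Maximal Steady-State Alteration
(MSSA) policy is the stationary deterministic policy maximizing the shift of
steady-state probability mass out of the undesirable states.

The optimum is characterized by the average-reward occupation-measure LP:
variables nu(s, a) >= 0 are long-run state-action frequencies, constrained
by the balance equations sum_a nu(j, a) = sum_{s,a} nu(s, a) P_a(s, j) and
normalization; the objective maximizes the occupation mass of desirable
states.  For an ergodic chain (p > 0 guarantees ergodicity under every
stationary policy) the LP vertex solutions correspond to deterministic
policies, so the extracted argmax policy attains the LP optimum.

Two interchangeable solvers are provided: Howard policy iteration (the
default), which performs block pivots between the deterministic-policy
vertices of the same LP and converges in a handful of iterations, and the
explicit LP via HiGHS (``solver="lp"``), practical for small state spaces
and used as a cross-check.  Either way the extracted policy is re-evaluated
exactly (controlled TPM + steady-state solve) so the reported shift never
depends on solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .network import BNp, NumericalError, build_tpm_bnp, steady_state, undesirable_mass

__all__ = [
    "ControlProblem",
    "MSSAResult",
    "flip_index",
    "controlled_row",
    "controlled_tpm",
    "delta_shift",
    "mssa_optimal_policy",
]


@dataclass(frozen=True)
class ControlProblem:
    """An intervention design task: which states are bad, which gene we may flip."""

    net: BNp
    undesirable: np.ndarray  # state indices
    control_gene: int

    def __post_init__(self) -> None:
        U = np.unique(np.asarray(self.undesirable, dtype=np.int64))
        object.__setattr__(self, "undesirable", U)
        N = self.net.n_states
        if U.size == 0 or U.size == N:
            raise ValueError("undesirable set must be a nonempty proper subset of states")
        if U.min() < 0 or U.max() >= N:
            raise ValueError("undesirable state index out of range")
        if not 1 <= self.control_gene <= self.net.n:
            raise ValueError(f"control gene {self.control_gene} out of range 1..{self.net.n}")


@dataclass(frozen=True)
class MSSAResult:
    """Optimal stationary deterministic intervention and its realized effect."""

    policy: np.ndarray        # 0/1 action per state index
    pi_original: np.ndarray
    pi_controlled: np.ndarray
    pi_U_original: float
    pi_U_controlled: float
    delta: float              # shift of undesirable mass achieved by the policy
    lp_objective: float       # desirable occupation mass reported by the solver


def flip_index(state: int, control_gene: int, n: int) -> int:
    """Index of the state with the control gene's bit toggled (gene 1 = MSB)."""
    return state ^ (1 << (n - control_gene))


def controlled_row(P: np.ndarray, state: int, action: int, control_gene: int, n: int) -> np.ndarray:
    """Transition row of ``state`` under the given action (0 = no-op, 1 = flip)."""
    if action == 0:
        return P[state]
    return P[flip_index(state, control_gene, n)]


def controlled_tpm(P: np.ndarray, policy: np.ndarray, control_gene: int, n: int) -> np.ndarray:
    """Row-replacement TPM for a stationary deterministic policy."""
    N = P.shape[0]
    idx = np.arange(N)
    flipped = idx ^ (1 << (n - control_gene))
    src = np.where(np.asarray(policy, dtype=np.int64) == 1, flipped, idx)
    return P[src]


def delta_shift(pi: np.ndarray, pi_ctrl: np.ndarray, undesirable: np.ndarray) -> float:
    """Shift of aggregated undesirable mass achieved by a policy."""
    return undesirable_mass(pi, undesirable) - undesirable_mass(pi_ctrl, undesirable)


def _solve_lp(P: np.ndarray, P1: np.ndarray, desirable: np.ndarray) -> tuple[np.ndarray, float]:
    """Occupation-measure LP over (state, action) frequencies; returns policy."""
    N = P.shape[0]
    eye = np.eye(N)
    A_eq = np.empty((N + 1, 2 * N))
    A_eq[:N, :N] = eye - P.T
    A_eq[:N, N:] = eye - P1.T
    A_eq[N, :] = 1.0
    b_eq = np.zeros(N + 1)
    b_eq[N] = 1.0
    c = -np.concatenate([desirable, desirable])  # maximize desirable mass
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise NumericalError(f"MSSA LP failed: {res.message}")
    nu0, nu1 = res.x[:N], res.x[N:]
    # ties nu(s,0) = nu(s,1) resolve to action 0 (no intervention)
    return (nu1 > nu0).astype(np.int64), float(-res.fun)


def _solve_policy_iteration(
    P: np.ndarray, P1: np.ndarray, desirable: np.ndarray, tol: float = 1e-10
) -> tuple[np.ndarray, float]:
    """Howard policy iteration on the average-reward criterion.

    Each step solves the gain/bias equations (I - P_pol) h + g 1 = r with
    h(0) = 0 (one linear solve) and greedily improves state-wise; the
    current action is kept unless the alternative improves the bias by more
    than ``tol``, so the all-no-op start makes ties conservative and the
    iteration cannot cycle.  Equivalent to block pivoting between the
    deterministic-policy vertices of the occupation-measure LP.
    """
    N = P.shape[0]
    policy = np.zeros(N, dtype=np.int64)
    gain = float("nan")
    for _ in range(200):
        P_pol = np.where(policy[:, None] == 1, P1, P)
        M = np.eye(N) - P_pol
        M[:, 0] = 1.0  # unknown 0 becomes the gain; h(0) fixed to 0
        try:
            x = np.linalg.solve(M, desirable)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"policy-evaluation solve failed: {exc}") from exc
        gain = float(x[0])
        h = x.copy()
        h[0] = 0.0
        improved = (P1 @ h) > (P @ h) + tol
        new_policy = improved.astype(np.int64)
        if np.array_equal(new_policy, policy):
            return policy, gain
        policy = new_policy
    raise NumericalError("policy iteration failed to converge in 200 iterations")


def mssa_optimal_policy(
    prob: ControlProblem, P: np.ndarray | None = None, solver: str = "policy-iteration"
) -> MSSAResult:
    """Optimal stationary deterministic policy maximizing the undesirable-mass shift.

    ``solver`` is "policy-iteration" (default) or "lp"; both solve the same
    occupation-measure program exactly.  The zero policy is always feasible,
    so the realized shift is nonnegative.
    """
    net = prob.net
    n = net.n
    N = net.n_states
    if P is None:
        P = build_tpm_bnp(net)
    flipped = np.arange(N) ^ (1 << (n - prob.control_gene))
    P1 = P[flipped]
    desirable = np.ones(N)
    desirable[prob.undesirable] = 0.0

    if solver == "lp":
        policy, lp_obj = _solve_lp(P, P1, desirable)
    elif solver == "policy-iteration":
        policy, lp_obj = _solve_policy_iteration(P, P1, desirable)
    else:
        raise ValueError(f"unknown solver {solver!r}")

    pi = steady_state(P)
    pi_ctrl = steady_state(controlled_tpm(P, policy, prob.control_gene, n))
    pi_U = undesirable_mass(pi, prob.undesirable)
    pi_U_ctrl = undesirable_mass(pi_ctrl, prob.undesirable)
    if abs((1.0 - lp_obj) - pi_U_ctrl) > 1e-6:
        raise NumericalError(
            f"extracted policy realizes undesirable mass {pi_U_ctrl:.9f} "
            f"but the solver reports {1.0 - lp_obj:.9f}"
        )
    return MSSAResult(
        policy=policy,
        pi_original=pi,
        pi_controlled=pi_ctrl,
        pi_U_original=pi_U,
        pi_U_controlled=pi_U_ctrl,
        delta=pi_U - pi_U_ctrl,
        lp_objective=lp_obj,
    )
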