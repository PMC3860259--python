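"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bnpval import (
    BNp,
    TruthTable,
    build_tpm_bnp,
    controlled_tpm,
    melanoma_network,
    steady_state,
    undesirable_mass,
)


@pytest.fixture(scope="session")
def melanoma():
    return melanoma_network(p=0.01)


def identity_network(n: int, p: float = 0.1) -> BNp:
    """Each gene copies itself: the noise-free dynamics are constant."""
    return BNp(
        tuple(TruthTable(i, (i,), np.array([0, 1])) for i in range(1, n + 1)), p
    )


def brute_force_tpm(net: BNp) -> np.ndarray:
    """TPM by enumerating every perturbation vector gamma (oracle, n <= 6).

    Accumulates p^|gamma| (1-p)^(n-|gamma|) onto x xor gamma for gamma != 0
    and (1-p)^n onto f(x); independent of the closed-form construction.
    """
    from bnpval import next_state, index_to_state, state_to_index

    n, p = net.n, net.p
    N = 2 ** n
    P = np.zeros((N, N))
    for x in range(N):
        bits = index_to_state(x, n)
        P[x, state_to_index(next_state(net, bits))] += (1.0 - p) ** n
        for gamma in range(1, N):
            d = bin(gamma).count("1")
            P[x, x ^ gamma] += p ** d * (1.0 - p) ** (n - d)
    return P


def power_iteration_pi(P: np.ndarray, iters: int = 200000, tol: float = 1e-13) -> np.ndarray:
    """Steady state by repeated multiplication (oracle)."""
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    for _ in range(iters):
        new = pi @ P
        if np.abs(new - pi).max() < tol:
            return new
        pi = new
    return pi


def exhaustive_best_delta(net: BNp, U: np.ndarray, control_gene: int):
    """Best shift over ALL stationary deterministic policies by enumeration.

    Oracle for the MSSA solvers; only feasible for small n.
    """
    P = build_tpm_bnp(net)
    pi = steady_state(P)
    base = undesirable_mass(pi, U)
    N = net.n_states
    best, best_policy = -np.inf, None
    for mask in range(2 ** N):
        policy = np.array([(mask >> s) & 1 for s in range(N)])
        pv = steady_state(controlled_tpm(P, policy, control_gene, net.n))
        delta = base - undesirable_mass(pv, U)
        if delta > best:
            best, best_policy = delta, policy
    return best, best_policy


def full_coverage_series(net: BNp):
    """Noise-free transitions (x, f(x)) for every state, as 2-row series.

    Gives any consistency-based algorithm complete information about the
    generating functions.
    """
    from bnpval import TimeSeries, index_to_state, next_state

    out = []
    for x in range(net.n_states):
        bits = index_to_state(x, net.n)
        out.append(TimeSeries(np.vstack([bits, next_state(net, bits)]), series_id=x))
    return out
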