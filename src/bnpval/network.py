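"""Boolean networks with perturbation (BNp) and probabilistic Boolean networks (PBN).

A BNp is a synchronous Boolean network in which, at every time step, each
gene independently flips its value with probability ``p``; if no gene flips,
all genes update through their Boolean functions simultaneously.  For
``p > 0`` the induced Markov chain on the 2**n gene-activity profiles (GAPs)
is ergodic and possesses a unique steady-state distribution, which is the
object all downstream control and validation computations consume.

A PBN is a family of BNp "contexts" sharing the gene set, with a context
switch occurring at each step with probability ``q``; on a switch the new
context is drawn from the selection distribution ``c`` (possibly re-selecting
the current one).

Bit convention: gene 1 is the most significant bit of the state index, so
state (1,0,0) of a 3-gene network has index 4.  Gene indices are 1-based in
all public data structures and files, 0-based only inside array code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TruthTable",
    "BNp",
    "PBN",
    "NumericalError",
    "state_to_index",
    "index_to_state",
    "evaluate_function",
    "next_state",
    "next_index_map",
    "build_tpm_bnp",
    "build_tpm_pbn",
    "steady_state",
    "undesirable_mass",
    "marker_states",
    "adjacency",
]


class NumericalError(RuntimeError):
    """Raised when a linear solve fails to meet its residual tolerance."""


@dataclass(frozen=True)
class TruthTable:
    """One gene's regulator set and Boolean function.

    ``outputs[r]`` is the next value of the gene when the tuple of regulator
    values, first regulator as most significant bit, encodes the integer
    ``r``.
    """

    gene: int
    regulators: tuple[int, ...]
    outputs: np.ndarray

    def __post_init__(self) -> None:
        regs = tuple(int(r) for r in self.regulators)
        object.__setattr__(self, "regulators", regs)
        if len(regs) < 1:
            raise ValueError(f"gene {self.gene}: needs at least one regulator")
        if any(b >= a for a, b in zip(regs[1:], regs)):
            raise ValueError(f"gene {self.gene}: regulators must be strictly increasing")
        out = np.asarray(self.outputs, dtype=np.uint8)
        object.__setattr__(self, "outputs", out)
        if out.ndim != 1 or out.size != 2 ** len(regs):
            raise ValueError(
                f"gene {self.gene}: expected {2 ** len(regs)} outputs, got {out.size}"
            )
        if not np.isin(out, (0, 1)).all():
            raise ValueError(f"gene {self.gene}: outputs must be 0/1")

    @property
    def k(self) -> int:
        return len(self.regulators)


@dataclass(frozen=True)
class BNp:
    """Boolean network with perturbation probability ``p``.

    ``tables`` holds one :class:`TruthTable` per gene, in gene order 1..n.
    ``p`` is the per-gene, per-step flip probability; ergodicity of the state
    chain requires ``p > 0`` (``p = 0`` is accepted for noise-free
    simulation but has no guaranteed steady state).
    """

    tables: tuple[TruthTable, ...]
    p: float

    def __post_init__(self) -> None:
        tables = tuple(self.tables)
        object.__setattr__(self, "tables", tables)
        n = len(tables)
        if [t.gene for t in tables] != list(range(1, n + 1)):
            raise ValueError("tables must be ordered by gene index 1..n, each exactly once")
        for t in tables:
            if max(t.regulators) > n:
                raise ValueError(f"gene {t.gene}: regulator index exceeds n={n}")
        if not 0.0 <= self.p < 0.5:
            raise ValueError(f"perturbation probability must lie in [0, 0.5), got {self.p}")

    @property
    def n(self) -> int:
        return len(self.tables)

    @property
    def n_states(self) -> int:
        return 2 ** self.n


@dataclass(frozen=True)
class PBN:
    """Probabilistic Boolean network: BNp contexts plus switching law.

    At each step, with probability ``q`` the governing context is re-drawn
    from ``c`` (a switch may re-select the current context) before the GAP
    update; with probability ``1 - q`` the context is kept.
    """

    contexts: tuple[BNp, ...]
    q: float
    c: np.ndarray

    def __post_init__(self) -> None:
        ctx = tuple(self.contexts)
        object.__setattr__(self, "contexts", ctx)
        if len(ctx) < 1:
            raise ValueError("PBN needs at least one context")
        if len({b.n for b in ctx}) != 1:
            raise ValueError("all contexts must share the gene count")
        if not 0.0 < self.q <= 1.0:
            raise ValueError(f"switch probability q must lie in (0, 1], got {self.q}")
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "c", c)
        if c.size != len(ctx) or (c < 0).any() or abs(c.sum() - 1.0) > 1e-9:
            raise ValueError("selection probabilities c must be nonnegative and sum to 1")

    @property
    def m(self) -> int:
        return len(self.contexts)

    @property
    def n(self) -> int:
        return self.contexts[0].n


def state_to_index(bits: Sequence[int]) -> int:
    """Encode a GAP as an integer, gene 1 as the most significant bit."""
    idx = 0
    for b in bits:
        if b not in (0, 1):
            raise ValueError(f"state entries must be 0/1, got {b!r}")
        idx = (idx << 1) | int(b)
    return idx


def index_to_state(index: int, n: int) -> np.ndarray:
    """Decode a state index into its length-``n`` bit vector (gene 1 MSB)."""
    if not 0 <= index < 2 ** n:
        raise ValueError(f"index {index} out of range for n={n}")
    return np.array([(index >> (n - 1 - i)) & 1 for i in range(n)], dtype=np.uint8)


def evaluate_function(tt: TruthTable, bits: Sequence[int]) -> int:
    """Value of gene ``tt.gene`` at t+1 given the full GAP at t."""
    row = 0
    for r in tt.regulators:
        row = (row << 1) | int(bits[r - 1])
    return int(tt.outputs[row])


def next_state(net: BNp, bits: Sequence[int]) -> np.ndarray:
    """Synchronous noise-free update: every gene applies its function at once."""
    return np.array([evaluate_function(t, bits) for t in net.tables], dtype=np.uint8)


def next_index_map(net: BNp) -> np.ndarray:
    """Deterministic successor index f(x) for every state index x.

    Vectorized over all 2**n states: for each gene, the regulator bits of
    every state are packed into the truth-table row and looked up.
    """
    n = net.n
    idx = np.arange(net.n_states, dtype=np.int64)
    nxt = np.zeros_like(idx)
    for t in net.tables:
        rows = np.zeros_like(idx)
        for r in t.regulators:
            rows = (rows << 1) | ((idx >> (n - r)) & 1)
        nxt = (nxt << 1) | t.outputs[rows].astype(np.int64)
    return nxt


def build_tpm_bnp(net: BNp) -> np.ndarray:
    """Transition probability matrix of the BNp state chain.

    P(x -> j) = (1-p)^n [j = f(x)] + p^d (1-p)^(n-d) [d >= 1],
    d = Hamming(x, j): either no gene is perturbed and the network function
    fires, or the perturbation vector (never the zero vector) is applied.
    """
    n, p = net.n, net.p
    N = net.n_states
    idx = np.arange(N, dtype=np.uint64)
    d = np.bitwise_count(idx[:, None] ^ idx[None, :]).astype(np.int64)
    with np.errstate(divide="ignore"):
        P = np.where(d > 0, p ** d * (1.0 - p) ** (n - d), 0.0)
    P[np.arange(N), next_index_map(net)] += (1.0 - p) ** n
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    return P


def build_tpm_pbn(pbn: PBN) -> np.ndarray:
    """TPM of the PBN joint chain on (context, GAP) states.

    Joint state (x, y) has index y * 2**n + x (context-major blocks).  The
    context is resampled first (kept with probability 1-q, redrawn from c
    with probability q) and the GAP then follows the row of the new context.
    For a single context this reduces exactly to :func:`build_tpm_bnp`.
    """
    m, n = pbn.m, pbn.n
    N = 2 ** n
    blocks = [build_tpm_bnp(b) for b in pbn.contexts]
    P = np.zeros((m * N, m * N))
    for y in range(m):
        for y2 in range(m):
            w = pbn.q * pbn.c[y2] + (1.0 - pbn.q) * (y == y2)
            if w > 0:
                P[y * N:(y + 1) * N, y2 * N:(y2 + 1) * N] = w * blocks[y2]
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    return P


def steady_state(P: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution of an ergodic chain by direct linear solve.

    Solves pi^T P = pi^T with one balance equation replaced by the
    normalization sum(pi) = 1.  Raises :class:`NumericalError` if the system
    is singular or the residual exceeds ``tol``.
    """
    N = P.shape[0]
    A = P.T - np.eye(N)
    A[-1, :] = 1.0
    b = np.zeros(N)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"steady-state system singular: {exc}") from exc
    residual = float(np.max(np.abs(pi @ P - pi)))
    if residual > tol or abs(pi.sum() - 1.0) > tol:
        raise NumericalError(
            f"steady-state residual {residual:.3e} (sum {pi.sum():.12f}) exceeds {tol:.1e}; "
            "chain may not be ergodic (is p > 0?)"
        )
    return pi


def undesirable_mass(pi: np.ndarray, states: Iterable[int] | np.ndarray) -> float:
    """Aggregated steady-state probability of a set of state indices."""
    states = np.asarray(list(states) if not isinstance(states, np.ndarray) else states)
    if states.size == 0:
        return 0.0
    if states.dtype == bool:
        return float(pi[states].sum())
    return float(pi[states.astype(np.int64)].sum())


def marker_states(n: int, gene: int, value: int) -> np.ndarray:
    """Indices of all states in which ``gene`` takes ``value`` (e.g. a marker
    gene's aberrant level defining the undesirable set)."""
    if not 1 <= gene <= n:
        raise ValueError(f"gene {gene} out of range 1..{n}")
    idx = np.arange(2 ** n)
    return idx[((idx >> (n - gene)) & 1) == value]


def adjacency(net: BNp) -> np.ndarray:
    """0/1 adjacency matrix: entry (i, j) = 1 iff gene i+1 regulates gene j+1."""
    A = np.zeros((net.n, net.n), dtype=np.uint8)
    for t in net.tables:
        for r in t.regulators:
            A[r - 1, t.gene - 1] = 1
    return A
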