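"""Random network generation and time-series simulation.

Random BNps emulate sparse regulatory topologies: each gene receives an
in-degree drawn uniformly from {1..K} (average connectivity 2 for K=3, 3 for
K=5), a uniformly chosen regulator subset (self-regulation allowed), and a
truth table filled with i.i.d. Bernoulli bits whose bias is drawn once per
gene from a Beta distribution concentrated at 0.5 (sd 0.01), so networks are
unbiased on average but not exactly balanced.

Time series are sampled from the exact BNp mechanism: at each step a
perturbation vector gamma with i.i.d. Bernoulli(p) entries is drawn; if gamma
is zero the synchronous update fires, otherwise the flagged genes flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import BNp, TruthTable, next_index_map

__all__ = ["GenConfig", "TimeSeries", "beta_shape", "generate_random_bnp", "generate_time_series"]


@dataclass(frozen=True)
class GenConfig:
    """Parameters of the random-BNp ensemble.

    n: gene count; K: maximum in-degree (in-degree ~ Uniform{1..K});
    p: perturbation probability; bias_mean/bias_sd: Beta law of the per-gene
    truth-table bias; seed: root seed (structure and table streams are
    spawned from it, so topology is reproducible independent of later use).
    """

    n: int
    K: int
    p: float = 0.01
    bias_mean: float = 0.5
    bias_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.K <= self.n:
            raise ValueError(f"need 1 <= K <= n, got K={self.K}, n={self.n}")
        if self.bias_sd ** 2 >= self.bias_mean * (1.0 - self.bias_mean):
            raise ValueError("bias_sd^2 must be < bias_mean*(1-bias_mean)")


@dataclass(frozen=True)
class TimeSeries:
    """One observed trajectory: a (T+1, n) 0/1 array of consecutive GAPs."""

    states: np.ndarray
    series_id: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.uint8)
        object.__setattr__(self, "states", s)
        if s.ndim != 2:
            raise ValueError("states must be a 2-D (time x gene) array")

    @property
    def n_transitions(self) -> int:
        return self.states.shape[0] - 1

    @property
    def n(self) -> int:
        return self.states.shape[1]


def beta_shape(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta shape parameters for a given mean and sd.

    For mean 0.5, sd 0.01 this gives alpha = beta = 1249.5.
    """
    var = sd * sd
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def generate_random_bnp(cfg: GenConfig) -> BNp:
    """Draw one random BNp from the ensemble defined by ``cfg``."""
    ss = np.random.SeedSequence(cfg.seed)
    s_struct, s_tab = ss.spawn(2)
    rng_s = np.random.default_rng(s_struct)
    rng_t = np.random.default_rng(s_tab)
    alpha, beta = beta_shape(cfg.bias_mean, cfg.bias_sd)
    tables = []
    for gene in range(1, cfg.n + 1):
        k = int(rng_s.integers(1, cfg.K + 1))
        regs = np.sort(rng_s.choice(cfg.n, size=k, replace=False)) + 1
        bias = rng_t.beta(alpha, beta)
        outputs = (rng_t.random(2 ** k) < bias).astype(np.uint8)
        tables.append(TruthTable(gene, tuple(int(r) for r in regs), outputs))
    return BNp(tuple(tables), cfg.p)


def _split_transitions(M: int, n_series: int) -> list[int]:
    base, extra = divmod(M, n_series)
    counts = [base + (i < extra) for i in range(n_series)]
    if min(counts) < 1:
        raise ValueError(f"cannot split M={M} transitions into {n_series} nonempty series")
    return counts


def generate_time_series(
    net: BNp,
    M: int,
    seed: int | np.random.SeedSequence,
    n_series: int = 1,
    init: str = "uniform",
) -> list[TimeSeries]:
    """Simulate observed state transitions from the BNp mechanism.

    The total number of transitions across all series is ``M`` (one series
    of M+1 states by default; with ``n_series > 1`` M is split as evenly as
    possible).  Initial states are uniform over the 2**n GAPs.
    """
    if M < 1:
        raise ValueError(f"need at least one transition, got M={M}")
    if init != "uniform":
        raise ValueError(f"unknown init scheme {init!r}")
    rng = np.random.default_rng(seed)
    n, N = net.n, net.n_states
    nxt = next_index_map(net)
    pow2 = (1 << np.arange(n - 1, -1, -1)).astype(np.int64)
    out = []
    for sid, m in enumerate(_split_transitions(M, n_series)):
        s = int(rng.integers(N))
        # pre-draw all perturbation vectors for the series, packed as ints
        gammas = ((rng.random((m, n)) < net.p) @ pow2).astype(np.int64)
        path = np.empty(m + 1, dtype=np.int64)
        path[0] = s
        for t in range(m):
            g = gammas[t]
            s = int(nxt[s]) if g == 0 else s ^ int(g)
            path[t + 1] = s
        bits = (path[:, None] >> (n - 1 - np.arange(n))[None, :]) & 1
        out.append(TimeSeries(bits.astype(np.uint8), series_id=sid))
    return out
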