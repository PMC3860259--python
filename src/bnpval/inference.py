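"""Boolean network inference from binary state-transition time series.

Five algorithms, all sharing the same search space (regulator subsets of
size 1..K per target gene, enumerated in order of increasing size and then
lexicographically) and the same function-fitting rule, differing only in the
subset-selection criterion:

* Best-Fit       -- minimum number of misclassified transitions;
* REVEAL         -- smallest subset whose plug-in mutual information with
                    the target's next value reaches the target entropy
                    (in-sample consistency);
* BIC / MDL      -- penalized data coding length, lambda * model complexity;
* uMDL           -- normalized-maximum-likelihood (NML) code length, no
                    tuning parameter.

Ties always resolve to the sparsest subset, then lexicographically, so
inference is deterministic.  Fitted functions may be partially defined when
some input patterns are never observed; unseen rows are filled with the
target gene's overall majority next-value, and the fill is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .network import BNp, TruthTable, adjacency  # noqa: F401  (adjacency re-exported)
from .generate import TimeSeries

__all__ = [
    "TransitionCounts",
    "GeneFit",
    "InferredNetwork",
    "count_transitions",
    "best_fit_error",
    "fit_function",
    "conditional_entropy",
    "mutual_information",
    "mdl_score",
    "nml_complexity",
    "infer_best_fit",
    "infer_reveal",
    "infer_mdl",
    "infer_umdl",
    "infer",
    "adjacency",
]

_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class TransitionCounts:
    """Empirical next-value counts of one target gene under one regulator subset.

    ``n0[w]`` / ``n1[w]`` count observed transitions whose regulator pattern
    (first regulator MSB) encodes ``w`` and whose target next-value is 0 / 1.
    """

    target: int
    regulators: tuple[int, ...]
    n0: np.ndarray
    n1: np.ndarray

    @property
    def total(self) -> int:
        return int(self.n0.sum() + self.n1.sum())


@dataclass(frozen=True)
class GeneFit:
    """Provenance of one gene's inferred function."""

    regulators: tuple[int, ...]
    score: float
    n_unseen_rows: int
    fill_value: int


@dataclass(frozen=True)
class InferredNetwork:
    """A BNp reconstructed from data plus per-gene fit provenance."""

    net: BNp
    fits: tuple[GeneFit, ...]
    algorithm: str


def _pairs(series: Sequence[TimeSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Stack consecutive (x_t, x_{t+1}) pairs; never across series boundaries."""
    prev, nxt = [], []
    for s in series:
        st = s.states
        if st.shape[0] >= 2:
            prev.append(st[:-1])
            nxt.append(st[1:])
    if not prev:
        raise ValueError("no observed transitions in the provided time series")
    return np.concatenate(prev).astype(np.int64), np.concatenate(nxt).astype(np.int64)


def _counts_from_pairs(
    prev: np.ndarray, nxt: np.ndarray, target: int, regulators: tuple[int, ...]
) -> TransitionCounts:
    k = len(regulators)
    cols = np.array(regulators) - 1
    pow2 = 1 << np.arange(k - 1, -1, -1)
    w = prev[:, cols] @ pow2
    y = nxt[:, target - 1]
    n1 = np.bincount(w[y == 1], minlength=2 ** k).astype(np.int64)
    n0 = np.bincount(w[y == 0], minlength=2 ** k).astype(np.int64)
    return TransitionCounts(target, tuple(regulators), n0, n1)


def count_transitions(
    series: Sequence[TimeSeries], target: int, regulators: Sequence[int]
) -> TransitionCounts:
    """Tally transitions of ``target`` conditioned on a candidate regulator subset."""
    prev, nxt = _pairs(series)
    return _counts_from_pairs(prev, nxt, target, tuple(int(r) for r in regulators))


def best_fit_error(counts: TransitionCounts) -> int:
    """Minimum transitions any Boolean function on the subset must misclassify."""
    return int(np.minimum(counts.n0, counts.n1).sum())


def fit_function(counts: TransitionCounts) -> tuple[np.ndarray, int, int]:
    """Majority-vote truth table; unseen rows filled by the gene's overall majority.

    Both the per-pattern vote and the gene-majority fill break ties toward 0.
    Returns (outputs, number of unseen rows, fill value).
    """
    seen = (counts.n0 + counts.n1) > 0
    fill = int(counts.n1.sum() > counts.n0.sum())
    outputs = np.where(counts.n1 > counts.n0, 1, 0).astype(np.uint8)
    outputs[~seen] = fill
    return outputs, int((~seen).sum()), fill


def _entropy_bits(p1: float) -> float:
    if p1 <= 0.0 or p1 >= 1.0:
        return 0.0
    return -(p1 * math.log2(p1) + (1 - p1) * math.log2(1 - p1))


def conditional_entropy(counts: TransitionCounts) -> float:
    """Plug-in H(target' | regulators) in bits per transition."""
    M = counts.total
    h = 0.0
    for a, b in zip(counts.n0, counts.n1):
        m_w = a + b
        if m_w:
            h += (m_w / M) * _entropy_bits(b / m_w)
    return h


def mutual_information(counts: TransitionCounts) -> float:
    """Plug-in I(regulators ; target') = H(target') - H(target'|regulators), bits."""
    M = counts.total
    return _entropy_bits(counts.n1.sum() / M) - conditional_entropy(counts)


def mdl_score(
    counts: TransitionCounts, k: int, M: int, n: int, lam: float, variant: str
) -> float:
    """Penalized description length: data bits plus lambda * model bits.

    variant "mdl": model length k*log2(n) + 2**k (regulator identities plus
    truth-table bits); variant "bic": (2**k / 2) * log2(M).
    """
    l_data = M * conditional_entropy(counts)
    if variant == "mdl":
        l_model = k * math.log2(n) + 2 ** k
    elif variant == "bic":
        l_model = (2 ** k / 2.0) * math.log2(M)
    else:
        raise ValueError(f"unknown MDL variant {variant!r}")
    return l_data + lam * l_model


def nml_complexity(m_w: int) -> float:
    """Bernoulli NML parametric complexity COMP(m) in bits.

    COMP(m) = log2 sum_{j=0}^{m} C(m,j) (j/m)^j ((m-j)/m)^(m-j), with the
    convention 0^0 = 1; COMP(0) = 0.
    """
    if m_w == 0:
        return 0.0
    j = np.arange(m_w + 1)
    log_c = gammaln(m_w + 1) - gammaln(j + 1) - gammaln(m_w - j + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(j > 0, j * np.log(j / m_w), 0.0)
        t2 = np.where(m_w - j > 0, (m_w - j) * np.log((m_w - j) / m_w), 0.0)
    return float(logsumexp(log_c + t1 + t2) / _LOG2)


def _umdl_code_length(counts: TransitionCounts, comp_cache: dict[int, float]) -> float:
    """Total NML code length: per-pattern data bits plus parametric complexity."""
    total = 0.0
    for a, b in zip(counts.n0, counts.n1):
        m_w = int(a + b)
        if m_w == 0:
            continue
        if m_w not in comp_cache:
            comp_cache[m_w] = nml_complexity(m_w)
        total += m_w * _entropy_bits(b / m_w) + comp_cache[m_w]
    return total


def _search(
    series: Sequence[TimeSeries],
    K: int,
    p: float,
    algorithm: str,
    score_fn,
    accept_fn=None,
) -> InferredNetwork:
    """Shared subset search: sizes 1..K ascending, lexicographic within a size.

    ``score_fn(counts, k, M, n) -> float`` (lower is better); strict
    improvement required, so the first subset attaining the global minimum
    (sparsest, then lexicographically first) wins.  If ``accept_fn`` is
    given, the first subset it accepts short-circuits the search (REVEAL's
    consistency rule).
    """
    prev, nxt = _pairs(series)
    n = prev.shape[1]
    M = prev.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds gene count n={n}")
    tables, fits = [], []
    for target in range(1, n + 1):
        best_score, best_counts = math.inf, None
        accepted = False
        for k in range(1, K + 1):
            for regs in combinations(range(1, n + 1), k):
                counts = _counts_from_pairs(prev, nxt, target, regs)
                score = score_fn(counts, k, M, n)
                if accept_fn is not None and accept_fn(counts):
                    best_score, best_counts, accepted = score, counts, True
                    break
                if score < best_score:
                    best_score, best_counts = score, counts
            if accepted:
                break
        outputs, n_unseen, fill = fit_function(best_counts)
        tables.append(TruthTable(target, best_counts.regulators, outputs))
        fits.append(GeneFit(best_counts.regulators, best_score, n_unseen, fill))
    return InferredNetwork(BNp(tuple(tables), p), tuple(fits), algorithm)


def infer_best_fit(series: Sequence[TimeSeries], K: int, p: float = 0.01) -> InferredNetwork:
    """Best-Fit extension: minimize misclassified transitions, sparsest wins ties."""
    return _search(series, K, p, "bestfit", lambda c, k, M, n: float(best_fit_error(c)))


def infer_reveal(
    series: Sequence[TimeSeries], K: int, p: float = 0.01, eps: float = 1e-9
) -> InferredNetwork:
    """REVEAL: accept the first subset whose mutual information with the target's
    next value reaches the target entropy (in-sample consistency within
    ``eps`` bits); if no subset of size <= K is consistent, fall back to the
    size-K subset maximizing mutual information."""

    def score(c, k, M, n):
        # fallback ranking: only size-K subsets compete, by max MI (strict <,
        # so lexicographically first among maximizers wins)
        return -mutual_information(c) if k == K else math.inf

    return _search(series, K, p, "reveal", score, accept_fn=lambda c: conditional_entropy(c) <= eps)


def infer_mdl(
    series: Sequence[TimeSeries],
    K: int,
    lam: float = 0.3,
    variant: str = "mdl",
    p: float = 0.01,
) -> InferredNetwork:
    """Penalized-description-length inference (variant "mdl" or "bic")."""
    return _search(
        series, K, p, variant, lambda c, k, M, n: mdl_score(c, k, M, n, lam, variant)
    )


def infer_umdl(series: Sequence[TimeSeries], K: int, p: float = 0.01) -> InferredNetwork:
    """Universal-MDL inference: minimize the tuning-free NML code length.

    The total description length of a candidate regulator set is the NML
    code of the data (per-pattern entropy plus Bernoulli parametric
    complexity) plus the log2 C(n, k) bits needed to state which genes are
    the predictors; without the subset-identity term the one-part code would
    be free to grow the predictor set at tiny sample sizes.  No weighting
    parameter is involved.
    """
    cache: dict[int, float] = {}
    return _search(
        series,
        K,
        p,
        "umdl",
        lambda c, k, M, n: _umdl_code_length(c, cache) + math.log2(math.comb(n, k)),
    )


_DEFAULT_LAMBDA = {"bic": 0.5, "mdl": 0.3}


def infer(
    series: Sequence[TimeSeries],
    K: int,
    algorithm: str,
    p: float = 0.01,
    lam: float | None = None,
) -> InferredNetwork:
    """Dispatch to one of the five algorithms by name."""
    algorithm = algorithm.lower()
    if algorithm == "bestfit":
        return infer_best_fit(series, K, p)
    if algorithm == "reveal":
        return infer_reveal(series, K, p)
    if algorithm in ("bic", "mdl"):
        lam = _DEFAULT_LAMBDA[algorithm] if lam is None else lam
        return infer_mdl(series, K, lam=lam, variant=algorithm, p=p)
    if algorithm == "umdl":
        return infer_umdl(series, K, p)
    raise ValueError(f"unknown inference algorithm {algorithm!r}")
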