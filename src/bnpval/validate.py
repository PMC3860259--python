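"""Inferential-validity semi-metrics and the experiment harness.

Three semi-metrics compare an inferred network against the ground truth:

* mu_ham  -- Hamming distance between adjacency matrices (topology), by
  default normalized by the true network's edge count;
* mu_ss   -- L1 distance between the steady-state distributions (dynamics);
* mu_ctrl -- controllability loss: the excess undesirable steady-state mass
  when the intervention policy designed on the *inferred* network is applied
  to the *true* network, relative to the policy designed with full knowledge
  of the truth.  Always nonnegative, since the true-network MSSA policy is
  optimal there.

The harness estimates expectations of these quantities over an ensemble of
random networks, one simulated sample per network per sample size, matching
the study protocol: marker gene 1 (undesirable when down-regulated) and the
last gene as control target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import (
    BNp,
    TruthTable,
    adjacency,
    build_tpm_bnp,
    marker_states,
    steady_state,
    undesirable_mass,
)
from .generate import GenConfig, generate_random_bnp, generate_time_series
from .control import ControlProblem, controlled_tpm, mssa_optimal_policy
from .inference import InferredNetwork, infer

__all__ = [
    "ValidationReport",
    "ExperimentConfig",
    "mu_hamming",
    "mu_steady_state",
    "mu_controllability",
    "control_ensemble",
    "run_experiment",
    "melanoma_network",
    "MELANOMA_GENES",
]


@dataclass(frozen=True)
class ValidationReport:
    """All three validity measurements for one (true net, inferred net) pair."""

    mu_ham: float
    mu_ss: float
    mu_ctrl: float
    pi_U_original: float
    pi_U_opt: float
    pi_U_inferred_policy: float
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ExperimentConfig:
    """One ensemble experiment: network law, sample sizes, algorithms."""

    n: int
    K: int
    p: float = 0.01
    count: int = 100
    seed: int = 0
    M_values: tuple[int, ...] = (10, 30, 50)
    marker_gene: int = 1
    undesirable_value: int = 0
    control_gene: int | None = None  # defaults to the last gene
    algorithms: tuple[str, ...] = ("reveal", "bic", "mdl", "umdl", "bestfit")
    lambdas: dict = field(default_factory=lambda: {"bic": 0.5, "mdl": 0.3})

    def __post_init__(self) -> None:
        if self.count < 1 or min(self.M_values) < 1:
            raise ValueError("count and every M must be >= 1")


def mu_hamming(A_true: np.ndarray, A_inf: np.ndarray, normalize: bool = True) -> float:
    """Adjacency Hamming distance, optionally per true edge."""
    dist = float(np.abs(A_true.astype(int) - A_inf.astype(int)).sum())
    if normalize:
        dist /= float(A_true.sum())
    return dist


def mu_steady_state(pi: np.ndarray, omega: np.ndarray) -> float:
    """L1 distance between two steady-state distributions (range [0, 2])."""
    return float(np.abs(pi - omega).sum())


def mu_controllability(
    true_net: BNp,
    inferred: InferredNetwork | BNp,
    marker_gene: int,
    undesirable_value: int,
    control_gene: int,
) -> ValidationReport:
    """Design policies on both networks, apply both to the truth, compare.

    The inferred network only proposes a policy; every steady state entering
    the metrics is computed on the true network's chain.
    """
    inf_net = inferred.net if isinstance(inferred, InferredNetwork) else inferred
    if inf_net.n != true_net.n:
        raise ValueError("true and inferred networks must share the gene set")
    n = true_net.n
    U = marker_states(n, marker_gene, undesirable_value)

    P_true = build_tpm_bnp(true_net)
    pi_true = steady_state(P_true)
    opt_true = mssa_optimal_policy(ControlProblem(true_net, U, control_gene), P=P_true)
    opt_inf = mssa_optimal_policy(ControlProblem(inf_net, U, control_gene))

    pi_cross = steady_state(controlled_tpm(P_true, opt_inf.policy, control_gene, n))
    pi_U_cross = undesirable_mass(pi_cross, U)

    pi_inf = steady_state(build_tpm_bnp(inf_net))
    report = ValidationReport(
        mu_ham=mu_hamming(adjacency(true_net), adjacency(inf_net)),
        mu_ss=mu_steady_state(pi_true, pi_inf),
        mu_ctrl=pi_U_cross - opt_true.pi_U_controlled,
        pi_U_original=undesirable_mass(pi_true, U),
        pi_U_opt=opt_true.pi_U_controlled,
        pi_U_inferred_policy=pi_U_cross,
        metadata={
            "algorithm": getattr(inferred, "algorithm", None),
            "marker_gene": marker_gene,
            "undesirable_value": undesirable_value,
            "control_gene": control_gene,
        },
    )
    return report


def control_ensemble(
    n: int,
    K: int,
    p: float = 0.01,
    count: int = 1000,
    seed: int = 0,
    marker_gene: int = 1,
    undesirable_value: int = 0,
    control_gene: int | None = None,
) -> pd.DataFrame:
    """Original and MSSA-controlled undesirable masses over a random ensemble.

    One row per network, columns ``pi_U_original`` and ``pi_U_controlled``.
    """
    control_gene = n if control_gene is None else control_gene
    U = marker_states(n, marker_gene, undesirable_value)
    child_seeds = np.random.SeedSequence(seed).generate_state(count) % (2 ** 31)
    rows = []
    for i in range(count):
        net = generate_random_bnp(GenConfig(n=n, K=K, p=p, seed=int(child_seeds[i])))
        res = mssa_optimal_policy(ControlProblem(net, U, control_gene))
        rows.append((res.pi_U_original, res.pi_U_controlled))
    return pd.DataFrame(rows, columns=["pi_U_original", "pi_U_controlled"])


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Ensemble means and sds of all three metrics per (algorithm, M).

    For each replicate network: simulate one time series per M, run every
    algorithm, and validate against the generating network.  Returns a tidy
    table with one row per (algorithm, M) carrying mean and sd columns, plus
    the ensemble averages of the original and optimally controlled
    undesirable masses.
    """
    control_gene = cfg.n if cfg.control_gene is None else cfg.control_gene
    U = marker_states(cfg.n, cfg.marker_gene, cfg.undesirable_value)
    root = np.random.SeedSequence(cfg.seed)
    net_seeds = root.generate_state(cfg.count) % (2 ** 31)
    sim_root = root.spawn(cfg.count)

    records = []
    originals, optimals = [], []
    for i in range(cfg.count):
        net = generate_random_bnp(GenConfig(n=cfg.n, K=cfg.K, p=cfg.p, seed=int(net_seeds[i])))
        P = build_tpm_bnp(net)
        pi = steady_state(P)
        opt = mssa_optimal_policy(ControlProblem(net, U, control_gene), P=P)
        A_true = adjacency(net)
        originals.append(opt.pi_U_original)
        optimals.append(opt.pi_U_controlled)
        sim_streams = sim_root[i].spawn(len(cfg.M_values))
        for j, M in enumerate(cfg.M_values):
            series = generate_time_series(net, M, sim_streams[j])
            for algo in cfg.algorithms:
                inferred = infer(series, cfg.K, algo, p=cfg.p, lam=cfg.lambdas.get(algo))
                inf_net = inferred.net
                opt_inf = mssa_optimal_policy(ControlProblem(inf_net, U, control_gene))
                pi_cross = steady_state(
                    controlled_tpm(P, opt_inf.policy, control_gene, cfg.n)
                )
                pi_U_cross = undesirable_mass(pi_cross, U)
                records.append(
                    {
                        "net": i,
                        "algo": algo,
                        "M": M,
                        "mu_ham": mu_hamming(A_true, adjacency(inf_net)),
                        "mu_ss": mu_steady_state(pi, steady_state(build_tpm_bnp(inf_net))),
                        "mu_ctrl": pi_U_cross - opt.pi_U_controlled,
                        "pi_U_ctrl": pi_U_cross,
                        "edges": int(adjacency(inf_net).sum()),
                    }
                )
    per_net = pd.DataFrame(records)
    out = (
        per_net.groupby(["algo", "M"], sort=False)[
            ["mu_ham", "mu_ss", "mu_ctrl", "pi_U_ctrl", "edges"]
        ]
        .agg(["mean", "std"])
        .reset_index()
    )
    out.columns = ["algo", "M"] + [f"{a}_{b}" for a, b in out.columns[2:]]
    out.attrs["pi_U_original_mean"] = float(np.mean(originals))
    out.attrs["pi_U_original_sd"] = float(np.std(originals, ddof=1))
    out.attrs["pi_U_opt_mean"] = float(np.mean(optimals))
    out.attrs["pi_U_opt_sd"] = float(np.std(optimals, ddof=1))
    return out


MELANOMA_GENES = (
    "WNT5A", "PIR", "S100P", "RET1", "MMP3",
    "PLCG1", "MART1", "HADHB", "SNCA", "STC2",
)

# regulator indices (1-based, ascending) and the gene's update rule over the
# full GAP x (1-based); gene 1 = WNT5A is the most significant bit
_MELANOMA_RULES: tuple[tuple[tuple[int, ...], object], ...] = (
    ((3, 5, 6), lambda x: (x[3] and x[5] and not x[6]) or (not x[5] and x[6])),
    ((1, 3, 5), lambda x: (not x[1] and not x[3] and x[5]) or (x[1] and not x[3] and not x[5])),
    ((7,), lambda x: x[7]),
    ((1, 2, 4), lambda x: (not x[1] and x[2] and x[4]) or (not x[2] and x[4])),
    ((4, 9), lambda x: (x[4] and x[9]) or (not x[9])),
    ((4, 7, 10), lambda x: (not x[4] and not x[7]) or (x[4] and x[7] and x[10])),
    ((7,), lambda x: x[7]),
    ((1, 5, 9), lambda x: (x[1] and x[5]) or (not x[5] and not x[9]) or (x[1] and not x[5] and x[9])),
    ((1, 4, 7, 10), lambda x: (not x[1] and not x[7] and not x[10]) or (x[4] and not x[7] and x[10]) or x[7]),
    ((3,), lambda x: not x[3]),
)


def melanoma_network(p: float = 0.01) -> BNp:
    """The 10-gene metastatic melanoma BNp (WNT5A ... STC2, MSB first).

    Up-regulated WNT5A (gene 1 = 1) marks the undesirable, metastasis-prone
    states; use ``marker_states(10, 1, 1)`` for the undesirable set.
    """
    tables = []
    for gene, (regs, rule) in enumerate(_MELANOMA_RULES, start=1):
        k = len(regs)
        outputs = np.zeros(2 ** k, dtype=np.uint8)
        for row in range(2 ** k):
            x = {r: (row >> (k - 1 - j)) & 1 for j, r in enumerate(regs)}
            outputs[row] = 1 if rule(x) else 0
        tables.append(TruthTable(gene, regs, outputs))
    return BNp(tuple(tables), p)
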