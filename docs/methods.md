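# Methods

## Model

A Boolean network with perturbation (BNp) on n binary genes updates
synchronously: gene i has an ordered regulator set {x_{i1} < … < x_{ik_i}}
and a truth table f_i whose row index packs the regulator values with the
first regulator as most significant bit. At each time step an i.i.d.
perturbation vector γ ∈ {0,1}^n with P(γ_i = 1) = p is drawn; if γ = 0 the
network function fires, otherwise the flagged genes flip and the function
does not fire. The one-step transition probabilities are therefore

    P(x → j) = (1−p)^n [j = f(x)] + p^d (1−p)^{n−d} [d ≥ 1],  d = Hamming(x, j),

which is row-stochastic by construction. Gene 1 is the most significant bit
of the state index throughout (files, arrays, policies). For p > 0 the
chain is ergodic; the steady state π solves π^T P = π^T and is computed by a
direct dense linear solve with one balance equation replaced by the
normalization (residual tolerance 1e-10, `NumericalError` otherwise). Power
iteration exists in the test suite only, as an independent oracle. State
spaces stay ≤ 2^10 (plus a context factor for multi-context networks), so
dense linear algebra is deliberate; nothing here scales past ~15 genes, at
which point state-space reduction would be required and is out of scope.

A probabilistic Boolean network (PBN) is a family of BNp contexts with
switch probability q and selection distribution c. The joint chain lives on
(context, GAP) pairs, indexed context-major. Convention: the context is
resampled *before* the GAP update of a step (kept with probability 1−q,
redrawn from c otherwise — a redraw may re-select the current context), and
the GAP then moves by the new context's row. The within-step ordering is a
modeling convention; with the reversed order the joint chain differs but
the single-context case (the only one used by the experiments) is
unaffected, reducing exactly to the BNp matrix.

`BNp` accepts p = 0 so that noise-free trajectories can be simulated and
tested; the steady-state solver will (correctly) refuse the resulting
reducible chains unless the deterministic map happens to be ergodic.

## Intervention (MSSA)

The control action flips one designated control gene: action 1 in state x
replaces x's row of the transition matrix by the row of x with the control
bit toggled. Over stationary policies υ : state → {0,1}, the objective is
the steady-state shift Δπ_U(υ) of undesirable mass. The optimum over all
policies (an optimal stationary deterministic policy exists because every
policy's chain is ergodic when p > 0) is characterized by the
occupation-measure linear program

    max Σ_{s∈D, a} ν(s,a)   s.t.   Σ_a ν(j,a) = Σ_{s,a} ν(s,a) P_a(s,j) ∀j,
                                   Σ ν = 1,  ν ≥ 0.

Two solvers are provided. `solver="lp"` hands this program to HiGHS and
reads the policy off the occupation measure (argmax over actions, ties to
no-op). The default, `solver="policy-iteration"`, runs Howard policy
iteration on the equivalent average-reward dynamic program: each step
solves the gain/bias system (I − P_υ)h + g·1 = r with h(0) = 0 (one dense
solve) and improves greedily with a 1e-10 improvement margin, keeping the
incumbent action on ties. Policy iteration is block pivoting between the
deterministic-policy vertices of the same LP and terminates at the same
optimum; it is the default because general-purpose simplex on this highly
degenerate program needs thousands of iterations on a fully dense
1024-state constraint matrix (the perturbation kernel connects every state
pair), while policy iteration converges in a handful of dense solves. The
two solvers and an exhaustive policy-enumeration oracle are asserted to
agree on small instances in the test suite.

Whatever the solver reports, the extracted policy is re-evaluated exactly
(row-replacement matrix + steady-state solve), and the reported shift comes
from that re-evaluation; a >1e-6 disagreement with the solver objective
raises instead of returning silently.

## Random-network generator

The generator emulates sparse regulatory topologies and is the data source
for every ensemble experiment; its defaults are the experiment conditions,
not knobs. Per gene: in-degree k ~ Uniform{1..K} (mean connectivity 2 at
K=3, 3 at K=5), regulators a uniform k-subset of all genes (self-loops
allowed — the melanoma network contains one), and truth-table bits i.i.d.
Bernoulli(b) with one bias b per gene drawn from Beta(α, β) with mean 0.5
and sd 0.01 (α = β = 1249.5 by method of moments). Drawing one bias per
gene (rather than per table row or per network) is the most natural reading
of bias-driven table filling; at sd 0.01 the distinction is numerically
almost invisible. Defaults n=7 or 9, K=3 or 5, p=0.01.

Structure and table bits come from seed streams spawned from one root seed,
so a network's wiring is reproducible independently of how much data is
later simulated from it. Time series follow the exact BNp mechanism (draw
γ; flip or fire); M counts observed transitions, by default in one series
of M+1 states, optionally split evenly across several series since the
inference algorithms accept several series and never count transitions
across a series boundary.

What the generator does *not* emulate: measurement noise beyond the model's
own perturbation, continuous expression levels and their binarization,
scale-free or curated topologies, and unequal gene-wise noise. Passing
ensemble tests therefore says the algorithms behave as claimed *within the
model class the data came from*, not that they survive real microarray
preprocessing.

## Inference

All five algorithms share one deterministic search: regulator subsets of
size 1..K per target gene, enumerated by increasing size and
lexicographically within a size, scored from the empirical transition
counts; strict improvement is required to displace the incumbent, so the
sparsest, lexicographically first optimum wins (the "most sparse solution"
tie-break made reproducible). Fitted tables take the majority next-value
per observed input pattern (ties → 0); patterns never observed are filled
with the gene's overall majority next-value (ties → 0), and the number of
filled rows is recorded per gene so experiments can audit how partially
defined the fitted functions were. The inferred network inherits the
assumed p; p itself is never inferred.

Scores:

* **Best-Fit**: Σ_w min(n0(w), n1(w)), the minimum number of transitions any
  Boolean function on the subset must misclassify.
* **REVEAL**: accept the first subset whose plug-in mutual information with
  the target's next value reaches the target's entropy within ε = 1e-9 bits
  (in-sample consistency, i.e. conditional entropy ≤ ε); if no subset of
  size ≤ K qualifies, fall back to the size-K subset of maximal mutual
  information.
* **BIC / MDL**: data bits M·Ĥ(target′ | subset) plus λ times a model
  length — k·log2(n) + 2^k for MDL (regulator identities plus table bits),
  (2^k/2)·log2(M) for BIC — with λ = 0.3 and 0.5 respectively, the weights
  reported to work well for this model class. The absolute cell values of
  any published comparison table depend on coding-length constants that
  differ between implementations; this package reproduces trend-level
  behavior, not specific table cells.
* **uMDL**: the normalized-maximum-likelihood code length
  Σ_w [m_w·Ĥ_w + COMP(m_w)] + log2 C(n,k), where COMP(m) =
  log2 Σ_j C(m,j)(j/m)^j((m−j)/m)^{m−j} is the Bernoulli NML parametric
  complexity (computed in log space; COMP(0)=0) and the log2 C(n,k) term is
  the cost of stating which genes are the predictors. The structure term
  carries no weighting parameter; without it a one-part code pays nothing
  for naming predictors and inflates the predictor sets precisely in the
  small-sample regime where the NML code is supposed to be conservative.

## Validity semi-metrics and experiments

μ_ham is the adjacency Hamming distance, normalized by the true network's
edge count in reports; μ_ss the L1 distance between steady states; μ_ctrl
designs MSSA policies on the inferred and the true network, applies *both*
to the true network, and reports the excess undesirable mass of the
inferred-network policy — nonnegative by the optimality of the true-network
policy, and zero exactly when the two policies agree on the recurrent mass.

`run_experiment` follows the single-sample protocol: per replicate network,
one simulated series per sample size M, every algorithm applied to the same
series, all metrics computed against the generating network; means and sds
are taken across networks. The ensemble defaults put the marker on gene 1
(undesirable when down-regulated) and control on the last gene.

The melanoma network ships as code (10 genes, WNT5A PIR S100P RET1 MMP3
PLCG1 MART1 HADHB SNCA STC2, most to least significant bit; p = 0.01;
undesirable = WNT5A up). Its baseline undesirable mass (0.2073) and the
optimal shifts for all ten control genes are exercised to 4 decimal places
in the acceptance tests, and `scripts/acceptance.py` recomputes them
together with the random-ensemble averages at the published ensemble sizes
(1000 networks for n=7, 200 for n=9 — the n=9 count keeps the 512-state
policy optimizations cheap while leaving the standard error of the mean
near 0.025).

## Numerical choices and limitations

* Steady-state residual tolerance 1e-10; TPM row sums asserted to 1e-12.
* Policy-improvement margin 1e-10; occupation-measure ties → no-op; both
  choices make reported policies reproducible bit-for-bit.
* NML complexity via `logsumexp`, stable for the sample sizes used here
  (hundreds of transitions); complexities are cached per sample count.
* Subset search is exhaustive over C(n,k) subsets, k ≤ K; practical for the
  n ≤ 10, K ≤ 5 regime the model targets and exponential beyond it.
* Trend-level assertions (improvement with sample size, sparsity ordering)
  are made on seeded ensembles of 60–200 networks with a one-standard-error
  slack; individual-network behavior varies widely (sds of the same order
  as the means are normal here).
* Multi-context chains get a transition matrix and steady state; control
  and inference operate on single-context networks only.
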