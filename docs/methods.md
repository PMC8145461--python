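# Methods

## Model

The package simulates a three-stage gene expression cascade in discrete
time. Molecule levels are real-valued concentrations, not integer counts:
the model describes the net change of pre-mRNA, mRNA and protein over a
fixed reporting interval δ, not individual reaction events. While the gene
state i is constant, one step is the linear map

    ξ₁ ← R·i + a·ξ₁,   ξ₂ ← C·ξ₁ + b·ξ₂,   ξ₃ ← P·ξ₂ + c·ξ₃,

with retention factors a = 1−C−μ_PR, b = 1−μ_R, c = 1−μ_P. Admissibility
(`KineticParams` validation) demands all rates positive and
0 < C+μ_PR < 1, 0 < μ_R+P < 1, 0 < μ_P < 1 — one step cannot degrade or
convert more material than is present. The bound on μ_R+P is enforced as
stated even though only μ_R enters b; it is the natural per-step mass
constraint on the mRNA pool.

Because the step is affine with diagonalizable linear part, the
constant-gene solution splits into geometric modes: coordinate k at time t
is Σ_m coef_{k,m}·r_m^{t/δ} + w_k·i with r = (a, b, c) and w the
active-gene steady state (R/(C+μ_PR), RC/((C+μ_PR)μ_R),
PCR/((C+μ_PR)μ_R μ_P)). `mode_decomposition` evaluates the closed-form
coefficients; `flow` accepts any real t ≥ 0 (the geometric interpolation of
the integer-step orbit), while `step` is integer-only. The internal clock
is the integer step index; physical time t = n·δ is formed only at the I/O
boundary, avoiding floating-point drift in long runs.

Repeated retention factors (a=b, b=c or c=a) would need confluent
polynomial-times-geometric modes; such parameter sets are rejected with
`DegenerateParameterError` (pairwise-distinctness tolerance 1e-12) rather
than handled specially. The gene-state timing convention is fixed: the
update producing the state at t+δ uses i(t), so a switch recorded at t
first affects molecule levels at t+δ.

A triangular linear change of variables (exact as written in
`_reduction_matrix`) turns both gene states into the diagonal affine
contractions S_i(x) = diag(a,b,c)·x + u·i with
u = (1/((a−c)(a−b)), 1/((b−a)(b−c)), 1/((c−a)(c−b))). Both maps are
Lipschitz with constant max{a,b,c} < 1; S₀ fixes the origin and S₁ fixes
v = u/(1−a, 1−b, 1−c). All attractor and measure work happens in these
reduced coordinates; `from_reduced` maps results back for overlay with
biological trajectories.

## Switching semantics

Two random-switching mechanisms are first-class and clearly labelled in
trajectory metadata:

* **Per-step place-dependent probabilities** (`simulate_ifs_process`): at
  each step the next gene state j is drawn with probabilities p₀(x), p₁(x)
  evaluated at the current point, before moving; the draw is independent of
  the current gene state. This is the semantics behind the
  invariant-measure theory and the canonical stochastic run (rates as in
  the worked example, p₀(x) = 1/(2(1+|x|²)), start (1/2,1/2,1/2)).
* **Intensity-driven jump times** (`simulate_jump_process`): in gene state
  i started at x₀ the switch time has survival function
  Φ(t) = exp(−Σ_{s=0}^{⌊t⌋−1} q_i(π_i(s, x₀))) — the discrete analogue of
  the exponential-of-integrated-hazard law, with the sum over the orbit
  replacing the integral. Jump times are sampled by exact inverse CDF on
  the integer grid: draw U, accumulate the hazard along the orbit, return
  the first n with the sum ≥ −log(1−U); a jump is always ≥ 1 step. A
  sampled jump beyond the simulation horizon is censored (no switch this
  run) — this equals restricting the inverse-CDF search to the steps
  actually simulated. At a jump step the molecule state is the flow
  endpoint of the finished segment and the gene index already carries the
  flipped value.

The exact product-form survival Π(1−q(π(s,x₀))) is kept alongside the
exponential form (`survival_product` vs `life_span`); they agree to first
order in q, with |difference| ≲ t·q_max². The two semantics are linked by
`switch_rule_from_intensities`: telescoping the product form gives the
per-step rule "leave state i with probability q_i(x)", which reproduces the
product-form jump law exactly. Note the mismatch this exposes: the bridged
rule depends on the current gene state whenever q₀ ≠ q₁, whereas the
per-step semantics is gene-state independent by construction. No exact
q↔p correspondence exists in general; the bridge is the only relation
derivable from the telescoping identity, and trajectories flag
`gene_state_dependent` in their metadata. Biologically a switch probability
that ignores whether the gene is currently on is odd; it is implemented as
specified for the per-step semantics, with the intensity semantics
available when distinct on/off hazards matter.

Intensity and probability functions are supplied as named built-ins
(constant; the inverse-quadratic p₀(x) = scale/(1+|x|²); a logistic in
|x|²) or as restricted arithmetic expressions vetted by an AST whitelist —
no arbitrary code execution. Claimed bounds (q_max, the uniform lower
probability bound δ₀) are spot-checked at construction on a 1024-point
Sobol sample of the invariant box; violations warn rather than raise,
since the asymptotic hypotheses are the user's responsibility.

## Invariant measure and diagnostics

The per-step process induces the transition kernel
P(x,B) = p₀(x)1_B(S₀x) + p₁(x)1_B(S₁x); `markov_operator_T` and
`pushforward_F` implement its two adjoints on test functions and on
finitely supported measures. Push-forward of a point mass enumerates the
2ⁿ composition words exactly when pruning is disabled; the default pruning
threshold 1e-12 (of total mass, with renormalization) keeps long
push-forwards tractable.

With choice probabilities bounded below by some δ₀ > 0 and Hölder
continuous, the process has a unique attracting invariant measure whose
support is the IFS attractor. The package verifies the *behavior*, not the
hypotheses: `estimate_invariant_measure` takes equal-weight occupation
statistics of a post-burn-in orbit, and `energy_distance` (unhalved
convention, 2E|X−Y|−E|X−X'|−E|Y−Y'|; two point masses at x,y are at
distance 2|x−y|) compares estimates launched from distant starts. Energy
distance was chosen over Hausdorff distance because it metrizes weak
convergence of distributions on the bounded invariant box, is cheap to
estimate from weighted samples (pairwise distances, chunked to bound
memory), and distinguishes differently weighted measures with equal
support. The convergence diagnostic reports the distance at occupation
sizes (10², 10³, 10⁴) and passes when strictly decreasing; the decay mixes
the O(1/n) transient contribution with O(n^{-1/2}) Monte-Carlo noise, so
occasional non-monotonicity at close sizes would indicate noise, not
divergence.

Mode-count inspection of marginal histograms (possible bimodality of the
stationary law) is deliberately left as a visual diagnostic with no
pass/fail contract; no reliable criterion is available.

## Attractor geometry

Composing the real-time reduced flows shows that every state reachable
after two switches from the anchor points (v for a start in the off state,
the origin for a start in the on state) lies in the solid

    A = { v ⊙ (x − y + z,  x^eb − y^eb + z^eb,  x^ec − y^ec + z^ec)^T
          applied coordinate-wise : 1 ≥ x ≥ y ≥ z ≥ 0 },

with exponents eb = log_a b, ec = log_a c and the convention 0^e := 0
(continuity of t ↦ t^e on [0,1]). The complementary parametrization with
1 − x + y − z is exactly v − A = A: the solid is symmetric through v/2.
Its boundary is the pair of one-switch surfaces A₀ (the z = 0 slice) and
A₁ (the x = 1 slice), reflections of each other through v/2.
`two_switch_state` implements the three-segment composition in closed form
for either starting gene state.

The chaos game and all simulated orbits are integer-time objects; the
integer-time attractor is a discrete subset of the real-time solid A, so
membership testing against A is the right containment check for both.

**Membership is sample-based.** Inverting the parametrization would mean
solving three coupled monotone power equations; instead `attractor_cloud`
evaluates the parametrization on a deterministic grid of the ordered
simplex and `membership` reports the scaled nearest-neighbor distance.
Two numerical choices matter:

* *Warped grid levels.* t ↦ t^e with e < 1 has unbounded slope at 0, so a
  uniform simplex grid leaves large image gaps near the origin. Levels are
  taken as (k/n)^{1/e_min} with e_min = min(1, eb, ec), which bounds every
  coordinate's image increment by O(1/n).
* *Per-axis scaling.* The attractor's extent differs by orders of
  magnitude across coordinates (48 vs 192 vs 216 for the canonical
  factors). Distances are measured after dividing each axis by the grid's
  largest image increment on that axis, so "distance 1" means "one grid
  cell" uniformly. The default tolerance is 3 grid units with the default
  101 levels per axis (≈ 176,000 cloud points); a tolerance at or below 1
  grid unit triggers a warning since false negatives become likely.

The Hutchinson set iteration deduplicates points on a uniform grid
(default 1e-4 in reduced coordinates) purely to bound the 2ⁿ growth;
convergence is in the Hausdorff metric, which the deduplication perturbs
by at most the grid diagonal. The chaos game defaults to a burn-in of 10³
steps: the maps contract by max{a,b,c} per step, so the initial condition's
influence after burn-in is below (3/4)^1000 for the canonical factors —
far below any tolerance used.

## Problem sizes and determinism

Default problem sizes were chosen so each check is decisive for its claim:
100,000 chaos-game points (the canonical attractor figure's count),
10,000-step stochastic runs for box invariance and occupation measures,
10,000 Monte-Carlo repetitions for the jump-count bound at hazard 0.1 and
horizon 20 (bound e² ≈ 7.39 against an empirical mean near 1.8, standard
error ≈ 0.01). Every stochastic routine takes an explicit
`numpy.random.Generator` or integer seed; identical (config, seed) pairs
produce byte-identical CSV output.

## What the tests do and do not show

The synthetic configurations exercise the model exactly as specified —
they are the model, not data: there is no measurement noise, no integer
molecule discreteness, no cell-to-cell parameter variability, and rates
are constant in time. Passing tests therefore certify the mathematical
behavior of the implementation (exact closed forms, invariance, symmetry,
convergence diagnostics), not agreement with any experimental expression
data. Parameter inference from data, chemical-master-equation semantics,
and continuous-time simulation are out of scope; so are the degenerate
parameter cases excluded above, whose limiting behavior is an open
question.
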