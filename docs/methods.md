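# Methods

## Model and procedure

The substrate is a constraint-based metabolic model: stoichiometric matrix
`S` over internal (non-boundary) metabolites, per-reaction flux bounds in
mmol·gDW⁻¹·h⁻¹, and a single-reaction objective.  All analyses operate on
the optimal face

```
F(γ) = { v : S·v = 0,  v_min ≤ v ≤ v_max,  γ·z* ≤ fᵀv ≤ z* }
```

where `z*` is the FBA optimum and γ ∈ (0, 1] the optimality fraction
(γ = 1 is the exactly optimal face; 99.9% is the customary relaxation when
a model sits numerically at the edge of feasibility).  Because the
objective is a single reaction, the γ-window is implemented as that
reaction's bounds during FVA, so fixing the objective (lb = ub) and
γ-relaxation are one mechanism: γ = 1 reproduces exact fixing.  For a
negative optimum the window is `[z* − (1−γ)|z*|, z*]`, preserving the
"within (1−γ) of optimum" meaning; for a minimization objective it is
mirrored above the optimum.

The perturbation procedure: determine variable reactions by FVA (interval
width > θ), then fix each variable reaction at `k` uniform random values
inside its own FVA interval (one reaction at a time, all other bounds
untouched) and re-solve.  Each successful re-solution is a genuine member
of `F(γ)` with the same objective value, so the sample set is a cheap,
non-exhaustive probe of the alternate-optima space — by design it measures
the *reachability* of alternative flux combinations, not their probability
density (contrast Monte-Carlo/CHRR samplers, which need orders of magnitude
more points).

Classification per reaction `r` with reference flux `v_ref(r)` (one FBA
solution of the unperturbed model):

- **variable** — FVA width > θ (default 10⁻⁶); otherwise **stable**;
- **sensitive** — variable, and in ≥ 1 optimal sample
  `|v_s(r) − v_ref(r)| > δ·|v_ref(r)|` (δ default 0.05), with the absolute
  threshold 10⁻⁶ replacing the relative one when `|v_ref(r)| ≤ 10⁻⁶`;
- **robust** — variable but never responding;
- **undetermined** — an FVA direction failed; excluded from both classes.

A reaction's own fixing counts toward its sensitivity by default
(`include_self`): a wide FVA interval means the reaction itself can take
values far from its reference.  Reversals are strict sign flips with both
magnitudes above 10⁻⁶, reported as a percentage of sensitive reactions.
The per-sample distribution is the single FBA solution (`mode="fba"`,
default) or the midpoints of a per-sample FVA (`mode="fva"`); both are
supported because the frequency-type statistics are known to be
solver-sensitive, while the classification itself is not.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `k` | 10 | samples | draws per variable reaction |
| `delta` | 0.05 | relative | sensitivity threshold (±5%) |
| `zero_threshold` | 1e-6 | flux | response threshold at zero reference |
| `theta_var` | 1e-6 | flux | variable/stable width threshold (1e-3 as the coarse second threshold in ladder reports) |
| `gamma` | 1.0 | fraction | FVA optimality window |
| rate tolerance | 0.20 | relative | ±20% band around measured exchange rates |
| bound cap | 1000 | flux | infinity proxy; readers clamp and warn |
| relaxation ε | 0.05 | flux | bound nudge that restores feasibility slack |

Constraint integration applies medium bounds, then measured-rate bands
(endpoints sorted so the formula is correct for negative uptake rates),
then proteome-absent closures (lb = ub = 0), then explicit fixings; later
steps override earlier ones and every override is logged.  The precedence
is this package's convention — the cumulative protocol it models does not
state one — and is deliberately "most specific last".

## Numerical choices

One LP solver is pinned (HiGHS via `scipy.optimize.linprog`) with primal
and dual feasibility tolerances of 10⁻⁹, because variable/sensitive counts
measurably differ between solvers; determinism of a study is then exact
(same model + seed ⇒ byte-identical report).  Per-direction FVA failures
are recorded as data (`status_min`/`status_max`), never raised: failed
optimizations at an exhausted constraint are the diagnostic signature of
the feasibility edge, and the scan flags a grid point when any FVA
optimization fails there *or* its variable count falls below half the
median of the interior points (the latter heuristic catches exact-LP cases
where the face collapses to a point without numerical failure).

The flux-module partition computes the null space of `[S; fᵀ]` restricted
to variable-reaction coordinates (stable coordinates forced to zero),
canonicalizes the basis by reduced row echelon form with entries below
10⁻⁹ zeroed — without canonicalization the support pattern would depend on
an arbitrary basis choice — and joins reactions that co-occur in any
canonical vector's support.  This summarizes the face's degrees of freedom
in the spirit of vertex/ray/lineality decompositions but does not
enumerate vertices, so module counts are not comparable to tools that do.

Degenerate inputs: a degenerate sampling interval returns `k` copies of
its endpoint with a warning; a branch sample whose total consumption of
the focus metabolite is ≤ 10⁻⁹ gets undefined fractions; production at a
branch is clipped to zero (consumption splits only, |s|-weighted so
fractions measure metabolite fate); an empty variable set yields an empty
study with a warning, not an error.

## Synthetic fixtures and what they show

The fixture generators produce networks whose optimal-face geometry is
known in closed form, each verified against an independent brute-force
oracle that enumerates polytope vertices by fixing coordinate subsets at
their bounds (exact for bounded polytopes, capped at 12 reactions):

- **chain** — unique optimum; the null case (0 variable reactions);
- **diamond** (n parallel paths) — minimal alternate-optima face: 2n path
  reactions with intervals [0, uptake], one module, an n-way branch point;
- **double diamond** — two independent modules of four; fixing a reaction
  in one leaves the other's intervals unchanged;
- **ATP toy** — two fermentation routes of different ATP yield with a
  maintenance drain; with the objective fixed at z the feasible
  maintenance interval is [0, yield_high·uptake − z] and at its right
  endpoint every flux is forced: the edge-of-feasibility collapse in
  miniature, curable by relaxing the uptake bound by ε.

Default study sizes on these fixtures (k = 10, 4–8 variable reactions,
scans of ~6 grid points; 10,000 draws / 10,000 pooled histogram values for
the distributional checks) keep every analysis exact or
sampling-error-free at the tolerances tested while running in seconds.

These fixtures are deterministic, loop-free and tiny; they exercise the
machinery exactly but do not emulate properties of real genome-scale
models — thermodynamically infeasible loops, nested/overlapping modules,
numerically ill-scaled bounds, or objectives coupling hundreds of
reactions.  Passing tests therefore certify the algorithms and their edge
handling, not organism-specific conclusions; applying the pipeline to a
published SBML model is supported (SBML L3 + FBC reader with the ±1000
clamp) but requires that external model as input.

One statistical subtlety is baked into the tests rather than the library:
on the two-path diamond each uniform draw v produces path fluxes
{v, v, u−v, u−v}, so the pooled 20-bin position histogram is exactly
mirror-symmetric with four-fold duplicated placements.  A naive χ²
against a flat multinomial is miscalibrated (~4× inflated) on perfectly
uniform data; the tests fold the histogram (each draw then fills exactly
one folded cell) to obtain a proper null.

## Known limitations

- The reference distribution is one arbitrary optimal vertex; sensitivity
  counts depend on it in principle.  Determinism pins it; a user-supplied
  reference is accepted by `classify_sensitivity`.
- `mode="fva"` costs one full FVA per sample and its midpoint vector is
  generally not itself a feasible flux distribution (it is a per-reaction
  summary); it exists for comparability of frequency statistics.
- The module partition treats near-zero null-space entries (< 10⁻⁹) as
  structural zeros; pathological scaling could merge or split modules.
- Gene–protein–reaction logic is out of scope: proteome absence must
  already be mapped to reaction ids.
- The brute-force oracle is combinatorial and refuses models with more
  than 12 reactions; it is a test instrument, not an analysis tool.
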