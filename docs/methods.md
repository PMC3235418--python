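# Methods

## Scope and data model

`fuzzygrn` infers directed regulatory relationships among genes — and from
genes to a scalar cellular phenotype — from a short expression time course,
and simulates the consolidated network to predict knockout viability.  The
working currency is an `ExpressionDataset`: a genes × time matrix of log2
expression ratios (NaN marks missing spots), strictly increasing time
points in minutes, and an optional phenotype track (fraction of budding
cells, in [0, 1]).  Upstream microarray preprocessing (background
correction, between-array normalization) is out of scope; the pipeline
starts from log2 ratios.

## Transforms

* Gene scale: x = arctan(log2)/(π/2), strictly inside (−1, 1); inverted by
  tan(x·π/2).  The arctangent gives a symmetric, outlier-tolerant
  compression with no tuned parameters.
* Phenotype scale: defuzzified predictions in [0, 1] are pushed through the
  logistic 1/(1+exp(−C(2x−1))) with steepness C = 6, centered so that
  0.5 ↦ 0.5.  The logistic undoes the sigmoidal bias that the arctangent
  introduces on the gene side and spreads predictions over (0, 1).
  Observed phenotype values are used as-is for fitting (the phenotype is an
  output, so it is never forward-fuzzified); the inverse logistic is used
  only to seed simulations from observed fractions.
* Missing expression values are dropped listwise at fit time, over the
  union {output ∪ candidate inputs}, so every model for one output is
  scored on the same time points and CODs stay comparable.  No imputation.

## Fuzzy algebra

Three triangular membership sets (low/medium/high) with apexes at −1/0/+1
(genes) and 0/0.5/1 (phenotype).  Fuzzification of a single value yields a
triple summing to exactly 1.  An edge's rule vector (r₁,r₂,r₃) ∈ {1,2,3}³
selects which input set drives each output set; all 27 vectors are
admitted, including degenerate ones.  Multiple inputs combine by
componentwise addition (algebraic-sum OR); the simplified centroid
(z₃−z₁)/(z₁+z₂+z₃) — or (0.5z₂+z₃)/Σz for the phenotype — renormalizes
implicitly, so combined triples are never pre-scaled.  With this design
defuzzify∘fuzzify is the identity to machine precision, and the monotone
rules (1,2,3)/(3,2,1) reproduce linear activation/inhibition exactly.

Degenerate cases are errors or sentinel scores, never silent values: an
all-zero combined triple has no centroid (it indicates an empty model), and
during model scoring any model that produces such a triple — or a centroid
of exactly ±1, whose log2 back-transform would sit on the tangent pole —
receives fitness −inf and sorts last.

## Model search

For one output, every input subset of size 1..`max_inputs` (default 5) and
every per-input rule assignment is enumerated: Σₙ C(m,n)·27ⁿ models for m
candidates.  A hard cap (default 10⁹ evaluated models) refuses infeasible
requests with an estimate instead of running them.  Fitness is the
coefficient of determination 1 − SSE/SST, computed by default on the
back-transformed scale (log2 ratios for genes, fractions for the
phenotype); `scale="normalized"` scores on the bounded scale instead, and
the two can rank models differently.

Temporal alignment is explicit: at `lag=0` inputs at time t predict the
output at t (the co-expression reading), and the output is excluded from
its own candidate pool because the identity rule would be a trivial perfect
fit; at `lag≥1` inputs at t predict t+lag and self-input is allowed, which
admits self-stimulation loops.  Ranking is fully deterministic: descending
fitness, ties broken by fewer inputs, then lexicographic input labels, then
lexicographic rule encoding.  The top-m (default 100) models per output are
retained, and the per-candidate frequency of appearance among them is the
consensus ("alternative models") table.

Homologous gene pairs are merged by configuration, not automatically: a
merged candidate "A/B" takes max(A, B) of the normalized values before
fuzzification, replacing its members in the candidate pool.  Edge signs for
export are classified from the rule's single-input response curve:
monotone increasing → positive, decreasing → negative, anything else
(including flat or partially undefined responses) → biphasic.

## Composite network and relaxation dynamics

Per-node best models are consolidated over shared nodes; nodes without a
model are pure inputs and hold their value.  The phenotype node is a sink.
The state vector lives on the bounded scale (genes in [−1,1], phenotype
carried internally as its defuzzified [0,1] value) — this avoids tangent
poles entirely during iteration.  One step applies every model
synchronously to the current state (F), then mixes:

    I[n+1] = α·F(I[n]) + (1−α)·I[n],   α = 0.01 (default)

stopping when ‖I[n+1] − I[n]‖∞ < 10⁻⁷ (default) or `max_iter` = 100 000 is
reached; non-convergence returns a flagged trajectory with a warning, not
an exception.  The conservative α trades iterations (typically a few
thousand) for smooth convergence; larger α converges faster but can
overshoot.  Identical inputs give bitwise-identical trajectories.

Knockout clamps one or two gene nodes at the low extreme −1 (the extreme
of the low membership set; the phenotype node cannot be clamped), and a
clamped node ignores its model at every step.  For merged homolog inputs
the max-merge still applies, so knocking out one member leaves the pair's
input at the surviving member's value — the mechanism behind redundancy
and synthetic lethality in the screen.

Viability is read from the converged budding fractions across many initial
conditions (each observed time point provides one): *inviable* when the
spread (max − min) falls below the arrest threshold 0.1 **or** all
fractions land on one side of the 0.5 regime boundary (cell-cycle arrest);
*viable* otherwise (the bistable high/low pattern of a cycling
population).  Both thresholds are configuration, logged with every run;
the classifier handles ≥2 regimes but is calibrated for the two-attractor
picture.  Trajectories that fail to converge are excluded with a warning;
if none converge the screen errors out.

## Synthetic data generator

The generator exists so that search, dynamics and screening are testable
without any external download, and it is built so that model recovery is a
strict self-consistency test: the data are generated by exactly the
dynamical law the inference assumes.

* **Topology.**  Two planted negative-feedback rings — 3 genes and 4
  genes, each a directed cycle with a single inhibitory edge.  Under the
  synchronous update these rings are exact isometries with sustained
  oscillations of period 6 and 8; over the default 24 columns every column
  is a distinct phase of the joint orbit (lcm = 24).  Remaining genes take
  1–2 ring inputs with rules biased 3:1 toward monotone
  activation/inhibition (the remainder drawn from saturating
  near-monotone variants); two-input genes take one input from each ring.
  These choices are identifiability-driven: lagged copies within one ring
  are near ±copies of each other, and sums of two same-ring inputs can be
  reproduced by a single decoy, so a single-ring design makes planted
  inputs observationally ambiguous.
* **Trajectories.**  The recorded columns are an exact orbit of the full
  synchronous update map, col[t+1] = F(col[t]), from a randomized start
  with well-separated ring amplitudes (≈0.33–0.87, shuffled signs).  Every
  gene's true model therefore reproduces its series exactly at lag 1, and
  the phenotype — computed instantaneously from the noise-free gene state
  through its own model and the logistic — exactly at lag 0.  Recovery
  tests and fits on synthetic data accordingly use lag 1 for genes and
  lag 0 for the phenotype.
* **Noise.**  Additive Gaussian noise (sd `noise_sd`, default 0.1) on the
  log2 scale, where microarray error is approximately additive, applied
  after the true states are laid down — mirroring the real pipeline order.
  The phenotype track is recorded noise-free.
* **Homolog pairs.**  Optional twins duplicate a driven gene's model and
  starting value, so true twin trajectories are identical and the recorded
  pair differs only by independent measurement noise.
* **Rejection.**  `generate_dataset` deterministically re-draws (salted
  from the seed) until every gene series has spread (sd ≥ 0.1 on the
  normalized scale), no two distinct genes coincide up to sign (rms margin
  0.2), and the phenotype visits both regimes.  These are validity
  conditions on identifiability, not tuning knobs.
* **Defaults.**  17 genes + phenotype over 24 time points mirror the scale
  of the motivating cell-cycle series; the recovery test bed uses 8 genes
  with in-degree ≤ 2.  The seed fully determines the draw.

What the generator does **not** emulate: array-platform artifacts (dye
bias, spatial effects), missing spots, unequal time spacing, biological
(process) noise inside the dynamics, and regulation by more inputs than
the fit allows.  Passing recovery tests therefore demonstrates internal
consistency of search + dynamics under realistic measurement noise, not
performance on real biology.  Note also that the sampled oscillator
networks, once relaxed with damped mixing, settle to the single baseline
equilibrium (genes at 0, phenotype at 0.5): sustained oscillation is a
property of the undamped update.  Bistable viability semantics are
exercised by the hand-designed `budding_switch_network`, which plants a
mutually-inhibiting memory pair, an essential activator, a redundant
(synthetic-lethal) homolog pair, and a pathway-free reporter gene.

## Numerical choices

* Search scoring is vectorized over all 27² rule assignments of the last
  two inputs at a time; earlier inputs are looped, bounding memory for
  5-input subsets.
* Per-subset ranking uses a stable argsort so rule-vector ties resolve
  lexicographically; the global merge re-sorts under the full deterministic
  key.  The production ranking is cross-checked model-for-model against an
  independent scalar enumerator in the test suite.
* Relaxation uses scalar arithmetic compiled per network (the per-node
  fuzzy chain in plain floats); the scalar and array fuzzification paths
  are property-tested for exact agreement.
* Round-trip identities hold to 1e−10 over dense grids; reference values
  in tests were computed independently (high-precision arithmetic or by
  hand) before being frozen.

## Known limitations

* The exhaustive search is exponential in `max_inputs`; practical use
  stays at ≤ 5 inputs (and fewer for large candidate pools).  No
  significance statistics are attached to COD values.
* At lag 0, exact recovery of a feedback network from its own trajectory
  is impossible in principle (only fixed points satisfy all instantaneous
  relations simultaneously); lag-0 fitting reads co-expression, lag-1
  fitting reads the update map.
* Consensus dominance of true inputs degrades as the candidate pool grows:
  with many driven genes the top-100 tables become diffuse, matching the
  qualitative behavior of consensus heat maps on real data.
* The viability classifier reduces a trajectory ensemble to one spread
  statistic and a regime count; graded fitness phenotypes are out of
  scope.
* Synchronous deterministic updates only; no asynchronous or stochastic
  schemes, and no posttranscriptional regulation.
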