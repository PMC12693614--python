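# Methods

## Model

The crown is an idealized, perfectly balanced binary tree of depth `D`.
Internode segments are addressed by `(level s, index i)` with `0 ≤ i < 2^s`;
the continuation child of `(s, i)` is `(s+1, 2i)` and the lateral child is
`(s+1, 2i+1)`. The model fixes no embedding, so any consistent convention is
equivalent; with this one a tip's binary address records the lateral turns
on its path, the leftmost descendant of a segment is its main-axis tip, and
every lateral subtree occupies a contiguous tip-index block — which is what
makes the simulator's bookkeeping O(1) per draw. Branch orders (main axis
vs. lateral derivatives) are the popcount of the segment index. The root
below the crown base is not materialized as a separate edge: the basal
segment `s = 0` carries it, since every formula indexes segments `0..D`.

Total developmental time `T` (years, or cell divisions — any unit consistent
with `mu`) is distributed over the `D+1` levels by an exponential tilt,
`w_s(λ) = e^{λs} / Σ_r e^{λr}`. Weights are computed as a max-shifted
softmax so that `|λ|·D` up to several hundred cannot overflow; the infinite
limits are represented by the explicit sentinels `"stick"` and `"star"`
rather than large floats, because they are exact regimes (one-hot weight
vectors), not approximations. `±inf` inputs are mapped to the sentinels;
NaN is rejected.

Each of the `m` apical stem cells per meristem layer mutates as a Poisson
process with rate `2·G·mu` (haploid genome size `G`, diploid factor 2). At
each of the `B_s = D − s` lateral branch points above a segment, exactly one
of the `m` lineages founds the new meristem; the terminal organ adds one
more uniform draw. All burden expectations follow from the two shorthand
probabilities `q_s = 1 − (1 − 1/m)^{B_s}` and
`p_det(s) = 1 − (1 − 1/m)^{B_s+1}`; powers of `(1 − 1/m)` are evaluated via
`exp(k·log1p(−1/m))` to keep large-`k` products accurate, with `m = 1`
special-cased exactly.

The unique-burden prefactor is `2·G·mu·m·T`: each level supplies
`2^s · m · 2Gμ t_s` Poisson events and uniqueness keeps every event that is
detected anywhere, with no 1/m thinning (thinning applies only to the
per-tip count, where the terminal draw selects one lineage). This reading
is validated rather than assumed: the simulator's expected unique count is
`Σ_s 2^s (m·2Gμ t_s) p_det(s)` by construction, and the acceptance suite
confirms agreement on a 12-cell grid; the `m = 1` stick case correctly
reduces to `2GμT`.

## Simulator

One replicate: (1) allocate segment times by the tilt; (2) draw a Poisson
count of mutation events per segment with mean `m·2Gμ·t_s`; (3) give each
event independent Bernoulli(1/m) draws at its `B_s` lateral bottlenecks and
the terminal founder. A lateral success fixes the mutation in the entire
lateral subtree (a contiguous tip block); the terminal success adds the
main-axis tip. ASC identity is not tracked in the default `per_mutation`
mode because draws are exchangeable with per-event success 1/m, and timing
within a segment never enters any expectation. Along the continuation axis
the mutant remains exactly one of `m` lineages (no drift between branch
points); tips inside a fixed lateral subtree undergo no terminal draw, since
the whole meristem there is mutant.

The alternative `shared_founder` mode draws one founder label per branch
point per replicate, shared by all co-segmental events, and compares it with
each event's own ASC label — the more mechanistic reading. The two modes
coincide in expectation (both are tested against the closed forms);
replicate-level variances may differ and are not characterized analytically,
so no variance assertions are made beyond confidence-interval behavior.

Polyclonal founding (`founders_per_branch = k > 1`) realizes lateral entry
in two stages — mutant among the `k` sampled founders with probability
`k/m`, then surviving within-meristem drift with probability `1/k` — leaving
the net entry probability at 1/m; the acceptance suite checks that unique
burden means for `k ∈ {1,2,3}` at `m = 5` agree within Monte Carlo error.
The two-stage draw is defined per event, so it is only available in
`per_mutation` mode.

Randomness uses one root seed with `SeedSequence` spawn keys per replicate
(and per grid cell / per layer where applicable), so outputs are
bit-reproducible and replicate `r` is invariant to the total replicate
count. Statistics kept per replicate are the unique count, the total tip
occurrences, the event total and the mean per-tip burden; full per-tip
vectors are materialized (via a difference-array accumulation) only on
request and only for `D ≤ 16`, and per-event tables only for fixture-sized
runs.

## Layer model

The three SAM layers share the architecture, `G` and `m` but may have
different rates `mu_k`; bulk tissue mixes them in fractions `alpha_k`
(summing to 1), so a layer-k mutation sits at allele frequency `alpha_k/2`.
Detection is an all-or-nothing indicator `alpha_k ≥ 2·phi` (boundary
inclusive) — a layer-level visibility model, not a read-sampling model;
read-depth noise is outside scope. Layer event sets are simulated as
disjoint processes: independent recurrence of the same site in two layers
has negligible probability under the Poisson model and is not merged.

## Statistical checks and defaults

Theory-vs-simulation grids flag a cell when the z-score of the replicate
mean against the closed form exceeds 4 (not 1.96): across 12+ cells a
nominal 5% test would routinely false-alarm, and the claim under test is
agreement of means, not a calibrated size. Empirical 95% intervals are the
2.5/97.5 replicate quantiles; standard errors use `ddof = 1`.

Default study conditions: `G = 4e8` bp and `mu = 5e-10` per base per year —
representative of a temperate tree genome and per-year somatic rate — over
`T = 25` years, giving `2GμT = 10` mutations per root-to-tip path, which
puts grid expectations at O(10–10^4) where 300 replicates resolve means
tightly. Validation grids use depth 10 with `m ∈ {1,3,5,10}` and
`λ ∈ {−5,0,5}`, 300 replicates; invariance checks use depth 8. Fold-change
tables default to `λ ∈ [−5, 5]` in steps of 0.5 and `D ∈ {1..12}` (display
defaults, not model constraints). Fixtures are capped at depth 6 so the
materialized event and tip tables stay small.

## What the generator does and does not emulate

The synthetic crowns are exactly the model's idealization: balanced, binary,
with level-homogeneous segment durations and a single effective meristem
layer per simulation. Passing tests therefore demonstrate internal
consistency of formulas and simulator — they do not validate the model
against real trees, whose crowns are unbalanced and non-binary, whose branch
points may sample founders non-uniformly, and whose mutation supply may vary
with age. Epimutations fit the same machinery with a higher rate, but
reversion over very long timescales is ignored. Estimating `G`, `mu`, `m`,
`λ` or `alpha_k` from sequencing data, selection among mutant lineages, and
within-meristem spatial geometry are out of scope.

## Numerical and degenerate cases

`depth = 0` is a single basal-and-terminal segment with one tip and
`B_0 = 0`; `mu = 0` yields empty replicates everywhere; `m = 1` makes every
draw succeed, so the unique count equals the Poisson event total exactly and
every event fixes its origin's whole subtree (both asserted, not just in
expectation). Weight vectors satisfy `Σ w_s = 1` to 1e−12 across
`λ ∈ [−50, 50]`, `D ≤ 14`; tilts of magnitude `50·(D+1)` agree with the
sentinel vectors to 1e−9. Ties at the detection boundary
(`alpha_k = 2·phi`) count as detected.
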