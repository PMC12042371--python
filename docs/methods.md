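# Methods

## The process being modelled

The state of a lineage is its geographic range: a non-empty subset of
`n` discrete operational areas, capped at `max_range_size` areas (the
shipped Magnoliaceae configuration uses ten areas and a cap of two,
giving 1 + 10 + 45 = 56 states including the empty range). The empty
(null) range is a valid interior state of the Markov process — a lineage
can lose its last area along a branch and is then dead — but never a
legal observation, because sampled tips are extant. The null range is
absorbing: there is no resurrection.

**Anagenesis** (along branches) is a continuous-time Markov chain with
generator `Q` over the range states. Range `R` gains an unoccupied area
`k` at rate `d · Σ_{a∈R} m[a,k]` — every occupied area is a potential
source, weighted by the dispersal-multiplier matrix `m` of the current
time stratum — and loses any one occupied area at rate `e`. Extirpation
is a single shared per-area rate, unmodified by multipliers, because the
scenarios vary only dispersal. Gains that would exceed the range-size
cap are forbidden.

**Cladogenesis** (at nodes) partitions the ancestral range between the
two daughters. Events and their fixed weights per family:

| event | daughters | DEC | DIVALIKE | BAYAREALIKE |
|---|---|---|---|---|
| narrow sympatry (singleton ancestor) | (A, A) | 1 | 1 | 1 |
| range copy (wider ancestor) | (R, R) | – | – | 1 |
| subset sympatry | (R, A), A ∈ R | 1 | – | – |
| vicariance | (R₁, R₂), R₁∪R₂ = R | 1 (one daughter single-area) | 1 (any bipartition) | – |
| founder-event jump (+J only) | (R, {k}), k ∉ R | j | j | j |

Daughters are ordered and both orders are listed, which makes the
likelihood symmetric under swapping a node's children without per-node
bookkeeping. Each ancestor's event probabilities are its weights
normalized to sum to one. `j` is bounded at 3 with the base weights
fixed at 1, so every +J model nests its base model exactly at `j = 0` —
a property the tests exercise directly.

## Time stratification

Strata are half-open intervals `[younger, older)` in age (mya before
present): an age lying exactly on a boundary belongs to the stratum
whose lower bound it is, so a branch ending on a boundary produces no
zero-length segments. The shipped strata are 0–3, 3–20, 20–30, 30–40
and 40–120 mya. Each branch is cut at stratum boundaries and the branch
transition matrix is the rootward-to-tipward product of per-segment
matrix exponentials `exp(Q_s Δt)`. When all strata share one multiplier
matrix this reduces (exactly, by the semigroup property) to the
unstratified likelihood, which is asserted to 1e-10 in the tests.

Four scenarios are shipped. The baseline multiplier matrix is built
from an editable land/water classification of area pairs: staying costs
1 (unit diagonal), adjacent land 0.5, across water 0.25; non-adjacent
land pairs also get 0.25 since no third tier is defined. The null
scenario is all ones in every stratum. The Panama scenario applies the
baseline after the isthmus closes (0–3 mya) and shuts the
Mesoamerica↔Pacific corridor to 0.01 in every older stratum. Closing
Americas grades the corridor: baseline after 3 mya, 0.5 between 3 and
20 mya, 0.01 before 20 mya. GAARlandia adds to Closing Americas an
elevated multiplier (default 0.5, configurable — no published value
exists) on every route to and from the Caribbean in the 30–40 mya
stratum, with the oldest stratum mirroring 20–30 mya.

## Likelihood, fitting and model choice

Felsenstein pruning over the range states: tip vectors are indicators
of the observed ranges; internal-node vectors combine the two daughter
branch-top vectors through the cladogenesis table,
`L(R) = Σ p(R→(R₁,R₂)) L₁(R₁) L₂(R₂)`. Every node vector is rescaled
by its maximum with the log factors accumulated, so 56-state vectors do
not underflow on deep trees. The root likelihood averages over a prior
on the root range — uniform over non-null states by default, exposed as
an option. Data with probability zero under a parameter set yield −∞
(reported, not raised) so the optimizer can traverse such regions.

Fitting maximizes over `(d, e[, j])` with L-BFGS-B on log10-transformed
parameters (the bounds — `d, e ∈ [1e-12, 5]`, `j ∈ [1e-5, 3]` — span
many orders of magnitude, and the log transform makes finite-difference
steps scale-free). Three deterministic starts, `(d, e) ∈ {10⁻³, 10⁻²,
10⁻¹}²` paired with `j ∈ {10⁻⁴, 0.5, 2}`, guard against local optima
without random restarts; non-convergence is flagged on the result
rather than raised. Models are compared by
`AICc = −2 lnL + 2k + 2k(k+1)/(n−k−1)` with `n` the number of tips and
`k ∈ {2, 3}`; with four or fewer tips and `k = 3` the correction term is
undefined and the criterion is reported as NaN. Akaike weights are
`exp(−Δᵢ/2)/Σ exp(−Δⱼ/2)`; ties rank the model with fewer parameters
first, then alphabetically.

Ancestral range marginals use the standard two-pass algorithm: the
pruning (tipward) partials are combined with rootward partials
propagated through the transposed branch matrices and through the
cladogenesis table with the sibling side summed out. Each node's vector
is normalized to a probability distribution over states; the reported
state is the range *entering* the node's cladogenetic event. On trees
small enough to enumerate every internal-state assignment, both the
likelihood and the marginals match brute-force enumeration to 1e-8
(they agree to machine precision in practice).

## The packaged Magnoliaceae fixture

The fixture chronogram has 39 tips; the 14 published mean clade ages
(family root 92.92 mya, genus crown 44.02, the two major clades at
38.91, and so on down to the Yulania crown at 9.7) are fixed at the
corresponding nodes. Internal nodes with no published age are placed by
even division: an unconstrained node splits the interval between its
nearest fixed-age ancestor and the oldest fixed-age node on the longest
unconstrained chain below it, evenly by node count. The rule is
deterministic and documented, and the within-subsection topologies it
applies to are resolved arbitrarily — the fixture is an illustrative
stand-in for the (unpublished) posterior tree, not a reproduction of it.

The tip geography codes each species into the ten areas through an
editable locality gazetteer (species → country/state → area). The
published coding is shown only graphically, so this transcription is
best-effort; species collected in gardens or arboreta are coded by
their native occurrence. All ranges respect the two-area cap.

## The simulator and what passing tests show

`simulate_yule_tree` draws pure-birth trees conditioned on the tip
count (waiting time `Exp(kλ)` with `k` extant lineages, a uniform
lineage splits), so the expected root age `Σ_{k=2..n} 1/(kλ)` serves as
a closed-form oracle. `simulate_ranges` runs a Gillespie walk within
each stratum segment using that stratum's generator, draws one
cladogenetic event per node from the model's table, and logs every
event. Datasets with any extinct tip are rejected wholesale and
resimulated with an incremented seed (the count is reported so the
conditioning bias is visible); more than 1000 consecutive rejections is
an error indicating extinction-prone parameters. Jumps occur only at
nodes, never along branches. One integer seed drives a separate stream
per replicate (`seed + 1000·replicate`), making experiments
reproducible and parallel-safe.

Default study conditions for the recovery experiment: 100-tip Yule
trees at λ = 0.2 per my (crown depths around 25 my — genus-scale trees
for which whole-dataset rejection remains practical), six areas with a
two-area cap, DEC with `d = 0.05`, `e = 0.02`, root in a single area.
Under these conditions the median relative error of the dispersal-rate
estimate over 20 replicates stays within 50% (typically ~12%). The
extirpation rate is systematically underestimated under these settings:
conditioning on survival removes precisely the histories that carry
most information about `e`. This is a property of the inference
assumption (extant sampling), not an implementation artifact, and the
simulator makes it visible rather than hiding it.

What the simulator does not emulate: fossil or extinct-tip sampling,
diversification rates that depend on range (GeoSSE-style feedback),
within-area population structure, distance-scaled dispersal, or
phylogenetic/dating error in the input tree. Passing recovery tests
therefore demonstrate correctness of the likelihood machinery under the
model's own assumptions, not robustness of DEC-family inference on real
data.

## Numerical choices and limitations

- Ultrametricity tolerance `1e-6 × root age` absorbs decimal rounding
  of printed ages; polytomies are rejected rather than arbitrarily
  resolved, because the cladogenesis model is defined for bifurcations.
- Transition matrices use `scipy.linalg.expm` with entries in
  `[−1e-12, 0)` clipped to zero; per-(stratum, duration) matrices are
  cached within a likelihood evaluation.
- The cladogenesis table is stored as flat ancestor/left/right/probability
  arrays so the per-node combination is a vectorized bincount.
- AICc assumes the tip count is the effective sample size — the
  convention for this model family, stated here because AICc is
  undefined without it.
- The 24-model grid on the 39-taxon fixture ranks founder-event (+J)
  variants first, consistent with the original analysis, but the exact
  AICc values of that analysis were never published, so the ranking is
  exercised qualitatively rather than asserted numerically.
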