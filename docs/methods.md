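# Methods

## Model

A genotype is a gene regulatory network of `N` genes represented by a
signed directed graph: entry `J[i, j] ∈ {−1, 0, +1}` of the interaction
matrix is the regulation exerted by gene `j` on gene `i` (activation,
none, repression; all interaction magnitudes are 1).  Three structural
constraints apply to every genotype: no self-regulation (`J[i, i] = 0`),
no mutual regulation (never both `J[i, j] ≠ 0` and `J[j, i] ≠ 0`), and a
fixed edge count `K` (mean degree `C = 2K/N`).  The no-mutual rule
deliberately excludes the textbook bistability module of two mutually
repressing, self-activating genes, so any bistability that appears is a
cooperative, many-gene effect.  Gene 0 receives the external input `I`.

Expression levels `x_i ∈ [0, 1]` evolve synchronously:

    x_i(t+1) = R( I(t)·[i = 0] + Σ_{j≠i} J_ij x_j(t) ),
    R(u) = 1 / (1 + exp(−a(u − b))),

with steepness `a = 1` and threshold `b = 0` by default, so an
unregulated gene sits at the spontaneous level `R(0) = 0.5`.  The
response `x̄_i(I)` to a constant input is the steady state reached from
the uniform `x_i = 0.5` start — the fixed point, or the temporal average
if the trajectory does not settle.  The per-gene sensitivity is
`s_i = |x̄_i(1) − x̄_i(0)|`; the output gene is the non-input gene
maximizing `s_i` and its sensitivity is the genotype's fitness
`f ∈ [0, 1]`.  A genotype is *valid* only if the input gene has a
directed path to every gene and every gene has a directed path to the
selected output; invalid genotypes are excluded from sampling (genes
outside those paths could not contribute to the response).

Steady-state criterion: iteration stops when successive states differ by
less than `1e-10` in max norm (`convergence_tol`), capped at 5000 steps
(`max_steps`); without convergence the response is the mean over the
final 1000 iterations (`average_window`).  The tolerance is far below
the 0.01 bistability detection threshold and the 0.001 input-sweep step,
so fixed-point error never contaminates those classifications.  The cap
and window sizes match the granularity of the 1000-step input phases
used in the dynamic protocols.

## Multicanonical sampling

Under uniform random generation almost all valid genotypes have small
fitness (97%+ below `f = 0.2` at `N = 32`, `C = 5`), and the fittest
bin is rarer than 10⁻¹⁸, far beyond direct sampling.  The package
therefore samples with the entropic-sampling variant of multicanonical
Monte Carlo: a Markov chain over valid genotypes whose stationary weight
is constant within each fitness bin and inversely proportional to the
number of genotypes `Ω(bin)`, making visits near-uniform across bins.
The fitness range `[0, 1]` is divided into 100 equal bins (half-open,
last closed).

The elementary move relocates one uniformly chosen edge to a uniformly
chosen admissible empty position (off-diagonal, reverse direction empty,
computed after removal) with a freshly randomized sign, conserving `K`.
The removal-intermediate network is shared by a move and its reverse, so
the proposal is symmetric and Metropolis acceptance
`min(1, exp(lnΩ̂(old) − lnΩ̂(new)))` preserves detailed balance.
Structurally invalid proposals are rejected moves (the chain stays put
and the current bin is re-counted), so the stationary measure is over
valid genotypes only.  Re-randomizing the sign on relocation matches the
generative symmetry of the random ensemble; carrying the old sign is
available as an option.  One Monte Carlo step (MCS) is `K` attempted
moves; measurements record a sample every 10 MCS to thin correlations
(configurable; the toy validation runs record every MCS, accepting
correlation in exchange for sample count).

Weights are learned with the Wang-Landau scheme: every attempted move
adds the current modification factor `ln f_mod` (initial 1.0) to the
occupied bin's running `ln Ω̂` and one count to the stage histogram; when
the histogram is flat over all bins seen so far (minimum ≥ 0.8 × mean)
the factor halves and the histogram resets, stopping at `1e-8` by
default.  Two departures from the plain textbook loop matter here:

- *Discovery-aware staging.*  The factor is held constant while the walk
  is still discovering new reachable bins (any check interval in which a
  previously unseen bin was visited postpones the flatness test).
  Without this, the factor decays while the walk is still expanding its
  fitness frontier, and penalty accumulation becomes too weak to push
  into the exponentially rarer high-fitness bins.  This matters because
  the landscape is not hill-climbable: greedy uphill edge moves stall
  near `f ≈ 0.33` (cooperative bistable structures are not reachable by
  fitness-monotone single-edge changes), so the sampler must grind
  through the entropic barrier.
- *Flatness over the ever-visited set.*  The reachable bin set is not
  known a priori (the maximum attainable `f` depends on `N` and `K`,
  and tiny toys populate only a few bins), so flatness is judged over
  bins visited at least once during the whole run.
- *Level inheritance at discovery.*  A newly discovered bin's `ln Ω̂` is
  initialized to the level of the bin the walker arrived from rather
  than zero.  A zero-initialized frontier bin sits tens of thousands of
  nats below its mature neighbours and traps the walk for as long as it
  takes to regrow that arbitrary offset; inheritance removes the trap
  while later stages refine the level as usual (the offset of `ln Ω̂`
  carries no information).

The measurement stage is a fixed-weight Metropolis run; the density of
states is estimated per bin as `ln Ω = ln(hist) − ln W` and normalized
so the probabilities over resolved bins sum to one.  Because the
estimate reweights the *measured* histogram, imperfect weights bias only
the visit uniformity, not the estimator.  Empty bins are reported as
unresolved rather than zero.  Production runs pool five independent
measurement runs, each continuing the previous chain endpoint under a
fresh stream.

Validation: on exhaustively enumerable systems — (N = 4, K = 4) with
3 840 genotypes and (N = 5, K = 6) with 860 160 — the estimated density
agrees with exact enumeration to a KL divergence below 0.05 (measured
values are of order 10⁻⁴) at 10⁵ recorded samples.

## Bistability and switch classes

Bistability is detected by quasistatic hysteresis: the input is swept
0 → 1 in steps of 0.001, fully relaxing at each value and seeding each
relaxation with the previous steady state; the downward sweep continues
from the upward branch's endpoint at `I = 1`.  A branch discrepancy
exceeding 0.01 at any grid point flags bistability — a lower bound,
since weaker bistability slips under the threshold.  The bistable
interval is the closure of exceeding grid points at grid resolution (no
bisection refinement).  Classification: interval strictly inside (0, 1)
→ toggle switch; touching exactly one endpoint → one-way switch;
covering both → unswitchable; no interval → monostable.

The dynamic counterpart drives the network from the 0.5 start through
`I = 0 → 1 → 0` in 1000-step phases and asks whether the output
*follows*: phase means are taken over each phase's last 200 steps, and
following requires an excursion `|m₂ − m₁| ≥ 0.5` with a return
`|m₃ − m₁| ≤ 0.1`.  These three constants operationalize a judgment
that is qualitative in origin; they are calibrated to the near-0/1
output levels of highly-fit networks and are all configurable.

## Noise and mutation protocols

Input noise adds an independent uniform `[−0.3, 0.3]` draw to `I` at
every step (the input may transiently go negative); internal noise adds
an independent uniform `[−0.1, 0.1]` draw to each transmitted expression
per regulating pair per step (a `±0.2` preset exists).  Each protocol
invocation uses one seeded stream and a single noise realization per
network, with replicate realizations available by reseeding.  Zero
amplitude draws nothing, so the noiseless trajectory is reproduced bit
for bit.  A network that fails to follow deterministically but follows
under noise exhibits a noise-induced response (NIR).

Mutational scans perturb one site at a time and re-evaluate fitness `f′`
with the parent's input and output genes held fixed; mutants are not
re-validated structurally (a disconnected mutant simply scores whatever
its dynamics yield).  Deletion scans remove each edge; knockout scans
silence each non-input, non-output gene (row and column zeroed and
expression clamped to 0 — the gene product is absent, which is stronger
than merely removing its edges since regulated targets lose a 0.5-level
activator input); addition scans try both signs at every admissible
empty position.  A deletion or knockout is lethal when `f′ < 0.9`; the
same threshold defines "kept high fitness" for additions, one consistent
criterion throughout.  Toggle switches with no lethal edge (TSwoLE) are
filtered as the doubly-robust class.  All scans leave the parent matrix
bit-identical.

## Motif census

With self- and mutual regulation forbidden, any gene triple inducing
exactly three edges is a triangle: a feedback loop (directed 3-cycle) or
a feedforward loop (one gene regulates two, one regulated by two).  Each
splits by the parity of repressions: even → +FBL / coherent +FFL, odd →
−FBL / incoherent −FFL.  The production counter is algebraic (traces and
elementwise products of the signed and unsigned adjacency matrices); the
test suite checks it against an independently written exhaustive
triple-enumeration oracle up to `N = 8`.

## Randomness and reproducibility

Every stochastic stage derives its stream from a single master seed via
SHA-256 of a fixed stage label, so runs are bit-reproducible and adding
an analysis never perturbs earlier stages' draws.  The JIT-compiled
chain kernels use 32-bit child seeds drawn from the stage streams.

## The attainable-fitness ceiling

The maximum fitness a network of given size can express is bounded by
an edge-budget argument.  For fixed-point responses the two steady
states satisfy, gene by gene, `|Δh_i| ≤ Σ_{j→i} s_j (+ ΔI for the
input gene)` and `s_i ≤ tanh(|Δh_i|/4)` (the maximal logistic swing at
the optimally centred operating point), so summing over genes gives
`Σ_i |Δh_i| ≤ K + 1`.  An output swing of 0.99 costs `|Δh_out| ≥
4·atanh(0.99) ≈ 10.6` supplied by at most `N − 1` regulators, whose own
swings must be paid for in turn; at `N = 16`, `K = 40` the requirement
(≈ 63) exceeds the budget (41), so the `f ∈ [0.99, 1]` window is empty
at that size, while at `N = 32`, `K = 80` it is marginally feasible —
consistent with such networks existing but being spectacularly rare.
Empirically, annealed and greedy searches at `N = 16` plateau near
`f ≈ 0.36`, the feedforward-amplification limit, and the sampler's
fitness frontier advances past it only slowly.  Limit-cycle responses
(where the response is a duty-cycle-weighted temporal average) evade
the fixed-point bound in principle; none were ever observed above the
plateau.

## Problem sizes used in the test suite

The default test and validation runs are desk-scale: exact-enumeration
comparisons at (4, 4) and (5, 6) with 10⁵ recorded samples; the
random-sampling mass check with 5 000 valid genotypes at `N = 32`,
`C = 5`; and a fittest-window sampling attempt at `N = 16`, `C = 5`
with weights learned to a final modification factor of `1e-3`
(sufficient for sampling — the density estimator reweights by the
measured histogram).  Reproducing the full-scale `N = 32` statistics
(≈5 000 samples per bin × 100 bins, five runs, the `f ∈ [0.99, 1]`
ensemble) is a long single-CPU computation best launched through the
CLI (`grnscape landscape -N 32 -C 5`).

## Known limitations

- The generator and sampler treat the no-self, no-mutual constraints as
  hard; the relaxed variants are expressible only through custom
  matrices, not validated presets.
- Steeper response functions (`a > 1`) are supported as parameters but
  the analysis defaults are tuned to `a = 1` response scales.
- Bistable-interval endpoints are grid-resolution quantities; a
  one-way/toggle boundary within 0.001 of an endpoint can be
  misclassified.
- The "follows" criterion tail window (200 steps) assumes phases long
  enough to settle; very short phases demote every network to
  non-following by construction.
- Knockout semantics (clamp to 0) are one of two defensible readings of
  gene deletion; removing the gene from the graph without clamping is
  available via plain row/column deletion but is not the default.
- Wang-Landau frontier expansion through the `f ≈ 0.36` entropic
  bottleneck is slow (the conditional probability that an edge move
  from a frontier network lands higher is tiny), so reaching the upper
  landscape at production sizes requires long runs.
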