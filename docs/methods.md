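# Methods

## The evolutionary model

A single lineage is modeled by a continuous-time Markov chain on the copy
numbers (U, V) of two adjacent genomic bins, each bounded by a maximum copy
number k (default 10). Off-diagonal rates are:

| move | rate |
| --- | --- |
| both bins ±1 together | γ(α+β) |
| both bins ±n, n>1, together | γβ |
| one bin ±1 | α+β |
| one bin ±n, n>1 | β |
| bins change by different amounts | 0 |

Diagonal entries make rows sum to zero; moves that would leave {0,…,k}
simply do not occur (no reflecting mass). α adds extra rate to ±1 events so
small events can outpace large ones; γ scales events that span both bins,
so γ ≫ 1 corresponds to CNAs that usually cover multiple bins. The finite
state space and the independence of nonadjacent bins are both
approximations; the genome process is not truly Markovian because CNAs
create breakpoints in pairs.

For a pair of cells (A, B) with shared branch t1 from a diploid ancestor
(state (2,2)) and private branches t2, t3, the joint distribution of
adjacent-bin states in both cells marginalizes the unobserved divergence
state (W, Y):

    F[(c_iA, c_iB), (c_jA, c_jB)] =
        Σ_{W,Y} P(2,2)→(W,Y)(t1) · P(W,Y)→(c_iA,c_jA)(t2) · P(W,Y)→(c_iB,c_jB)(t3)

with P(t) = exp(Qt) (scaling-and-squaring Padé via `scipy.linalg.expm`).
Row-normalizing F gives the genome-wide transition chain M over paired
states (CN_A, CN_B); its stationary vector initializes each chromosome.
Conditioning the same construction on one lineage (divide the (2,2) row of
P(t), reshaped to (k+1)×(k+1), by its row sums) gives the single-cell
genome chain used in stage 1.

State indexing is row-major throughout: (U, V) ↦ U·(k+1)+V.

## Emissions and the HMM

Window i of a cell with copy number CN emits a negative binomial count with
mean λ = (CN·μ_i/2)·s + ε and variance aλ²+bλ+c, where μ_i is the
per-window mean diploid depth and {a,b,c} are fitted to the diploid
(mean, variance) pairs by least squares with a, c ≥ 0. ε (default 0.01
reads) is a fixed constant, not estimated: it keeps the zero-copy state
emittable. When the fitted quadratic dips to or below the Poisson line the
variance is floored at λ(1+10⁻⁶) rather than rejected, since fitted
coefficients commonly undershoot at small λ. Cells are conditionally
independent given their copy numbers, so the pair emission is the sum of
two single-cell log-pmfs. Windows with μ_i = 0 are masked (uninformative
rows) and their decoded values are filled from the nearest unmasked window.

The forward pass uses scaled probabilities with per-window normalization
constants accumulated in log space; Viterbi runs in log space with ties
broken toward the smaller state index. Chromosomes are independent: the
state distribution resets to the stationary vector at each chromosome
start, and log-likelihoods add across chromosomes.

## Four-stage pipeline

1. **Independent fits.** A modified Baum-Welch pass estimates an
   unconstrained (k+1)-state genome chain with CN-structured emissions,
   holding the initial distribution uniform and interleaving one bounded
   golden-section refinement of s per sweep (a refinement is only accepted
   if it does not lower the likelihood). s starts at the cell's total-count
   ratio against the diploid average — necessary because s and the overall
   copy-number level are confounded in an unconstrained chain. The model
   chain is then moment-matched to the Baum-Welch chain over a geometric
   grid of candidate t (Frobenius distance, rates held at fixed starting
   values), and L-BFGS-B refines log{s, α, β, γ, t} on the forward
   log-likelihood (log-parameters enforce positivity; up to 3 seeded
   restarts). Viterbi decoding yields the independent integer profile.
2. **Rate combination.** α, β, γ are combined across cells by the
   component-wise median.
3. **Pair fits.** Only [t1, t2, t3] is estimated per pair (s and {a,b,c}
   stay fixed), by L-BFGS-B on the two-cell forward log-likelihood in log
   branch lengths, rebuilding P/F/M and the stationary vector at every
   evaluation. Branch lengths are floored at 10⁻⁶ to keep the chain
   irreducible. Matrix exponentials are cached per pair, keyed by the exact
   float time: rounding the key (even at 10⁻⁹) silently zeroes
   finite-difference gradients, whose steps perturb t below the rounding
   resolution. The starting point splits the single-cell totals:
   t1 = min(t_A, t_B)/2, t2 = t_A − t1, t3 = t_B − t1. Because the
   single-cell likelihood depends on rates and time only through the
   products αt, βt, per-cell t estimates live on arbitrary per-cell scales;
   each cell's total branch length is therefore re-estimated (1-D bounded
   search) under the shared median rates before the split, putting all
   starting points on one time scale.
4. **Consensus.** Each cell's paired Viterbi profiles are summarized per
   window by mean (default), median, or mode; mode ties break toward the
   smaller copy number (conservative). Mean and median may be fractional,
   which genuinely reflects CNAs split across window boundaries; outputs
   carry a flag so writers can round (half-up) for integer-only consumers.
   Pair selection may be restricted to each cell's κ nearest neighbors
   (default κ=10, Euclidean distance between stage-1 profiles); excluded
   pairs are simply not fitted and the consensus denominator is the number
   of profiles actually present. A complete t2+t3 distance matrix, by
   contrast, requires all pairs.

Neighbor joining is delegated to scikit-bio (negative branch lengths
clamped to zero with a warning) and Robinson–Foulds to dendropy's
bipartition machinery (unweighted count; rooted inputs are unrooted
first); both are verified in the test suite against independent oracles
(additive-tree recovery, brute-force bipartition enumeration).

## The simulator

The simulated genome is a multiset of line segments over a fixed reference
[0, 100); ploidy at a point is the number of covering segments, and the
diploid ancestor has two full-length copies. Along each tree branch,
amplification and deletion counts are Poisson(rate × branch length ×
genome length) with rates per unit time per unit genome; each event draws a
uniform start and an exponential length (mean 1% of the genome, truncated
at the reference end), then duplicates or excises the overlapped portion of
one uniformly chosen covering segment. Children inherit parent genomes plus
their own branch's events. Defaults: amp and del rates 0.05, chosen to give
roughly 20 events per leaf at the study tree scaling (tree height 1, root
branch 1). Four tree shapes are provided: pectinate ultrametric (A),
balanced ultrametric (B), pectinate with uniform branches (C), and
pectinate with terminal branches decaying as 1/ln(j+1) (D); trees are
rescaled to height 1 and a root branch is prepended so every cell shares
ancestral events.

Reads are drawn per window from a negative binomial with size r = 50 and
mean proportional to the window's average ploidy, scaled to 4,000,000
expected reads per cell over 12,397 windows (322.7 per window); the window
grid is split into 22 synthetic chromosome blocks. The simulator makes
breakpoints in pairs and allows unbounded copy number — deliberately
mismatched to the inference model — but it does not include GC or
mappability bias, whole-genome doubling, or allelic information, so passing
tests say nothing about those error modes in real data.

Accuracy metrics: SSE = Σ_i (inferred_i − truth_i)²; breakpoints are window
boundaries where the profile changes within a chromosome; the breakpoint
distance sums, over true breakpoints, the distance in windows to the
nearest inferred breakpoint on the same chromosome (a chromosome with no
inferred breakpoints contributes its full length per true breakpoint); and
ω is the ratio of inferred to true breakpoint counts, undefined when there
are no true breakpoints.

## Validation experiments and problem sizes

The self-simulation experiments draw hidden paired states from the model's
own genome chain and NB counts from the emission model, with rates
α = 5·10⁻³, β = 5·10⁻⁴, γ = 10 — calibrated so segments span tens of
windows, genomes stay mostly diploid, and two cells at t2+t3 = 1 disagree
in roughly 10% of windows — and dispersion a = 0.02, b = 1, c = 0
(equivalent to NB size 50). Branch recovery uses 12,000 windows at
(t1, t2, t3) = (1, 0.5, 0.5); the divergence ladder uses 5 levels × 5
replicates at 2,000 windows.

The end-to-end pipeline experiment runs 8 tumor cells plus 20 diploids on a
pectinate ultrametric tree at 1,200 windows (per-window coverage held at
the study value of ~322.7 reads), k = 10. The phylogeny comparison runs 10
replicates of 8 cells at 600 windows, k = 6: with fewer cells the
Robinson–Foulds distance is too coarse (three non-trivial bipartitions) to
separate methods. These sizes are reductions of the full study conditions
(128-cell trees analyzed in 20-cell subsets at 12,397 windows) chosen so
the whole validation runs in minutes on one core; the directional
comparisons (consensus vs. independent SSE and ω, t2+t3 vs. Euclidean RF)
are preserved under the reduction, absolute SSE/RF magnitudes are not.

## Known limitations

- The pairwise model shares information between two cells only; no joint
  model across all n cells.
- Per-pair profiles of one cell can disagree; the consensus resolves but
  does not model this.
- t1 is weakly identified relative to t2+t3 (events are hard to place on
  specific branches), mirrored in noisier t1 estimates.
- The along-genome process is an approximating Markov chain; paired
  breakpoints are not modeled jointly, so unpaired decoded breakpoints can
  occur.
- Real-data preprocessing (alignment, binning, GC/mappability handling) is
  out of scope; inputs are assumed to be binned counts with matched
  diploids from the same protocol.
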