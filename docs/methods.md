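# Methods

## Task and data model

The protocol collects *max-choice* judgments: on each trial the observer
views M of the N stimuli and selects the one eliciting the largest
subjective value; the selection disappears and the observer selects again,
until the trial's response quota is met or two stimuli remain and are
resolved.  A selection among m displayed stimuli contributes m−1 ordered
pairwise outcomes (chosen beats each remaining stimulus).  Outcomes are
stored as an integer win-count matrix `wins[i, j]`; win *rates* are always
derived on demand, so repeated updates cannot accumulate rounding error.
Trials may legitimately stop before the final pair, and the tally makes no
completeness assumption.  Stimulus IDs are opaque strings with a stable
ID→index map serialized alongside every export.

## Sorting the comparison matrix

Sorted position ascends with estimated magnitude (position N = largest).
The initial permutation ranks stimuli by the row sums of observed win
rates, P_i = Σ_j p_ij over defined cells; stimuli with no data receive a
random P of 0 or 1 and rate ties are broken randomly, all from the session
seed.  (The ascending convention fixes the mirror ambiguity of the
boundary conditions: a virtual rank-0 stimulus loses to everything, a
virtual rank-(N+1) stimulus beats everything, each boundary cell entering
the likelihood with weight one.)

For each sorted position a two-parameter increasing logistic
ψ(r) = 1/(1+e^{−a(r−x)}) is fitted to that stimulus's win rates as a
function of opponent rank by binomial maximum likelihood, each cell
weighted by its outcome count.  The slope is constrained to
a ∈ [0.05, 50] rank⁻¹: the lower bound keeps a scale defined when a
stimulus's data are near-uniform, the upper bound keeps JND thresholds
finite on step-like (perfectly separated) data.  Stimuli with no data get
a substitute fit — slope 1.0 (a JND of about one rank spacing, a neutral
assumption), centroid at their own position — so the scale stays defined
early in a session.  Inside the sort the N fits are computed by a
vectorized damped-Newton iteration over the non-empty cells (projected
onto the slope bounds, with backtracking on the likelihood); the public
single-fit API solves the same objective with bounded L-BFGS-B, and a unit
test keeps the two in agreement.

The estimated rate matrix averages the column fit of j' at i' with the
complement of the row fit of i' at j',

q_{i'j'} = [ψ_{j'}(i') + 1 − ψ_{i'}(j')]/2,

which makes q + qᵀ = 1 exact, including a 0.5 diagonal.  The sort then
performs a greedy descent over permutations: a re-rank is proposed first
by the row sums of q (the same larger-sum-higher-rank rule as the initial
step) and, when that proposal no longer helps, by maximum-likelihood
placement — each stimulus is rescored at every candidate rank against the
other stimuli's fitted fields and moved to its best rank.  The placement
move exists because the row-sum key contains a positional term that is
monotone in rank by construction and therefore anchors stimuli near their
current positions; badly misplaced stimuli need a long-range jump that row
sums cannot express.  A proposal is accepted when the regression residual
(summed squared observed-minus-estimated rates over observed cells)
strictly decreases, or stays equal for a not-yet-visited permutation
(adjacent swaps can be residual-neutral because the diagonal carries no
data, yet the keys still demand them; equal-residual acceptances are
rationed to eight per sort).  The descent stops when no proposal is
acceptable or after `max_iterations = 40` fit evaluations; acceptance by
strict decrease guarantees termination.  During a session each trial's
sort is warm-started from the previous trial's order, and the better of
the cold and warm starts (by residual) seeds the descent; the cold-start
contract of `sort_matrix` itself is unchanged.

## Adaptive stimulus sampling

Each ordered pair carries the stress S_ij = |2p_ij − 1| + n_j/N, with p
taken from the fitted rate matrix and n_j the number of outcomes involving
j.  Before any fit exists — and for any pair in which one member has no
observed outcome at all — p defaults to 0.5, so such pairs contribute no
rate term.  This matters: boundary-driven fits would otherwise claim
confident rates for untested stimuli, inflating stress at the start of a
session, suppressing the early exploration sweep, and driving the
responses-per-trial quota to its maximum immediately.  The next set
minimizes the summed stress over all ordered pairs in the candidate
(so each member's n term counts M−1 times) across up to 50 000 random
M-subsets, stopping early at stress zero.  The search is evaluated in
vectorized batches; with fresh sessions the very first candidate wins, so
early trials sweep through unsampled stimuli.

The same stress total fixes the trial's response quota
k = clamp(round((S/M)·(M−1)/s_cap), 1, M−1) (the squared variant
substitutes (S/M)²; the fixed rule always uses M−1).  The normalizer
s_cap has no principled unit in the stress scale and was calibrated once,
at 5.0, so that simulated N=100, M=8 sessions show the intended behavior:
a single response per trial early, a gradual climb, and the full
elimination before termination.  The calibration criterion was the shape
of that ramp, not any downstream benchmark value (which proved insensitive
to s_cap in the 1–8 range).

## JND scale

The magnitude of the lowest-ranked stimulus is 0; each next magnitude adds
the discrimination threshold between adjacent ranks, defined as half the
rank-distance between the 25% and 75% points of the pair's psychometric
function — ln 3/a for a logistic of slope a — expressed on the 0–1
normalized rank axis (division by N−1, a constant that cancels in the
final normalization).  The slope governing an adjacent pair is the
geometric mean of the two stimuli's fitted slopes, a symmetric choice that
avoids direction bias; magnitudes are finally divided by their maximum.
Consequently the scale is invariant to a uniform rescaling of all slopes,
and thresholds are finite by the slope bounds.  A four-parameter
hyperbolic response function R = A·C^p/(z^q + C^q) can be least-squares
fitted to map magnitudes onto a physical axis such as contrast.

## Model observer and simulator

True psychological values live on [0, 1]: an equally spaced grid for the
linear shape, warped by y = x² (power) or y = x²/(0.5² + x²) rescaled to
[0, 1] (hyperbolic, compressive at the top).  Values are randomly permuted
against stimulus IDs so labels carry no information.  On every selection
step the observer adds fresh independent Gaussian noise (default
sd 0.05, i.e. 1/20 of the response range) to each displayed stimulus's
value and picks the argmax.  A session terminates when the Pearson
correlation between the JND-based magnitudes and the true values reaches
0.95 (for N = 2, where correlation is degenerate, exact order agreement),
or at a response cap of 50·N — the cap exists only to bound runtime at
extreme noise and is reported, never raised as an error.  Benchmarks run
at least 20 replicates per condition; replicate seeds derive from
`SeedSequence([master, replicate])` and spawn separate streams for value
assignment, observer noise, sampling and sorting, so any replicate reruns
in isolation and different arms share matched observers replicate by
replicate.

What the simulator does *not* emulate: sequential dependencies within a
trial (the model observer is memoryless, whereas human rankings can show
carry-over between successive eliminations), lapses and criterion drift,
reaction times, and stimulus rendering.  Passing simulations therefore
demonstrate the statistical efficiency of the protocol under a
well-behaved observer, not robustness to human response artifacts.

## Problem sizes and observed behavior

The test and acceptance benchmarks use the simulation study's own
conditions: N=100, M=8, noise sd 0.05, linear values, 20 replicates per
arm (plus N=100 with M ∈ {2, 4}, and desk-scale N ∈ {8, 16, 32} sweeps
for the monotonicity properties).  Under those conditions the adaptive
protocol reaches the r ≥ 0.95 criterion in roughly 150 responses.  The
relative penalties of the two control arms — uniform-random next-set
selection and the fixed M−1 responses rule — come out near 2.5× and 1.2×
here.  Both contrasts point in the expected direction but are smaller than
the published ≈5× and ≈1.6×: the residual-descent sorter (placement moves,
warm starts) extracts close to the maximum-likelihood information from
*any* response set, so degrading only the sampling policy or the response
quota costs less than it does with a weaker estimator.  Dropping the
placement/warm-start machinery restores large contrasts (≈3× and ≈4.5×)
but then the absolute efficiency target is missed by a wide margin; the
package keeps the stronger estimator.

## Known limitations

* Stimuli spaced so far apart that all win rates pin at 0 or 1 leave
  adjacent thresholds unidentified (slopes at the upper bound, thresholds
  ln 3/50); only direct comparisons can order true-adjacent pairs in the
  noiseless limit.  The scale degrades into a rank order in that regime.
* The stress heuristic trusts the fitted rate matrix; a confidently wrong
  fit can defer sampling of the very pair that would correct it.  The
  n_j/N coverage term guarantees every stimulus keeps accruing data, which
  bounds but does not eliminate the effect.
* Per-stimulus slopes are high-variance with sparse data; thresholds
  inherit that variance as 1/a.  The JND scale is accordingly noisier than
  the rank order, and termination driven by its correlation is slightly
  conservative.
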