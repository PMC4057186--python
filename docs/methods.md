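# Methods

## Model

A binding-site model over L-mers `s` on the alphabet A, C, G, T
(indices 0..3, fixed in that order) assigns

```
P(s) = exp(-E(s)) / Z,
E(s) = sum_i h_i(s_i) + sum_{(i,j) in A} J_ij(s_i, s_j),
Z    = sum_s exp(-E(s)),
```

with `A` a set of "active" position pairs, i < j. This is the
maximum-entropy distribution constrained to reproduce the single-site
marginals at every position and the pairwise marginals on the active
pairs: entropy maximization with Lagrange multipliers on those marginals
yields exactly the exponential family above, with the multipliers as
fields and couplings. The PWM (independent-positions) model is the `A = ∅`
case; the nearest-neighbor model (NNM) restricts `A` to `(i, i+1)` and is
equivalent to a first-order Markov chain along the site.

Energies are in natural-log units internally; all reported entropies,
divergences, and scores are in bits. Positions are 0-based in code and
1-based in every exported file.

### Exactness and component factorization

All model quantities — partition function, marginals, likelihoods, exact
sampling — are computed by enumeration, never by mean-field or
pseudo-likelihood approximation. Positions not connected by any coupling
are independent, so the distribution factorizes over the connected
components of the coupling graph; within a component of size m all 4^m
states are enumerated (streamed in blocks above 4^12 states, hard bound
m <= 14). This is an algebraic identity, not an approximation, and it is
what keeps fitting at L = 12 cheap while the active set is sparse — which
the BIC guarantees in practice.

### Gauge

The parameterization is redundant: per-position constants can shift
between fields and the normalization, and row/column profiles of a
coupling block can shift into the fields. Uniqueness is restored by the
minimum-norm zero-sum gauge: `sum_a h_i(a) = 0` for every i, and
`sum_a J_ij(a, b) = 0 = sum_b J_ij(a, b)` for every block. `fix_gauge`
imposes it by double-centering each block (absorbing row/column means into
the fields) and then centering the fields; the distribution is unchanged
to machine precision and the operation is idempotent.

## Estimation

### Frequencies and pseudo-counts

Single-site frequencies use Laplace pseudo-counts,
`p_i(a) = (n_i(a) + beta) / (N + 4 beta)` with `beta = 1` per cell by
default; pairwise tables use `beta = 1/16` per cell (one prior observation
per pair distribution). Results are insensitive to these values at the
sample sizes of interest. Because the two pseudo-counts differ, the raw
pair tables are marginally inconsistent with the singles at O(beta/N), and
no distribution can satisfy both constraint sets exactly; each pair table
is therefore rebalanced by iterative proportional fitting to match the
pseudo-counted singles before fitting. With `beta = 0` the rebalancing is
a no-op.

### Fitting

Given targets, the convex maximum-likelihood problem is solved by gradient
descent on the marginal residuals:

```
h_i(a)     <- h_i(a)     - eta * (f_i^data(a)     - f_i^model(a))
J_ij(a,b)  <- J_ij(a,b)  - eta * (f_ij^data(a,b)  - f_ij^model(a,b))
```

(the sign follows from `P ∝ exp(-E)`: a marginal the model underpredicts
needs a lower field). Model marginals are recomputed exactly every step.
Convergence: largest absolute residual over all constrained marginals
<= `tol = 1e-4` (tightened to 1e-5..1e-9 where a test needs it);
`max_iter = 20000`. The default step `eta = 1.0` was chosen because the
problem is convex with indicator-covariance curvature well below 1, so
steps far above the conservative regime remain stable while cutting
iteration counts by an order of magnitude; instability appears only near
`eta ≈ 4`. The step is additionally adaptive: the stability region shrinks
as strong couplings merge positions into larger components, so when the
residual rises well above the best seen, the best parameters are restored
and the step halves. Fits are returned gauge-fixed.

### Greedy coupling selection and BIC

Starting from the coupling-free fit, the candidate pair whose dinucleotide
statistics deviate most from the data is added, the model refit
(warm-started), and the Bayesian Information Criterion

```
BIC = -log L_hat + (k/2) log N     (natural logs)
```

recorded. The deviance score of a pair is the minimum over its 16 cells of
the exact two-sided binomial tail probability of the observed count under
the model probability (outcomes no more likely than the observation);
smallest score wins, ties break lexicographically. The loop stops after
the BIC fails to improve for 3 consecutive additions (patience) and the
BIC-minimal model is returned with the full trace.

Parameter counting uses the gauge-independent dimensions: 3 per position
for the fields (one zero-sum constraint each) and (4-1)^2 = 9 per coupling
block (zero-sum rows and columns). The counting is configurable in the
sense that `bic` takes `k` explicitly.

### Mixture baseline

The mixture of K PWMs is estimated by K-means on the sites under Hamming
distance, centroids being per-position modal nucleotides (ties to alphabet
order), 10 restarts seeded from the master seed, empty clusters re-seeded
from the farthest points. A PWM is estimated per cluster and weighted by
cluster size. Model selection fits K = 1..K_max and minimizes the BIC with
`k = K*3L + (K-1)`; the likelihood is that of the mixture distribution
itself (hard clustering is only the estimation device). Parameter count
for K = 5, L = 12: 184.

## Refinement workflow

Sites are not given; only bound fragments are. The workflow alternates:

1. Scan both strands of every fragment; score each L-window
   `log2 P_model / P_background` in bits. Windows containing N are
   skipped; minus-strand windows are reverse complements of the slice,
   reported at the slice's 0-based offset and kept in matched orientation.
2. Choose the cutoff as the ceil(tpr*M)-th largest per-fragment best score
   (default tpr = 0.5: half the fragments retain at least one site — a
   heuristic that suppresses false-positive peaks).
3. Collect training sites: above-cutoff windows, greedily non-overlapping
   per fragment by descending score.
4. Relearn the model on the training sites and repeat until the selected
   (fragment, offset, strand) multiset is exactly stable (cap 20 rounds;
   non-convergence is flagged, last state returned).

The background model is the position-independent nucleotide composition of
all windows on both strands (hence exactly strand-symmetric); a full
pairwise background can be fit instead for background-interaction
controls. The PWM stage re-centers the matrix every round on the
information-content center of mass (information measured against the
background; integer shift = round(center - (L-1)/2), half-up); for the
richer builders (PIM/NNM/mixture) the PWM stage is run to convergence
first to pin the window frame — re-centering is what prevents the loop
from settling in a frame shifted by one column — and the richer model then
iterates in that frame without re-centering.

Note one inherent property: the thresholded training set is
score-enriched (it keeps the better-scoring half of fragments), so PWMs
learned from it are systematically sharper than the generating
distribution. Unbiased recovery checks should use per-fragment best
windows without the threshold; the test suite does.

## Analysis toolkit

* **DKL and self-DKL.** Model quality is `DKL(sample || model)` in bits
  over the observed site multiset. Its expected floor from finite sampling
  is estimated by drawing `reps` samples of size N from the model itself
  (mean ~ (k-1)/(2 N ln 2) for k effective categories); an observed DKL
  above mean + 2 sd flags a genuinely inadequate model.
* **Direct information.** For a coupled pair, the direct two-site
  distribution `P_dir(a,b) ∝ exp(-J_ij(a,b) - htilde_i(a) - htilde_j(b))`
  is built with fields solved (Levenberg–Marquardt, six unknowns after
  anchoring the T component to zero, residual tolerance 1e-10) so its
  marginals match the single-site frequencies; DI is the divergence of
  `P_dir` from the product of those marginals. Pairs without a coupling
  have DI exactly 0 by construction. The anchor letter (T) is a
  convention; DI is anchor-independent.
* **Normalization.** NDI and NMI divide by min(H_i, H_j) (bits). Since
  MI <= min marginal entropy, NMI lies in [0, 1] and reaches 1 for a
  deterministic copy of equal-entropy positions; the same denominator is
  applied to DI for comparability. Two zero-entropy positions define the
  value as 0 (no variability, no correlation).
* **Participation ratio.** With per-pair weights `w_ij` (default NDI^2,
  configurable to NDI), `R = (sum w)^2 / (N_pairs * sum w^2)` with
  `N_pairs = L(L-1)` counting both orientations: 1 for uniform weights,
  1/N_pairs for a single concentrated interaction. Squaring emphasizes the
  strong links, which is the regime the ratio is meant to resolve.
* **Distance profile.** Weights averaged over the (L-d) pairs at each
  separation d and normalized to sum to 1 — the (L-d) correction removes
  the overrepresentation of short distances that pure pair counting would
  produce.
* **Landscape.** Local minima are states none of whose 3L single
  substitutions strictly lowers the energy (plateaus therefore terminate
  descent; deterministic ties break by position then alphabet order).
  Sites descend once each (random mode draws per-site sub-seeds from the
  master seed); basins are keyed by terminal minimum, weighted by member
  fraction, summarized by per-basin PWMs, and matched to mixture
  components by position-summed PWM divergence (exact for
  independent-position models). Exhaustive verification of the minima set
  is available for L <= 8.
* **Spectral decomposition.** The couplings extend to a symmetric 4L x 4L
  matrix over (position, letter) with zero diagonal blocks, satisfying
  `E = sum_i h_i(s_i) + x^T Jhat x / 2` for one-hot `x`. Eigenpairs are
  ranked by decreasing |lambda| (then decreasing lambda, then index;
  eigenvector sign fixed by a positive largest-magnitude coordinate).
  Rank-p truncations re-zero the within-position diagonal blocks that
  truncation introduces, so the result is again a valid coupling matrix;
  p = 4L reproduces the original exactly.

## Synthetic data

The generator emulates the structure of ChIP peak data: fragments of a few
hundred bp (default 300, 1000 fragments) from a stationary first-order
Markov background with a mildly AT-rich composition (0.3/0.2/0.2/0.3) and
a CpG-depletion factor (default 0.5) — the C→G transition is damped and
the dinucleotide joint rebalanced by iterative proportional fitting so the
stationary composition is exact. One site per fragment is planted at a
uniform non-overlapping offset on a uniform strand, drawn exactly from the
planted model (component-wise categorical sampling). The default planted
model (`demo_pim`) is a sharp (> 8 bits), non-palindromic motif whose
central pair carries a strong coupling producing two basins of comparable
weight — the regime where pairwise structure matters.

What the generator does **not** emulate: read-level signal (coverage,
peak shape), repeats and masking beyond N handling, fragment-length
variation, cooperative or homotypic multi-site arrangements, and genomic
heterogeneity of the background along a fragment. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
generative assumptions, not performance on any particular real dataset.

## Problem sizes in the shipped tests

The suite exercises the exact algebra at L <= 6 (where brute-force oracles
are feasible), parameter recovery at L = 8 with N = 50,000 exact samples
and five couplings, and the full workflow at L = 12 on 1,000 fragments of
300 bp — sizes chosen so every oracle comparison stays exact and the whole
suite runs in about a minute on one core.

## Known limitations

* Enumeration bounds joint component size at 14 positions; motifs whose
  coupling graph percolates into one large component at L > 14 are out of
  reach by design (the exactness guarantee is the point).
* The binomial selection score tests cells independently; a pair whose
  deviation spreads thinly over many cells can rank below a pair with one
  sharp cell.
* Hamming K-means is a local optimizer; restarts mitigate but do not
  eliminate dependence on initialization.
* Variable-length spacers inside motifs are not modeled; the fixed-L
  window must cover the motif.
* The refinement fixed point is not unique in principle; with
  uninformative initial matrices the loop can converge to a shifted or
  spurious frame. The information-content re-centering removes the
  one-column drift mode but cannot rescue an initial matrix that does not
  overlap the true motif.
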