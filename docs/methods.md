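# Methods

## Structure space and ensemble model

A secondary structure on a length-L sequence is a set of 1-based pairs
(i, j), i < j, in which every position pairs at most once, no two pairs cross
(i < k < j < l is excluded — the space is pseudoknot-free), and every pair
encloses at least `min_hairpin` unpaired bases (default 3, the standard
steric folding convention; configurable). Lone pairs are allowed: the model
imposes no helix-stacking constraint.

The probability distribution p(θ|x) is defined by a multiplicative
pair-scoring model: weight(θ) = Π w(x_i, x_j) over the pairs of θ, with
defaults w(G,C)=3, w(A,U)=2, w(G,U)=1 and all other pair types forbidden,
and weight 1 for the empty structure. The weights mirror the relative
stability ordering of canonical Watson–Crick and wobble pairs (3/2/1 ≈ the
hydrogen-bond count) while keeping every quantity exactly computable and
testable offline. This deliberately simple ensemble is *not* a
nearest-neighbour thermodynamic model — no stacking, dangles or loop
penalties — but the estimators consume only the base-pairing probability
matrix {p_ij}, so posteriors computed by any external engine can be supplied
as a text matrix (`peafold fold --bpp-in`) and every prediction rule applies
unchanged.

Input normalization: T is silently folded to U; any other non-ACGU code is
rejected with its position. IUPAC wildcards are not folded because no
pairing rule is defined for them here.

## Algorithms

**Inside (partition) pass.** Z(i, j), the weight-sum over structures of the
subsequence i..j, cases on position i: unpaired, or paired with k where
k − i − 1 ≥ min_hairpin, giving
Z(i,j) = Z(i+1,j) + Σ_k w_ik · Z(i+1,k−1) · Z(k+1,j). Each structure is
generated exactly once, so Z = Z(1, L) is the exact partition value. O(L³).

**Outside pass.** Context weights O(i, j) are propagated down the same
recursion from O(1, L) = 1; the marginal of pair (i, k) accumulates
O(i,j)·w_ik·Z(i+1,k−1)·Z(k+1,j) over enclosing spans and is divided by Z.
Marginals satisfy the single-partner bound Σ over entries touching a
position ≤ 1, which is validated whenever a matrix is constructed or read.

**Stochastic sampling.** Exact traceback of the inside recursion: at each
span the decomposition case is drawn with probability proportional to its
inside weight. The per-span case lists and cumulative weights are frozen
once per (sequence, model), so each traceback is a few uniform draws plus
binary searches. One integer seed drives a single sequential stream
(`numpy.random.default_rng`); the sample of size m is a prefix of the sample
of size n > m at the same seed. This nesting makes the M1 consistency
property (selected score non-decreasing in n) hold per seed, not just in
expectation.

**Enumeration oracle.** The same recursion expanded exhaustively, memoized
per span. It is the independent ground truth for partition values, pairing
marginals, expected accuracies and estimator optimality in the tests. The
default length cap of 18 nt guards against accidental exponential blow-up
(≈1.8^L structures); it is a guard, not a correctness bound, and can be
raised explicitly.

## Accuracy algebra

Exact confusion counts compare pair sets over the L(L−1)/2 upper triangle;
expected counts replace indicators by marginals (TP̂ = Σ_σ p_ij, etc.) and
conserve the same total. The pseudo-expected accuracy evaluates a measure at
the expected counts; the exact expected accuracy averages the measure over
the enumerated ensemble; the sampled variant averages over a stochastic
sample.

Zero-denominator convention: SEN, PPV, MCC and F return 0.0 with a separate
"defined" flag whenever their denominator vanishes (empty prediction for
PPV, empty reference mass for SEN, any zero MCC factor). Published
evaluations rarely meet these cases; a flagged 0 keeps every selection rule
total and conservative, including the per-term convention inside the exact
expectation (an empty sampled θ contributes 0 to expected SEN of a non-empty
σ). The conservation identity TP+TN+FP+FN = L(L−1)/2 is a property of the
producing functions, not of the counts container, so free-standing
quadruples can still be scored.

## Estimators

**γ-centroid.** argmax γ·TP̂(σ) + TN̂(σ). Up to a constant this is
Σ_σ [(γ+1)p_ij − 1], maximized by a Nussinov-style DP:
M[i][j] = max(M[i+1][j], M[i][j−1], M[i+1][j−1] + g_ij, max_k M[i][k] +
M[k+1][j]) with g_ij = (γ+1)p_ij − 1 and only strictly positive gains
eligible (pairs at exactly zero gain are excluded, matching the strict
threshold rule below). The traceback tries the cases in exactly the listed
order with k ascending — any argmax is a valid prediction, so a fixed order
is chosen purely to make outputs deterministic and testable.

**Thresholding shortcut.** For γ ≤ 1 the DP is unnecessary: the prediction
is exactly the pairs with p_ij > 1/(γ+1) ≥ 1/2, which cannot conflict when
the matrix comes from a coherent pseudoknot-free ensemble (incompatible
pairs have marginals summing to ≤ 1). A conflicting selection is therefore
diagnosed as a broken external matrix and raised as an error rather than
silently resolved.

**Closed forms.** Pseudo-SEN has a σ-independent denominator, so its
maximizer is the maximum-total-probability structure (computed exactly by
the same DP with gains p_ij, rather than by a "large enough" finite γ);
pseudo-PPV is maximized by the single most probable pair (ties: smallest i,
then j).

**Method M1.** Sample n structures, deduplicate, score each candidate's
pseudo-expected MCC/F against {p_ij}, return the argmax (ties: fewer pairs,
then lexicographic pair order). Deduplication is purely a speed measure —
scores depend only on the structure. SEN/PPV requests are rejected since
their maximizers are closed-form.

**Method M2.** The 17-value grid {2^k : −5 ≤ k ≤ 10} ∪ {6} spans the SEN–PPV
curve from near-empty to near-maximal predictions; γ ≤ 1 candidates come
from thresholding (γ = 1 included there) and γ > 1 candidates from the DP.
Candidates are deduplicated keeping the smallest generating γ as provenance
(this affects only diagnostics, never the argmax) and the best
pseudo-expected MCC/F wins, ties to the smaller γ. The selected score
dominates every single-γ prediction by construction, which is asserted in
the acceptance suite. Direct optimization of the expected or pseudo-expected
MCC/F over the whole structure space is not implemented: the ratio/product
structure of these measures prevents decomposition into subproblems, and the
enumeration oracle covers exact comparisons at small lengths.

## Test fixtures and what they show

Tests and the acceptance script run on seeded random sequences (uniform
A/C/G/U composition, lengths 10–14, 20 instances; M1 convergence uses
12-nt instances) under both the default and the uniform (all canonical
weights equal) models, with sample size N = 50,000 where sampling fidelity
or M1 convergence is measured. These sizes keep every property checkable
against exhaustive enumeration while exercising each code path; random
uniform-composition sequences lack the base-composition bias, conserved
helices and length of real RNAs, so passing tests demonstrate algorithmic
correctness of the estimators and the ensemble machinery — not predictive
accuracy on biological sequences, which depends on the quality of the
supplied probability model.

Statistical checks use fixed seeds with explicit error budgets: binomial
frequency checks at 3–4 standard errors (the sampled-expectation check
averages 5 independent seeds to tighten its Monte-Carlo bound), chi-square
goodness of fit at α = 0.01 with low-expectation bins (< 5) merged, and
Spearman rank correlation > 0.9 between pseudo-expected and exact expected
accuracy pooled over all γ-grid candidates.

## Numerical choices and limitations

- Probabilities and DP scores are double precision; oracle agreement is
  asserted at 1e−9 (absolute for probabilities, relative for Z) and exact
  float equality is used inside DP tracebacks, which is safe because fill
  and traceback evaluate identical expressions.
- Matrix constructors clamp entries to [0, 1] within a 1e−6 read tolerance
  (1e−9 for internally computed matrices) and validate the single-partner
  bound.
- Coordinates are 1-based inclusive everywhere (CT convention).
- Structure readers (dot-bracket, CT) accept hairpins of any size
  (min_hairpin = 0): external reference structures may close loops shorter
  than the folding default, and evaluation must not reject them. Folding
  and sampling keep the default of 3.
- The CLI maps each named error class to a distinct nonzero exit status
  (3–11); conflicting flags are usage errors (status 2).
- Known limitations: no nearest-neighbour energies, no pseudoknots, no
  suboptimal-structure enumeration by energy band, no slippage-tolerant
  ("relaxed") accuracy variants, and no common-structure prediction over
  alignments. The built-in model is a testbed ensemble; biological use
  should supply posteriors from a full thermodynamic or machine-learned
  model via `--bpp-in`.
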