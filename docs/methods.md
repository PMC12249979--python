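# Methods

## The model of rare-character evidence

The analysis treats two kinds of rare characters as phylogenetic evidence
for placing a fast-evolving query clade inside a candidate group:
individual amino-acid residues in mitochondrial proteins, and oriented
gene-order adjacencies. Each character carries two database frequencies:
its stability `s` (fraction of group members retaining it) and its
homoplasy `h` (fraction of species outside the group showing the same
state). Query species are excluded from both denominators so they cannot
contaminate the evidence they are being tested against; residues `X`
(observed but unknown) and `-` (absent) are excluded from numerator and
denominator alike, and an empty denominator is reported as "no data",
never as zero.

Two competing hypotheses are quantified:

* **Independent emergence.** If the query clade does not belong to the
  group, each shared feature arose independently with probability `h_i`.
  The count of shared features is then Poisson-binomial; the package
  computes exact `q_k` by dynamic-programming convolution (cross-validated
  against exhaustive subset enumeration to 1e-12 for n ≤ 20), tail sums
  `x_k`, and the subset-average `q_k / C(n,k)` — the mean over all
  k-subsets of the probability that exactly that subset emerges, which is
  the right scale for "this particular set of k features". Both are always
  reported, labelled. Pairwise dependencies between features can be
  supplied as conditional probabilities P(j | i); the involved features are
  then enumerated jointly (each feature may condition on at most one other;
  cycles are rejected) and convolved with the independent remainder. When
  P(j | ¬i) is not given it defaults to the marginal-preserving value
  `(h_j − P(j|i)·h_i)/(1 − h_i)`, so supplying P(j|i) = h_j reproduces
  independence exactly. With no dependency table the default is
  independence, which understates `q_k` for k ≥ 2 when features are
  positively coupled; reports therefore flag whether adjustments were
  applied.

* **Rate-adjusted loss.** If the query clade does belong to the group, the
  features it lacks must have been lost. A feature retained by a fraction
  `s_i` of ordinary group members is retained by a lineage evolving r-fold
  faster with probability `a_i = s_i^r`; the probability of losing a
  specific subset M is `p = Π_{i∈M} (1 − s_i^r)`, computed via `expm1` in
  log space so near-one retentions do not cancel. The rate ratio r is
  measured on the input tree as the mean root-to-tip path length of the
  focal leaves over that of the other group leaves, both from their common
  ancestor.

The gene-order side uses oriented adjacencies of signed circular orders,
canonicalized so a reading and its reverse-complement are one key; a
circle of n tokens yields exactly n keys, invariant under rotation. The
conventional closed-form bound for a designated adjacency in a randomized
order is ½ × 1/n (orientation factor times a uniform choice among n
features); the exact probability for an n-token circle is ½ × 1/(n−1) —
at n = 37 the two differ by 0.04 percentage points, far inside Monte-Carlo
noise at 10⁵ draws, and the package reports the conventional form while
its tests verify both against permutation sampling. Residue-level and
adjacency-level probabilities are combined by simple multiplication under
an explicit independence assumption, and the summary report always shows
emergence and loss probabilities side by side rather than a combined
verdict: the argument is two-sided by nature.

## Ancestral reconstruction

A column is apomorphic for a clade when the state assigned at the clade
root differs from the state at the next deeper node. Two reconstruction
modes are implemented on the fixed input tree (branch lengths taken as
given, no re-optimization):

* **Fitch parsimony**, two-pass, generalized to polytomies by sequential
  intersection/union folding; gaps and `X` are wildcards. Any multi-state
  set at the clade root or its parent suppresses the call (conservative).
* **ML marginal posteriors** under the 20-state equal-exchangeability
  model with empirical stationary frequencies (pseudocount 1), for which
  transition probabilities have the closed form
  `P(t) = e^{−βt} I + (1 − e^{−βt}) 1 π^T` with `β = 1/(1 − Σπ²)` so branch
  lengths are expected substitutions per site. Discrete-gamma rate
  heterogeneity (median rates of equal-probability bins, renormalized to
  mean 1) is available; posteriors are computed by pruning (up) and down
  messages with per-column log-scaling, mixed over rate categories by their
  column likelihoods, and are verified against brute-force enumeration
  over all internal labelings on small trees to 1e-10. A call requires the
  MAP posterior at the clade root to reach `p_min` (default 0.5, plain
  argmax with a floor; ties are ambiguity, hence no call).

The pipeline's candidate generation unions the calls of both modes.
Parsimony ignores branch lengths and therefore resists the pull a long
group stem exerts on the ML posterior at the crown; ML supplies posterior
confidence. Recall is the priority at this stage because every candidate
is subsequently re-screened against the database, which is where the
specificity comes from; reconstruction-model refinement has little
downstream effect for the same reason. Reconstruction runs on a reduced
tree (all group members plus a seeded sample of 40 outside exemplars,
query species excluded so the group is monophyletic and the queries cannot
shape the calls); screening then uses the full database.

## The synthetic reference database

Real reference databases are downloads of 10⁴ genomes; the generator
produces a statistically equivalent mock at configurable scale so the
whole pipeline runs offline. Defaults are the study-scale conditions: a
157-species group, 5,000 outside species, a 3-species query clade at rate
ratio 18.83, five protein genes totalling 530 columns, and nine planted
features whose `s_true` (0.63–0.99) and `h_true` (0.001–0.030) profiles
span the screening thresholds, four of them carried by the query clade.

* **Trees.** Pure-birth (Yule) topologies with lognormal relaxed-clock
  jitter (σ = 0.3) on every branch; the group crown is scaled to a mean
  depth of 0.87 substitutions/site and grafted, with a 0.6 stem, onto a
  shallow internal edge of the outside tree (mean depth 1.2) — nesting the
  group inside the outside diversity is what gives the node below the
  group crown close outside relatives, as in a real reference-wide
  phylogeny. The query clade is grafted near the base of the group crown
  (attachment depth capped at 0.15 × group depth) and the entire grafted
  path is multiplied by `r_true`, so the realized rate ratio is recoverable
  from path lengths and the clade degenerates to an ordinary subclade at
  `r_true = 1`.
* **Sequences.** Non-planted columns evolve by the same
  equal-exchangeability model used in reconstruction, with per-site gamma
  rates (α = 0.8) and a hydrophobic, AT-leaning stationary composition;
  query-clade branches draw replacement residues from frequencies
  reweighted 2.5× toward the AT-rich codon amino acids F, M, I, N, K,
  which reproduces the compositional-attraction axis the diagnostics
  measure. Planted columns bypass the substitution model: the derived
  residue is fixed at the group stem and each group leaf retains it
  independently with `s_true`, each outside leaf shows it with `h_true`,
  and query leaves show it iff flagged — direct Bernoulli control is what
  makes exact parameter-recovery tests possible.
* **Gene orders.** 37 tokens (13 protein-coding genes, 22 tRNAs, 2 rRNAs;
  the control region is an optional 38th). Orders evolve by random
  inversions and transpositions at Poisson(rate × branch length), default
  2 events per substitution/site. The ancestral order deliberately
  separates the planted pair; the adjacency is created on the group stem
  and events that would break it are redrawn within the group clade, so it
  is a derived character fixed in the group and present outside only
  through chance rearrangement.

What the generator does **not** emulate: indels and alignment error, codon
structure, clustered (lineage-correlated) feature loss — losses are i.i.d.
across leaves, which scatters reversals and if anything favours detection —
database taxon-sampling imbalance beyond the configured group sizes, and
real compositional covariation between sites. Passing tests therefore show
the pipeline's operations are correct and calibrated under the stated
model, not that the thresholds are optimal for real mitogenome data.

## Numerical and design choices

* All column indices are 0-based half-open internally; reports are 1-based
  and say so.
* Probability products run in log space where many small factors occur;
  the Poisson-binomial DP stays in linear space (n is small and the terms
  are convex combinations, so it is stable).
* MAP ties (posterior within 1e-9 of the maximum, or multi-state Fitch
  sets) are treated as ambiguity and yield no call.
* Screening comparisons are inclusive inequalities on exact fractions
  (`h ≤ h_max`, `s ≥ s_min`); a feature whose true `h` sits exactly at the
  cutoff is retained or dropped by sampling noise in `ĥ`, which is the
  expected behaviour at a boundary, not an artefact.
* The stability rule "lost in more than 40% of the group" is implemented
  as `s ≥ 0.60`, so a 63%-stable feature passes.
* The expected number of database species reaching a tail event is the
  plain product `n × x_k`; no multiple-testing correction is applied
  across columns, matching the analysis this package implements.
* Determinism: every stochastic stage draws from generators derived from
  the single config seed (fixed stream ids per stage), so identical
  configs give byte-identical trees, alignments, orders and reports.

## Known limitations

* Detection of weakly retained features is genuinely boundary-limited: at
  `s_true = 0.63` (just above the 0.60 stability cutoff) the clade-root
  reconstruction sits near the decision boundary and the feature is missed
  in a minority of random replicates under either reconstruction mode.
  This is the method's sensitivity limit at study conditions, not a bug;
  the union-mode default reduces but does not eliminate it.
* Emergence probabilities for k ≥ 2 are reported under independence unless
  a dependency table is supplied; positively coupled features make the
  independence values underestimates.
* The shared-feature excess statistic counts a position once per qualifying
  residue and compares against a sum-of-frequencies expectation; it is a
  screening heuristic, not a calibrated test.
* Problem sizes in the test suite are scaled to the defaults above
  (5,160 species, 530 columns, one full end-to-end replicate), which the
  package's own tests complete in well under a minute each.
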