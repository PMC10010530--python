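# Methods

## The evolutionary model

Directed laboratory evolution iterates mutagenesis and selection on a
population of protein-coding sequences.  We model one round as a Markov
transition on the space Ω of codon sequences of fixed length L over the 61
sense codons: a parent x produces a descendant y with probability

    p(x → y) = g(x → y) π(y) / Σ_z g(x → z) π(z)

where g is the mutation kernel and π the relative fitness.  The model makes
four assumptions, each explicit and separately testable in the package:

1. **Independent per-base mutation.**  g factorizes over DNA positions; the
   per-position codon kernel is the 3-fold product of a single 4×4 base
   substitution matrix.
2. **Time homogeneity.**  Neither g nor π changes between rounds.
3. **Effectively infinite population.**  Sequence prevalence depends only on
   relative fitness, not on demographic noise.
4. **Lineage-local selection.**  Competition happens only among a parent's
   direct descendants.  This is the "simplified dynamics" approximation; in a
   real experiment all lineages compete globally.  It is accurate when
   competing sequences have similar fitness (a locally flat landscape, low
   mutation rates, early rounds).

Fitness is parameterized as a generalized Potts model on amino acids:
log π(x) = Σ_i h_i(a_i) + Σ_{i<j} e_ij(a_i, a_j) up to an additive constant.
The partition function over |Ω| = 61^L states is never evaluated; every
computation in the package uses score differences (log fitness ratios) only.
Consequently the overall scale of the parameters is meaningful for the
dynamics (unlike in equilibrium DCA, doubling θ changes the model), but it is
only weakly identified from trajectory data; recovery claims in the test
suite are rank-based, never absolute.

### Mutation kernel construction

The 4×4 substitution-bias table (shipped default: a synthetic, representative
Taq error-prone-PCR spectrum — AT-biased, transition-heavy; substitute your
own when the experimental spectrum is known) is scaled by a single global
factor so the expected number of DNA substitutions per gene per round equals
the target load (default 4.0), evaluated at uniform base composition; the
true expectation depends weakly on the actual base composition of the gene.
Transitions into the three stop codons are treated as lethal: stop columns
are removed and rows renormalized over the 61 sense codons, which keeps the
chain on Ω.  If the requested load would push any per-base substitution
probability to 1, construction fails rather than silently saturating.

### Simulation

Exact sampling from p(x → ·) requires the intractable normalizer, so the
simulator uses finite-brood sampling: each parent draws B offspring
independently from g, and one is retained with probability proportional to
its fitness (Gumbel-max over the brood's scores).  As B → ∞ the per-parent
transition law converges to the exact kernel; at L = 1 with B = 1000 the
empirical law is within total variation 0.02 of the exact one (asserted in
the tests).  Defaults: B = 100, constant population size N (default 10⁴ for
the library, 5×10³ for the desk-scale fixture).  On enumerable toy spaces
(61^L states, L ≤ 2) the package also builds the exact transition matrix and
propagates distributions exactly; this is the oracle every approximation is
tested against.

## Moment propagation

Tracking p^(r) exactly is impossible at realistic L, so the inference works
with first- and second-order codon marginals.  Under a weak-dependence
assumption the round-(r+1) marginals follow from the round-r marginals, the
kernel g, and the marginals μ of π itself:

    μ_i^(r+1)(c) ∝ μ_i(c) · Σ_c′ g_i(c′→c) μ_i^(r)(c′) / (Σ_c″ g_i(c′→c″) μ_i(c″))

with the analogous pairwise update using the product kernel g_i ⊗ g_j and
the pair marginals μ_ij.  The recursion preserves normalization exactly (an
algebraic identity, asserted on every call) and is exact when π factorizes
over positions — verified against exact propagation on an enumerable L = 2
space to 1e-10 per entry per round.  With couplings it is an approximation
whose error grows with interaction strength.  Evolution starts from a pure
wild-type population, so round 0 is a point mass on the wild-type codons.
A zero denominator (a populated codon from which no landscape mass is
reachable) raises an error naming the position and codon state: it signals
an inconsistent landscape/kernel configuration, not a numerical accident, so
it is never epsilon-floored.

## Inference

### Parameterization

The landscape marginals are reparameterized at the amino-acid level:
ν_i = softmax(γ_i) over 20 amino acids, and μ_i(c) = ν_i(AC(c)) normalized
over codons (synonymous codons share mass by construction), with the
pairwise analogue (softmax over 400 amino-acid pairs).  This enforces
normalization and amino-acid-level structure exactly; global consistency of
the mean vector (realizability by a joint distribution) is a
marginal-polytope constraint that is deliberately relaxed.

### Objective

The loss is the aggregated cross-entropy between observed codon frequencies
f^(r) (first order, and second order over ordered position pairs) and the
propagated marginals μ^(r)(γ) at every sequenced round, plus

* ℓ2 penalties λ_main Σ‖γ_i‖² and 2 λ_int Σ‖γ_ij‖² (defaults 1e-3 and 1e-4),
* a local-consistency penalty ρ Σ_i Σ_a (ν_i(a) − mean_j Σ_b ν_ij(a,b))²
  with ρ = 1e5, tying single-site marginals to the pair tables.

Defaults follow the published framework: Adam, learning rate 0.03, 300
steps.  Optimization starts from the log amino-acid frequencies of the last
sequenced round (pseudocount 1e-6, small enough not to distort observed
frequencies at n ≥ 10³), runs deterministically (no stochastic minibatching,
so identical inputs give bit-identical fits), keeps the best-loss iterate,
and stops early when the relative loss change over a 10-step window falls
below 1e-6.  The early-stopping form and the pseudocount value are this
implementation's choices; the published description states only that both
exist.

Gradients are computed by hand-written reverse-mode differentiation through
the propagation recursion.  The graph decomposes per position and per pair,
so the backward pass is a stack of batched 61×61 matrix products mirroring
the forward pass; it is verified against central finite differences to
relative 1e-4 on an L = 3 problem.  One fit at the fixture scale (L = 30,
435 pairs, 8 rounds) takes roughly a second per step on one CPU.

Notational note: the printed regularizer and penalty use a bare ‖·‖; both
are implemented as sums of squares, the standard ℓ2 reading.

### Mean-field inversion

Canonical parameters come from mean-field DCA on the fitted amino-acid
marginals: build the connected-correlation matrix C_ij(a,b) = ν̂_ij(a,b) −
ν̂_i(a) ν̂_j(b) over L×19 dimensions in a reference-state gauge (the
wild-type amino acid dropped at each site, matching the mutation-effect
convention; fall back to each site's most probable amino acid when no wild
type is supplied), then

    e = −(C + λ_reg I)⁻¹   (off-diagonal blocks),
    h_i(a) = log(ν̂_i(a)/ν̂_i(ref_i)) − Σ_{j≠i,b} e_ij(a,b) ν̂_j(b).

λ_reg defaults to 50 (the published real-data value); the accompanying
guidance is to set it several times larger than the magnitude of C's most
negative eigenvalue, which depends on the data scale.  On the desk-scale
fixture the Frobenius *ranking* is insensitive to λ_reg across three orders
of magnitude (large λ makes e ≈ C/λ², a pure rescaling), so the default is
safe for contact ranking; absolute coupling magnitudes, and therefore
epistasis counts on inferred models, do scale with it.  A numerically
singular (C + λI) raises an error advising a larger λ_reg.

## Analyses

* **Mutation-effect map**: (L × 20) single-mutant score changes from the
  wild type; wild-type entries are exactly 0.
* **Interaction scores**: couplings are gauge-redundant, so blocks are first
  converted to the zero-sum gauge (row and column means removed; score
  differences preserved when the means are absorbed into fields) and ranked
  by Frobenius norm F_ij.  Only long-range pairs (|i−j| > 5) are ranked; no
  average-product correction is applied, matching the published procedure.
* **Contact PPV**: fraction of the top ⌊L/2⌋ ranked long-range pairs within
  5 Å (and 8 Å) in a reference contact map, against the long-range contact
  density as the chance baseline.  Pairs absent from the map count as
  non-contacts.
* **Epistasis**: every double mutant of the wild type is classified by the
  sign pattern of the two single effects in each other's backgrounds:
  reciprocal sign (both flip — which in a pairwise model forces the signs to
  agree), sign (exactly one flips), additive (neither).  Effects smaller
  than a tolerance (default 1e-9) are treated as zero and never flip; the
  published counts state no tie rule, so these counts are reported
  properties, not targets.
* **Adaptive walks**: greedy steepest ascent at the amino-acid level with
  single or single+double move sets, deterministic tie-breaking (lowest
  position, then alphabetical amino acid; single preferred over an equal
  double).  Scores are updated incrementally (only the terms touching the
  mutated site change); endpoints can be re-verified by exhaustive
  neighborhood enumeration.  Codon-level accessibility is not imposed on
  in-silico walks.

## Synthetic data: what it does and does not emulate

The fixture generator plants a sparse ground truth: i.i.d. normal fields
(scale 1.0), zero-sum-gauged normal coupling blocks (scale 1.5) at 5
uniformly chosen long-range pairs, a wild type at the field argmax perturbed
at 2 sites, and a contact map in which exactly the planted pairs are < 5 Å
(decoys at 15 Å).  Trajectories use the packaged bias at 4 substitutions per
gene per round: L = 30, 8 rounds, N = 5000, B = 100, 2000 sequences sampled
per round.  These scales make coupling signal statistically visible at desk
scale while keeping the full pipeline within minutes on one CPU.

The generator reproduces the statistical structure the method assumes —
Markov dynamics over a planted landscape, mutation bias, delta
initialization, linearly growing distance from wild type.  It does not
emulate sequencing error, PCR recombination, read-level artifacts, global
(quasispecies) competition, selection-pressure schedules, or indels.
Passing recovery tests therefore demonstrates correctness of the machinery
under the model's own assumptions, not robustness to the ways real
experiments violate them.

## Design choices and measured behavior

* **Problem sizes.**  The real experiment (L = 186, 15 rounds, n up to 10⁵)
  is not desk-reproducible; all recovery surfaces are evaluated at the
  fixture scale above.  In-paper arithmetic (mutation load, top-L/2 rank
  counts, double-mutant combination counts) is asserted exactly.
* **Recovery is rank-based and imperfect by construction.**  On the pinned
  fixture, raw mutual information of the last round's pair frequencies
  already ranks only 4 of 5 planted pairs in its top 10 (one pair's signal
  never reaches the samples), which bounds what any inference can see.
* **Objective optimum ≠ truth.**  On an independent-site problem (L = 10,
  5 rounds, n = 2000) the fitted marginals' correlation with the planted
  ones peaks below 0.9 and *decreases* if optimization runs far beyond the
  default step budget: the approximate-recursion objective over-fits its own
  approximation error.  The default 300-step budget acts as implicit
  regularization.
* **Degenerate inputs.**  Empty rounds, mixed-length records, stop codons
  and ambiguity codes are rejected with counts logged, never imputed.
  Single-sequence rounds report pairwise distance 0 with a degeneracy flag.
  Pairwise distance uses all pairs up to a configurable budget (default
  2×10⁵), beyond which pairs are subsampled uniformly and flagged.

## Known limitations

* The moment recursion's accuracy degrades with coupling strength; no
  correction terms are included.
* The fitness scale is only weakly identified; mutation-effect magnitudes
  should be read comparatively.
* Mean-field inversion inherits the usual DCA failure modes (indirect
  correlations at high sample noise); no APC is applied by design.
* The finite quasispecies regime (global competition) is out of scope; the
  simulator's B and N knobs allow exploring the gap but no fidelity claim is
  made.
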