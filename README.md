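# evopotts

Infer protein fitness landscapes from directed laboratory evolution
sequencing data.

Directed evolution iterates random mutagenesis (error-prone PCR) and
functional selection on a protein population, and modern experiments
sequence the population at multiple rounds.  Those per-round snapshots are
neither labeled sequence-function data nor independent natural homologs, so
standard supervised models and standard DCA both ignore the thing that makes
them informative: the trajectory.  `evopotts` implements a statistical
framework that models the evolutionary process itself and infers the
landscape from how the population moves.

It is a library for computational biologists: the importable API is the main
interface (see `examples/` for narrative scripts), with a thin `evopotts`
command-line wrapper for file-based pipeline runs.

## The model

Evolution is a Markov chain on codon sequences x of length L over the 61
sense codons.  One round of mutagenesis + selection takes x to y with

    p(x → y) = g(x → y) π(y) / Σ_z g(x → z) π(z)

where g is the (known, experiment-derived) mutation kernel and π the
relative fitness, parameterized by a generalized Potts model on amino acids:

    log π(x) ∝ Σ_i h_i(AC(x_i)) + Σ_{i<j} e_ij(AC(x_i), AC(x_j)).

Exact likelihood maximization over 61^L states is hopeless, so inference is
approximate moment matching: (1) a recursion propagates first/second-order
codon marginals μ^(r) across rounds as functions of the landscape's own
marginals μ; (2) μ is estimated by minimizing the cross-entropy between
propagated and observed per-round frequencies (softmax-reparameterized at
the amino-acid level, with ℓ2 and local-consistency penalties, optimized by
Adam with hand-derived exact gradients); (3) canonical parameters (h, e)
come from mean-field DCA inversion of the estimated correlation matrix.

On top of the inferred landscape the package computes mutation-effect maps,
zero-sum-gauge Frobenius interaction scores F_ij, contact PPV against a
structure, sign/reciprocal-sign epistasis classification, and greedy
adaptive walks (single or single+double mutant moves) for landscape surveys
and trajectory extrapolation.  A forward simulator (finite-brood sampling of
the transition law, with an exact-enumeration oracle on tiny spaces) and a
planted-truth fixture generator make every stage testable with no external
data.

## Worked example

Infer a landscape from a simulated trajectory with planted ground truth
(L = 30 residues, 5 planted long-range couplings, 8 sequenced rounds of
2000 sequences; about six minutes on one CPU):

```bash
python examples/02_infer_landscape.py
```

```
optimization: 300 steps, loss 24138 -> 16090

top 10 inferred long-range interactions (1-based positions):
   10 - 24   F = 4.201e-05
   10 - 30   F = 3.562e-05  <- planted
    6 - 24   F = 3.506e-05  <- planted
    4 - 12   F = 2.901e-05  <- planted
    4 - 10   F = 2.319e-05
   10 - 27   F = 2.098e-05
   10 - 16   F = 2.070e-05
    4 - 30   F = 1.895e-05
   12 - 24   F = 1.845e-05
    3 - 10   F = 1.798e-05

3 of the 5 planted coupled pairs rank in the top 10.
```

Reading the output: each F value is the Frobenius norm of a
zero-sum-gauged 20×20 coupling block — the landscape's residue-residue
interaction strength (its absolute scale is set by the inversion
regularization; only the ranking is meaningful).  The method saw only
per-round FASTA samples, yet planted interacting pairs fill three of the
top four ranks, and the spurious entries share positions with planted
pairs (hitchhiking correlations from shared ancestry).  One planted pair's
signal never reaches the sequenced samples at all — its mutual information
in the data is indistinguishable from noise — which is an
information-theoretic ceiling, not an inference failure; see
`docs/methods.md` for what recovery at this desk scale does and does not
demonstrate.

The other example scripts cover simulation (`01`), epistasis and contact
PPV (`03`), and adaptive walks (`04`).  The same stages are available as
`evopotts synth | simulate | moments | infer | score | epistasis | walk |
survey | evaluate`, each emitting a JSON run manifest for reproducibility.

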