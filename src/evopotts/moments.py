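"""Codon marginals: empirical frequencies and approximate moment propagation.

The population's first- and second-order codon marginals at round r+1 are
approximated recursively from the round-r marginals, the mutation kernel g,
and the marginals mu of the fitness landscape itself:

    mu_i^(r+1)(c)      proportional to   mu_i(c) * sum_c' g_i(c'->c) w_i(c')
    with w_i(c') = mu_i^(r)(c') / sum_c'' g_i(c'->c'') mu_i(c'')

and the analogous pairwise update with the product kernel g_i x g_j.  The
recursion is derived under a weak-dependence assumption and is exact when the
landscape factorizes over positions; normalization is preserved exactly by
the update (an algebraic identity, asserted numerically on every call).

Evolution starts from a pure wild-type population, so the round-0 moment
vector is a point mass on the wild-type codons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mutation import MutationModel
from .potts import pair_indices
from .seqcore import ALPHABET, CodonSequence, RoundSample


class MomentPropagationError(ValueError):
    """A populated codon cannot reach any landscape mass (zero denominator)."""


@dataclass
class MomentVector:
    """First- and second-order codon marginals.

    ``first`` is (L, 61); ``second`` is (P, 61, 61) in :func:`pair_indices`
    order.  Each first-order block and each pair block sums to 1.
    """

    first: np.ndarray
    second: np.ndarray

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=float)
        self.second = np.asarray(self.second, dtype=float)
        L = self.first.shape[0]
        P = L * (L - 1) // 2
        if self.first.shape != (L, 61) or self.second.shape != (P, 61, 61):
            raise ValueError("inconsistent moment-vector shapes")

    @property
    def L(self) -> int:
        return self.first.shape[0]

    def check_normalized(self, atol: float = 1e-10) -> None:
        if not np.allclose(self.first.sum(axis=1), 1.0, atol=atol):
            raise ValueError("first-order blocks do not sum to 1")
        if not np.allclose(self.second.sum(axis=(1, 2)), 1.0, atol=atol):
            raise ValueError("second-order blocks do not sum to 1")


@dataclass
class EmpiricalFrequencies:
    """Observed codon frequencies of one sequenced round."""

    round_index: int
    first: np.ndarray  # (L, 61)
    second: np.ndarray  # (P, 61, 61)
    n: int


def empirical_frequencies(sample: RoundSample) -> EmpiricalFrequencies:
    """Indicator-average codon frequencies of a round sample.

    ``first[i, c]`` is the fraction of sequences carrying codon c at position
    i; ``second[p, c, d]`` the fraction carrying the codon pair (c, d) at the
    p-th position pair.  Marginal consistency (summing the pair table over
    one codon recovers the single-site table) holds exactly because both are
    averages of the same indicators.
    """
    X = sample.codons
    n, L = X.shape
    first = np.stack([np.bincount(X[:, i], minlength=61) for i in range(L)]) / n
    iu, ju = pair_indices(L)
    second = np.empty((iu.size, 61, 61))
    for p in range(iu.size):
        codes = X[:, iu[p]] * 61 + X[:, ju[p]]
        second[p] = np.bincount(codes, minlength=61 * 61).reshape(61, 61) / n
    return EmpiricalFrequencies(sample.round_index, first, second, n)


def aggregate_to_amino_acids(
    freqs: EmpiricalFrequencies,
) -> tuple[np.ndarray, np.ndarray]:
    """Amino-acid frequency tables ((L, 20), (P, 20, 20)) from codon tables."""
    T = np.zeros((61, 20))
    T[np.arange(61), ALPHABET.ac_map] = 1.0
    first = freqs.first @ T
    second = np.einsum("pcd,ca,db->pab", freqs.second, T, T)
    return first, second


def init_moments(wildtype: CodonSequence) -> MomentVector:
    """Round-0 moments: a point mass on the wild-type codons."""
    L = wildtype.length
    first = np.zeros((L, 61))
    first[np.arange(L), wildtype.codons] = 1.0
    iu, ju = pair_indices(L)
    second = np.zeros((iu.size, 61, 61))
    second[np.arange(iu.size), wildtype.codons[iu], wildtype.codons[ju]] = 1.0
    return MomentVector(first, second)


def propagate_moments(
    mu_landscape: MomentVector,
    mu_round: MomentVector,
    model: MutationModel,
) -> MomentVector:
    """One application of the recursive moment update (round r -> r + 1)."""
    L = mu_landscape.L
    v1 = mu_landscape.first
    M1 = mu_round.first

    if model.overrides:
        gs = model.kernels()
        D1 = np.einsum("icd,id->ic", gs, v1)  # D1[i, c'] = sum_c'' g_i(c'->c'') v
    else:
        D1 = v1 @ model.kernel.T
    _check_denominator(D1, M1, "position")
    W1 = np.divide(M1, D1, out=np.zeros_like(M1), where=M1 > 0)
    if model.overrides:
        S1 = np.einsum("ic,icd->id", W1, gs)
    else:
        S1 = W1 @ model.kernel
    first = v1 * S1

    iu, ju = pair_indices(L)
    V2 = mu_landscape.second
    M2 = mu_round.second
    gi = np.stack([model.kernel_for(int(i)) for i in iu]) if model.overrides else None
    gj = np.stack([model.kernel_for(int(j)) for j in ju]) if model.overrides else None
    if model.overrides:
        D2 = np.einsum("pce,pef,pdf->pcd", gi, V2, gj)
    else:
        g = model.kernel
        D2 = np.matmul(g, np.matmul(V2, g.T))
    _check_denominator(D2, M2, "pair")
    W2 = np.divide(M2, D2, out=np.zeros_like(M2), where=M2 > 0)
    if model.overrides:
        S2 = np.einsum("pec,pef,pfd->pcd", gi, W2, gj)
    else:
        S2 = np.matmul(g.T, np.matmul(W2, g))
    second = V2 * S2

    out = MomentVector(first, second)
    out.check_normalized()
    return out


def _check_denominator(D: np.ndarray, M: np.ndarray, what: str) -> None:
    bad = (D == 0) & (M > 0)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise MomentPropagationError(
            f"zero propagation denominator at {what} {idx[0]}, codon state {tuple(idx[1:])}: "
            "the landscape marginals place no mass reachable from a populated codon"
        )


def propagate_to_round(
    mu_landscape: MomentVector,
    wildtype: CodonSequence,
    model: MutationModel,
    rounds: int,
) -> list[MomentVector]:
    """Moment vectors for rounds 0..rounds, starting from the wild-type delta."""
    out = [init_moments(wildtype)]
    for _ in range(rounds):
        out.append(propagate_moments(mu_landscape, out[-1], model))
    return out


def export_first_order_tsv(first: np.ndarray, path) -> None:
    """Write an (L, 61) first-order codon table as TSV (1-based positions)."""
    pd.DataFrame(
        first, columns=ALPHABET.codons, index=np.arange(1, first.shape[0] + 1)
    ).to_csv(path, sep="\t", index_label="position")
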