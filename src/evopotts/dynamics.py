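"""Mutation-selection Markov-chain dynamics of directed evolution.

One round takes a parent sequence x to a descendant y with probability

    p(x -> y) = g(x -> y) pi(y) / sum_z g(x -> z) pi(z)

where g is the mutation kernel and pi the relative fitness under the Potts
landscape: selection acts only among a parent's direct descendants, and the
transition mechanism is identical every round (time homogeneity).

Two implementations are provided.  ``exact_kernel`` / ``propagate_exact``
enumerate the state space and serve as the brute-force oracle on toy spaces
(L <= 2 over the full codon alphabet).  ``simulate_round`` /
``simulate_trajectory`` scale to realistic gene lengths by finite-brood
sampling: each parent draws B offspring from g and one is retained with
probability proportional to pi, a per-parent scheme whose transition law
converges to the exact kernel as B grows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .mutation import MutationModel
from .potts import PottsModel, score_many
from .seqcore import ALPHABET, CodonSequence, RoundSample, TrajectoryDataset


class StateSpaceTooLargeError(ValueError):
    """Raised instead of silently truncating an unenumerable state space."""


def enumerate_states(L: int, max_states: int = 5000) -> np.ndarray:
    """All sense-codon sequences of length L as an (|Omega|, L) index matrix."""
    n = 61**L
    if n > max_states:
        raise StateSpaceTooLargeError(
            f"|Omega| = 61^{L} = {n} exceeds the enumeration budget {max_states}"
        )
    return np.array(list(itertools.product(range(61), repeat=L)), dtype=np.intp)


@dataclass
class TransitionKernel:
    """Exact per-round transition matrix on an enumerated state space."""

    states: np.ndarray  # (S, L) codon indices
    matrix: np.ndarray  # (S, S) row-stochastic

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    def state_index(self, seq: CodonSequence) -> int:
        hit = np.flatnonzero((self.states == seq.codons).all(axis=1))
        if hit.size != 1:
            raise ValueError("sequence not in state enumeration")
        return int(hit[0])


def mutation_matrix(model: MutationModel, states: np.ndarray) -> np.ndarray:
    """g(x -> y) over an enumerated state space (product over positions)."""
    S, L = states.shape
    g = np.ones((S, S))
    for i in range(L):
        k = model.kernel_for(i)
        g *= k[states[:, i][:, None], states[:, i][None, :]]
    return g


def landscape_weights(landscape: PottsModel, states: np.ndarray) -> np.ndarray:
    """Unnormalized relative fitness pi(x) over the enumerated states."""
    s = score_many(landscape, ALPHABET.ac_map[states])
    return np.exp(s - s.max())


def exact_kernel(
    model: MutationModel,
    landscape: PottsModel,
    states: np.ndarray | None = None,
    max_states: int = 5000,
) -> TransitionKernel:
    """Exact one-round transition kernel p(x->y) on an enumerable space.

    Refuses (with :class:`StateSpaceTooLargeError`) rather than truncating
    when the space exceeds ``max_states`` states.
    """
    if states is None:
        states = enumerate_states(landscape.L, max_states=max_states)
    states = np.asarray(states, dtype=np.intp)
    if states.shape[0] > max_states:
        raise StateSpaceTooLargeError(
            f"{states.shape[0]} states exceeds budget {max_states}"
        )
    g = mutation_matrix(model, states)
    pi = landscape_weights(landscape, states)
    p = g * pi[None, :]
    p /= p.sum(axis=1, keepdims=True)
    return TransitionKernel(states=states, matrix=p)


def propagate_exact(
    kernel: TransitionKernel, p0: np.ndarray, rounds: int
) -> np.ndarray:
    """Distributions p^(0..rounds) under repeated application of the kernel.

    Returns an (rounds + 1, S) array whose first row is ``p0``.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (kernel.n_states,) or not np.isclose(p0.sum(), 1.0):
        raise ValueError("p0 must be a probability vector over the states")
    out = np.empty((rounds + 1, kernel.n_states))
    out[0] = p0
    for r in range(rounds):
        out[r + 1] = out[r] @ kernel.matrix
    return out


def state_marginals(states: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-position codon marginals (L, 61) of a distribution over states."""
    S, L = states.shape
    out = np.zeros((L, 61))
    for i in range(L):
        np.add.at(out[i], states[:, i], p)
    return out


@dataclass
class PopulationState:
    """A fixed-size population of codon sequences at one round."""

    round_index: int
    codons: np.ndarray  # (N, L) integer codon indices

    @property
    def size(self) -> int:
        return self.codons.shape[0]


def _sample_offspring(
    parents: np.ndarray, model: MutationModel, B: int, rng: np.random.Generator
) -> np.ndarray:
    """(B, N, L) offspring codons, each drawn independently from g(x -> .)."""
    N, L = parents.shape
    offspring = np.empty((B, N, L), dtype=np.int16)
    if model.overrides:
        for i in range(L):
            cum = np.cumsum(model.kernel_for(i), axis=1)
            col = parents[:, i]
            for c in np.unique(col):
                sel = np.flatnonzero(col == c)
                u = rng.random((B, sel.size))
                offspring[:, sel, i] = np.searchsorted(cum[c], u, side="right")
    else:
        cum = np.cumsum(model.kernel, axis=1)
        for c in range(61):
            pos = np.nonzero(parents == c)
            if pos[0].size == 0:
                continue
            u = rng.random((B, pos[0].size))
            offspring[:, pos[0], pos[1]] = np.searchsorted(cum[c], u, side="right")
    return np.minimum(offspring, 60)


def simulate_round(
    pop: PopulationState,
    model: MutationModel,
    landscape: PottsModel,
    brood_size: int,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance the population one round of mutagenesis and lineage-local selection.

    Each parent independently draws ``brood_size`` offspring from the mutation
    kernel; one offspring per parent is retained with probability proportional
    to its fitness (Gumbel-max selection over the brood's scores).
    """
    if brood_size < 1:
        raise ValueError("brood_size must be >= 1")
    offspring = _sample_offspring(pop.codons, model, brood_size, rng)
    scores = score_many(landscape, ALPHABET.ac_map[offspring])  # (B, N)
    gumbel = -np.log(-np.log(rng.random(scores.shape)))
    winner = np.argmax(scores + gumbel, axis=0)  # (N,)
    chosen = offspring[winner, np.arange(pop.size)].astype(np.intp)
    return PopulationState(round_index=pop.round_index + 1, codons=chosen)


def simulate_trajectory(
    wildtype: CodonSequence,
    model: MutationModel,
    landscape: PottsModel,
    rounds: int,
    pop_size: int = 10_000,
    brood_size: int = 100,
    seed: int = 0,
    sample_sizes: int | dict[int, int] = 1000,
    sampled_rounds: list[int] | None = None,
) -> TrajectoryDataset:
    """Simulate a directed-evolution run and sample sequenced rounds.

    The population starts as ``pop_size`` copies of the wild type; every round
    applies :func:`simulate_round`.  At each requested round, ``sample_sizes``
    sequences are drawn without replacement.  All randomness derives from
    ``seed`` through named per-round substreams, so identical configurations
    produce identical datasets.
    """
    if rounds < 0 or pop_size < 1:
        raise ValueError("rounds must be >= 0 and pop_size >= 1")
    if sampled_rounds is None:
        sampled_rounds = list(range(1, rounds + 1))
    if isinstance(sample_sizes, int):
        sample_sizes = {r: sample_sizes for r in sampled_rounds}
    for r, n_r in sample_sizes.items():
        if n_r > pop_size:
            raise ValueError(f"sample size {n_r} at round {r} exceeds N={pop_size}")

    ss = np.random.SeedSequence(seed)
    round_rngs = [np.random.default_rng(s) for s in ss.spawn(rounds)]
    sample_rng = np.random.default_rng(ss.spawn(1)[0])

    pop = PopulationState(0, np.tile(wildtype.codons, (pop_size, 1)))
    samples: dict[int, RoundSample] = {}

    def take_sample(r: int) -> None:
        idx = sample_rng.choice(pop_size, size=sample_sizes[r], replace=False)
        samples[r] = RoundSample(r, pop.codons[np.sort(idx)].copy())

    if 0 in sampled_rounds:
        take_sample(0)
    for r in range(1, rounds + 1):
        pop = simulate_round(pop, model, landscape, brood_size, round_rngs[r - 1])
        if r in sampled_rounds:
            take_sample(r)
    return TrajectoryDataset(wildtype=wildtype, rounds=samples)
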