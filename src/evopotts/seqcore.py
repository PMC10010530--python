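"""Codon sequences, the sense-codon alphabet, FASTA I/O and population statistics.

The evolving state space is the set of length-``L`` codon sequences over the
61 sense codons (the 64 triplets minus the three stop codons).  All matrices
in the package index codons in a single canonical order: lexicographic over
``{A, C, G, T}^3`` with the stops removed.  Residue positions are 0-based
internally and 1-based in user-facing output (mutation names like ``N20D``).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_BASES = "ACGT"


class InvalidSequenceError(ValueError):
    """Raised for sequences containing stop codons, ambiguity codes, or bad lengths."""


class CodonAlphabet:
    """The 61 sense codons, the 20 amino acids, and the map between them.

    Attributes
    ----------
    codons : list[str]
        Sense codons in canonical (lexicographic, stops removed) order.
    amino_acids : str
        The 20 amino-acid letters in alphabetical order.
    ac_map : np.ndarray, shape (61,)
        ``ac_map[c]`` is the amino-acid index encoded by codon index ``c``.
    multiplicity : np.ndarray, shape (20,)
        Number of sense codons encoding each amino acid; sums to 61.
    """

    def __init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[1]  # the standard code
        stops = set(table.stop_codons)
        self.codons = [
            "".join(t)
            for t in itertools.product(DNA_BASES, repeat=3)
            if "".join(t) not in stops
        ]
        assert len(self.codons) == 61
        self.codon_index = {c: i for i, c in enumerate(self.codons)}
        self.amino_acids = "ACDEFGHIKLMNPQRSTVWY"
        self.aa_index = {a: i for i, a in enumerate(self.amino_acids)}
        self.ac_map = np.array(
            [self.aa_index[table.forward_table[c]] for c in self.codons], dtype=np.intp
        )
        self.multiplicity = np.bincount(self.ac_map, minlength=20)
        self.n_codons = 61
        self.n_amino_acids = 20

    def aa_of(self, codon: str) -> str:
        """Amino-acid letter encoded by a codon string (raises on stop/unknown)."""
        if codon not in self.codon_index:
            raise InvalidSequenceError(f"not a sense codon: {codon!r}")
        return self.amino_acids[self.ac_map[self.codon_index[codon]]]

    def preferred_codon(self, aa: str) -> int:
        """Canonical codon index for an amino acid (first in canonical order)."""
        return int(np.flatnonzero(self.ac_map == self.aa_index[aa])[0])


#: Module-level singleton; every model in the package shares this ordering.
ALPHABET = CodonAlphabet()


@dataclass(frozen=True)
class CodonSequence:
    """A length-L sequence over the 61 sense codons (the Markov chain state)."""

    codons: np.ndarray  # shape (L,), dtype intp, values in [0, 61)

    def __post_init__(self) -> None:
        arr = np.asarray(self.codons, dtype=np.intp)
        if arr.ndim != 1 or arr.size == 0:
            raise InvalidSequenceError("codon index array must be 1-D and non-empty")
        if arr.min() < 0 or arr.max() >= ALPHABET.n_codons:
            raise InvalidSequenceError("codon index out of range [0, 61)")
        object.__setattr__(self, "codons", arr)

    @property
    def length(self) -> int:
        return int(self.codons.size)

    @classmethod
    def from_dna(cls, dna: str) -> "CodonSequence":
        dna = dna.upper()
        if len(dna) == 0 or len(dna) % 3 != 0:
            raise InvalidSequenceError(
                f"DNA length {len(dna)} is not a positive multiple of 3"
            )
        idx = []
        for i in range(0, len(dna), 3):
            codon = dna[i : i + 3]
            if codon not in ALPHABET.codon_index:
                raise InvalidSequenceError(
                    f"invalid codon {codon!r} at nucleotide {i} (stop or ambiguity code)"
                )
            idx.append(ALPHABET.codon_index[codon])
        return cls(np.array(idx, dtype=np.intp))

    def to_dna(self) -> str:
        return "".join(ALPHABET.codons[c] for c in self.codons)

    def translate(self) -> str:
        return "".join(ALPHABET.amino_acids[a] for a in ALPHABET.ac_map[self.codons])

    def aa_indices(self) -> np.ndarray:
        return ALPHABET.ac_map[self.codons]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CodonSequence) and np.array_equal(
            self.codons, other.codons
        )

    def __hash__(self) -> int:
        return hash(self.codons.tobytes())


def translate(seq: CodonSequence) -> str:
    """Amino-acid string of ``seq`` under the standard genetic code."""
    return seq.translate()


@dataclass
class RoundSample:
    """Sequences sampled from one experimental round.

    The sample is stored as an (n, L) matrix of codon indices; iteration
    yields :class:`CodonSequence` objects.
    """

    round_index: int
    codons: np.ndarray  # (n, L) intp
    n_rejected: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.codons, dtype=np.intp)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("round sample needs at least one sequence")
        if self.round_index < 0:
            raise ValueError("round index must be non-negative")
        self.codons = arr

    @property
    def n(self) -> int:
        return int(self.codons.shape[0])

    @property
    def length(self) -> int:
        return int(self.codons.shape[1])

    def sequences(self) -> list[CodonSequence]:
        return [CodonSequence(row) for row in self.codons]

    def aa_matrix(self) -> np.ndarray:
        """(n, L) matrix of amino-acid indices."""
        return ALPHABET.ac_map[self.codons]

    @classmethod
    def from_sequences(cls, round_index: int, seqs: list[CodonSequence]) -> "RoundSample":
        lengths = {s.length for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"sequences of mixed lengths {sorted(lengths)}")
        return cls(round_index, np.stack([s.codons for s in seqs]))


@dataclass
class TrajectoryDataset:
    """Wild type plus per-round population samples from a directed-evolution run."""

    wildtype: CodonSequence
    rounds: dict[int, RoundSample] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r, sample in self.rounds.items():
            if sample.length != self.wildtype.length:
                raise ValueError(
                    f"round {r} length {sample.length} != wild-type {self.wildtype.length}"
                )

    @property
    def sequenced_rounds(self) -> list[int]:
        return sorted(self.rounds)

    @property
    def length(self) -> int:
        return self.wildtype.length


def aa_hamming(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamming distance between rows of amino-acid index matrices (broadcasting)."""
    return np.count_nonzero(np.asarray(a) != np.asarray(b), axis=-1)


def population_stats(
    dataset: TrajectoryDataset,
    pair_budget: int | None = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-round mean amino-acid distance to wild type and mean pairwise distance.

    Distances are computed on translated (amino-acid) sequences.  The mean
    pairwise distance averages over all unordered pairs; when a round has more
    than ``pair_budget`` pairs, that many pairs are subsampled uniformly
    (flagged in the ``pairwise_subsampled`` column).  A single-sequence round
    reports a pairwise mean of 0 with ``degenerate_pairwise=True``.
    """
    wt_aa = dataset.wildtype.aa_indices()
    rng = np.random.default_rng(seed)
    rows = []
    for r in dataset.sequenced_rounds:
        sample = dataset.rounds[r]
        aa = sample.aa_matrix()
        n = sample.n
        mean_to_wt = float(aa_hamming(aa, wt_aa[None, :]).mean())
        degenerate = n < 2
        subsampled = False
        if degenerate:
            mean_pair = 0.0
        else:
            n_pairs = n * (n - 1) // 2
            if pair_budget is not None and n_pairs > pair_budget:
                subsampled = True
                i = rng.integers(0, n, size=pair_budget)
                j = rng.integers(0, n - 1, size=pair_budget)
                j = np.where(j >= i, j + 1, j)  # uniform off-diagonal pairs
                mean_pair = float(aa_hamming(aa[i], aa[j]).mean())
            else:
                iu, ju = np.triu_indices(n, k=1)
                mean_pair = float(aa_hamming(aa[iu], aa[ju]).mean())
        rows.append(
            {
                "round": r,
                "n": n,
                "mean_dist_to_wt": mean_to_wt,
                "mean_pairwise_dist": mean_pair,
                "pairwise_subsampled": subsampled,
                "degenerate_pairwise": degenerate,
            }
        )
    return pd.DataFrame(rows)


def read_round_fasta(path, round_index: int) -> RoundSample:
    """Read one round's population from a DNA FASTA file.

    Records whose length differs from the first valid record, or that contain
    stop codons or ambiguity codes, are rejected; the count of rejected
    records is logged and stored on the returned sample (``n_rejected``).
    """
    valid: list[np.ndarray] = []
    n_rejected = 0
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = CodonSequence.from_dna(str(rec.seq))
        except InvalidSequenceError:
            n_rejected += 1
            continue
        if length is None:
            length = seq.length
        if seq.length != length:
            n_rejected += 1
            continue
        valid.append(seq.codons)
    if not valid:
        raise InvalidSequenceError(f"no valid records in {path}")
    if n_rejected:
        logger.warning("rejected %d record(s) while reading %s", n_rejected, path)
    return RoundSample(round_index, np.stack(valid), n_rejected=n_rejected)


def write_round_fasta(sample: RoundSample, path) -> None:
    """Write a round sample as DNA FASTA (ids ``r{round}_n{index}``)."""
    records = [
        SeqRecord(
            Seq(CodonSequence(row).to_dna()),
            id=f"r{sample.round_index}_n{i}",
            description="",
        )
        for i, row in enumerate(sample.codons)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_wildtype_fasta(path) -> CodonSequence:
    """Read the reference wild-type coding sequence (first FASTA record)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        return CodonSequence.from_dna(str(rec.seq))
    raise InvalidSequenceError(f"no records in {path}")
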