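"""Per-position codon mutation kernels from a nucleotide substitution bias.

Error-prone PCR mutagenesis is modelled as independent per-base substitution:
a 4x4 table of relative substitution propensities is scaled (one global
scale, preserving the published relative bias) so that the expected number of
nucleotide substitutions per gene per round matches a target load.  The codon
kernel is the 3-fold product of per-base transitions with transitions into
stop codons treated as lethal: stop columns are removed and rows renormalized
over the 61 sense codons, keeping the chain on the sense-codon state space.

The packaged default bias (``data/taq_eppcr_bias_synthetic.tsv``) is a
synthetic, representative Taq error-prone PCR spectrum (AT-biased and
transition-heavy); it stands in for experiment-specific measurements, which
users should substitute when available.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import ALPHABET, DNA_BASES, CodonSequence

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


@dataclass
class NucleotideBias:
    """4x4 relative substitution propensities (row = from base, col = to base)."""

    rates: np.ndarray
    source: str = "unspecified"

    def __post_init__(self) -> None:
        r = np.array(self.rates, dtype=float)
        if r.shape != (4, 4):
            raise ValueError("bias table must be 4x4")
        off = r[~np.eye(4, dtype=bool)]
        if (off < 0).any() or not (off > 0).any():
            raise ValueError("off-diagonal rates must be non-negative, not all zero")
        np.fill_diagonal(r, 0.0)  # diagonal unused
        self.rates = r

    @classmethod
    def from_tsv(cls, path, source: str | None = None) -> "NucleotideBias":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[list(DNA_BASES), list(DNA_BASES)]
        return cls(df.to_numpy(float), source=source or str(path))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.rates, index=list(DNA_BASES), columns=list(DNA_BASES)
        ).to_csv(path, sep="\t", index_label="base")

    @classmethod
    def default(cls) -> "NucleotideBias":
        """The packaged synthetic Taq error-prone PCR spectrum."""
        ref = importlib.resources.files("evopotts.data").joinpath(
            "taq_eppcr_bias_synthetic.tsv"
        )
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path, source="packaged synthetic Taq ep-PCR bias")


def _codon_base_indices() -> np.ndarray:
    """(61, 3) base indices of the sense codons in canonical order."""
    return np.array(
        [[_BASE_INDEX[b] for b in codon] for codon in ALPHABET.codons], dtype=np.intp
    )


@dataclass
class MutationModel:
    """Row-stochastic 61x61 codon transition kernels, shared across positions.

    ``kernel`` is the stop-renormalized sense-codon kernel used by the
    dynamics; ``base_matrix`` is the underlying 4x4 per-base transition matrix
    before stop handling.  Per-position overrides may be supplied via
    ``overrides`` (position -> 61x61 kernel); by default the mutagenesis model
    has no positional dependence.
    """

    kernel: np.ndarray
    base_matrix: np.ndarray
    target_load: float
    length: int
    overrides: dict[int, np.ndarray] = field(default_factory=dict)

    def kernel_for(self, i: int) -> np.ndarray:
        return self.overrides.get(i, self.kernel)

    def kernels(self) -> np.ndarray:
        """(L, 61, 61) stack of per-position kernels (view-broadcast)."""
        out = np.broadcast_to(self.kernel, (self.length, 61, 61)).copy()
        for i, k in self.overrides.items():
            out[i] = k
        return out

    def save(self, path) -> None:
        """Serialize the kernel container (rows/columns in canonical codon order)."""
        np.savez_compressed(
            path,
            format_version=1,
            codons=np.array(ALPHABET.codons),
            kernel=self.kernel,
            base_matrix=self.base_matrix,
            target_load=self.target_load,
            length=self.length,
            override_positions=np.array(sorted(self.overrides), dtype=np.intp),
            override_kernels=np.stack(
                [self.overrides[i] for i in sorted(self.overrides)]
            )
            if self.overrides
            else np.zeros((0, 61, 61)),
        )

    @classmethod
    def load(cls, path) -> "MutationModel":
        with np.load(path, allow_pickle=False) as z:
            if list(z["codons"]) != ALPHABET.codons:
                raise ValueError("codon order mismatch in kernel file")
            overrides = {
                int(i): k
                for i, k in zip(z["override_positions"], z["override_kernels"])
            }
            return cls(
                kernel=z["kernel"],
                base_matrix=z["base_matrix"],
                target_load=float(z["target_load"]),
                length=int(z["length"]),
                overrides=overrides,
            )


def build_kernels(
    bias: NucleotideBias, target_load: float, L: int
) -> MutationModel:
    """Build the codon mutation kernel for a gene of ``L`` residues.

    The per-base substitution probabilities are the bias rates under one
    global scale chosen so the expected number of substitutions over the
    ``3 L`` bases (at uniform base composition) equals ``target_load`` per
    round.  The codon kernel is the Kronecker 3-fold product of the per-base
    matrix with stop rows/columns removed and rows renormalized.
    """
    if target_load < 0:
        raise ValueError("target_load must be non-negative")
    if L < 1:
        raise ValueError("L must be >= 1")
    rates = bias.rates
    total = rates.sum()
    if target_load == 0:
        scale = 0.0
    else:
        # E[#subs] = 3L * mean_b(row_b sum * scale) = (3L/4) * scale * total
        scale = target_load * 4.0 / (3.0 * L * total)
    B = rates * scale
    row_sub = B.sum(axis=1)
    if (row_sub >= 1.0).any():
        raise ValueError(
            f"target_load {target_load} implies per-base substitution probability "
            f">= 1 (max {row_sub.max():.3g}); reduce the load"
        )
    np.fill_diagonal(B, 1.0 - row_sub)

    cb = _codon_base_indices()  # (61, 3)
    # kernel[c, c'] = prod over the 3 base positions of B[base_k(c), base_k(c')]
    kernel = (
        B[cb[:, None, 0], cb[None, :, 0]]
        * B[cb[:, None, 1], cb[None, :, 1]]
        * B[cb[:, None, 2], cb[None, :, 2]]
    )
    # transitions into stops are lethal: renormalize over the 61 sense codons
    kernel /= kernel.sum(axis=1, keepdims=True)
    return MutationModel(kernel=kernel, base_matrix=B, target_load=target_load, length=L)


def sequence_mutation_prob(
    model: MutationModel, x: CodonSequence, y: CodonSequence
) -> float:
    """Probability g(x -> y) that ``x`` mutates to ``y`` in one round."""
    if x.length != y.length:
        raise ValueError("sequence length mismatch")
    ks = [model.kernel_for(i) for i in range(x.length)]
    return float(
        np.prod([ks[i][x.codons[i], y.codons[i]] for i in range(x.length)])
    )


def expected_load(model: MutationModel) -> float:
    """Expected DNA substitutions per gene per round (uniform base composition).

    Computed from the per-base matrix, i.e. before stop renormalization;
    :func:`build_kernels` guarantees this equals the target load.
    """
    per_base = 1.0 - np.diag(model.base_matrix)
    return float(3 * model.length * per_base.mean())


def simulate_mutagenesis_loads(
    model: MutationModel, n_draws: int, seed: int
) -> np.ndarray:
    """Monte-Carlo substitution counts per gene for ``n_draws`` mutagenesis draws.

    Genes are drawn with uniform base composition, matching the analytic
    expectation convention of :func:`expected_load`.
    """
    rng = np.random.default_rng(seed)
    n_bases = 3 * model.length
    bases = rng.integers(0, 4, size=(n_draws, n_bases))
    p_sub = 1.0 - np.diag(model.base_matrix)
    return (rng.random((n_draws, n_bases)) < p_sub[bases]).sum(axis=1)
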