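"""The Potts fitness landscape over amino-acid sequences.

A sequence's (log, relative) fitness is

    score(s) = sum_i h_i(s_i) + sum_{i<j} e_ij(s_i, s_j)

with per-site fields ``h`` and pairwise couplings ``e``.  The partition
function is never computed: the state space is astronomically large, and
every downstream use (transition kernels, adaptive walks, epistasis) depends
only on score differences, i.e. log fitness ratios.

Couplings are stored once per unordered pair (i < j); access for j > i is
the transposed block (``e_ji(b, a) = e_ij(a, b)``).  The parameterization is
gauge-redundant, so residue-residue interaction scores are Frobenius norms of
the zero-sum-gauged blocks, the convention of direct coupling analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .seqcore import ALPHABET

Q = 20  # amino-acid alphabet size


def pair_indices(L: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangular pair indices (i < j) in canonical row-major order."""
    return np.triu_indices(L, k=1)


def pair_lookup(L: int) -> np.ndarray:
    """(L, L) matrix mapping (i, j) with i<j to its flat pair index (else -1)."""
    iu, ju = pair_indices(L)
    out = np.full((L, L), -1, dtype=np.intp)
    out[iu, ju] = np.arange(iu.size)
    out[ju, iu] = np.arange(iu.size)
    return out


@dataclass
class PottsModel:
    """Canonical Potts parameters (h, e) on amino acids.

    Parameters
    ----------
    h : (L, 20) fields.
    e : (P, 20, 20) coupling blocks, one per unordered pair in
        :func:`pair_indices` order; ``e[p][a, b]`` couples amino acid ``a`` at
        the smaller position with ``b`` at the larger.
    """

    h: np.ndarray
    e: np.ndarray
    _pair_idx: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        L = self.h.shape[0]
        P = L * (L - 1) // 2
        if self.h.shape != (L, Q):
            raise ValueError(f"h must be (L, {Q})")
        if self.e is None:
            self.e = np.zeros((P, Q, Q))
        self.e = np.asarray(self.e, dtype=float)
        if self.e.shape != (P, Q, Q):
            raise ValueError(f"e must be ({P}, {Q}, {Q}) for L={L}")
        if not (np.isfinite(self.h).all() and np.isfinite(self.e).all()):
            raise ValueError("parameters must be finite")
        self._pair_idx = pair_lookup(L)

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @classmethod
    def zeros(cls, L: int) -> "PottsModel":
        return cls(np.zeros((L, Q)), np.zeros((L * (L - 1) // 2, Q, Q)))

    def coupling_block(self, i: int, j: int) -> np.ndarray:
        """Symmetrized access: e_ij with rows indexing position ``i``'s amino acid."""
        if i == j:
            raise ValueError("no self-coupling")
        block = self.e[self._pair_idx[i, j]]
        return block if i < j else block.T

    def active_pairs(self) -> np.ndarray:
        """Flat indices of pairs with any nonzero coupling entry."""
        return np.flatnonzero(np.abs(self.e).sum(axis=(1, 2)) > 0)

    # -- serialization (runtime output container, version-tagged) ----------
    def save(self, path) -> None:
        np.savez_compressed(
            path,
            format_version=1,
            alphabet=np.array(list(ALPHABET.amino_acids)),
            h=self.h,
            e=self.e,
        )

    @classmethod
    def load(cls, path) -> "PottsModel":
        with np.load(path, allow_pickle=False) as z:
            if "".join(z["alphabet"]) != ALPHABET.amino_acids:
                raise ValueError("alphabet order mismatch in model file")
            return cls(z["h"], z["e"])


def _aa_indices(seq, L: int) -> np.ndarray:
    if isinstance(seq, str):
        seq = np.array([ALPHABET.aa_index[a] for a in seq], dtype=np.intp)
    seq = np.asarray(seq, dtype=np.intp)
    if seq.shape[-1] != L:
        raise ValueError(f"sequence length {seq.shape[-1]} != model L {L}")
    return seq


def score(model: PottsModel, aa_seq) -> float:
    """Log relative fitness of one amino-acid sequence (string or index array)."""
    return float(score_many(model, _aa_indices(aa_seq, model.L)[None, :])[0])


def score_many(model: PottsModel, aa: np.ndarray) -> np.ndarray:
    """Scores of a batch of sequences given as an (..., L) amino-acid index array.

    Coupling terms are accumulated over the nonzero blocks only, so sparse
    planted landscapes score in O(#active pairs).
    """
    aa = np.asarray(aa, dtype=np.intp)
    L = model.L
    s = np.take_along_axis(
        model.h[None, :, :], aa.reshape(-1, L)[:, :, None], axis=2
    )[:, :, 0].sum(axis=1)
    act = model.active_pairs()
    if act.size:
        iu, ju = pair_indices(L)
        ai = aa.reshape(-1, L)[:, iu[act]]
        aj = aa.reshape(-1, L)[:, ju[act]]
        s = s + model.e[act[None, :], ai, aj].sum(axis=1)
    return s.reshape(aa.shape[:-1])


def field_contributions(model: PottsModel, aa: np.ndarray) -> np.ndarray:
    """For a single background ``aa`` (L,), the (L, 20) array
    ``E[i, a] = h_i(a) + sum_{j != i} e_ij(a, aa_j)`` (used for fast
    single-mutant evaluation and incremental walk updates)."""
    aa = _aa_indices(aa, model.L)
    E = model.h.copy()
    iu, ju = pair_indices(model.L)
    for p in model.active_pairs():
        i, j = iu[p], ju[p]
        E[i] += model.e[p][:, aa[j]]
        E[j] += model.e[p][aa[i], :]
    return E


def mutation_effect_map(model: PottsModel, wt) -> np.ndarray:
    """(L, 20) single-mutant score changes relative to the wild type.

    Entry (i, a) is score(wt with a at i) - score(wt); the wild-type amino
    acid's entries are exactly 0.
    """
    wt = _aa_indices(wt, model.L)
    E = field_contributions(model, wt)
    return E - E[np.arange(model.L), wt][:, None]


def zero_sum_gauge(model: PottsModel) -> np.ndarray:
    """Zero-sum-gauged coupling blocks e'_ij (row and column means removed).

    e'_ij(a,b) = e_ij(a,b) - mean_a e_ij(.,b) - mean_b e_ij(a,.) + mean e_ij(.,.)
    Every returned block has zero row and column sums; the transform is
    idempotent.
    """
    e = model.e
    row = e.mean(axis=1, keepdims=True)
    col = e.mean(axis=2, keepdims=True)
    tot = e.mean(axis=(1, 2), keepdims=True)
    return e - row - col + tot


def to_zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Equivalent model in the zero-sum gauge (means absorbed into the fields).

    Pairwise score differences are preserved exactly (scores shift by a
    sequence-independent constant, which is dropped).
    """
    e = model.e
    col = e.mean(axis=2)  # (P, 20): mean over partner's amino acid, rows = i
    row = e.mean(axis=1)  # (P, 20): rows = j's amino acid
    tot = e.mean(axis=(1, 2))  # (P,)
    h = model.h.copy()
    iu, ju = pair_indices(model.L)
    np.add.at(h, iu, col - tot[:, None])
    np.add.at(h, ju, row - tot[:, None])
    return PottsModel(h, zero_sum_gauge(model))


@dataclass
class InteractionScores:
    """Frobenius interaction scores with the long-range bookkeeping."""

    F: np.ndarray  # (L, L) symmetric, zero diagonal
    min_separation: int

    @property
    def L(self) -> int:
        return self.F.shape[0]

    def long_range_mask(self) -> np.ndarray:
        """(L, L) boolean: |i - j| > min_separation."""
        idx = np.arange(self.L)
        return np.abs(idx[:, None] - idx[None, :]) > self.min_separation

    def ranked_long_range_pairs(self) -> np.ndarray:
        """(n, 3) array of (i, j, F) rows, i<j long-range, descending F.

        Ties broken by (i, j) lexicographic order for determinism.
        """
        iu, ju = np.triu_indices(self.L, k=1)
        keep = (ju - iu) > self.min_separation
        iu, ju, f = iu[keep], ju[keep], self.F[iu[keep], ju[keep]]
        order = np.lexsort((ju, iu, -f))
        return np.column_stack([iu[order], ju[order], f[order]])


def interaction_scores(model: PottsModel, min_separation: int = 5) -> InteractionScores:
    """Residue-residue interaction scores F_ij = ||e'_ij|| (zero-sum gauge)."""
    ep = zero_sum_gauge(model)
    fro = np.sqrt((ep**2).sum(axis=(1, 2)))
    F = np.zeros((model.L, model.L))
    iu, ju = pair_indices(model.L)
    F[iu, ju] = fro
    F[ju, iu] = fro
    return InteractionScores(F=F, min_separation=min_separation)


@dataclass
class EpistasisResult:
    """Double-mutant epistasis classification relative to a wild type.

    ``sign_pairs`` / ``reciprocal_pairs`` hold (i, j, a, b) rows: positions
    0-based i<j, amino-acid indices of the two mutations.
    """

    n_additive: int
    n_sign: int
    n_reciprocal: int
    sign_pairs: np.ndarray
    reciprocal_pairs: np.ndarray
    tolerance: float

    @property
    def n_total(self) -> int:
        return self.n_additive + self.n_sign + self.n_reciprocal


def classify_epistasis(
    model: PottsModel, wt, tolerance: float = 1e-9
) -> EpistasisResult:
    """Classify every double mutant of ``wt`` as additive / sign / reciprocal-sign.

    For mutations a at i and b at j (a != wt_i, b != wt_j), with Delta-A the
    effect of a in the wild-type background and Delta-A|B its effect in the
    b-mutant background (analogously for B):

    * reciprocal sign: both single effects change sign in the other mutant's
      background (which in a pairwise model forces sign(dA) = sign(dB) and
      sign(dA|B) = sign(dB|A));
    * sign: exactly one of the two effects changes sign;
    * additive: neither does.

    Effects with magnitude below ``tolerance`` are treated as zero and never
    count as sign changes.
    """
    wt = _aa_indices(wt, model.L)
    eff = mutation_effect_map(model, wt)  # (L, 20)
    L = model.L
    iu, ju = pair_indices(L)
    not_wt = np.ones((L, Q), dtype=bool)
    not_wt[np.arange(L), wt] = False

    sign_rows, recip_rows = [], []
    n_add = n_sign = n_recip = 0
    for p in range(iu.size):
        i, j = int(iu[p]), int(ju[p])
        ai = np.flatnonzero(not_wt[i])  # the 19 mutant amino acids at i
        bj = np.flatnonzero(not_wt[j])
        blk = model.e[p]
        # shared epistatic term of the pairwise model
        deps = (
            blk[np.ix_(ai, bj)]
            - blk[ai][:, [wt[j]]]
            - blk[[wt[i]], :][:, bj]
            + blk[wt[i], wt[j]]
        )
        dA = eff[i, ai][:, None]
        dB = eff[j, bj][None, :]
        dAB = dA + deps
        dBA = dB + deps
        flipA = (np.abs(dA) >= tolerance) & (np.abs(dAB) >= tolerance) & (
            np.sign(dA) != np.sign(dAB)
        )
        flipB = (np.abs(dB) >= tolerance) & (np.abs(dBA) >= tolerance) & (
            np.sign(dB) != np.sign(dBA)
        )
        recip = flipA & flipB
        sign_only = flipA ^ flipB
        n_recip += int(recip.sum())
        n_sign += int(sign_only.sum())
        n_add += int(recip.size - recip.sum() - sign_only.sum())
        for mask, rows in ((sign_only, sign_rows), (recip, recip_rows)):
            if mask.any():
                ia, jb = np.nonzero(mask)
                rows.append(
                    np.column_stack(
                        [np.full(ia.size, i), np.full(ia.size, j), ai[ia], bj[jb]]
                    )
                )
    empty = np.empty((0, 4), dtype=np.intp)
    return EpistasisResult(
        n_additive=n_add,
        n_sign=n_sign,
        n_reciprocal=n_recip,
        sign_pairs=np.concatenate(sign_rows) if sign_rows else empty,
        reciprocal_pairs=np.concatenate(recip_rows) if recip_rows else empty,
        tolerance=tolerance,
    )


def mutation_name(i: int, wt_aa: str, mut_aa: str) -> str:
    """Human-readable mutation name with 1-based position, e.g. ``N20D``."""
    return f"{wt_aa}{i + 1}{mut_aa}"


def export_effect_map_tsv(effects: np.ndarray, path) -> None:
    """Write an (L, 20) mutation-effect map as TSV (1-based positions)."""
    import pandas as pd

    df = pd.DataFrame(
        effects, columns=list(ALPHABET.amino_acids),
        index=np.arange(1, effects.shape[0] + 1),
    )
    df.to_csv(path, sep="\t", index_label="position")


def n_double_mutant_combinations(L: int) -> int:
    """Number of candidate double-mutant (position, amino-acid) combinations."""
    return (L * (L - 1) // 2) * 19 * 19
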