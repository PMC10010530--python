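"""Landscape exploration and evaluation.

Adaptive walks are greedy steepest-ascent searches at the amino-acid level
(the landscape is amino-acid-parameterized; codon constraints are not imposed
in silico): every move in the move set is evaluated, the best strictly
improving one is accepted, and the walk ends at a local fitness peak.  The
move set is either all single mutants, or all single and double mutants (the
trajectory-extrapolation setting).  Ties are broken deterministically by
lowest position, then alphabetical amino acid; a single mutant is preferred
over an equally good double.

Contact prediction is scored as positive predictive value (PPV): the
fraction of the top-ranked long-range interaction scores (|i - j| > 5,
top L/2 by default) whose residue pair lies within a distance threshold
(5 or 8 Angstrom) in the reference structure, against the random-chance
baseline of long-range contact density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .potts import InteractionScores, PottsModel, pair_indices, score
from .seqcore import ALPHABET


@dataclass
class ContactMap:
    """Minimum heavy-atom distances for residue pairs (0-based i < j keys)."""

    distances: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        clean = {}
        for (i, j), d in self.distances.items():
            if i >= j or d <= 0:
                raise ValueError(f"contact entries need i < j and distance > 0: {(i, j, d)}")
            clean[(int(i), int(j))] = float(d)
        self.distances = clean

    def distance(self, i: int, j: int) -> float:
        """Distance for a pair, +inf when the pair is absent from the map."""
        if i > j:
            i, j = j, i
        return self.distances.get((i, j), np.inf)

    @classmethod
    def from_tsv(cls, path) -> "ContactMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                (int(r.i) - 1, int(r.j) - 1): float(r.distance)
                for r in df.itertuples()
            }
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"i": i + 1, "j": j + 1, "distance": d}
            for (i, j), d in sorted(self.distances.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class Walk:
    """An adaptive walk: accepted moves with strictly increasing scores."""

    start: str
    endpoint: str
    scores: np.ndarray  # (n_steps + 1,): start score then score after each move
    moves: list[str]  # human-readable accepted moves, e.g. "N20D" or "N20D+K47A"
    move_set: str
    reached_max_steps: bool = False

    @property
    def n_steps(self) -> int:
        return len(self.moves)


def _dense_couplings(model: PottsModel) -> np.ndarray:
    """(L, L, 20, 20) symmetrized coupling tensor (zero diagonal blocks)."""
    L = model.L
    big = np.zeros((L, L, 20, 20))
    iu, ju = pair_indices(L)
    big[iu, ju] = model.e
    big[ju, iu] = model.e.transpose(0, 2, 1)
    return big


def _aa_arr(seq, L: int) -> np.ndarray:
    if isinstance(seq, str):
        seq = np.array([ALPHABET.aa_index[a] for a in seq], dtype=np.intp)
    seq = np.asarray(seq, dtype=np.intp)
    if seq.size != L:
        raise ValueError("start sequence length mismatch")
    return seq


def adaptive_walk(
    landscape: PottsModel,
    start,
    moves: str = "single",
    max_steps: int | None = None,
    _dense: np.ndarray | None = None,
) -> Walk:
    """Greedy steepest-ascent walk from ``start`` to a local fitness peak."""
    if moves not in ("single", "single+double"):
        raise ValueError("moves must be 'single' or 'single+double'")
    L = landscape.L
    aa = _aa_arr(start, L).copy()
    start_str = "".join(ALPHABET.amino_acids[a] for a in aa)
    big = _dense if _dense is not None else _dense_couplings(landscape)
    iu, ju = pair_indices(L)
    if max_steps is None:
        max_steps = 100 * L

    # E[i, a] = h_i(a) + sum_{j != i} e_ij(a, aa_j); updated incrementally.
    # big[:, arange(L), :, aa] puts the advanced (j) axis first: [j, i, a].
    E = landscape.h + big[:, np.arange(L), :, aa].sum(axis=0)
    w_pairs = big[iu, ju]  # (P, 20, 20) couplings for i < j

    s0 = score(landscape, aa)
    scores = [s0]
    accepted: list[str] = []
    hit_cap = False
    for _ in range(max_steps):
        d1 = E - E[np.arange(L), aa][:, None]  # single-mutant deltas
        best1_flat = int(np.argmax(d1))  # row-major: lowest position, then aa
        best1 = d1.ravel()[best1_flat]
        best2 = -np.inf
        if moves == "single+double":
            w = w_pairs
            d2 = (
                d1[iu][:, :, None]
                + d1[ju][:, None, :]
                + w
                - w[np.arange(iu.size), :, aa[ju]][:, :, None]
                - w[np.arange(iu.size), aa[iu], :][:, None, :]
                + w[np.arange(iu.size), aa[iu], aa[ju]][:, None, None]
            )
            best2_flat = int(np.argmax(d2))
            best2 = d2.ravel()[best2_flat]
        if max(best1, best2) <= 0:
            break
        if best1 >= best2:  # prefer the single mutant on exact ties
            i, a = divmod(best1_flat, 20)
            accepted.append(
                f"{ALPHABET.amino_acids[aa[i]]}{i + 1}{ALPHABET.amino_acids[a]}"
            )
            changes = [(i, a)]
            delta = best1
        else:
            p, rest = divmod(best2_flat, 400)
            a, b = divmod(rest, 20)
            i, j = int(iu[p]), int(ju[p])
            accepted.append(
                f"{ALPHABET.amino_acids[aa[i]]}{i + 1}{ALPHABET.amino_acids[a]}"
                f"+{ALPHABET.amino_acids[aa[j]]}{j + 1}{ALPHABET.amino_acids[b]}"
            )
            changes = [(i, a), (j, b)]
            delta = best2
        for i, a in changes:
            old = aa[i]
            aa[i] = a
            E += big[:, i, :, a] - big[:, i, :, old]
        scores.append(scores[-1] + float(delta))
    else:
        hit_cap = True

    return Walk(
        start=start_str,
        endpoint="".join(ALPHABET.amino_acids[a] for a in aa),
        scores=np.array(scores),
        moves=accepted,
        move_set=moves,
        reached_max_steps=hit_cap,
    )


def is_local_optimum(landscape: PottsModel, seq, moves: str = "single") -> bool:
    """Exhaustive re-check that no move in the move set strictly improves ``seq``."""
    aa = _aa_arr(seq, landscape.L)
    base = score(landscape, aa)
    L = landscape.L
    for i in range(L):
        for a in range(20):
            if a == aa[i]:
                continue
            mut = aa.copy()
            mut[i] = a
            if score(landscape, mut) > base:
                return False
    if moves == "single+double":
        for i in range(L):
            for j in range(i + 1, L):
                for a in range(20):
                    for b in range(20):
                        mut = aa.copy()
                        mut[i], mut[j] = a, b
                        if score(landscape, mut) > base:
                            return False
    return True


@dataclass
class SurveyResult:
    """Unique adaptive-walk endpoints with basin sizes."""

    endpoints: list[str]
    basin_sizes: np.ndarray
    distance_to_reference: np.ndarray
    n_starts: int

    @property
    def n_unique(self) -> int:
        return len(self.endpoints)


def convergence_survey(
    landscape: PottsModel,
    n_starts: int,
    seed: int = 0,
    reference=None,
    max_steps: int | None = None,
) -> SurveyResult:
    """Adaptive walks (single-mutant moves) from uniform random starts.

    Reports the unique endpoints, how many starts reach each (basin size,
    descending), and each endpoint's Hamming distance to ``reference``
    (default: the endpoint of the largest basin).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    L = landscape.L
    big = _dense_couplings(landscape)
    counts: dict[str, int] = {}
    for _ in range(n_starts):
        start = rng.integers(0, 20, size=L)
        walk = adaptive_walk(landscape, start, "single", max_steps, _dense=big)
        counts[walk.endpoint] = counts.get(walk.endpoint, 0) + 1
    endpoints = sorted(counts, key=lambda s: (-counts[s], s))
    sizes = np.array([counts[s] for s in endpoints])
    if reference is None:
        ref = _aa_arr(endpoints[0], L)
    else:
        ref = _aa_arr(reference, L)
    dist = np.array(
        [int((_aa_arr(s, L) != ref).sum()) for s in endpoints]
    )
    return SurveyResult(endpoints, sizes, dist, n_starts)


def contact_ppv(
    scores: InteractionScores,
    contacts: ContactMap,
    thresholds: tuple[float, ...] = (5.0, 8.0),
    top_k: int | None = None,
    ) -> pd.DataFrame:
    """PPV of the top-ranked long-range interaction scores against a structure.

    Rows: one per distance threshold, with the number of true contacts among
    the top ``top_k`` (default floor(L/2)) ranked long-range pairs, the PPV,
    and the random-chance baseline (long-range contact density).
    """
    L = scores.L
    if top_k is None:
        top_k = L // 2
    ranked = scores.ranked_long_range_pairs()
    top = ranked[:top_k]
    dists = np.array([contacts.distance(int(i), int(j)) for i, j, _ in top])
    iu, ju = np.triu_indices(L, k=1)
    lr = (ju - iu) > scores.min_separation
    all_d = np.array(
        [contacts.distance(int(i), int(j)) for i, j in zip(iu[lr], ju[lr])]
    )
    rows = []
    for thr in thresholds:
        n_true = int((dists < thr).sum())
        rows.append(
            {
                "threshold_angstrom": thr,
                "top_k": int(top.shape[0]),
                "n_true_contacts": n_true,
                "ppv": n_true / top.shape[0],
                "baseline": float((all_d < thr).mean()),
            }
        )
    return pd.DataFrame(rows)


def export_walk(walk: Walk, fasta_path, trace_path) -> None:
    """Write a walk as FASTA (one record per accepted step) plus a score trace TSV."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    seqs = [walk.start]
    aa = list(walk.start)
    for move in walk.moves:
        for sub in move.split("+"):
            pos = int(sub[1:-1]) - 1
            aa[pos] = sub[-1]
        seqs.append("".join(aa))
    records = [
        SeqRecord(Seq(s), id=f"step{k}", description=walk.moves[k - 1] if k else "start")
        for k, s in enumerate(seqs)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "step": np.arange(len(walk.scores)),
            "move": ["start"] + walk.moves,
            "score": walk.scores,
        }
    ).to_csv(trace_path, sep="\t", index=False)
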