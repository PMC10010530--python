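"""Planted-truth fixture generation.

Generates the statistical structure the inference method assumes, with full
ground truth: a Potts landscape whose couplings are zero except at a small
set of planted long-range pairs, a wild type near the landscape's additive
optimum, a contact map in which exactly the planted pairs are close in
space, and a simulated directed-evolution trajectory over that landscape
(error-prone-PCR-like mutation bias, delta initialization at wild type).

Every stage of the pipeline — moments, inference, interaction scoring,
contact PPV, adaptive walks — is thereby testable against known truth
without any external data.

Default shape: L = 30 residues, 5 planted pairs, 8 rounds with populations
of 5000 and 2000 sequences sampled per round, a mutation load of 4 DNA
substitutions per gene per round, field scale 1.0 and coupling scale 1.5
(strong enough selection that pair correlations are statistically visible at
n = 2000).  A paper-scale profile (L = 186, n_r = 1e5) is deliberately not
the default; recovery is assessed at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .analysis import ContactMap
from .dynamics import simulate_trajectory
from .mutation import MutationModel, NucleotideBias, build_kernels
from .potts import PottsModel, pair_indices, zero_sum_gauge
from .seqcore import ALPHABET, CodonSequence, TrajectoryDataset, population_stats


@dataclass
class GeneratorConfig:
    """Shape and scales of the planted fixture."""

    L: int = 30
    n_coupled_pairs: int = 5
    field_scale: float = 1.0
    coupling_scale: float = 1.5
    min_separation: int = 5
    wt_perturb_sites: int = 2
    contact_distance: float = 4.0
    decoy_distance: float = 15.0
    seed: int = 0


@dataclass
class PlantedTruth:
    """A planted landscape with its wild type and structural contact map."""

    landscape: PottsModel
    planted_pairs: list[tuple[int, int]]
    planted_strengths: np.ndarray
    wildtype: CodonSequence
    contacts: ContactMap
    config: GeneratorConfig

    def save(self, path) -> None:
        cfg = json.dumps(asdict(self.config))
        np.savez_compressed(
            path,
            format_version=1,
            h=self.landscape.h,
            e=self.landscape.e,
            wildtype=self.wildtype.codons,
            planted_pairs=np.array(self.planted_pairs, dtype=np.intp),
            planted_strengths=self.planted_strengths,
            contact_i=np.array([i for i, _ in sorted(self.contacts.distances)]),
            contact_j=np.array([j for _, j in sorted(self.contacts.distances)]),
            contact_d=np.array(
                [self.contacts.distances[k] for k in sorted(self.contacts.distances)]
            ),
            config_json=cfg,
        )

    @classmethod
    def load(cls, path) -> "PlantedTruth":
        with np.load(path, allow_pickle=False) as z:
            cfg = GeneratorConfig(**json.loads(str(z["config_json"])))
            contacts = ContactMap(
                {
                    (int(i), int(j)): float(d)
                    for i, j, d in zip(z["contact_i"], z["contact_j"], z["contact_d"])
                }
            )
            return cls(
                landscape=PottsModel(z["h"], z["e"]),
                planted_pairs=[tuple(p) for p in z["planted_pairs"]],
                planted_strengths=z["planted_strengths"],
                wildtype=CodonSequence(z["wildtype"]),
                contacts=contacts,
                config=cfg,
            )


def generate_landscape(
    L: int = 30,
    n_coupled_pairs: int = 5,
    field_scale: float = 1.0,
    coupling_scale: float = 1.5,
    seed: int = 0,
    min_separation: int = 5,
    wt_perturb_sites: int = 2,
) -> PlantedTruth:
    """Draw a planted sparse Potts landscape with ground-truth contacts.

    Fields are i.i.d. zero-mean normal with the given scale.  Couplings are
    zero except at ``n_coupled_pairs`` uniformly chosen long-range pairs
    (|i - j| > min_separation), where 20x20 blocks are drawn normal with the
    coupling scale and converted to the zero-sum gauge.  The wild type is the
    field-argmax sequence perturbed at ``wt_perturb_sites`` random sites,
    encoded with each amino acid's canonical codon.
    """
    cfg = GeneratorConfig(
        L=L,
        n_coupled_pairs=n_coupled_pairs,
        field_scale=field_scale,
        coupling_scale=coupling_scale,
        min_separation=min_separation,
        wt_perturb_sites=wt_perturb_sites,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, field_scale, size=(L, 20))

    iu, ju = pair_indices(L)
    long_range = np.flatnonzero((ju - iu) > min_separation)
    if n_coupled_pairs > long_range.size:
        raise ValueError("more planted pairs requested than long-range pairs exist")
    chosen = np.sort(rng.choice(long_range, size=n_coupled_pairs, replace=False))
    e = np.zeros((iu.size, 20, 20))
    if n_coupled_pairs:
        e[chosen] = rng.normal(0.0, coupling_scale, size=(n_coupled_pairs, 20, 20))
    landscape = PottsModel(h, e)
    landscape = PottsModel(h, zero_sum_gauge(landscape))
    strengths = np.sqrt((landscape.e[chosen] ** 2).sum(axis=(1, 2)))

    wt_aa = np.argmax(h, axis=1)
    if wt_perturb_sites:
        sites = rng.choice(L, size=wt_perturb_sites, replace=False)
        for s in sites:
            alt = rng.integers(0, 19)
            wt_aa[s] = alt + 1 if alt >= wt_aa[s] else alt  # any non-argmax aa
    wt_codons = np.array(
        [ALPHABET.preferred_codon(ALPHABET.amino_acids[a]) for a in wt_aa],
        dtype=np.intp,
    )

    distances = {}
    for p in long_range:
        i, j = int(iu[p]), int(ju[p])
        distances[(i, j)] = (
            cfg.contact_distance if p in set(chosen) else cfg.decoy_distance
        )
    return PlantedTruth(
        landscape=landscape,
        planted_pairs=[(int(iu[p]), int(ju[p])) for p in chosen],
        planted_strengths=strengths,
        wildtype=CodonSequence(wt_codons),
        contacts=ContactMap(distances),
        config=cfg,
    )


def generate_trajectory_dataset(
    truth: PlantedTruth,
    rounds: int = 8,
    pop_size: int = 5000,
    brood_size: int = 100,
    sample_sizes: int | dict[int, int] = 2000,
    sampled_rounds: list[int] | None = None,
    seed: int = 0,
    bias: NucleotideBias | None = None,
    target_load: float = 4.0,
) -> tuple[TrajectoryDataset, MutationModel, dict]:
    """Simulate a directed-evolution trajectory over a planted landscape.

    Uses the packaged default nucleotide bias and a mutation load of 4 DNA
    substitutions per gene per round unless overridden.  Returns the dataset,
    the mutation model used (needed downstream by inference), and a manifest
    recording the configuration, seed, and per-round population statistics.
    """
    bias = bias or NucleotideBias.default()
    model = build_kernels(bias, target_load, truth.wildtype.length)
    dataset = simulate_trajectory(
        truth.wildtype,
        model,
        truth.landscape,
        rounds=rounds,
        pop_size=pop_size,
        brood_size=brood_size,
        seed=seed,
        sample_sizes=sample_sizes,
        sampled_rounds=sampled_rounds,
    )
    stats = population_stats(dataset)
    manifest = {
        "generator_config": asdict(truth.config),
        "trajectory": {
            "rounds": rounds,
            "pop_size": pop_size,
            "brood_size": brood_size,
            "sample_sizes": sample_sizes
            if isinstance(sample_sizes, int)
            else {int(k): int(v) for k, v in sample_sizes.items()},
            "sampled_rounds": sorted(dataset.sequenced_rounds),
            "seed": seed,
            "target_load": target_load,
            "bias_source": bias.source,
        },
        "population_stats": stats.to_dict(orient="records"),
    }
    return dataset, model, manifest


def default_fixture(
    seed: int = 42,
) -> tuple[PlantedTruth, TrajectoryDataset, MutationModel, dict]:
    """The default desk-scale fixture: planted landscape plus trajectory."""
    truth = generate_landscape(seed=seed)
    dataset, model, manifest = generate_trajectory_dataset(truth, seed=seed)
    return truth, dataset, model, manifest
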