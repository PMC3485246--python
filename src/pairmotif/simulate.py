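"""Planted (l, d) instance generator with recorded ground truth.

Each dataset consists of t sequences of length n whose bases are i.i.d.
uniform over {A, C, G, T}; into each sequence one mutated occurrence of
a common random motif is written at a uniformly chosen position
(overwriting the background, so lengths are preserved).  Two mutation
models are provided:

``exactly_d``
    every occurrence differs from the motif in exactly d positions —
    the fixed-mutation benchmark model standard for planted-motif
    evaluations, and the default;
``at_most_d``
    the mutation count of each occurrence is drawn uniformly from
    {0, ..., d}.

All randomness flows from a single seeded generator consumed in a fixed
order (motif; then per sequence: background, implant position, mutation
count, mutated positions, replacement bases), so a seed fully determines
the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import BASES, PMSParams, SequenceRecord

__all__ = ["Implant", "PlantedDataset", "generate_planted"]

MutationMode = Literal["exactly_d", "at_most_d"]


@dataclass(frozen=True)
class Implant:
    """Ground truth for one sequence: where the motif occurrence sits."""

    position: int  # 0-based start of the window [position, position + l)
    instance: str
    mutations: int


@dataclass(frozen=True)
class PlantedDataset:
    """Simulator output: sequences plus the planted truth."""

    params: PMSParams
    sequences: tuple[SequenceRecord, ...]
    motif: str
    implants: tuple[Implant, ...]
    seed: int


def _indices_to_dna(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


def generate_planted(
    params: PMSParams,
    t: int,
    n: int,
    seed: int,
    mutation_mode: MutationMode = "exactly_d",
) -> PlantedDataset:
    """Generate a planted (l, d) dataset of t sequences of length n.

    Every occurrence differs from the motif in at most d positions (in
    exactly d under the default mode); mutated positions are a uniform
    subset and each mutated base is replaced by a uniformly chosen
    different base.  Identical seeds give identical datasets.
    """
    l, d = params.l, params.d
    if t < 1:
        raise ValueError(f"need t >= 1 sequences, got {t}")
    if n < l:
        raise ValueError(f"sequence length n={n} shorter than motif l={l}")
    if mutation_mode not in ("exactly_d", "at_most_d"):
        raise ValueError(f"unknown mutation mode {mutation_mode!r}")

    rng = np.random.default_rng(seed)
    motif_idx = rng.integers(0, 4, size=l)
    sequences = []
    implants = []
    for i in range(t):
        background = rng.integers(0, 4, size=n)
        position = int(rng.integers(0, n - l + 1))
        if mutation_mode == "exactly_d":
            n_mut = d
        else:
            n_mut = int(rng.integers(0, d + 1))
        mut_positions = rng.choice(l, size=n_mut, replace=False)
        instance_idx = motif_idx.copy()
        for p in mut_positions:
            # uniform over the three bases different from the motif's
            instance_idx[p] = (motif_idx[p] + 1 + rng.integers(0, 3)) % 4
        background[position : position + l] = instance_idx
        sequences.append(
            SequenceRecord(
                identifier=f"seq_{i + 1:03d}",
                residues=_indices_to_dna(background),
            )
        )
        implants.append(
            Implant(
                position=position,
                instance=_indices_to_dna(instance_idx),
                mutations=n_mut,
            )
        )
    return PlantedDataset(
        params=params,
        sequences=tuple(sequences),
        motif=_indices_to_dna(motif_idx),
        implants=tuple(implants),
        seed=seed,
    )
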