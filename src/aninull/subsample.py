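"""Seeded subsampling of read pairs into replicates, and disjoint pairing.

The null-simulation design: from one strain's read set, draw ``n_replicates``
independent subsamples of ``n_pairs`` whole read pairs (mates are never
separated), assemble each, and compare the resulting assemblies in disjoint
consecutive pairs so that no assembly enters more than one ANI comparison.
Per-replicate seeds are derived deterministically from a single master seed
and recorded, so the whole scheme is reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TypeVar

import numpy as np

from .formats import PairedReadSet

T = TypeVar("T")


class SamplingError(ValueError):
    """Raised when a subsample request cannot be satisfied."""


@dataclass
class ReplicateSet:
    """Ordered replicates of one strain with their subsampling seeds."""

    strain_label: str
    replicates: list = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.replicates) != len(self.seeds):
            raise ValueError("one seed per replicate is required")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replicate seeds must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.replicates)


def subsample_read_pairs(reads: PairedReadSet, n_pairs: int,
                         seed: int | None = None) -> PairedReadSet:
    """Uniform sample of ``n_pairs`` whole pairs without replacement.

    Output order follows input order.  Raises :class:`SamplingError` if
    more pairs are requested than the source holds (no silent truncation).
    """
    total = len(reads)
    if n_pairs > total:
        raise SamplingError(
            f"requested {n_pairs} pairs but source {reads.source_label!r} "
            f"holds only {total}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n_pairs, replace=False))
    return PairedReadSet(pairs=[reads.pairs[i] for i in idx],
                         source_label=reads.source_label)


def derive_seeds(master_seed, n: int) -> list[int]:
    """Derive ``n`` distinct seeds from one master seed (an int, or a tuple
    of ints naming an independent stream).

    Seeds come from the counter-based stream of ``numpy``'s
    :class:`~numpy.random.SeedSequence`; duplicates (astronomically rare)
    are skipped so the result is guaranteed pairwise distinct.
    """
    ss = np.random.SeedSequence(master_seed)
    seeds: list[int] = []
    seen: set[int] = set()
    batch = 0
    while len(seeds) < n:
        state = ss.generate_state(n + batch + 8, dtype=np.uint32)
        for v in state:
            v = int(v) % (2**31)
            if v not in seen:
                seen.add(v)
                seeds.append(v)
            if len(seeds) == n:
                break
        batch += 8
    return seeds[:n]


def make_replicates(reads: PairedReadSet, n_replicates: int, n_pairs: int,
                    master_seed: int) -> ReplicateSet:
    """Draw ``n_replicates`` independent seeded subsamples of ``reads``.

    ``n_replicates`` must be even because replicates are later compared in
    disjoint pairs.
    """
    if n_replicates % 2 != 0 or n_replicates < 2:
        raise ValueError(
            f"n_replicates must be even and >= 2 (replicates are compared in "
            f"disjoint pairs), got {n_replicates}")
    seeds = derive_seeds(master_seed, n_replicates)
    replicates = [subsample_read_pairs(reads, n_pairs, seed=s) for s in seeds]
    return ReplicateSet(strain_label=reads.source_label,
                        replicates=replicates, seeds=seeds)


def disjoint_pairs(items: Sequence[T]) -> list[tuple[T, T]]:
    """Pair items consecutively: (1,2), (3,4), ...; each item used once."""
    if len(items) % 2 != 0:
        raise ValueError(f"cannot form disjoint pairs from {len(items)} items")
    return [(items[i], items[i + 1]) for i in range(0, len(items), 2)]
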