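"""Synthetic genomes, strains, paired-end reads, and emulated assemblies.

This module provides the generative side of the pipeline: an ancestral
genome, derived strains at chosen SNV/indel rates (with an exact mutation
log as ground truth), 2x150 bp paired reads with base-call error, and a
desk-scale assembly emulator.  The emulator does not assemble reads; it
reproduces the statistical signature of short-read assembly that matters
for ANI work — contig fragmentation at coverage gaps and rare
coverage-dependent consensus errors — so that two assemblies emulated from
the same strain have ANI slightly below 100% with replicate-to-replicate
spread.

All four operations are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from ._encoding import decode, encode, revcomp
from .formats import Assembly, PairedReadSet, SequenceRecord, filter_contigs

logger = logging.getLogger(__name__)


@dataclass
class Genome:
    """A linear nucleotide sequence with a strain label and optional parent."""

    seq: str
    label: str
    lineage: str | None = None

    def __post_init__(self) -> None:
        if not set(self.seq) <= set("ACGT"):
            bad = sorted(set(self.seq) - set("ACGT"))
            raise ValueError(f"genome {self.label!r} contains non-ACGT bases: {bad}")

    def __len__(self) -> int:
        return len(self.seq)

    def to_assembly(self) -> Assembly:
        return Assembly(contigs=[SequenceRecord(id=self.label, seq=self.seq)],
                        label=self.label)


@dataclass
class MutationLog:
    """Ordered mutation events on parent coordinates.

    Each event is ``(position, type, payload)`` with type in
    {"SNV", "insertion", "deletion"}: an SNV's payload is the replacement
    base, an insertion's the inserted sequence (placed before the parent
    base at ``position``), a deletion's the number of parent bases removed
    starting at ``position``.  Positions are strictly increasing and event
    spans never overlap, so replaying the log on the parent reproduces the
    child exactly.
    """

    events: list[tuple[int, str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.events]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("mutation log positions must be strictly increasing")

    @property
    def snv_count(self) -> int:
        return sum(1 for _, t, _ in self.events if t == "SNV")

    def replay(self, parent: str) -> str:
        """Apply the log to ``parent`` and return the child sequence."""
        out: list[str] = []
        prev = 0
        for pos, etype, payload in self.events:
            out.append(parent[prev:pos])
            if etype == "SNV":
                out.append(str(payload))
                prev = pos + 1
            elif etype == "insertion":
                out.append(str(payload))
                prev = pos
            elif etype == "deletion":
                prev = pos + int(payload)
            else:
                raise ValueError(f"unknown event type {etype!r}")
        out.append(parent[prev:])
        return "".join(out)

    def write_tsv(self, path) -> None:
        with open(path, "w") as handle:
            for pos, etype, payload in self.events:
                handle.write(f"{pos}\t{etype}\t{payload}\n")


@dataclass
class AssemblyEmulationModel:
    """Parameters of the assembly emulator.

    ``mean_depth`` is the Poisson mean of the *effective* per-window depth
    driving consensus decisions.  It is deliberately an abstraction: real
    assemblers see deep but uneven evidence, and most consensus errors
    come from the thin or problematic tail, which this single parameter
    stands in for.  ``base_error_rate`` is the per-read per-base
    discordance of that evidence.  Windows with depth below
    ``min_contig_depth`` become coverage gaps that break contigs; contigs
    shorter than ``min_contig_len`` are then dropped, mirroring the
    pipeline's contig-length filter.
    """

    mean_depth: float = 8.0
    base_error_rate: float = 0.05
    min_contig_depth: int = 1
    window: int = 150
    min_contig_len: int = 1000
    max_cached_depth: int = 512

    def __post_init__(self) -> None:
        if not (self.mean_depth >= 0 and math.isfinite(self.mean_depth)):
            raise ValueError("mean_depth must be finite and >= 0")
        if not (0 <= self.base_error_rate < 1):
            raise ValueError("base_error_rate must lie in [0, 1)")
        if self.min_contig_depth < 1:
            raise ValueError("min_contig_depth must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    def consensus_error_prob(self, depth: int) -> float:
        """Exact probability that a strict majority of ``depth`` reads carry
        the same wrong base (each read wrong with ``base_error_rate``, the
        three wrong bases equiprobable; ties at even depth resolve to the
        correct base, so the probability is non-increasing along depths of
        equal parity).
        """
        if depth <= 0:
            return 0.0
        e3 = self.base_error_rate / 3.0
        need = depth // 2 + 1  # strictly more than half
        return float(min(1.0, 3.0 * binom.sf(need - 1, depth, e3)))

    def error_prob_by_depth(self, max_depth: int) -> np.ndarray:
        d = min(max_depth, self.max_cached_depth)
        return np.array([self.consensus_error_prob(i) for i in range(d + 1)])


def generate_ancestor(length: int, gc_fraction: float = 0.42,
                      seed: int | None = None, label: str = "ancestor") -> Genome:
    """Generate an i.i.d. random genome with the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return Genome(seq=decode(codes), label=label)


_OTHER_BASES = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def derive_strain(parent: Genome, snv_rate: float, indel_rate: float = 0.0,
                  seed: int | None = None,
                  label: str | None = None) -> tuple[Genome, MutationLog]:
    """Derive a child strain from ``parent`` by point mutations and indels.

    Each parent base is substituted (to a uniformly chosen different base)
    with probability ``snv_rate``; indel events occur at rate ``indel_rate``
    per base with geometric lengths (mean 3), insertions and deletions
    equally likely.  The returned :class:`MutationLog` replays the parent
    into the child exactly and records the ground-truth divergence.
    """
    for name, rate in (("snv_rate", snv_rate), ("indel_rate", indel_rate)):
        if not (0.0 <= rate <= 0.1):
            raise ValueError(f"{name} must lie in [0, 0.1], got {rate}")
    rng = np.random.default_rng(seed)
    n = len(parent)
    snv_pos = np.flatnonzero(rng.random(n) < snv_rate)
    indel_pos = np.flatnonzero(rng.random(n) < indel_rate)

    events: list[tuple[int, str, object]] = []
    snv_set = set(snv_pos.tolist())
    merged = sorted(set(snv_pos.tolist()) | set(indel_pos.tolist()))
    indel_set = set(indel_pos.tolist())
    blocked_until = 0
    for pos in merged:
        if pos < blocked_until:
            continue  # consumed by a previous deletion
        if pos in indel_set:
            length = int(rng.geometric(1.0 / 3.0))
            if rng.random() < 0.5:
                payload = decode(rng.integers(0, 4, size=length).astype(np.uint8))
                events.append((pos, "insertion", payload))
            else:
                length = min(length, n - pos)
                if length > 0:
                    events.append((pos, "deletion", length))
                    blocked_until = pos + length
        elif pos in snv_set:
            new = _OTHER_BASES[parent.seq[pos]][int(rng.integers(0, 3))]
            events.append((pos, "SNV", new))
    log = MutationLog(events=events)
    child_label = label or f"{parent.label}_d{snv_rate:g}"
    child = Genome(seq=log.replay(parent.seq), label=child_label,
                   lineage=parent.label)
    return child, log


def simulate_reads(genome: Genome, n_pairs: int, read_len: int = 150,
                   insert_mean: float = 400.0, insert_sd: float = 40.0,
                   error_rate: float = 0.001,
                   seed: int | None = None) -> PairedReadSet:
    """Simulate paired-end reads with uniform fragment starts.

    Mate 1 is the forward strand of the fragment's 5' end; mate 2 is the
    reverse complement of the fragment's 3' end.  Substitution errors are
    applied per base at ``error_rate``; qualities are constant Q40.
    """
    L = len(genome)
    if not (read_len <= insert_mean <= L):
        raise ValueError(
            f"need read_len <= insert_mean <= genome length "
            f"({read_len}, {insert_mean}, {L})")
    if not (0.0 <= error_rate <= 0.1):
        raise ValueError("error_rate must lie in [0, 0.1]")
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    rng = np.random.default_rng(seed)
    codes = encode(genome.seq)

    flen = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(np.int64)
    flen = np.clip(flen, read_len, L)
    starts = (rng.random(n_pairs) * (L - flen + 1)).astype(np.int64)

    offsets = np.arange(read_len, dtype=np.int64)
    m1 = codes[starts[:, None] + offsets]
    ends = starts + flen  # exclusive
    m2_fwd = codes[(ends - read_len)[:, None] + offsets]
    # reverse complement of the fragment's 3' end
    m2 = (3 - m2_fwd[:, ::-1]).astype(np.uint8)

    for mat in (m1, m2):
        err = rng.random(mat.shape) < error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            mat[err] = (mat[err] + shift) % 4

    qual = "I" * read_len
    pairs = []
    for i in range(n_pairs):
        stem = f"{genome.label}_read{i}"
        r1 = SequenceRecord(id=f"{stem}/1", seq=decode(m1[i]), quality=qual)
        r2 = SequenceRecord(id=f"{stem}/2", seq=decode(m2[i]), quality=qual)
        pairs.append((r1, r2))
    return PairedReadSet(pairs=pairs, source_label=genome.label)


def emulate_assembly(genome: Genome, model: AssemblyEmulationModel | None = None,
                     seed: int | None = None,
                     label: str | None = None) -> Assembly:
    """Emulate a short-read assembly of ``genome``.

    Per-window effective depth is Poisson(``mean_depth``); windows below
    ``min_contig_depth`` become coverage gaps that split the genome into
    contigs, and each retained base suffers a consensus substitution with
    the exact majority-vote error probability at its window's depth.
    Contigs shorter than ``min_contig_len`` are dropped.
    """
    model = model or AssemblyEmulationModel()
    label = label or f"{genome.label}_asm"
    if model.mean_depth == 0:
        logger.warning("mean_depth=0: emulated assembly of %r is empty", genome.label)
        return Assembly(contigs=[], label=label)
    rng = np.random.default_rng(seed)
    codes = encode(genome.seq).copy()
    L = len(codes)
    n_windows = (L + model.window - 1) // model.window
    depth = rng.poisson(model.mean_depth, size=n_windows)
    depth = np.minimum(depth, model.max_cached_depth)

    p_by_depth = model.error_prob_by_depth(int(depth.max()))
    per_window_p = p_by_depth[depth]
    per_base_p = np.repeat(per_window_p, model.window)[:L]
    err = rng.random(L) < per_base_p
    if err.any():
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        codes[err] = (codes[err] + shift) % 4

    covered = np.repeat(depth >= model.min_contig_depth, model.window)[:L]
    contigs: list[SequenceRecord] = []
    boundaries = np.flatnonzero(np.diff(covered.astype(np.int8)) != 0) + 1
    segments = np.split(np.arange(L), boundaries)
    idx = 0
    for seg in segments:
        if len(seg) == 0 or not covered[seg[0]]:
            continue
        start, stop = int(seg[0]), int(seg[-1]) + 1
        idx += 1
        contigs.append(SequenceRecord(
            id=f"{label}_ctg{idx}", seq=decode(codes[start:stop]),
            description=f"source={genome.label}:{start}-{stop}"))
    return filter_contigs(Assembly(contigs=contigs, label=label),
                          min_len=model.min_contig_len)


def hamming_identity(parent: Genome, log: MutationLog) -> float:
    """Ground-truth percent identity implied by a substitution-only log."""
    if any(t != "SNV" for _, t, _ in log.events):
        raise ValueError("hamming identity is defined for substitution-only logs")
    return 100.0 * (1.0 - log.snv_count / len(parent))
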