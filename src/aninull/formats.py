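"""Readers and writers for the sequence and tabular formats the pipeline touches.

FASTA assemblies, paired FASTQ (4-line records, Phred+33), and the 5-column
tab-separated ANI table dialect (query, reference, ANI %, mapped fragments,
total fragments).  Bases outside {A,C,G,T,N} — IUPAC ambiguity codes and the
like — are mapped to N with a logged count, since every downstream k-mer and
identity computation treats only unambiguous bases.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_CLEAN_TABLE = {c: (c if c in _VALID_BASES else "N") for c in
                "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared format."""


class PairingError(ValueError):
    """Raised when R1/R2 files cannot be paired record-for-record."""


def clean_sequence(seq: str) -> tuple[str, int]:
    """Uppercase ``seq`` and map characters outside {A,C,G,T,N} to N.

    Returns the cleaned sequence and the number of replaced characters.
    """
    up = seq.upper()
    cleaned = up.translate(str.maketrans(_CLEAN_TABLE))
    n_replaced = sum(1 for a, b in zip(up, cleaned) if a != b)
    return cleaned, n_replaced


@dataclass
class SequenceRecord:
    """A named nucleotide sequence; ``quality`` is set for FASTQ reads."""

    id: str
    seq: str
    description: str = ""
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if len(self.seq) == 0:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise ValueError(f"record {self.id!r}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """A genome assembly: ordered contigs plus a strain/sample label."""

    contigs: list[SequenceRecord]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate contig ids in assembly {self.label!r}: {dupes}")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def sequences(self) -> list[str]:
        return [c.seq for c in self.contigs]


@dataclass
class PairedReadSet:
    """Ordered paired-end reads; mates are kept in file order and never separated."""

    pairs: list[tuple[SequenceRecord, SequenceRecord]] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        for r1, r2 in self.pairs:
            if _mate_stem(r1.id) != _mate_stem(r2.id):
                raise PairingError(
                    f"mate ids do not correspond: {r1.id!r} vs {r2.id!r}")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ANIRecord:
    """One directional ANI comparison in the external tool's 5-column dialect."""

    query: str
    reference: str
    ani: float | None
    fragments_mapped: int
    fragments_total: int

    def __post_init__(self) -> None:
        if self.ani is not None and not (0.0 <= self.ani <= 100.0):
            raise ValueError(f"ANI {self.ani} outside [0, 100]")
        if self.fragments_total < 1:
            raise ValueError("fragments_total must be >= 1")
        if not (0 <= self.fragments_mapped <= self.fragments_total):
            raise ValueError("fragments_mapped must lie in [0, fragments_total]")


def _mate_stem(read_id: str) -> str:
    """Strip a trailing /1, /2 (or .1/.2) mate suffix from a read id."""
    for sep in ("/", "."):
        if len(read_id) > 2 and read_id[-2] == sep and read_id[-1] in "12":
            return read_id[:-2]
    return read_id


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, label: str | None = None) -> Assembly:
    """Read a FASTA file into an :class:`Assembly` (record order preserved).

    Characters outside {A,C,G,T,N} are mapped to N; the replacement count is
    logged.  Raises :class:`ParseError` on an empty file or malformed header.
    """
    path = Path(path)
    contigs: list[SequenceRecord] = []
    n_replaced = 0
    with _open_text(path) as handle:
        first = handle.readline()
        if not first.strip():
            raise ParseError(f"{path}: empty FASTA file (line 1)")
        if not first.startswith(">"):
            raise ParseError(f"{path}: malformed FASTA, line 1 does not start with '>'")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq, repl = clean_sequence(str(rec.seq))
            n_replaced += repl
            if len(seq) == 0:
                raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
            contigs.append(SequenceRecord(id=rec.id, seq=seq,
                                          description=rec.description))
    if n_replaced:
        logger.info("%s: mapped %d ambiguous bases to N", path, n_replaced)
    return Assembly(contigs=contigs, label=label if label is not None else path.stem)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(c.seq), id=c.id,
                         description=c.description or "")
               for c in assembly.contigs]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def _iter_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    path = Path(path)
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                seq, _ = clean_sequence(str(rec.seq))
                qual = "".join(chr(q + 33)
                               for q in rec.letter_annotations["phred_quality"])
                yield SequenceRecord(id=rec.id, seq=seq,
                                     description=rec.description, quality=qual)
        except ValueError as exc:  # Biopython signals truncated 4-line blocks
            raise ParseError(f"{path}: {exc}") from exc


def read_fastq_pair(path_r1: str | Path, path_r2: str | Path,
                    source_label: str = "") -> PairedReadSet:
    """Read an R1/R2 FASTQ file pair, zipping records in file order.

    Raises :class:`PairingError` when the two files have unequal record
    counts and :class:`ParseError` on truncated records.
    """
    reads1 = list(_iter_fastq(path_r1))
    reads2 = list(_iter_fastq(path_r2))
    if len(reads1) != len(reads2):
        raise PairingError(
            f"R1 has {len(reads1)} records but R2 has {len(reads2)}: "
            f"{path_r1} / {path_r2}")
    label = source_label or Path(path_r1).stem
    return PairedReadSet(pairs=list(zip(reads1, reads2)), source_label=label)


def write_fastq_pair(reads: PairedReadSet, path_r1: str | Path,
                     path_r2: str | Path) -> None:
    """Write mates to separate R1/R2 FASTQ files, qualities verbatim."""
    with open(path_r1, "w") as h1, open(path_r2, "w") as h2:
        for r1, r2 in reads.pairs:
            for rec, handle in ((r1, h1), (r2, h2)):
                qual = rec.quality if rec.quality is not None else "I" * len(rec)
                handle.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def filter_contigs(assembly: Assembly, min_len: int = 1000) -> Assembly:
    """Drop contigs strictly shorter than ``min_len`` (default 1000 bp).

    Contigs of length exactly ``min_len`` are kept; order is preserved.  An
    empty result is allowed but logged as a warning.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [c for c in assembly.contigs if len(c) >= min_len]
    if not kept and assembly.contigs:
        logger.warning("assembly %r: all %d contigs shorter than %d bp",
                       assembly.label, len(assembly.contigs), min_len)
    return Assembly(contigs=kept, label=assembly.label)


def parse_ani_table(path: str | Path) -> list[ANIRecord]:
    """Parse a 5-column tab-separated ANI table into :class:`ANIRecord` rows."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 5:
        raise ParseError(
            f"{path}: expected 5 tab-separated columns, found {df.shape[1]}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        query, reference, ani_s, mapped_s, total_s = row
        try:
            ani = float(ani_s)
            mapped = int(mapped_s)
            total = int(total_s)
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-numeric field ({exc})") from exc
        try:
            records.append(ANIRecord(query=query, reference=reference, ani=ani,
                                     fragments_mapped=mapped, fragments_total=total))
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return records


def write_ani_table(records: list[ANIRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in records:
            ani = f"{r.ani:.4f}" if r.ani is not None else "NA"
            handle.write(f"{r.query}\t{r.reference}\t{ani}\t"
                         f"{r.fragments_mapped}\t{r.fragments_total}\n")
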