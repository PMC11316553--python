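"""SNP counting and pairwise identity from whole-genome multiple alignments.

Consumes alignments produced externally (aligned FASTA, or XMFA with
blocks concatenated per genome in block order).  The SNP convention: a
column is *considered* only when every row carries an unambiguous base
(no gap, no N); a considered column is a SNP when at least two distinct
bases occur in it.  Percentages are reported over considered columns —
the only denominator under which a substitution is well defined for all
rows — and the convention is tagged in every report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

SNP_CONVENTION = "gap-free-columns"

_BASE_CODES = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows over {A,C,G,T,N,-} with genome labels."""

    sequences: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("a multiple alignment needs >= 2 rows")
        if len(self.sequences) != len(self.labels):
            raise ValueError("one label per row is required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
        for lab, seq in zip(self.labels, self.sequences):
            if all(c == "-" for c in seq):
                raise ValueError(f"row {lab!r} contains no non-gap character")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def _matrix(self) -> np.ndarray:
        """Rows as uint8 codes: 0..3 = ACGT, 255 = gap/N/ambiguous."""
        mat = np.full((len(self.sequences), self.length), 255, dtype=np.uint8)
        for i, seq in enumerate(self.sequences):
            raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            for byte, code in _BASE_CODES.items():
                mat[i, raw == byte] = code
        return mat


@dataclass
class SNPReport:
    snp_count: int
    columns_considered: int
    snp_percent: float | None
    convention: str = SNP_CONVENTION


def _read_xmfa(path: Path) -> MultipleAlignment:
    """Minimal XMFA reader: '=' separates blocks; headers look like
    '> id:start-end strand description'.  Blocks are concatenated per
    genome in block order; genomes are matched across blocks by header id.
    """
    blocks: list[dict[str, str]] = []
    current: dict[str, str] = {}
    cur_id = None
    header_re = re.compile(r">\s*(\S+?)(?::\d+-\d+)?(?:\s+[+-])?(?:\s+(.*))?$")
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("#") or not line.strip():
                continue
            if line.startswith("="):
                if current:
                    blocks.append(current)
                current, cur_id = {}, None
            elif line.startswith(">"):
                m = header_re.match(line)
                if not m:
                    raise ValueError(f"{path}: unparseable XMFA header: {line!r}")
                cur_id = m.group(1)
                current[cur_id] = ""
            else:
                if cur_id is None:
                    raise ValueError(f"{path}: sequence data before any header")
                current[cur_id] += line.strip()
    if current:
        blocks.append(current)
    if not blocks:
        raise ValueError(f"{path}: no alignment blocks found")
    labels = list(blocks[0].keys())
    rows = {lab: [] for lab in labels}
    for block in blocks:
        blen = {len(s) for s in block.values()}
        if len(blen) != 1:
            raise ValueError(f"{path}: ragged rows within an XMFA block")
        width = blen.pop()
        for lab in labels:
            rows[lab].append(block.get(lab, "-" * width))
    return MultipleAlignment(sequences=["".join(rows[lab]) for lab in labels],
                             labels=labels)


def read_alignment(path, dialect: str = "fasta") -> MultipleAlignment:
    """Read an aligned FASTA (``dialect="fasta"``) or XMFA (``"xmfa"``)."""
    path = Path(path)
    if dialect == "xmfa":
        return _read_xmfa(path)
    if dialect == "fasta":
        aln = AlignIO.read(str(path), "fasta")
        return MultipleAlignment(sequences=[str(r.seq).upper() for r in aln],
                                 labels=[r.id for r in aln])
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def count_snps(aln: MultipleAlignment) -> SNPReport:
    """Count SNP columns over the gap-free columns of the alignment."""
    mat = aln._matrix()
    considered = np.all(mat != 255, axis=0)
    n_considered = int(considered.sum())
    if n_considered == 0:
        return SNPReport(snp_count=0, columns_considered=0, snp_percent=None)
    sub = mat[:, considered]
    is_snp = np.any(sub != sub[0], axis=0)
    n_snp = int(is_snp.sum())
    return SNPReport(snp_count=n_snp, columns_considered=n_considered,
                     snp_percent=100.0 * n_snp / n_considered)


def pairwise_identity(aln: MultipleAlignment) -> np.ndarray:
    """Percent identity for every row pair over columns where both rows are
    unambiguous bases; symmetric, 100 on the diagonal."""
    mat = aln._matrix()
    n = mat.shape[0]
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = (mat[i] != 255) & (mat[j] != 255)
            total = int(both.sum())
            if total == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            matches = int((mat[i][both] == mat[j][both]).sum())
            out[i, j] = out[j, i] = 100.0 * matches / total
    return out
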