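"""Fragment-based average nucleotide identity between two assemblies.

The query is cut into non-overlapping fragments (default 3,000 bp; the
terminal remainder is discarded).  Each fragment is anchored to the
reference by shared k-mers (default k=16, both strands), placed on the
best-supported diagonal, and scored by ungapped percent identity against
the anchored contig; fragments whose best identity falls below a seed
threshold (default 80%) are unmapped.  ANI is the mean identity over
mapped fragments, reported as a percentage; when fewer than ``min_mapped``
fragments map, the ANI is undefined (``None``) rather than zero.

This estimator is deliberately ungapped after anchoring: the null
distribution machinery needs a fast, consistent identity statistic, not a
reimplementation of an external mapper.  External ANI tables can be used
downstream instead via :func:`aninull.formats.parse_ani_table`.
"""

from __future__ import annotations

import numpy as np

from ._encoding import N_CODE, encode
from .formats import ANIRecord, Assembly

DEFAULT_FRAGMENT_LEN = 3000
DEFAULT_K = 16
DEFAULT_MIN_IDENTITY_SEED = 0.8
DEFAULT_MIN_MAPPED = 10


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer k-mer values at every start position, plus a validity mask
    (k-mers touching an N are invalid)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    c = codes.astype(np.int64)
    for j in range(k):
        vals = vals * 4 + np.where(c[j:j + n] < 4, c[j:j + n], 0)
    bad = (codes >= N_CODE).astype(np.int32)
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0
    return vals, valid


class _ReferenceIndex:
    """Sorted k-mer index over an assembly's contigs (concatenated with N
    separators so no k-mer spans a contig boundary)."""

    def __init__(self, reference: Assembly, k: int):
        self.k = k
        parts = []
        starts = []
        pos = 0
        for contig in reference.contigs:
            starts.append(pos)
            parts.append(encode(contig.seq))
            pos += len(contig.seq)
            parts.append(np.full(1, N_CODE, dtype=np.uint8))
            pos += 1
        self.codes = (np.concatenate(parts) if parts
                      else np.empty(0, dtype=np.uint8))
        self.contig_starts = np.array(starts, dtype=np.int64)
        self.contig_ends = self.contig_starts + np.array(
            [len(c.seq) for c in reference.contigs], dtype=np.int64)
        vals, valid = _kmer_values(self.codes, k)
        keep = np.flatnonzero(valid)
        order = np.argsort(vals[keep], kind="stable")
        self.sorted_keys = vals[keep][order]
        self.sorted_pos = keep[order]

    def contig_bounds(self, gpos: int) -> tuple[int, int]:
        i = int(np.searchsorted(self.contig_starts, gpos, side="right")) - 1
        return int(self.contig_starts[i]), int(self.contig_ends[i])


def _best_diagonal_identity(frag_codes: np.ndarray, index: _ReferenceIndex,
                            max_hits_per_kmer: int,
                            anchor_stride: int = 4) -> float | None:
    """Identity of the fragment along its best-supported diagonal, or None
    when no k-mer anchors exist.  Anchoring uses every ``anchor_stride``-th
    fragment k-mer (identity is still scored base-by-base over the whole
    overlap, so the stride affects speed, not the statistic)."""
    vals, valid = _kmer_values(frag_codes, index.k)
    fpos = np.flatnonzero(valid)[::anchor_stride]
    if len(fpos) == 0:
        return None
    keys = vals[fpos]
    left = np.searchsorted(index.sorted_keys, keys, side="left")
    bounded = np.minimum(left, len(index.sorted_keys) - 1)
    present = (len(index.sorted_keys) > 0) & (index.sorted_keys[bounded] == keys)
    right = left.copy()
    hit_idx = np.flatnonzero(present)
    if len(hit_idx) == 0:
        return None
    right[hit_idx] = np.searchsorted(index.sorted_keys, keys[hit_idx],
                                     side="right")
    counts = right - left
    keep = np.flatnonzero((counts > 0) & (counts <= max_hits_per_kmer))
    if len(keep) == 0:
        return None
    single = keep[counts[keep] == 1]
    multi = keep[counts[keep] > 1]
    parts_ref = [index.sorted_pos[left[single]]]
    parts_frag = [fpos[single]]
    for i in multi:
        parts_ref.append(index.sorted_pos[left[i]:right[i]])
        parts_frag.append(np.full(counts[i], fpos[i]))
    hit_ref = np.concatenate(parts_ref)
    hit_frag = np.concatenate(parts_frag)
    diagonals = hit_ref - hit_frag

    # resolve each anchored position to the hit on the best-supported
    # diagonal, then chain runs of consecutive anchors sharing a diagonal;
    # small indels shift the true alignment onto a neighbouring diagonal,
    # which shows up as a new run
    uniq, inverse, cnt = np.unique(diagonals, return_inverse=True,
                                   return_counts=True)
    support = cnt[inverse]
    order = np.lexsort((-support, hit_frag))
    hf, dg = hit_frag[order], diagonals[order]
    first = np.concatenate(([True], hf[1:] != hf[:-1]))
    hf, dg = hf[first], dg[first]

    runs = []  # (first_anchor, last_anchor, diag, n_anchors)
    for pos, diag in zip(hf.tolist(), dg.tolist()):
        if runs and runs[-1][2] == diag:
            runs[-1] = (runs[-1][0], pos, diag, runs[-1][3] + 1)
        else:
            runs.append((pos, pos, diag, 1))
    strong = [r for r in runs if r[3] >= 2]
    if not strong:
        strong = [max(runs, key=lambda r: r[3])]
    merged = [strong[0]]
    for r in strong[1:]:
        if r[2] == merged[-1][2]:
            merged[-1] = (merged[-1][0], r[1], r[2], merged[-1][3] + r[3])
        else:
            merged.append(r)

    flen = len(frag_codes)
    # span boundaries at midpoints between adjacent runs' anchor extents
    bounds = [0]
    for prev, nxt in zip(merged, merged[1:]):
        bounds.append(max(bounds[-1],
                          min(flen, (prev[1] + index.k + nxt[0]) // 2)))
    bounds.append(flen)
    total_matches = 0
    total_compared = 0
    for (fs, fe), run in zip(zip(bounds, bounds[1:]), merged):
        m, c = _score_span(frag_codes, index, run[2], fs, fe)
        total_matches += m
        total_compared += c
    if total_compared < index.k:
        return None
    return total_matches / total_compared


def _score_span(frag_codes: np.ndarray, index: _ReferenceIndex, diag: int,
                fstart: int, fend: int) -> tuple[int, int]:
    """Ungapped match/compared counts for fragment span [fstart, fend) on
    ``diag``, clipped to the reference contig the span lands in."""
    anchor = diag + (fstart + fend) // 2
    anchor = min(max(anchor, 0), len(index.codes) - 1)
    cstart, cend = index.contig_bounds(anchor)
    lo = max(diag + fstart, cstart)
    hi = min(diag + fend, cend)
    if hi <= lo:
        return 0, 0
    ref_seg = index.codes[lo:hi]
    frag_seg = frag_codes[lo - diag:hi - diag]
    comparable = (ref_seg < N_CODE) & (frag_seg < N_CODE)
    matches = int(((ref_seg == frag_seg) & comparable).sum())
    return matches, int(comparable.sum())


def fragment_ani(query: Assembly, reference: Assembly,
                 fragment_len: int = DEFAULT_FRAGMENT_LEN, k: int = DEFAULT_K,
                 min_identity_seed: float = DEFAULT_MIN_IDENTITY_SEED,
                 min_mapped: int = DEFAULT_MIN_MAPPED,
                 max_hits_per_kmer: int = 16,
                 _index: "_ReferenceIndex | None" = None) -> ANIRecord:
    """Directional fragment ANI of ``query`` against ``reference``.

    Both strands of each fragment are tried; the higher-identity strand
    wins, ties going to the forward strand.  Returns an
    :class:`~aninull.formats.ANIRecord`; ``ani`` is ``None`` when fewer
    than ``min_mapped`` fragments map.
    """
    if len(query.contigs) == 0 or len(reference.contigs) == 0:
        raise ValueError("fragment_ani requires two non-empty assemblies")
    index = _index if _index is not None else _ReferenceIndex(reference, k)

    identities = []
    n_fragments = 0
    for contig in query.contigs:
        codes = encode(contig.seq)
        for start in range(0, len(codes) - fragment_len + 1, fragment_len):
            n_fragments += 1
            frag = codes[start:start + fragment_len]
            ident_f = _best_diagonal_identity(frag, index, max_hits_per_kmer)
            if ident_f is not None and ident_f >= 0.99:
                ident_r = None  # near-perfect forward match: no real sequence
                # can beat it on the opposite strand
            else:
                rc = ((3 - frag[::-1].astype(np.int16)) % 5).astype(np.uint8)
                ident_r = _best_diagonal_identity(rc, index, max_hits_per_kmer)
            best = max((x for x in (ident_f, ident_r) if x is not None),
                       default=None)
            if best is not None and ident_f is not None and ident_f >= best:
                best = ident_f  # tie-break toward forward strand
            if best is not None and best >= min_identity_seed:
                identities.append(best)
    n_mapped = len(identities)
    if n_fragments == 0:
        raise ValueError(
            f"query {query.label!r} has no contig of length >= {fragment_len}")
    ani = 100.0 * float(np.mean(identities)) if n_mapped >= min_mapped else None
    return ANIRecord(query=query.label, reference=reference.label, ani=ani,
                     fragments_mapped=n_mapped, fragments_total=n_fragments)


def symmetric_ani(a: Assembly, b: Assembly, **kwargs) -> float | None:
    """Arithmetic mean of the two directional fragment ANIs.

    Returns ``None`` (missing) when either direction is undefined.
    """
    fwd = fragment_ani(a, b, **kwargs)
    rev = fragment_ani(b, a, **kwargs)
    if fwd.ani is None or rev.ani is None:
        return None
    return (fwd.ani + rev.ani) / 2.0
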