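"""Local alignment and read-complexity filtering.

Desk-scale stand-in for the heuristic read mapper used on full ocean
metagenomes: every read is aligned to every catalog sequence with an
affine-gap Smith–Waterman (Gotoh) algorithm under a fixed, fully explicit
scoring scheme, so that assignments are reproducible and checkable against
an exhaustive dynamic-programming oracle.

Conventions (these are load-bearing for downstream filters):

* scoring defaults: match +1, mismatch −1, gap open −2, gap extend −1;
  a gap of length k costs ``open + (k − 1) · extend``;
* ``N`` never counts as a match — it scores as a mismatch and is never
  counted towards identity;
* identity = matches / alignment columns (gap columns included), in %;
* aligned read fraction = aligned read bases / read length, in %;
* traceback ties prefer diagonal, then a gap in the reference (read base
  consumed), then a gap in the read; the start cell is the highest-scoring
  cell with the smallest (row, column) index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_BASE_CODE = np.full(256, 4, dtype=np.int8)  # everything unknown -> N
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0, C=1, G=2, T=3, N/other=4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap alignment scores. Penalties are negative by convention."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a read against one reference."""

    read_id: str
    reference_id: str
    score: int
    identity: float  # percent, matches / alignment columns
    aligned_read_fraction: float  # percent, aligned read bases / read length
    aligned_columns: int
    matches: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must lie in [0, 100]")
        if not (0.0 <= self.aligned_read_fraction <= 100.0):
            raise ValueError("aligned_read_fraction must lie in [0, 100]")


@njit(cache=True)
def _gotoh_kernel(read, ref, match, mismatch, open_pen, extend_pen):  # pragma: no cover
    """Affine-gap local DP returning (score, matches, columns, read_bases_aligned).

    open_pen / extend_pen are positive penalty magnitudes.
    """
    m = read.shape[0]
    n = ref.shape[0]
    NEG = -10_000_000
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in read (consumes ref)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in ref (consumes read)

    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - open_pen
            ee = E[i, j - 1] - extend_pen
            if ee > e:
                e = ee
            E[i, j] = e
            f = H[i - 1, j] - open_pen
            ff = F[i - 1, j] - extend_pen
            if ff > f:
                f = ff
            F[i, j] = f
            if ri == ref[j - 1] and ri < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:  # strict: ties keep the smallest (i, j)
                best = h
                bi = i
                bj = j

    # traceback with state machine; 0 = M, 1 = E (gap in read), 2 = F (gap in ref)
    matches = 0
    columns = 0
    read_bases = 0
    i = bi
    j = bj
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if read[i - 1] == ref[j - 1] and read[i - 1] < 4:
                s = match
            else:
                s = mismatch
            if h == H[i - 1, j - 1] + s:
                columns += 1
                read_bases += 1
                if s == match:
                    matches += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            elif h == E[i, j]:
                state = 1
            else:  # unreachable for a well-formed matrix
                break
        elif state == 2:
            columns += 1
            read_bases += 1
            if F[i, j] == H[i - 1, j] - open_pen:
                state = 0
            i -= 1
        else:
            columns += 1
            if E[i, j] == H[i, j - 1] - open_pen:
                state = 0
            j -= 1
    return best, matches, columns, read_bases


def local_align(
    read: str,
    reference: str,
    scoring: ScoringScheme | None = None,
    read_id: str = "read",
    reference_id: str = "ref",
) -> AlignmentHit:
    """Best local (Smith–Waterman, affine gaps) alignment of *read* to *reference*.

    Returns an :class:`AlignmentHit` with identity and aligned-read-fraction
    computed from the traceback. Both sequences must be non-empty.
    """
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    sc = scoring or ScoringScheme()
    score, matches, columns, read_bases = _gotoh_kernel(
        encode(read),
        encode(reference),
        np.int32(sc.match),
        np.int32(sc.mismatch),
        np.int32(-sc.gap_open),
        np.int32(-sc.gap_extend),
    )
    identity = 100.0 * matches / columns if columns else 0.0
    fraction = 100.0 * read_bases / len(read)
    return AlignmentHit(
        read_id=read_id,
        reference_id=reference_id,
        score=int(score),
        identity=identity,
        aligned_read_fraction=fraction,
        aligned_columns=int(columns),
        matches=int(matches),
    )


def complexity_ok(
    sequence: str,
    complexity_percent: float = 75.0,
    complexity_number: int = 30,
) -> bool:
    """Low-complexity gate applied to reads before alignment.

    A read fails when the most frequent nucleotide exceeds
    ``complexity_percent`` % of its length, or when its longest
    mononucleotide run is at least ``complexity_number`` bases long.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    n = len(seq)
    counts: dict[str, int] = {}
    for b in seq:
        counts[b] = counts.get(b, 0) + 1
    if 100.0 * max(counts.values()) / n > complexity_percent:
        return False
    run = 1
    longest = 1
    for k in range(1, n):
        if seq[k] == seq[k - 1]:
            run += 1
            if run > longest:
                longest = run
        else:
            run = 1
    return longest < complexity_number
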