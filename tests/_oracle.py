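"""Independent brute-force oracles for recruitment checks.

Plain-Python exhaustive dynamic programming (no numpy, no numba) with the
same declared conventions as the library: match +1 / mismatch −1, a gap of
length k costs 2 + (k − 1), N never matches, traceback prefers diagonal,
then gap-in-reference, then gap-in-read, and the start cell is the
highest-scoring cell with the smallest (row, column) index.
"""

from collections import Counter
from itertools import groupby

NEG = -(10**9)


def oracle_align(read: str, ref: str, match=1, mismatch=-1, open_pen=2, extend_pen=1):
    """Return (score, matches, columns, read_bases_aligned) for the best local
    affine-gap alignment, by explicit full-matrix DP."""
    m, n = len(read), len(ref)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        a = read[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - open_pen, E[i][j - 1] - extend_pen)
            F[i][j] = max(H[i - 1][j] - open_pen, F[i - 1][j] - extend_pen)
            s = match if (a == ref[j - 1] and a in "ACGT") else mismatch
            h = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j

    matches = columns = read_bases = 0
    i, j, state = bi, bj, "M"
    while i > 0 and j > 0:
        if state == "M":
            h = H[i][j]
            if h == 0:
                break
            s = match if (read[i - 1] == ref[j - 1] and read[i - 1] in "ACGT") else mismatch
            if h == H[i - 1][j - 1] + s:
                columns += 1
                read_bases += 1
                if s == match:
                    matches += 1
                i -= 1
                j -= 1
            elif h == F[i][j]:
                state = "F"
            elif h == E[i][j]:
                state = "E"
            else:
                break
        elif state == "F":
            columns += 1
            read_bases += 1
            if F[i][j] == H[i - 1][j] - open_pen:
                state = "M"
            i -= 1
        else:
            columns += 1
            if E[i][j] == H[i][j - 1] - open_pen:
                state = "M"
            j -= 1
    return best, matches, columns, read_bases


def oracle_complexity_ok(seq: str, percent=75.0, number=30) -> bool:
    counts = Counter(seq.upper())
    if 100.0 * max(counts.values()) / len(seq) > percent:
        return False
    longest = max(len(list(g)) for _, g in groupby(seq.upper()))
    return longest < number


def oracle_recruit(reads, catalog, params):
    """Exhaustive align-then-argmax-then-filter assignment.

    *reads* is a list of (read_id, sequence); *catalog* a MarkerCatalog;
    *params* a RecruitmentParams.  Returns {read_id: (reference_id, status)}
    mirroring the library's status vocabulary.
    """
    out = {}
    for rid, seq in reads:
        if len(seq) < params.min_read_size:
            out[rid] = ("", "unassigned_too_short")
            continue
        if not oracle_complexity_ok(seq, params.complexity_percent, params.complexity_number):
            out[rid] = ("", "unassigned_low_complexity")
            continue
        best = None  # (score, identity, columns, ref_id, fraction)
        for ref in catalog:
            score, matches, columns, read_bases = oracle_align(seq, ref.sequence)
            identity = 100.0 * matches / columns if columns else 0.0
            fraction = 100.0 * read_bases / len(seq)
            cand = (score, identity, columns, ref.id, fraction)
            if best is None:
                best = cand
            elif (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]):
                best = cand
            elif (cand[0], cand[1], cand[2]) == (best[0], best[1], best[2]) and cand[3] < best[3]:
                best = cand
        score, identity, columns, ref_id, fraction = best
        if identity < params.min_identity or fraction < params.min_aligned_fraction:
            out[rid] = ("", "unassigned_below_thresholds")
        elif catalog[ref_id].is_outgroup:
            out[rid] = (ref_id, "outgroup")
        else:
            out[rid] = (ref_id, "assigned")
    return out
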