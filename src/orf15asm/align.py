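"""Global contig-to-reference alignment with affine gaps.

A Gotoh-style dynamic program with one asymmetry: terminal gap columns in the
*reference row* (contig overhang beyond the reference) are free, while
terminal gaps in the contig row (contig not reaching a reference end) are
charged like any deletion. Contigs assembled from primer-boosted amplicon
reads routinely overhang the reference, and those overhangs are artifacts of
library structure, not variants.

The low gap-extension penalty relative to the opening penalty is deliberate:
in the ORF15 repeat tract it keeps a 15-51 bp duplication as one contiguous
gap run instead of a scatter of short gaps and mismatches, which is what makes
downstream indel calls clean. A gap run of length L costs
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NEG = -1e30


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -12.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.mismatch < self.match):
            raise ValueError("require gap_open <= mismatch < match")
        if not (self.gap_extend < 0):
            raise ValueError("gap_extend must be negative")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be <= gap_extend (affine convention)")

    def gap_cost(self, length: int) -> float:
        return 0.0 if length <= 0 else self.gap_open + (length - 1) * self.gap_extend


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped contig/reference pair.

    ``ref_row`` and ``query_row`` are equal-length strings over ACGT plus
    ``-``; no column is gap/gap; removing gaps recovers the inputs.
    """

    ref_row: str
    query_row: str
    score: float
    params: AlignParams

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.query_row):
            raise ValueError("alignment rows differ in length")
        if any(a == "-" and b == "-" for a, b in zip(self.ref_row, self.query_row)):
            raise ValueError("gap/gap column in alignment")

    @property
    def ref(self) -> str:
        return self.ref_row.replace("-", "")

    @property
    def query(self) -> str:
        return self.query_row.replace("-", "")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def global_align(query: str, ref: str, params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal affine-gap alignment of ``query`` (contig) against ``ref``.

    Free end gaps on the query only: unaligned query overhangs at either end
    cost nothing. Traceback ties prefer diagonal, then gap-in-query
    (reference base vs ``-``), then gap-in-ref.
    """
    if params is None:
        params = AlignParams()
    if not query or not ref:
        raise ValueError("empty sequence")
    p = params
    q = _encode(query)
    r = _encode(ref)
    m, n = len(q), len(r)

    H = np.empty((m + 1, n + 1), dtype=np.float64)
    D = np.full((m + 1, n + 1), _NEG)  # gap in query row (ref consumed)
    I = np.full((m + 1, n + 1), _NEG)  # gap in ref row (query consumed)

    j_idx = np.arange(1, n + 1, dtype=np.float64)
    H[0, 0] = 0.0
    H[0, 1:] = p.gap_open + (j_idx - 1) * p.gap_extend  # leading deletion: charged
    D[0, 1:] = H[0, 1:]
    H[1:, 0] = 0.0  # leading query overhang: free
    I[1:, 0] = 0.0

    ext_j = p.gap_extend * np.arange(0, n + 1, dtype=np.float64)
    for i in range(1, m + 1):
        s = np.where(r == q[i - 1], p.match, p.mismatch)
        I[i, 1:] = np.maximum(H[i - 1, 1:] + p.gap_open, I[i - 1, 1:] + p.gap_extend)
        h0 = np.maximum(H[i - 1, :-1] + s, I[i, 1:])
        # D within-row recursion solved as a prefix max; re-opening a gap from
        # a D cell is never optimal because gap_open <= gap_extend
        b = np.empty(n + 1)
        b[0] = H[i, 0] - ext_j[0]
        b[1:] = h0 - ext_j[1:]
        run = np.maximum.accumulate(b)
        D[i, 1:] = p.gap_open + ext_j[1:] - p.gap_extend + run[:-1]
        H[i, 1:] = np.maximum(h0, D[i, 1:])

    # trailing query overhang is free: finish at the best row of the last
    # column, preferring to consume more query on exact ties
    best = H[:, n]
    i_best = int(np.flatnonzero(best == best.max())[-1])
    score = float(best[i_best])

    ref_row: list[str] = []
    query_row: list[str] = []
    # trailing overhang
    for k in range(m, i_best, -1):
        ref_row.append("-")
        query_row.append(query[k - 1])

    i, j = i_best, n
    state = "H"
    eps = 1e-9
    while i > 0 and j > 0:
        if state == "H":
            sc = p.match if q[i - 1] == r[j - 1] else p.mismatch
            if abs(H[i, j] - (H[i - 1, j - 1] + sc)) < eps:
                ref_row.append(ref[j - 1])
                query_row.append(query[i - 1])
                i, j = i - 1, j - 1
            elif abs(H[i, j] - D[i, j]) < eps:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            ref_row.append(ref[j - 1])
            query_row.append("-")
            if abs(D[i, j] - (H[i, j - 1] + p.gap_open)) < eps:
                state = "H"
            j -= 1
        else:  # state == "I"
            ref_row.append("-")
            query_row.append(query[i - 1])
            if abs(I[i, j] - (H[i - 1, j] + p.gap_open)) < eps:
                state = "H"
            i -= 1
    while j > 0:  # leading deletion (charged)
        ref_row.append(ref[j - 1])
        query_row.append("-")
        j -= 1
    while i > 0:  # leading query overhang (free)
        ref_row.append("-")
        query_row.append(query[i - 1])
        i -= 1

    return PairwiseAlignment(
        ref_row="".join(reversed(ref_row)),
        query_row="".join(reversed(query_row)),
        score=score,
        params=p,
    )
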