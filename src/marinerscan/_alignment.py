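"""Pairwise alignment primitives.

The classification metric used throughout the package treats a gap as a
fifth character state: percent identity is the number of identical columns
divided by the total number of alignment columns, so a base aligned to a
gap counts as a mismatch (gap-vs-gap columns cannot occur in a pairwise
alignment).  Because downstream clustering depends on exact, reproducible
identities, the Needleman-Wunsch implementation here controls its own
tie-breaking instead of delegating to a library aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVNacgtrykmswbdhvn",
                            "TGCAYRMKSWVHDBNtgcayrmkswvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gap5Alignment:
    """A global pairwise alignment scored with gap-as-fifth-state identity.

    Attributes
    ----------
    aligned_a, aligned_b:
        The two rows of the alignment, equal length, over {A,C,G,T,N,-}.
    score:
        Needleman-Wunsch score under the configured scheme.
    identity:
        Percent of columns in which the two rows carry the same base.
        Columns pairing a base with ``-`` count against identity.
    """

    aligned_a: str
    aligned_b: str
    score: int
    identity: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def _nw_fill(a: str, b: str, match: int, mismatch: int, gap: int) -> np.ndarray:
    """Fill the NW score matrix with a linear gap penalty.

    Rows are vectorised: the within-row left-dependency collapses to a
    running maximum because the gap penalty is linear
    (H[i,j] = max_{k<=j} t[k] + gap*(j-k) = cummax(t[k] - gap*k) + gap*j).
    """
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], match, mismatch).astype(np.int32)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = gap * np.arange(m + 1, dtype=np.int32)
    jg = gap * np.arange(m + 1, dtype=np.int32)  # gap * j
    for i in range(1, n + 1):
        t = np.empty(m + 1, dtype=np.int32)
        t[0] = gap * i
        np.maximum(H[i - 1, :m] + sub[i - 1], H[i - 1, 1:] + gap, out=t[1:])
        # H[i,j] = max_{k<=j} t[k] - gap*(j-k); cummax of (t - gap*k) then +gap*j...
        # with negative gap: t[k] + gap*(j-k) decreasing in (j-k).
        H[i] = np.maximum.accumulate(t - jg) + jg
    return H


def nw_align(a: str, b: str, match: int = 1, mismatch: int = -1,
             gap: int = -2) -> tuple[str, str, int]:
    """Global alignment with linear gap costs and deterministic traceback.

    Tie-breaking during traceback prefers the diagonal move (match, then
    mismatch) over gaps, and a gap in ``a`` over a gap in ``b``.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return a + "-" * m, "-" * n + b, gap * (n + m)
    H = _nw_fill(a, b, match, mismatch, gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and h == H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif j > 0 and h == H[i, j - 1] + gap:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        else:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(H[n, m])


def gap5_identity(row_a: str, row_b: str) -> float:
    """Percent identical columns with gap treated as a fifth state."""
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    if not row_a:
        raise ValueError("empty alignment")
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return 100.0 * matches / len(row_a)


def align_gap5(a: str, b: str, match: int = 1, mismatch: int = -1,
               gap: int = -2) -> Gap5Alignment:
    """Globally align two DNA sequences and score gap-as-fifth-state identity.

    The result is symmetric in its two arguments: the pair is aligned in a
    canonical order (lexicographically smaller sequence first) so that
    tie-breaking cannot produce order-dependent identities.
    """
    if not a or not b:
        raise ValueError("align_gap5 requires two non-empty sequences")
    a = a.upper()
    b = b.upper()
    swapped = b < a
    first, second = (b, a) if swapped else (a, b)
    ra, rb, score = nw_align(first, second, match, mismatch, gap)
    if swapped:
        ra, rb = rb, ra
    return Gap5Alignment(ra, rb, score, gap5_identity(ra, rb))
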