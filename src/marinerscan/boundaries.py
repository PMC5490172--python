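"""TIR and TSD detection: fixing element boundaries around candidate loci.

A terminal-inverted-repeat pair is the highest-scoring ungapped match
between a window left of the homology core and the reverse complement of
a window right of it (match +1 / mismatch -1, Kadane maximal run per
diagonal).  Element boundaries are set at the outer TIR edges, with a
TSD-aware trim: if shifting both boundaries inward by the same small
offset exposes the TA target-site duplication immediately outside both
arms, that trim is applied (the TA duplication itself would otherwise be
absorbed into the arms, since TA...rc(...)TA extends the inverted
repeat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._alignment import revcomp


@dataclass(frozen=True)
class TIRPair:
    """The two terminal inverted-repeat arms, in locus coordinates."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    arm_len: int
    identity: float           # arm vs reverse-complemented arm, %
    left_seq: str


@dataclass
class ElementBoundary:
    scaffold: str
    start: int                # genomic 0-based half-open
    end: int
    strand: str
    tir: TIRPair | None
    tsd_present: str          # yes | no | indeterminate


def _best_ungapped_pair(left: str, right_rc: str, min_len: int,
                        min_id: float, min_score: int = 0) -> list[tuple]:
    """Best ungapped runs between ``left`` and ``right_rc``.

    Returns candidate tuples (score, length, i_start, j_start, matches)
    sorted best-first with ties broken toward longer arms, then outermost
    (smaller i, smaller j).
    """
    if not left or not right_rc:
        return []
    a = np.frombuffer(left.encode(), dtype=np.uint8)
    b = np.frombuffer(right_rc.encode(), dtype=np.uint8)
    n, m = len(a), len(b)
    cands = []
    for d in range(-(m - 1), n):
        if d >= 0:
            i0, j0 = d, 0
        else:
            i0, j0 = 0, -d
        L = min(n - i0, m - j0)
        if L < min_len:
            continue
        v = np.where(a[i0:i0 + L] == b[j0:j0 + L], 1, -1).astype(np.int32)
        P = np.concatenate([[0], np.cumsum(v)])
        runmin = np.minimum.accumulate(P[:-1])
        scores = P[1:] - runmin
        k = int(np.argmax(scores))
        best = int(scores[k])
        if best < min_len * (2 * min_id / 100.0 - 1):
            continue
        start = int(np.argmin(P[:k + 1]))
        length = k + 1 - start
        matches = (best + length) // 2
        if length >= min_len and best >= min_score:
            cands.append((best, length, i0 + start, j0 + start, matches))
    cands.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    return cands


def detect_tir(locus_seq: str, core_start: int, core_end: int,
               window: int = 800, inner_margin: int = 150,
               min_tir: int = 10, min_arm_id: float = 80.0,
               min_score: int = 15,
               tsd: str = "TA", max_tsd_trim: int = 8) -> TIRPair | None:
    """Locate the TIR pair flanking a homology core inside a locus.

    Windows of ``window`` bp outside plus ``inner_margin`` bp inside each
    core edge are scanned.  For nucleotide-recovered loci whose core
    covers the whole element, raise ``inner_margin`` so long arms lying
    inside the core stay visible.

    ``min_score`` (matches minus mismatches) filters the chance
    reverse-complement matches that 800 bp windows inevitably contain at
    the 10 bp / 80% floor; the default keeps every perfect arm of 15 bp
    or more detectable.
    """
    seq = locus_seq.upper()
    ls0 = max(0, core_start - window)
    le0 = min(len(seq), core_start + inner_margin)
    rs0 = max(le0, core_end - inner_margin)
    re0 = min(len(seq), core_end + window)
    left = seq[ls0:le0]
    right = seq[rs0:re0]
    rrc = revcomp(right)
    cands = _best_ungapped_pair(left, rrc, min_tir, min_arm_id,
                                min_score=min_score)
    w = 8

    def _ragged(cs, ln):
        return (ln >= 3 and not all(cs[ln - 3:ln])) or not cs[ln - 1] \
            or (ln >= w and sum(cs[ln - w:ln]) < w - 1)

    chosen = None
    for _score, length, i, j, _m in cands[:10]:
        # edge-identity trim: the maximal-score run can creep into
        # unrelated flanking sequence on net-positive chance matches;
        # shrink each end until its terminal window is near-perfect,
        # then judge identity on the trimmed arm.
        cols = [left[i + t] == rrc[j + t] for t in range(length)]
        while length > min_tir and _ragged(cols, length):
            length -= 1
        while length > min_tir and _ragged(cols[:length][::-1], length):
            cols = cols[1:]
            i += 1
            j += 1
            length -= 1
        matches = sum(cols[:length])
        if length < min_tir or 100.0 * matches / length < min_arm_id:
            continue
        left_start = ls0 + i
        left_end = left_start + length
        right_end = re0 - j
        right_start = right_end - length
        if right_start < left_end:
            continue
        chosen = (length, matches, left_start, left_end, right_start, right_end, i, j)
        break
    if chosen is None:
        return None
    length, matches, left_start, left_end, right_start, right_end, i, j = chosen
    # TSD-aware trim: the TA duplication extends the inverted repeat, so
    # test small symmetric trims for a TA immediately outside both arms.
    trim = 0
    for t in range(0, min(max_tsd_trim, length - min_tir) + 1):
        lo, hi = left_start + t, right_end - t
        if seq[lo - len(tsd):lo] == tsd and seq[hi:hi + len(tsd)] == tsd:
            trim = t
            break
    if trim:
        left_start += trim
        right_end -= trim
        length -= trim
        arm = seq[left_start:left_start + length]
        arm_rc = revcomp(seq[right_end - length:right_end])
        matches = sum(1 for x, y in zip(arm, arm_rc) if x == y)
        left_end = left_start + length
        right_start = right_end - length
    return TIRPair(left_start, left_end, right_start, right_end, length,
                   100.0 * matches / length, seq[left_start:left_end])


def detect_tsd(locus_seq: str, tir: TIRPair, tsd: str = "TA") -> str:
    """'yes' iff the TSD 2-mer sits immediately outside both arms."""
    lo = tir.left_start
    hi = tir.right_end
    left_flank = locus_seq[max(0, lo - len(tsd)):lo].upper()
    right_flank = locus_seq[hi:hi + len(tsd)].upper()
    if len(left_flank) < len(tsd) or len(right_flank) < len(tsd) \
            or "N" in left_flank or "N" in right_flank:
        return "indeterminate"
    return "yes" if left_flank == tsd and right_flank == tsd else "no"


def tir_structure_props(arm: str, min_mirror: int = 8):
    """Palindrome and mirror-repeat structure of one TIR arm.

    A palindrome equals its own reverse complement; a mirror repeat is a
    maximal substring (>= ``min_mirror``) equal to its plain reversal.
    Returns ``(palindrome, mirrors)`` with mirrors as (start, end,
    substring) in 0-based arm coordinates.
    """
    if not arm:
        raise ValueError("empty arm sequence")
    arm = arm.upper()
    palindrome = arm == revcomp(arm)
    n = len(arm)
    found = []
    for center in range(2 * n - 1):
        if center % 2 == 0:
            l, r = center // 2 - 1, center // 2 + 1
        else:
            l, r = center // 2, center // 2 + 1
        while l >= 0 and r < n and arm[l] == arm[r]:
            l -= 1
            r += 1
        s, e = l + 1, r
        if e - s >= min_mirror:
            found.append((s, e))
    # keep only maximal intervals
    mirrors = []
    for s, e in sorted(set(found), key=lambda iv: (iv[0], -iv[1])):
        if any(s2 <= s and e <= e2 and (s2, e2) != (s, e) for s2, e2 in found):
            continue
        mirrors.append((s, e, arm[s:e]))
    return palindrome, mirrors
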