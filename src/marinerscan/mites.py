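"""MITE analysis: deletion breakpoints, microhomology typing, sublineages.

A MITE is a short copy flanked by two TIRs with evidence of transposition
(at least two copies).  Each MITE is aligned globally to a candidate
autonomous partner with deletion-tolerant gap costs; the single largest
internal gap on the MITE side is the main deletion, left-normalised so
that breakpoints are reported canonically.  Microhomologies are short
direct repeats with one copy in each breakpoint-edge window of the
partner: BPEE when both copies start exactly at the edges, BPNN when
both start within the near window, mixed classes (BPEN/BPNE) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner

from ._alignment import align_gap5


@dataclass
class DeletionBreakpoint:
    """Main internal deletion of a MITE relative to its partner."""

    partner_id: str
    del_start: int            # partner coordinates, 0-based half-open
    del_end: int
    junction: int             # MITE coordinate of the junction
    flank_identity: float     # % identity outside the deletion (gap5 columns)
    aux_deletions: list[tuple[int, int]]


@dataclass(frozen=True)
class MicrohomologyCall:
    micro_type: str           # BPEE | BPNN | BPEN | BPNE | none
    repeat: str
    length: int
    offsets: tuple[int, int]  # repeat-start distance from each deletion edge
    edge_shift: int           # breakpoint re-anchoring applied (equal offsets)


@dataclass
class MITESublineage:
    id: str
    members: list[str]
    partner: str              # partner element id or "orphan"
    del_start: int | None
    del_end: int | None
    is_mite: bool             # >= 2 members (evidence of transposition)


def _edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _deletion_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "global"
    aln.match_score = 2.0
    aln.mismatch_score = -2.0
    aln.open_gap_score = -12.0
    aln.extend_gap_score = -0.05
    return aln


def call_deletion_breakpoints(mite: str, partner: str, partner_id: str = "",
                              min_del: int = 50,
                              min_flank_id: float = 60.0) -> DeletionBreakpoint | None:
    """Locate the main internal deletion of a MITE against a partner.

    Global alignment with cheap gap extension lets the deleted region
    come out as one long gap; the largest partner-side gap >= ``min_del``
    is the main deletion, left-normalised (shifted maximally left over
    identical flanking bases) so repeat-induced placement ambiguity
    cannot move the reported edges.  Returns None if no such gap exists
    or the identity outside the deletion is below ``min_flank_id``.
    """
    if len(partner) <= len(mite):
        return None
    mite = mite.upper()
    partner = partner.upper()
    aln = _deletion_aligner().align(partner, mite)
    try:
        best = aln[0]
    except IndexError:
        return None
    tb, qb = best.aligned  # blocks: partner (target), mite (query)
    raw: list[tuple[int, int, int]] = []  # (p_start, p_end, mite_pos)
    for k in range(1, len(tb)):
        p_gap = int(tb[k][0]) - int(tb[k - 1][1])
        m_gap = int(qb[k][0]) - int(qb[k - 1][1])
        if p_gap >= 20 and m_gap <= 5:
            raw.append((int(tb[k - 1][1]), int(tb[k][0]), int(qb[k - 1][1])))
    # merge big gaps separated by short re-aligned islands: they are one
    # deletion that the aligner split on a chance match
    merged: list[tuple[int, int, int]] = []
    for g in raw:
        if merged and g[0] - merged[-1][1] <= 15:
            merged[-1] = (merged[-1][0], g[1], merged[-1][2])
        else:
            merged.append(g)
    gaps = [g for g in merged if g[1] - g[0] >= min_del]
    if not gaps:
        return None
    gaps.sort(key=lambda g: -(g[1] - g[0]))
    s, e, junction = gaps[0]
    # canonical left-normalisation
    while s > 0 and junction > 0 and partner[s - 1] == partner[e - 1]:
        s -= 1
        e -= 1
        junction -= 1
    # refine each edge independently against the junction context:
    # substitutions and indels next to the junction can push the
    # aligner's gap a few bases off and even change the apparent
    # deletion length, so re-anchor every edge at the shift whose
    # partner context is edit-closest to the MITE's flank (ties favour
    # no shift)
    c = 14
    left_ctx = mite[max(0, junction - c):junction]
    right_ctx = mite[junction:junction + c]

    def _edge_shift(ctx: str, take) -> int:
        if len(ctx) < c // 2:
            return 0
        costs = {}
        for d in range(-6, 7):
            ref = take(d)
            if ref is None:
                continue
            costs[d] = _edit_distance(ctx, ref)
        return min(costs, key=lambda d: (costs[d], abs(d), d)) if costs else 0

    s += _edge_shift(left_ctx,
                     lambda d: partner[s + d - len(left_ctx):s + d]
                     if s + d - len(left_ctx) >= 0 else None)
    e += _edge_shift(right_ctx,
                     lambda d: partner[e + d:e + d + len(right_ctx)]
                     if e + d + len(right_ctx) <= len(partner) and e + d > s else None)
    if e - s < min_del:
        return None
    # re-apply canonical left-normalisation after refinement
    while s > 0 and partner[s - 1] == partner[e - 1]:
        s -= 1
        e -= 1
        junction = max(junction - 1, 0)
    aux = [(a, b) for a, b, _ in gaps[1:]]
    # identity outside the main deletion: re-align flanks gap5-style
    left_id = align_gap5(partner[:s], mite[:junction]).identity \
        if s and junction else None
    right_id = align_gap5(partner[e:], mite[junction:]).identity \
        if e < len(partner) and junction < len(mite) else None
    parts = [x for x in (left_id, right_id) if x is not None]
    if not parts:
        return None
    flank_identity = sum(parts) / len(parts)
    if flank_identity < min_flank_id:
        return None
    return DeletionBreakpoint(partner_id, s, e, junction, flank_identity, aux)


def best_shared_repeat(w1: str, w2: str, near_window: int = 10,
                       min_micro: int = 3) -> tuple[int, int, int] | None:
    """Longest repeat with one copy starting within ``near_window`` of
    each window start; ties prefer smaller total offset.  Returns
    (length, offset1, offset2) or None."""
    best: tuple[int, int, int] | None = None
    for o1 in range(min(near_window, max(len(w1) - 1, 0)) + 1):
        for o2 in range(min(near_window, max(len(w2) - 1, 0)) + 1):
            l = 0
            while o1 + l < len(w1) and o2 + l < len(w2) and w1[o1 + l] == w2[o2 + l]:
                l += 1
            if l >= min_micro:
                cand = (l, o1, o2)
                if best is None or (-cand[0], cand[1] + cand[2], cand[1:]) < \
                        (-best[0], best[1] + best[2], best[1:]):
                    best = cand
    return best


def classify_microhomology(partner: str, bp: DeletionBreakpoint,
                           min_micro: int = 3, near_window: int = 10,
                           max_repeat: int = 12) -> MicrohomologyCall:
    """Type the direct-repeat microhomology at a deletion's breakpoints.

    Windows extend rightward from each deletion edge (the convention
    matching left-normalised deletions: one repeat copy starts the
    deleted region, its twin survives just after the junction).  The
    longest repeat with one copy starting within ``near_window`` of each
    edge wins; ties prefer smaller total offset.

    Equal non-zero offsets are re-anchored to BPEE: a repeat sitting the
    same distance inside both edges is exactly the signature of a
    breakpoint normalisation shift, not of a near-near repeat.
    """
    partner = partner.upper()
    win = near_window + max_repeat
    w1 = partner[bp.del_start:bp.del_start + win]
    w2 = partner[bp.del_end:bp.del_end + win]
    best = best_shared_repeat(w1, w2, near_window, min_micro)
    if best is None:
        return MicrohomologyCall("none", "", 0, (0, 0), 0)
    l, o1, o2 = best
    rep = w1[o1:o1 + l]
    if o1 == o2:
        return MicrohomologyCall("BPEE", rep, l, (0, 0), o1)
    t1 = "E" if o1 == 0 else "N"
    t2 = "E" if o2 == 0 else "N"
    return MicrohomologyCall(f"BP{t1}{t2}", rep, l, (o1, o2), 0)


def assign_mite_sublineages(mites: list[dict], tir_min_id: float = 90.0,
                            bp_tol: int = 10) -> list[MITESublineage]:
    """Group MITEs into sublineages by TIR identity and shared breakpoints.

    ``mites`` entries need keys ``id``, ``tir_seq`` (left arm), and
    optionally ``partner``, ``del_start``, ``del_end``.  Two MITEs share
    a sublineage when their TIR arms are >= ``tir_min_id`` % identical
    and their deletion intervals agree within ``bp_tol`` bp (orphans —
    no partner alignment — group by TIR alone).  Groups of one are
    reported but flagged as non-MITE (no evidence of transposition).
    Deterministic and invariant to input order (processing is sorted by
    id).
    """
    subs: list[dict] = []
    for rec in sorted(mites, key=lambda r: r["id"]):
        placed = False
        for sub in subs:
            if sub["partner"] != rec.get("partner", "orphan"):
                continue
            if rec.get("del_start") is not None and sub["del_start"] is not None:
                if abs(rec["del_start"] - sub["del_start"]) > bp_tol \
                        or abs(rec["del_end"] - sub["del_end"]) > bp_tol:
                    continue
            m = min(len(rec["tir_seq"]), len(sub["tir_seq"]))
            if m == 0:
                continue
            # arms are anchored at the element edge but trimmed to
            # slightly different maximal lengths; compare the shared span
            if align_gap5(rec["tir_seq"][:m], sub["tir_seq"][:m]).identity < tir_min_id:
                continue
            sub["members"].append(rec["id"])
            placed = True
            break
        if not placed:
            subs.append({
                "members": [rec["id"]], "tir_seq": rec["tir_seq"],
                "partner": rec.get("partner", "orphan"),
                "del_start": rec.get("del_start"), "del_end": rec.get("del_end"),
            })
    out = []
    for i, sub in enumerate(subs):
        out.append(MITESublineage(
            id=f"sub{i + 1}", members=sub["members"], partner=sub["partner"],
            del_start=sub["del_start"], del_end=sub["del_end"],
            is_mite=len(sub["members"]) >= 2,
        ))
    return out
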