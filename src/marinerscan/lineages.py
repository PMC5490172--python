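"""Lineage clustering and ascending hierarchical classification (UPGM-VM).

Two groupings are produced:

* greedy 75%-identity clustering into *lineages* (longest sequence
  founds a cluster; each copy joins the first cluster whose
  representative it matches at >= 75% gap-as-fifth-state identity);

* UPGM-VM, an ascending classification analogous to UPGMA but with no
  arithmetic mean: nodes are represented by the relative-majority
  consensus of their members' multiple alignment (gap counted as a fifth
  character state), and after every merge distances are recomputed by
  re-aligning consensuses — so the metric varies as the classification
  ascends.  This is what lets a full-length element gather its truncated
  and internally deleted derivatives (MITEs) into one group before
  unrelated elements join.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._alignment import align_gap5, nw_align

# IUPAC ambiguity codes for base-set ties in the relative-majority rule
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("AC"): "M", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class ConsensusProfile:
    """Per-column symbol counts over {A,C,G,T,-} and the derived consensus.

    ``kept`` marks columns retained in the consensus string (columns where
    the gap wins the relative majority are dropped from the string but
    stay in the profile).
    """

    counts: list[dict[str, int]]
    consensus: str
    kept: list[bool]


def consensus_relative_majority(rows: list[str]) -> ConsensusProfile:
    """Relative-majority consensus of pre-aligned rows.

    Per column the most frequent of {A,C,G,T,-} wins; ties among bases
    emit the IUPAC code of the tied set; a strict gap majority drops the
    column from the consensus string.  A base tied with the gap beats the
    gap (the column is kept).
    """
    if not rows:
        raise ValueError("no rows")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("rows are not aligned to equal length")
    counts: list[dict[str, int]] = []
    kept: list[bool] = []
    out: list[str] = []
    for col in range(L):
        c: dict[str, int] = {}
        for r in rows:
            ch = r[col].upper()
            c[ch] = c.get(ch, 0) + 1
        counts.append(c)
        base_counts = {b: n for b, n in c.items() if b != "-"}
        gap_n = c.get("-", 0)
        best = max(base_counts.values(), default=0)
        if gap_n > best:
            kept.append(False)
            continue
        kept.append(True)
        tied = frozenset(b for b, n in base_counts.items() if n == best)
        if tied <= frozenset("ACGT"):
            out.append(_IUPAC[tied])
        else:  # ambiguity codes / N among members: fall back to N
            out.append(sorted(tied)[0] if len(tied) == 1 else "N")
    return ConsensusProfile(counts, "".join(out), kept)


# ---------------------------------------------------------------------------
# greedy lineage clustering


@dataclass
class Lineage:
    id: str
    representative: str          # member id of the founder (longest member)
    members: list[str]
    rep_seq: str


def greedy_cluster(copies: list[tuple[str, str]], threshold: float = 75.0) -> list[Lineage]:
    """Greedy centroid clustering at >= ``threshold`` % gap5 identity.

    Copies are processed longest-first (ties by id); each joins the first
    existing lineage whose representative it matches, else founds a new
    lineage.  Deterministic.
    """
    if not copies:
        return []
    ordered = sorted(copies, key=lambda c: (-len(c[1]), c[0]))
    lineages: list[Lineage] = []
    for cid, seq in ordered:
        placed = False
        for lin in lineages:
            if align_gap5(seq, lin.rep_seq).identity >= threshold:
                lin.members.append(cid)
                placed = True
                break
        if not placed:
            lineages.append(Lineage(f"L{len(lineages) + 1}", cid, [cid], seq))
    return lineages


# ---------------------------------------------------------------------------
# UPGM-VM


@dataclass
class _Node:
    id: str                       # lexicographic id (min of member leaf ids)
    members: list[str]
    rows: list[str]               # MSA rows parallel to members
    consensus: str
    kept: list[bool]
    height: float = 0.0
    children: tuple["_Node", "_Node"] | None = None

    @classmethod
    def leaf(cls, name: str, seq: str) -> "_Node":
        return cls(name, [name], [seq.upper()], seq.upper(), [True] * len(seq))


def _attachments(kept: list[bool]) -> tuple[list[int], list[list[int]]]:
    """Retained-column indices and dropped columns attached to each.

    Dropped (gap-majority) columns are carried along with the preceding
    retained column; a leading run is attached before the first one
    (slot -1 -> index 0 of the leading list).
    """
    retained = [i for i, k in enumerate(kept) if k]
    attached: list[list[int]] = [[] for _ in range(len(retained) + 1)]
    slot = 0
    for i, k in enumerate(kept):
        if k:
            slot += 1
        else:
            attached[slot].append(i)
    return retained, attached


def merge_nodes(x: _Node, y: _Node) -> _Node:
    """Merge two nodes by aligning their consensuses and fusing the MSAs."""
    ca, cb, _score = nw_align(x.consensus, y.consensus)
    rx, ax = _attachments(x.kept)
    ry, ay = _attachments(y.kept)
    nx, ny = len(x.rows), len(y.rows)
    cols: list[tuple[int | None, int | None]] = []  # (x msa col, y msa col)
    for i in ax[0]:
        cols.append((i, None))
    for j in ay[0]:
        cols.append((None, j))
    ia = ib = 0
    for cha, chb in zip(ca, cb):
        if cha != "-" and chb != "-":
            cols.append((rx[ia], ry[ib]))
            for i in ax[ia + 1]:
                cols.append((i, None))
            for j in ay[ib + 1]:
                cols.append((None, j))
            ia += 1
            ib += 1
        elif cha != "-":
            cols.append((rx[ia], None))
            for i in ax[ia + 1]:
                cols.append((i, None))
            ia += 1
        else:
            cols.append((None, ry[ib]))
            for j in ay[ib + 1]:
                cols.append((None, j))
            ib += 1
    rows = []
    for r in x.rows:
        rows.append("".join(r[cx] if cx is not None else "-" for cx, _ in cols))
    for r in y.rows:
        rows.append("".join(r[cy] if cy is not None else "-" for _, cy in cols))
    prof = consensus_relative_majority(rows)
    a, b = (x, y) if x.id <= y.id else (y, x)
    return _Node(a.id, x.members + y.members, rows, prof.consensus, prof.kept,
                 children=(a, b))


@dataclass
class Dendrogram:
    """Binary merge tree with per-merge heights (1 - identity/100)."""

    root: _Node
    merges: list[tuple[frozenset, frozenset, float]]  # member sets + height

    def newick(self) -> str:
        def rec(node: _Node, parent_h: float) -> str:
            bl = max(parent_h - node.height, 0.0)
            if node.children is None:
                return f"{node.members[0]}:{bl:.6f}"
            a, b = node.children
            return f"({rec(a, node.height)},{rec(b, node.height)}):{bl:.6f}"
        return rec(self.root, self.root.height) + ";"

    def merge_order(self) -> list[tuple[frozenset, frozenset]]:
        return [(a, b) for a, b, _h in self.merges]


def upgm_vm_classify(sequences: list[tuple[str, str]]) -> Dendrogram:
    """Ascending hierarchical classification with a varying metric.

    Iteratively merges the pair of current nodes with the highest
    gap-as-fifth-state identity between their consensuses; the merged
    node is represented by the relative-majority consensus of the fused
    multiple alignment, and all distances involving it are recomputed.
    Ties break toward the lexicographically smallest (id, id) pair.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    nodes = [_Node.leaf(name, seq) for name, seq in sequences]
    if len({n.id for n in nodes}) != len(nodes):
        raise ValueError("duplicate sequence ids")
    ident: dict[tuple[str, str], float] = {}

    def pair_key(a: _Node, b: _Node) -> tuple[str, str]:
        return (a.id, b.id) if a.id <= b.id else (b.id, a.id)

    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            ident[pair_key(a, b)] = align_gap5(a.consensus, b.consensus).identity
    merges = []
    while len(nodes) > 1:
        best = None
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                key = pair_key(a, b)
                cand = (-ident[key], key)
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        _, a, b = best
        h = 1.0 - ident[pair_key(a, b)] / 100.0
        merged = merge_nodes(a, b)
        merged.height = h
        merges.append((frozenset(a.members), frozenset(b.members), h))
        nodes = [n for n in nodes if n is not a and n is not b]
        for n in nodes:
            ident[pair_key(n, merged)] = align_gap5(n.consensus, merged.consensus).identity
        nodes.append(merged)
    return Dendrogram(nodes[0], merges)


def progressive_msa(sequences: list[tuple[str, str]]) -> _Node:
    """Progressive multiple alignment in input order (star-like growth).

    Used where a node consensus is needed for a known group, e.g. a MITE
    sublineage, without re-running the full classification.
    """
    if not sequences:
        raise ValueError("no sequences")
    node = _Node.leaf(*sequences[0])
    for name, seq in sequences[1:]:
        node = merge_nodes(node, _Node.leaf(name, seq))
    return node
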