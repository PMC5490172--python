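"""Independent brute-force oracle for the ascending classification.

Reimplements, from the written definitions only, the gap-as-fifth-state
global alignment (plain-python DP, same scoring and tie-breaks), the
relative-majority consensus and the consensus-merge bookkeeping, then
agglomerates greedily.  Used to check that the package's implementation
produces the same merge order on small inputs.
"""

from __future__ import annotations

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def align(a: str, b: str, match=1, mismatch=-1, gap=-2):
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        H[i][0] = gap * i
    for j in range(m + 1):
        H[0][j] = gap * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + gap,
                          H[i][j - 1] + gap)
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        h = H[i][j]
        s = match if i > 0 and j > 0 and a[i - 1] == b[j - 1] else mismatch
        if i > 0 and j > 0 and h == H[i - 1][j - 1] + s:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i -= 1
            j -= 1
        elif j > 0 and h == H[i][j - 1] + gap:
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
        else:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


def identity(a: str, b: str) -> float:
    first, second = (b, a) if b < a else (a, b)
    ra, rb = align(first, second)
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return 100.0 * matches / len(ra)


def consensus(rows):
    out, kept = [], []
    for col in range(len(rows[0])):
        c = {}
        for r in rows:
            c[r[col]] = c.get(r[col], 0) + 1
        bases = {k: v for k, v in c.items() if k != "-"}
        top = max(bases.values(), default=0)
        if c.get("-", 0) > top:
            kept.append(False)
            continue
        kept.append(True)
        tied = frozenset(k for k, v in bases.items() if v == top)
        out.append(IUPAC[tied] if tied <= frozenset("ACGT")
                   else (sorted(tied)[0] if len(tied) == 1 else "N"))
    return "".join(out), kept


class Node:
    def __init__(self, name, seq):
        self.id = name
        self.members = [name]
        self.rows = [seq]
        self.cons, self.kept = seq, [True] * len(seq)


def merge(x: Node, y: Node) -> Node:
    ca, cb = align(x.cons, y.cons)
    rx = [i for i, k in enumerate(x.kept) if k]
    ry = [i for i, k in enumerate(y.kept) if k]

    def attachments(kept, retained):
        att = [[] for _ in range(len(retained) + 1)]
        slot = 0
        for i, k in enumerate(kept):
            if k:
                slot += 1
            else:
                att[slot].append(i)
        return att

    ax, ay = attachments(x.kept, rx), attachments(y.kept, ry)
    cols = [(i, None) for i in ax[0]] + [(None, j) for j in ay[0]]
    ia = ib = 0
    for cha, chb in zip(ca, cb):
        if cha != "-" and chb != "-":
            cols.append((rx[ia], ry[ib]))
            cols += [(i, None) for i in ax[ia + 1]]
            cols += [(None, j) for j in ay[ib + 1]]
            ia += 1
            ib += 1
        elif cha != "-":
            cols.append((rx[ia], None))
            cols += [(i, None) for i in ax[ia + 1]]
            ia += 1
        else:
            cols.append((None, ry[ib]))
            cols += [(None, j) for j in ay[ib + 1]]
            ib += 1
    rows = [
        "".join(r[cx] if cx is not None else "-" for cx, _ in cols)
        for r in x.rows
    ] + [
        "".join(r[cy] if cy is not None else "-" for _, cy in cols)
        for r in y.rows
    ]
    a = x if x.id <= y.id else y
    out = Node.__new__(Node)
    out.id = a.id
    out.members = x.members + y.members
    out.rows = rows
    out.cons, out.kept = consensus(rows)
    return out


def merge_order(sequences):
    """List of (frozenset, frozenset) member-set pairs, in merge order."""
    nodes = [Node(n, s) for n, s in sequences]
    ident = {}

    def key(a, b):
        return (a.id, b.id) if a.id <= b.id else (b.id, a.id)

    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            ident[key(a, b)] = identity(a.cons, b.cons)
    order = []
    while len(nodes) > 1:
        best = None
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                cand = (-ident[key(a, b)], key(a, b))
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        _, a, b = best
        order.append((frozenset(a.members), frozenset(b.members)))
        merged = merge(a, b)
        nodes = [n for n in nodes if n is not a and n is not b]
        for n in nodes:
            ident[key(n, merged)] = identity(n.cons, merged.cons)
        nodes.append(merged)
    return order
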