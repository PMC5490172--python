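"""Translated homology search and candidate-locus extraction.

Candidate mariner-like loci are found by searching a transposase protein
panel against all six reading frames of the genome (k-mer seeding +
local Smith-Waterman extension under BLOSUM62), merging nearby hits into
loci, extracting each locus with flanking sequence, and applying the
survey filtering rules: minimum element length 250 bp, removal of
truncated copies at scaffold ends, and exclusion of candidates scoring
closer to a DDxE (Tc1-like) reference panel than to the DDxD panels.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from ._alignment import revcomp
from .references import RefTransposase, ddxd_panel, ddxe_panel

FRAMES = (1, 2, 3, -1, -2, -3)


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate all six frames (standard code, '*' for stops, X for ambiguity).

    Frames +1..+3 read the forward strand with offsets 0..2; -1..-3 read
    the reverse complement likewise.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    fwd = seq.upper()
    rev = revcomp(fwd)
    out: dict[int, str] = {}
    for f in range(3):
        for strand, s in ((1, fwd), (-1, rev)):
            sub = s[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            out[(f + 1) * strand] = str(Seq(sub).translate())
    return out


@dataclass(frozen=True)
class TranslatedHit:
    """One translated local alignment mapped back to genome coordinates."""

    scaffold: str
    start: int          # genomic, 0-based half-open
    end: int
    frame: int          # +1..+3 forward, -1..-3 reverse
    query: str
    score: float
    pct_id: float
    aln_len: int        # aligned residues (alignment columns)


@dataclass
class SearchParams:
    k: int = 4
    min_id: float = 35.0
    min_len: int = 80
    gap_open: float = -11.0
    gap_extend: float = -1.0
    diag_band: int = 16          # seeds within this diagonal distance group together
    min_seeds: int = 2           # two-hit rule before extension
    min_ungapped: float = 30.0   # x-drop ungapped extension score gate
    xdrop: float = 12.0


def _protein_aligner(params: SearchParams) -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.mode = "local"
    aln.open_gap_score = params.gap_open
    aln.extend_gap_score = params.gap_extend
    return aln


def _sanitize(aa: str) -> str:
    """Restrict to BLOSUM62 alphabet (stops/amb. to X)."""
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in allowed else "X" for c in aa)


def _aa_to_genomic(frame: int, aa_start: int, aa_end: int, seq_len: int) -> tuple[int, int]:
    f = abs(frame) - 1
    lo, hi = f + 3 * aa_start, f + 3 * aa_end
    if frame > 0:
        return lo, hi
    return seq_len - hi, seq_len - lo


def _blosum_dict() -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    letters = mat.alphabet
    return {(a, b): float(mat[a, b]) for a in letters for b in letters}


_BLOSUM: dict[tuple[str, str], float] | None = None


def _ungapped_score(qseq: str, taa: str, qpos: int, tpos: int, k: int,
                    xdrop: float) -> float:
    """X-drop ungapped extension of one seed along its diagonal."""
    global _BLOSUM
    if _BLOSUM is None:
        _BLOSUM = _blosum_dict()
    B = _BLOSUM
    score = sum(B.get((qseq[qpos + i], taa[tpos + i]), -4.0) for i in range(k))
    best = score
    # rightward
    i, j = qpos + k, tpos + k
    cur = best
    while i < len(qseq) and j < len(taa):
        cur += B.get((qseq[i], taa[j]), -4.0)
        if cur > best:
            best = cur
        if best - cur > xdrop:
            break
        i += 1
        j += 1
    # leftward
    i, j = qpos - 1, tpos - 1
    cur = best
    peak = best
    while i >= 0 and j >= 0:
        cur += B.get((qseq[i], taa[j]), -4.0)
        if cur > peak:
            peak = cur
        if peak - cur > xdrop:
            break
        i -= 1
        j -= 1
    return peak if peak > best else best


def translated_search(genome: dict[str, str], panel: dict[str, str],
                      params: SearchParams | None = None) -> list[TranslatedHit]:
    """Seed-and-extend search of a protein panel against six-frame translations.

    Exact ``k``-mer seeds are grouped by diagonal band; groups passing a
    two-hit rule and an x-drop ungapped extension gate are refined by
    local alignment under BLOSUM62 (gap open/extend -11/-1).  Hits are
    reported when percent identity over the local alignment is at least
    ``min_id`` across at least ``min_len`` aligned columns.
    Deterministic: scaffolds, frames and queries are processed in sorted
    order and each seed group yields at most one best alignment.
    """
    if not panel:
        raise ValueError("empty query panel")
    params = params or SearchParams()
    aligner = _protein_aligner(params)
    k = params.k
    index: dict[str, list[tuple[str, int]]] = {}
    for qname in sorted(panel):
        qseq = panel[qname]
        for i in range(len(qseq) - k + 1):
            index.setdefault(qseq[i:i + k], []).append((qname, i))
    hits: list[TranslatedHit] = []
    for scaffold in sorted(genome):
        seq = genome[scaffold].upper()
        if len(seq) < 3:
            continue
        frames = six_frame_translate(seq)
        for frame in FRAMES:
            aa = _sanitize(frames[frame])
            seeds: dict[str, list[tuple[int, int]]] = {}  # qname -> [(diag, tpos)]
            for p in range(len(aa) - k + 1):
                for qname, qpos in index.get(aa[p:p + k], ()):
                    seeds.setdefault(qname, []).append((p - qpos, p))
            for qname in sorted(seeds):
                qseq = panel[qname]
                qlen = len(qseq)
                # chain seeds whose diagonals lie within the band
                groups: list[list[tuple[int, int]]] = []
                for d, p in sorted(seeds[qname]):
                    if groups and d - groups[-1][-1][0] <= params.diag_band:
                        groups[-1].append((d, p))
                    else:
                        groups.append([(d, p)])
                for grp in groups:
                    if len(grp) < params.min_seeds:
                        continue
                    d_mid, p_mid = grp[len(grp) // 2]
                    if _ungapped_score(qseq, aa, p_mid - d_mid, p_mid, k,
                                       params.xdrop) < params.min_ungapped:
                        continue
                    lo = max(0, min(p - (p - d) for d, p in grp) - 30)
                    hi = min(len(aa), max(p + (qlen - (p - d)) for d, p in grp) + 30)
                    window = aa[lo:hi]
                    alns = aligner.align(qseq, window)
                    try:
                        best = alns[0]
                    except IndexError:
                        continue
                    cols = matches = 0
                    for x, y in zip(best[0], best[1]):
                        cols += 1
                        if x == y and x != "-":
                            matches += 1
                    pct = 100.0 * matches / cols if cols else 0.0
                    if cols < params.min_len or pct < params.min_id:
                        continue
                    t0 = int(best.aligned[1][0][0]) + lo
                    t1 = int(best.aligned[1][-1][1]) + lo
                    g0, g1 = _aa_to_genomic(frame, t0, t1, len(seq))
                    hits.append(TranslatedHit(scaffold, g0, g1, frame, qname,
                                              float(best.score), round(pct, 2), cols))
    hits.sort(key=lambda h: (h.scaffold, h.start, h.end, h.frame, h.query))
    return hits


# ---------------------------------------------------------------------------
# loci


@dataclass
class CandidateLocus:
    """Merged hit region extracted with flanking sequence."""

    scaffold: str
    core_start: int
    core_end: int
    ext_start: int
    ext_end: int
    best_query: str
    best_score: float
    at_scaffold_end: bool = False
    has_N_run: bool = False
    source: str = "translated"   # translated | nucleotide
    strand: str = "+"            # orientation hint from the hits

    @property
    def locus_id(self) -> str:
        return f"{self.scaffold}:{self.core_start}-{self.core_end}"


def build_candidate_loci(hits: list[TranslatedHit], scaffold_lengths: dict[str, int],
                         flank: int = 5000, merge_gap: int = 1000,
                         genome: dict[str, str] | None = None) -> list[CandidateLocus]:
    """Merge hits <= ``merge_gap`` apart into loci and extend by ``flank``.

    The extraction interval is clipped to the scaffold; clipping raises
    the ``at_scaffold_end`` flag.  An N run (>= 10) inside the extraction
    interval raises ``has_N_run``.
    """
    by_scaffold: dict[str, list[TranslatedHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold, []).append(h)
    loci: list[CandidateLocus] = []
    for scaffold in sorted(by_scaffold):
        hs = sorted(by_scaffold[scaffold], key=lambda h: (h.start, h.end))
        group = [hs[0]]
        for h in hs[1:]:
            if h.start - max(g.end for g in group) <= merge_gap:
                group.append(h)
            else:
                loci.append(_make_locus(scaffold, group, scaffold_lengths, flank, genome))
                group = [h]
        loci.append(_make_locus(scaffold, group, scaffold_lengths, flank, genome))
    return loci


def _make_locus(scaffold, group, scaffold_lengths, flank, genome) -> CandidateLocus:
    cs = min(h.start for h in group)
    ce = max(h.end for h in group)
    L = scaffold_lengths[scaffold]
    es, ee = cs - flank, ce + flank
    clipped = es < 0 or ee > L
    es, ee = max(0, es), min(L, ee)
    best = max(group, key=lambda h: h.score)
    has_n = False
    if genome is not None:
        has_n = "N" * 10 in genome[scaffold][es:ee]
    return CandidateLocus(scaffold, cs, ce, es, ee, best.query, best.score,
                          at_scaffold_end=clipped, has_N_run=has_n,
                          strand="+" if best.frame > 0 else "-")


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterDecision:
    retained: bool
    reason: str = ""


def _best_panel_score(aa: str, panel: list[RefTransposase],
                      aligner: PairwiseAligner) -> float:
    best = float("-inf")
    for ref in panel:
        alns = aligner.align(_sanitize(aa), ref.aa)
        try:
            best = max(best, float(alns.score))
        except (IndexError, ValueError):
            pass
    return best


def filter_candidates(records, min_len: int = 250,
                      ddxd: list[RefTransposase] | None = None,
                      ddxe: list[RefTransposase] | None = None,
                      ddxe_margin: float = 20.0):
    """Apply the survey retention rules to annotated candidate records.

    ``records`` need attributes ``element_length``, ``n_tirs``,
    ``at_scaffold_end`` and optionally ``orf_aa`` (protein used for the
    DDxD-vs-DDxE score comparison).  Elements shorter than 250 bp are
    discarded (strict less-than), truncated copies at scaffold ends are
    discarded, and candidates whose protein scores higher against the
    DDxE reference panel than against the DDxD panel are excluded.
    ``ddxe_margin`` demands a clear score difference before exclusion,
    so that copies whose only protein evidence is a degraded fragment
    (where both panels score at noise level) are not discarded on a
    coin-flip.

    Returns ``(retained, decisions)`` where decisions maps record id ->
    :class:`FilterDecision`.
    """
    ddxd = ddxd if ddxd is not None else ddxd_panel()
    ddxe = ddxe if ddxe is not None else ddxe_panel()
    aligner = _protein_aligner(SearchParams())
    retained = []
    decisions: dict[str, FilterDecision] = {}
    for rec in records:
        rid = rec.record_id
        if rec.element_length < min_len:
            decisions[rid] = FilterDecision(False, "min_length")
            continue
        if rec.n_tirs <= 1 and rec.at_scaffold_end:
            decisions[rid] = FilterDecision(False, "scaffold_end_truncated")
            continue
        aa = getattr(rec, "orf_aa", None)
        if aa:
            if _best_panel_score(aa, ddxe, aligner) > \
                    _best_panel_score(aa, ddxd, aligner) + ddxe_margin:
                decisions[rid] = FilterDecision(False, "DDxE")
                continue
        decisions[rid] = FilterDecision(True)
        retained.append(rec)
    return retained, decisions
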