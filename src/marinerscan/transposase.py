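"""Transposase ORF annotation: catalytic triad, domains, completeness.

The catalytic-triad family label of a Tc1/mariner transposase (DD34D,
DD37D, DD40D, DD41D, DD34E, ...) is derived by projecting the annotated
triad columns of the best-matching reference transposase onto the query
through a global protein alignment; the label records the number of
residues strictly between the 2nd and 3rd catalytic positions and the
identity (D/E) of the 3rd.  Domain annotation uses transparent
heuristics: fuzzy scans for the WVPHEL / YSPDLA motifs (<= 2 of 6
mismatches), a helix-turn-helix window score, a basic-residue NLS scan,
and an AATAAA polyadenylation-site scan in the UTRs.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from ._alignment import revcomp
from .references import RefTransposase, default_reference_panel

STOP = "*"
_HYDROPHOBIC = set("AVLIMFWY")
_BASIC = set("KR")


# ---------------------------------------------------------------------------
# ORF finding


@dataclass
class ORFRecord:
    """Best transposase reading frame within the inter-TIR region.

    ``aa`` may contain stop symbols when the only qualifying reading is
    interrupted (``has_internal_stop``); ``coverage`` is the fraction of
    the inter-TIR region spanned by the record.
    """

    start: int            # element-internal nt coordinates, 0-based half-open
    end: int
    strand: str
    aa: str
    has_internal_stop: bool
    frameshift_evidence: bool
    coverage: float


def _frame_translations(seq: str):
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for f in range(3):
            sub = s[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                yield strand, f, str(Seq(sub).translate())


def _nt_interval(strand: str, frame: int, aa_start: int, aa_end: int, L: int):
    lo, hi = frame + 3 * aa_start, frame + 3 * aa_end
    return (lo, hi) if strand == "+" else (L - hi, L - lo)


def _panel_score(aa: str, panel: list[RefTransposase]) -> float:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    best = 0.0
    q = _clean_aa(aa)
    for ref in panel:
        alns = aligner.align(q, ref.aa)
        try:
            best = max(best, float(alns.score))
        except (IndexError, ValueError):
            pass
    return best


def find_orf(internal_seq: str, min_orf_aa: int = 200,
             cover_frac: float = 0.6,
             panel: list[RefTransposase] | None = None) -> ORFRecord | None:
    """Longest transposase reading within the inter-TIR region.

    Preference order: (1) a proper ORF (M..stop, no internal stops)
    spanning >= ``cover_frac`` of the region; (2) an interrupted reading
    from the first start codon across the region (internal stops
    recorded — the mark of a dead copy); (3) two compatible stop-free
    stretches in different frames (frameshift evidence); (4) a proper
    ORF >= ``min_orf_aa`` even if short.  Returns None when nothing
    reaches ``min_orf_aa``.

    When a reference ``panel`` is given, competing candidate readings
    are ranked by their best local alignment score against it
    (homology-guided ORF selection) instead of by raw length; this
    resolves ties against spurious stop-free readings that arise on the
    opposite strand of strongly codon-biased coding sequence.
    """
    L = len(internal_seq)
    if L < 3 * min_orf_aa:
        return None
    proper: list[tuple[int, str, int, int, str]] = []   # (len, strand, s, e, aa)
    interrupted: list[tuple[float, str, int, int, str]] = []
    stretches: dict[str, list[tuple[int, int, int]]] = {"+": [], "-": []}
    for strand, f, aa in _frame_translations(internal_seq):
        # proper ORFs
        i = 0
        while i < len(aa):
            if aa[i] == "M":
                j = aa.find(STOP, i)
                end = j if j != -1 else len(aa)
                if end - i >= min_orf_aa:
                    s, e = _nt_interval(strand, f, i, end, L)
                    proper.append((end - i, strand, s, e, aa[i:end]))
                i = end + 1 if j != -1 else len(aa)
            else:
                i += 1
        # interrupted reading from the first start codon
        m = aa.find("M")
        if m != -1 and len(aa) - m >= min_orf_aa:
            s, e = _nt_interval(strand, f, m, len(aa), L)
            cov = (e - s) / L
            if cov >= cover_frac:
                interrupted.append((cov, strand, s, e, aa[m:]))
        # stop-free stretches for frameshift detection
        prev = 0
        for part in aa.split(STOP):
            if len(part) >= 60:
                s, e = _nt_interval(strand, f, prev, prev + len(part), L)
                stretches[strand].append((s, e, len(part)))
            prev += len(part) + 1
    def rank(candidates, key):
        if panel is not None and len(candidates) > 1:
            return max(candidates, key=lambda c: _panel_score(c[4], panel))
        return max(candidates, key=key)

    if proper:
        spanning = [p for p in proper if (p[3] - p[2]) / L >= cover_frac]
        if spanning:
            ln, strand, s, e, aa = rank(spanning, key=lambda p: p[0])
            return ORFRecord(s, e, strand, aa, False, False, (e - s) / L)
    if interrupted:
        cov, strand, s, e, aa = rank(interrupted, key=lambda c: c[0])
        core = aa[:-1] if aa.endswith(STOP) else aa
        return ORFRecord(s, e, strand, core, STOP in core, False, cov)
    # frameshift: two non-overlapping stretches on one strand covering the region
    for strand in "+-":
        ivs = sorted(stretches[strand])
        for a in ivs:
            for b in ivs:
                if a is b or b[0] < a[1] - 30:
                    continue
                cov = ((a[1] - a[0]) + (b[1] - b[0])) / L
                if cov >= cover_frac and (a[1] - a[0] + b[1] - b[0]) // 3 >= min_orf_aa:
                    return ORFRecord(a[0], b[1], strand, "", False, True, cov)
    if proper:
        ln, strand, s, e, aa = rank(proper, key=lambda p: p[0])
        return ORFRecord(s, e, strand, aa, False, False, (e - s) / L)
    return None


# ---------------------------------------------------------------------------
# catalytic triad


@dataclass(frozen=True)
class TriadCall:
    positions: tuple[int, int, int]   # 0-based in the query protein
    residues: tuple[str, str, str]
    spacing12: int                    # residues strictly between 1st and 2nd
    spacing23: int                    # residues strictly between 2nd and 3rd
    label: str                        # e.g. "DD34D"
    reference: str


def _triad_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.mode = "global"
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    try:
        aln.end_insertion_score = 0.0
        aln.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aln.target_end_gap_score = 0.0
        aln.query_end_gap_score = 0.0
    return aln


def _clean_aa(aa: str) -> str:
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX")
    return "".join(c if c in allowed else "X" for c in aa)


def map_catalytic_triad(orf_aa: str,
                        panel: list[RefTransposase] | None = None) -> TriadCall | None:
    """Project reference triad columns onto a query transposase.

    The query is globally aligned (free end gaps) to every reference;
    the best-scoring reference lends its annotated triad columns.  If a
    projected column lands in a gap, or either of the first two
    projected residues is not D, the triad is unresolved (None).
    """
    if not orf_aa:
        return None
    panel = panel if panel is not None else default_reference_panel()
    if not panel:
        raise ValueError("empty reference panel")
    aligner = _triad_aligner()
    query = _clean_aa(orf_aa)
    best = None
    for ref in sorted(panel, key=lambda r: r.id):
        alns = aligner.align(ref.aa, query)
        try:
            if best is None or alns.score > best[0]:
                best = (float(alns.score), ref, alns[0])
        except IndexError:
            pass
    if best is None:
        return None
    _score, ref, aln = best
    # map reference positions to query positions through aligned blocks
    tblocks, qblocks = aln.aligned
    pos_map: dict[int, int] = {}
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for k in range(te - ts):
            pos_map[ts + k] = qs + k
    proj = []
    for rp in ref.triad_positions:
        qp = pos_map.get(int(rp))
        if qp is None:
            return None
        proj.append(int(qp))
    p1, p2, p3 = proj
    r = (orf_aa[p1], orf_aa[p2], orf_aa[p3])
    if r[0] != "D" or r[1] != "D" or r[2] not in "DE":
        return None
    return TriadCall((p1, p2, p3), r, p2 - p1 - 1, p3 - p2 - 1,
                     f"DD{p3 - p2 - 1}{r[2]}", ref.id)


# ---------------------------------------------------------------------------
# domains


@dataclass
class MotifHit:
    position: int      # 1-based within the ORF
    mismatches: int
    sequence: str


@dataclass
class DomainAnnotation:
    wvphel: MotifHit | None
    yspdla: MotifHit | None
    hth: tuple[int, int] | None   # 1-based inclusive interval in the ORF
    nls_present: bool
    polya_sites: list[int]        # 1-based positions in the concatenated UTRs


def fuzzy_find(motif: str, seq: str, max_mismatch: int = 2) -> MotifHit | None:
    best: MotifHit | None = None
    for i in range(len(seq) - len(motif) + 1):
        mm = sum(1 for a, b in zip(motif, seq[i:i + len(motif)]) if a != b)
        if mm <= max_mismatch and (best is None or mm < best.mismatches):
            best = MotifHit(i + 1, mm, seq[i:i + len(motif)])
    return best


_HTH_LEN = 22
_HTH_KEYS = (2, 8, 13, 17)   # hydrophobic key positions (0-based in window)
_HTH_GLY = 7                 # turn glycine


def hth_score(window: str) -> float:
    if len(window) != _HTH_LEN or window[_HTH_GLY] != "G":
        return 0.0
    score = 3.0
    score += sum(2.0 for k in _HTH_KEYS if window[k] in _HYDROPHOBIC)
    score += 0.5 * min(sum(1 for c in window if c in _BASIC), 4)
    return score


def find_hth(orf_aa: str, threshold: float = 8.0) -> tuple[int, int] | None:
    """Best helix-turn-helix window (hydrophobic helix faces around a turn)."""
    best = (0.0, None)
    for i in range(len(orf_aa) - _HTH_LEN + 1):
        s = hth_score(orf_aa[i:i + _HTH_LEN])
        if s > best[0]:
            best = (s, (i + 1, i + _HTH_LEN))
    return best[1] if best[0] >= threshold else None


def find_nls(orf_aa: str) -> bool:
    """Classic monopartite (>= 4 basics in a 6-mer) or bipartite pattern."""
    for i in range(len(orf_aa) - 5):
        if sum(1 for c in orf_aa[i:i + 6] if c in _BASIC) >= 4:
            return True
    for i in range(len(orf_aa) - 17):
        if all(c in _BASIC for c in orf_aa[i:i + 2]) \
                and sum(1 for c in orf_aa[i + 12:i + 17] if c in _BASIC) >= 3:
            return True
    return False


def annotate_domains(orf_aa: str, utr5: str = "", utr3: str = "") -> DomainAnnotation:
    if not orf_aa:
        raise ValueError("empty ORF")
    utrs = (utr5 + utr3).upper()
    polya = []
    start = 0
    while True:
        k = utrs.find("AATAAA", start)
        if k == -1:
            break
        polya.append(k + 1)
        start = k + 1
    return DomainAnnotation(
        wvphel=fuzzy_find("WVPHEL", orf_aa),
        yspdla=fuzzy_find("YSPDLA", orf_aa),
        hth=find_hth(orf_aa),
        nls_present=find_nls(orf_aa),
        polya_sites=polya,
    )


# ---------------------------------------------------------------------------
# completeness


@dataclass(frozen=True)
class CompletenessCall:
    cls: str                  # complete | deleted | truncated | dead
    potentially_active: bool


def classify_completeness(n_tirs: int, element_len: int,
                          lineage_complete_len: int | None,
                          orf: ORFRecord | None,
                          triad: TriadCall | None,
                          hth_present: bool) -> CompletenessCall:
    """Completeness class of one copy.

    complete: two TIRs and an intact ORF spanning the transposase
    region; dead: full-length but the reading is interrupted by stops or
    a frameshift; deleted: two TIRs, markedly shorter than the lineage's
    complete length, no qualifying ORF; truncated: at most one TIR.
    ``potentially_active`` additionally requires a resolved triad and an
    HTH domain.
    """
    if n_tirs <= 1:
        return CompletenessCall("truncated", False)
    full_length = lineage_complete_len is None \
        or element_len >= lineage_complete_len - 100
    orf_ok = orf is not None and not orf.has_internal_stop \
        and not orf.frameshift_evidence and orf.coverage >= 0.6
    if orf_ok and full_length:
        # an ORF spanning a markedly shortened element is only a residual
        # fragment of the lineage's transposase, so full length is required
        active = triad is not None and hth_present
        return CompletenessCall("complete", active)
    if full_length and lineage_complete_len is not None:
        return CompletenessCall("dead", False)
    if lineage_complete_len is None and orf is not None:
        # no complete partner known: an interrupted full-span reading
        # still marks a dead rather than a deleted copy
        return CompletenessCall("dead", False)
    return CompletenessCall("deleted", False)
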