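"""Consensus-divergence dating, cross-genome screening and HT flagging.

Sublineage age is read from the identity of each copy to the sublineage
consensus: copies still nearly identical to their consensus (>= 97%)
amplified recently and may still be trans-mobilizable; identities of
85-95% mark ancient amplification; below 85% only relics remain.  A
cross-genome screen retains nucleotide hits with > 60% identity over
> 65% of the query, and flags potential horizontal transfer between
species when identity and query coverage both exceed 90%.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner

from ._alignment import align_gap5, revcomp
from .lineages import progressive_msa

AGE_BINS = ((97.0, "recent"), (95.0, "intermediate"), (85.0, "ancient"))


def age_class_of(identity: float) -> str:
    """Deterministic, total, half-open binning of identity into age classes."""
    for edge, label in AGE_BINS:
        if identity >= edge:
            return label
    return "relic"


@dataclass
class AgeEstimate:
    sublineage: str
    identities: dict[str, float]   # per-copy % identity to the consensus
    mean_identity: float
    age_class: str


def identity_to_consensus(sublineage_id: str,
                          members: list[tuple[str, str]]) -> AgeEstimate:
    """Date a sublineage from copy-to-consensus identities.

    The consensus is the relative-majority consensus of a progressive
    multiple alignment of the members (gap as fifth state); each copy is
    then re-aligned to it and the age class derives from the mean
    identity.
    """
    if len(members) < 2:
        raise ValueError("a sublineage needs at least two members")
    node = progressive_msa(members)
    cons = node.consensus
    idents = {name: align_gap5(seq, cons).identity for name, seq in members}
    mean = sum(idents.values()) / len(idents)
    return AgeEstimate(sublineage_id, idents, mean, age_class_of(mean))


# ---------------------------------------------------------------------------
# cross-genome screen


@dataclass
class CrossGenomeHit:
    query: str
    subject: str
    s_start: int
    s_end: int
    strand: str
    identity: float        # % identical columns over the local alignment
    coverage: float        # % of the query length covered by the alignment


def _nt_local_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.match_score = 1.0
    aln.mismatch_score = -1.0
    aln.open_gap_score = -2.0
    aln.extend_gap_score = -0.5
    return aln


def nucleotide_search(query: str, subject: str, k: int = 12,
                      max_hits: int = 200) -> list[tuple[int, int, str, float, float]]:
    """Seeded local search of one query against one subject sequence.

    Returns (s_start, s_end, strand, identity%, coverage%) tuples for
    non-overlapping candidate regions on both strands.  Seeds are exact
    k-mers; each seed cluster is refined by local alignment.
    """
    query = query.upper()
    out = []
    qkmers: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        qkmers.setdefault(query[i:i + k], []).append(i)
    for strand in "+-":
        subj = subject.upper() if strand == "+" else revcomp(subject).upper()
        pos: list[int] = []
        for j in range(len(subj) - k + 1):
            if subj[j:j + k] in qkmers:
                pos.append(j)
        if not pos:
            continue
        clusters: list[list[int]] = [[pos[0]]]
        for p in pos[1:]:
            if p - clusters[-1][-1] <= len(query):
                clusters[-1].append(p)
            else:
                clusters.append([p])
        aligner = _nt_local_aligner()
        for cl in clusters[:max_hits]:
            w0 = max(0, cl[0] - len(query))
            w1 = min(len(subj), cl[-1] + k + len(query))
            alns = aligner.align(query, subj[w0:w1])
            try:
                best = alns[0]
            except IndexError:
                continue
            cols = matches = qcols = 0
            for x, y in zip(best[0], best[1]):
                cols += 1
                if x != "-":
                    qcols += 1
                if x == y and x != "-":
                    matches += 1
            if cols == 0:
                continue
            identity = 100.0 * matches / cols
            coverage = 100.0 * qcols / len(query)
            s0 = w0 + int(best.aligned[1][0][0])
            s1 = w0 + int(best.aligned[1][-1][1])
            if strand == "-":
                s0, s1 = len(subj) - s1, len(subj) - s0
            out.append((s0, s1, strand, identity, coverage))
    out.sort(key=lambda h: (h[0], h[1], h[2]))
    return out


def screen_cross_genome(queries: dict[str, str], subjects: dict[str, str],
                        min_identity: float = 60.0,
                        min_coverage: float = 65.0) -> list[CrossGenomeHit]:
    """Retain cross-genome homologs per the 60% identity / 65% length rule.

    Both thresholds are strict greater-than.  Deterministic and
    independent of subject ordering (results sorted).
    """
    if not subjects:
        raise ValueError("empty subject database")
    hits = []
    for qname in sorted(queries):
        for sname in sorted(subjects):
            for s0, s1, strand, ident, cov in nucleotide_search(queries[qname],
                                                                subjects[sname]):
                if ident > min_identity and cov > min_coverage:
                    hits.append(CrossGenomeHit(qname, sname, s0, s1, strand,
                                               round(ident, 2), round(cov, 2)))
    hits.sort(key=lambda h: (h.query, h.subject, h.s_start, h.s_end))
    return hits


# ---------------------------------------------------------------------------
# horizontal transfer


@dataclass
class HTCandidate:
    query: str
    subject: str
    query_species: str
    subject_species: str
    identity: float
    coverage: float
    flagged: bool


def flag_horizontal_transfer(hit: CrossGenomeHit,
                             species_of: dict[str, str],
                             min_identity: float = 90.0,
                             min_coverage: float = 90.0) -> HTCandidate:
    """Flag a retained hit as a potential horizontal transfer.

    Flagged iff identity > 90%, query coverage > 90% and the two
    records come from different species.  Missing species metadata is an
    error.
    """
    try:
        qs = species_of[hit.query]
        ss = species_of[hit.subject]
    except KeyError as exc:
        raise ValueError(f"missing species metadata for {exc}") from exc
    flagged = hit.identity > min_identity and hit.coverage > min_coverage and qs != ss
    return HTCandidate(hit.query, hit.subject, qs, ss,
                       hit.identity, hit.coverage, flagged)
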