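"""Synthetic genomes with implanted mariner-like elements and known truth.

The generator emulates what a homology-based transposon survey actually
sees in an assembly: multi-scaffold genomes carrying

* autonomous elements — terminal inverted repeat (TIR), 5' UTR,
  transposase ORF with a chosen catalytic-triad spacing, 3' UTR,
  reverse-complemented TIR — flanked by the TA target-site duplication,
* internally deleted derivatives (MITEs) whose deletion breakpoints carry
  controlled microhomologies (BPEE: a direct repeat starting exactly at
  both deletion edges; BPNN: repeat copies a few bases inside each edge;
  none: breakpoint windows scrubbed of any shared >= 3-mer),
* truncated copies (one TIR lost) and copies interrupted by an N run,

all under a per-copy substitution/indel divergence model.  Every planted
copy is recorded in a machine-readable truth set so that the discovery
pipeline can be scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from ._alignment import revcomp
from .references import back_translate, make_lineage_transposase, parse_family_label

_BASES = np.array(list("ACGT"))


def _rng_for(*parts) -> np.random.Generator:
    """Deterministic generator keyed by a tuple of ints/strings."""
    seed = [p if isinstance(p, int) else zlib.crc32(str(p).encode()) for p in parts]
    return np.random.default_rng(np.random.SeedSequence(seed))


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    return "".join(rng.choice(_BASES, size=n, p=[p_at, p_gc, p_gc, p_at]))


# ---------------------------------------------------------------------------
# element specifications


@dataclass(frozen=True)
class ElementSpec:
    """Blueprint for one autonomous element lineage.

    ``triad_spacings`` counts residues strictly between catalytic
    positions 1-2 and 2-3.  Total element length is
    ``2*len(tir_seq) + utr5_len + utr3_len + 3*(len(orf_aa)+1)``
    (the +1 is the stop codon).
    """

    name: str
    tir_seq: str
    utr5_len: int
    utr3_len: int
    orf_aa: str
    triad_spacings: tuple[int, int]
    tsd: str = "TA"
    family_label: str = "DD34D"
    triad_positions: tuple[int, int, int] | None = None

    def __post_init__(self):
        if len(self.tir_seq) < 10:
            raise ValueError("TIR must be at least 10 bp")
        if self.triad_positions is not None:
            d1, d2, d3 = self.triad_positions
            inner2, res3 = parse_family_label(self.family_label)
            if self.orf_aa[d1] != "D" or self.orf_aa[d2] != "D":
                raise ValueError("first two catalytic residues must be D")
            if d2 - d1 - 1 != self.triad_spacings[0] or d3 - d2 - 1 != self.triad_spacings[1]:
                raise ValueError("triad positions do not match triad_spacings")
            if self.orf_aa[d3] != res3 or inner2 != self.triad_spacings[1]:
                raise ValueError("triad does not match family label")

    @property
    def length(self) -> int:
        return 2 * len(self.tir_seq) + self.utr5_len + self.utr3_len + 3 * (len(self.orf_aa) + 1)


def make_element_spec(name: str, family_label: str, tir_seq: str,
                      orf_len: int = 354, utr5_len: int = 220,
                      utr3_len: int = 220, tsd: str = "TA") -> ElementSpec:
    """Convenience constructor wiring a lineage transposase to a spec."""
    inner2, _ = parse_family_label(family_label)
    aa, triad = make_lineage_transposase(family_label, name, length=orf_len)
    return ElementSpec(
        name=name, tir_seq=tir_seq, utr5_len=utr5_len, utr3_len=utr3_len,
        orf_aa=aa, triad_spacings=(triad[1] - triad[0] - 1, inner2),
        tsd=tsd, family_label=family_label, triad_positions=triad,
    )


# short-TIR sequences modelled on mariner/rosa elements; the long-TIR
# lineage gets a seeded 460 bp arm.
_MACRO_TIR = "CGAGGCGTGTCCAGAAAGTAAGTGTACT"            # 28 bp, mariner-like
_BAT_TIR = "CGAGGTATGACAATAAAATAACGAGACTTT"           # 30 bp, mirror motif inside
_ROSA_TIR = "AAGGGTGTCTCAAAAAGAACGCCGGATTTGAA"        # 32 bp, rosa-like
_MAT_TIR = "CAGTGGTCCAAAAAGTTGCAAGCCTTTACT"           # 30 bp
_TC_TIR = "CAGTGCTGGCCAAAAAGATATCCACTTG"              # 28 bp, Tc1-like


def default_element_specs() -> dict[str, ElementSpec]:
    """Four study lineages (incl. one long-TIR spec) plus two extras."""
    ltir = random_dna(460, _rng_for("ltir-arm"))
    return {
        s.name: s for s in [
            make_element_spec("Macromar1", "DD34D", _MACRO_TIR, orf_len=354),
            make_element_spec("Batmar1", "DD34D", _BAT_TIR, orf_len=354),
            make_element_spec("Rosamar1", "DD41D", _ROSA_TIR, orf_len=361),
            make_element_spec("Ltirmar1", "DD40D", ltir, orf_len=351),
            make_element_spec("Matmar1", "DD37D", _MAT_TIR, orf_len=346),
            make_element_spec("Tcmar1", "DD34E", _TC_TIR, orf_len=343),
        ]
    }


def _utr_seqs(spec: ElementSpec) -> tuple[str, str]:
    rng = _rng_for("utr", spec.name)
    utr5 = random_dna(spec.utr5_len, rng)
    if spec.utr5_len >= 9:
        # in-frame stop cassette just upstream of the start codon, so the
        # annotated ORF begins at the real ATG
        utr5 = utr5[:-9] + "TAATAGTGA"
    utr3 = list(random_dna(spec.utr3_len, rng))
    if spec.utr3_len >= 40:  # plant a polyadenylation signal
        utr3[30:36] = list("AATAAA")
    return utr5, "".join(utr3)


def build_autonomous_element(spec: ElementSpec) -> str:
    """Assemble the full element: TIR + UTR5 + ORF(+stop) + UTR3 + rc(TIR).

    Deterministic given the spec (UTR content is seeded by the spec name;
    the ORF is back-translated with the fixed codon table).
    """
    utr5, utr3 = _utr_seqs(spec)
    orf_nt = back_translate(spec.orf_aa + "*")
    elem = spec.tir_seq + utr5 + orf_nt + utr3 + revcomp(spec.tir_seq)
    assert len(elem) == spec.length
    return elem


# ---------------------------------------------------------------------------
# deletion derivatives and microhomology planting

MICRO_TYPES = ("BPEE", "BPNN", "none")
_MICRO_WINDOW_PAD = 12  # window length = near_window + pad


def _shared_kmer(w1: str, w2: str, k: int) -> bool:
    kmers = {w1[i:i + k] for i in range(len(w1) - k + 1)}
    return any(w2[j:j + k] in kmers for j in range(len(w2) - k + 1))


def _longest_shared(w1: str, w2: str) -> int:
    best = 0
    for i in range(len(w1)):
        for j in range(len(w2)):
            l = 0
            while i + l < len(w1) and j + l < len(w2) and w1[i + l] == w2[j + l]:
                l += 1
            best = max(best, l)
    return best


def _orf_intact(seq: str, orf_region: tuple[int, int]) -> bool:
    from Bio.Seq import Seq

    s, e = orf_region
    aa = str(Seq(seq[s:e]).translate())
    return "*" not in aa[:-1]


def plant_microhomology(parent: str, del_start: int, del_end: int,
                        micro: str = "BPEE", micro_len: int = 5,
                        offsets: tuple[int, int] = (2, 3),
                        near_window: int = 10, tir_len: int = 0,
                        orf_region: tuple[int, int] | None = None,
                        seed: int = 0) -> str:
    """Rewrite the two breakpoint windows of a parent element.

    The windows start at each deletion edge and extend rightward
    (matching the left-aligned deletion convention of the breakpoint
    caller).  For BPEE a direct repeat is stamped starting exactly at
    both edges; for BPNN the copies start ``offsets`` bases inside each
    edge; for ``none`` the windows are guaranteed to share no >= 3-mer.
    Window content is resampled until the planted repeat is the unique
    longest shared substring, so the microhomology class of the copy is
    unambiguous by construction.  When the edges fall inside the
    transposase ORF, pass ``orf_region`` (element coordinates of the
    coding sequence incl. stop) and the rewrite is additionally required
    to keep the parent ORF free of premature stop codons.
    """
    if micro not in MICRO_TYPES:
        raise ValueError(f"unknown microhomology type {micro!r}")
    win = near_window + _MICRO_WINDOW_PAD
    if not (tir_len < del_start < del_end < len(parent) - tir_len):
        raise ValueError("deletion interval must lie strictly between the TIRs")
    if del_end + win > len(parent) - tir_len:
        raise ValueError("no room for the right breakpoint window inside the element")
    rng = _rng_for("micro", seed, del_start, del_end, micro)
    for _ in range(10_000):
        w1 = list(random_dna(win, rng))
        w2 = list(random_dna(win, rng))
        if _shared_kmer("".join(w1), "".join(w2), 3):
            continue
        if micro != "none":
            from .mites import best_shared_repeat

            rep = random_dna(micro_len, rng)
            o1, o2 = (0, 0) if micro == "BPEE" else offsets
            w1[o1:o1 + micro_len] = list(rep)
            w2[o2:o2 + micro_len] = list(rep)
            s1, s2 = "".join(w1), "".join(w2)
            if _longest_shared(s1, s2) != micro_len:
                continue
            # the planted repeat must be what a breakpoint classifier
            # finds — no competing shared substring may win the tie-break
            if best_shared_repeat(s1, s2, near_window) != (micro_len, o1, o2):
                continue
        out = list(parent)
        out[del_start:del_start + win] = w1
        out[del_end:del_end + win] = w2
        cand = "".join(out)
        if orf_region is not None and not _orf_intact(cand, orf_region):
            continue
        return cand
    raise RuntimeError("could not scrub breakpoint windows")  # pragma: no cover


def derive_deletion_derivative(parent: str, del_start: int, del_end: int,
                               micro: str = "none", micro_len: int = 5,
                               near_window: int = 10, tir_len: int = 0) -> str:
    """Delete ``[del_start, del_end)`` from a parent element.

    When a microhomology type is declared, the parent is checked to
    actually carry the corresponding direct repeat at its breakpoint
    windows (plant it first with :func:`plant_microhomology`).
    """
    if not (0 < del_start < del_end < len(parent)):
        raise ValueError("deletion interval out of bounds")
    if tir_len and not (tir_len < del_start and del_end < len(parent) - tir_len):
        raise ValueError("deletion must not overlap a TIR")
    if micro in ("BPEE", "BPNN"):
        win = near_window + _MICRO_WINDOW_PAD
        w1 = parent[del_start:del_start + win]
        w2 = parent[del_end:del_end + win]
        if _longest_shared(w1, w2) < micro_len:
            raise ValueError(f"parent lacks the declared {micro} microhomology")
    return parent[:del_start] + parent[del_end:]


# ---------------------------------------------------------------------------
# divergence model


_STOPS = {"TAA", "TAG", "TGA"}


def mutate_copy(seq: str, divergence: float, indel_rate: float, seed: int,
                protect: list[tuple[int, int]] | None = None,
                keep_orf: tuple[int, int] | None = None,
                no_sub: list[tuple[int, int]] | None = None) -> str:
    """Apply i.i.d. substitutions and short indels to a copy.

    Substitution probability per site is ``divergence``; indels occur at
    ``indel_rate`` per site, are 1-3 bp with geometric(0.5) lengths, and
    are suppressed inside ``protect`` intervals (e.g. the TIR arms).
    Deterministic given ``seed``.

    ``keep_orf`` models purifying selection on a copy that is meant to
    stay functional: no indels fall inside the interval and any
    substitution that would create a stop codon (reading frame anchored
    at the interval start) is discarded.  ``no_sub`` intervals (e.g. the
    catalytic-triad codons) receive no substitutions at all.
    """
    if not (0 <= divergence <= 0.5 and 0 <= indel_rate <= 0.5):
        raise ValueError("rates must lie in [0, 0.5]")
    rng = _rng_for("mutate", seed)
    protect = list(protect or [])
    no_sub = list(no_sub or [])
    n = len(seq)
    cur = list(seq)
    # substitution pass (length-preserving)
    for i in range(n):
        if cur[i] not in "ACGT" or rng.random() >= divergence:
            continue
        if any(s <= i < e for s, e in no_sub):
            continue
        new = rng.choice([b for b in "ACGT" if b != cur[i]])
        if keep_orf is not None and keep_orf[0] <= i < keep_orf[1]:
            c0 = keep_orf[0] + 3 * ((i - keep_orf[0]) // 3)
            codon = cur[c0:c0 + 3]
            codon[i - c0] = new
            if "".join(codon) in _STOPS and i < keep_orf[1] - 3:
                continue
        cur[i] = new
    # indel pass
    if keep_orf is not None:
        protect.append(keep_orf)
    out: list[str] = []
    i = 0
    while i < n:
        protected = any(s <= i < e for s, e in protect)
        if not protected and rng.random() < indel_rate:
            length = min(int(rng.geometric(0.5)), 3)
            if rng.random() < 0.5:  # insertion after this site
                out.append(cur[i])
                out.append(random_dna(length, rng))
                i += 1
                continue
            else:  # deletion starting here
                i += length
                continue
        out.append(cur[i])
        i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# implantation


@dataclass(frozen=True)
class Placement:
    """One copy to implant (position in final scaffold coordinates)."""

    scaffold: int
    pos: int
    name: str
    seq: str                      # un-mutated element (or derivative)
    parent: str = ""              # parent element name ("" = self)
    strand: str = "+"
    divergence: float = 0.0
    indel_rate: float = 0.0
    truncation: str = "none"      # none | left | right | N
    trunc_len: int = 0
    tsd: str | None = "TA"
    planted_class: str = "complete"   # complete | deleted | truncated | N-truncated
    deletion: tuple[int, int] | None = None  # element coords of the deletion
    micro: str = "none"
    family_label: str = ""
    tir_len: int = 0
    keep_orf: tuple[int, int] | None = None      # purifying selection
    no_sub: tuple[tuple[int, int], ...] = ()     # substitution-free intervals


@dataclass
class ImplantPlan:
    scaffold_lengths: list[int]
    placements: list[Placement]
    seed: int = 0
    gc: float = 0.5


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted copy (0-based half-open, TSD excluded)."""

    copy_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    planted_class: str
    parent: str
    family_label: str
    deletion: tuple[int, int] | None
    micro: str
    tsd_start: int   # TSD-inclusive convention
    tsd_end: int
    tir_len: int


def _final_insert(p: Placement, plan_seed: int, idx: int) -> tuple[str, int, int]:
    """Mutate/truncate one placement; returns (insert, elem_off, elem_len)."""
    protect = [(0, p.tir_len), (len(p.seq) - p.tir_len, len(p.seq))] if p.tir_len else []
    seq = mutate_copy(p.seq, p.divergence, p.indel_rate,
                      seed=zlib.crc32(f"{plan_seed}|{idx}|{p.name}".encode()) & 0x7FFFFFFF,
                      protect=protect, keep_orf=p.keep_orf, no_sub=list(p.no_sub))
    if p.truncation == "left":
        seq = seq[p.trunc_len:]
    elif p.truncation == "right":
        seq = seq[:len(seq) - p.trunc_len]
    elif p.truncation == "N":
        a = max(p.tir_len + 10, (len(seq) - p.trunc_len) // 2)
        seq = seq[:a] + "N" * p.trunc_len + seq[a + p.trunc_len:]
    tsd = p.tsd or ""
    left = tsd if p.truncation != "left" else ""
    right = tsd if p.truncation != "right" else ""
    return left + seq + right, len(left), len(seq)


def implant_genome(plan: ImplantPlan) -> tuple[dict[str, str], list[TruthRecord]]:
    """Generate background scaffolds and overwrite them with planted copies.

    Non-truncated copies are flanked by the TA target-site duplication on
    both sides.  Placements must not overlap (TSD included); positions are
    final scaffold coordinates.
    """
    rng = _rng_for("background", plan.seed)
    scaffolds = {
        f"scaffold_{i + 1}": list(random_dna(n, rng, gc=plan.gc))
        for i, n in enumerate(plan.scaffold_lengths)
    }
    truth: list[TruthRecord] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    for idx, p in enumerate(sorted(plan.placements, key=lambda q: (q.scaffold, q.pos))):
        insert, off, elem_len = _final_insert(p, plan.seed, idx)
        if p.strand == "-":
            insert = revcomp(insert)
            off = len(insert) - off - elem_len
        sname = f"scaffold_{p.scaffold + 1}"
        L = plan.scaffold_lengths[p.scaffold]
        if p.pos < 0 or p.pos + len(insert) > L:
            raise ValueError(f"placement {p.name} exceeds scaffold bounds")
        iv = (p.pos, p.pos + len(insert))
        for s, e in occupied.setdefault(p.scaffold, []):
            if iv[0] < e and s < iv[1]:
                raise ValueError(f"placement {p.name} overlaps another copy")
        occupied[p.scaffold].append(iv)
        scaffolds[sname][iv[0]:iv[1]] = list(insert)
        start = p.pos + off
        truth.append(TruthRecord(
            copy_id=f"{p.name}_c{idx}", scaffold=sname,
            start=start, end=start + elem_len, strand=p.strand,
            planted_class=p.planted_class, parent=p.parent or p.name,
            family_label=p.family_label, deletion=p.deletion, micro=p.micro,
            tsd_start=iv[0], tsd_end=iv[1], tir_len=p.tir_len,
        ))
    return {k: "".join(v) for k, v in scaffolds.items()}, truth


# ---------------------------------------------------------------------------
# ready-made plans


def orf_region_of(spec: ElementSpec) -> tuple[int, int]:
    """Element coordinates of the coding sequence (incl. stop codon)."""
    s = len(spec.tir_seq) + spec.utr5_len
    return s, s + 3 * (len(spec.orf_aa) + 1)


def _planted_parent(spec: ElementSpec, micro: str, seed: int = 0,
                    del_len: int = 419, del_offset: int = 420,
                    ) -> tuple[str, tuple[int, int]]:
    """Parent element with breakpoint windows prepared inside the ORF.

    The deletion removes an internal chunk of the transposase gene (the
    default 419 bp spans the first two catalytic residues and breaks the
    reading frame), emulating internally deleted derivatives that retain
    ~70% of their parent.  The rewrite is codon-safe: the parent's own
    ORF stays intact.
    """
    elem = build_autonomous_element(spec)
    tir = len(spec.tir_seq)
    orf = orf_region_of(spec)
    del_start = orf[0] + del_offset
    del_end = del_start + del_len
    planted = plant_microhomology(elem, del_start, del_end, micro=micro,
                                  tir_len=tir, orf_region=orf, seed=seed)
    return planted, (del_start, del_end)


def study_plan(seed: int = 0, n_scaffolds: int = 5, scaffold_len: int = 200_000,
               divergence: float = 0.03, indel_rate: float = 0.002,
               specs: dict[str, ElementSpec] | None = None) -> ImplantPlan:
    """The study conditions: 30 copies across 4 lineages on 5 scaffolds.

    Per lineage: complete copies (one on the minus strand), one truncated
    copy, and for three lineages a group of MITEs sharing a planted
    breakpoint (BPEE, BPNN and repeat-free respectively).
    """
    specs = specs or default_element_specs()
    chosen = [specs["Macromar1"], specs["Batmar1"], specs["Rosamar1"], specs["Ltirmar1"]]
    micro_of = {"Macromar1": "BPEE", "Batmar1": "BPNN", "Rosamar1": "none"}
    placements: list[Placement] = []
    rng = _rng_for("plan", seed)

    def put(name, seq, **kw):
        placements.append(Placement(scaffold=0, pos=0, name=name, seq=seq, **kw))

    for spec in chosen:
        tir = len(spec.tir_seq)
        if spec.name in micro_of:
            parent, (ds, de) = _planted_parent(spec, micro_of[spec.name], seed=seed)
        else:
            parent, (ds, de) = build_autonomous_element(spec), (None, None)
        orf_reg = orf_region_of(spec)
        triad_nt = tuple(
            (orf_reg[0] + 3 * p, orf_reg[0] + 3 * p + 3)
            for p in (spec.triad_positions or ()))
        n_complete = 4
        for i in range(n_complete):
            put(f"{spec.name}", parent, strand="-" if i == 1 else "+",
                divergence=divergence, indel_rate=indel_rate,
                planted_class="complete", family_label=spec.family_label, tir_len=tir,
                keep_orf=orf_reg, no_sub=triad_nt)
        # one truncated copy: lose the left TIR plus 60% of the ORF
        cut = tir + spec.utr5_len + int(0.6 * 3 * len(spec.orf_aa))
        put(f"{spec.name}_tr", parent, divergence=divergence, indel_rate=indel_rate,
            truncation="left", trunc_len=cut, planted_class="truncated",
            family_label=spec.family_label, tir_len=0)
        if spec.name in micro_of:
            micro = micro_of[spec.name]
            mite = derive_deletion_derivative(parent, ds, de, micro=micro, tir_len=tir)
            n_mites = 4 if spec.name == "Macromar1" else 3
            for _ in range(n_mites):
                put(f"{spec.name}_mite", mite, parent=spec.name,
                    divergence=divergence, indel_rate=indel_rate,
                    planted_class="deleted", deletion=(ds, de), micro=micro,
                    family_label=spec.family_label, tir_len=tir)
    # scatter the placements over the scaffolds, non-overlapping
    per_scaffold = -(-len(placements) // n_scaffolds)
    spacing = scaffold_len // (per_scaffold + 1)
    final: list[Placement] = []
    order = rng.permutation(len(placements))
    for slot, pidx in enumerate(order):
        scaf = slot // per_scaffold
        rank = slot % per_scaffold
        jitter = int(rng.integers(0, max(1, spacing - 6000)))
        pos = 1000 + rank * spacing + jitter % max(1, spacing - 5500)
        final.append(replace(placements[pidx], scaffold=scaf, pos=pos))
    return ImplantPlan(scaffold_lengths=[scaffold_len] * n_scaffolds,
                       placements=final, seed=seed)


def microhomology_benchmark(seed: int = 0, n_each: int = 20,
                            divergence: float = 0.0, indel_rate: float = 0.0,
                            spec: ElementSpec | None = None):
    """(mite, partner, true_micro, true_interval) tuples for benchmarking.

    Partners stay pristine; only the MITE copies are mutated, mirroring a
    comparison of diverged non-autonomous copies against a reference
    autonomous element.
    """
    spec = spec or default_element_specs()["Macromar1"]
    out = []
    i = 0
    for micro in MICRO_TYPES:
        for r in range(n_each):
            parent, (ds, de) = _planted_parent(spec, micro, seed=seed * 1000 + i)
            mite = derive_deletion_derivative(parent, ds, de, micro=micro,
                                              tir_len=len(spec.tir_seq))
            mite = mutate_copy(mite, divergence, indel_rate,
                               seed=(seed * 7919 + i) & 0x7FFFFFFF)
            out.append((mite, parent, micro, (ds, de)))
            i += 1
    return out


# ---------------------------------------------------------------------------
# writers


def write_genome_fasta(scaffolds: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in scaffolds.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_truth_gff3(truth: list[TruthRecord], path) -> None:
    """Truth set as GFF3 (1-based inclusive), TSD-exclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truth:
            attrs = (f"ID={t.copy_id};class={t.planted_class};parent_element={t.parent};"
                     f"family={t.family_label};micro={t.micro};"
                     f"tsd_start={t.tsd_start + 1};tsd_end={t.tsd_end}")
            if t.deletion:
                attrs += f";deletion={t.deletion[0] + 1}-{t.deletion[1]}"
            fh.write(f"{t.scaffold}\tmarinerscan_sim\ttransposable_element\t"
                     f"{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n")


def write_truth_tsv(truth: list[TruthRecord], path) -> None:
    import pandas as pd

    rows = [{
        "copy_id": t.copy_id, "scaffold": t.scaffold, "start": t.start,
        "end": t.end, "strand": t.strand, "class": t.planted_class,
        "parent": t.parent, "family": t.family_label,
        "deletion_start": t.deletion[0] if t.deletion else "",
        "deletion_end": t.deletion[1] if t.deletion else "",
        "micro": t.micro, "tsd_start": t.tsd_start, "tsd_end": t.tsd_end,
    } for t in truth]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
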