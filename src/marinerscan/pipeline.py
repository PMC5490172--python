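"""End-to-end discovery pipeline and catalog summarisation.

Stage order mirrors the survey it models: translated homology mining ->
locus extraction -> TIR/TSD boundary annotation -> retention filters ->
a nucleotide recovery round (each complete element is used to retrieve
its non-autonomous relatives, which carry no transposase homology) ->
lineage clustering -> transposase annotation -> UPGM-VM classification
-> MITE breakpoint/microhomology analysis -> consensus-divergence
dating.  Every stage is deterministic given the inputs and writes its
intermediates to disk when an output directory is provided.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import boundaries, evolution, lineages, mining, mites, transposase
from ._alignment import align_gap5, revcomp
from .references import RefTransposase, ddxd_panel, ddxe_panel, default_reference_panel


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, serialisable to YAML."""

    flank: int = 5000
    merge_gap: int = 1000
    min_element_len: int = 250
    min_hit_id: float = 35.0
    min_hit_len: int = 80
    tir_window: int = 800
    tir_inner_margin: int = 150
    tir_inner_margin_recovered: int = 600
    min_tir: int = 10
    min_arm_id: float = 80.0
    min_tir_score: int = 15
    tsd: str = "TA"
    cluster_threshold: float = 75.0
    min_orf_aa: int = 200
    min_deletion: int = 50
    min_micro: int = 3
    micro_near_window: int = 10
    mite_tir_id: float = 90.0
    mite_bp_tol: int = 10
    screen_min_id: float = 60.0
    screen_min_cov: float = 65.0
    ht_min_id: float = 90.0
    ht_min_cov: float = 90.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ElementRecord:
    """One annotated candidate copy."""

    record_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."
    source: str = "translated"
    n_tirs: int = 0
    tir: boundaries.TIRPair | None = None
    tir_seq: str = ""
    tsd_present: str = "indeterminate"
    at_scaffold_end: bool = False
    has_N_run: bool = False
    seq: str = ""
    orf: transposase.ORFRecord | None = None
    orf_aa: str = ""
    triad: transposase.TriadCall | None = None
    domains: transposase.DomainAnnotation | None = None
    lineage: str = ""
    completeness: str = ""
    potentially_active: bool = False
    mite_sublineage: str = ""
    mite_partner: str = ""
    breakpoint: mites.DeletionBreakpoint | None = None
    micro_type: str = ""
    age_class: str = ""

    @property
    def element_length(self) -> int:
        return self.end - self.start


@dataclass
class PipelineResult:
    catalog: pd.DataFrame
    records: list[ElementRecord]
    lineages: list[lineages.Lineage]
    dendrogram: lineages.Dendrogram | None
    sublineages: list[mites.MITESublineage]
    ages: list[evolution.AgeEstimate]
    rejections: dict[str, mining.FilterDecision]
    counts: dict[str, int]
    summary: dict


def _annotate_locus(genome: dict[str, str], locus: mining.CandidateLocus,
                    cfg: PipelineConfig, idx: int) -> ElementRecord:
    seq = genome[locus.scaffold][locus.ext_start:locus.ext_end]
    inner = cfg.tir_inner_margin if locus.source == "translated" \
        else cfg.tir_inner_margin_recovered
    tir = boundaries.detect_tir(
        seq, locus.core_start - locus.ext_start, locus.core_end - locus.ext_start,
        window=cfg.tir_window, inner_margin=inner, min_tir=cfg.min_tir,
        min_arm_id=cfg.min_arm_id, min_score=cfg.min_tir_score, tsd=cfg.tsd)
    rec = ElementRecord(
        record_id=f"copy{idx:03d}", scaffold=locus.scaffold,
        start=locus.ext_start + (tir.left_start if tir else
                                 locus.core_start - locus.ext_start),
        end=locus.ext_start + (tir.right_end if tir else
                               locus.core_end - locus.ext_start),
        source=locus.source, at_scaffold_end=locus.at_scaffold_end,
        has_N_run=locus.has_N_run,
    )
    if tir:
        rec.n_tirs = 2
        rec.tir = tir
        rec.tsd_present = boundaries.detect_tsd(seq, tir, cfg.tsd)
        if rec.at_scaffold_end:
            rec.tsd_present = "indeterminate" if rec.tsd_present != "yes" \
                else rec.tsd_present
    rec.strand = locus.strand
    raw = genome[rec.scaffold][rec.start:rec.end]
    rec.seq = raw if rec.strand != "-" else revcomp(raw)
    if tir:
        rec.tir_seq = rec.seq[:tir.arm_len]
    return rec


def _orient(rec: ElementRecord) -> None:
    """Flip a record to its element strand once the ORF strand is known."""
    if rec.orf is None or rec.orf.strand != "-":
        return
    rec.strand = "-" if rec.strand == "+" else "+"
    rec.seq = revcomp(rec.seq)
    if rec.tir is not None:
        rec.tir_seq = rec.seq[:rec.tir.arm_len]
    rec.orf.strand = "+"


def _cigar_stats(query: str, target: str, cigar: str) -> tuple[int, int]:
    """(matching columns, total columns) from an edlib extended CIGAR."""
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            matches += n
    return matches, cols


def _recovery_scan(genome: dict[str, str], queries: list[ElementRecord],
                   cfg: PipelineConfig, k: int = 12):
    """Fast nucleotide retrieval of additional copies of known elements.

    One k-mer index per scaffold serves every query and both strands;
    seed clusters are verified with an infix edit-distance alignment
    (edlib) whose CIGAR yields the identity over alignment columns.
    Yields (scaffold, start, end, strand, identity, query_record).
    """
    import edlib

    for sname in sorted(genome):
        seq = genome[sname].upper()
        index: dict[str, list[int]] = {}
        for j in range(len(seq) - k + 1):
            index.setdefault(seq[j:j + k], []).append(j)
        for q in queries:
            for strand, qseq in (("+", q.seq), ("-", revcomp(q.seq))):
                pos = sorted({j for i in range(len(qseq) - k + 1)
                              for j in index.get(qseq[i:i + k], ())})
                if not pos:
                    continue
                clusters: list[list[int]] = [[pos[0]]]
                for p in pos[1:]:
                    if p - clusters[-1][-1] <= len(qseq):
                        clusters[-1].append(p)
                    else:
                        clusters.append([p])
                for cl in clusters:
                    if len(cl) < 5:
                        continue
                    w0 = max(0, cl[0] - len(qseq))
                    w1 = min(len(seq), cl[-1] + k + len(qseq))
                    res = edlib.align(qseq, seq[w0:w1], mode="HW", task="path")
                    if res["editDistance"] < 0 or not res["locations"]:
                        continue
                    matches, cols = _cigar_stats(qseq, seq[w0:w1], res["cigar"])
                    if cols == 0:
                        continue
                    identity = 100.0 * matches / cols
                    loc = res["locations"][0]
                    yield sname, w0 + loc[0], w0 + loc[1] + 1, strand, identity, q


def _overlaps(rec_iv, existing, frac: float = 0.5) -> bool:
    s, e = rec_iv
    for s2, e2 in existing:
        inter = min(e, e2) - max(s, s2)
        if inter > 0 and inter >= frac * min(e - s, e2 - s2):
            return True
    return False


def run_pipeline(genome: dict[str, str], panel: dict[str, str],
                 cfg: PipelineConfig | None = None,
                 species: str = "genome", out_dir=None,
                 triad_panel: list[RefTransposase] | None = None) -> PipelineResult:
    """Run the full discovery pipeline on one genome.

    ``panel`` is the transposase protein query panel; ``triad_panel``
    (default: the built-in synthetic reference panel) supplies annotated
    catalytic-triad columns and the DDxD/DDxE sub-panels for filtering.
    """
    cfg = cfg or PipelineConfig()
    triad_panel = triad_panel if triad_panel is not None else default_reference_panel()
    d_panel = [r for r in triad_panel if r.family.endswith("D")] or ddxd_panel()
    e_panel = [r for r in triad_panel if r.family.endswith("E")] or ddxe_panel()
    counts: dict[str, int] = {}
    scaffold_lengths = {k: len(v) for k, v in genome.items()}

    # 1. translated mining
    params = mining.SearchParams(min_id=cfg.min_hit_id, min_len=cfg.min_hit_len)
    hits = mining.translated_search(genome, panel, params)
    counts["translated_hits"] = len(hits)
    loci = mining.build_candidate_loci(hits, scaffold_lengths, flank=cfg.flank,
                                       merge_gap=cfg.merge_gap, genome=genome) if hits else []
    counts["translated_loci"] = len(loci)

    # 2. boundary annotation
    records = [_annotate_locus(genome, lc, cfg, i) for i, lc in enumerate(loci)]

    # 3. ORFs for filtering (and orientation)
    for rec in records:
        _annotate_orf(rec, cfg, triad_panel)
        _orient(rec)

    retained, rejections = mining.filter_candidates(
        records, min_len=cfg.min_element_len, ddxd=d_panel, ddxe=e_panel)
    counts["retained_primary"] = len(retained)

    # 4. recovery round: complete-looking elements retrieve their
    #    non-autonomous relatives by nucleotide search
    complete_like = [r for r in retained
                     if r.n_tirs == 2 and r.orf is not None and not r.orf.has_internal_stop]
    recov_queries: list[ElementRecord] = []
    seen_lineage_seqs: list[str] = []
    for rec in sorted(complete_like, key=lambda r: (-r.element_length, r.record_id)):
        if any(align_gap5(rec.seq, s).identity >= cfg.cluster_threshold
               for s in seen_lineage_seqs):
            continue
        seen_lineage_seqs.append(rec.seq)
        recov_queries.append(rec)
    occupied = {sc: [] for sc in genome}
    for rec in retained:
        occupied[rec.scaffold].append((rec.start, rec.end))
    next_idx = len(records)
    recovered: list[ElementRecord] = []
    for sname, s0, s1, strand, ident, q in _recovery_scan(genome, recov_queries, cfg):
        if ident <= cfg.screen_min_id or s1 - s0 < cfg.min_element_len:
            continue
        if _overlaps((s0, s1), occupied[sname]):
            continue
        locus = mining.CandidateLocus(
            sname, s0, s1,
            max(0, s0 - cfg.flank), min(scaffold_lengths[sname], s1 + cfg.flank),
            q.record_id, 0.0,
            at_scaffold_end=(s0 - cfg.flank < 0
                             or s1 + cfg.flank > scaffold_lengths[sname]),
            has_N_run="N" * 10 in genome[sname][s0:s1],
            source="nucleotide", strand=strand)
        rec = _annotate_locus(genome, locus, cfg, next_idx)
        next_idx += 1
        _annotate_orf(rec, cfg, triad_panel)
        _orient(rec)
        occupied[sname].append((rec.start, rec.end))
        recovered.append(rec)
    counts["recovered"] = len(recovered)
    rec_retained, rec_rej = mining.filter_candidates(
        recovered, min_len=cfg.min_element_len, ddxd=d_panel, ddxe=e_panel)
    rejections.update(rec_rej)
    retained = retained + rec_retained
    counts["retained_total"] = len(retained)

    # 5. lineage clustering
    lins = lineages.greedy_cluster([(r.record_id, r.seq) for r in retained],
                                   threshold=cfg.cluster_threshold)
    lin_of = {m: l for l in lins for m in l.members}
    for rec in retained:
        rec.lineage = lin_of[rec.record_id].id
    counts["lineages"] = len(lins)

    # 6. deleted-copy detection against autonomous partners, then
    #    completeness classification
    def orf_ok(r: ElementRecord) -> bool:
        return r.orf is not None and not r.orf.has_internal_stop \
            and not r.orf.frameshift_evidence and r.orf.coverage >= 0.6

    by_lineage: dict[str, list[ElementRecord]] = {}
    for rec in retained:
        by_lineage.setdefault(rec.lineage, []).append(rec)
    # one partner candidate per lineage that has an intact full ORF
    partner_pool: list[ElementRecord] = []
    for lid in sorted(by_lineage):
        comp = [r for r in by_lineage[lid] if r.n_tirs == 2 and orf_ok(r)]
        if comp:
            partner_pool.append(max(comp, key=lambda r: (r.element_length, r.record_id)))
    for rec in sorted(retained, key=lambda r: r.record_id):
        if rec.n_tirs != 2:
            continue
        best = None
        for p in partner_pool:
            if p is rec or p.element_length < rec.element_length + 100:
                continue
            for flipped, mseq in ((False, rec.seq), (True, revcomp(rec.seq))):
                bp = mites.call_deletion_breakpoints(mseq, p.seq, p.record_id,
                                                     min_del=cfg.min_deletion)
                if bp and bp.flank_identity >= cfg.cluster_threshold and \
                        (best is None or bp.flank_identity > best[0].flank_identity):
                    best = (bp, p, flipped)
        if best:
            bp, p, flipped = best
            if flipped:
                # the partner alignment, not a residual ORF fragment, is
                # authoritative for the orientation of a deleted copy
                rec.strand = "-" if rec.strand == "+" else "+"
                rec.seq = revcomp(rec.seq)
                if rec.tir is not None:
                    rec.tir_seq = rec.seq[:rec.tir.arm_len]
            rec.breakpoint = bp
            rec.mite_partner = p.record_id
            mc = mites.classify_microhomology(p.seq, bp, min_micro=cfg.min_micro,
                                              near_window=cfg.micro_near_window)
            rec.micro_type = mc.micro_type
    complete_len: dict[str, int | None] = {}
    for lid, members in by_lineage.items():
        lens = [r.element_length for r in members
                if r.n_tirs == 2 and orf_ok(r) and r.breakpoint is None]
        complete_len[lid] = max(lens) if lens else None
    for rec in retained:
        if rec.n_tirs == 2 and rec.breakpoint is not None:
            rec.completeness = "deleted"
            rec.potentially_active = False
            continue
        hth = rec.domains.hth is not None if rec.domains else False
        call = transposase.classify_completeness(
            rec.n_tirs, rec.element_length, complete_len[rec.lineage],
            rec.orf, rec.triad, hth)
        rec.completeness = call.cls
        rec.potentially_active = call.potentially_active

    # 7. UPGM-VM classification
    dendro = None
    if len(retained) >= 2:
        dendro = lineages.upgm_vm_classify(
            sorted(((r.record_id, r.seq) for r in retained), key=lambda t: t[0]))

    # 8. MITE sublineages
    mite_cands = [r for r in retained if r.completeness == "deleted"]
    mite_rows = [{
        "id": rec.record_id, "tir_seq": rec.tir_seq,
        "partner": rec.mite_partner or "orphan",
        "del_start": rec.breakpoint.del_start if rec.breakpoint else None,
        "del_end": rec.breakpoint.del_end if rec.breakpoint else None,
    } for rec in sorted(mite_cands, key=lambda r: r.record_id)]
    subs = mites.assign_mite_sublineages(mite_rows, tir_min_id=cfg.mite_tir_id,
                                         bp_tol=cfg.mite_bp_tol)
    sub_of = {m: s for s in subs for m in s.members}
    for rec in mite_cands:
        s = sub_of.get(rec.record_id)
        if s is not None and s.is_mite:
            rec.mite_sublineage = s.id
    counts["mite_sublineages"] = sum(1 for s in subs if s.is_mite)

    # 9. consensus-divergence dating of sublineages
    ages = []
    rec_by_id = {r.record_id: r for r in retained}
    for s in subs:
        if not s.is_mite:
            continue
        est = evolution.identity_to_consensus(
            s.id, [(m, rec_by_id[m].seq) for m in s.members])
        ages.append(est)
        for m in s.members:
            rec_by_id[m].age_class = est.age_class
    counts["copies"] = len(retained)

    catalog = _catalog_frame(retained, species)
    summary = summarize_catalog(catalog)
    result = PipelineResult(catalog, retained, lins, dendro, subs, ages,
                            rejections, counts, summary)
    if out_dir is not None:
        _write_outputs(result, hits, loci, cfg, Path(out_dir))
    return result


def _annotate_orf(rec: ElementRecord, cfg: PipelineConfig,
                  triad_panel: list[RefTransposase]) -> None:
    if rec.n_tirs == 2 and rec.tir is not None:
        inner = rec.seq[rec.tir.arm_len:len(rec.seq) - rec.tir.arm_len]
    else:
        inner = rec.seq
    orf = transposase.find_orf(inner, min_orf_aa=cfg.min_orf_aa, panel=triad_panel)
    rec.orf = orf
    if orf is not None and orf.aa:
        rec.orf_aa = orf.aa
        rec.triad = transposase.map_catalytic_triad(orf.aa, triad_panel)
        rec.domains = transposase.annotate_domains(orf.aa)


def clade_label(rec: ElementRecord) -> str:
    if rec.triad is None:
        return "unresolved"
    prefix = "LTIR " if rec.tir is not None and rec.tir.arm_len >= 100 else ""
    return f"{prefix}{rec.triad.label}"


def _catalog_frame(records: list[ElementRecord], species: str) -> pd.DataFrame:
    rows = []
    for r in sorted(records, key=lambda x: (x.scaffold, x.start)):
        rows.append({
            "copy_id": r.record_id, "species": species, "scaffold": r.scaffold,
            "start": r.start, "end": r.end, "strand": r.strand,
            "length": r.element_length, "lineage": r.lineage,
            "clade": clade_label(r), "n_tirs": r.n_tirs,
            "tir_len": r.tir.arm_len if r.tir else 0,
            "tsd": r.tsd_present, "class": r.completeness,
            "potentially_active": r.potentially_active,
            "triad": r.triad.label if r.triad else "",
            "mite_sublineage": r.mite_sublineage, "micro_type": r.micro_type,
            "age_class": r.age_class,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summary


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_catalog(catalog: pd.DataFrame) -> dict:
    """Aggregate statistics of a catalog (counts and percentages).

    Percentages are reported half-up at two decimals with a one-decimal
    variant alongside.
    """
    if catalog.empty:
        return {"total_copies": 0, "per_species": {}, "lineages": 0,
                "per_class": {}, "pct_complete": 0.0, "pct_mite": 0.0}
    total = int(len(catalog))
    per_species = catalog.groupby("species").size().to_dict()
    per_class = catalog.groupby("class").size().to_dict() if "class" in catalog else {}
    n_complete = int((catalog["class"] == "complete").sum()) if "class" in catalog else 0
    if "mite_sublineage" in catalog:
        n_mite = int((catalog["mite_sublineage"] != "").sum())
    else:
        n_mite = 0
    n_lineages = catalog["lineage"].nunique() if "lineage" in catalog else 0
    per_clade = catalog.groupby("clade").size().to_dict() if "clade" in catalog else {}
    pct_complete = 100.0 * n_complete / total
    pct_mite = 100.0 * n_mite / total
    return {
        "total_copies": total,
        "per_species": {k: int(v) for k, v in per_species.items()},
        "lineages": int(n_lineages),
        "per_class": {k: int(v) for k, v in per_class.items()},
        "per_clade": {k: int(v) for k, v in per_clade.items()},
        "n_complete": n_complete,
        "n_mite": n_mite,
        "pct_complete": _round_half_up(pct_complete, 2),
        "pct_complete_1dp": _round_half_up(pct_complete, 1),
        "pct_mite": _round_half_up(pct_mite, 2),
        "pct_mite_1dp": _round_half_up(pct_mite, 1),
    }


def example_survey_catalog() -> pd.DataFrame:
    """Worked-example catalog mirroring a three-genome aphid survey.

    115 copies from the pea aphid, 45 from the Russian wheat aphid and
    23 from the green peach aphid (183 in all), of which 23 are complete
    potentially autonomous elements and 43 are MITEs.  Used to exercise
    the summary arithmetic at realistic proportions.
    """
    rows = []
    spec = [("A. pisum", 115, 10, 27), ("D. noxia", 45, 7, 10),
            ("M. persicae", 23, 6, 6)]
    i = 0
    for species, n, n_complete, n_mite in spec:
        for j in range(n):
            cls = "complete" if j < n_complete else "other"
            mite = f"sub{i}" if n_complete <= j < n_complete + n_mite else ""
            rows.append({"copy_id": f"c{i:03d}", "species": species,
                         "lineage": f"{species}-L{j % 7}", "clade": "",
                         "class": cls, "mite_sublineage": mite})
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output writers


def _write_outputs(result: PipelineResult, hits, loci, cfg: PipelineConfig,
                   out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([asdict(h) for h in hits]).to_csv(out_dir / "hits.tsv",
                                                   sep="\t", index=False)
    with open(out_dir / "loci.bed", "w") as fh:
        for lc in loci:
            fh.write(f"{lc.scaffold}\t{lc.ext_start}\t{lc.ext_end}\t"
                     f"{lc.locus_id}\t0\t.\n")
    result.catalog.to_csv(out_dir / "catalog.tsv", sep="\t", index=False)
    with open(out_dir / "elements.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sorted(result.records, key=lambda x: (x.scaffold, x.start)):
            attrs = (f"ID={r.record_id};class={r.completeness};"
                     f"lineage={r.lineage};tsd={r.tsd_present};"
                     f"active={str(r.potentially_active).lower()}")
            fh.write(f"{r.scaffold}\tmarinerscan\ttransposable_element\t"
                     f"{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n")
            if r.tir is not None:
                fh.write(f"{r.scaffold}\tmarinerscan\tterminal_inverted_repeat\t"
                         f"{r.start + 1}\t{r.start + r.tir.arm_len}\t.\t{r.strand}"
                         f"\t.\tParent={r.record_id}\n")
                fh.write(f"{r.scaffold}\tmarinerscan\tterminal_inverted_repeat\t"
                         f"{r.end - r.tir.arm_len + 1}\t{r.end}\t.\t{r.strand}"
                         f"\t.\tParent={r.record_id}\n")
    if result.dendrogram is not None:
        (out_dir / "classification.nwk").write_text(result.dendrogram.newick() + "\n")
    lin_rows = [{"lineage": l.id, "representative": l.representative,
                 "n_members": len(l.members), "members": ",".join(l.members)}
                for l in result.lineages]
    pd.DataFrame(lin_rows).to_csv(out_dir / "lineages.tsv", sep="\t", index=False)
    mite_rows = [{"sublineage": s.id, "partner": s.partner,
                  "del_start": s.del_start, "del_end": s.del_end,
                  "n_members": len(s.members), "is_mite": s.is_mite,
                  "members": ",".join(s.members)} for s in result.sublineages]
    pd.DataFrame(mite_rows).to_csv(out_dir / "mites.tsv", sep="\t", index=False)
    age_rows = [{"sublineage": a.sublineage, "mean_identity": round(a.mean_identity, 2),
                 "age_class": a.age_class} for a in result.ages]
    pd.DataFrame(age_rows).to_csv(out_dir / "ages.tsv", sep="\t", index=False)
    (out_dir / "summary.json").write_text(json.dumps(result.summary, indent=2))
    cfg.to_yaml(out_dir / "config.yaml")
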