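"""Translated homology search, locus building, retention filters."""

import numpy as np
import pytest

from marinerscan import mining, simulate as sim
from marinerscan._alignment import revcomp
from marinerscan.references import (back_translate, ddxd_panel, ddxe_panel,
                                    default_query_panel)


class TestSixFrameTranslate:
    def test_forward_frame(self):
        frames = mining.six_frame_translate("ATGGCC")
        assert frames[1] == "MA"

    def test_stop_symbol(self):
        frames = mining.six_frame_translate("ATGTAAGGG")
        assert frames[1] == "M*G"

    def test_minus_frame_holds_reverse_complement_reading(self):
        pep = "MKLVNPQW"
        coding = back_translate(pep)
        frames = mining.six_frame_translate(revcomp(coding))
        assert sum(pep in frames[f] for f in (-1, -2, -3)) == 1
        assert all(pep not in frames[f] for f in (1, 2, 3))

    def test_too_short(self):
        with pytest.raises(ValueError):
            mining.six_frame_translate("AT")


class TestTranslatedSearch:
    def test_exact_self_hit(self):
        panel = default_query_panel()
        qname = sorted(panel)[0]
        genome = {"s1": "ACGT" * 30 + back_translate(panel[qname]) + "TGCA" * 30}
        hits = mining.translated_search(genome, {qname: panel[qname]})
        assert hits
        best = max(hits, key=lambda h: h.score)
        assert best.pct_id == 100.0
        assert best.aln_len == len(panel[qname])

    def test_minus_strand_hit_interval_matches_truth(self, specs, macro_element):
        plan = sim.ImplantPlan([8000], [sim.Placement(
            0, 2500, "X", macro_element, strand="-", tir_len=28)], seed=11)
        genome, truth = sim.implant_genome(plan)
        hits = mining.translated_search(genome, default_query_panel())
        t = truth[0]
        minus = [h for h in hits if h.frame < 0]
        assert minus
        h = max(minus, key=lambda x: x.score)
        assert t.start <= h.start < h.end <= t.end

    def test_random_background_yields_no_hits(self):
        rng = np.random.default_rng(123)
        genome = {"bg": "".join(rng.choice(list("ACGT"), 100_000))}
        assert mining.translated_search(genome, default_query_panel()) == []

    def test_scaffold_order_invariance(self, macro_element):
        plan = sim.ImplantPlan([8000, 8000], [
            sim.Placement(0, 2500, "A", macro_element, tir_len=28),
            sim.Placement(1, 1500, "B", macro_element, tir_len=28)], seed=4)
        genome, _ = sim.implant_genome(plan)
        panel = default_query_panel()
        h1 = mining.translated_search(genome, panel)
        h2 = mining.translated_search(dict(reversed(list(genome.items()))), panel)
        assert h1 == h2

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            mining.translated_search({"s": "ACGTACGT"}, {})


class TestBuildLoci:
    def _hit(self, scaffold, start, end, frame=1, q="q", score=100.0):
        return mining.TranslatedHit(scaffold, start, end, frame, q, score, 90.0, 100)

    def test_nearby_hits_merge(self):
        hits = [self._hit("s", 10_000, 10_300), self._hit("s", 10_500, 10_800)]
        loci = mining.build_candidate_loci(hits, {"s": 50_000})
        assert len(loci) == 1
        assert (loci[0].core_start, loci[0].core_end) == (10_000, 10_800)

    def test_distant_hits_stay_separate(self):
        hits = [self._hit("s", 10_000, 10_300), self._hit("s", 20_000, 20_300)]
        assert len(mining.build_candidate_loci(hits, {"s": 50_000})) == 2

    def test_clipping_sets_scaffold_end_flag(self):
        hits = [self._hit("s", 2000, 2300)]
        (locus,) = mining.build_candidate_loci(hits, {"s": 50_000})
        assert locus.ext_start == 0
        assert locus.at_scaffold_end

    def test_hits_on_different_scaffolds_make_distinct_loci(self):
        hits = [self._hit("a", 10_000, 10_300), self._hit("b", 10_000, 10_300)]
        loci = mining.build_candidate_loci(hits, {"a": 50_000, "b": 50_000})
        assert {l.scaffold for l in loci} == {"a", "b"}


class _Rec:
    def __init__(self, rid, length, n_tirs=2, at_end=False, orf_aa=""):
        self.record_id = rid
        self.element_length = length
        self.n_tirs = n_tirs
        self.at_scaffold_end = at_end
        self.orf_aa = orf_aa


class TestFilterCandidates:
    def test_min_length_is_strict_less_than(self):
        recs = [_Rec("a", 249), _Rec("b", 250)]
        kept, dec = mining.filter_candidates(recs)
        assert [r.record_id for r in kept] == ["b"]
        assert dec["a"].reason == "min_length"

    def test_truncated_at_scaffold_end_discarded(self):
        recs = [_Rec("a", 800, n_tirs=1, at_end=True),
                _Rec("b", 800, n_tirs=1, at_end=False)]
        kept, dec = mining.filter_candidates(recs)
        assert [r.record_id for r in kept] == ["b"]
        assert dec["a"].reason == "scaffold_end_truncated"

    def test_ddxe_like_transposase_excluded(self):
        e_ref = ddxe_panel()[0]
        d_ref = ddxd_panel()[0]
        kept, dec = mining.filter_candidates(
            [_Rec("tc1", 1500, orf_aa=e_ref.aa), _Rec("mar", 1500, orf_aa=d_ref.aa)])
        assert dec["tc1"].reason == "DDxE"
        assert dec["mar"].retained
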