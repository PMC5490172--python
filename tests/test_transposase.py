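"""ORF finding, catalytic-triad labelling, domain heuristics, completeness."""

import pytest

from marinerscan import simulate as sim, transposase as tp
from marinerscan._alignment import revcomp
from marinerscan.references import (FAMILY_LENGTHS, default_reference_panel,
                                    make_lineage_transposase,
                                    make_transposase_aa)

PANEL = default_reference_panel()


def _internal(spec):
    elem = sim.build_autonomous_element(spec)
    t = len(spec.tir_seq)
    return elem, elem[t:-t]


class TestFindOrf:
    def test_intact_element_orf_length(self, specs):
        _, internal = _internal(specs["Macromar1"])
        orf = tp.find_orf(internal, panel=PANEL)
        assert orf is not None
        assert len(orf.aa) == 354
        assert not orf.has_internal_stop
        assert orf.strand == "+"

    def test_planted_stop_marks_interrupted_reading(self, specs):
        spec = specs["Macromar1"]
        elem = sim.build_autonomous_element(spec)
        s, e = sim.orf_region_of(spec)
        dead = elem[:s + 600] + "TAA" + elem[s + 603:]
        orf = tp.find_orf(dead[28:-28], panel=PANEL)
        assert orf is not None
        assert orf.has_internal_stop

    def test_minus_strand_reported(self, specs):
        _, internal = _internal(specs["Macromar1"])
        orf = tp.find_orf(revcomp(internal), panel=PANEL)
        assert orf.strand == "-"

    def test_short_region_returns_none(self):
        assert tp.find_orf("ACGT" * 50) is None


class TestTriad:
    @pytest.mark.parametrize("family", ["DD34D", "DD37D", "DD40D", "DD41D",
                                        "DD34E"])
    def test_family_labels_exact(self, family):
        aa, triad = make_lineage_transposase(family, f"probe-{family}",
                                             length=FAMILY_LENGTHS[family])
        call = tp.map_catalytic_triad(aa, PANEL)
        assert call is not None
        assert call.label == family
        assert call.positions == triad
        assert call.residues[:2] == ("D", "D")

    def test_spacing_is_strictly_between(self):
        aa, (d1, d2, d3) = make_transposase_aa("DD34D")
        call = tp.map_catalytic_triad(aa, PANEL)
        assert call.spacing23 == d3 - d2 - 1 == 34

    def test_mutated_catalytic_residue_unresolved(self):
        aa, (d1, d2, d3) = make_transposase_aa("DD34D")
        broken = aa[:d2] + "A" + aa[d2 + 1:]
        assert tp.map_catalytic_triad(broken, PANEL) is None

    def test_empty_query(self):
        assert tp.map_catalytic_triad("", PANEL) is None


class TestDomains:
    def test_designed_domains_found(self, specs):
        spec = specs["Macromar1"]
        dom = tp.annotate_domains(spec.orf_aa)
        assert dom.wvphel is not None and dom.wvphel.mismatches == 0
        assert dom.yspdla is not None
        assert dom.nls_present
        # helix-turn-helix in the N-terminal DNA-binding region
        assert dom.hth == (87, 108)

    def test_polya_site_positions(self):
        aa, _ = make_transposase_aa("DD34D")
        dom = tp.annotate_domains(aa, utr5="", utr3="GG" + "AATAAA" + "CC")
        assert dom.polya_sites == [3]

    def test_hth_absent_when_not_designed(self):
        aa, _ = make_transposase_aa("DD34D", with_hth=False)
        dom = tp.annotate_domains(aa)
        assert dom.hth is None

    def test_nls_absent_when_not_designed(self):
        aa, _ = make_transposase_aa("DD34D", with_nls=False)
        assert not tp.annotate_domains(aa).nls_present

    def test_positions_stable_under_utr_changes(self, specs):
        spec = specs["Macromar1"]
        d1 = tp.annotate_domains(spec.orf_aa, utr5="A" * 10)
        d2 = tp.annotate_domains(spec.orf_aa, utr5="A" * 500)
        assert d1.hth == d2.hth
        assert d1.wvphel.position == d2.wvphel.position


class TestCompleteness:
    def _orf(self, stop=False, fs=False, cov=0.8):
        return tp.ORFRecord(0, 1000, "+", "M" * 300, stop, fs, cov)

    def test_intact_full_length_complete_and_active(self):
        call = tp.classify_completeness(2, 1500, 1500, self._orf(),
                                        triad=object(), hth_present=True)
        assert call.cls == "complete"
        assert call.potentially_active

    def test_stop_makes_dead_never_active(self):
        call = tp.classify_completeness(2, 1500, 1500, self._orf(stop=True),
                                        triad=object(), hth_present=True)
        assert call.cls == "dead"
        assert not call.potentially_active

    def test_single_tir_is_truncated(self):
        call = tp.classify_completeness(1, 800, 1500, self._orf(), None, False)
        assert call.cls == "truncated"

    def test_short_copy_without_orf_is_deleted(self):
        call = tp.classify_completeness(2, 500, 1500, None, None, False)
        assert call.cls == "deleted"

    def test_active_monotone_in_stops(self):
        # adding a stop can never turn potentially_active on
        for triad, hth in [(object(), True), (None, True), (object(), False)]:
            clean = tp.classify_completeness(2, 1500, 1500, self._orf(),
                                             triad, hth)
            broken = tp.classify_completeness(2, 1500, 1500,
                                              self._orf(stop=True), triad, hth)
            assert broken.potentially_active <= clean.potentially_active
            assert not broken.potentially_active
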