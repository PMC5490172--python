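"""Synthetic-genome generator: element assembly, derivatives, implantation."""

import numpy as np
import pytest

from marinerscan import simulate as sim
from marinerscan._alignment import align_gap5, revcomp
from marinerscan.mites import best_shared_repeat, call_deletion_breakpoints
from marinerscan.references import make_transposase_aa


class TestBuildElement:
    def test_tir_at_both_ends(self, specs, macro_element):
        tir = specs["Macromar1"].tir_seq
        assert len(tir) == 28
        assert macro_element[:28] == tir
        assert macro_element[-28:] == revcomp(tir)

    def test_length_bookkeeping_empty_utrs(self):
        aa, triad = make_transposase_aa("DD34D", length=310)
        spec = sim.ElementSpec("bare", "CGAGGCGTGTCCAG", 0, 0, aa, (90, 34),
                               family_label="DD34D", triad_positions=triad)
        elem = sim.build_autonomous_element(spec)
        assert len(elem) == 2 * 14 + 3 * (310 + 1)

    def test_long_tir_element_exceeds_2_3_kb(self, specs):
        elem = sim.build_autonomous_element(specs["Ltirmar1"])
        assert len(specs["Ltirmar1"].tir_seq) == 460
        assert len(elem) > 2300

    def test_short_tir_rejected(self):
        with pytest.raises(ValueError):
            sim.ElementSpec("x", "ACGTACGT", 0, 0, "M" * 210, (90, 34))


class TestDeletionDerivative:
    def test_length_and_intact_tirs(self, planted_macro):
        parent, (ds, de) = planted_macro
        mite = sim.derive_deletion_derivative(parent, ds, de, micro="BPEE",
                                              tir_len=28)
        assert len(mite) == len(parent) - (de - ds)
        assert mite[:28] == parent[:28]
        assert mite[-28:] == parent[-28:]

    def test_bpee_junction_recovered_by_breakpoint_caller(self, planted_macro):
        # re-align the derivative to the parent: the caller must recover
        # exactly the planted interval, whose edges carry the direct repeat
        parent, (ds, de) = planted_macro
        mite = sim.derive_deletion_derivative(parent, ds, de, micro="BPEE",
                                              tir_len=28)
        bp = call_deletion_breakpoints(mite, parent, "p")
        assert (bp.del_start, bp.del_end) == (ds, de)
        rep_len = 5
        assert parent[ds:ds + rep_len] == parent[de:de + rep_len]
        # exactly one copy survives in the derivative at the junction
        assert mite[ds:ds + rep_len] == parent[de:de + rep_len]

    def test_none_micro_has_no_shared_repeat(self, specs):
        parent, (ds, de) = sim._planted_parent(specs["Macromar1"], "none", seed=3)
        w1, w2 = parent[ds:ds + 22], parent[de:de + 22]
        assert best_shared_repeat(w1, w2, near_window=10, min_micro=3) is None

    def test_deletion_overlapping_tir_rejected(self, macro_element):
        with pytest.raises(ValueError):
            sim.derive_deletion_derivative(macro_element, 10, 400, tir_len=28)


class TestMutateCopy:
    def test_zero_rates_identity(self, macro_element):
        assert sim.mutate_copy(macro_element, 0.0, 0.0, seed=1) == macro_element

    def test_deterministic(self, macro_element):
        a = sim.mutate_copy(macro_element, 0.05, 0.01, seed=42)
        b = sim.mutate_copy(macro_element, 0.05, 0.01, seed=42)
        assert a == b

    def test_divergence_matches_binomial_expectation(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), 1000))
        idents = [align_gap5(base, sim.mutate_copy(base, 0.03, 0.0, seed=s)).identity
                  for s in range(100)]
        mean = float(np.mean(idents))
        # E[identity] = 97%; 3 sigma of the replicate mean is well inside
        assert 95.5 <= mean <= 98.5

    def test_keep_orf_preserves_reading(self, specs):
        spec = specs["Macromar1"]
        elem = sim.build_autonomous_element(spec)
        orf = sim.orf_region_of(spec)
        # substitutions only: coordinates fixed, reading must stay stop-free
        out = sim.mutate_copy(elem, 0.08, 0.0, seed=9, keep_orf=orf)
        assert len(out) == len(elem)
        assert sim._orf_intact(out, orf)
        # indels only: the protected ORF block survives verbatim
        out = sim.mutate_copy(elem, 0.0, 0.02, seed=9, keep_orf=orf)
        assert elem[orf[0]:orf[1]] in out

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            sim.mutate_copy("ACGT", 0.9, 0.0, seed=0)


class TestImplantGenome:
    def test_tsd_flanks_planted_copy(self, macro_element):
        plan = sim.ImplantPlan([6000], [sim.Placement(0, 2000, "X", macro_element,
                                                      tir_len=28)], seed=5)
        genome, truth = sim.implant_genome(plan)
        t = truth[0]
        s = genome[t.scaffold]
        assert s[t.start - 2:t.start] == "TA"
        assert s[t.end:t.end + 2] == "TA"
        assert s[t.start:t.end] == macro_element
        assert (t.tsd_start, t.tsd_end) == (t.start - 2, t.end + 2)

    def test_left_truncated_copy_lacks_left_tir(self, macro_element):
        plan = sim.ImplantPlan([6000], [sim.Placement(
            0, 0, "T", macro_element, truncation="left", trunc_len=600,
            planted_class="truncated")], seed=5)
        genome, truth = sim.implant_genome(plan)
        t = truth[0]
        assert t.planted_class == "truncated"
        assert t.start == 0  # no left TSD either
        assert genome[t.scaffold][t.start:t.start + 28] != macro_element[:28]

    def test_empty_plan(self):
        genome, truth = sim.implant_genome(sim.ImplantPlan([500], [], seed=1))
        assert truth == []
        assert len(genome["scaffold_1"]) == 500

    def test_overlapping_placements_rejected(self, macro_element):
        plan = sim.ImplantPlan([6000], [
            sim.Placement(0, 100, "A", macro_element),
            sim.Placement(0, 300, "B", macro_element)], seed=1)
        with pytest.raises(ValueError):
            sim.implant_genome(plan)

    def test_n_truncation_marks_element(self, macro_element):
        plan = sim.ImplantPlan([6000], [sim.Placement(
            0, 2000, "N", macro_element, truncation="N", trunc_len=120,
            planted_class="N-truncated", tir_len=28)], seed=5)
        genome, truth = sim.implant_genome(plan)
        t = truth[0]
        assert "N" * 120 in genome[t.scaffold][t.start:t.end]


def test_study_plan_composition():
    plan = sim.study_plan(seed=0)
    classes = [p.planted_class for p in plan.placements]
    assert len(classes) == 30
    assert classes.count("complete") == 16
    assert classes.count("deleted") == 10
    assert classes.count("truncated") == 4
    genome, truth = sim.implant_genome(plan)
    assert len(truth) == 30
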