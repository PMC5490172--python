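"""TIR pair and TSD detection, structural properties of arms."""

import numpy as np
import pytest

from marinerscan import boundaries, simulate as sim
from marinerscan._alignment import revcomp


def _locus_for(element, flank=1500, seed=7, tsd=True):
    """Element embedded in random background, TA-duplicated if tsd."""
    rng = np.random.default_rng(seed)
    bg = lambda n: "".join(rng.choice(list("ACGT"), n))
    t = "TA" if tsd else ""
    left = bg(flank)
    seq = left + t + element + t + bg(flank)
    start = len(left) + len(t)
    return seq, start, start + len(element)


class TestDetectTir:
    def test_exact_recovery_of_table_style_arm(self, specs, macro_element):
        tir = specs["Macromar1"].tir_seq
        locus, es, ee = _locus_for(macro_element)
        # homology core = the ORF region, inside the element
        found = boundaries.detect_tir(locus, es + 400, ee - 400)
        assert found is not None
        assert found.arm_len == 28
        assert found.left_seq == tir
        assert found.identity == 100.0
        assert (found.left_start, found.right_end) == (es, ee)

    def test_random_sequence_has_no_tir(self):
        rng = np.random.default_rng(99)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        assert boundaries.detect_tir(seq, 800, 1200) is None

    def test_long_arm_recovered_within_tolerance_under_divergence(self, specs):
        elem = sim.build_autonomous_element(specs["Ltirmar1"])
        errs = []
        for s in range(5):
            mutated = sim.mutate_copy(elem, 0.03, 0.0, seed=s)
            locus, es, ee = _locus_for(mutated, seed=100 + s)
            found = boundaries.detect_tir(locus, es + 700, ee - 700)
            assert found is not None
            errs.append(abs(found.arm_len - 460))
        assert max(errs) <= 10

    def test_strand_symmetry(self, macro_element):
        locus, es, ee = _locus_for(macro_element)
        fwd = boundaries.detect_tir(locus, es + 400, ee - 400)
        rc = revcomp(locus)
        n = len(locus)
        rev = boundaries.detect_tir(rc, n - (ee - 400), n - (es + 400))
        assert fwd is not None and rev is not None
        assert rev.arm_len == fwd.arm_len
        assert (rev.left_start, rev.right_end) == (n - fwd.right_end,
                                                   n - fwd.left_start)

    def test_arm_identity_symmetric(self, macro_element):
        locus, es, ee = _locus_for(macro_element)
        found = boundaries.detect_tir(locus, es + 400, ee - 400)
        arm = found.left_seq
        other = revcomp(locus[found.right_start:found.right_end])
        matches = sum(1 for a, b in zip(arm, other) if a == b)
        assert found.identity == pytest.approx(100.0 * matches / len(arm))


class TestDetectTsd:
    def test_planted_element_has_tsd(self, macro_element):
        locus, es, ee = _locus_for(macro_element)
        found = boundaries.detect_tir(locus, es + 400, ee - 400)
        assert boundaries.detect_tsd(locus, found) == "yes"

    def test_mismatched_flank_is_no(self, macro_element):
        locus, es, ee = _locus_for(macro_element)
        found = boundaries.detect_tir(locus, es + 400, ee - 400)
        broken = locus[:found.left_start - 2] + "TG" + locus[found.left_start:]
        assert boundaries.detect_tsd(broken, found) == "no"

    def test_scaffold_edge_is_indeterminate(self, macro_element):
        locus, es, ee = _locus_for(macro_element)
        found = boundaries.detect_tir(locus, es + 400, ee - 400)
        clipped = locus[found.left_start:]
        shifted = boundaries.detect_tir(clipped, es + 400 - found.left_start,
                                        ee - 400 - found.left_start)
        assert boundaries.detect_tsd(clipped, shifted) == "indeterminate"


class TestStructureProps:
    def test_mirror_repeat_detected(self):
        palindrome, mirrors = boundaries.tir_structure_props("CAATAAAATAAC")
        assert not palindrome
        assert mirrors
        s, e, sub = mirrors[0]
        assert sub == sub[::-1]
        assert sub == "CAATAAAATAAC"

    def test_even_palindrome(self):
        assert boundaries.tir_structure_props("GAATTC")[0] is True

    def test_non_palindrome(self):
        assert boundaries.tir_structure_props("ACGTAC")[0] is False

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            boundaries.tir_structure_props("")

    def test_mirror_motif_inside_real_arm(self, specs):
        # the Batmar-style arm contains a planted mirror motif
        _, mirrors = boundaries.tir_structure_props(specs["Batmar1"].tir_seq)
        assert any("CAATAAAATAAC" in sub for _s, _e, sub in mirrors)
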