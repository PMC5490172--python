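"""Deletion breakpoints, microhomology typing, MITE sublineages."""

import numpy as np
import pytest

from marinerscan import mites, simulate as sim


class TestBreakpoints:
    def test_noise_free_recovery_is_exact(self, planted_macro):
        parent, (ds, de) = planted_macro
        mite = sim.derive_deletion_derivative(parent, ds, de, micro="BPEE",
                                              tir_len=28)
        bp = mites.call_deletion_breakpoints(mite, parent, "p")
        assert bp is not None
        assert (bp.del_start, bp.del_end) == (ds, de)
        assert bp.flank_identity == pytest.approx(100.0)

    def test_diverged_recovery_within_tolerance(self, specs):
        errs = []
        for s in range(20):
            parent, (ds, de) = sim._planted_parent(specs["Macromar1"], "BPEE",
                                                   seed=s)
            mite = sim.derive_deletion_derivative(parent, ds, de, micro="BPEE",
                                                  tir_len=28)
            mutated = sim.mutate_copy(mite, 0.05, 0.0, seed=1000 + s)
            bp = mites.call_deletion_breakpoints(mutated, parent, "p")
            assert bp is not None
            errs.append(max(abs(bp.del_start - ds), abs(bp.del_end - de)))
        assert sorted(errs)[int(0.9 * len(errs))] <= 5

    def test_unrelated_sequence_yields_none(self, planted_macro):
        parent, _ = planted_macro
        rng = np.random.default_rng(2)
        stranger = "".join(rng.choice(list("ACGT"), 600))
        assert mites.call_deletion_breakpoints(stranger, parent, "p") is None

    def test_partner_must_be_longer(self, planted_macro):
        parent, _ = planted_macro
        assert mites.call_deletion_breakpoints(parent, parent, "p") is None


class TestMicrohomology:
    @pytest.mark.parametrize("micro,expected_offsets", [
        ("BPEE", (0, 0)),
        ("BPNN", (2, 3)),
    ])
    def test_planted_types_called(self, specs, micro, expected_offsets):
        parent, (ds, de) = sim._planted_parent(specs["Macromar1"], micro,
                                               seed=7)
        mite = sim.derive_deletion_derivative(parent, ds, de, micro=micro,
                                              tir_len=28)
        bp = mites.call_deletion_breakpoints(mite, parent, "p")
        call = mites.classify_microhomology(parent, bp)
        assert call.micro_type == micro
        assert call.offsets == expected_offsets
        assert call.length >= 3

    def test_scrubbed_windows_have_no_microhomology(self, specs):
        parent, (ds, de) = sim._planted_parent(specs["Macromar1"], "none",
                                               seed=7)
        mite = sim.derive_deletion_derivative(parent, ds, de, tir_len=28)
        bp = mites.call_deletion_breakpoints(mite, parent, "p")
        call = mites.classify_microhomology(parent, bp)
        assert call.micro_type == "none"

    def test_equal_offsets_reanchor_to_bpee(self, specs):
        parent, (ds, de) = sim._planted_parent(specs["Macromar1"], "BPEE",
                                               seed=9)
        mite = sim.derive_deletion_derivative(parent, ds, de, micro="BPEE",
                                              tir_len=28)
        bp = mites.call_deletion_breakpoints(mite, parent, "p")
        shifted = mites.DeletionBreakpoint(bp.partner_id, bp.del_start - 2,
                                           bp.del_end - 2, bp.junction,
                                           bp.flank_identity, [])
        call = mites.classify_microhomology(parent, shifted)
        assert call.micro_type == "BPEE"
        assert call.offsets == (0, 0)


class TestSublineages:
    def _mite(self, rid, tir, partner="P1", ds=100, de=500):
        return {"id": rid, "tir_seq": tir, "partner": partner,
                "del_start": ds, "del_end": de}

    def test_shared_breakpoint_groups(self):
        tir = "CGAGGCGTGTCCAGAAAGTAAGTGTACT"
        rows = [self._mite(f"m{i}", tir) for i in range(5)]
        subs = mites.assign_mite_sublineages(rows)
        assert len(subs) == 1
        assert subs[0].is_mite
        assert len(subs[0].members) == 5

    def test_distinct_breakpoints_split(self):
        tir = "CGAGGCGTGTCCAGAAAGTAAGTGTACT"
        rows = ([self._mite(f"a{i}", tir, ds=100, de=500) for i in range(2)]
                + [self._mite(f"b{i}", tir, ds=300, de=700) for i in range(2)])
        subs = mites.assign_mite_sublineages(rows)
        assert len(subs) == 2
        assert all(s.is_mite for s in subs)

    def test_singleton_flagged_not_mite(self):
        subs = mites.assign_mite_sublineages(
            [self._mite("solo", "CGAGGCGTGTCCAGAAAGTAAGTGTACT")])
        assert len(subs) == 1
        assert not subs[0].is_mite

    def test_order_invariance(self):
        tir1 = "CGAGGCGTGTCCAGAAAGTAAGTGTACT"
        tir2 = "AATGTGTCAAACTTCTAGAGGTGTTTCT"
        rows = ([self._mite(f"x{i}", tir1) for i in range(3)]
                + [self._mite(f"y{i}", tir2, partner="P2") for i in range(2)])
        a = mites.assign_mite_sublineages(rows)
        b = mites.assign_mite_sublineages(list(reversed(rows)))
        assert sorted(sorted(s.members) for s in a) == \
            sorted(sorted(s.members) for s in b)

    def test_every_mite_has_two_members_minimum(self):
        rows = [self._mite(f"m{i}", "CGAGGCGTGTCCAGAAAGTAAGTGTACT")
                for i in range(4)] + [self._mite("solo", "TTTTTTTTTTGGGGGGGG")]
        for s in mites.assign_mite_sublineages(rows):
            assert s.is_mite == (len(s.members) >= 2)
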