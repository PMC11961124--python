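"""Cysteine census, disulfide detection, titration and activity arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import exhaustive_disulfide_pairs
from redoxstruct.redox import (cysteine_report, detect_disulfides,
                               dtnb_stoichiometry, reconcile_titration,
                               specific_activity)
from redoxstruct.sasa import shrake_rupley
from redoxstruct.structio import AtomRecord, Residue, Structure
from redoxstruct.synthetic_data import CysPlacement, make_toy_structure


def _cys_constellation(positions):
    """A bare structure whose CYS residues carry only SG atoms."""
    s = Structure(id="sgs")
    residues = []
    for i, pos in enumerate(positions):
        residues.append(Residue(
            chain_id="A", number=i + 1, insertion_code="", name="CYS",
            atoms=[AtomRecord(i + 1, "SG", "S", "", 1.0, 0.0,
                              np.asarray(pos, float))]))
    s.chains["A"] = residues
    return s


class TestDetectDisulfides:
    def test_planted_bond_found(self):
        s = make_toy_structure(cys_placements=[
            CysPlacement("A", 105, partner=("A", 106), distance=2.05)])
        assert detect_disulfides(s) == [(("A", 105), ("A", 106))]

    def test_separation_beyond_cutoff_yields_nothing(self):
        s = _cys_constellation([[0, 0, 0], [2.6, 0, 0]])
        assert detect_disulfides(s, bond_cutoff=2.3) == []

    def test_matches_exhaustive_oracle_on_random_constellations(self, rng):
        for _ in range(200):
            n = rng.integers(2, 12)
            pos = rng.uniform(0, 12, (n, 3))
            s = _cys_constellation(pos)
            got = detect_disulfides(s, bond_cutoff=3.0)
            sites = [((r.chain_id, r.number), r.atom("SG").position)
                     for r in s.chain("A")]
            assert got == exhaustive_disulfide_pairs(sites, 3.0)
            # partner uniqueness
            flat = [x for p in got for x in p]
            assert len(flat) == len(set(flat))

    def test_no_cysteines_empty(self):
        s = make_toy_structure(residues_per_chain=5)
        assert detect_disulfides(s) == []

    def test_nonpositive_cutoff_rejected(self, two_chain_toy):
        with pytest.raises(ValueError):
            detect_disulfides(two_chain_toy, bond_cutoff=0.0)


class TestCysteineReport:
    def test_studied_constellation_classes(self, redox_constellation,
                                           redox_constellation_sasa):
        rep = cysteine_report(redox_constellation, redox_constellation_sasa)
        assert len(rep.entries) == 10
        assert rep.disulfide_pairs() == [(("A", 115), ("A", 120))]
        by_class = {}
        for e in rep.entries:
            by_class.setdefault(e.cysteine_class, set()).add(e.number)
        assert by_class["disulfide"] == {115, 120}
        assert by_class["exposed_free"] == {149, 153, 231, 355}
        assert by_class["buried_free"] == {169, 222, 340, 362}
        assert rep.predicted_reactive() == 4

    def test_class_partition_is_exhaustive(self, redox_constellation,
                                           redox_constellation_sasa):
        rep = cysteine_report(redox_constellation, redox_constellation_sasa)
        s = rep.summary
        assert (s["disulfide"] + s["exposed_free"] + s["buried_free"]
                + s["unresolved"]) == s["total"]

    def test_exchange_tiers_as_constructed(self):
        # free pair at 4.0 Å (direct tier) and a thiol 9 Å away
        # (rearrangement tier)
        s = make_toy_structure(
            residues_per_chain=30,
            cys_placements=[
                CysPlacement("A", 105, partner=("A", 106), distance=4.0),
                CysPlacement("A", 109, partner=("A", 110), distance=9.0),
            ])
        t = shrake_rupley(s)
        rep = cysteine_report(s, t)
        e105 = next(e for e in rep.entries if e.number == 105)
        tiers = {tuple(c["partner"]): c["tier"] for c in e105.exchange_candidates}
        assert tiers[("A", 106)] == "direct"
        e109 = next(e for e in rep.entries if e.number == 109)
        tiers109 = {tuple(c["partner"]): c["tier"]
                    for c in e109.exchange_candidates}
        assert tiers109[("A", 110)] == "rearrangement"

    def test_cysteine_free_structure_empty_report(self):
        s = make_toy_structure(residues_per_chain=6)
        t = shrake_rupley(s)
        rep = cysteine_report(s, t)
        assert rep.entries == []
        assert rep.predicted_reactive() == 0

    def test_mismatched_sasa_table_rejected(self, redox_constellation):
        other = make_toy_structure(residues_per_chain=5)
        t = shrake_rupley(other)
        with pytest.raises(ValueError, match="SASA table"):
            cysteine_report(redox_constellation, t)

    def test_missing_sg_flagged_unresolved(self, redox_constellation_sasa,
                                           redox_constellation):
        import copy
        s = copy.deepcopy(redox_constellation)
        res = s.residue("A", 149)
        res.atoms = [a for a in res.atoms if a.name != "SG"]
        rep = cysteine_report(s, redox_constellation_sasa)
        e = next(e for e in rep.entries if e.number == 149)
        assert e.cysteine_class == "unresolved"
        assert rep.predicted_reactive() == 3


class TestTitration:
    def test_worked_example_four_thiols(self):
        r = dtnb_stoichiometry(A412=0.283, path_length=1.0,
                               protein_conc=0.005, epsilon=14.15)
        assert r.thiols_per_monomer == pytest.approx(4.0)

    def test_zero_absorbance_zero_thiols(self):
        assert dtnb_stoichiometry(0.0, 1.0, 0.01).thiols_per_monomer == 0.0

    @given(a=st.floats(0.001, 2.0), l=st.floats(0.1, 5.0),
           c=st.floats(1e-4, 1.0), eps=st.floats(1.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_exact_linearity_in_all_arguments(self, a, l, c, eps):
        base = dtnb_stoichiometry(a, l, c, eps).thiols_per_monomer
        assert dtnb_stoichiometry(2 * a, l, c, eps).thiols_per_monomer == \
            pytest.approx(2 * base, rel=1e-12)
        assert dtnb_stoichiometry(a, 2 * l, c, eps).thiols_per_monomer == \
            pytest.approx(base / 2, rel=1e-12)
        assert dtnb_stoichiometry(a, l, 2 * c, eps).thiols_per_monomer == \
            pytest.approx(base / 2, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            dtnb_stoichiometry(0.1, 1.0, 0.0)
        with pytest.raises(ValueError):
            dtnb_stoichiometry(0.1, 0.0, 0.01)


class TestReconcileTitration:
    def _report(self, n_exposed):
        placements = [CysPlacement("A", 105 + i) for i in range(n_exposed)]
        s = make_toy_structure(residues_per_chain=20,
                               cys_placements=placements)
        return cysteine_report(s, shrake_rupley(s))

    def test_matching_count_is_consistent(self, redox_constellation,
                                          redox_constellation_sasa):
        rep = cysteine_report(redox_constellation, redox_constellation_sasa)
        verdict = reconcile_titration(rep, measured=4.0, sd=0.6)
        assert verdict["verdict"] == "consistent"
        assert verdict["predicted_reactive"] == 4

    def test_gross_mismatch_is_inconsistent(self):
        rep = self._report(8)
        assert reconcile_titration(rep, 4.0, 0.6)["verdict"] == "inconsistent"

    def test_within_two_sd_is_consistent(self):
        rep = self._report(3)
        assert reconcile_titration(rep, 4.0, 0.6)["verdict"] == "consistent"

    def test_negative_sd_rejected(self):
        rep = self._report(1)
        with pytest.raises(ValueError):
            reconcile_titration(rep, 4.0, -0.1)


class TestSpecificActivity:
    def test_worked_example(self):
        r = specific_activity(dA340_per_min=0.0622, epsilon_NADPH=6.22,
                              path_length=1.0, assay_volume=1.0,
                              enzyme_mass=0.001)
        assert r.specific_activity == pytest.approx(10.0)

    def test_zero_slope_zero_activity(self):
        assert specific_activity(0.0, enzyme_mass=0.01).specific_activity == 0.0

    def test_halving_mass_doubles_activity(self):
        a1 = specific_activity(0.1, enzyme_mass=0.002).specific_activity
        a2 = specific_activity(0.1, enzyme_mass=0.001).specific_activity
        assert a2 == pytest.approx(2 * a1)

    def test_negative_slope_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            r = specific_activity(-0.5, enzyme_mass=0.001)
        assert r.specific_activity == 0.0

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            specific_activity(0.1, enzyme_mass=0.0)
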