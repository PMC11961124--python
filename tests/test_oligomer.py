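"""Interfaces, assemblies, SEC calibration/deconvolution, mass and ε280."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import least_squares_line, monte_carlo_buried_area
from redoxstruct.oligomer import (apparent_mass, buried_area, deconvolve,
                                  detect_assemblies, elution_volume,
                                  mass_extinction, repartition, sec_calibrate)
from redoxstruct.sasa import DEFAULT_VDW_RADII
from redoxstruct.structio import Chromatogram
from redoxstruct.synthetic_data import make_chromatogram, make_toy_structure


@pytest.fixture(scope="module")
def docked_dimer():
    """Two chains laid close enough to bury a genuine interface."""
    return make_toy_structure(n_chains=2, residues_per_chain=12,
                              chain_offset=(7.0, 2.0, 0.0))


@pytest.fixture(scope="module")
def far_dimer():
    return make_toy_structure(n_chains=2, residues_per_chain=12,
                              chain_offset=(100.0, 0.0, 0.0))


class TestBuriedArea:
    def test_far_chains_bury_nothing(self, far_dimer):
        rep = buried_area(far_dimer, "A", "B", n_points=240)
        assert rep.buried_area == 0.0
        assert rep.contacting_residues == []

    def test_symmetric_in_chain_order(self, docked_dimer):
        ab = buried_area(docked_dimer, "A", "B", n_points=240)
        ba = buried_area(docked_dimer, "B", "A", n_points=240)
        assert ab.buried_area == pytest.approx(ba.buried_area, abs=1e-9)

    def test_docked_dimer_matches_monte_carlo_oracle(self, docked_dimer):
        rep = buried_area(docked_dimer, "A", "B", n_points=960)
        assert rep.buried_area > 100.0
        elements, centers, chains = [], [], []
        for cid in ("A", "B"):
            for res in docked_dimer.chain(cid):
                for a in res.atoms:
                    elements.append(a.element)
                    centers.append(a.position)
                    chains.append(cid)
        centers = np.array(centers)
        radii = np.array([DEFAULT_VDW_RADII[e] for e in elements])
        oracle = monte_carlo_buried_area(centers, radii, chains, probe=1.4,
                                         n_samples=20000, seed=11)
        assert rep.buried_area == pytest.approx(oracle, rel=0.02)

    def test_missing_chain_rejected(self, docked_dimer):
        with pytest.raises(KeyError):
            buried_area(docked_dimer, "A", "Z")


class TestAssemblies:
    def test_far_chains_are_two_monomers(self, far_dimer):
        g = detect_assemblies(far_dimer, n_points=240)
        assert [len(c) for c in g.components] == [1, 1]
        assert g.labeled_components()[0][0] == "monomer"

    def test_docked_pair_is_one_dimer(self, docked_dimer):
        g = detect_assemblies(docked_dimer, threshold=100.0, n_points=240)
        assert g.components == [["A", "B"]]
        assert g.labeled_components()[0][0] == "dimer"

    def test_single_chain_is_monomer(self):
        s = make_toy_structure(n_chains=1, residues_per_chain=8)
        g = detect_assemblies(s, n_points=240)
        assert g.components == [["A"]]

    def test_raising_threshold_never_merges(self, docked_dimer):
        low = detect_assemblies(docked_dimer, threshold=50.0, n_points=240)
        high = detect_assemblies(docked_dimer, threshold=1e6, n_points=240)
        # every high-threshold component is contained in a low-threshold one
        for comp in high.components:
            assert any(set(comp) <= set(c) for c in low.components)


class TestCalibration:
    def test_exact_line_recovered(self):
        slope, intercept = -0.18, 4.2
        std = [(v, 10 ** (slope * v + intercept)) for v in (10.0, 12.5, 15.0, 18.0)]
        c = sec_calibrate(std)
        assert c.slope == pytest.approx(slope, abs=1e-12)
        assert c.intercept == pytest.approx(intercept, abs=1e-12)
        assert c.r_squared == pytest.approx(1.0)

    def test_two_points_interpolate_exactly(self):
        c = sec_calibrate([(10.0, 400.0), (16.0, 20.0)])
        assert apparent_mass(c, 10.0) == pytest.approx(400.0)
        assert apparent_mass(c, 16.0) == pytest.approx(20.0)

    def test_noisy_standards_match_normal_equations_oracle(self, rng):
        ve = np.linspace(9, 19, 8)
        logm = -0.2 * ve + 4.5 + rng.normal(0, 0.05, 8)
        std = list(zip(ve, 10 ** logm))
        c = sec_calibrate(std)
        slope, intercept = least_squares_line(ve, logm)
        assert c.slope == pytest.approx(slope, abs=1e-12)
        assert c.intercept == pytest.approx(intercept, abs=1e-12)

    def test_duplicate_elution_volume_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sec_calibrate([(10.0, 100.0), (10.0, 50.0)])

    def test_positive_slope_flagged(self):
        c = sec_calibrate([(10.0, 20.0), (16.0, 400.0)])
        assert c.warning is not None

    def test_kav_mode_agrees_with_volume_mode_prediction(self):
        # Kav is an affine map of Ve, so the fitted prediction is identical
        std = [(10.0, 400.0), (13.0, 100.0), (16.0, 20.0)]
        c_kav = sec_calibrate(std, v0=8.0, vc=24.0)
        c_ve = sec_calibrate(std)
        assert c_kav.uses_kav and not c_ve.uses_kav
        for ve in (11.0, 13.0, 15.5):
            assert apparent_mass(c_kav, ve) == pytest.approx(
                apparent_mass(c_ve, ve), rel=1e-9)

    def test_mass_to_volume_round_trip(self):
        c = sec_calibrate([(10.0, 400.0), (13.0, 100.0), (16.0, 20.0)])
        ve = elution_volume(c, 150.0)
        assert apparent_mass(c, ve) == pytest.approx(150.0, rel=1e-9)


class TestDeconvolve:
    def test_single_noiseless_gaussian_exact(self):
        c = make_chromatogram(peaks=[(14.0, 0.5, 2.0)], noise_sigma=0.0)
        model = deconvolve(c, 1, [13.7])
        p = model.peaks[0]
        assert p.center == pytest.approx(14.0, rel=1e-6)
        assert p.width == pytest.approx(0.5, rel=1e-6)
        assert p.area == pytest.approx(2.0, rel=1e-6)
        assert model.converged

    def test_three_planted_peaks_at_study_composition(self):
        # areas in the 10:53:37 proportion, 1% noise
        c = make_chromatogram(seed=1)
        model = deconvolve(c, 3, [12.2, 14.6, 15.9])
        truth = c.metadata["truth"]["areas"]
        for got, want in zip(model.areas(), truth):
            assert got == pytest.approx(want, rel=0.02)
        rep = repartition(model, ["tetramer", "dimer", "monomer"])
        for got, want in zip(rep.percentages,
                             c.metadata["truth"]["percentages"]):
            assert got == pytest.approx(want, abs=1.0)

    def test_shoulder_pair_resolved_with_area_conserved(self):
        peaks = [(14.0, 0.5, 3.0), (14.5, 0.5, 1.2)]
        c = make_chromatogram(peaks=peaks, noise_sigma=0.0)
        model = deconvolve(c, 2, [13.9, 14.6])
        assert len(model.peaks) == 2
        assert model.areas().sum() == pytest.approx(4.2, rel=0.01)

    def test_baseline_only_trace_flags_degenerate_fit(self):
        c = make_chromatogram(peaks=[], baseline=0.1, noise_sigma=0.0)
        model = deconvolve(c, 1, [14.0])
        assert (not model.converged) or model.peaks[0].area < 1e-6

    def test_init_center_outside_range_rejected(self):
        c = make_chromatogram(seed=0)
        with pytest.raises(ValueError, match="outside"):
            deconvolve(c, 1, [99.0])


class TestRepartition:
    def test_study_proportion(self):
        from redoxstruct.oligomer import Peak, PeakModel
        model = PeakModel(peaks=[Peak(12, 0.5, 1.0), Peak(14, 0.5, 5.3),
                                 Peak(16, 0.5, 3.7)],
                          baseline=0.0, residual_norm=0.0, converged=True)
        rep = repartition(model, ["tetramer", "dimer", "monomer"])
        assert rep.percentages == pytest.approx([10.0, 53.0, 37.0])

    def test_single_peak_is_everything(self):
        from redoxstruct.oligomer import Peak, PeakModel
        model = PeakModel([Peak(12, 0.5, 2.0)], 0.0, 0.0, True)
        assert repartition(model, ["only"]).percentages == [100.0]

    def test_equal_areas_split_evenly(self):
        from redoxstruct.oligomer import Peak, PeakModel
        model = PeakModel([Peak(12, 0.5, 2.0), Peak(14, 0.5, 2.0)],
                          0.0, 0.0, True)
        assert repartition(model, ["a", "b"]).percentages == [50.0, 50.0]

    def test_percentages_sum_to_100(self, rng):
        from redoxstruct.oligomer import Peak, PeakModel
        for _ in range(20):
            areas = rng.dirichlet([2, 2, 2, 2]) * rng.uniform(1, 100)
            model = PeakModel([Peak(10 + i, 0.5, a)
                               for i, a in enumerate(areas)],
                              0.0, 0.0, True)
            rep = repartition(model, list("abcd"))
            assert sum(rep.percentages) == pytest.approx(100.0, abs=1e-6)

    def test_zero_total_area_rejected(self):
        from redoxstruct.oligomer import Peak, PeakModel
        model = PeakModel([Peak(12, 0.5, 0.0)], 0.0, 0.0, True)
        with pytest.raises(ValueError, match="zero"):
            repartition(model, ["x"])

    def test_label_count_must_match(self):
        from redoxstruct.oligomer import Peak, PeakModel
        model = PeakModel([Peak(12, 0.5, 1.0)], 0.0, 0.0, True)
        with pytest.raises(ValueError):
            repartition(model, ["a", "b"])


class TestMassExtinction:
    def test_single_glycine_is_residue_plus_water(self):
        assert mass_extinction("G")["average_mass_da"] == pytest.approx(75.07,
                                                                        abs=0.01)

    def test_single_tryptophan_extinction(self):
        assert mass_extinction("W")["epsilon280_reduced"] == 5500.0

    def test_cystine_variant_adds_125_per_pair(self):
        out = mass_extinction("CCCC")
        assert out["epsilon280_cystines"] - out["epsilon280_reduced"] == 250.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mass_extinction("")

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError, match="B"):
            mass_extinction("AAB")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_concatenation_additive_minus_one_water(self, a, b):
        ma = mass_extinction(a)["average_mass_da"]
        mb = mass_extinction(b)["average_mass_da"]
        mab = mass_extinction(a + b)["average_mass_da"]
        assert mab == pytest.approx(ma + mb - 18.0153, abs=1e-6)
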