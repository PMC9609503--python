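import numpy as np
import pytest

import ramagg as rg
from ramagg.bands import AMIDE1_CATEGORIES, default_band_library
from ramagg.exceptions import AxisOrderError, ConfigError, DomainError
from ramagg.peakfit import lorentzian
from ramagg.synthetic import (
    DEFAULT_TIMEPOINTS,
    DEFAULT_TOTAL_AMIDE1_AREA,
    SS_FOLDED,
    ContactSpec,
    ChainTemplate,
    KineticParams,
    ground_truth_timecourse,
)


class TestBandLibrary:
    def test_default_library_has_the_four_amide1_components(self):
        lib = default_band_library()
        centers = lib.amide1_centers
        assert centers["amide1_coil"] == 1647.0
        assert centers["amide1_alpha"] == 1657.0
        assert centers["amide1_beta"] == 1671.0
        assert centers["amide1_turn"] == 1688.0

    def test_default_library_houses_the_marker_bands(self):
        lib = default_band_library()
        for c in (505, 759, 830, 876, 900, 932, 1004, 1280, 1341, 1363, 1446):
            assert lib.by_center(float(c)).center == float(c)

    def test_duplicate_centers_rejected(self):
        from ramagg.bands import Band, BandLibrary

        entries = default_band_library().entries
        with pytest.raises(ConfigError):
            BandLibrary(entries + [Band(505.0, 10.0, "dup", "other", 0.1)])


class TestGenerateSpectrum:
    def test_single_band_peaks_at_its_center(self, folded_gt):
        from ramagg.bands import Band, BandLibrary

        lib = BandLibrary([
            Band(1647.0, 20.0, "coil", "amide1_coil"),
            Band(1657.0, 20.0, "alpha", "amide1_alpha"),
            Band(1671.0, 20.0, "beta", "amide1_beta"),
            Band(1688.0, 20.0, "turn", "amide1_turn"),
        ])
        gt = rg.GroundTruthSlice(
            time_h=0.0,
            ss={"alpha": 100.0, "beta_sheet": 0.0, "beta_turn": 0.0, "coil": 0.0},
            markers={},
        )
        s = rg.generate_spectrum(gt, band_library=lib, noise_sd=0.0)
        peak_wn = s.wavenumbers[np.argmax(s.intensities)]
        assert peak_wn == pytest.approx(1657.0, abs=0.5)

    def test_same_seed_is_bit_identical(self, folded_gt):
        a = rg.generate_spectrum(folded_gt, noise_sd=0.02, spike_count=3, seed=7)
        b = rg.generate_spectrum(folded_gt, noise_sd=0.02, spike_count=3, seed=7)
        assert np.array_equal(a.intensities, b.intensities)

    def test_noiseless_generation_is_deterministic_without_seed_effects(self, folded_gt):
        a = rg.generate_spectrum(folded_gt, noise_sd=0.0, spike_count=0, seed=1)
        b = rg.generate_spectrum(folded_gt, noise_sd=0.0, spike_count=0, seed=99)
        assert np.array_equal(a.intensities, b.intensities)

    def test_amide1_areas_proportional_to_percentages(self, folded_gt):
        s = rg.generate_spectrum(folded_gt, noise_sd=0.0)
        lib = default_band_library()
        x = s.wavenumbers
        # rebuild the amide components analytically and check their share
        expected = np.zeros_like(x)
        for cat, key in zip(AMIDE1_CATEGORIES,
                            ("coil", "alpha", "beta_sheet", "beta_turn")):
            band = lib.by_category(cat)[0]
            area = folded_gt.ss[key] / 100.0 * DEFAULT_TOTAL_AMIDE1_AREA
            expected += lorentzian(x, band.center, band.gamma, area)
        window = (x > 1630) & (x < 1700)
        residual = s.intensities[window] - expected[window]
        # whatever remains in the window must be smooth tails, not components
        assert np.max(np.abs(residual)) < 0.05 * np.max(expected)

    def test_baseline_polynomial_added(self, folded_gt):
        flat = rg.generate_spectrum(folded_gt, noise_sd=0.0)
        ramped = rg.generate_spectrum(folded_gt, baseline_coeffs=(1.0, 0.5), noise_sd=0.0)
        u = (flat.wavenumbers - 300.0) / 1500.0
        np.testing.assert_allclose(
            ramped.intensities - flat.intensities, u + 0.5, atol=1e-12
        )

    def test_spikes_are_single_point_and_large(self, folded_gt):
        clean = rg.generate_spectrum(folded_gt, noise_sd=0.01, spike_count=0, seed=5)
        spiked = rg.generate_spectrum(folded_gt, noise_sd=0.01, spike_count=4, seed=5)
        diff = spiked.intensities - clean.intensities
        hit = np.nonzero(diff)[0]
        assert hit.size == 4
        assert np.all(diff[hit] >= 20 * 0.01)

    def test_descending_axis_rejected(self, folded_gt):
        with pytest.raises(AxisOrderError):
            rg.generate_spectrum(folded_gt, axis=np.arange(1800.0, 300.0, -1.0))

    def test_negative_noise_rejected(self, folded_gt):
        with pytest.raises(DomainError):
            rg.generate_spectrum(folded_gt, noise_sd=-0.1)


class TestGroundTruth:
    def test_percentages_must_sum_to_100(self):
        with pytest.raises(ValueError):
            rg.GroundTruthSlice(
                time_h=0.0,
                ss={"alpha": 50.0, "beta_sheet": 23.0, "beta_turn": 17.0, "coil": 11.0},
            )

    def test_unknown_regime_rejected(self):
        with pytest.raises(ConfigError):
            rg.GroundTruthSlice(time_h=0.0, ss=dict(SS_FOLDED), regime="oscillating")


class TestGenerateTimecourse:
    def test_static_regime_keeps_ground_truth_constant(self):
        pairs = rg.generate_timecourse("static", noise_sd=0.0)
        assert len(pairs) == len(DEFAULT_TIMEPOINTS)
        first = pairs[0][1]
        for _, gt in pairs:
            assert gt.ss == first.ss
            assert gt.ss["alpha"] == 50.0 and gt.ss["beta_sheet"] == 23.0

    def test_isodesmic_reaches_end_state(self):
        # rate chosen so the course is essentially complete by 240 h
        kp = KineticParams(rate=0.05)
        slices = ground_truth_timecourse("isodesmic", kinetic_params=kp)
        final = slices[-1]
        assert final.ss["alpha"] == pytest.approx(20.0, abs=0.01)
        assert final.ss["beta_sheet"] == pytest.approx(45.0, abs=0.01)

    def test_isodesmic_changes_monotonically_from_t0(self):
        slices = ground_truth_timecourse("isodesmic")
        betas = [s.ss["beta_sheet"] for s in slices]
        assert all(b2 > b1 for b1, b2 in zip(betas, betas[1:]))
        # no lag: already moving within the first half hour
        assert betas[1] > betas[0]

    def test_nucleated_has_a_pre_lag_plateau(self):
        kp = KineticParams(t50=48.0, rate=0.5)
        slices = ground_truth_timecourse("nucleated", kinetic_params=kp)
        assert slices[0].ss["alpha"] == pytest.approx(50.0, abs=0.5)

    def test_ground_truth_returned_alongside_each_spectrum(self):
        pairs = rg.generate_timecourse("nucleated", noise_sd=0.0)
        for spec, gt in pairs:
            assert spec.meta.time_h == gt.time_h

    def test_unknown_regime_is_a_config_error(self):
        with pytest.raises(ConfigError):
            rg.generate_timecourse("second-order")

    def test_seed_determinism(self):
        a = rg.generate_timecourse("isodesmic", noise_sd=0.03, seed=9)
        b = rg.generate_timecourse("isodesmic", noise_sd=0.03, seed=9)
        for (sa, _), (sb, _) in zip(a, b):
            assert np.array_equal(sa.intensities, sb.intensities)


class TestGenerateDimerTrajectory:
    def test_com_endpoints_are_exact(self):
        traj = rg.generate_dimer_trajectory(n_frames=6, com_start=27.19, com_end=23.0)
        coms = rg.com_distance_series(traj, "A", "B")
        assert coms[0] == pytest.approx(27.19, abs=1e-6)
        assert coms[-1] == pytest.approx(23.0, abs=1e-6)
        assert np.all(np.diff(coms) < 0)

    def test_planted_hydrogen_bond_round_trips_through_detection(self):
        traj = rg.generate_dimer_trajectory(
            n_frames=4, com_start=27.19, com_end=23.0,
            planted_contacts=[ContactSpec("hydrogen_bond", 8, 8)],
        )
        _, counts = rg.detect_interactions(traj.frame(traj.n_frames - 1))
        assert counts["hydrogen_bond"] >= 1

    def test_eight_cys_chains_give_64_combinations(self):
        template = ChainTemplate(n_residues=129,
                                 cys_positions=(6, 30, 64, 76, 80, 94, 115, 127))
        traj = rg.generate_dimer_trajectory(
            chain_template=template, n_frames=2, com_start=27.19, com_end=23.0
        )
        _, _, d = rg.cys_pair_distances(traj.frame(0))
        assert d.size == 64

    def test_nonpositive_com_end_rejected(self):
        with pytest.raises(DomainError):
            rg.generate_dimer_trajectory(n_frames=3, com_start=10.0, com_end=0.0)

    def test_jitter_is_seeded(self):
        a = rg.generate_dimer_trajectory(n_frames=3, com_start=27.0, com_end=23.0,
                                         jitter=0.1, seed=4)
        b = rg.generate_dimer_trajectory(n_frames=3, com_start=27.0, com_end=23.0,
                                         jitter=0.1, seed=4)
        assert np.array_equal(a.frames, b.frames)


class TestHewlLikeStructures:
    def test_monomer_has_129_residues_and_native_disulphides(self):
        mono = rg.hewl_like_monomer()
        assert len(mono.chains[0].residues) == 129
        pairs = {frozenset((i, j)) for (_, i), (_, j) in rg.find_disulphides(mono)}
        assert pairs == {frozenset(p) for p in ((6, 127), (30, 115), (64, 80), (76, 94))}
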