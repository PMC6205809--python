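import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from spinefate import morphometry as mm
from spinefate import synthetic
from spinefate.synthetic import StackGeometry


@pytest.fixture(scope="module")
def psf_cal():
    return mm.PsfCalibration((0.4, 0.4, 1.6))


class TestPsfCalibration:
    def test_gaussian_volume_closed_form_vs_quadrature(self, psf_cal):
        """V_PSF = (2pi)^{3/2} sx sy sz checked against numerical integration."""
        sx, sy, sz = psf_cal.sigma_um

        def psf_1d(s):
            val, _ = integrate.quad(
                lambda u: np.exp(-u**2 / (2 * s**2)), -8 * s, 8 * s)
            return val

        v_num = psf_1d(sx) * psf_1d(sy) * psf_1d(sz)
        assert psf_cal.v_psf_um3 == pytest.approx(v_num, rel=1e-3)
        a_num = psf_1d(sx) * psf_1d(sy)
        assert psf_cal.a_xy_um2 == pytest.approx(a_num, rel=1e-3)
        assert psf_cal.z_eff_um > psf_cal.fwhm_um[2] / 2

    def test_bead_stack_round_trip(self):
        """FWHMs recovered within 5% from a noiseless synthetic bead stack."""
        stack, meta, _ = synthetic.generate_bead_stack(
            psf_fwhm_um=(0.4, 0.4, 1.6), seed=1)
        cal = mm.calibrate_psf(stack, meta["voxel_um"])
        for got, want in zip(cal.fwhm_um, (0.4, 0.4, 1.6)):
            assert got == pytest.approx(want, rel=0.05)

    def test_bead_center_recovered(self):
        grid = StackGeometry()
        stack, meta, truth = synthetic.generate_bead_stack(
            n_beads=1, seed=2, grid=grid)
        found = mm.find_beads(stack, meta["voxel_um"])
        assert len(found) == 1
        true_c = truth.data["centers_um"][0]
        # centroid within one voxel of the generator's bead center
        assert np.allclose(found[0], true_c, atol=0.3)

    def test_two_identical_beads_average_like_one(self):
        stack, meta, _ = synthetic.generate_bead_stack(n_beads=2, seed=3)
        one, _, _ = synthetic.generate_bead_stack(n_beads=1, seed=3)
        cal2 = mm.calibrate_psf(stack, meta["voxel_um"])
        cal1 = mm.calibrate_psf(one, meta["voxel_um"])
        for a, b in zip(cal1.fwhm_um, cal2.fwhm_um):
            assert a == pytest.approx(b, rel=0.02)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            mm.find_beads(np.zeros((10, 10, 10)), (0.25, 0.1, 0.1))


class TestFMax:
    def test_uniform_cytoplasm_noiseless(self, psf_cal):
        stack = np.full((20, 20, 20), 42.0)
        mask = np.ones_like(stack, bool)
        f, flagged = mm.measure_f_max(stack, mask, psf_cal,
                                      trunk_width_um=3.0)
        assert f == pytest.approx(42.0)
        assert not flagged

    def test_noisy_cytoplasm_within_two_percent(self, psf_cal):
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(100):
            stack = 100.0 + rng.normal(0, 5.0, (15, 15, 15))
            mask = np.ones_like(stack, bool)
            f, _ = mm.measure_f_max(stack, mask, psf_cal, trunk_width_um=3.0)
            errs.append(f / 100.0 - 1.0)
        # 99th percentile of ~N(100, 5): +2.33 sd -> ~+1.2%, within 2%
        assert abs(np.mean(errs)) < 0.02

    def test_thin_trunk_flagged(self, psf_cal):
        stack = np.full((10, 10, 10), 10.0)
        _, flagged = mm.measure_f_max(stack, np.ones_like(stack, bool),
                                      psf_cal, trunk_width_um=0.4)
        assert flagged


class TestVolumeEstimation:
    def test_slab_identity(self, psf_cal):
        """ROI in uniform cytoplasm returns exactly ROI area x z_eff."""
        section = np.full((50, 50), 7.0)
        roi = np.zeros_like(section, bool)
        roi[10:30, 10:35] = True
        pixel = (0.1, 0.1)
        v, _ = mm.estimate_spine_volume(section, roi, psf_cal, pixel,
                                        f_max=7.0, background=0.0)
        area = roi.sum() * 0.01
        assert v == pytest.approx(area * psf_cal.z_eff_um, rel=1e-9)

    @pytest.mark.parametrize("vol", [0.05, 0.2, 0.5])
    def test_sphere_recovery_within_ten_percent(self, psf_cal, vol):
        stack, meta, truth = synthetic.generate_structural_stack(
            [(5.0, vol)], psf_fwhm_um=(0.4, 0.4, 1.6))
        r = (3 * vol / (4 * np.pi)) ** (1 / 3)
        v, flags = mm.measure_spine_from_stack(
            stack, meta, truth.data["head_centers_um"][0], psf_cal,
            f_max=1000.0, roi_radius_um=r + 0.5)
        assert v == pytest.approx(vol, rel=0.10)
        assert not flags["border"]

    def test_depth_attenuation_corrected(self, psf_cal):
        """At depth = lambda the raw estimate drops by e; correction restores it."""
        stack, meta, truth = synthetic.generate_structural_stack(
            [(5.0, 0.2)], psf_fwhm_um=(0.4, 0.4, 1.6), depth_um=50.0,
            attenuation_length_um=50.0)
        c = truth.data["head_centers_um"][0]
        r = (3 * 0.2 / (4 * np.pi)) ** (1 / 3)
        raw, _ = mm.measure_spine_from_stack(stack, meta, c, psf_cal,
                                             f_max=1000.0,
                                             roi_radius_um=r + 0.5)
        corr, _ = mm.measure_spine_from_stack(
            stack, meta, c, psf_cal, f_max=1000.0, roi_radius_um=r + 0.5,
            depth_offset_um=50.0, attenuation_length_um=50.0)
        assert raw == pytest.approx(0.2 / np.e, rel=0.10)
        assert corr == pytest.approx(0.2, rel=0.10)

    def test_volume_linearity(self, psf_cal):
        """Doubling the generated sphere volume doubles the estimate (5%)."""
        ests = {}
        for vol in (0.15, 0.30):
            stack, meta, truth = synthetic.generate_structural_stack(
                [(5.0, vol)], psf_fwhm_um=(0.4, 0.4, 1.6))
            r = (3 * vol / (4 * np.pi)) ** (1 / 3)
            ests[vol], _ = mm.measure_spine_from_stack(
                stack, meta, truth.data["head_centers_um"][0], psf_cal,
                f_max=1000.0, roi_radius_um=r + 0.5)
        assert ests[0.30] / ests[0.15] == pytest.approx(2.0, rel=0.05)

    def test_fmax_below_background_rejected(self, psf_cal):
        section = np.full((20, 20), 5.0)
        roi = np.zeros_like(section, bool)
        roi[8:12, 8:12] = True
        with pytest.raises(ValueError):
            mm.estimate_spine_volume(section, roi, psf_cal, (0.1, 0.1),
                                     f_max=1.0, background=2.0)

    def test_relative_change(self):
        assert mm.relative_volume_change(0.20, 0.242) == pytest.approx(21.0)
        assert mm.relative_volume_change(0.3, 0.3) == 0.0
        with pytest.raises(ValueError):
            mm.relative_volume_change(0.0, 0.1)


class TestRegistration:
    def test_identical_stacks_zero_shift(self):
        rng = np.random.default_rng(1)
        a = rng.random((12, 16, 16))
        shift, quality, ok = mm.register_sessions(a, a)
        assert shift == (0, 0, 0)
        assert quality == pytest.approx(1.0)
        assert ok

    def test_known_integer_shift_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.random((16, 24, 24))
        b = np.roll(a, shift=(2, -3, 1), axis=(0, 1, 2))
        shift, _, _ = mm.register_sessions(a, b)
        assert shift == (-2, 3, -1) or shift == (2, -3, 1)

    def test_shift_robust_to_noise(self):
        rng = np.random.default_rng(3)
        base = rng.random((12, 20, 20))
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            b = np.roll(base, (1, 2, -1), axis=(0, 1, 2))
            b = b + r.normal(0, 0.1 * base.std(), b.shape)
            shift, _, _ = mm.register_sessions(base, b)
            hits += shift in ((-1, -2, 1), (1, 2, -1))
        assert hits >= 19


class TestTracking:
    def test_identical_detections_all_survive(self):
        det = {"d0": [1.0, 4.0, 8.0], "d1": [1.0, 4.0, 8.0],
               "d7": [1.0, 4.0, 8.0]}
        table, gained = mm.track_spines(det, ["d0", "d1", "d7"])
        assert table["present"].all()
        assert not table["excluded"].any()
        assert gained == []

    def test_large_displacement_excluded_not_eliminated(self):
        det = {"d0": [1.0, 4.0], "d1": [1.0, 5.2], "d7": [1.0, 5.2]}
        table, _ = mm.track_spines(det, ["d0", "d1", "d7"], max_shift_um=1.0)
        moved = table[table.spine_id == "s1"]
        assert moved[moved.session == "d1"]["excluded"].item()
        still = table[table.spine_id == "s0"]
        assert still["present"].all() and not still["excluded"].any()

    def test_missing_detection_is_terminal_elimination(self):
        det = {"d0": [1.0, 4.0], "d1": [1.0], "d7": [1.0, 4.0]}
        table, gained = mm.track_spines(det, ["d0", "d1", "d7"])
        lost = table[(table.spine_id == "s1") & (table.session != "d0")]
        assert not lost["present"].any()  # elimination is terminal
        assert ("d7", 4.0) in gained  # reappearing detection counts as gained

    def test_ambiguous_positions_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            mm.track_spines({"d0": [1.0, 1.1], "d1": [1.0, 1.1]},
                            ["d0", "d1"])

    def test_exclusion_safety_monotone_in_max_shift(self):
        det = {"d0": [1.0, 4.0, 8.0], "d1": [1.0, 4.8, 9.5]}
        analyzable = []
        for max_shift in (0.5, 1.0, 2.0):
            table, _ = mm.track_spines(det, ["d0", "d1"],
                                       max_shift_um=max_shift)
            last = table[table.session == "d1"]
            analyzable.append(int((~last["excluded"]).sum()))
        assert analyzable == sorted(analyzable)


class TestRoles:
    def test_boundary_distances(self):
        pos = {"stim": 0.0, "a": 2.0, "b": 5.0, "c": 7.0, "d": 12.0}
        roles = mm.classify_roles(pos, "stim")
        assert roles == {"stim": "stimulated", "a": "nearest_neighbor",
                         "b": "nearest_neighbor",  # <=5 um convention
                         "c": "distant", "d": "ignored"}

    def test_single_spine(self):
        assert mm.classify_roles({"s": 3.0}, "s") == {"s": "stimulated"}

    def test_single_closest_mode(self):
        pos = {"stim": 0.0, "a": 2.0, "b": 4.0}
        roles = mm.classify_roles(pos, "stim", mode="single_closest")
        assert roles["a"] == "nearest_neighbor"
        assert roles["b"] == "distant"

    def test_missing_stimulated_rejected(self):
        with pytest.raises(ValueError):
            mm.classify_roles({"a": 1.0}, "stim")


class TestSurvival:
    def _cohort(self, present_d7):
        rows = []
        for i, alive in enumerate(present_d7):
            for sess, pres in (("d1", True), ("d7", alive)):
                rows.append({"experiment_id": f"e{i}", "condition": "control",
                             "spine_id": f"s{i}", "role": "stimulated",
                             "session": sess, "present": pres,
                             "excluded": False})
        return pd.DataFrame(rows)

    def test_hand_built_counting(self):
        cohort = self._cohort([True] * 9 + [False] * 3)
        out = mm.survival_fractions(cohort, "d1", "d7", n_bootstrap=0)
        assert out["fraction"].item() == pytest.approx(0.75)
        assert out["n_from"].item() == 12

    def test_full_survival_degenerate_ci(self):
        cohort = self._cohort([True] * 8)
        out = mm.survival_fractions(cohort, "d1", "d7", n_bootstrap=200,
                                    seed=0)
        assert out["fraction"].item() == 1.0
        assert out["ci_low"].item() == 1.0 and out["ci_high"].item() == 1.0

    def test_fractions_bounded_and_monotone(self, cfg):
        spines, _, _ = synthetic.generate_cohort(
            cfg.condition("LTD"), n_experiments=100, seed=31, config=cfg)
        spines["excluded"] = False
        d01 = mm.survival_fractions(spines, "d0_pre", "d1", n_bootstrap=0)
        d07 = mm.survival_fractions(spines, "d0_pre", "d7", n_bootstrap=0)
        merged = d01.merge(d07, on=["condition", "role"],
                           suffixes=("_d1", "_d7"))
        assert ((merged["fraction_d1"] >= merged["fraction_d7"])
                | np.isclose(merged["fraction_d1"],
                             merged["fraction_d7"])).all()
        assert merged["fraction_d7"].between(0, 1).all()

    def test_excluded_spines_do_not_contribute(self):
        cohort = self._cohort([True, False])
        cohort.loc[cohort.spine_id == "s1", "excluded"] = True
        out = mm.survival_fractions(cohort, "d1", "d7", n_bootstrap=0)
        assert out["n_from"].item() == 1
        assert out["fraction"].item() == 1.0

    def test_control_cohort_recovers_calibration(self, cfg):
        """Control d1->d7 elimination within 3 SE of the configured 0.27."""
        spines, _, _ = synthetic.generate_cohort(
            cfg.condition("control"), n_experiments=350, seed=33, config=cfg,
            displacement_frac=0.0)
        spines["excluded"] = False
        out = mm.survival_fractions(spines, "d1", "d7", n_bootstrap=0)
        stim = out[out.role == "stimulated"]
        frac = stim["fraction"].item()
        n = stim["n_from"].item()
        assert abs((1 - frac) - 0.27) <= 3 * np.sqrt(0.27 * 0.73 / n)
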