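"""Dipole physics, QSM, Dr regression and the non-negative inversion."""

import numpy as np
import pytest

from srcsep.io import AcquisitionGeometry, ScalarVolume
from srcsep.phantom import roi_means, REPORT_ROIS
from srcsep.separation import (RelaxometricConstant, SeparationConfig,
                               SeparationError, closed_form_decomposition,
                               default_dr, dipole_kernel, estimate_dr,
                               forward_field, qsm_closed_form, separate)


@pytest.fixture(scope="module")
def geom():
    return AcquisitionGeometry((32, 32, 32), (1.0, 1.0, 1.0))


class TestDipoleKernel:
    def test_closed_form_extremes(self, geom):
        d = dipole_kernel(geom).values
        # k along B0 (z): 1/3 - 1 = -2/3; k perpendicular: 1/3
        assert d[0, 0, 1] == pytest.approx(-2.0 / 3.0)
        assert d[1, 0, 0] == pytest.approx(1.0 / 3.0)
        assert d[0, 0, 0] == 0.0
        assert d.min() >= -2.0 / 3.0 - 1e-12 and d.max() <= 1.0 / 3.0 + 1e-12

    def test_sphere_field_matches_analytic_dipole(self):
        """The forward field of a digitised unit-susceptibility sphere
        follows the analytic external dipole pattern within 5 % of the
        peak outside a 2-voxel shell."""
        n, a = 64, 8.0
        g = AcquisitionGeometry((n, n, n), (1, 1, 1))
        idx = np.indices((n, n, n)) - (n - 1) / 2
        r = np.sqrt((idx ** 2).sum(0))
        chi = (r <= a).astype(float)  # 1 ppm inside
        df = forward_field(ScalarVolume(chi, (1, 1, 1), "ppm"),
                           dipole_kernel(g), 1e6)  # 1 Hz per ppm
        with np.errstate(all="ignore"):
            cos2 = np.where(r > 0, (idx[2] / np.where(r > 0, r, 1)) ** 2, 0.0)
            analytic = (a ** 3 / (3 * r ** 3)) * (3 * cos2 - 1)
        shell = (r > a + 2) & (r < n / 2 - 4)
        err = np.abs(df.data[shell] - analytic[shell]).max()
        assert err <= 0.05 * np.abs(analytic[shell]).max()


class TestForwardField:
    def test_zero_and_uniform_susceptibility(self, geom):
        k = dipole_kernel(geom)
        zero = ScalarVolume(np.zeros(geom.matrix_size), (1, 1, 1), "ppm")
        assert not forward_field(zero, k, 1e8).data.any()
        uniform = ScalarVolume(np.ones(geom.matrix_size), (1, 1, 1), "ppm")
        assert np.abs(forward_field(uniform, k, 1e8).data).max() < 1e-9

    def test_geometry_mismatch_rejected(self, geom):
        k = dipole_kernel(geom)
        wrong = ScalarVolume(np.zeros((8, 8, 8)), (1, 1, 1), "ppm")
        with pytest.raises(SeparationError):
            forward_field(wrong, k, 1e8)


class TestQsmClosedForm:
    def test_zero_field_gives_zero(self, geom):
        k = dipole_kernel(geom)
        mask = np.ones(geom.matrix_size, bool)
        zero = ScalarVolume(np.zeros(geom.matrix_size), (1, 1, 1), "Hz")
        assert not qsm_closed_form(zero, k, 1e8, mask).data.any()

    def test_brain_average_reference(self, small_truth):
        k = dipole_kernel(small_truth.geometry)
        brain = small_truth.rois.brain_mask()
        q = qsm_closed_form(small_truth.delta_f, k,
                            small_truth.geometry.imaging_frequency, brain)
        assert abs(q.data[brain].mean()) < 1e-9

    def test_round_trip_recovers_roi_contrasts(self, small_truth):
        """forward field -> thresholded inversion recovers brain-referenced
        ROI mean susceptibility within 15 % of the strongest contrast."""
        brain = small_truth.rois.brain_mask()
        k = dipole_kernel(small_truth.geometry)
        q = qsm_closed_form(small_truth.delta_f, k,
                            small_truth.geometry.imaging_frequency, brain)
        truth_tot = small_truth.chi_para.data - small_truth.chi_dia.data
        ref = truth_tot[brain].mean()
        got = roi_means(q, small_truth.rois)
        want = roi_means(truth_tot - ref, small_truth.rois)
        scale = max(abs(v) for v in want.values())
        for n in REPORT_ROIS:
            assert abs(got[n] - want[n]) <= 0.15 * scale

    def test_threshold_contract(self, geom):
        k = dipole_kernel(geom)
        vol = ScalarVolume(np.zeros(geom.matrix_size), (1, 1, 1), "Hz")
        with pytest.raises(SeparationError):
            qsm_closed_form(vol, k, 1e8, np.ones(geom.matrix_size, bool), 0.5)
        with pytest.raises(SeparationError, match="mask"):
            qsm_closed_form(vol, k, 1e8, np.zeros(geom.matrix_size, bool))


class TestDrEstimation:
    def test_exact_collinear_slope(self, small_truth):
        """Six ROI points lying exactly on a slope-137 line through the
        origin regress to 137 Hz/ppm."""
        rois = small_truth.rois
        rng = np.random.default_rng(0)
        chi = ScalarVolume(rng.uniform(0.02, 0.2, rois.labels.shape) * 1000.0,
                           (1, 1, 1), "ppb")
        # paint constant |chi| per regression ROI, R2' = 137 |chi|
        r2p = np.zeros(rois.labels.shape)
        for i, name in enumerate(("caudate_L", "caudate_R", "globus_pallidus_L",
                                  "globus_pallidus_R", "putamen_L", "putamen_R")):
            m = rois.labels == rois.names[name]
            chi.data[m] = 1000.0 * 0.03 * (i + 1)
            r2p[m] = 137.0 * 0.03 * (i + 1)
        fit = estimate_dr(chi, ScalarVolume(r2p, (1, 1, 1), "Hz"), rois)
        assert fit.dr == pytest.approx(137.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.source == "regressed"

    def test_scaling_r2prime_scales_slope(self, small_truth):
        rois = small_truth.rois
        brain = small_truth.rois.brain_mask()
        chi = ScalarVolume(small_truth.chi_para.data - small_truth.chi_dia.data,
                           (1, 1, 1), "ppb", brain)
        r2p = ScalarVolume(small_truth.r2star.data - small_truth.r2.data,
                           (1, 1, 1), "Hz", brain)
        base = estimate_dr(chi, r2p, rois)
        scaled = estimate_dr(chi, r2p.with_data(1.2 * r2p.data), rois)
        assert scaled.dr == pytest.approx(1.2 * base.dr, rel=1e-12)

    def test_default_mode_bypasses_regression(self):
        assert default_dr().dr == 137.0
        assert default_dr().source == "default"

    def test_degenerate_inputs_rejected(self, small_truth):
        rois = small_truth.rois
        const = ScalarVolume(np.full(rois.labels.shape, 50.0), (1, 1, 1), "ppb")
        r2p = ScalarVolume(np.full(rois.labels.shape, 10.0), (1, 1, 1), "Hz")
        with pytest.raises(SeparationError, match="variance"):
            estimate_dr(const, r2p, rois)


class TestClosedFormDecomposition:
    def test_worked_example(self):
        xp, xd, bad = closed_form_decomposition(13.7, 0.06, 137.0)
        assert (xp, xd) == (pytest.approx(0.08), pytest.approx(0.02))
        assert not bad

    def test_symmetric_split_at_zero_total(self):
        xp, xd, _ = closed_form_decomposition(13.7, 0.0, 137.0)
        assert xp == pytest.approx(0.05) and xd == pytest.approx(0.05)

    def test_inconsistent_voxel_clamped_and_flagged(self):
        xp, xd, bad = closed_form_decomposition(0.0, 0.05, 137.0)
        assert (xp, xd) == (pytest.approx(0.05), 0.0)
        assert bad
        xp2, xd2, bad2 = closed_form_decomposition(0.0, -0.04, 137.0)
        assert (xp2, xd2) == (0.0, pytest.approx(0.04))
        assert bad2

    def test_requires_positive_dr(self):
        with pytest.raises(SeparationError):
            closed_form_decomposition(1.0, 0.0, 0.0)


class TestSeparate:
    def test_zero_data_gives_zero_solution(self, geom):
        shape = geom.matrix_size
        mask = np.zeros(shape, bool)
        mask[8:24, 8:24, 8:24] = True
        zero_hz = ScalarVolume(np.zeros(shape), (1, 1, 1), "Hz", mask)
        res = separate(zero_hz, zero_hz, default_dr(), geom, mask)
        assert not res.chi_para.data.any()
        assert not res.chi_dia.data.any()

    def test_output_invariants(self, small_truth):
        """Non-negativity and the exact total = para - dia identity."""
        brain = small_truth.rois.brain_mask()
        r2p = ScalarVolume(small_truth.r2star.data - small_truth.r2.data,
                           small_truth.r2.voxel_size, "Hz", brain)
        res = separate(r2p, small_truth.delta_f,
                       RelaxometricConstant(small_truth.dr_true),
                       small_truth.geometry, brain,
                       SeparationConfig(max_iters=60))
        assert (res.chi_para.data >= 0).all()
        assert (res.chi_dia.data >= 0).all()
        np.testing.assert_array_equal(
            res.chi_total.data, res.chi_para.data - res.chi_dia.data)
        assert res.cost_history[-1] <= res.cost_history[0]

    def test_agrees_with_closed_form_on_consistent_phantom(self, small_truth):
        """Where data are exactly self-consistent and regularization is
        small, the solver matches the per-voxel closed form given the true
        total susceptibility, within 5 % on ROI means."""
        brain = small_truth.rois.brain_mask()
        r2p_data = small_truth.r2star.data - small_truth.r2.data
        r2p = ScalarVolume(np.where(brain, r2p_data, 0.0),
                           small_truth.r2.voxel_size, "Hz", brain)
        res = separate(r2p, small_truth.delta_f,
                       RelaxometricConstant(small_truth.dr_true),
                       small_truth.geometry, brain,
                       SeparationConfig(lambda_reg=0.3, max_iters=700))
        chi_tot_ppm = (small_truth.chi_para.data - small_truth.chi_dia.data) / 1000.0
        xp, xd, _ = closed_form_decomposition(
            np.where(brain, r2p_data, 0.0), chi_tot_ppm, small_truth.dr_true)
        for vol, oracle in ((res.chi_para, xp * 1000), (res.chi_dia, xd * 1000)):
            got = roi_means(vol, small_truth.rois)
            want = roi_means(oracle, small_truth.rois)
            for n in REPORT_ROIS:
                assert got[n] == pytest.approx(want[n], rel=0.05, abs=0.5)

    def test_r2prime_scaling_preserves_total(self, small_truth):
        """Scaling R2' by 1.25 moves the component sum but leaves ROI
        means of the total map nearly unchanged."""
        brain = small_truth.rois.brain_mask()
        r2p = ScalarVolume(
            np.where(brain, small_truth.r2star.data - small_truth.r2.data, 0.0),
            small_truth.r2.voxel_size, "Hz", brain)
        cfgs = SeparationConfig(max_iters=400)
        dr = RelaxometricConstant(small_truth.dr_true)
        base = separate(r2p, small_truth.delta_f, dr, small_truth.geometry,
                        brain, cfgs)
        up = separate(r2p.with_data(1.25 * r2p.data), small_truth.delta_f, dr,
                      small_truth.geometry, brain, cfgs)
        tot_b = roi_means(base.chi_total, small_truth.rois)
        tot_u = roi_means(up.chi_total, small_truth.rois)
        sum_b = roi_means(base.chi_para.data + base.chi_dia.data, small_truth.rois)
        sum_u = roi_means(up.chi_para.data + up.chi_dia.data, small_truth.rois)
        scale = max(abs(v) for v in tot_b.values())
        for n in REPORT_ROIS:
            assert abs(tot_u[n] - tot_b[n]) <= 0.05 * scale
            assert sum_u[n] > 1.1 * sum_b[n]

    def test_congruence_contract(self, geom):
        mask = np.ones(geom.matrix_size, bool)
        ok = ScalarVolume(np.zeros(geom.matrix_size), (1, 1, 1), "Hz", mask)
        bad = ScalarVolume(np.zeros((8, 8, 8)), (1, 1, 1), "Hz")
        with pytest.raises(SeparationError):
            separate(bad, ok, default_dr(), geom, mask)
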