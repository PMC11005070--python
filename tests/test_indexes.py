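"""Screening-index oracles: analytic zone integrals, hand-computed spreads,
simulator-pair orderings and laterality equivariance."""

import dataclasses
import math

import numpy as np
import pytest

from keratoscreen.scan import PolarGrid, ScalarMap, mirror_scan
from keratoscreen.geometry import ZernikeSpectrum, fit_zernike, gaussian_curvature_map, zernike_nm_pairs
from keratoscreen.indexes import (
    ABNORMAL_DIRECTION,
    INDEX_NAMES,
    EIWeights,
    NotablePoints,
    Profile,
    center_surrounding_index,
    compute_index_vector,
    dz_max,
    ectatic_index,
    epi_pti_index,
    k_avg,
    k_max,
    nps_spread,
    pct_thickness_increase_profile,
    pti_index,
    rms_vs_reference,
    symmetry_index,
    thickness_min,
    thickness_symmetry_index,
    train_ei_weights,
)
from keratoscreen.evaluation import empirical_auc

from conftest import sphere_elevation


def curvature_map_from(values, grid, apex=None):
    apex = float(values.mean()) if apex is None else apex
    return ScalarMap(grid, values, apex, "curvature", side="anterior")


class TestSymmetryIndexes:
    def test_rotationally_symmetric_map_gives_zero(self, grid):
        r, _ = grid.mesh_polar()
        m = curvature_map_from(43.0 + 0.5 * r**2, grid, 43.0)
        assert symmetry_index(m, "OD") == pytest.approx(0.0, abs=1e-9)
        assert symmetry_index(m, "OS") == pytest.approx(0.0, abs=1e-9)

    def test_inferior_steep_gives_positive_si(self, matched_pair):
        _, scan_k = matched_pair
        cm = gaussian_curvature_map(scan_k.anterior_elevation, "anterior")
        assert symmetry_index(cm, "OD") > 0

    def test_mirrored_map_equal_si(self, grid):
        rng = np.random.default_rng(0)
        vals = 43.0 + rng.normal(0, 1, (grid.n_rings, grid.n_meridians))
        m = curvature_map_from(vals, grid, 43.0)
        n = grid.n_meridians
        j = np.arange(n)
        mirrored = curvature_map_from(vals[:, (n // 2 - j) % n], grid, 43.0)
        assert symmetry_index(m, "OD") == pytest.approx(
            symmetry_index(mirrored, "OS"), abs=1e-12
        )

    def test_thickness_si_sign(self, grid, matched_pair):
        ones = np.ones((grid.n_rings, grid.n_meridians))
        assert thickness_symmetry_index(
            ScalarMap(grid, 540 * ones, 540.0, "thickness"), "OD"
        ) == pytest.approx(0.0)
        _, scan_k = matched_pair
        assert thickness_symmetry_index(scan_k.corneal_thickness, "OD") < 0


class TestCenterSurroundingIndex:
    def test_uniform_map_zero(self, grid):
        m = curvature_map_from(np.full((grid.n_rings, grid.n_meridians), 44.0), grid, 44.0)
        assert center_surrounding_index(m) == pytest.approx(0.0)

    def test_quadratic_map_analytic(self, grid):
        # map = a - b r^2: CSI = b (<r^2>_annulus - <r^2>_disc)
        # <r^2>_disc(0,1.5) = 1.5^2/2; <r^2>_annulus(1.5,3) = (3^4-1.5^4)/(2(3^2-1.5^2))
        r, _ = grid.mesh_polar()
        a, b = 46.0, 0.8
        m = curvature_map_from(a - b * r**2, grid, a)
        want = b * ((3**4 - 1.5**4) / (2 * (3**2 - 1.5**2)) - 1.5**2 / 2)
        assert center_surrounding_index(m) == pytest.approx(want, abs=0.1)

    def test_cone_raises_csi(self, matched_pair):
        scan_n, scan_k = matched_pair
        csi_n = center_surrounding_index(
            gaussian_curvature_map(scan_n.anterior_elevation, "anterior")
        )
        csi_k = center_surrounding_index(
            gaussian_curvature_map(scan_k.anterior_elevation, "anterior")
        )
        assert csi_k > csi_n


class TestEctaticIndex:
    def _spectrum(self, coeffs):
        return ZernikeSpectrum(8, coeffs, 4.0)

    def test_zero_weights(self):
        nm = zernike_nm_pairs(8)
        w = EIWeights(nm, np.zeros(len(nm)), np.zeros(len(nm)), 0.0, "anterior")
        spec = self._spectrum(np.random.default_rng(0).normal(size=len(nm)))
        assert ectatic_index(spec, w) == 0.0

    def test_selector_weight(self):
        nm = zernike_nm_pairs(8)
        a1 = np.zeros(len(nm))
        a1[nm.index((2, 0))] = 1.0
        w = EIWeights(nm, a1, np.zeros(len(nm)), 0.0, "anterior")
        coeffs = np.arange(len(nm), dtype=float)
        assert ectatic_index(self._spectrum(coeffs), w) == pytest.approx(
            coeffs[nm.index((2, 0))]
        )

    def test_mismatched_support_raises(self):
        nm = zernike_nm_pairs(6)
        w = EIWeights(nm, np.zeros(len(nm)), np.zeros(len(nm)), 0.0, "anterior")
        spec = self._spectrum(np.zeros(45))
        with pytest.raises(ValueError):
            ectatic_index(spec, w)

    def test_trained_ei_dominates_single_coefficients(self, trained_ei):
        w_f, _, spec_f, labels = trained_ei
        y = np.array(labels) == "Kcn"
        ei_scores = [ectatic_index(s, w_f) for s in spec_f]
        ei_auc = empirical_auc(ei_scores, y).auc
        coeff_mat = np.vstack([s.coefficients for s in spec_f])
        best_single = max(
            empirical_auc(coeff_mat[:, j], y).auc for j in range(coeff_mat.shape[1])
        )
        assert ei_auc >= best_single - 1e-9


class TestTrainEIWeights:
    def _toy_spectra(self, values):
        nm = zernike_nm_pairs(4)
        out = []
        for v in values:
            c = np.zeros(len(nm))
            c[3] = v
            out.append(ZernikeSpectrum(4, c, 4.0))
        return out

    def test_separable_toy_is_perfect(self):
        spectra = self._toy_spectra(np.r_[np.zeros(20), np.ones(20) * 5.0])
        labels = ["Normal"] * 20 + ["Kcn"] * 20
        w = train_ei_weights(spectra, labels, "anterior")
        scores = np.array([ectatic_index(s, w) for s in spectra])
        assert np.all(scores[:20] < 0) and np.all(scores[20:] > 0)

    def test_shuffled_labels_near_chance(self):
        # permutation null: in-sample AUC of a fitted discriminant is biased
        # upward by O(sqrt(p/n)), so the chance band needs n >> p features
        rng = np.random.default_rng(12)
        nm = zernike_nm_pairs(4)
        n = 3000
        spectra = [
            ZernikeSpectrum(4, rng.normal(size=len(nm)), 4.0) for _ in range(n)
        ]
        labels = ["Normal", "Kcn"] * (n // 2)
        shuffled = list(np.array(labels)[rng.permutation(n)])
        w = train_ei_weights(spectra, shuffled, "anterior")
        scores = [ectatic_index(s, w) for s in spectra]
        auc = empirical_auc(scores, np.array(shuffled) == "Kcn").auc
        assert auc == pytest.approx(0.5, abs=0.1)

    def test_duplicated_data_same_weights(self):
        spectra = self._toy_spectra(np.r_[np.linspace(0, 1, 20), np.linspace(4, 5, 20)])
        labels = ["Normal"] * 20 + ["Kcn"] * 20
        w1 = train_ei_weights(spectra, labels, "anterior")
        w2 = train_ei_weights(spectra + spectra, labels + labels, "anterior")
        np.testing.assert_allclose(w1.alpha1, w2.alpha1, atol=1e-5)

    def test_single_class_rejected(self):
        spectra = self._toy_spectra(np.zeros(10))
        with pytest.raises(ValueError):
            train_ei_weights(spectra, ["Normal"] * 10, "anterior")


class TestDeviationIndexes:
    def _dev(self, grid, values, apex=0.0):
        return ScalarMap(grid, values, apex, "deviation")

    def test_rms_trivials(self, grid):
        zeros = np.zeros((grid.n_rings, grid.n_meridians))
        assert rms_vs_reference(self._dev(grid, zeros)) == 0.0
        assert rms_vs_reference(self._dev(grid, zeros + 3.5, 3.5)) == pytest.approx(3.5)

    def test_rms_of_sinusoid(self, grid):
        _, t = grid.mesh_polar()
        h = 4.0
        dev = self._dev(grid, h * np.sin(2 * t))
        assert rms_vs_reference(dev) == pytest.approx(h / math.sqrt(2), abs=0.01)

    def test_dz_max_zero_map_at_vertex(self, grid):
        val, loc = dz_max(self._dev(grid, np.zeros((grid.n_rings, grid.n_meridians))))
        assert val == 0.0 and loc == (0.0, 0.0)

    def test_dz_max_constructed_bump(self, grid):
        x, y = grid.mesh_cartesian()
        bump = 12.0 * np.exp(-((x - 1.0) ** 2 + (y + 1.5) ** 2) / (2 * 0.5**2))
        val, loc = dz_max(self._dev(grid, bump))
        assert val == pytest.approx(12.0, abs=0.2)
        assert math.hypot(loc[0] - 1.0, loc[1] + 1.5) < 0.15


class TestThicknessIndexes:
    def test_uniform_min_at_vertex(self, grid):
        ones = np.ones((grid.n_rings, grid.n_meridians))
        val, loc = thickness_min(ScalarMap(grid, 540 * ones, 540.0, "thickness"))
        assert val == 540.0 and loc == (0.0, 0.0)

    def test_crater_min_located(self, grid):
        x, y = grid.mesh_cartesian()
        base = 540.0 + 5 * (x**2 + y**2)
        crater = 80.0 * np.exp(-((x - 0.8) ** 2 + (y + 0.6) ** 2) / (2 * 0.5**2))
        val, loc = thickness_min(ScalarMap(grid, base - crater, 540.0, "thickness"))
        assert math.hypot(loc[0] - 0.8, loc[1] + 0.6) < 0.15
        assert val < 540.0 - 70.0

    def test_corneal_min_at_least_stromal_min(self, small_cohort):
        for scan, _ in small_cohort[:8]:
            assert thickness_min(scan.corneal_thickness)[0] >= thickness_min(
                scan.stromal_thickness
            )[0]


class TestPTIProfiles:
    def test_uniform_map_zero_profile(self, grid):
        ones = np.ones((grid.n_rings, grid.n_meridians))
        prof = pct_thickness_increase_profile(ScalarMap(grid, 540 * ones, 540.0, "thickness"))
        np.testing.assert_allclose(prof.values[np.isfinite(prof.values)], 0.0, atol=1e-9)

    def test_paraboloid_profile_analytic(self, grid):
        # thickness t_min + a d^2 centered at the vertex: PTI(d) ~ 100 a d^2 / t_min
        r, _ = grid.mesh_polar()
        a, t_min = 6.0, 500.0
        prof = pct_thickness_increase_profile(
            ScalarMap(grid, t_min + a * r**2, t_min, "thickness")
        )
        finite = np.isfinite(prof.values)
        want = 100.0 * a * prof.d[finite] ** 2 / t_min
        np.testing.assert_allclose(prof.values[finite], want, rtol=0.05, atol=0.05)
        assert np.all(np.diff(prof.values[finite]) > 0)

    def test_pti_index_trivials(self, grid):
        d = np.arange(0.1, 3.05, 0.1)
        base = Profile(d, 2.0 * d**2)
        assert pti_index(base, base) == pytest.approx(0.0)
        below = Profile(d, base.values - 3.0)
        assert pti_index(below, base) == pytest.approx(-3.0)
        with pytest.raises(ValueError):
            pti_index(Profile(d[:-1], base.values[:-1]), base)

    def test_kcn_rises_faster_than_normal(self, matched_pair):
        scan_n, scan_k = matched_pair
        p_n = pct_thickness_increase_profile(scan_n.corneal_thickness)
        p_k = pct_thickness_increase_profile(scan_k.corneal_thickness)
        sel = (p_n.d <= 2.0) & np.isfinite(p_n.values) & np.isfinite(p_k.values)
        assert np.mean(p_k.values[sel] - p_n.values[sel]) > 0


class TestNotablePoints:
    def test_coincident_points_zero_spread(self):
        pts = NotablePoints(*([(0.3, -0.4)] * 7))
        assert nps_spread(pts) == pytest.approx(0.0)

    def test_two_cluster_hand_oracle(self):
        # 4 points at the origin, 3 at (1.4, 0): barycenter (0.6, 0),
        # spread = (4*0.6 + 3*0.8)/7 = 0.6857...
        pts = NotablePoints(*([(0.0, 0.0)] * 4 + [(1.4, 0.0)] * 3))
        assert nps_spread(pts) == pytest.approx(4.8 / 7.0, abs=1e-12)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(size=(7, 2))
        base = nps_spread(NotablePoints(*[tuple(p) for p in raw]))
        ang = 0.7
        R = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        moved = raw @ R.T + np.array([0.5, -1.2])
        assert nps_spread(NotablePoints(*[tuple(p) for p in moved])) == pytest.approx(
            base, abs=1e-12
        )


class TestIndexVector:
    def test_deterministic_and_equivariant(self, matched_pair, trained_ei, normative_from_pair):
        _, scan_k = matched_pair
        w_f, w_b, _, _ = trained_ei
        iv1 = compute_index_vector(scan_k, w_f, w_b, normative_from_pair)
        iv2 = compute_index_vector(scan_k, w_f, w_b, normative_from_pair)
        np.testing.assert_array_equal(iv1.as_array(), iv2.as_array())
        iv3 = compute_index_vector(mirror_scan(scan_k), w_f, w_b, normative_from_pair)
        np.testing.assert_allclose(iv1.as_array(), iv3.as_array(), atol=1e-9)

    def test_kcn_more_extreme_than_matched_normal(
        self, matched_pair, trained_ei, normative_from_pair
    ):
        scan_n, scan_k = matched_pair
        w_f, w_b, _, _ = trained_ei
        iv_n = compute_index_vector(scan_n, w_f, w_b, normative_from_pair)
        iv_k = compute_index_vector(scan_k, w_f, w_b, normative_from_pair)
        more_extreme = sum(
            1
            for name in INDEX_NAMES
            if ABNORMAL_DIRECTION[name] * (getattr(iv_k, name) - getattr(iv_n, name)) > 0
        )
        assert more_extreme >= 15

    def test_k_avg_analytic(self, grid):
        assert k_avg(sphere_elevation(grid, 7.5)) == pytest.approx(45.0, abs=0.1)
        from conftest import toric_elevation

        m = toric_elevation(grid, 7.9, 7.6, 25.0)
        want = 0.5 * (337.5 / 7.9 + 337.5 / 7.6)
        assert k_avg(m) == pytest.approx(want, abs=0.1)

    def test_k_max_constructed_cone(self, grid):
        vals = np.full((grid.n_rings, grid.n_meridians), 43.0)
        vals[10, 17] = 55.0
        val, loc = k_max(ScalarMap(grid, vals, 43.0, "curvature"))
        assert val == 55.0
        r = grid.radii[10]
        a = math.radians(grid.angles_deg[17])
        assert loc == pytest.approx((r * math.cos(a), r * math.sin(a)))
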