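import numpy as np
import pytest

from mvmar.core import StructureMask
from mvmar.dose import (
    BeamSpec,
    DoseGrid,
    GammaCriteria,
    PAPER_METRIC_SET,
    dose_compare,
    dvh_metrics,
    gamma_pass_rate,
    toy_dose,
)


def brute_force_gamma_rate(ref, test, crit):
    """Exhaustive gamma over all test points (no search-radius shortcut)."""
    rd, td = ref.dose, test.dose
    dn = rd.max() if crit.normalization == "global-max" else ref.prescription
    sy, sx = ref.spacing
    ii, jj = np.mgrid[0 : td.shape[0], 0 : td.shape[1]]
    passed = total = 0
    for i in range(rd.shape[0]):
        for j in range(rd.shape[1]):
            if rd[i, j] < crit.low_dose_cutoff * dn:
                continue
            dist2 = ((ii - i) * sy) ** 2 + ((jj - j) * sx) ** 2
            g2 = dist2 / crit.dta**2 + ((td - rd[i, j]) / (crit.dose_diff * dn)) ** 2
            total += 1
            passed += np.sqrt(g2.min()) <= 1.0
    return 100.0 * passed / total


class TestToyDose:
    def test_uniform_slab_matches_closed_form(self):
        red = np.ones((40, 40))
        beams = BeamSpec(angles=(0.0,), k=0.005, prescription=6000.0, norm_point=(0, 0))
        dg = toy_dose(red, beams, spacing=(1.0, 1.0))
        depth = (np.arange(40) + 0.5) * 1.0
        closed = np.exp(-0.005 * depth)
        closed *= 6000.0 / closed[0]
        assert np.max(np.abs(dg.dose[:, 20] - closed) / 6000.0) < 1e-6

    def test_denser_medium_attenuates_more(self):
        beams = BeamSpec(angles=(0.0,), norm_point=(0, 20))
        d1 = toy_dose(np.ones((40, 40)), beams)
        d2 = toy_dose(2 * np.ones((40, 40)), beams)
        assert np.all(d2.dose[5:, 20] < d1.dose[5:, 20])

    def test_vacuum_gives_flat_profile(self):
        dg = toy_dose(np.zeros((20, 20)), BeamSpec(angles=(0.0,)))
        assert np.allclose(dg.dose, dg.dose[0, 0])

    def test_dose_strictly_decreasing_along_ray(self):
        dg = toy_dose(np.ones((30, 30)), BeamSpec(angles=(0.0,)))
        assert np.all(np.diff(dg.dose[:, 15]) < 0)

    def test_zero_beams_errors(self):
        with pytest.raises(ValueError, match="beam"):
            BeamSpec(angles=())

    def test_oblique_angles_rejected(self):
        with pytest.raises(ValueError, match="90"):
            BeamSpec(angles=(45.0,))

    def test_negative_red_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            toy_dose(np.full((8, 8), -1.0), BeamSpec())


class TestGamma:
    def test_identical_grids_pass_fully(self, rng):
        g = DoseGrid(rng.uniform(1000, 6000, (16, 16)), (1.0, 1.0))
        for crit in (GammaCriteria(2.0, 0.02), GammaCriteria(1.0, 0.01)):
            rate, gmap = gamma_pass_rate(g, g, crit)
            assert rate == 100.0
            assert np.nanmax(gmap) == 0.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(3):
            a = DoseGrid(rng.uniform(1000, 6000, (20, 20)), (1.0, 1.0))
            b = DoseGrid(np.clip(a.dose + rng.normal(0, 80, a.dose.shape), 0, None), (1.0, 1.0))
            for crit in (GammaCriteria(2.0, 0.02), GammaCriteria(1.0, 0.01)):
                rate, _ = gamma_pass_rate(a, b, crit)
                assert rate == pytest.approx(brute_force_gamma_rate(a, b, crit), abs=1e-9)

    def test_loosening_criteria_never_decreases_rate(self, rng):
        for _ in range(5):
            a = DoseGrid(rng.uniform(1000, 6000, (16, 16)), (1.0, 1.0))
            b = DoseGrid(np.clip(a.dose + rng.normal(0, 120, a.dose.shape), 0, None), (1.0, 1.0))
            loose, _ = gamma_pass_rate(a, b, GammaCriteria(2.0, 0.02))
            tight, _ = gamma_pass_rate(a, b, GammaCriteria(1.0, 0.01))
            assert loose >= tight

    def test_refinement_never_decreases_rate(self, rng):
        a = DoseGrid(rng.uniform(1000, 6000, (16, 16)), (1.0, 1.0))
        b = DoseGrid(np.clip(a.dose + rng.normal(0, 100, a.dose.shape), 0, None), (1.0, 1.0))
        crit = GammaCriteria(1.0, 0.01)
        coarse, _ = gamma_pass_rate(a, b, crit)
        fine, _ = gamma_pass_rate(a, b, crit, refine=4)
        assert fine >= coarse

    def test_cutoff_excluding_everything_errors(self):
        g = DoseGrid(np.full((8, 8), 100.0), (1.0, 1.0))
        t = DoseGrid(np.full((8, 8), 100.0), (1.0, 1.0))
        with pytest.raises(ValueError, match="evaluable"):
            gamma_pass_rate(g, t, GammaCriteria(2.0, 0.02, low_dose_cutoff=1.5))

    def test_mismatched_geometry_errors(self):
        a = DoseGrid(np.zeros((8, 8)), (1.0, 1.0))
        b = DoseGrid(np.zeros((8, 8)), (2.0, 2.0))
        with pytest.raises(ValueError, match="geometry"):
            gamma_pass_rate(a, b, GammaCriteria())


class TestDvh:
    def test_uniform_dose(self):
        g = DoseGrid(np.full((10, 10), 6000.0), (1.0, 1.0), prescription=6000.0)
        roi = StructureMask("ptv", np.ones((10, 10), dtype=bool))
        rep = dvh_metrics(g, roi)
        assert rep["Dmean"] == rep["D5"] == rep["D95"] == 6000.0
        assert rep["V95%"] == rep["V100%"] == 100.0
        assert rep["V110%"] == 0.0

    def test_two_voxel_counting(self):
        g = DoseGrid(np.array([[5000.0, 7000.0]]), (1.0, 1.0), prescription=6000.0)
        roi = StructureMask("roi", np.array([[True, True]]))
        rep = dvh_metrics(g, roi)
        assert rep["V100%"] == 50.0

    def test_linear_ramp_median(self):
        vals = np.linspace(0.0, 6000.0, 100).reshape(10, 10)
        g = DoseGrid(vals, (1.0, 1.0), prescription=6000.0)
        roi = StructureMask("roi", np.ones((10, 10), dtype=bool))
        step = 6000.0 / 99
        assert dvh_metrics(g, roi)["D50"] == pytest.approx(3000.0, abs=step)

    def test_order_statistics_consistency_on_random_grids(self, rng):
        for _ in range(10):
            g = DoseGrid(rng.uniform(0, 7000, (12, 12)), (1.0, 1.0), prescription=6000.0)
            roi = StructureMask("roi", rng.random((12, 12)) > 0.3)
            rep = dvh_metrics(g, roi)
            assert rep["D95"] <= rep["D50"] <= rep["D5"]
            assert rep["V95%"] >= rep["V100%"] >= rep["V110%"]

    def test_small_roi_d01cc_falls_back_to_dmax(self):
        g = DoseGrid(np.array([[1000.0, 2000.0]]), (5.0, 5.0), prescription=6000.0)
        roi = StructureMask("cord", np.array([[True, True]]))  # 0.05 cc < 0.1 cc
        with pytest.warns(UserWarning, match="0.1 cc"):
            rep = dvh_metrics(g, roi)
        assert rep["D0.1cc"] == 2000.0

    def test_empty_roi_errors(self):
        g = DoseGrid(np.zeros((4, 4)), (1.0, 1.0))
        with pytest.raises(ValueError, match="empty"):
            dvh_metrics(g, StructureMask("roi", np.zeros((4, 4), dtype=bool)))


class TestDoseCompare:
    @staticmethod
    def _rois(shape=(20, 20)):
        rois = []
        rng = np.random.default_rng(0)
        for name in PAPER_METRIC_SET:
            m = np.zeros(shape, dtype=bool)
            m[rng.integers(0, 10) : 20, rng.integers(0, 10) : 20] = True
            rois.append(StructureMask(name, m))
        return rois

    def test_identical_plans_give_zero_differences(self, rng):
        g = DoseGrid(rng.uniform(1000, 6000, (20, 20)), (1.0, 1.0))
        df = dose_compare(g, g, self._rois())
        assert (df["abs_diff"] == 0).all()

    def test_report_schema_matches_clinical_metric_set(self, rng):
        g = DoseGrid(rng.uniform(1000, 6000, (20, 20)), (1.0, 1.0))
        df = dose_compare(g, g, self._rois())
        got = {(r.roi, r.metric) for r in df.itertuples()}
        want = {(roi, m) for roi, ms in PAPER_METRIC_SET.items() for m in ms}
        assert got == want

    def test_missing_roi_errors(self, rng):
        g = DoseGrid(rng.uniform(1000, 6000, (20, 20)), (1.0, 1.0))
        with pytest.raises(ValueError, match="missing ROIs"):
            dose_compare(g, g, self._rois()[:2])
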