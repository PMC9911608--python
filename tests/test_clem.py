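"""FLIM->EM registration, ROI statistics, per-cell summaries and
morphometrics."""

import math

import numpy as np
import pandas as pd
import pytest

from fretclem import (
    AffineTransform2D,
    CCSRecord,
    CellSummary,
    FlimImage,
    filter_cells_by_lifetime,
    fit_affine,
    morphometrics,
    roi_mean_lifetime,
    summarize_cell,
    transform_image_nn,
)
from fretclem.errors import (
    DegenerateFiducialsError,
    InsufficientPhotonsError,
    InvalidParameterError,
)


def make_affine(angle_deg, scale, tx, ty):
    th = math.radians(angle_deg)
    A = scale * np.array([[math.cos(th), -math.sin(th)],
                          [math.sin(th), math.cos(th)]])
    return AffineTransform2D(A, np.array([tx, ty]))


def uniform_image(shape=(16, 16), lifetime=2.2, counts=100, pixel=80.0):
    c = np.full(shape, counts)
    return FlimImage(c, c * lifetime, pixel)


class TestFitAffine:
    def test_identity_pairs(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 7.0], [5.0, 5.0]])
        T, res = fit_affine(pts, pts)
        np.testing.assert_allclose(T.A, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(T.b, 0.0, atol=1e-12)
        assert res < 1e-12

    def test_recovers_flim_to_em_scale_rotation_translation(self):
        """Exact recovery of the 80 nm -> 1.2 nm scale change (x66.67) with
        rotation and translation, from noise-free fiducials."""
        truth = make_affine(17.0, 80.0 / 1.2, 500.0, -300.0)
        rng = np.random.default_rng(0)
        flim = rng.uniform(0, 64, (8, 2))
        T, res = fit_affine(flim, truth(flim))
        np.testing.assert_allclose(T.A, truth.A, rtol=1e-9)
        np.testing.assert_allclose(T.b, truth.b, atol=1e-9 * 500)
        assert res < 1e-9 * 66.67 * 64

    def test_collinear_fiducials_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(DegenerateFiducialsError):
            fit_affine(pts, pts)

    def test_too_few_pairs_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DegenerateFiducialsError):
            fit_affine(pts, pts)

    def test_residual_grows_with_fiducial_jitter(self):
        truth = make_affine(10.0, 66.67, 100.0, 50.0)
        rng = np.random.default_rng(1)
        flim = rng.uniform(0, 64, (12, 2))
        em = truth(flim)
        residuals = []
        for jitter in (0.5, 1.0, 2.0, 4.0):
            _, res = fit_affine(flim, em + rng.normal(0, jitter, em.shape))
            residuals.append(res)
        assert np.all(np.diff(residuals) > 0)


class TestTransformImage:
    def test_identity_returns_input(self):
        img = uniform_image()
        out = transform_image_nn(img, make_affine(0, 1, 0, 0), img.shape)
        np.testing.assert_array_equal(out.photon_counts, img.photon_counts)
        np.testing.assert_array_equal(
            out.lifetime_weighted_sum, img.lifetime_weighted_sum
        )

    def test_integer_translation_shifts_and_conserves_photons(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(5.0, (12, 12))
        img = FlimImage(counts, counts * 2.0, 80.0)
        out = transform_image_nn(img, make_affine(0, 1, 3, 2), (20, 20))
        np.testing.assert_array_equal(out.photon_counts[2:14, 3:15], counts)
        assert out.photon_counts.sum() == counts.sum()

    def test_integer_translation_round_trip(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5.0, (10, 10))
        img = FlimImage(counts, counts * 1.5, 80.0)
        T = make_affine(0, 1, 4, 1)
        fwd = transform_image_nn(img, T, (20, 20))
        back = transform_image_nn(fwd, T.inverse(), (10, 10))
        np.testing.assert_array_equal(back.photon_counts, img.photon_counts)

    def test_counts_stay_integral_under_scaling(self):
        img = uniform_image(counts=7)
        out = transform_image_nn(img, make_affine(13, 3.7, 5, 5), (70, 70))
        assert np.issubdtype(out.photon_counts.dtype, np.integer)
        assert set(np.unique(out.photon_counts)) <= {0, 7}

    def test_singular_transform_rejected(self):
        with pytest.raises(InvalidParameterError):
            AffineTransform2D(np.zeros((2, 2)), np.zeros(2))

    def test_matches_skimage_nearest_neighbour(self):
        """Independent cross-check against scikit-image's order-0 warp."""
        skimage_tf = pytest.importorskip("skimage.transform")
        rng = np.random.default_rng(4)
        counts = rng.poisson(4.0, (24, 24))
        img = FlimImage(counts, counts * 2.1, 80.0)
        T = make_affine(9.0, 2.5, 6.0, 3.0)
        out = transform_image_nn(img, T, (70, 70))
        M = np.eye(3)
        M[:2, :2] = T.A
        M[:2, 2] = T.b
        ref = skimage_tf.warp(
            counts.astype(float),
            skimage_tf.AffineTransform(matrix=M).inverse,
            output_shape=(70, 70), order=0, mode="constant", cval=0.0,
        )
        # NN rounding at exact half-pixel boundaries may differ; require
        # near-total agreement
        agree = np.mean(out.photon_counts == ref)
        assert agree > 0.99


class TestRoiMeanLifetime:
    def test_uniform_image_any_roi(self):
        img = uniform_image(lifetime=2.2)
        for roi in ((0, 0, 16, 16), (3, 5, 9, 11), (15, 15, 16, 16)):
            tau, _ = roi_mean_lifetime(img, roi)
            assert tau == pytest.approx(2.2)

    def test_photon_weighted_mean(self):
        counts = np.zeros((4, 8))
        counts[:, :4] = 100
        counts[:, 4:] = 300
        sums = np.where(counts == 100, counts * 2.0, counts * 3.0)
        img = FlimImage(counts, sums, 80.0)
        tau, photons = roi_mean_lifetime(img, (0, 0, 8, 4))
        assert tau == pytest.approx(2.75)
        assert photons == 4 * 4 * 100 + 4 * 4 * 300

    def test_union_additivity(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(20.0, (10, 10)) + 1
        img = FlimImage(counts, counts * rng.uniform(1.5, 3.0, counts.shape), 80.0)
        t1, n1 = roi_mean_lifetime(img, (0, 0, 10, 5))
        t2, n2 = roi_mean_lifetime(img, (0, 5, 10, 10))
        tu, nu = roi_mean_lifetime(img, (0, 0, 10, 10))
        assert nu == n1 + n2
        assert tu == pytest.approx((t1 * n1 + t2 * n2) / (n1 + n2))

    def test_empty_roi_raises(self):
        img = FlimImage(np.zeros((4, 4), int), np.zeros((4, 4)), 80.0)
        with pytest.raises(InsufficientPhotonsError):
            roi_mean_lifetime(img, (0, 0, 4, 4))

    def test_out_of_bounds_roi_rejected(self):
        img = uniform_image()
        with pytest.raises(InvalidParameterError):
            roi_mean_lifetime(img, (0, 0, 17, 4))


def make_record(cls, tau, cell="c0", photons=10_000):
    make_record.counter = getattr(make_record, "counter", 0) + 1
    return CCSRecord(
        structure_id=f"s{make_record.counter}",
        cell_id=cell,
        curvature_class=cls,
        area_nm2=30_000.0,
        centroid_em_xy=(0.0, 0.0),
        mean_lifetime_ns=tau,
        photons=photons,
    )


class TestSummarizeCell:
    def test_uniform_lifetimes_zero_deltas(self):
        recs = [make_record(c, 2.3) for c in ("flat", "domed", "sphere")]
        s = summarize_cell(recs)
        assert all(v == pytest.approx(0.0) for v in s.delta_vs_flat_ns.values())

    def test_delta_arithmetic(self):
        recs = [make_record("flat", 2.40), make_record("sphere", 2.50)]
        s = summarize_cell(recs)
        assert s.delta_vs_flat_ns["sphere"] == pytest.approx(0.10)
        assert s.delta_vs_flat_ns["flat"] == 0.0
        assert math.isnan(s.delta_vs_flat_ns["domed"])  # absent class -> NaN

    def test_no_flat_reference_raises(self):
        recs = [make_record("domed", 2.4), make_record("sphere", 2.5)]
        with pytest.raises(InvalidParameterError):
            summarize_cell(recs)

    def test_recovers_generated_class_shift_across_cells(self):
        """Cells generated with a +0.08 ns sphere shift recover it in the
        across-cell mean within the spread of the per-cell estimates."""
        rng = np.random.default_rng(6)
        deltas = []
        for cell in range(6):
            recs = [
                make_record("flat", rng.normal(2.40, 0.02), cell=f"c{cell}")
                for _ in range(8)
            ] + [
                make_record("sphere", rng.normal(2.48, 0.02), cell=f"c{cell}")
                for _ in range(8)
            ]
            deltas.append(summarize_cell(recs).delta_vs_flat_ns["sphere"])
        ci = 3 * np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert np.mean(deltas) == pytest.approx(0.08, abs=ci)


class TestCellFilter:
    @staticmethod
    def cell(tau, cid="c"):
        return CellSummary(
            cell_id=cid,
            class_mean_ns={"flat": tau},
            delta_vs_flat_ns={"flat": 0.0},
            cellular_average_lifetime_ns=tau,
            n_structures={"flat": 1},
        )

    def test_strict_threshold_boundary(self):
        kept = filter_cells_by_lifetime([self.cell(2.09), self.cell(2.10)])
        assert [c.cellular_average_lifetime_ns for c in kept] == [2.09]

    def test_infinite_threshold_keeps_all(self):
        cells = [self.cell(t) for t in (1.5, 2.5, 5.0)]
        assert filter_cells_by_lifetime(cells, math.inf) == cells

    def test_separates_acceptor_and_donor_only_populations(self):
        rng = np.random.default_rng(7)
        acceptor = [self.cell(rng.normal(1.9, 0.05), f"a{i}") for i in range(6)]
        donor = [self.cell(rng.normal(2.5, 0.05), f"d{i}") for i in range(6)]
        kept = filter_cells_by_lifetime(acceptor + donor)
        assert kept == acceptor


class TestMorphometrics:
    def test_occupied_fraction_arithmetic(self):
        mask = np.zeros((40, 40), int)  # 1600 px at 1 nm -> area ratio direct
        mask[0:10, 0:10] = 1
        mask[20:30, 20:30] = 2
        classes = pd.DataFrame(
            {"label": [1, 2], "curvature_class": ["flat", "flat"]}
        )
        out = morphometrics(mask, classes, membrane_area_nm2=1000.0,
                            pixel_size_nm=1.0)
        assert out.loc["flat", "occupied_pct"] == pytest.approx(20.0)
        assert out.loc["flat", "n"] == 2
        assert out.loc["flat", "mean_area_nm2"] == pytest.approx(100.0)

    def test_empty_mask_all_zero(self):
        classes = pd.DataFrame({"label": [], "curvature_class": []})
        out = morphometrics(np.zeros((10, 10), int), classes, 1e4, 1.0)
        assert (out[["n", "mean_area_nm2", "density_per_um2", "occupied_pct"]]
                .to_numpy() == 0).all()

    def test_total_area_conserved_across_classes(self):
        rng = np.random.default_rng(8)
        mask = rng.integers(0, 4, (50, 50))
        classes = pd.DataFrame(
            {"label": [1, 2, 3],
             "curvature_class": ["flat", "domed", "sphere"]}
        )
        membrane = mask.size * 1.44
        out = morphometrics(mask, classes, membrane, 1.2)
        total_px_area = np.sum(mask > 0) * 1.44
        assert out["occupied_pct"].sum() == pytest.approx(
            100.0 * total_px_area / membrane
        )

    def test_generator_truth_recovered_exactly(self):
        """Areas laid down by a bookkeeping generator come back exactly."""
        mask = np.zeros((64, 64), int)
        truth = {}
        label = 1
        rng = np.random.default_rng(9)
        for cls, n in (("flat", 3), ("domed", 2), ("sphere", 2)):
            areas = []
            for _ in range(n):
                w = int(rng.integers(3, 8))
                x0, y0 = rng.integers(0, 50, 2)
                mask[y0:y0 + w, x0:x0 + w] = label
                label += 1
            truth[cls] = None  # areas recomputed below from the final mask
        classes = pd.DataFrame(
            {
                "label": np.arange(1, label),
                "curvature_class": ["flat"] * 3 + ["domed"] * 2 + ["sphere"] * 2,
            }
        )
        pixel = 2.0
        out = morphometrics(mask, classes, mask.size * pixel**2, pixel)
        for cls in ("flat", "domed", "sphere"):
            lbls = classes.loc[classes["curvature_class"] == cls, "label"]
            areas = [np.sum(mask == l) * pixel**2 for l in lbls if np.any(mask == l)]
            n_present = len(areas)
            assert out.loc[cls, "n"] == n_present
            if n_present:
                assert out.loc[cls, "mean_area_nm2"] == pytest.approx(
                    np.mean(areas)
                )

    def test_missing_label_named_in_error(self):
        mask = np.zeros((8, 8), int)
        mask[0:2, 0:2] = 3
        classes = pd.DataFrame({"label": [1], "curvature_class": ["flat"]})
        with pytest.raises(InvalidParameterError, match="3"):
            morphometrics(mask, classes, 1e4, 1.0)
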