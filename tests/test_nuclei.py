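"""Nucleus detection, per-nucleus intensities, positive calls,
marker/coexpression quantification and the polarisation index."""

import numpy as np
import pytest

from spheromet.nuclei import (MarkerQuantification, NucleusSet, call_positive,
                              detect_nuclei, polarisation_index,
                              quantify_coexpression, quantify_marker,
                              sample_intensities)
from spheromet.stack import ChannelStack


def _nucleus_set(centroids, flags=None, means=None):
    ns = NucleusSet(centroids_um=np.asarray(centroids, float),
                    scores=np.ones(len(centroids)))
    if flags is not None:
        ns.flags.update({k: np.asarray(v, bool) for k, v in flags.items()})
    if means is not None:
        ns.means.update({k: np.asarray(v, float) for k, v in means.items()})
    return ns


def exhaustive_otsu(values):
    """Oracle: threshold maximising between-class variance by brute force."""
    vals = np.sort(np.unique(values))
    best, best_var = None, -np.inf
    v = np.asarray(values, float)
    for cut in (vals[:-1] + vals[1:]) / 2.0:
        lo, hi = v[v <= cut], v[v > cut]
        w0, w1 = len(lo) / len(v), len(hi) / len(v)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best, best_var = cut, var
    return best


class TestDetectNuclei:
    def test_single_gaussian_blob_found_at_centre(self):
        zz, yy, xx = np.mgrid[:21, :41, :41]
        blob = np.exp(-((zz - 10.0) ** 2 / (2 * 2.0**2)
                        + (yy - 20.0) ** 2 / (2 * 4.0**2)
                        + (xx - 20.0) ** 2 / (2 * 4.0**2)))
        stack = ChannelStack({"dapi": 100 * blob}, (2.0, 1.0, 1.0))
        mask = np.ones(blob.shape, bool)
        nuclei = detect_nuclei(stack, mask, nucleus_radius_um=4.0)
        assert len(nuclei) == 1
        assert np.allclose(nuclei.centroids_um[0], (20.0, 20.0, 20.0),
                           atol=2.0)

    def test_zero_channel_yields_no_nuclei(self):
        stack = ChannelStack({"dapi": np.zeros((8, 16, 16))}, (1, 1, 1))
        nuclei = detect_nuclei(stack, np.ones((8, 16, 16), bool))
        assert len(nuclei) == 0

    def test_empty_mask_yields_no_nuclei(self):
        stack = ChannelStack({"dapi": np.ones((8, 16, 16))}, (1, 1, 1))
        nuclei = detect_nuclei(stack, np.zeros((8, 16, 16), bool))
        assert len(nuclei) == 0

    def test_count_accuracy_on_well_separated_panel(self, counting_spheroid):
        spec, stack, truth = counting_spheroid
        nuclei = detect_nuclei(stack, truth.occupancy,
                               nucleus_radius_um=spec.nucleus_radius_um)
        assert len(nuclei) == pytest.approx(300, abs=15)  # within 5%

    def test_detections_stay_inside_mask(self, counting_spheroid):
        spec, stack, truth = counting_spheroid
        nuclei = detect_nuclei(stack, truth.occupancy)
        spacing = np.asarray(stack.spacing)
        vox = np.round(nuclei.centroids_um / spacing).astype(int)
        assert truth.occupancy[tuple(vox.T)].all()

    def test_deterministic(self, counting_spheroid):
        _, stack, truth = counting_spheroid
        n1 = detect_nuclei(stack, truth.occupancy)
        n2 = detect_nuclei(stack, truth.occupancy)
        assert np.array_equal(n1.centroids_um, n2.centroids_um)


class TestSampleIntensities:
    def test_constant_channel_gives_constant_means(self):
        stack = ChannelStack({"m": np.full((10, 20, 20), 7.5)}, (1, 1, 1))
        ns = _nucleus_set([[5, 10, 10], [5, 4, 15]])
        means = sample_intensities(ns, stack, "m", sampling_radius_um=2.0)
        assert np.allclose(means, 7.5)
        assert np.array_equal(ns.means["m"], means)

    def test_edge_nucleus_uses_clipped_ball(self):
        img = np.full((6, 12, 12), 3.0)
        stack = ChannelStack({"m": img}, (1, 1, 1))
        ns = _nucleus_set([[0.0, 0.0, 0.0]])
        means = sample_intensities(ns, stack, "m", sampling_radius_um=3.0)
        assert means[0] == pytest.approx(3.0)

    def test_bright_nucleus_scores_higher_than_dim(self):
        img = np.zeros((10, 30, 30))
        img[5, 8, 8] = 100.0
        img[5, 8, 22] = 10.0
        stack = ChannelStack({"m": img}, (1, 1, 1))
        ns = _nucleus_set([[5, 8, 8], [5, 8, 22]])
        means = sample_intensities(ns, stack, "m", sampling_radius_um=2.0)
        assert means[0] > means[1] > 0

    def test_nonpositive_radius_rejected(self):
        stack = ChannelStack({"m": np.zeros((4, 4, 4))}, (1, 1, 1))
        with pytest.raises(ValueError):
            sample_intensities(_nucleus_set([[1, 1, 1]]), stack, "m", 0.0)


class TestCallPositive:
    def test_manual_threshold_is_exact(self):
        means = np.array([1.0, 4.0, 5.0, 9.0])
        flags, thr = call_positive(means, method="manual",
                                   manual_threshold=4.5)
        assert thr == 4.5
        assert flags.tolist() == [False, False, True, True]

    def test_manual_extremes(self):
        means = np.array([1.0, 2.0, 3.0])
        assert call_positive(means, "manual", -1.0)[0].all()
        assert not call_positive(means, "manual", 100.0)[0].any()

    def test_manual_without_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_positive(np.array([1.0]), method="manual")

    def test_otsu_matches_exhaustive_oracle_on_bimodal(self):
        rng = np.random.default_rng(7)
        means = np.concatenate([rng.normal(10, 1, 300),
                                rng.normal(50, 3, 200)])
        flags, thr = call_positive(means, method="otsu")
        oracle = exhaustive_otsu(means)
        # same partition as the brute-force between-class optimum, except
        # possibly for samples within one 256-bin histogram width of the
        # threshold (skimage quantises the search to bin centres)
        bin_width = np.ptp(means) / 256
        disagree = flags != (means > oracle)
        assert (np.abs(means[disagree] - thr) <= bin_width).all()
        assert abs(flags.sum() - 200) <= disagree.sum() <= 2

    def test_otsu_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(8)
        means = np.concatenate([rng.normal(10, 1, 100),
                                rng.normal(40, 2, 100)])
        f1, _ = call_positive(means, "otsu")
        f2, _ = call_positive(3.0 * means + 17.0, "otsu")
        assert np.array_equal(f1, f2)

    def test_otsu_constant_warns_all_negative(self):
        with pytest.warns(UserWarning, match="constant"):
            flags, _ = call_positive(np.full(50, 2.0), "otsu")
        assert not flags.any()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            call_positive(np.array([1.0]), method="median")


class TestQuantification:
    def test_percent_positive_trivial_cases(self):
        ns = _nucleus_set(np.zeros((4, 3)),
                          flags={"a": [True, True, False, False]})
        q = quantify_marker(ns, "a")
        assert (q.n_total, q.n_positive, q.percent_positive) == (4, 2, 50.0)

    def test_empty_set_reports_none(self):
        q = MarkerQuantification.from_flags("a", np.zeros(0, bool))
        assert q.percent_positive is None and q.n_total == 0

    def test_coexpression_of_channel_with_itself_is_marker_percent(self):
        rng = np.random.default_rng(9)
        flags = rng.uniform(size=200) > 0.6
        ns = _nucleus_set(np.zeros((200, 3)), flags={"a": flags})
        assert quantify_coexpression(ns, "a", "a").percent_positive == \
            quantify_marker(ns, "a").percent_positive

    def test_coexpression_of_independent_labels_near_product(self):
        rng = np.random.default_rng(10)
        n = 20_000
        a = rng.uniform(size=n) < 0.5
        b = rng.uniform(size=n) < 0.4
        ns = _nucleus_set(np.zeros((n, 3)), flags={"a": a, "b": b})
        q = quantify_coexpression(ns, "a", "b")
        sd = 100.0 * np.sqrt(0.2 * 0.8 / n)
        assert abs(q.percent_positive - 20.0) <= 3 * sd

    def test_coexpression_bounded_by_each_marker(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(size=500) < 0.3
        b = rng.uniform(size=500) < 0.7
        ns = _nucleus_set(np.zeros((500, 3)), flags={"a": a, "b": b})
        q = quantify_coexpression(ns, "a", "b").percent_positive
        assert q <= quantify_marker(ns, "a").percent_positive
        assert q <= quantify_marker(ns, "b").percent_positive


class TestPolarisationIndex:
    def _line_set(self, flags):
        n = len(flags)
        pts = np.stack([np.zeros(n), np.zeros(n), np.linspace(0, 100, n)],
                       axis=1)
        return _nucleus_set(pts, flags={"m": flags})

    def test_all_positives_in_distal_half_gives_one(self):
        flags = np.zeros(100, bool)
        flags[80:] = True
        ns = self._line_set(flags)
        assert polarisation_index(ns, "m", (0, 0, 1)) == 1.0
        assert polarisation_index(ns, "m", (0, 0, 1), orient="positive") == 1.0

    def test_auto_orientation_folds_proximal_cap_to_one(self):
        flags = np.zeros(100, bool)
        flags[:20] = True  # proximal cap w.r.t. +x axis direction
        ns = self._line_set(flags)
        assert polarisation_index(ns, "m", (0, 0, 1)) == 1.0
        assert polarisation_index(ns, "m", (0, 0, 1), orient="positive") == 0.0

    def test_uniform_positives_near_half(self):
        rng = np.random.default_rng(12)
        flags = rng.uniform(size=2000) < 0.5
        ns = self._line_set(flags)
        idx = polarisation_index(ns, "m", (0, 0, 1))
        assert 0.5 <= idx <= 0.55

    def test_no_positives_returns_none(self):
        ns = self._line_set(np.zeros(10, bool))
        assert polarisation_index(ns, "m", (0, 0, 1)) is None

    def test_axis_normalisation_irrelevant(self):
        flags = np.zeros(50, bool)
        flags[40:] = True
        ns = self._line_set(flags)
        assert polarisation_index(ns, "m", (0, 0, 10.0)) == \
            polarisation_index(ns, "m", (0, 0, 0.1))

    def test_invalid_orient_rejected(self):
        ns = self._line_set(np.ones(10, bool))
        with pytest.raises(ValueError):
            polarisation_index(ns, "m", (0, 0, 1), orient="down")
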