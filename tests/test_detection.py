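"""Detection stage: projection, masking, labeling, features, shape tests.

Each numeric operation is checked against a brute-force reimplementation
on random instances, plus the hand-checkable special cases.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliascreen import (
    CiliumTruth,
    DetectionParams,
    ImageStack,
    apply_shape_tests,
    build_candidate_mask,
    compute_features,
    detect_cilia,
    extract_candidates,
    make_cilium_stack,
    max_z_project,
)
from conftest import NOISELESS_PARAMS


# ---------------------------------------------------------------- oracles

def brute_force_median_filter(image, radius):
    """Sliding-window median with reflected borders, explicit loops."""
    padded = np.pad(image, radius, mode="symmetric")  # edge-repeating reflection
    out = np.empty_like(image, dtype=float)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = np.median(padded[r : r + 2 * radius + 1, c : c + 2 * radius + 1])
    return out


def brute_force_components(mask, connectivity):
    """Flood-fill component count."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                count += 1
                frontier = [(r, c)]
                seen[r, c] = True
                while frontier:
                    rr, cc = frontier.pop()
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                                and mask[nr, nc] and not seen[nr, nc]):
                            seen[nr, nc] = True
                            frontier.append((nr, nc))
    return count


def brute_force_solidity(pixels):
    """area / #lattice points inside-or-on the hull, via orientation tests."""
    pts = [tuple(p) for p in pixels]
    if len(pts) <= 2:
        return 1.0
    hull = _gift_wrap(pts)
    if hull is None:  # collinear
        return 1.0
    rs = [p[0] for p in pts]
    cs = [p[1] for p in pts]
    inside = 0
    for r in range(min(rs), max(rs) + 1):
        for c in range(min(cs), max(cs) + 1):
            if _point_in_convex_polygon((r, c), hull):
                inside += 1
    return len(pts) / inside


def _gift_wrap(points):
    pts = sorted(set(points))
    if len(pts) < 3:
        return None

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    return hull if len(hull) >= 3 else None


def _point_in_convex_polygon(point, hull):
    sign = 0
    for i in range(len(hull)):
        a, b = hull[i], hull[(i + 1) % len(hull)]
        cr = (b[0] - a[0]) * (point[1] - a[1]) - (b[1] - a[1]) * (point[0] - a[0])
        if abs(cr) < 1e-12:
            continue
        if sign == 0:
            sign = 1 if cr > 0 else -1
        elif (cr > 0) != (sign > 0):
            return False
    return True


# ---------------------------------------------------------------- max_z_project

class TestMaxZProject:
    def test_single_plane_identity(self, rng):
        plane = rng.random((1, 1, 8, 8))
        stack = ImageStack(plane, {"cilia_marker": 0})
        np.testing.assert_array_equal(max_z_project(stack), plane[0, 0])

    def test_two_plane_max(self):
        voxels = np.zeros((2, 1, 2, 2))
        voxels[0, 0, 0, 0], voxels[1, 0, 0, 0] = 1.0, 3.0
        stack = ImageStack(voxels, {"cilia_marker": 0})
        assert max_z_project(stack)[0, 0] == 3.0

    def test_matches_brute_force_loop(self, rng):
        voxels = rng.random((5, 2, 12, 9))
        stack = ImageStack(voxels, {"cilia_marker": 1})
        expected = voxels[0, 1].copy()
        for z in range(1, 5):
            for r in range(12):
                for c in range(9):
                    expected[r, c] = max(expected[r, c], voxels[z, 1, r, c])
        np.testing.assert_array_equal(max_z_project(stack), expected)

    def test_unmapped_channel_raises(self, rng):
        stack = ImageStack(rng.random((2, 1, 4, 4)), {"cilia_marker": 0})
        with pytest.raises(KeyError):
            max_z_project(stack, "probe")


# ---------------------------------------------------------------- candidate mask

class TestBuildCandidateMask:
    def test_uniform_image_below_absolute_threshold(self):
        assert not build_candidate_mask(np.full((10, 10), 3.0), 1, 5.0).any()

    def test_median_removes_single_hot_pixel(self):
        image = np.zeros((9, 9))
        image[4, 4] = 100.0
        assert not build_candidate_mask(image, 1, 10.0).any()

    def test_radius_zero_is_plain_threshold(self):
        image = np.zeros((5, 5))
        image[2, 2] = 9.0
        mask = build_candidate_mask(image, 0, 5.0)
        assert mask.sum() == 1 and mask[2, 2]

    @pytest.mark.parametrize("radius", [1, 2])
    def test_matches_brute_force_median(self, rng, radius):
        for _ in range(25):
            image = rng.integers(0, 50, size=(14, 11)).astype(float)
            threshold = float(rng.uniform(5, 40))
            expected = brute_force_median_filter(image, radius) > threshold
            np.testing.assert_array_equal(
                build_candidate_mask(image, radius, threshold), expected
            )

    def test_degenerate_quantile_warns_and_empties(self):
        with pytest.warns(UserWarning):
            mask = build_candidate_mask(np.full((8, 8), 7.0), 1, ("quantile", 0.9))
        assert not mask.any()


# ---------------------------------------------------------------- labeling

class TestExtractCandidates:
    def test_empty_mask(self):
        assert extract_candidates(np.zeros((5, 5), bool), np.zeros((5, 5))) == []

    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        image = np.ones((4, 4))
        assert len(extract_candidates(mask, image, connectivity=8)) == 1
        assert len(extract_candidates(mask, image, connectivity=4)) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_count_matches_flood_fill(self, rng, connectivity):
        for _ in range(25):
            mask = rng.random((16, 16)) < 0.35
            got = len(extract_candidates(mask, np.ones((16, 16)), connectivity))
            assert got == brute_force_components(mask, connectivity)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            extract_candidates(np.zeros((4, 4), bool), np.zeros((5, 5)))

    def test_labels_deterministic(self, rng):
        mask = rng.random((20, 20)) < 0.3
        image = rng.random((20, 20))
        a = extract_candidates(mask, image)
        b = extract_candidates(mask, image)
        assert [c.label for c in a] == [c.label for c in b]
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.pixels, cb.pixels)


# ---------------------------------------------------------------- features

class TestComputeFeatures:
    def test_horizontal_line(self):
        pixels = np.array([(3, c) for c in range(5)])
        f = compute_features(pixels, np.ones((8, 8)))
        assert f["area_px"] == 5
        assert f["solidity"] == 1.0
        assert f["length_px"] == pytest.approx(4.0)
        assert f["eccentricity"] > 0.95

    def test_filled_disk_is_round(self):
        rr, cc = np.mgrid[0:21, 0:21]
        pixels = np.argwhere(np.hypot(rr - 10, cc - 10) <= 5)
        f = compute_features(pixels, np.ones((21, 21)))
        assert f["eccentricity"] < 0.1

    def test_single_pixel_degenerate(self):
        f = compute_features(np.array([[4, 4]]), np.full((9, 9), 2.0))
        assert f["eccentricity"] == 0.0
        assert f["solidity"] == 1.0
        assert f["length_px"] == 0.0
        assert f["mean_intensity"] == 2.0

    def test_l_tromino_solidity_matches_oracle(self):
        pixels = np.array([[0, 0], [1, 0], [0, 1]])
        f = compute_features(pixels, np.ones((3, 3)))
        assert f["solidity"] == pytest.approx(brute_force_solidity(pixels))

    def test_random_blobs_solidity_matches_oracle(self, rng):
        for _ in range(30):
            mask = rng.random((10, 10)) < 0.3
            if not mask.any():
                continue
            pixels = np.argwhere(mask)
            f = compute_features(pixels, np.ones((10, 10)))
            assert f["solidity"] == pytest.approx(brute_force_solidity(pixels))
            assert 0 < f["solidity"] <= 1.0
            assert 0 <= f["eccentricity"] < 1.0

    def test_mean_intensity_is_over_member_pixels(self, rng):
        image = rng.random((6, 6))
        pixels = np.array([[0, 0], [5, 5], [2, 3]])
        f = compute_features(pixels, image)
        assert f["mean_intensity"] == pytest.approx(
            (image[0, 0] + image[5, 5] + image[2, 3]) / 3
        )


# ---------------------------------------------------------------- shape tests

def _candidate_from_pixels(pixels, shape=(64, 64), intensity=None):
    from ciliascreen.detection import CandidateObject

    image = intensity if intensity is not None else np.ones(shape)
    return CandidateObject(1, np.asarray(pixels), compute_features(pixels, image), shape)


class TestApplyShapeTests:
    def test_disk_rejected_by_eccentricity(self):
        rr, cc = np.mgrid[0:64, 0:64]
        pixels = np.argwhere(np.hypot(rr - 30, cc - 30) <= 5)
        cand = apply_shape_tests(
            _candidate_from_pixels(pixels),
            DetectionParams(eccentricity_min=0.8, length_px=(1, 120)),
        )
        assert not cand.passed["eccentricity"]
        assert not cand.passed["overall"]

    def test_conjunction_single_failure_rejects(self):
        # a short rod: passes area/ecc/solidity/intensity, fails length_min
        pixels = np.array([(30, c) for c in range(28, 33)])
        params = DetectionParams(area_px=(2, 500), length_px=(10, 120),
                                 eccentricity_min=0.8)
        cand = apply_shape_tests(_candidate_from_pixels(pixels), params)
        assert cand.passed["area"] and cand.passed["eccentricity"]
        assert not cand.passed["length"]
        assert not cand.passed["overall"]
        assert cand.fail_reasons == ["length"]

    def test_border_exclusion(self):
        pixels = np.array([(0, c) for c in range(12)])
        params = DetectionParams(area_px=(2, 500), length_px=(5, 120))
        cand = apply_shape_tests(_candidate_from_pixels(pixels), params)
        assert not cand.passed["border"]

    def test_synthetic_stack_three_pass_two_distractors_fail(self, noiseless_stack):
        stack, _ = noiseless_stack
        projection = max_z_project(stack)
        mask = build_candidate_mask(projection, 0, 50.0)
        candidates = extract_candidates(mask, projection)
        assert len(candidates) == 5
        flags = [apply_shape_tests(c, NOISELESS_PARAMS).passed["overall"]
                 for c in candidates]
        assert sum(flags) == 3


# ---------------------------------------------------------------- full detection

class TestDetectCilia:
    def test_noiseless_count_equals_planted(self, noiseless_stack):
        stack, truth = noiseless_stack
        assert len(detect_cilia(stack)) == len(truth)

    def test_blank_stack_empty(self):
        stack, _ = make_cilium_stack([], noise_model="none", seed=0)
        assert detect_cilia(stack) == []

    def test_blank_noisy_stack_empty(self):
        stack, _ = make_cilium_stack([], noise_model="poisson", seed=7)
        assert detect_cilia(stack) == []

    def test_rerun_identical(self, noiseless_stack):
        stack, _ = noiseless_stack
        a, b = detect_cilia(stack), detect_cilia(stack)
        assert [c.label for c in a] == [c.label for c in b]
        assert [c.features for c in a] == [c.features for c in b]

    def test_additive_offset_invariance_with_quantile_threshold(self):
        truth = CiliumTruth(center=(64.0, 64.0), orientation_deg=30.0)
        stack, _ = make_cilium_stack([truth], shape=(3, 128, 128),
                                     noise_model="poisson", seed=3)
        params = DetectionParams(threshold=("quantile", 0.99))
        base = detect_cilia(stack, params)
        shifted = ImageStack(stack.voxels + 37.0, stack.channel_map)
        offset = detect_cilia(shifted, params)
        assert len(base) == len(offset)
        for a, b in zip(base, offset):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    @given(
        ecc_min=st.floats(0.0, 0.95),
        sol_min=st.floats(0.1, 1.0),
        int_min=st.floats(0.0, 600.0),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_raising_thresholds_never_adds_detections(self, ecc_min, sol_min, int_min):
        truths = [
            CiliumTruth(center=(40.0, 40.0), orientation_deg=15.0),
            CiliumTruth(center=(90.0, 90.0), orientation_deg=70.0),
        ]
        stack, _ = make_cilium_stack(truths, shape=(3, 128, 128),
                                     distractors="default", seed=0)
        loose = DetectionParams(median_radius_px=0)
        tight = DetectionParams(
            median_radius_px=0,
            eccentricity_min=max(ecc_min, loose.eccentricity_min),
            solidity_min=max(sol_min, loose.solidity_min),
            intensity_min=max(int_min, loose.intensity_min),
        )
        assert len(detect_cilia(stack, tight)) <= len(detect_cilia(stack, loose))
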