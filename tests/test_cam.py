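"""Grad-CAM, Otsu binarization and largest-region boxes against oracles."""

from collections import deque

import numpy as np
import pytest
from skimage.transform import resize

from mosaicsoft.cam import (
    BinaryMask,
    BoundingBox,
    EmptyRegionError,
    ImportanceMap,
    UnsupportedModelError,
    binarize_otsu,
    compute_grad_cam,
    extract_roi,
    largest_region_bbox,
)
from mosaicsoft.nn import SmallCNN, _conv3x3
from mosaicsoft.synthetic import LabeledImage

# ---------------------------------------------------------------------------
# Grad-CAM


class MeanChannelToyModel:
    """Single conv layer; logit_k is the spatial mean of channel k.

    The gradient of logit_k w.r.t. channel c of the activation is the
    constant 1/(H*W) when c = k and zero otherwise — derivable by hand.
    """

    def __init__(self, seed=0, channels=3):
        rng = np.random.default_rng(seed)
        self.W = rng.standard_normal((3, 3, 3, channels)) * 0.3
        self.b = np.zeros(channels)

    def cam_data(self, image01, target_class):
        A = _conv3x3(image01[None].astype(np.float64), self.W, self.b)[0]
        dA = np.zeros_like(A)
        h, w = A.shape[:2]
        dA[:, :, target_class] = 1.0 / (h * w)
        return A, dA


def test_toy_model_cam_is_rectified_normalized_activation():
    rng = np.random.default_rng(3)
    image = rng.random((24, 24, 3)).astype(np.float32)
    model = MeanChannelToyModel(seed=1)
    for target in range(3):
        imap = compute_grad_cam(model, image, target)
        A, _ = model.cam_data(image, target)
        expected = np.maximum(A[:, :, target], 0.0)
        expected = resize(expected, (24, 24), order=1, mode="edge", anti_aliasing=False)
        expected = (expected - expected.min()) / (expected.max() - expected.min())
        assert np.allclose(imap.values, expected, atol=1e-6)
        assert imap.source_class == target


def test_constant_zero_activations_give_all_zero_map():
    class ZeroModel:
        def cam_data(self, image01, target_class):
            return np.zeros((6, 6, 4)), np.full((6, 6, 4), 0.1)

    imap = compute_grad_cam(ZeroModel(), np.zeros((12, 12, 3), np.uint8), 0)
    assert np.all(imap.values == 0)


def test_model_without_conv_access_rejected():
    class HeadlessModel:
        def predict(self, X):
            return np.zeros(len(X))

    with pytest.raises(UnsupportedModelError):
        compute_grad_cam(HeadlessModel(), np.zeros((12, 12, 3), np.uint8), 0)


def test_cam_gradients_match_finite_differences():
    """Backprop to an inner conv layer agrees with finite differences.

    Compared only where the pooling window has a unique maximum with a
    clear margin; elsewhere the pooled map is non-differentiable and a
    central difference straddles the kink.
    """
    net = SmallCNN(image_size=16, n_classes=3, channels=(4, 5, 6), seed=1)
    net.conv_W = [w.astype(np.float64) for w in net.conv_W]
    net.conv_b = [b.astype(np.float64) for b in net.conv_b]
    net.dense_W = net.dense_W.astype(np.float64)
    net.dense_b = net.dense_b.astype(np.float64)
    rng = np.random.default_rng(0)
    x = rng.random((16, 16, 3))
    layer, target = 1, 2
    A, dA = net.cam_data(x, target, layer=layer)
    _, cache = net.forward(x[None], want_cache=True)
    a = cache["acts"][layer][0].astype(np.float64).copy()

    unique_max = np.zeros(a.shape, dtype=bool)
    for i in range(a.shape[0] // 2):
        for j in range(a.shape[1] // 2):
            for c in range(a.shape[2]):
                win = a[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, c]
                top2 = np.sort(win.ravel())[-2:]
                if top2[1] - top2[0] > 1e-4:
                    ii, jj = np.unravel_index(win.argmax(), (2, 2))
                    unique_max[2 * i + ii, 2 * j + jj, c] = True

    full = a[None]
    eps = 1e-6
    checked = 0
    for idx in np.argwhere(unique_max)[::3]:
        idx = tuple(idx)
        orig = full[(0, *idx)]
        full[(0, *idx)] = orig + eps
        lp = net.forward_from(layer, full)[0, target]
        full[(0, *idx)] = orig - eps
        lm = net.forward_from(layer, full)[0, target]
        full[(0, *idx)] = orig
        assert (lp - lm) / (2 * eps) == pytest.approx(dA[idx], abs=1e-3)
        checked += 1
    assert checked >= 10


def test_cam_invariant_to_non_target_logit_shift():
    net = SmallCNN(image_size=16, n_classes=3, channels=(4, 6), seed=2)
    x = np.random.default_rng(5).random((16, 16, 3)).astype(np.float32)
    before = compute_grad_cam(net, x, target_class=0).values
    net.dense_b[1] += 5.0  # shift a non-target logit
    after = compute_grad_cam(net, x, target_class=0).values
    assert np.allclose(before, after)


# ---------------------------------------------------------------------------
# Otsu


def brute_force_otsu_mask(values: np.ndarray) -> np.ndarray:
    """Exhaustive 256-bin threshold search maximizing between-class variance."""
    hist, edges = np.histogram(values.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_t = -1.0, None
    for i in range(255):
        w0 = hist[: i + 1].sum()
        w1 = hist[i + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[: i + 1] * centers[: i + 1]).sum() / w0
        m1 = (hist[i + 1 :] * centers[i + 1 :]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[i]
    return values > best_t


def test_otsu_bimodal_map():
    values = np.full((10, 10), 0.1)
    values[:, 5:] = 0.9
    mask = binarize_otsu(ImportanceMap(values=values, source_class=0)).mask
    assert np.array_equal(mask, values > 0.5)


def test_otsu_matches_brute_force_on_random_maps():
    rng = np.random.default_rng(12)
    for _ in range(100):
        shape = (int(rng.integers(8, 40)), int(rng.integers(8, 40)))
        if rng.random() < 0.5:
            values = rng.random(shape)
        else:  # smooth bimodal-ish maps closer to real CAMs
            values = rng.random(shape)
            values = (values > 0.6) * rng.random(shape) * 0.5 + values * 0.5
        values = (values - values.min()) / np.ptp(values)
        mask = binarize_otsu(values).mask
        assert np.array_equal(mask, brute_force_otsu_mask(values))


def test_otsu_constant_map_all_true():
    mask = binarize_otsu(np.full((9, 9), 0.4)).mask
    assert mask.all()


# ---------------------------------------------------------------------------
# largest region bounding box


def flood_fill_components(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components by breadth-first search, in scan order."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                queue, members = deque([(i, j)]), []
                seen[i, j] = True
                while queue:
                    a, b = queue.popleft()
                    members.append((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            na, nb = a + da, b + db
                            if (
                                0 <= na < h
                                and 0 <= nb < w
                                and mask[na, nb]
                                and not seen[na, nb]
                            ):
                                seen[na, nb] = True
                                queue.append((na, nb))
                comps.append(np.array(members))
    return comps


def test_bbox_single_rectangle():
    mask = np.zeros((10, 12), dtype=bool)
    mask[2:5, 3:8] = True  # rows 2-4, cols 3-7 inclusive
    box = largest_region_bbox(mask)
    assert (box.x_min, box.y_min, box.x_max, box.y_max) == (3, 2, 8, 5)


def test_bbox_picks_larger_component():
    mask = np.zeros((12, 12), dtype=bool)
    mask[1:4, 1:5] = True  # 12 pixels
    mask[8:9, 6:11] = True  # 5 pixels
    comps = flood_fill_components(mask)
    assert sorted(len(c) for c in comps) == [5, 12]
    box = largest_region_bbox(mask)
    assert (box.x_min, box.y_min, box.x_max, box.y_max) == (1, 1, 5, 4)


def test_bbox_all_false_raises():
    with pytest.raises(EmptyRegionError):
        largest_region_bbox(np.zeros((5, 5), dtype=bool))


def test_bbox_tight_around_winning_component():
    rng = np.random.default_rng(77)
    for _ in range(25):
        mask = rng.random((20, 20)) < 0.25
        if not mask.any():
            continue
        comps = flood_fill_components(mask)
        sizes = [len(c) for c in comps]
        winner = comps[int(np.argmax(sizes))]  # scan order breaks ties
        box = largest_region_bbox(mask)
        rows, cols = winner[:, 0], winner[:, 1]
        assert box.y_min == rows.min() and box.y_max == rows.max() + 1
        assert box.x_min == cols.min() and box.x_max == cols.max() + 1


# ---------------------------------------------------------------------------
# full pipeline


def test_extract_roi_returns_valid_box(trained_model, balanced_images):
    for im in balanced_images[::10]:
        box = extract_roi(trained_model, im)
        h, w = im.shape
        assert 0 <= box.x_min < box.x_max <= w
        assert 0 <= box.y_min < box.y_max <= h


def test_extract_roi_falls_back_to_full_image(balanced_images):
    class ZeroModel:
        def cam_data(self, image01, target_class):
            return np.zeros((8, 8, 2)), np.zeros((8, 8, 2))

    im = balanced_images[0]
    # constant (all-zero) CAM -> constant map -> all-true mask -> full box,
    # so the fallback path needs a mask that is all false: not reachable via
    # binarize_otsu; exercise largest_region_bbox's error contract instead
    box = extract_roi(ZeroModel(), im)
    assert (box.x_min, box.y_min, box.x_max, box.y_max) == (0, 0, 32, 32)
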