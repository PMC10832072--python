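"""Mosaic formation: split sampling, quadrant assignment, soft labels."""

import numpy as np
import pytest
from skimage.transform import resize

from mosaicsoft.cam import BoundingBox
from mosaicsoft.mosaic import (
    QUADRANTS,
    DegenerateQuadrantError,
    MosaicConfig,
    MosaicSpec,
    QuadrantPatch,
    SoftLabel,
    SplitPoint,
    assign_quadrants,
    build_mosaic_dataset,
    compute_soft_label,
    inverse_frequency_allocation,
    sample_split_point,
    synthesize_mosaic,
)
from mosaicsoft.synthetic import LabeledImage

# measure of {max quadrant > 1/2} in the unit square: four disjoint corner
# regions, each of area 1/2 - (ln 2)/2
ACCEPT_RATE = 2 - 2 * np.log(2)


class TestSplitPoint:
    def test_sampled_points_satisfy_majority_constraint(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            assert sample_split_point(rng).max_area > 0.5

    def test_acceptance_rate_matches_analytic_measure(self):
        rng = np.random.default_rng(1)
        n = 100_000
        xy = rng.random((n, 2))
        accepted = 0
        for fx, fy in xy:
            p = SplitPoint(fx=float(fx), fy=float(fy))
            accepted += p.max_area > 0.5
        rate = accepted / n
        # 99% binomial CI half-width
        half = 2.576 * np.sqrt(ACCEPT_RATE * (1 - ACCEPT_RATE) / n)
        assert abs(rate - ACCEPT_RATE) < half

    def test_deterministic_given_rng_state(self):
        a = sample_split_point(np.random.default_rng(42))
        b = sample_split_point(np.random.default_rng(42))
        assert (a.fx, a.fy) == (b.fx, b.fy)

    def test_mean_largest_area_matches_numerical_integration(self):
        # E[max area | accepted] by 2-D numerical integration on a fine grid
        g = (np.arange(2001) + 0.5) / 2001
        X, Y = np.meshgrid(g, g)
        areas = np.stack([X * Y, (1 - X) * Y, X * (1 - Y), (1 - X) * (1 - Y)])
        mx = areas.max(axis=0)
        sel = mx > 0.5
        expected = mx[sel].mean()
        rng = np.random.default_rng(7)
        draws = np.array([sample_split_point(rng).max_area for _ in range(20_000)])
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 4 * se

    def test_out_of_range_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitPoint(fx=0.0, fy=0.5)


class TestAssignQuadrants:
    POOLS = [["a0", "a1"], ["b0"], ["c0", "c1", "c2"]]

    def test_every_class_represented(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            split = sample_split_point(rng)
            assignment = assign_quadrants(rng, split, self.POOLS)
            classes = {c for c, _ in assignment.values()}
            assert classes == {0, 1, 2}
            for q, (c, img) in assignment.items():
                assert img in self.POOLS[c]

    def test_degenerate_allocation_always_wins_largest(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            split = sample_split_point(rng)
            assignment = assign_quadrants(
                rng, split, self.POOLS, allocation=(0.0, 1.0, 0.0)
            )
            assert assignment[split.largest_quadrant][0] == 1

    def test_uniform_allocation_is_even(self):
        rng = np.random.default_rng(2)
        n = 10_000
        wins = np.zeros(3)
        for _ in range(n):
            split = sample_split_point(rng)
            assignment = assign_quadrants(rng, split, self.POOLS)
            wins[assignment[split.largest_quadrant][0]] += 1
        # 99.9% binomial CI around 1/3
        half = 3.29 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert np.all(np.abs(wins / n - 1 / 3) < half)

    def test_empty_pool_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            assign_quadrants(rng, sample_split_point(rng), [["a"], [], ["c"]])


def rasterized_soft_label(split, quadrant_classes, n_classes=3, res=1000):
    """Oracle: count pixels per class on a res x res rasterized grid."""
    px = int(round(split.fx * res))
    py = int(round(split.fy * res))
    counts = np.zeros(n_classes)
    tl, tr, bl, br = quadrant_classes
    counts[tl] += py * px
    counts[tr] += py * (res - px)
    counts[bl] += (res - py) * px
    counts[br] += (res - py) * (res - px)
    return counts / res**2


class TestSoftLabel:
    def test_single_class_mosaic_is_one_hot(self):
        split = SplitPoint(0.61, 0.33)
        label = compute_soft_label(split, (2, 2, 2, 2))
        assert np.allclose(label.probs, [0, 0, 1])

    def test_symmetric_split(self):
        label = compute_soft_label(SplitPoint(0.5, 0.5), (0, 1, 2, 2))
        assert np.allclose(label.probs, [0.25, 0.25, 0.5])

    def test_area_example(self):
        label = compute_soft_label(SplitPoint(0.8, 0.9), (1, 2, 0, 2))
        assert np.allclose(label.probs, [0.08, 0.72, 0.20])

    def test_agrees_with_rasterization_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            split = sample_split_point(rng)
            classes = tuple(rng.integers(0, 3, 4))
            label = compute_soft_label(split, classes)
            oracle = rasterized_soft_label(split, classes)
            assert abs(label.probs.sum() - 1) < 1e-9
            assert np.all(np.abs(label.probs - oracle) < 2e-3)

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            SoftLabel(probs=np.array([0.5, 0.2, 0.2]))

    def test_allocation_increases_expected_class_mass(self):
        # soft-label mass of class 1 grows with its dominant-quadrant share
        rng = np.random.default_rng(5)
        masses = []
        for alloc in ((0.45, 0.1, 0.45), (1 / 3, 1 / 3, 1 / 3), (0.1, 0.8, 0.1)):
            total = 0.0
            for _ in range(2000):
                split = sample_split_point(rng)
                assignment = assign_quadrants(
                    rng, split, [["a"], ["b"], ["c"]], allocation=alloc
                )
                classes = tuple(assignment[q][0] for q in QUADRANTS)
                total += compute_soft_label(split, classes).probs[1]
            masses.append(total / 2000)
        assert masses[0] < masses[1] < masses[2]


def _uniform_image(value, size=40, label=0, id="src"):
    pixels = np.full((size, size, 3), value, dtype=np.uint8)
    return LabeledImage(pixels=pixels, label=label, id=id)


def _spec(split, sources, size=64):
    quadrants = {
        q: QuadrantPatch(
            class_index=i % 3,
            image_id=sources[i].id,
            crop=BoundingBox(0, 0, *sources[i].shape[::-1]),
        )
        for i, q in enumerate(QUADRANTS)
    }
    return MosaicSpec(split=split, quadrants=quadrants, output_size=size)


class TestSynthesize:
    def test_identical_sources_tile(self):
        src = _uniform_image(150)
        spec = MosaicSpec(
            split=SplitPoint(0.5, 0.5),
            quadrants={
                q: QuadrantPatch(0, "src", BoundingBox(5, 5, 25, 25))
                for q in QUADRANTS
            },
            output_size=64,
        )
        out = synthesize_mosaic(spec, {"src": src})
        assert out.shape == (64, 64, 3)
        tile = out[:32, :32]
        for rows, cols in ((slice(32, 64), slice(0, 32)),
                           (slice(0, 32), slice(32, 64)),
                           (slice(32, 64), slice(32, 64))):
            assert np.array_equal(out[rows, cols], tile)

    def test_corner_pixel_identity(self):
        rng = np.random.default_rng(0)
        sources = [
            LabeledImage(
                rng.integers(0, 255, (40, 40, 3)).astype(np.uint8), i % 3, f"s{i}"
            )
            for i in range(4)
        ]
        spec = _spec(SplitPoint(0.4, 0.6), sources)
        out = synthesize_mosaic(spec, {s.id: s for s in sources})
        tl = spec.quadrants["TL"]
        crop = tl.crop.crop(sources[0].pixels)
        px, py = round(0.4 * 64), round(0.6 * 64)
        expected = resize(
            crop.astype(np.float64), (py, px), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        assert out[0, 0, 0] == np.clip(np.round(expected), 0, 255).astype(np.uint8)[0, 0, 0]

    def test_quadrant_pixel_extents(self):
        sources = [
            _uniform_image(v, label=i % 3, id=f"s{i}")
            for i, v in enumerate((250, 10, 120, 60))
        ]
        spec = _spec(SplitPoint(0.8, 0.9), sources, size=100)
        out = synthesize_mosaic(spec, {s.id: s for s in sources})
        # extents 80x90, 20x90, 80x10, 20x10 (width x height)
        assert np.all(out[:90, :80] == 250)
        assert np.all(out[:90, 80:] == 10)
        assert np.all(out[90:, :80] == 120)
        assert np.all(out[90:, 80:] == 60)

    def test_degenerate_quadrant_raises(self):
        sources = [_uniform_image(9, id=f"s{i}", label=i % 3) for i in range(4)]
        spec = _spec(SplitPoint(0.995, 0.5), sources, size=64)
        with pytest.raises(DegenerateQuadrantError):
            synthesize_mosaic(spec, {s.id: s for s in sources})


class TestBuildDataset:
    def test_build_counts_labels_and_determinism(self, trained_model, balanced_images):
        config = MosaicConfig(n_images=12, output_size=32, seed=3)
        mosaics = build_mosaic_dataset(balanced_images, trained_model, config)
        assert len(mosaics) == 12
        for m in mosaics:
            assert m.pixels.shape == (32, 32, 3)
            assert abs(m.soft_label.probs.sum() - 1) < 1e-9
            present = {c for c in m.spec.quadrant_classes()}
            assert present == {0, 1, 2}
            assert np.all(m.soft_label.probs > 0)
        again = build_mosaic_dataset(balanced_images, trained_model, config)
        assert all(
            np.array_equal(a.pixels, b.pixels)
            and np.allclose(a.soft_label.probs, b.soft_label.probs)
            for a, b in zip(mosaics, again)
        )

    def test_zero_mosaics(self, trained_model, balanced_images):
        config = MosaicConfig(n_images=0, output_size=32, seed=0)
        assert build_mosaic_dataset(balanced_images, trained_model, config) == []


def test_inverse_frequency_allocation():
    alloc = inverse_frequency_allocation((372, 141, 1297))
    assert abs(sum(alloc) - 1) < 1e-12
    assert alloc[1] > alloc[0] > alloc[2]


def test_mosaic_config_validation():
    with pytest.raises(ValueError):
        MosaicConfig(n_images=-1)
    with pytest.raises(ValueError):
        MosaicConfig(oversample_allocation=(0.5, 0.2, 0.2))
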