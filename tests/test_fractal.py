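import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from octafractal.exceptions import DegenerateInputError, EmptyMaskError, StageError, ValidationError
from octafractal.fractal import (
    AnalysisConfig,
    BoxCountCurve,
    analyze_slab,
    box_count,
    default_box_sizes,
    fd_fit_sizes,
    fit_fd,
    gliding_box_lacunarity,
    grid_offsets,
    summarize_lac,
)
from octafractal.synthetic_data import FixtureKind, FixtureSpec, generate_plexus, make_fixture, sierpinski_carpet

from conftest import make_slab
from oracles import brute_box_count, brute_gliding_box

DYADIC = (2, 4, 8, 16, 32, 64)


class TestBoxCount:
    def test_filled_image_closed_form(self):
        full = np.ones((256, 256), dtype=bool)
        c = box_count(full, DYADIC, n_origins=1)
        assert c.counts[0] == 16384  # (256/2)^2
        assert c.counts[1] == 4096   # (256/4)^2
        assert list(c.counts) == [(256 // e) ** 2 for e in DYADIC]

    def test_single_pixel_always_one(self):
        img = np.zeros((64, 64), dtype=bool)
        img[10, 50] = True
        c = box_count(img, (2, 4, 8, 16), n_origins=4)
        assert all(n == 1.0 for n in c.counts)

    def test_offsets_deterministic_and_include_origin(self):
        offs = grid_offsets(8, 4)
        assert offs[0] == (0, 0)
        assert offs == [(0, 0), (0, 4), (4, 0), (4, 4)]
        assert grid_offsets(8, 1) == [(0, 0)]

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000), st.sampled_from([1, 3, 4, 7]))
    def test_matches_brute_force(self, seed, n_origins):
        rng = np.random.default_rng(seed)
        img = rng.random((64, 64)) < 0.08
        if not img.any():
            return
        for eps in (2, 3, 5, 8, 16):
            per = [brute_box_count(img, eps, off) for off in grid_offsets(eps, n_origins)]
            c = box_count(img, [eps], n_origins)
            assert c.counts[0] == pytest.approx(np.mean(per), abs=0)

    def test_mean_counts_non_increasing(self, healthy_slab):
        from octafractal.preprocess import binarize, skeletonize

        skel = skeletonize(binarize(healthy_slab))
        c = box_count(skel, DYADIC, 4)
        assert all(a >= b for a, b in zip(c.counts, c.counts[1:]))

    def test_errors(self):
        with pytest.raises(EmptyMaskError):
            box_count(np.zeros((32, 32), dtype=bool), (2, 4, 8), 1)
        img = np.ones((32, 32), dtype=bool)
        with pytest.raises(ValidationError):
            box_count(img, (2, 64), 1)  # box larger than image


class TestFitFd:
    def test_filled_power_law_exact(self):
        sizes = (2, 4, 8, 16, 32, 64)
        counts = tuple(float((256 // e) ** 2) for e in sizes)
        fd, fd_raw, r2 = fit_fd(BoxCountCurve(sizes, counts, 1))
        assert fd == 2.0
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_counts_give_zero(self):
        fd, _, _ = fit_fd(BoxCountCurve((2, 4, 8), (1.0, 1.0, 1.0), 1))
        assert fd == 0.0

    def test_sierpinski_carpet_similarity_dimension(self):
        carpet = sierpinski_carpet(5)
        c = box_count(carpet, (1, 3, 9, 27, 81), n_origins=1)
        # self-similarity: N(3^k) = 8^(5-k)
        assert list(c.counts) == [8**5, 8**4, 8**3, 8**2, 8]
        fd, _, _ = fit_fd(c)
        assert fd == pytest.approx(np.log(8) / np.log(3), abs=0.05)

    def test_requires_three_sizes(self):
        with pytest.raises(ValidationError):
            fit_fd(BoxCountCurve((2, 4), (10.0, 5.0), 1))

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 10_000))
    def test_fd_clamped_to_plane_bounds(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((64, 64)) < rng.uniform(0.01, 0.9)
        if not img.any():
            return
        fd, fd_raw, _ = fit_fd(box_count(img, (2, 4, 8, 16), 4))
        assert 0.0 <= fd <= 2.0
        assert abs(fd_raw - fd) < 0.2  # raw slope never far outside [0, 2]


class TestGlidingBox:
    def test_full_image_homogeneous(self):
        lc = gliding_box_lacunarity(np.ones((32, 32), dtype=bool), (2, 4, 8))
        assert all(lam == pytest.approx(1.0) for _, lam in lc)

    def test_single_pixel_bernoulli(self):
        img = np.zeros((16, 20), dtype=bool)
        img[3, 7] = True
        lc = dict(gliding_box_lacunarity(img, (1,)))
        assert lc[1] == pytest.approx(16 * 20)  # 1/p with p = 1/(H*W)

    def test_block_fixture_matches_brute_force(self):
        img = np.zeros((16, 16), dtype=bool)
        img[4:8, 6:10] = True
        for r, lam in gliding_box_lacunarity(img, (2, 4)):
            assert lam == pytest.approx(brute_gliding_box(img, r), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((24, 31)) < 0.15
        if not img.any():
            return
        for r, lam in gliding_box_lacunarity(img, (2, 3, 5, 8)):
            assert lam == pytest.approx(brute_gliding_box(img, r), rel=1e-12)

    def test_empty_skeleton_rejected(self):
        with pytest.raises(EmptyMaskError):
            gliding_box_lacunarity(np.zeros((16, 16), dtype=bool), (2,))


class TestSummarizeLac:
    def test_homogeneous_limit(self):
        assert summarize_lac([(2, 1.0), (4, 1.0)]) == 0.0

    def test_simple_arithmetic(self):
        assert summarize_lac([(2, 2.0), (4, 2.0)]) == pytest.approx(0.5)

    def test_monotone_in_each_lambda(self, rng):
        base = [(2, 1.5), (4, 2.5), (8, 4.0)]
        v0 = summarize_lac(base)
        for i in range(3):
            bumped = list(base)
            bumped[i] = (bumped[i][0], bumped[i][1] + 0.5)
            assert summarize_lac(bumped) > v0

    def test_alternative_modes(self):
        curve = [(2, 2.0), (4, 4.0)]
        assert summarize_lac(curve, "raw") == pytest.approx(3.0)
        assert summarize_lac(curve, "cv2") == pytest.approx(2.0)
        with pytest.raises(ValidationError):
            summarize_lac(curve, "bogus")


class TestAnalyzeSlab:
    def test_healthy_plexus_fd_range(self, healthy_slab):
        res = analyze_slab(healthy_slab)
        assert 1.5 < res.fd <= 2.0
        assert 0.0 <= res.lac < 1.0
        assert res.fit_r2 > 0.9

    def test_all_zero_slab_names_binarize_stage(self):
        with pytest.raises(StageError) as exc:
            analyze_slab(make_slab(np.zeros((64, 64), dtype=np.uint8)))
        assert exc.value.stage == "binarize"

    def test_bit_identical_reruns(self, healthy_slab):
        r1 = analyze_slab(healthy_slab)
        r2 = analyze_slab(healthy_slab)
        assert r1 == r2

    def test_default_fit_range_is_coarse_dyadic(self):
        assert fd_fit_sizes((256, 256)) == [8, 16, 32, 64]
        assert default_box_sizes((256, 256)) == [2, 4, 8, 16, 32, 64]
        assert fd_fit_sizes((64, 64)) == [2, 4, 8, 16]


class TestMonotoneDegradation:
    def test_dropout_decreases_fd_and_increases_lac(self):
        """Increasing ischemic dropout on a fixed plexus should monotonically
        erode space-filling (FD down) and increase gappiness (LAC up);
        checked as a Spearman trend per seed plus an exact sign test."""
        levels = np.linspace(0.0, 0.9, 10)
        n_seeds = 10
        fd_rho, lac_rho = [], []
        for seed in range(n_seeds):
            fds, lacs = [], []
            for d in levels:
                res = analyze_slab(generate_plexus(0.5, float(d), size_px=128, seed=seed))
                fds.append(res.fd)
                lacs.append(res.lac)
            fd_rho.append(sps.spearmanr(levels, fds).statistic)
            lac_rho.append(sps.spearmanr(levels, lacs).statistic)
        # sign test: P(all negative | no trend) = 2^-10 < 0.01
        assert sum(r < 0 for r in fd_rho) == n_seeds
        assert sum(r > 0 for r in lac_rho) == n_seeds
        p_sign = 0.5 ** n_seeds
        assert p_sign < 0.01
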