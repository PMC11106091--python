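import numpy as np
import pytest
from scipy import ndimage

from octafractal.exceptions import ValidationError
from octafractal.fractal import box_count
from octafractal.preprocess import binarize, skeletonize
from octafractal.slab_io import Plexus, read_eye_table
from octafractal.synthetic_data import (
    CohortSpec,
    FixtureKind,
    FixtureSpec,
    GroupCalibration,
    generate_cohort,
    generate_plexus,
    make_fixture,
    sierpinski_carpet,
    write_cohort,
)


class TestFixtures:
    def test_filled(self):
        img = make_fixture(FixtureSpec(FixtureKind.FILLED, 64))
        assert img.shape == (64, 64) and img.all()

    def test_carpet_level3_pixel_count(self):
        img = make_fixture(FixtureSpec(FixtureKind.SIERPINSKI_CARPET, 27, level=3))
        assert img.shape == (27, 27)
        assert int(img.sum()) == 8**3

    def test_carpet_size_level_mismatch(self):
        with pytest.raises(ValidationError):
            make_fixture(FixtureSpec(FixtureKind.SIERPINSKI_CARPET, 32, level=3))

    def test_carpet_level5_self_similar_counts(self):
        img = sierpinski_carpet(5)
        c = box_count(img, [3**k for k in range(6)], n_origins=1)
        assert list(c.counts) == [8 ** (5 - k) for k in range(6)]

    def test_line_and_single_pixel(self):
        line = make_fixture(FixtureSpec(FixtureKind.LINE, 33))
        assert int(line.sum()) == 33
        px = make_fixture(FixtureSpec(FixtureKind.SINGLE_PIXEL, 33))
        assert int(px.sum()) == 1

    def test_random_dust_deterministic(self):
        a = make_fixture(FixtureSpec(FixtureKind.RANDOM_DUST, 64, seed=3))
        b = make_fixture(FixtureSpec(FixtureKind.RANDOM_DUST, 64, seed=3))
        assert np.array_equal(a, b)


class TestGeneratePlexus:
    def test_intact_mesh_touches_all_quadrants(self):
        slab = generate_plexus(0.5, 0.0, seed=5)
        skel = skeletonize(binarize(slab)).skeleton
        H, W = skel.shape
        assert skel[: H // 2, : W // 2].any()
        assert skel[: H // 2, W // 2 :].any()
        assert skel[H // 2 :, : W // 2].any()
        assert skel[H // 2 :, W // 2 :].any()

    def test_faz_is_cleared(self):
        slab = generate_plexus(0.5, 0.0, seed=5)
        mask = binarize(slab).mask
        c = mask.shape[0] // 2
        assert not mask[c - 5 : c + 5, c - 5 : c + 5].any()

    def test_dropout_removes_skeleton(self):
        s0 = skeletonize(binarize(generate_plexus(0.5, 0.0, seed=9))).n_pixels
        s9 = skeletonize(binarize(generate_plexus(0.5, 0.9, seed=9))).n_pixels
        assert s9 < s0

    def test_deterministic_from_seed(self):
        a = generate_plexus(0.5, 0.4, seed=13)
        b = generate_plexus(0.5, 0.4, seed=13)
        assert np.array_equal(a.pixels, b.pixels)

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            generate_plexus(0.0, 0.0)
        with pytest.raises(ValidationError):
            generate_plexus(0.5, 1.0)
        with pytest.raises(ValidationError):
            generate_plexus(0.5, 0.0, size_px=16)


class TestGenerateCohort:
    def test_default_composition(self):
        recs, slabs = generate_cohort(CohortSpec(seed=1, image_size_px=64))
        assert len(recs) == 50
        n_npa = sum(r.npa_quadrants >= 1 for r in recs)
        assert n_npa == 30 and len(recs) - n_npa == 20
        hist = {q: sum(r.npa_quadrants == q for r in recs) for q in (1, 2, 3, 4)}
        assert hist == {1: 6, 2: 4, 3: 9, 4: 11}
        assert len(slabs) == 100  # both plexuses per eye

    def test_covariates_in_clinical_ranges(self):
        recs, _ = generate_cohort(CohortSpec(seed=2, image_size_px=64))
        for r in recs:
            assert 0 <= r.bcva_letters <= 100
            assert 150 <= r.cmt_um <= 900
            assert 18 <= r.age_years <= 95

    def test_spec_invariant_quadrant_sum(self):
        with pytest.raises(ValidationError):
            CohortSpec(n_eyes=50, quadrant_distribution=(6, 4, 9, 10))

    def test_write_cohort_deterministic(self, tmp_path):
        d1 = write_cohort(tmp_path / "a", CohortSpec(seed=3, n_eyes=5, npa_fraction=0.6,
                                                     quadrant_distribution=(1, 1, 0, 1),
                                                     image_size_px=64))
        d2 = write_cohort(tmp_path / "b", CohortSpec(seed=3, n_eyes=5, npa_fraction=0.6,
                                                     quadrant_distribution=(1, 1, 0, 1),
                                                     image_size_px=64))
        assert (d1 / "eyes.csv").read_bytes() == (d2 / "eyes.csv").read_bytes()
        for rec in read_eye_table(d1 / "eyes.csv"):
            for plexus in ("SCP", "DCP"):
                f1 = d1 / rec.eye_id / f"{rec.eye_id}_{plexus}.png"
                f2 = d2 / rec.eye_id / f"{rec.eye_id}_{plexus}.png"
                assert f1.read_bytes() == f2.read_bytes()

    def test_effect_direction_single_seed(self):
        """NPA eyes must show lower FD and higher LAC than well-perfused eyes
        at both plexuses in any default cohort."""
        from octafractal.fractal import analyze_slab

        recs, slabs = generate_cohort(CohortSpec(seed=11))
        res = {k: analyze_slab(s) for k, s in slabs.items()}
        for plexus in (Plexus.SCP, Plexus.DCP):
            fd_npa = np.mean([res[(r.eye_id, plexus)].fd for r in recs if r.npa_quadrants >= 1])
            fd_wp = np.mean([res[(r.eye_id, plexus)].fd for r in recs if r.npa_quadrants == 0])
            lac_npa = np.mean([res[(r.eye_id, plexus)].lac for r in recs if r.npa_quadrants >= 1])
            lac_wp = np.mean([res[(r.eye_id, plexus)].lac for r in recs if r.npa_quadrants == 0])
            assert fd_npa < fd_wp
            assert lac_npa > lac_wp


class TestGroupCalibration:
    def test_defaults_transcribe_group_targets(self):
        calib = GroupCalibration()
        assert (calib.fd_scp_npa.mean, calib.fd_scp_npa.sd) == (1.21, 0.58)
        assert (calib.fd_scp_wp.mean, calib.fd_scp_wp.sd) == (1.92, 0.03)
        assert (calib.lac_scp_npa.mean, calib.lac_scp_npa.sd) == (0.39, 0.06)
        assert (calib.fd_dcp_wp.mean, calib.fd_dcp_wp.sd) == (1.94, 0.03)
        assert (calib.bcva_npa.mean, calib.bcva_npa.sd) == (61.83, 12.23)
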