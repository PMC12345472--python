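"""Tests for the longitudinal synthetic face generator."""

import dataclasses
import math

import numpy as np
import pytest

from sheepface import synthetic_faces as sf


class TestIdentity:
    def test_same_seed_gives_identical_params(self):
        assert sf.make_identity(7) == sf.make_identity(7)

    def test_distinct_seeds_give_distinct_params(self):
        params = [sf.make_identity(s) for s in range(1, 101)]
        assert len({(p.eye_spacing, p.nose_offset, p.base_hue) for p in params}) == 100

    @pytest.mark.parametrize("seed", [0, 1, 17, 999, 2**31 - 1])
    def test_fields_within_bounds(self, seed):
        p = sf.make_identity(seed)
        lo, hi = sf.EYE_SPACING_RANGE
        assert lo <= p.eye_spacing <= hi
        assert sf.NOSE_DX_RANGE[0] <= p.nose_offset[0] <= sf.NOSE_DX_RANGE[1]
        assert 0.0 <= p.base_hue <= 1.0
        assert 0 <= p.marking_code < sf.N_MARKINGS

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            sf.IdentityParams(eye_spacing=0.9, nose_offset=(0.0, 0.3),
                              coat_seed=1, marking_code=0, base_hue=0.5)


class TestGrowthScale:
    def test_zero_age(self):
        assert sf.growth_scale(0.0, sf.GrowthModel()) == 0.0

    def test_at_tau_closed_form(self):
        g = sf.GrowthModel(s_max=2.0, tau=3.0)
        expected = 2.0 * (1.0 - math.exp(-1.0))
        assert sf.growth_scale(3.0, g) == pytest.approx(expected, abs=1e-12)

    def test_asymptote(self):
        g = sf.GrowthModel(s_max=1.0, tau=2.0)
        assert sf.growth_scale(120.0, g) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_nondecreasing(self):
        g = sf.GrowthModel()
        vals = [sf.growth_scale(a, g) for a in np.linspace(0, 12, 49)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            sf.GrowthModel(tau=0.0)

    def test_fur_zero_before_onset(self):
        g = sf.GrowthModel()
        assert g.fur_gain * max(0.0, 7 - g.fur_onset) == 0.0


class TestRenderFace:
    def test_deterministic(self):
        ident = sf.make_identity(3)
        nuis = sf.NuisanceParams(gain=1.1, rotation_deg=5.0, noise_sigma=0.01,
                                 seed=42)
        a = sf.render_face(ident, 6, nuis)
        b = sf.render_face(ident, 6, nuis)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.box == b.box

    def test_identity_nuisance_is_noop(self):
        ident = sf.make_identity(3)
        clean = sf.NuisanceParams()
        noisy_seed = sf.NuisanceParams(gain=1.0, bias=0.0, rotation_deg=0.0,
                                       noise_sigma=0.0, seed=777)
        assert np.array_equal(sf.render_face(ident, 6, clean).pixels,
                              sf.render_face(ident, 6, noisy_seed).pixels)

    def test_growth_confined_to_predicted_region(self):
        # ages 3 vs 9 with zero nuisance differ only inside the larger head box
        ident = sf.make_identity(5)
        clean = sf.NuisanceParams()
        young = sf.render_face(ident, 3, clean)
        old = sf.render_face(ident, 9, clean)
        diff = np.abs(young.pixels - old.pixels).max(axis=0)
        x, y, w, h = old.box
        outside = np.ones_like(diff, dtype=bool)
        outside[y:y + h, x:x + w] = False
        assert diff[outside].max() < 1e-6
        assert diff[~outside].max() > 0.01

    def test_valid_image_contract(self):
        face = sf.render_face(sf.make_identity(1), 12,
                              sf.NuisanceParams(rotation_deg=30.0,
                                                noise_sigma=0.05, seed=1))
        face.validate()

    def test_bad_age_rejected(self):
        with pytest.raises(ValueError):
            sf.render_face(sf.make_identity(1), 0, sf.NuisanceParams())

    def test_too_small_canvas_rejected(self):
        with pytest.raises(ValueError):
            sf.render_face(sf.make_identity(1), 6, sf.NuisanceParams(),
                           size=(8, 8))


class TestAugmentation:
    def test_output_length_is_four(self):
        face = sf.render_face(sf.make_identity(2), 4, sf.NuisanceParams())
        out = sf.augment_image(face, seed=0)
        assert len(out) == 4
        assert out[0] is face
        assert all(im.sheep_id == face.sheep_id for im in out)
        assert all(im.age_months == face.age_months for im in out)
        assert all(im.origin == "augmented" for im in out[1:])

    def test_zero_ranges_give_copies(self):
        face = sf.render_face(sf.make_identity(2), 4, sf.NuisanceParams())
        policy = sf.AugmentPolicy(gain_range=0.0, bias_range=0.0,
                                  noise_sigma=0.0, rotation_deg=0.0)
        out = sf.augment_image(face, policy, seed=5)
        for im in out:
            assert np.allclose(im.pixels, face.pixels, atol=1e-7)

    def test_deterministic_given_seed(self):
        face = sf.render_face(sf.make_identity(2), 4, sf.NuisanceParams())
        a = sf.augment_image(face, seed=9)
        b = sf.augment_image(face, seed=9)
        for im1, im2 in zip(a, b):
            assert np.array_equal(im1.pixels, im2.pixels)

    def test_configurable_multiplier(self):
        face = sf.render_face(sf.make_identity(2), 4, sf.NuisanceParams())
        out = sf.augment_image(face, sf.AugmentPolicy(multiplier=6), seed=0)
        assert len(out) == 6


class TestCohortGeneration:
    def test_record_count_arithmetic(self):
        _, records = sf.generate_cohort(10, ages=range(1, 13), reps_per_cell=2,
                                        seed=0)
        assert len(records) == 10 * 12 * 2

    def test_age_based_split_counts(self):
        _, records = sf.generate_cohort(10, ages=range(1, 13), reps_per_cell=2,
                                        seed=0)
        counts = {}
        for r in records:
            counts[r.split] = counts.get(r.split, 0) + 1
        assert counts == {"train": 80, "val": 80, "test": 80}

    def test_augment_multiplies_train_only(self):
        _, records = sf.generate_cohort(10, ages=range(1, 13), reps_per_cell=2,
                                        seed=0, augment_train=True)
        counts = {}
        for r in records:
            counts[r.split] = counts.get(r.split, 0) + 1
        assert counts == {"train": 320, "val": 80, "test": 80}

    def test_id_based_split_disjoint(self):
        _, records = sf.generate_cohort(10, ages=[2, 6, 10], reps_per_cell=1,
                                        protocol="id_based", seed=4)
        by_split = {}
        for r in records:
            by_split.setdefault(r.split, set()).add(r.sheep_id)
        assert by_split["train"] & by_split["val"] == set()
        assert by_split["train"] & by_split["test"] == set()
        assert by_split["val"] & by_split["test"] == set()

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            sf.generate_cohort(4, protocol="random", seed=0)

    def test_empty_ages_rejected(self):
        with pytest.raises(ValueError):
            sf.generate_cohort(4, ages=[], seed=0)

    def test_reproducible_bit_for_bit(self):
        im1, _ = sf.generate_cohort(3, ages=[1, 5], reps_per_cell=1, seed=77)
        im2, _ = sf.generate_cohort(3, ages=[1, 5], reps_per_cell=1, seed=77)
        for a, b in zip(im1, im2):
            assert np.array_equal(a.pixels, b.pixels)

    def test_identity_age_independence(self):
        # identity factors are drawn independently of age by construction:
        # sample correlation over >= 1000 cells stays near zero
        n_ids, ages = 100, list(range(1, 13))
        root = np.random.SeedSequence(123)
        seeds = root.generate_state(n_ids)
        spacings = np.array([sf.make_identity(int(s)).eye_spacing for s in seeds])
        hues = np.array([sf.make_identity(int(s)).base_hue for s in seeds])
        grid_ages = np.repeat(ages, n_ids)
        for field in (spacings, hues):
            vals = np.tile(field, len(ages))
            assert abs(np.corrcoef(vals, grid_ages)[0, 1]) < 0.05

    def test_dataset_written_to_disk(self, tmp_path):
        manifest = sf.generate_dataset(3, ages=[1, 5, 9], reps_per_cell=1,
                                       seed=0, out_dir=tmp_path)
        assert len(manifest.records) == 9
        for rec in manifest.records:
            assert (tmp_path / rec.path).exists()
        px = sf.load_png(tmp_path / manifest.records[0].path)
        assert px.shape == (3, 64, 64)
        assert 0.0 <= px.min() and px.max() <= 1.0


class TestManifestInvariants:
    def test_age_window_violation_rejected(self):
        rec = sf.ManifestRecord(path="a.png", sheep_id="s0", age_months=9,
                                box=(0, 0, 4, 4), split="train")
        with pytest.raises(ValueError):
            sf.DatasetManifest(records=[rec], protocol="age_based")

    def test_id_overlap_rejected(self):
        recs = [
            sf.ManifestRecord("a.png", "s0", 3, (0, 0, 4, 4), "train"),
            sf.ManifestRecord("b.png", "s0", 5, (0, 0, 4, 4), "val"),
        ]
        with pytest.raises(ValueError):
            sf.DatasetManifest(records=recs, protocol="id_based")

    def test_counts_match_tallies(self):
        _, records = sf.generate_cohort(4, ages=[2, 6, 10], reps_per_cell=2,
                                        seed=1)
        m = sf.DatasetManifest(records=records, protocol="age_based")
        assert sum(m.counts.values()) == len(records)
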