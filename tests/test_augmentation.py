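"""Geometric label transport and the DCGAN generator/discriminator."""

import numpy as np
import pytest

from scintiseg.annotation import LesionMask
from scintiseg.augment import (AugmentedSample, GanConfig, GeometricTransform,
                               apply_transform, augment_dataset, default_recipe,
                               gan_value, generate_gan_samples, train_dcgan)
from scintiseg.scan_io import CountMatrix


def _sample(rng, i=0, size=32):
    img = CountMatrix(rng.integers(0, 300, (size, size), dtype=np.uint16))
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[8:14, 10:18] = 1
    return AugmentedSample(sample_id=f"s{i}", image=img,
                           mask=LesionMask(mask), patient_key=f"p{i % 4}")


class TestApplyTransform:
    def test_hflip_involution(self, rng):
        s = _sample(rng)
        t = GeometricTransform("hflip")
        img1, m1 = apply_transform(s.image, s.mask, t)
        img2, m2 = apply_transform(img1, m1, t)
        np.testing.assert_array_equal(img2.counts, s.image.counts)
        np.testing.assert_array_equal(m2.mask, s.mask.mask)

    def test_four_quarter_turns_are_identity_on_mask(self, rng):
        s = _sample(rng)
        img, mask = s.image, s.mask
        for _ in range(4):
            img, mask = apply_transform(img, mask,
                                        GeometricTransform("rotate",
                                                           angle_deg=90.0))
        np.testing.assert_array_equal(mask.mask, s.mask.mask)

    def test_integer_translation_matches_index_oracle(self, rng):
        s = _sample(rng)
        img, mask = apply_transform(s.image, s.mask,
                                    GeometricTransform("translate",
                                                       shift=(5.0, 0.0)))
        h, w = s.image.counts.shape
        for r in range(h):
            for c in range(w - 5):
                assert img.counts[r, c + 5] == s.image.counts[r, c]
        assert (img.counts[:, :5] == 0).all()
        assert mask.mask.sum() == s.mask.mask.sum()

    def test_mask_stays_binary_under_rotation(self, rng):
        s = _sample(rng)
        _, mask = apply_transform(s.image, s.mask,
                                  GeometricTransform("rotate", angle_deg=17.0))
        assert set(np.unique(mask.mask)) <= {0, 1}

    def test_oversized_translation_rejected(self, rng):
        s = _sample(rng)
        with pytest.raises(ValueError, match="larger than image"):
            apply_transform(s.image, s.mask,
                            GeometricTransform("translate", shift=(40.0, 0.0)))

    def test_label_transport_flip_dsc_one(self, rng):
        s = _sample(rng)
        img, mask = apply_transform(s.image, s.mask, GeometricTransform("vflip"))
        np.testing.assert_array_equal(mask.mask, s.mask.mask[::-1, :])


class TestAugmentDataset:
    def test_default_recipe_scale_matches_targets(self, rng):
        # 112 sources x (19 variants + original) = 2240 ~ the 2280-sample
        # augmented-set scale
        assert len(default_recipe()) == 19
        sources = 112
        expected = sources * (len(default_recipe()) + 1)
        assert abs(expected - 2280) / 2280 < 0.05

    def test_empty_recipe_returns_originals(self, rng):
        samples = [_sample(rng, i) for i in range(3)]
        assert augment_dataset(samples, []) == samples

    def test_provenance_complete_and_patient_preserved(self, rng):
        samples = [_sample(rng, i, size=16) for i in range(4)]
        recipe = [[GeometricTransform("hflip")],
                  [GeometricTransform("translate", shift=(2.0, 0.0))]]
        out = augment_dataset(samples, recipe)
        assert len(out) == 4 * 3
        ids = {s.sample_id for s in samples}
        for s in out:
            if s.provenance == "original":
                continue
            assert s.source_id in ids
            assert s.patient_key == next(o.patient_key for o in samples
                                         if o.sample_id == s.source_id)
            assert s.transform

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            augment_dataset([], [])


class TestGanValue:
    def test_equilibrium_value(self):
        v = gan_value(np.full(8, 0.5), np.full(8, 0.5))
        assert v == pytest.approx(-2 * np.log(2), abs=1e-12)

    def test_perfect_discriminator_limit(self):
        eps = 1e-6
        v = gan_value(np.full(4, 1 - eps), np.full(4, eps))
        assert -1e-5 < v < 0

    def test_matches_scalar_oracle(self, rng):
        for _ in range(10):
            dr = rng.uniform(0.01, 0.99, 17)
            df = rng.uniform(0.01, 0.99, 13)
            oracle = (sum(np.log(x) for x in dr) / len(dr)
                      + sum(np.log(1 - x) for x in df) / len(df))
            assert gan_value(dr, df) == pytest.approx(oracle, abs=1e-10)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gan_value(np.array([]), np.array([0.5]))


def _blob_images(rng, n, size=16):
    """Toy distribution: Gaussian blobs at random positions."""
    yy, xx = np.mgrid[0:size, 0:size]
    imgs = []
    for _ in range(n):
        cy, cx = rng.uniform(4, size - 4, 2)
        img = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 8.0)
        imgs.append(img)
    return np.asarray(imgs)


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    real = _blob_images(rng, 48, 16)
    cfg = GanConfig(image_size=16, latent_dim=8, base_channels=4,
                    steps=60, batch_size=12, seed=0)
    return real, cfg, train_dcgan(real, cfg)


class TestDcgan:

    def test_k_discriminator_steps_per_generator_step(self, trained):
        _, cfg, result = trained
        assert cfg.iterations_k == 3
        for step in range(cfg.steps):
            entries = [h for h in result.history if h["step"] == step]
            phases = [h["phase"] for h in entries]
            assert phases == ["discriminator"] * 3 + ["generator"]

    def test_discriminator_approaches_chance(self, trained):
        real, cfg, result = trained
        values = [h["value"] for h in result.history
                  if h["phase"] == "discriminator"]
        # the minimax value rises toward the equilibrium -2 ln 2 as the
        # generator catches up: late values exceed the early ones on average
        early = np.mean(values[:30])
        late = np.mean(values[-30:])
        assert late > early

    def test_fixed_seed_reproducible_history(self, trained):
        real, cfg, _ = trained
        h1 = train_dcgan(real, cfg).history
        h2 = train_dcgan(real, cfg).history
        assert [e["loss"] for e in h1[:20]] == [e["loss"] for e in h2[:20]]

    def test_generated_samples_shape_range_determinism(self, trained):
        _, cfg, result = trained
        a = generate_gan_samples(result.generator, 5, seed=3)
        b = generate_gan_samples(result.generator, 5, seed=3)
        assert a.shape == (5, 16, 16)
        assert (a >= 0).all() and (a <= 1).all()
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            generate_gan_samples(result.generator, 0)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            train_dcgan(np.zeros((4, 16, 17)),
                        GanConfig(image_size=16, steps=1))
        with pytest.raises(ValueError):
            GanConfig(iterations_k=0)
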