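import numpy as np
import pytest

import _oracles
from mammogc import (
    GCParams,
    SeedSet,
    data_cost,
    energy,
    estimate_label_models,
    expansion_move,
    generate_phantom,
    remove_pectoral,
    sample_truth_seeds,
    segment,
    smooth_weight,
)
from mammogc import PhantomSpec
from mammogc import labels as L


class TestLabelModels:
    def test_degenerate_histogram_concentrates_at_seed_intensity(self):
        img = np.full((5, 5), 100, dtype=np.uint8)
        models = estimate_label_models(img, [(0, 0, 0), (1, 1, 0), (4, 4, 1)])
        eps = GCParams().epsilon
        assert models[0][100] == pytest.approx(1 / (1 + 255 * eps))
        assert (models[0] > 0).all()
        assert models[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_seed_intensities_give_identical_models(self):
        img = np.full((4, 4), 60, dtype=np.uint8)
        models = estimate_label_models(img, [(0, 0, 0), (3, 3, 1)])
        assert np.array_equal(models[0], models[1])

    def test_two_to_one_bin_ratio(self):
        img = np.zeros((1, 4), dtype=np.uint8)
        img[0, :2] = 50
        img[0, 2] = 150
        img[0, 3] = 200
        models = estimate_label_models(
            img, [(0, 0, 4), (0, 1, 4), (0, 2, 4), (0, 3, 1)]
        )
        assert models[4][50] / models[4][150] == pytest.approx(2.0)

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            estimate_label_models(np.zeros((3, 3), dtype=np.uint8), [])

    def test_parzen_smoothing_spreads_mass_but_keeps_peak(self):
        img = np.full((3, 3), 100, dtype=np.uint8)
        m = estimate_label_models(img, [(0, 0, 0), (2, 2, 1)],
                                  GCParams(model_sigma=4.0))
        assert m[0].argmax() == 100
        assert m[0][104] > m[0][120] > 0


class TestDataCost:
    def test_uniform_model_costs_ln256(self):
        models = {0: np.full(256, 1 / 256)}
        assert data_cost(models, 37, 0) == pytest.approx(np.log(256))

    def test_seed_override(self):
        params = GCParams()
        assert data_cost({}, 10, 3, seed_label=3, params=params) == 0.0
        assert data_cost({}, 10, 2, seed_label=3, params=params) == params.hard_cost

    def test_mode_near_one_costs_near_zero(self):
        img = np.full((4, 4), 200, dtype=np.uint8)
        models = estimate_label_models(img, [(0, 0, 0), (1, 1, 1)])
        assert data_cost(models, 200, 0) == pytest.approx(0.0, abs=1e-3)


class TestSmoothWeight:
    def test_zero_contrast_unit_distance(self):
        assert smooth_weight(80, 80, 1.0) == 1.0

    def test_one_sigma_contrast(self):
        p = GCParams()
        assert smooth_weight(100, 100 + p.sigma, 1.0, p) == pytest.approx(np.exp(-0.5))

    def test_diagonal_distance(self):
        assert smooth_weight(80, 80, np.sqrt(2)) == pytest.approx(1 / np.sqrt(2))


class TestEnergy:
    def test_uniform_labeling_has_zero_smooth_term(self, rng):
        img = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        seeds = [(0, 0, 0), (4, 4, 1)]
        models = estimate_label_models(img, seeds)
        lab = np.zeros((5, 5), dtype=int)
        assert energy(img, lab, models, seeds).smooth_term == 0.0

    def test_two_seeded_pixels_different_labels(self):
        img = np.full((2, 1), 90, dtype=np.uint8)
        seeds = [(0, 0, 0), (1, 0, 1)]
        models = estimate_label_models(img, seeds)
        lab = np.array([[0], [1]])
        e = energy(img, lab, models, seeds)
        # both pixels seeded with their own labels: data 0; one unit-weight pair
        assert e.data_term == 0.0
        assert e.smooth_term == pytest.approx(1.0)
        assert e.total == pytest.approx(GCParams().mu)

    def test_matches_independent_loop_oracle(self, rng):
        params = GCParams()
        for _ in range(5):
            img = rng.integers(0, 256, (3, 4)).astype(np.uint8)
            seeds = SeedSet([(0, 0, 0), (2, 3, 1)])
            models = estimate_label_models(img, seeds, params)
            lab = rng.integers(0, 2, (3, 4))
            expected = _oracles.oracle_energy(
                img, lab, models, seeds.seed_label_map(img.shape),
                params.lam, params.mu, params.sigma, params.hard_cost,
            )
            got = energy(img, lab, models, seeds, params).total
            assert got == pytest.approx(expected, rel=1e-12)

    def test_label_outside_scheme_rejected(self):
        img = np.zeros((2, 2), dtype=np.uint8)
        seeds = [(0, 0, 0), (1, 1, 1)]
        models = estimate_label_models(img, seeds)
        with pytest.raises(ValueError):
            energy(img, np.full((2, 2), 5), models, seeds)


class TestExpansionMove:
    def test_all_alpha_labeling_unchanged(self, rng):
        img = rng.integers(0, 256, (4, 4)).astype(np.uint8)
        seeds = [(0, 0, 1), (3, 3, 2), (0, 3, 3)]
        models = estimate_label_models(img, seeds)
        lab = np.full((4, 4), 1)
        out = expansion_move(lab, 1, img, models, seeds)
        assert np.array_equal(out, lab)

    def test_binary_expansion_reaches_global_optimum(self, rng):
        params = GCParams()
        for _ in range(5):
            img = rng.integers(0, 256, (3, 3)).astype(np.uint8)
            seeds = SeedSet([(0, 0, 0), (2, 2, 1)])
            models = estimate_label_models(img, seeds, params)
            out = expansion_move(np.zeros((3, 3), dtype=int), 1, img, models,
                                 seeds, params)
            e_gc = energy(img, out, models, seeds, params).total
            e_bf = _oracles.brute_force_min_energy_binary(
                img, models, seeds.seed_label_map(img.shape),
                params.lam, params.mu, params.sigma, params.hard_cost,
            )
            assert e_gc == pytest.approx(e_bf, rel=1e-9, abs=1e-6)

    def test_seeded_pixels_never_flip(self, rng):
        img = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        entries = [(0, 0, 0), (5, 5, 1), (0, 5, 2), (2, 2, 2)]
        models = estimate_label_models(img, entries)
        lab = np.zeros((6, 6), dtype=int)
        for r, c, l in entries:
            lab[r, c] = l
        for alpha in (0, 1, 2):
            lab = expansion_move(lab, alpha, img, models, entries)
            for r, c, l in entries:
                assert lab[r, c] == l


class TestSegment:
    def test_two_intensity_halves_recovered_exactly(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[:, :2] = 50
        img[:, 2:] = 200
        seeds = SeedSet([(0, 0, 0), (0, 3, 1)])
        params = GCParams()
        lab, e = segment(img, seeds, params)
        expected = np.where(img == 50, 0, 1)
        assert np.array_equal(lab, expected)
        models = estimate_label_models(img, seeds, params)
        e_bf = _oracles.brute_force_min_energy_binary(
            img, models, seeds.seed_label_map(img.shape),
            params.lam, params.mu, params.sigma, params.hard_cost,
        )
        assert e.total == pytest.approx(e_bf, rel=1e-9)

    def test_noiseless_phantom_recovered(self, noiseless_phantom):
        ph = noiseless_phantom
        img = remove_pectoral(ph.image, (ph.truth == L.PECTORAL).astype(np.uint8))
        img[ph.truth == L.ARTIFACT] = 0  # preprocessing would have erased it
        seeds = sample_truth_seeds(ph, per_region=3, rng=2)
        seeds += [(int(r), int(c), L.BACKGROUND)
                  for r, c in zip(*np.nonzero(ph.truth == L.PECTORAL))]
        lab, _ = segment(img, seeds, GCParams())
        truth = ph.truth.copy()
        truth[(ph.truth == L.PECTORAL) | (ph.truth == L.ARTIFACT)] = L.BACKGROUND
        assert (lab == truth).mean() >= 0.99

    def test_mu_zero_reduces_to_data_argmin(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        entries = [(0, 0, 0), (7, 7, 1), (0, 7, 2)]
        params = GCParams(mu=0.0)
        lab, _ = segment(img, SeedSet(entries), params)
        models = estimate_label_models(img, entries, params)
        costs = np.stack([-np.log(models[j][img]) for j in (0, 1, 2)], axis=-1)
        expected = np.argmin(costs, axis=-1)
        for r, c, l in entries:
            expected[r, c] = l
        assert np.array_equal(lab, expected)

    def test_energy_history_never_increases(self, rng):
        for _ in range(3):
            img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
            entries = [(0, 0, 0), (7, 7, 1), (0, 7, 2), (7, 0, 4)]
            _, _, hist = segment(img, SeedSet(entries), GCParams(),
                                 return_history=True)
            assert all(b <= a for a, b in zip(hist, hist[1:]))

    def test_deterministic(self, rng):
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        entries = [(0, 0, 0), (9, 9, 1), (0, 9, 2)]
        a, ea = segment(img, SeedSet(entries), GCParams())
        b, eb = segment(img, SeedSet(entries), GCParams())
        assert np.array_equal(a, b)
        assert ea == eb

    def test_joint_scaling_of_weights_preserves_argmin(self, rng):
        img = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        entries = [(0, 0, 0), (5, 5, 1), (0, 5, 3)]
        lab1, e1 = segment(img, SeedSet(entries), GCParams(lam=10, mu=20))
        lab2, e2 = segment(img, SeedSet(entries), GCParams(lam=30, mu=60))
        assert np.array_equal(lab1, lab2)
        assert e2.total == pytest.approx(3 * e1.total, rel=1e-6)

    def test_seed_preservation_end_to_end(self, noisy_phantom):
        ph = noisy_phantom
        seeds = sample_truth_seeds(ph, per_region=4, rng=5)
        lab, _ = segment(ph.image, seeds, GCParams(model_sigma=4.0))
        for r, c, l in seeds:
            assert lab[r, c] == l

    def test_mass_centroid_inside_truth_disk(self):
        spec = PhantomSpec(noise_sd=6.0, has_mass=True, rng_seed=21)
        ph = generate_phantom(spec)
        seeds = sample_truth_seeds(ph, per_region=25, rng=6)
        seeds += [(int(r), int(c), L.BACKGROUND)
                  for r, c in zip(*np.nonzero(ph.truth == L.PECTORAL))]
        img = remove_pectoral(ph.image, (ph.truth == L.PECTORAL).astype(np.uint8))
        lab, _ = segment(img, seeds, GCParams(model_sigma=4.0))
        rows, cols = np.nonzero(lab == L.MASS)
        assert rows.size > 0
        cy, cx = rows.mean(), cols.mean()
        trows, tcols = np.nonzero(ph.truth == L.MASS)
        tcy, tcx = trows.mean(), tcols.mean()
        radius = np.sqrt((ph.truth == L.MASS).sum() / np.pi)
        assert np.hypot(cy - tcy, cx - tcx) <= radius

    def test_validation_errors(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):  # conflicting seeds at one pixel
            segment(img, [(0, 0, 0), (0, 0, 1), (3, 3, 2)], GCParams())
        with pytest.raises(ValueError):  # too few labels
            segment(img, [(0, 0, 0)], GCParams())
        with pytest.raises(ValueError):  # out of bounds
            segment(img, [(9, 9, 0), (0, 0, 1)], GCParams())
        with pytest.raises(ValueError):  # empty image
            segment(np.zeros((0, 0), dtype=np.uint8), [(0, 0, 0)], GCParams())
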