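"""Superpixel segmentation, surrogate fitting, explanation masks and
geometric region attribution."""

import numpy as np
import pytest

import mycotax as mt
from mycotax.explanation import (
    _mean_fill,
    explain,
    fit_surrogate,
    perturb_and_query,
    quickshift_segment,
    region_area_shares,
    region_attribution,
)
from mycotax.synthetic import IsolateRecord


class TestQuickshiftSegment:
    def test_constant_image_single_segment(self):
        img = np.full((48, 48, 3), 120, np.uint8)
        seg = quickshift_segment(img)
        assert seg.n_segments == 1
        assert (seg.labels == 0).all()

    def test_homogeneous_halves_respect_boundary(self):
        img = np.zeros((48, 48, 3), np.uint8)
        img[:, :24] = (200, 30, 30)
        img[:, 24:] = (30, 30, 200)
        seg = quickshift_segment(img)
        left = set(np.unique(seg.labels[:, :24]).tolist())
        right = set(np.unique(seg.labels[:, 24:]).tolist())
        assert not left & right

    def test_colony_segment_count_band(self, small_dataset):
        """Colony renders at working resolution segment into a sane number
        of superpixels with fine-grained parameters."""
        for img in small_dataset.images[:4]:
            seg = quickshift_segment(img, kernel_size=3, max_distance=10)
            assert 5 <= seg.n_segments <= 300

    def test_labels_cover_every_pixel(self, small_dataset):
        seg = quickshift_segment(small_dataset.images[0], kernel_size=3, max_distance=10)
        assert seg.labels.min() == 0
        assert seg.labels.max() == seg.n_segments - 1
        assert np.array_equal(np.unique(seg.labels), np.arange(seg.n_segments))

    def test_rejects_nonpositive_params(self):
        img = np.zeros((10, 10, 3), np.uint8)
        with pytest.raises(ValueError):
            quickshift_segment(img, kernel_size=0)


class _StubModel:
    """Deterministic model whose class-0 probability is the kept-pixel
    fraction of a designated segment (plus a floor), for contract tests."""

    def __init__(self, segments, target=0):
        self.segments = segments
        self.target = target
        self.classes = {"phylum": ["on", "off"]}

    def predict_proba(self, images):
        probs = np.empty((len(images), 2))
        for i, img in enumerate(images):
            m = self.segments.labels == self.target
            # bright fraction of the target segment stands in for "kept"
            frac = (img[m].astype(float).mean() / 255.0)
            probs[i] = (0.2 + 0.6 * frac, 0.8 - 0.6 * frac)
        return {"phylum": probs}


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(0)
    img = np.zeros((24, 24, 3), np.uint8)
    img[:12] = 230
    img[12:, :12] = 30
    img[12:, 12:] = rng.integers(100, 140, (12, 12, 3))
    seg = quickshift_segment(img, kernel_size=2, max_distance=6)
    model = _StubModel(seg)
    return img, seg, model


class TestPerturbAndQuery:
    def test_first_row_is_unperturbed(self, setup):
        img, seg, model = setup
        designs, outputs, distances = perturb_and_query(img, seg, model, "phylum",
                                                        n=32, seed=1)
        assert designs.shape == (32, seg.n_segments)
        assert (designs[0] == 1).all()
        assert distances[0] == pytest.approx(0.0, abs=1e-12)
        p0 = model.predict_proba(img[None])["phylum"][0, 0]
        assert outputs[0] == pytest.approx(p0)

    def test_outputs_match_manual_masking(self, setup):
        img, seg, model = setup
        designs, outputs, _ = perturb_and_query(img, seg, model, "phylum", n=16, seed=2)
        filled = _mean_fill(img, seg)
        for row, out in list(zip(designs, outputs))[:8]:
            keep = row.astype(bool)[seg.labels]
            manual = np.where(keep[:, :, None], img, filled)
            expect = model.predict_proba(manual[None])["phylum"][0, 0]
            assert out == pytest.approx(expect)

    def test_distance_is_cosine_to_all_ones(self, setup):
        img, seg, model = setup
        designs, _, distances = perturb_and_query(img, seg, model, "phylum", n=32, seed=3)
        k = seg.n_segments
        for row, d in zip(designs, distances):
            kept = row.sum()
            expect = 1.0 - kept / (np.sqrt(kept) * np.sqrt(k)) if kept else 1.0
            assert d == pytest.approx(expect)

    def test_rejects_tiny_neighborhood(self, setup):
        img, seg, model = setup
        with pytest.raises(ValueError):
            perturb_and_query(img, seg, model, "phylum", n=1)


class TestFitSurrogate:
    def test_planted_single_segment_signal(self):
        rng = np.random.default_rng(4)
        designs = (rng.random((200, 8)) < 0.5).astype(float)
        designs[0] = 1
        outputs = designs[:, 3].copy()
        distances = 1 - designs.mean(axis=1)
        w = fit_surrogate(designs, outputs, distances)
        assert np.argmax(np.abs(w)) == 3
        assert w[3] > 10 * np.abs(np.delete(w, 3)).max()

    def test_constant_outputs_zero_coefficients(self):
        rng = np.random.default_rng(5)
        designs = (rng.random((50, 6)) < 0.5).astype(float)
        w = fit_surrogate(designs, np.full(50, 0.7), np.zeros(50))
        assert np.abs(w).max() < 1e-8

    def test_duplicated_rows_equal_summed_weights(self):
        """WLS algebra: duplicating a design row is the same fit as doubling
        its kernel weight."""
        rng = np.random.default_rng(6)
        designs = (rng.random((30, 5)) < 0.5).astype(float)
        outputs = rng.random(30)
        distances = rng.random(30) * 0.5
        dup = np.concatenate([designs, designs])
        w_dup = fit_surrogate(dup, np.concatenate([outputs, outputs]),
                              np.concatenate([distances, distances]))
        # equivalent single-copy fit with doubled weights: same distances
        # scaled so exp(-d^2/kw^2) doubles is messy; instead fit directly
        # against the normal equations with 2x weights
        kw = 0.25
        wts = 2 * np.exp(-(distances**2) / kw**2)
        X = np.hstack([designs, np.ones((30, 1))])
        A = X.T @ (X * wts[:, None])
        A[np.diag_indices_from(A)] += 1e-8
        beta = np.linalg.solve(A, (X * wts[:, None]).T @ outputs)
        assert np.allclose(w_dup, beta[:-1], atol=1e-6)

    def test_matches_exact_normal_equations(self):
        """On small designs the fit equals an independent lstsq solve on the
        weighted system to 1e-6."""
        rng = np.random.default_rng(7)
        designs = (rng.random((300, 10)) < 0.5).astype(float)
        outputs = rng.random(300)
        distances = rng.random(300) * 0.8
        w = fit_surrogate(designs, outputs, distances, ridge=0.0)
        kw = 0.25
        sw = np.sqrt(np.exp(-(distances**2) / kw**2))
        X = np.hstack([designs, np.ones((300, 1))])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], outputs * sw, rcond=None)
        assert np.allclose(w, beta[:-1], atol=1e-6)

    def test_rejects_degenerate_designs(self):
        with pytest.raises(ValueError):
            fit_surrogate(np.ones((5, 3)), np.ones(5), np.zeros(5))


class TestExplain:
    def test_selection_capped_at_segment_count(self, trained_phylum_model, separable_dataset):
        model, _ = trained_phylum_model
        img = separable_dataset.images[separable_dataset.test_indices()[0]]
        em = explain(img, model, "phylum", kernel_size=3, max_distance=10,
                     n=64, selected_features=100, seed=0)
        assert len(em.segment_ids) == em.segments.n_segments
        assert em.mask.all()

    def test_deterministic_per_seed(self, trained_phylum_model, separable_dataset):
        model, _ = trained_phylum_model
        img = separable_dataset.images[separable_dataset.test_indices()[1]]
        a = explain(img, model, "phylum", kernel_size=3, max_distance=10,
                    n=64, selected_features=3, seed=1)
        b = explain(img, model, "phylum", kernel_size=3, max_distance=10,
                    n=64, selected_features=3, seed=1)
        assert np.array_equal(a.mask, b.mask)
        assert np.allclose(a.weights, b.weights)

    def test_masking_top_segments_beats_random(self, separable_dataset):
        """Faithfulness: deleting the top-weighted segments moves the
        explained probability more than deleting random segments (paired
        over test images; direction asserted).  A lightly trained model is
        used so probabilities are not saturated at 1."""
        var = mt.DatasetVariant("original", separable_dataset)
        model, _ = mt.train_sl(var, "phylum", mt.BackboneSpec(),
                               mt.TrainingConfig(epochs=2, seed=31))
        rng = np.random.default_rng(8)
        top_drops, rand_drops = [], []
        for idx in separable_dataset.test_indices()[:20]:
            img = separable_dataset.images[idx]
            em = explain(img, model, "phylum", kernel_size=3, max_distance=10,
                         n=128, selected_features=5, seed=2)
            seg = em.segments
            p0 = model.predict_proba(img[None])["phylum"][0]
            cls = int(np.argmax(p0))
            filled = _mean_fill(img, seg)

            def drop(segment_ids):
                m = np.isin(seg.labels, segment_ids)
                pert = np.where(m[:, :, None], filled, img)
                return p0[cls] - model.predict_proba(pert[None])["phylum"][0, cls]

            k = min(5, seg.n_segments)
            top_drops.append(drop(em.segment_ids[:k]))
            rand_drops.append(drop(rng.choice(seg.n_segments, size=k, replace=False)))
        assert np.mean(top_drops) > np.mean(rand_drops)


class TestRegionAttribution:
    @staticmethod
    def _record(**kw):
        defaults = dict(isolate_id="x", labels={}, dish_circle=(32, 32, 28),
                        colony_radius=14.0)
        defaults.update(kw)
        return IsolateRecord(**defaults)

    def test_colony_interior_mask_is_pure(self):
        rec = self._record()
        yy, xx = np.mgrid[0:64, 0:64]
        mask = np.hypot(xx - 32, yy - 32) <= 0.8 * rec.colony_radius
        ra = region_attribution(mask, rec)
        assert ra.fractions["colony_interior"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rec = self._record(confounder_box=(40, 40, 50, 50))
        rng = np.random.default_rng(9)
        for _ in range(10):
            mask = rng.random((64, 64)) < 0.3
            ra = region_attribution(mask, rec)
            assert sum(ra.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_random_masks_recover_area_shares(self):
        """A uniform random mask attributes each region close to its area
        share (mean over 20 seeds)."""
        rec = self._record(confounder_box=(44, 20, 54, 30))
        shares = region_area_shares((64, 64), rec)
        sums = {k: 0.0 for k in shares}
        for seed in range(20):
            mask = np.random.default_rng(seed).random((64, 64)) < 0.5
            ra = region_attribution(mask, rec)
            for k in sums:
                sums[k] += ra.fractions[k]
        for k in shares:
            assert abs(sums[k] / 20 - shares[k]) <= 0.05

    def test_empty_mask_and_missing_geometry_raise(self):
        rec = self._record()
        with pytest.raises(ValueError, match="empty"):
            region_attribution(np.zeros((64, 64), bool), rec)
        bare = IsolateRecord(isolate_id="y", labels={})
        with pytest.raises(ValueError, match="geometry"):
            region_attribution(np.ones((64, 64), bool), bare)
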