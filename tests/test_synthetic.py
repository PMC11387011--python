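"""Generator contracts: taxonomy structure, missingness, morphology
inheritance, and rendering geometry."""

import numpy as np
import pytest
from scipy import stats

import mycotax as mt
from mycotax.synthetic import RANKS, draw_handwriting_mark


class TestGenerateTaxonomy:
    def test_collection_scale_counts(self):
        tree = mt.generate_taxonomy([5, 11, 20, 40, 80, 190], 1.5, seed=0)
        for r, expect in enumerate([5, 11, 20, 40, 80, 190]):
            assert len(tree.nodes_at_rank(r)) == expect
        assert len(tree.leaf_paths) == 190
        assert np.isclose(tree.leaf_weights.sum(), 1.0)

    def test_nesting_invariants(self, small_tree):
        for node, parent in small_tree.parent.items():
            if small_tree.rank_of[node] == 0:
                assert parent is None
            else:
                assert small_tree.rank_of[parent] == small_tree.rank_of[node] - 1
        assert len(set(small_tree.leaf_paths)) == len(small_tree.leaf_paths)

    def test_single_path_tree(self):
        tree = mt.generate_taxonomy([1] * 6, 1.5, seed=0)
        assert len(tree.leaf_paths) == 1
        assert tree.leaf_weights[0] == pytest.approx(1.0)

    def test_zero_skew_uniform_weights(self):
        tree = mt.generate_taxonomy([2, 4, 4, 4, 4, 4], 0.0, seed=3)
        assert np.allclose(tree.leaf_weights, 0.25, atol=1e-9)

    @pytest.mark.parametrize("bad", [[5, 4, 6, 6, 6, 6], [0, 1, 1, 1, 1, 1]])
    def test_rejects_invalid_counts(self, bad):
        with pytest.raises(ValueError):
            mt.generate_taxonomy(bad, 1.0, seed=0)

    def test_leaf_frequencies_match_weights(self):
        """Empirical leaf distribution is consistent with the tree weights
        (chi-square GOF, majority of seeds above p=0.01)."""
        tree = mt.generate_taxonomy([1, 1, 1, 1, 1, 5], 1.0, seed=2)
        passes = 0
        for seed in range(5):
            recs = mt.sample_isolates(tree, 10_000, [0] * 6, seed=seed)
            species = [r.labels["species"] for r in recs]
            order = [p[-1] for p in tree.leaf_paths]
            counts = np.array([species.count(s) for s in order])
            p = stats.chisquare(counts, 10_000 * tree.leaf_weights).pvalue
            passes += p > 0.01
        assert passes >= 3


class TestSampleIsolates:
    def test_collection_scale_missingness(self):
        rates = [11 / 606, 39 / 606, 40 / 606, 67 / 606, 119 / 606, 319 / 606]
        tree = mt.generate_taxonomy([5, 11, 20, 40, 80, 190], 1.5, seed=0)
        recs = mt.sample_isolates(tree, 606, rates, seed=1)
        for k, r in enumerate(RANKS):
            frac = np.mean([rec.labels[r] == mt.MISSING for rec in recs])
            se = np.sqrt(rates[k] * (1 - rates[k]) / 606)
            assert abs(frac - rates[k]) <= 3 * se + 1e-12

    def test_no_missing_when_rates_zero(self, small_tree):
        recs = mt.sample_isolates(small_tree, 50, [0] * 6, seed=0)
        assert all(rec.labels[r] != mt.MISSING for rec in recs for r in RANKS)

    def test_species_missingness_binomial(self, small_tree):
        """Mean species-missing fraction over 20 seeds within 3 SE of 0.5."""
        fracs = [
            np.mean([
                rec.labels["species"] == mt.MISSING
                for rec in mt.sample_isolates(small_tree, 10_000, [0, 0, 0, 0, 0, 0.5], seed=s)
            ])
            for s in range(20)
        ]
        se = np.sqrt(0.25 / 10_000) / np.sqrt(20)
        assert abs(np.mean(fracs) - 0.5) <= 3 * se

    def test_missingness_downward_closed(self, small_tree):
        for seed in range(5):
            recs = mt.sample_isolates(small_tree, 200, [0, 0.1, 0.2, 0.3, 0.5, 0.8], seed=seed)
            for rec in recs:
                flags = [rec.labels[r] == mt.MISSING for r in RANKS]
                assert flags == sorted(flags)  # once missing, missing below
                present = [rec.labels[r] for r in RANKS if rec.labels[r] != mt.MISSING]
                if present:
                    assert small_tree.is_valid_path(present)

    def test_rejects_bad_arguments(self, small_tree):
        with pytest.raises(ValueError):
            mt.sample_isolates(small_tree, 0, [0] * 6, seed=0)
        with pytest.raises(ValueError):
            mt.sample_isolates(small_tree, 5, [0.5, 0, 0, 0, 0, 0], seed=0)


class TestMorphology:
    def test_zero_decay_uniform_within_phylum(self, small_tree):
        by_phylum = {}
        for path in small_tree.leaf_paths:
            p = mt.morphology_from_taxon(small_tree, path, 0.0, seed=0)
            by_phylum.setdefault(path[0], []).append(p)
        for params in by_phylum.values():
            assert all(q == params[0] for q in params)

    def test_full_decay_within_phylum_variance(self):
        tree = mt.generate_taxonomy([2, 4, 8, 16, 32, 64], 0.0, seed=1)
        ext = {}
        for path in tree.leaf_paths:
            p = mt.morphology_from_taxon(tree, path, 1.0, seed=0)
            ext.setdefault(path[0], []).append(p.extension_fraction)
        for vals in ext.values():
            assert np.var(vals) > 0

    def test_phylum_hue_separation(self, small_tree):
        """Hues of different phyla stay at least the configured minimum
        separation apart even at full decay (2 phyla: spacing 0.5, min 0.25)."""
        hues = {}
        for path in small_tree.leaf_paths:
            p = mt.morphology_from_taxon(small_tree, path, 1.0, seed=3)
            hues.setdefault(path[0], []).append(p.base_hue)
        (h1, h2) = hues.values()
        min_gap = min(abs(a - b) for a in h1 for b in h2)
        assert min_gap >= 0.25 - 1e-9

    def test_deterministic_and_validates_path(self, small_tree):
        path = small_tree.leaf_paths[0]
        a = mt.morphology_from_taxon(small_tree, path, 0.5, seed=4)
        b = mt.morphology_from_taxon(small_tree, path, 0.5, seed=4)
        assert a == b
        with pytest.raises(ValueError):
            mt.morphology_from_taxon(small_tree, ("nope",) * 6, 0.5, seed=4)


def _flat_params(**kw):
    base = dict(base_hue=0.6, saturation=0.7, brightness=0.6, extension_fraction=0.5,
                edge_roughness=0.0, patch_density=0.0, ring_contrast=0.0, texture_scale=2.0)
    base.update(kw)
    return mt.MorphologyParams(**base)


class TestRenderColony:
    def test_full_extension_fills_dish(self):
        img, (cx, cy, r) = mt.render_colony(_flat_params(extension_fraction=1.0), 30, 64, seed=0)
        yy, xx = np.mgrid[0:64, 0:64]
        dish = np.hypot(xx - cx, yy - cy) <= r
        base = np.asarray([int(v * 255) for v in
                           __import__("matplotlib.colors", fromlist=["hsv_to_rgb"]).hsv_to_rgb([0.6, 0.7, 0.6])])
        close = np.abs(img[dish].astype(int) - base).max(axis=1) < 30
        assert close.mean() > 0.99

    def test_area_ratio_tracks_extension(self):
        """Colony area over dish area ~ extension^2 (0.25 +/- 0.02 at 0.5)."""
        img, (cx, cy, r) = mt.render_colony(_flat_params(), 60, 128, seed=1)
        yy, xx = np.mgrid[0:128, 0:128]
        rr = np.hypot(xx - cx, yy - cy)
        dish = rr <= r
        agar = np.asarray(mt.synthetic.AGAR_COLOR)
        colony = dish & (np.abs(img.astype(int) - agar).sum(axis=2) > 60) & (rr < 0.94 * r)
        ratio = colony.sum() / dish.sum()
        assert abs(ratio - 0.25) <= 0.02

    def test_flat_colony_interior_is_uniform(self):
        img, (cx, cy, r) = mt.render_colony(_flat_params(), 60, 128, seed=2)
        yy, xx = np.mgrid[0:128, 0:128]
        interior = np.hypot(xx - cx, yy - cy) <= 0.35 * r
        assert img[interior].std(axis=0).max() < 3.0  # only the texture-noise floor

    def test_deterministic_per_seed(self):
        p = _flat_params(patch_density=1.0, edge_roughness=0.5)
        a, _ = mt.render_colony(p, 30, 64, seed=5)
        b, _ = mt.render_colony(p, 30, 64, seed=5)
        c, _ = mt.render_colony(p, 30, 64, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_rejects_oversized_dish(self):
        with pytest.raises(ValueError):
            mt.render_colony(_flat_params(), 40, 64, seed=0)


class TestGroupScan:
    def test_twelve_nonoverlapping_circles(self, group_scan):
        assert len(group_scan.true_circles) == 12
        H, W = group_scan.image.shape[:2]
        for i, (x, y, r) in enumerate(group_scan.true_circles):
            assert r <= x <= W - r and r <= y <= H - r
            for x2, y2, r2 in group_scan.true_circles[i + 1:]:
                assert np.hypot(x - x2, y - y2) > r + r2

    def test_empty_scan(self):
        scan = mt.render_group_scan([], layout=(3, 4), cell_px=100, seed=0)
        assert scan.true_circles == []
        assert (scan.image == np.asarray(mt.synthetic.BLUE_BACKGROUND)).all()

    def test_confounder_inside_dish_outside_colony(self, group_scan):
        for rec in group_scan.records:
            assert rec.confounder_box is not None
            x0, y0, x1, y1 = rec.confounder_box
            cx, cy, r = rec.dish_circle
            corners = [(x0, y0), (x0, y1), (x1, y0), (x1, y1)]
            for x, y in corners:
                d = np.hypot(x - cx, y - cy)
                assert d <= r + 1e-9
                assert d >= rec.colony_radius - 1e-9

    def test_rejects_overfull_layout(self, small_tree):
        recs = mt.sample_isolates(small_tree, 13, [0] * 6, seed=0)
        mt.attach_morphology(small_tree, recs, 0.0, seed=0)
        with pytest.raises(ValueError):
            mt.render_group_scan(recs, layout=(3, 4), seed=0)

    def test_generator_determinism(self, small_tree):
        recs = mt.sample_isolates(small_tree, 6, [0] * 6, seed=9)
        mt.attach_morphology(small_tree, recs, 0.2, seed=9)
        a = mt.render_group_scan(recs, cell_px=100, confounder_prob=0.5, seed=10)
        b = mt.render_group_scan(recs, cell_px=100, confounder_prob=0.5, seed=10)
        assert np.array_equal(a.image, b.image)
        assert a.true_circles == b.true_circles


def test_handwriting_mark_skips_thin_annulus():
    """A colony filling the dish leaves no agar to write on."""
    img, circle = mt.render_colony(_flat_params(extension_fraction=1.0), 30, 64, seed=0)
    rng = np.random.default_rng(0)
    assert draw_handwriting_mark(img, circle, 30.0, rng) is None
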