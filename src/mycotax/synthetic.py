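"""Synthetic fungal colony-image collections with known ground truth.

Real collections of soil-fungus isolates come as group scans of Petri dishes
on a blue background, annotated with a six-rank taxonomy (phylum > class >
order > family > genus > species) that is skewed (a few dominant taxa, many
singletons) and incompletely labelled (annotation fails from some rank
downward).  This module simulates such a collection end to end: a nested
taxonomy with power-law leaf frequencies, per-taxon colony morphologies that
are heritable along the tree, parametric colony renderings on dishes, and
composite group scans with optional handwriting-like confounder marks.

Every generated quantity is deterministic given the configuration and seed,
and all geometric ground truth (dish circles, colony radii, confounder
boxes) is recorded so downstream stages can be tested against it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.ndimage import gaussian_filter

RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")
MISSING = ""

#: default canvas colors, 8-bit RGB
BLUE_BACKGROUND = (40, 70, 160)
AGAR_COLOR = (212, 202, 172)
INK_COLOR = (28, 24, 24)

_RANK_PREFIX = ("phy", "cls", "ord", "fam", "gen", "sp")


def _subrng(*parts) -> np.random.Generator:
    """Stable, order-sensitive RNG derived from arbitrary key parts."""
    key = "|".join(str(p) for p in parts).encode()
    digest = hashlib.sha256(key).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTree:
    """A six-rank nested taxonomy with leaf frequency weights.

    ``parent`` maps every non-phylum taxon to its taxon at the immediately
    higher rank; ``leaf_paths`` holds one full path per species and
    ``leaf_weights`` the corresponding sampling probabilities (sum to 1).
    """

    ranks: tuple[str, ...]
    parent: dict[str, str | None]
    rank_of: dict[str, int]
    leaf_paths: list[tuple[str, ...]]
    leaf_weights: np.ndarray
    seed: int

    def nodes_at_rank(self, r: int) -> list[str]:
        return sorted(n for n, k in self.rank_of.items() if k == r)

    @property
    def n_phyla(self) -> int:
        return len(self.nodes_at_rank(0))

    def path_for_species(self, species: str) -> tuple[str, ...]:
        node, path = species, [species]
        while self.parent[node] is not None:
            node = self.parent[node]
            path.append(node)
        return tuple(reversed(path))

    def is_valid_path(self, path) -> bool:
        """True when consecutive labels obey the parent-child relation.

        Accepts prefixes (phylum..rank r) as well as full 6-rank paths.
        """
        path = [p for p in path if p not in (MISSING, None)]
        if not path:
            return False
        for child, par in zip(path[1:], path[:-1]):
            if self.parent.get(child, object()) != par:
                return False
        return self.rank_of.get(path[0]) == 0

    def with_imputed_nodes(self, names_by_rank: dict[int, set[str]]) -> "TaxonomyTree":
        """Extend the tree with suffix-imputed taxa so imputed paths validate.

        An imputed name ``<ancestor>_<rank>`` hangs below the deepest real or
        imputed node of its lineage; ``Unknown_<rank>`` chains form their own
        lineage rooted at an ``Unknown_phylum`` pseudo-phylum.
        """
        parent = dict(self.parent)
        rank_of = dict(self.rank_of)
        for r in range(len(self.ranks)):
            for name in names_by_rank.get(r, set()):
                if name in rank_of:
                    continue
                rank_of[name] = r
                if r == 0:
                    parent[name] = None
                else:
                    stem = name.rsplit("_", 1)[0]
                    if stem in rank_of and rank_of[stem] < r:
                        anc_rank = rank_of[stem]
                        node = stem
                        # walk down through the imputed chain already added
                        for rr in range(anc_rank + 1, r):
                            node = f"{stem}_{self.ranks[rr]}"
                        parent[name] = node
                    else:  # Unknown_* chain
                        parent[name] = f"{stem}_{self.ranks[r - 1]}"
        return replace(self, parent=parent, rank_of=rank_of)


def generate_taxonomy(n_per_rank, skew: float, seed: int) -> TaxonomyTree:
    """Build a random nested taxonomy with power-law leaf frequencies.

    Parameters
    ----------
    n_per_rank
        Number of distinct taxa at each of the six ranks, non-decreasing
        from phylum to species (e.g. ``[5, 11, 20, 40, 80, 190]``).
    skew
        Power-law exponent for leaf frequency weights: weight of the leaf
        with frequency rank ``i`` is proportional to ``(i+1)**-skew``.
        ``skew -> 0`` yields uniform weights; larger values concentrate
        frequency on a few dominant species.
    seed
        Seed for tree topology and the leaf-order permutation.
    """
    n_per_rank = [int(x) for x in n_per_rank]
    if len(n_per_rank) != len(RANKS):
        raise ValueError(f"n_per_rank must have {len(RANKS)} entries")
    if any(n <= 0 for n in n_per_rank):
        raise ValueError("taxon counts must be positive")
    if any(b < a for a, b in zip(n_per_rank, n_per_rank[1:])):
        raise ValueError("n_per_rank must be non-decreasing from phylum to species")
    if not skew >= 0:
        raise ValueError("skew must be nonnegative")

    rng = np.random.default_rng(seed)
    names = [
        [f"{_RANK_PREFIX[r]}{i:03d}" for i in range(n_per_rank[r])]
        for r in range(len(RANKS))
    ]
    parent: dict[str, str | None] = {n: None for n in names[0]}
    rank_of: dict[str, int] = {n: 0 for n in names[0]}
    for r in range(1, len(RANKS)):
        n_prev, n_cur = n_per_rank[r - 1], n_per_rank[r]
        # every parent gets at least one child; the rest attach at random
        parents_idx = np.concatenate(
            [np.arange(n_prev), rng.integers(0, n_prev, size=n_cur - n_prev)]
        )
        rng.shuffle(parents_idx)
        for j, name in enumerate(names[r]):
            parent[name] = names[r - 1][int(parents_idx[j])]
            rank_of[name] = r

    tree = TaxonomyTree(RANKS, parent, rank_of, [], np.empty(0), seed)
    leaf_paths = [tree.path_for_species(sp) for sp in names[-1]]
    order = rng.permutation(len(leaf_paths))
    w = np.empty(len(leaf_paths))
    w[order] = (np.arange(len(leaf_paths)) + 1.0) ** (-skew)
    w /= w.sum()
    tree.leaf_paths = leaf_paths
    tree.leaf_weights = w
    return tree


# ---------------------------------------------------------------------------
# isolates and morphology
# ---------------------------------------------------------------------------


@dataclass
class MorphologyParams:
    """Macroscopic colony characters driving the parametric renderer.

    ``extension_fraction`` is colony radius over dish radius — the
    macroscopic proxy for hyphal growth speed; ``patch_density`` controls
    the count intensity of interior blobs (patchiness); ``ring_contrast``
    darkens a concentric growth ring; ``texture_scale`` is the correlation
    length (pixels) of the fine interior texture.
    """

    base_hue: float
    saturation: float
    brightness: float
    extension_fraction: float
    edge_roughness: float
    patch_density: float
    ring_contrast: float
    texture_scale: float

    def __post_init__(self):
        for name in ("base_hue", "saturation", "brightness", "ring_contrast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.extension_fraction <= 1.0:
            raise ValueError("extension_fraction must lie in (0, 1]")
        if self.edge_roughness < 0 or self.patch_density < 0:
            raise ValueError("edge_roughness and patch_density must be nonnegative")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be positive")


@dataclass
class IsolateRecord:
    """One cultured isolate: labels, morphology, and image-frame geometry."""

    isolate_id: str
    labels: dict[str, str]
    morphology: MorphologyParams | None = None
    image_path: str | None = None
    dish_circle: tuple[float, float, float] | None = None
    colony_radius: float | None = None
    confounder_box: tuple[int, int, int, int] | None = None  # x0, y0, x1, y1
    #: full leaf path the isolate was drawn from (set by sample_isolates);
    #: drives morphology even when deep labels are missing
    true_path: tuple[str, ...] | None = None

    def label_path(self) -> tuple[str, ...]:
        return tuple(self.labels[r] for r in RANKS)


def sample_isolates(tree: TaxonomyTree, n: int, missing_rates, seed: int) -> list[IsolateRecord]:
    """Draw ``n`` isolates with downward-closed label missingness.

    Leaf paths are drawn proportional to the tree's frequency weights.  A
    single uniform draw per record against the non-decreasing
    ``missing_rates`` truncates its labels: the record is missing at rank
    ``r`` iff ``u < missing_rates[r]``, which makes missingness
    downward-closed by construction and matches the requested marginal
    missing fraction at every rank exactly in expectation.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rates = [float(x) for x in missing_rates]
    if len(rates) != len(RANKS) or any(not 0 <= x <= 1 for x in rates):
        raise ValueError("missing_rates must be six values in [0, 1]")
    if any(b < a for a, b in zip(rates, rates[1:])):
        raise ValueError("missing_rates must be non-decreasing from phylum to species")

    rng = np.random.default_rng(seed)
    leaf_idx = rng.choice(len(tree.leaf_paths), size=n, p=tree.leaf_weights)
    u = rng.random(n)
    records = []
    for i in range(n):
        path = tree.leaf_paths[leaf_idx[i]]
        labels = {
            r: (MISSING if u[i] < rates[k] else path[k]) for k, r in enumerate(RANKS)
        }
        records.append(
            IsolateRecord(isolate_id=f"iso{i:05d}", labels=labels, true_path=path)
        )
    return records


def morphology_from_taxon(
    tree: TaxonomyTree,
    leaf_path,
    inheritance_decay: float,
    seed: int,
    hue_min_separation: float | None = None,
) -> MorphologyParams:
    """Derive colony morphology for a species as a perturbed inheritance.

    The phylum fixes the mean characters (hues are evenly spaced across the
    color wheel, separated by at least ``hue_min_separation``, default half
    the phylum spacing); each deeper taxon adds a zero-mean perturbation
    scaled by ``inheritance_decay**depth``.  ``inheritance_decay = 0`` makes
    all species of a phylum identical (maximal phylum separability);
    ``1`` keeps full within-phylum variation at every rank.
    """
    leaf_path = tuple(leaf_path)
    if not tree.is_valid_path(leaf_path) or len(leaf_path) != len(RANKS):
        raise ValueError(f"invalid leaf path {leaf_path!r}")
    if not 0.0 <= inheritance_decay <= 1.0:
        raise ValueError("inheritance_decay must lie in [0, 1]")

    phyla = tree.nodes_at_rank(0)
    spacing = 1.0 / len(phyla)
    min_sep = spacing / 2.0 if hue_min_separation is None else hue_min_separation
    if not 0 <= min_sep <= spacing:
        raise ValueError("hue_min_separation must lie in [0, phylum spacing]")
    hue_window = (spacing - min_sep) / 2.0

    p_idx = phyla.index(leaf_path[0])
    prng = _subrng(tree.seed, seed, "base", leaf_path[0])
    base = {
        "base_hue": (p_idx + 0.5) * spacing,
        "saturation": prng.uniform(0.45, 0.9),
        "brightness": prng.uniform(0.4, 0.85),
        "extension_fraction": prng.uniform(0.3, 0.8),
        "edge_roughness": prng.uniform(0.0, 0.6),
        "patch_density": prng.uniform(0.0, 1.2),
        "ring_contrast": prng.uniform(0.0, 0.6),
        "texture_scale": prng.uniform(1.5, 4.0),
    }
    scales = {
        "base_hue": hue_window / 2.0,
        "saturation": 0.15,
        "brightness": 0.15,
        "extension_fraction": 0.15,
        "edge_roughness": 0.2,
        "patch_density": 0.4,
        "ring_contrast": 0.2,
        "texture_scale": 0.8,
    }
    hue_offset = 0.0
    for depth in range(1, len(RANKS)):
        nrng = _subrng(tree.seed, seed, "perturb", leaf_path[depth])
        amp = inheritance_decay**depth
        for name, sc in scales.items():
            delta = amp * sc * nrng.uniform(-1.0, 1.0)
            if name == "base_hue":
                hue_offset += delta
            else:
                base[name] += delta
    base["base_hue"] += float(np.clip(hue_offset, -hue_window, hue_window))

    base["base_hue"] = float(np.clip(base["base_hue"], 0.0, 1.0))
    base["saturation"] = float(np.clip(base["saturation"], 0.0, 1.0))
    base["brightness"] = float(np.clip(base["brightness"], 0.05, 1.0))
    base["extension_fraction"] = float(np.clip(base["extension_fraction"], 0.05, 1.0))
    base["edge_roughness"] = float(max(base["edge_roughness"], 0.0))
    base["patch_density"] = float(max(base["patch_density"], 0.0))
    base["ring_contrast"] = float(np.clip(base["ring_contrast"], 0.0, 1.0))
    base["texture_scale"] = float(max(base["texture_scale"], 0.25))
    return MorphologyParams(**base)


def attach_morphology(
    tree: TaxonomyTree,
    records: list[IsolateRecord],
    inheritance_decay: float,
    seed: int,
    hue_min_separation: float | None = None,
    full_paths: dict[str, tuple[str, ...]] | None = None,
) -> None:
    """Fill ``record.morphology`` in place for every record.

    Morphology is driven by the true leaf path (the organism), not by the
    possibly truncated labels, so label missingness never changes how a
    colony looks.  Records sampled by :func:`sample_isolates` with missing
    deep labels therefore need ``full_paths`` (isolate_id -> leaf path);
    when omitted, the labels themselves must form a full path.
    """
    for rec in records:
        path = (full_paths or {}).get(rec.isolate_id) or rec.true_path or rec.label_path()
        rec.morphology = morphology_from_taxon(
            tree, path, inheritance_decay, seed, hue_min_separation
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _colony_boundary_profile(theta, edge_roughness, rng):
    """Radial boundary modulation in [1 - 0.12*rough, 1 + 0.12*rough]."""
    if edge_roughness == 0:
        return np.ones_like(theta)
    w = np.zeros_like(theta)
    for k in range(3, 8):
        w += rng.uniform(0.3, 1.0) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    w /= np.max(np.abs(w))
    return 1.0 + 0.12 * edge_roughness * w


def render_colony(
    params: MorphologyParams,
    dish_radius_px: int,
    img_size: int,
    seed: int,
    background=BLUE_BACKGROUND,
    agar=AGAR_COLOR,
):
    """Render a single Petri-dish colony tile.

    Returns ``(image, dish_circle)`` where ``image`` is ``img_size ×
    img_size × 3`` uint8 and ``dish_circle = (center_x, center_y, radius)``
    in float pixels.  The dish is an agar-colored disk with a darker rim
    band; the colony is a disk of radius ``extension_fraction *
    dish_radius_px`` with a roughness-perturbed boundary, interior blob
    patches, an optional concentric ring, and correlated fine texture.
    Pixels outside the dish are the background color.
    """
    if img_size < 2 * dish_radius_px:
        raise ValueError("dish does not fit: img_size must be >= 2 * dish_radius_px")
    rng = np.random.default_rng(seed)
    c = (img_size - 1) / 2.0
    yy, xx = np.mgrid[0:img_size, 0:img_size].astype(np.float64)
    rr = np.hypot(xx - c, yy - c)
    theta = np.arctan2(yy - c, xx - c)

    img = np.empty((img_size, img_size, 3), np.float64)
    img[:] = np.asarray(background, np.float64) / 255.0

    dish = rr <= dish_radius_px
    img[dish] = np.asarray(agar, np.float64) / 255.0
    rim = dish & (rr >= 0.94 * dish_radius_px)
    img[rim] *= 0.68

    radius = params.extension_fraction * dish_radius_px
    boundary = radius * _colony_boundary_profile(theta, params.edge_roughness, rng)
    np.clip(boundary, 0, dish_radius_px, out=boundary)
    colony = rr <= boundary
    base_rgb = hsv_to_rgb([params.base_hue, params.saturation, params.brightness])
    img[colony] = base_rgb

    if params.ring_contrast > 0:
        ring = colony & (rr >= 0.55 * radius) & (rr <= 0.72 * radius)
        img[ring] *= 1.0 - 0.5 * params.ring_contrast

    n_blobs = int(np.round(params.patch_density * 10))
    for _ in range(n_blobs):
        br = radius * np.sqrt(rng.random()) * 0.85
        ba = rng.uniform(0, 2 * np.pi)
        bx, by = c + br * np.cos(ba), c + br * np.sin(ba)
        brad = radius * rng.uniform(0.06, 0.16)
        factor = rng.uniform(0.55, 0.85) if rng.random() < 0.6 else rng.uniform(1.1, 1.35)
        blob = colony & (np.hypot(xx - bx, yy - by) <= brad)
        img[blob] *= factor

    noise = rng.normal(size=(img_size, img_size))
    noise = gaussian_filter(noise, sigma=params.texture_scale)
    sd = noise.std()
    if sd > 0:
        img[colony] *= (1.0 + 0.015 * noise[colony, None] / sd)

    np.clip(img, 0, 1, out=img)
    return (img * 255).astype(np.uint8), (c, c, float(dish_radius_px))


def draw_handwriting_mark(
    image: np.ndarray,
    dish_circle,
    colony_radius: float,
    rng: np.random.Generator,
    color=INK_COLOR,
):
    """Draw a handwriting-like glyph on the agar annulus of a rendered dish.

    The glyph (a few dark strokes) is confined to a square box lying fully
    inside the dish but outside the colony disk, mimicking the hand-written
    isolate code present on real dishes.  Returns the box ``(x0, y0, x1,
    y1)`` or ``None`` when the agar annulus is too thin to host a mark.
    """
    cx, cy, dish_r = dish_circle
    inner = colony_radius
    outer = 0.93 * dish_r
    gap = outer - inner
    if gap < 5.0:
        return None
    side = min(gap / 1.6, 0.3 * dish_r)
    rad_mid = (inner + outer) / 2.0
    ang = rng.uniform(0, 2 * np.pi)
    bx, by = cx + rad_mid * np.cos(ang), cy + rad_mid * np.sin(ang)
    x0, y0 = int(round(bx - side / 2)), int(round(by - side / 2))
    x1, y1 = int(round(bx + side / 2)), int(round(by + side / 2))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1 = min(x1, image.shape[1] - 1)
    y1 = min(y1, image.shape[0] - 1)

    base = np.asarray(color, np.float64)
    for _ in range(rng.integers(2, 4)):
        sx, sy = rng.uniform(x0, x1), rng.uniform(y0, y1)
        ex, ey = rng.uniform(x0, x1), rng.uniform(y0, y1)
        n = max(int(np.hypot(ex - sx, ey - sy)) * 2, 2)
        ts = np.linspace(0, 1, n)
        px = np.clip(np.round(sx + ts * (ex - sx)).astype(int), x0, x1)
        py = np.clip(np.round(sy + ts * (ey - sy)).astype(int), y0, y1)
        for dx in (0, 1):
            # pen pressure varies along the stroke: jitter the ink darkness
            # per pixel so the mark blends into its surroundings' segments
            ink = np.clip(base[None, :] + rng.uniform(0, 90, size=(n, 1)), 0, 255)
            image[py, np.clip(px + dx, 0, image.shape[1] - 1)] = ink.astype(np.uint8)
    return (x0, y0, x1, y1)


@dataclass
class GroupScan:
    """Composite scan of up to ``rows*cols`` dishes plus its ground truth."""

    image: np.ndarray
    layout: tuple[int, int]
    true_circles: list[tuple[float, float, float]]
    background_color: tuple[int, int, int]
    records: list[IsolateRecord] = field(default_factory=list)


def render_group_scan(
    records: list[IsolateRecord],
    layout: tuple[int, int] = (3, 4),
    cell_px: int = 150,
    background=BLUE_BACKGROUND,
    confounder_prob: float = 0.0,
    seed: int = 0,
) -> GroupScan:
    """Compose dishes on a grid over a blue background screen.

    Dishes are placed at jittered cell centers (jitter bounded so circles
    never overlap nor leave the raster).  With probability
    ``confounder_prob`` per dish a handwriting-like mark is drawn on the
    agar and its bounding box recorded on the record.  Each record's
    ``dish_circle``, ``colony_radius`` and ``confounder_box`` are set in
    scan coordinates.
    """
    rows, cols = layout
    if len(records) > rows * cols:
        raise ValueError(f"{len(records)} records exceed layout capacity {rows * cols}")
    rng = np.random.default_rng(seed)
    H, W = rows * cell_px, cols * cell_px
    canvas = np.empty((H, W, 3), np.uint8)
    canvas[:] = background
    dish_r = int(round(0.42 * cell_px))
    max_jitter = max(cell_px // 2 - dish_r - 2, 0)

    circles = []
    for i, rec in enumerate(records):
        if rec.morphology is None:
            raise ValueError(f"record {rec.isolate_id} has no morphology attached")
        r, cgrid = divmod(i, cols)
        cy = r * cell_px + cell_px // 2 + int(rng.integers(-max_jitter, max_jitter + 1))
        cx = cgrid * cell_px + cell_px // 2 + int(rng.integers(-max_jitter, max_jitter + 1))
        tile, (tc, _, _) = render_colony(
            rec.morphology, dish_r, 2 * dish_r + 3, seed=int(rng.integers(2**31)),
            background=background,
        )
        ty, tx = np.mgrid[0 : tile.shape[0], 0 : tile.shape[1]]
        mask = np.hypot(tx - tc, ty - tc) <= dish_r
        ys, xs = np.nonzero(mask)
        canvas[cy - int(tc) + ys, cx - int(tc) + xs] = tile[ys, xs]

        rec.dish_circle = (float(cx), float(cy), float(dish_r))
        rec.colony_radius = rec.morphology.extension_fraction * dish_r
        rec.confounder_box = None
        if rng.random() < confounder_prob:
            rec.confounder_box = draw_handwriting_mark(
                canvas, rec.dish_circle, rec.colony_radius, rng
            )
        circles.append(rec.dish_circle)
    return GroupScan(canvas, layout, circles, tuple(background), list(records))


def render_isolate_images(
    records: list[IsolateRecord],
    img_size: int,
    seed: int,
    hires_size: int | None = None,
    confounder_prob: float = 0.0,
    background=BLUE_BACKGROUND,
):
    """Render one centred dish tile per record (fast path, no group scans).

    Geometry on each record is expressed in the ``img_size`` frame.  When
    ``hires_size`` is given a second, higher-resolution rendering of the
    identical scene is returned as well (for crop-based augmentation).
    Returns ``(images, hires_images_or_None)``.
    """
    rng = np.random.default_rng(seed)
    imgs = np.empty((len(records), img_size, img_size, 3), np.uint8)
    hires = (
        np.empty((len(records), hires_size, hires_size, 3), np.uint8)
        if hires_size
        else None
    )
    for i, rec in enumerate(records):
        if rec.morphology is None:
            raise ValueError(f"record {rec.isolate_id} has no morphology attached")
        rseed = int(rng.integers(2**31))
        glyph = rng.random() < confounder_prob
        glyph_seed = int(rng.integers(2**31))

        dish_r = int(round(0.46 * img_size))
        img, circle = render_colony(rec.morphology, dish_r, img_size, rseed, background)
        colony_r = rec.morphology.extension_fraction * dish_r
        box = None
        if glyph:
            box = draw_handwriting_mark(
                img, circle, colony_r, np.random.default_rng(glyph_seed)
            )
        imgs[i] = img
        rec.dish_circle, rec.colony_radius, rec.confounder_box = circle, colony_r, box

        if hires is not None:
            dr2 = int(round(0.46 * hires_size))
            img2, circ2 = render_colony(rec.morphology, dr2, hires_size, rseed, background)
            if glyph:
                draw_handwriting_mark(
                    img2,
                    circ2,
                    rec.morphology.extension_fraction * dr2,
                    np.random.default_rng(glyph_seed),
                )
            hires[i] = img2
    return imgs, hires


# ---------------------------------------------------------------------------
# collection-level simulation and I/O
# ---------------------------------------------------------------------------


@dataclass
class CollectionConfig:
    """Study conditions for a simulated collection.

    Defaults emulate a 606-isolate soil-fungus culture collection: six
    nested ranks with 5 phyla / 11 classes / 190 species, power-law
    frequency skew, rank-wise missing-label fractions matching molecular
    annotation failure (11, 39, 40, 67, 119 and 319 of 606 from phylum to
    species), 3x4 dish group scans on a blue background, and occasional
    handwritten marks on the agar.
    """

    n_isolates: int = 606
    n_per_rank: tuple[int, ...] = (5, 11, 20, 40, 80, 190)
    skew: float = 1.5
    missing_rates: tuple[float, ...] = (
        11 / 606, 39 / 606, 40 / 606, 67 / 606, 119 / 606, 319 / 606,
    )
    inheritance_decay: float = 0.3
    hue_min_separation: float | None = None
    layout: tuple[int, int] = (3, 4)
    cell_px: int = 150
    confounder_prob: float = 0.05
    background: tuple[int, int, int] = BLUE_BACKGROUND


@dataclass
class SimulatedCollection:
    config: CollectionConfig
    seed: int
    tree: TaxonomyTree
    records: list[IsolateRecord]
    scans: list[GroupScan]
    true_paths: dict[str, tuple[str, ...]]


def simulate_collection(config: CollectionConfig, seed: int) -> SimulatedCollection:
    """Run the full generator: taxonomy -> isolates -> morphology -> scans."""
    tree = generate_taxonomy(config.n_per_rank, config.skew, seed)
    records = sample_isolates(tree, config.n_isolates, config.missing_rates, seed + 1)
    true_paths = {rec.isolate_id: rec.true_path for rec in records}
    attach_morphology(
        tree, records, config.inheritance_decay, seed + 2, config.hue_min_separation
    )
    per_scan = config.layout[0] * config.layout[1]
    scans = []
    for s in range(0, len(records), per_scan):
        scans.append(
            render_group_scan(
                records[s : s + per_scan],
                layout=config.layout,
                cell_px=config.cell_px,
                background=config.background,
                confounder_prob=config.confounder_prob,
                seed=seed + 100 + s,
            )
        )
    return SimulatedCollection(config, seed, tree, records, scans, true_paths)


def write_collection(outdir, collection: SimulatedCollection) -> Path:
    """Write scans (PNG), metadata (TSV) and a JSON manifest; returns TSV path."""
    import pandas as pd
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "scans").mkdir(parents=True, exist_ok=True)
    rows = []
    for s, scan in enumerate(collection.scans):
        path = outdir / "scans" / f"scan{s:04d}.png"
        Image.fromarray(scan.image).save(path)
        for rec in scan.records:
            row = {"isolate_id": rec.isolate_id}
            row.update({r: rec.labels[r] for r in RANKS})
            row["scan"] = str(path.relative_to(outdir))
            cx, cy, rr = rec.dish_circle
            row.update(circle_x=cx, circle_y=cy, circle_r=rr, colony_r=rec.colony_radius)
            if rec.confounder_box:
                row.update(zip(("conf_x0", "conf_y0", "conf_x1", "conf_y1"), rec.confounder_box))
            rows.append(row)
    meta = outdir / "metadata.tsv"
    pd.DataFrame(rows).to_csv(meta, sep="\t", index=False)
    cfg = {k: v for k, v in vars(collection.config).items()}
    manifest = {"config": cfg, "seed": collection.seed, "n_scans": len(collection.scans)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return meta
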