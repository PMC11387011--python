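"""Group scans to fixed-size, fully labelled per-dish training images.

The stages mirror how a colony-image collection is prepared for modelling:

1. locate every Petri dish in a group scan with a gradient-based Circle
   Hough Transform (edge map -> circular voting -> non-maximum suppression);
2. crop a square sub-image per dish (small margin so the dish rim stays
   visible) and resize it with pixel area relation (exact box averaging);
3. replace missing taxonomic labels hierarchically: a missing rank takes
   the name of its nearest known ancestor plus a suffix naming the current
   rank (``Ascomycota`` -> ``Ascomycota_class`` ... ``Ascomycota_species``);
   isolates with no known rank at all root at ``Unknown``;
4. assign stratified 70/30 train/test splits and 5-fold CV folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .synthetic import MISSING, RANKS

UNKNOWN_STEM = "Unknown"


# ---------------------------------------------------------------------------
# dish detection
# ---------------------------------------------------------------------------


@dataclass
class HoughParams:
    """Circle Hough Transform settings, derivable from the scan layout."""

    radius_min: int
    radius_max: int
    radius_step: int = 1
    min_center_distance: int = 0
    canny_sigma: float = 2.0
    accumulator_threshold: float = 0.35
    max_circles: int = 64

    @classmethod
    def for_layout(cls, image_shape, layout=(3, 4)) -> "HoughParams":
        """Derive radius bounds from grid geometry: dish radius is close to
        half the smaller cell side, so search that value +/- 20%."""
        rows, cols = layout
        cell = min(image_shape[0] / rows, image_shape[1] / cols)
        nominal = 0.42 * cell
        return cls(
            radius_min=int(round(0.8 * nominal)),
            radius_max=int(round(1.2 * nominal)),
            min_center_distance=int(round(1.5 * 0.8 * nominal)),
            max_circles=rows * cols + 4,
        )


@dataclass
class CircleDetection:
    """Detected dish circles, sorted row-major (top-to-bottom, left-to-right)."""

    circles: list[tuple[float, float, float]]
    params: HoughParams
    accumulators: list[float] = field(default_factory=list)


def _sort_row_major(circles, row_tol):
    if not circles:
        return circles
    circles = sorted(circles, key=lambda c: c[1])
    rows, current = [], [circles[0]]
    for c in circles[1:]:
        if c[1] - current[-1][1] <= row_tol:
            current.append(c)
        else:
            rows.append(current)
            current = [c]
    rows.append(current)
    return [c for row in rows for c in sorted(row, key=lambda c: c[0])]


def detect_dishes(image: np.ndarray, params: HoughParams | None = None, layout=(3, 4)) -> CircleDetection:
    """Detect Petri dishes in a group scan via the Circle Hough Transform.

    An edge map (Canny) feeds circular Hough voting over the radius range;
    peaks are kept above the accumulator threshold with non-maximum
    suppression at the minimum center distance.
    """
    if image is None or image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 color raster")
    if params is None:
        params = HoughParams.for_layout(image.shape, layout)
    if params.radius_min <= 0 or params.radius_max < params.radius_min:
        raise ValueError("invalid radius bounds")

    edges = canny(rgb2gray(image), sigma=params.canny_sigma)
    radii = np.arange(params.radius_min, params.radius_max + 1, params.radius_step)
    acc = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(
        acc,
        radii,
        min_xdistance=params.min_center_distance,
        min_ydistance=params.min_center_distance,
        threshold=params.accumulator_threshold,
        total_num_peaks=params.max_circles,
    )
    circles = [(float(x), float(y), float(r)) for x, y, r in zip(cx, cy, rad)]
    circles = _sort_row_major(circles, row_tol=params.radius_min)
    return CircleDetection(circles, params, [float(a) for a in accums])


def crop_dish(image: np.ndarray, circle, margin_fraction: float = 0.05, background=None) -> np.ndarray:
    """Square crop around a dish circle, padded with background off-raster.

    Side length is ``2 * radius * (1 + margin_fraction)`` rounded to int;
    the small default margin keeps the dish rim inside the crop.
    """
    cx, cy, r = circle
    side = int(round(2 * r * (1 + margin_fraction)))
    x0 = int(round(cx - side / 2))
    y0 = int(round(cy - side / 2))
    H, W = image.shape[:2]
    if x0 >= W or y0 >= H or x0 + side <= 0 or y0 + side <= 0:
        raise ValueError("circle (with margin) lies entirely outside the image")
    if background is None:
        background = image[0, 0]
    out = np.empty((side, side, 3), image.dtype)
    out[:] = background
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + side, W), min(y0 + side, H)
    out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = image[sy0:sy1, sx0:sx1]
    return out


def resize_area(image: np.ndarray, target_side: int = 224) -> np.ndarray:
    """Resize with pixel area relation: each output pixel is the exact mean
    of its (possibly fractional) source footprint.

    Equivalent to box/area averaging; for integer downscale factors it is
    exact block averaging. Implemented as two sparse averaging matrices
    (rows then columns) applied per channel.
    """
    if target_side < 1:
        raise ValueError("target_side must be >= 1")
    img = np.asarray(image)
    single = img.ndim == 2
    if single:
        img = img[:, :, None]
    H, W, C = img.shape
    tmp = _area_matrix(target_side, H) @ img.reshape(H, W * C).astype(np.float64)
    tmp = tmp.reshape(target_side, W, C)
    out = np.einsum("tw,hwc->htc", _area_matrix(target_side, W), tmp)
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.round(out), 0, 255).astype(image.dtype)
    return out[:, :, 0] if single else out


def _area_matrix(target: int, source: int) -> np.ndarray:
    """(target x source) row-stochastic matrix of fractional box coverage."""
    M = np.zeros((target, source))
    scale = source / target
    for t in range(target):
        a, b = t * scale, (t + 1) * scale
        lo, hi = int(np.floor(a)), int(np.ceil(b))
        for s in range(lo, min(hi, source)):
            M[t, s] = min(b, s + 1) - max(a, s)
    M /= M.sum(axis=1, keepdims=True)
    return M


# ---------------------------------------------------------------------------
# label imputation
# ---------------------------------------------------------------------------


def impute_missing_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing taxonomy cells with suffix names from the nearest known
    ancestor.

    A record labelled ``(Ascomycota, missing, ...)`` becomes
    ``(Ascomycota, Ascomycota_class, Ascomycota_order, ...)``.  Records
    missing even the phylum root at ``Unknown`` (``Unknown_phylum``,
    ``Unknown_class``, ...).  Missingness must be downward-closed — a known
    label below a missing one signals corrupt metadata.  Idempotent.
    """
    out = table.copy()
    for col in RANKS:
        if col not in out.columns:
            raise ValueError(f"metadata table lacks rank column {col!r}")
    for idx, row in out.iterrows():
        labels = [row[r] for r in RANKS]
        labels = ["" if (pd.isna(v) or v == MISSING) else str(v) for v in labels]
        seen_missing = False
        stem = UNKNOWN_STEM
        for k, r in enumerate(RANKS):
            if labels[k]:
                if seen_missing:
                    raise ValueError(
                        f"record {idx}: label {labels[k]!r} at rank {r} below a "
                        "missing rank (missingness must be downward-closed)"
                    )
                stem = labels[k]
            else:
                seen_missing = True
                labels[k] = f"{stem}_{r}"
        out.loc[idx, list(RANKS)] = labels
    return out


def records_to_table(records) -> pd.DataFrame:
    """Metadata table (isolate_id + six rank columns) from isolate records."""
    rows = [{"isolate_id": rec.isolate_id, **{r: rec.labels[r] for r in RANKS}} for rec in records]
    return pd.DataFrame(rows).set_index("isolate_id")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def split_train_test(labels, ratio: float = 0.7, seed: int = 0) -> np.ndarray:
    """Stratified train/test assignment (array of ``'train'``/``'test'``).

    The global train count is ``round_half_up(ratio * n)``; it is allocated
    over classes by largest remainder so each class's train fraction sits
    within one sample of ``ratio``.  Singleton classes go to train (a test
    class with no train examples can never be predicted and breaks
    correlation scoring).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two records to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(ratio * n + 0.5))

    classes, inv = np.unique(labels, return_inverse=True)
    members = [np.flatnonzero(inv == k) for k in range(len(classes))]
    ideal = np.array([ratio * len(m) for m in members])
    take = np.floor(ideal).astype(int)
    take = np.maximum(take, [1 if len(m) == 1 else 0 for m in members])
    take = np.minimum(take, [len(m) for m in members])
    # largest-remainder top-up toward the exact global train count
    while take.sum() < n_train:
        rem = ideal - take
        rem[take >= [len(m) for m in members]] = -np.inf
        take[int(np.argmax(rem))] += 1
    while take.sum() > n_train:
        rem = take - ideal
        rem[[len(m) == 1 for m in members]] = -np.inf
        rem[take == 0] = -np.inf
        take[int(np.argmax(rem))] -= 1

    assignment = np.full(n, "test", dtype=object)
    for m, t in zip(members, take):
        chosen = rng.permutation(m)[:t]
        assignment[chosen] = "train"
    return assignment.astype(str)


def kfold_splits(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment (array of fold indices ``0..k-1``).

    Classes are processed largest first; each class's shuffled members are
    dealt one at a time to the currently smallest fold, so overall fold
    sizes differ by at most one and every record is test exactly once.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k exceeds the number of records")
    rng = np.random.default_rng(seed)
    classes, inv = np.unique(labels, return_inverse=True)
    members = sorted(
        (np.flatnonzero(inv == c) for c in range(len(classes))),
        key=len,
        reverse=True,
    )
    folds = np.empty(n, dtype=int)
    sizes = np.zeros(k, dtype=int)
    for m in members:
        for i in rng.permutation(m):
            f = int(np.argmin(sizes))
            folds[i] = f
            sizes[f] += 1
    return folds


# ---------------------------------------------------------------------------
# scan-level driver
# ---------------------------------------------------------------------------


def extract_dishes(scan_image: np.ndarray, layout=(3, 4), target_side: int = 224,
                   margin_fraction: float = 0.05, hires_side: int | None = None):
    """Detect, crop and area-resize every dish in one group scan.

    Returns ``(images, circles, hires_images_or_None)`` with dishes in
    row-major order.
    """
    det = detect_dishes(scan_image, layout=layout)
    imgs, hires = [], [] if hires_side else None
    for circ in det.circles:
        crop = crop_dish(scan_image, circ, margin_fraction)
        imgs.append(resize_area(crop, target_side))
        if hires is not None:
            hires.append(resize_area(crop, hires_side))
    stack = np.stack(imgs) if imgs else np.empty((0, target_side, target_side, 3), np.uint8)
    hstack = (np.stack(hires) if hires else None) if hires_side else None
    return stack, det.circles, hstack
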