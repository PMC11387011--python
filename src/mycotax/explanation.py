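"""Local surrogate explanations of colony classifiers, LIME-style.

To explain one prediction, the dish image is segmented into superpixels
with the quickshift mode-seeking algorithm (kernel size 6, max distance
50, color/space ratio 0.5 — the reference settings for this task); a
neighborhood of binary perturbations (each superpixel independently kept
or masked with probability 1/2, masked segments filled with their mean
color) is scored by the model; and a weighted linear surrogate is fit to
the model's class probability for the explained label, with exponential
proximity weights on the cosine distance to the unperturbed design.  The
top-|weight| segments (at most ``selected_features``) form the explanation
mask.

For synthetic dishes with known geometry, the explanation mass can be
attributed quantitatively to named regions — colony interior, colony rim,
agar, dish rim, confounder mark, background — to answer *where* the model
looks (e.g. whether a handwriting-like mark confounds the prediction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import quickshift as _skimage_quickshift

from .synthetic import IsolateRecord

REGIONS = ("colony_interior", "colony_rim", "agar", "dish_rim", "confounder", "background")


@dataclass
class SuperpixelMap:
    """Superpixel segmentation: a label raster with segments ``0..n-1``."""

    labels: np.ndarray
    n_segments: int
    params: dict

    def masks(self) -> list[np.ndarray]:
        return [self.labels == s for s in range(self.n_segments)]


@dataclass
class ExplanationMask:
    """Selected superpixels with surrogate weights for one rank."""

    rank: str
    segment_ids: np.ndarray
    weights: np.ndarray  # surrogate coefficient per selected segment
    mask: np.ndarray  # boolean union of the selected segments
    segments: SuperpixelMap
    params: dict


@dataclass
class RegionAttribution:
    """Fractions of the explanation mask falling in each named dish region."""

    fractions: dict[str, float]

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"region fractions sum to {total}, not 1")


def quickshift_segment(image: np.ndarray, kernel_size: float = 6,
                       max_distance: float = 50, ratio: float = 0.5) -> SuperpixelMap:
    """Quickshift superpixel segmentation.

    Mode seeking in the joint (color * ratio, position) space with a
    Gaussian density at ``kernel_size``; parent links are capped at
    ``max_distance``.  Segments are relabelled ``0..n-1``.  On an exactly
    constant image the density plateau collapses to a single segment.
    """
    if min(kernel_size, max_distance, ratio) <= 0:
        raise ValueError("kernel_size, max_distance and ratio must be positive")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 color raster")
    img = image.astype(np.float64)
    if img.max() > 1:
        img = img / 255.0
    labels = _skimage_quickshift(
        img, ratio=ratio, kernel_size=kernel_size, max_dist=max_distance,
        rng=0,
    )
    uniq, relabelled = np.unique(labels, return_inverse=True)
    return SuperpixelMap(
        labels=relabelled.reshape(labels.shape),
        n_segments=len(uniq),
        params={"kernel_size": kernel_size, "max_distance": max_distance, "ratio": ratio},
    )


# ---------------------------------------------------------------------------
# perturbation neighborhood and surrogate fit
# ---------------------------------------------------------------------------


def _mean_fill(image: np.ndarray, segments: SuperpixelMap) -> np.ndarray:
    """Image with every segment replaced by its mean color."""
    filled = np.empty_like(image, dtype=np.float64)
    for s in range(segments.n_segments):
        m = segments.labels == s
        filled[m] = image[m].reshape(-1, image.shape[2]).mean(axis=0)
    return filled.astype(image.dtype)


def perturb_and_query(image: np.ndarray, segments: SuperpixelMap, model, rank: str,
                      explained_class: str | int | None = None,
                      n: int = 1000, seed: int = 0, batch_size: int = 64):
    """Score ``n`` binary superpixel perturbations with the model.

    Each design row keeps every segment independently with probability
    1/2; the first row is the unperturbed all-ones design.  Masked
    segments take their mean color.  Returns ``(designs, outputs,
    distances)`` where ``outputs`` is the model probability of the
    explained class (default: the class the model predicts for the intact
    image) and ``distances`` the cosine distance of each design to the
    all-ones vector.
    """
    if n < 2:
        raise ValueError("neighborhood size n must be >= 2")
    rng = np.random.default_rng(seed)
    k = segments.n_segments
    designs = (rng.random((n, k)) < 0.5)
    designs[0] = True
    filled = _mean_fill(image, segments)

    probs0 = model.predict_proba(image[None])[rank][0]
    if explained_class is None:
        cls_idx = int(np.argmax(probs0))
    elif isinstance(explained_class, (int, np.integer)):
        cls_idx = int(explained_class)
    else:
        cls_idx = model.classes[rank].index(explained_class)

    outputs = np.empty(n)
    seg_lab = segments.labels
    for s in range(0, n, batch_size):
        chunk = designs[s : s + batch_size]
        batch = np.empty((len(chunk),) + image.shape, image.dtype)
        for i, row in enumerate(chunk):
            keep = row[seg_lab]
            batch[i] = np.where(keep[:, :, None], image, filled)
        outputs[s : s + len(chunk)] = model.predict_proba(batch)[rank][:, cls_idx]

    # cosine distance of each binary design to the all-ones design
    norms = np.sqrt((designs.sum(axis=1)).astype(float)) * np.sqrt(k)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(norms > 0, designs.sum(axis=1) / norms, 0.0)
    distances = 1.0 - cos
    return designs.astype(float), outputs, distances


def fit_surrogate(designs: np.ndarray, outputs: np.ndarray, distances: np.ndarray,
                  kernel_width: float = 0.25, ridge: float = 1e-8) -> np.ndarray:
    """Weighted least-squares linear surrogate; returns one coefficient per
    segment.

    Sample weights are ``exp(-d^2 / kernel_width^2)``.  The design is
    augmented with an intercept; a small ridge term keeps rank-deficient
    neighborhoods (duplicated designs, segments never toggled) solvable.
    """
    designs = np.asarray(designs, dtype=np.float64)
    if len(np.unique(designs, axis=0)) < 2:
        raise ValueError("need at least two distinct designs")
    w = np.exp(-(np.asarray(distances) ** 2) / kernel_width**2)
    X = np.hstack([designs, np.ones((len(designs), 1))])
    Xw = X * w[:, None]
    A = X.T @ Xw
    A[np.diag_indices_from(A)] += ridge
    beta = np.linalg.solve(A, Xw.T @ np.asarray(outputs, dtype=np.float64))
    return beta[:-1]


def explain(image: np.ndarray, model, rank: str, explained_class=None,
            kernel_size: float = 6, max_distance: float = 50, ratio: float = 0.5,
            n: int = 1000, selected_features: int = 100,
            kernel_width: float = 0.25, seed: int = 0) -> ExplanationMask:
    """Segment, perturb, fit, and select the top-|weight| superpixels."""
    segments = quickshift_segment(image, kernel_size, max_distance, ratio)
    designs, outputs, distances = perturb_and_query(
        image, segments, model, rank, explained_class, n=n, seed=seed
    )
    weights = fit_surrogate(designs, outputs, distances, kernel_width)
    k = min(selected_features, segments.n_segments)
    order = np.argsort(-np.abs(weights))[:k]
    mask = np.isin(segments.labels, order)
    return ExplanationMask(
        rank=rank,
        segment_ids=order,
        weights=weights[order],
        mask=mask,
        segments=segments,
        params={
            "neighborhood_size": n, "selected_features": selected_features,
            "kernel_width": kernel_width, **segments.params,
        },
    )


# ---------------------------------------------------------------------------
# geometric region attribution
# ---------------------------------------------------------------------------


def region_map(shape, record: IsolateRecord, rim_fraction: float = 0.1) -> np.ndarray:
    """Label every pixel with its region index (order of ``REGIONS``).

    Rim bands are the outer ``rim_fraction`` of the colony and dish radii.
    Requires synthetic-mode geometry (dish circle and colony radius; the
    confounder box is optional).
    """
    if record.dish_circle is None or record.colony_radius is None:
        raise ValueError("record lacks geometry; attribution needs synthetic-mode ground truth")
    cx, cy, dish_r = record.dish_circle
    col_r = record.colony_radius
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    rr = np.hypot(xx - cx, yy - cy)
    out = np.full(shape[:2], REGIONS.index("background"), dtype=np.int8)
    out[rr <= dish_r] = REGIONS.index("agar")
    out[(rr <= dish_r) & (rr >= (1 - rim_fraction) * dish_r)] = REGIONS.index("dish_rim")
    out[rr <= col_r] = REGIONS.index("colony_interior")
    out[(rr <= col_r) & (rr >= (1 - rim_fraction) * col_r)] = REGIONS.index("colony_rim")
    if record.confounder_box is not None:
        x0, y0, x1, y1 = record.confounder_box
        box = np.zeros(shape[:2], bool)
        box[y0 : y1 + 1, x0 : x1 + 1] = True
        out[box & (rr <= dish_r)] = REGIONS.index("confounder")
    return out


def region_attribution(mask: np.ndarray, record: IsolateRecord,
                       rim_fraction: float = 0.1) -> RegionAttribution:
    """Fractions of the explanation mask area per named region."""
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty explanation mask: nothing to attribute")
    regions = region_map(mask.shape, record, rim_fraction)
    fr = {
        name: float((regions[mask] == i).sum()) / float(mask.sum())
        for i, name in enumerate(REGIONS)
    }
    return RegionAttribution(fr)


def region_area_shares(shape, record: IsolateRecord, rim_fraction: float = 0.1) -> dict[str, float]:
    """Area share of each region over the whole raster (uniform-mask null)."""
    regions = region_map(shape, record, rim_fraction)
    n = regions.size
    return {name: float((regions == i).sum()) / n for i, name in enumerate(REGIONS)}
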