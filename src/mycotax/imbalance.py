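"""Class-imbalance profiling and the three training-set variants.

Colony collections are heavily skewed: a handful of taxa dominate while
many species are singletons.  This module quantifies that skew (category
count C, majority count MC+, minority count MC-, and the likelihood-ratio
imbalance degree LRiD against the uniform distribution) and builds the
three datasets used for model training:

* ``original`` — the preprocessed images untouched;
* ``naive`` random oversampling — minority-class training images are
  re-added with random axis flips and a lighting shift until every class
  matches the majority count;
* ``augmented`` random oversampling — as naive, but each synthetic image
  is a random crop taken from a higher-resolution (356 px) rendition of
  the donor dish plus brightness/contrast/saturation jitter.

Oversampling happens after the train/test split and only ever touches the
train partition, so no synthetic copy of a test image can leak into
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ColonyDataset, DatasetVariant

VARIANTS = ("original", "naive", "augmented")


# ---------------------------------------------------------------------------
# imbalance profile
# ---------------------------------------------------------------------------


@dataclass
class ImbalanceProfile:
    """Summary of class-frequency skew at one taxonomic rank."""

    C: int
    MC_plus: int
    MC_minus: int
    LRiD: float
    counts: dict[str, int]
    majority: dict[str, bool]


def imbalance_profile(labels) -> ImbalanceProfile:
    """Profile observed class counts at one rank.

    A category is majority when its count exceeds the average count per
    category (``n / C``).  LRiD is the likelihood-ratio (G) statistic of
    the observed counts against the uniform distribution,
    ``2 * sum_c n_c * ln(n_c * C / n)``; it is zero iff counts are uniform
    and grows with concentration.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label list")
    classes, cnt = np.unique(labels, return_counts=True)
    n, C = int(cnt.sum()), len(classes)
    lrid = float(2.0 * np.sum(cnt * np.log(cnt * C / n)))
    return ImbalanceProfile(
        C=C,
        MC_plus=int(cnt.max()),
        MC_minus=int(cnt.min()),
        LRiD=max(lrid, 0.0),
        counts={str(c): int(k) for c, k in zip(classes, cnt)},
        majority={str(c): bool(k > n / C) for c, k in zip(classes, cnt)},
    )


# ---------------------------------------------------------------------------
# image transforms
# ---------------------------------------------------------------------------


@dataclass
class AugmentationSpec:
    """Transform settings for the oversampling variants.

    Jitter factor ranges are symmetric around 1 (identity); the lighting
    shift is additive in fractions of full scale.  ``pre_crop_side`` is the
    resolution the donor dish is kept at for random cropping and
    ``crop_side`` the final output side.
    """

    variant: str = "naive"
    flip_horizontal: bool = True
    flip_vertical: bool = True
    lighting_range: float = 0.1
    brightness: tuple[float, float] = (0.8, 1.2)
    contrast: tuple[float, float] = (0.8, 1.2)
    saturation: tuple[float, float] = (0.8, 1.2)
    pre_crop_side: int = 356
    crop_side: int = 224
    center_crop: bool = False

    def __post_init__(self):
        if self.crop_side > self.pre_crop_side:
            raise ValueError("crop_side must not exceed pre_crop_side")
        for name in ("brightness", "contrast", "saturation"):
            lo, hi = getattr(self, name)
            if not lo <= 1.0 <= hi:
                raise ValueError(f"{name} jitter range must bracket identity (1.0)")


def _apply_flips(img: np.ndarray, flip_h: bool, flip_v: bool) -> np.ndarray:
    if flip_h:
        img = img[:, ::-1]
    if flip_v:
        img = img[::-1, :]
    return img


def _apply_lighting(img: np.ndarray, shift: float) -> np.ndarray:
    out = img.astype(np.float64) + shift * 255.0
    return np.clip(out, 0, 255).astype(np.uint8)


def _apply_color_jitter(img: np.ndarray, fb: float, fc: float, fs: float) -> np.ndarray:
    out = img.astype(np.float64)
    out = out * fb
    mean = out.mean()
    out = (out - mean) * fc + mean
    gray = out.mean(axis=2, keepdims=True)
    out = gray + fs * (out - gray)
    return np.clip(out, 0, 255).astype(np.uint8)


def _naive_transform(img: np.ndarray, rng: np.random.Generator, spec: AugmentationSpec):
    flip_h = spec.flip_horizontal and bool(rng.integers(2))
    flip_v = spec.flip_vertical and bool(rng.integers(2))
    shift = float(rng.uniform(-spec.lighting_range, spec.lighting_range))
    out = _apply_lighting(_apply_flips(img, flip_h, flip_v), shift)
    return out, {"flip_h": flip_h, "flip_v": flip_v, "lighting": shift}


def _augmented_transform(hires: np.ndarray, rng: np.random.Generator, spec: AugmentationSpec):
    side = spec.crop_side
    if spec.center_crop:
        y0 = x0 = (hires.shape[0] - side) // 2
    else:
        y0 = int(rng.integers(0, hires.shape[0] - side + 1))
        x0 = int(rng.integers(0, hires.shape[1] - side + 1))
    out = hires[y0 : y0 + side, x0 : x0 + side]
    flip_h = spec.flip_horizontal and bool(rng.integers(2))
    flip_v = spec.flip_vertical and bool(rng.integers(2))
    out = _apply_flips(out, flip_h, flip_v)
    fb = float(rng.uniform(*spec.brightness))
    fc = float(rng.uniform(*spec.contrast))
    fs = float(rng.uniform(*spec.saturation))
    out = _apply_color_jitter(out, fb, fc, fs)
    return np.ascontiguousarray(out), {
        "crop": (x0, y0), "flip_h": flip_h, "flip_v": flip_v,
        "brightness": fb, "contrast": fc, "saturation": fs,
    }


# ---------------------------------------------------------------------------
# oversampling
# ---------------------------------------------------------------------------


def _oversample(ds: ColonyDataset, rank: str, seed: int, spec: AugmentationSpec,
                mode: str) -> DatasetVariant:
    rng = np.random.default_rng(seed)
    train_idx = ds.train_indices()
    if train_idx.size == 0:
        raise ValueError("no training samples to oversample")
    if mode == "augmented":
        if ds.images_hires is None:
            raise ValueError(
                "augmented oversampling needs high-resolution source images "
                f"(>= {spec.pre_crop_side} px); dataset has none"
            )
        if ds.images_hires.shape[1] < spec.pre_crop_side:
            raise ValueError(
                f"high-resolution sources are {ds.images_hires.shape[1]} px, "
                f"smaller than pre_crop_side={spec.pre_crop_side}"
            )
        if spec.crop_side != ds.side:
            raise ValueError(
                f"crop_side={spec.crop_side} must match dataset image side {ds.side}"
            )

    train_labels = ds.labels_at(rank, train_idx)
    prof = imbalance_profile(train_labels)
    new_images, new_rows, new_hires, provenance = [], [], [], []
    for cls, count in prof.counts.items():
        if count >= prof.MC_plus:
            continue
        donors = train_idx[train_labels == cls]
        chosen = rng.choice(donors, size=prof.MC_plus - count, replace=True)
        for d in chosen:
            d = int(d)
            if mode == "naive":
                img, tf = _naive_transform(ds.images[d], rng, spec)
                hi = None
                if ds.images_hires is not None:
                    hi = _apply_lighting(
                        _apply_flips(ds.images_hires[d], tf["flip_h"], tf["flip_v"]),
                        tf["lighting"],
                    )
            else:
                img, tf = _augmented_transform(ds.images_hires[d], rng, spec)
                hi = ds.images_hires[d]
            new_images.append(img)
            if ds.images_hires is not None:
                new_hires.append(hi)
            new_rows.append(ds.labels.iloc[d])
            provenance.append({"donor_index": d, "transform": tf, "class": cls})

    if new_images:
        import pandas as pd

        images = np.concatenate([ds.images, np.stack(new_images)])
        labels = pd.concat([ds.labels, pd.DataFrame(new_rows)], ignore_index=True)
        partition = np.concatenate([ds.partition, np.full(len(new_images), "train")])
        hires = (
            np.concatenate([ds.images_hires, np.stack(new_hires)])
            if ds.images_hires is not None
            else None
        )
    else:
        images, labels, partition, hires = ds.images, ds.labels, ds.partition, ds.images_hires
    out = ColonyDataset(images=images, labels=labels, partition=partition, images_hires=hires)
    return DatasetVariant(name=mode, dataset=out, balanced_rank=rank, provenance=provenance)


def naive_oversample(ds: ColonyDataset, rank: str, seed: int,
                     spec: AugmentationSpec | None = None) -> DatasetVariant:
    """Balance every class at ``rank`` up to the majority count by re-adding
    flipped / lighting-shifted copies of minority training images."""
    spec = spec or AugmentationSpec(variant="naive")
    return _oversample(ds, rank, seed, spec, "naive")


def augmented_oversample(ds: ColonyDataset, rank: str, seed: int,
                         spec: AugmentationSpec | None = None) -> DatasetVariant:
    """Balance like :func:`naive_oversample`, but synthesize images as random
    ``crop_side`` crops of the donor's ``pre_crop_side`` rendition with
    brightness/contrast/saturation jitter and flips."""
    spec = spec or AugmentationSpec(variant="augmented")
    return _oversample(ds, rank, seed, spec, "augmented")


def make_variants(ds: ColonyDataset, rank: str, seed: int,
                  spec: AugmentationSpec | None = None) -> dict[str, DatasetVariant]:
    """Build the three treatments; all share the identical test partition."""
    aug_spec = spec if spec is not None and spec.variant == "augmented" else _augmented_spec_like(spec, ds)
    return {
        "original": DatasetVariant(name="original", dataset=ds, balanced_rank=None),
        "naive": naive_oversample(ds, rank, seed, spec),
        "augmented": augmented_oversample(ds, rank, seed, aug_spec),
    }


def write_variant(variant: DatasetVariant, outdir) -> "Path":
    """Write a variant to disk: per-image PNGs plus a TSV manifest.

    The manifest carries image path, the six labels, the partition tag and
    — for synthetic (oversampled) rows — the donor row index and the
    transform record as JSON, so every image's provenance is auditable.
    Returns the manifest path.
    """
    import json
    from pathlib import Path

    import pandas as pd
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    ds = variant.dataset
    n_original = ds.n - len(variant.provenance)
    rows = []
    for i in range(ds.n):
        rel = f"images/{variant.name}_{i:05d}.png"
        Image.fromarray(ds.images[i]).save(outdir / rel)
        row = {"image": rel, **ds.labels.iloc[i].to_dict()}
        row["partition"] = ds.partition[i]
        if i >= n_original:
            entry = variant.provenance[i - n_original]
            row["donor_index"] = entry["donor_index"]
            row["transform"] = json.dumps(entry["transform"])
        rows.append(row)
    manifest = outdir / f"{variant.name}.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def _augmented_spec_like(spec: AugmentationSpec | None, ds: ColonyDataset) -> AugmentationSpec:
    base = spec or AugmentationSpec()
    pre = ds.images_hires.shape[1] if ds.images_hires is not None else base.pre_crop_side
    return AugmentationSpec(
        variant="augmented",
        flip_horizontal=base.flip_horizontal,
        flip_vertical=base.flip_vertical,
        lighting_range=base.lighting_range,
        brightness=base.brightness,
        contrast=base.contrast,
        saturation=base.saturation,
        pre_crop_side=pre,
        crop_side=ds.side,
        center_crop=base.center_crop,
    )
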