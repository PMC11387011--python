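"""Reproducible experiment orchestration: the architectures-by-treatments grid.

``run_grid`` executes every (architecture, dataset-variant) cell of the
3 x 3 study design — {SL, ML, HC} x {original, naive, augmented} — on one
simulated collection: simulate -> preprocess -> split -> balance -> train
-> evaluate, writing a tidy summary CSV, per-cell training histories,
best-epoch confusion matrices and a provenance manifest.  ``report``
renders the standard figures (per-epoch curves, best-score bars, confusion
heatmaps) from a completed archive.

Balancing follows the per-classifier loss exposure: each SL/HC rank model
is trained on data balanced at its own rank, while the ML model balances
at the deepest rank (species).  Cell seeds are derived from the global
seed by stable hashing of the cell name, so adding cells never shifts
existing results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import models as mdl
from .data import ColonyDataset, DatasetVariant
from .imbalance import AugmentationSpec, augmented_oversample, naive_oversample
from .preprocessing import (
    extract_dishes,
    impute_missing_labels,
    kfold_splits,
    records_to_table,
    split_train_test,
)
from .synthetic import RANKS, CollectionConfig, render_isolate_images, simulate_collection

log = logging.getLogger("mycotax")

ARCHITECTURES = ("sl", "ml", "hc")


@dataclass
class ExperimentConfig:
    """Fully serializable description of one grid experiment."""

    outdir: str = "results"
    seed: int = 0
    collection: CollectionConfig = field(default_factory=CollectionConfig)
    image_side: int = 64
    hires_side: int = 96
    use_group_scans: bool = False
    split_ratio: float = 0.7
    stratify_rank: str = "phylum"
    architectures: tuple[str, ...] = ARCHITECTURES
    variants: tuple[str, ...] = ("original", "naive", "augmented")
    ranks: tuple[str, ...] = RANKS
    backbone: mdl.BackboneSpec = field(default_factory=mdl.BackboneSpec)
    training: mdl.TrainingConfig = field(default_factory=mdl.TrainingConfig)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, sub in (("collection", CollectionConfig),
                         ("backbone", mdl.BackboneSpec),
                         ("training", mdl.TrainingConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in raw[key].items()})
        for key in ("architectures", "variants", "ranks"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def cell_seed(global_seed: int, *parts) -> int:
    """Stable per-cell seed below 2**31 from the global seed and cell name."""
    key = f"{global_seed}|" + "|".join(str(p) for p in parts)
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def build_dataset(config: ExperimentConfig):
    """Simulate a collection and turn it into a split ColonyDataset.

    With ``use_group_scans`` the full path is exercised (group scans,
    Circle Hough detection, per-dish crops, area resize); otherwise dishes
    are rendered directly at the working resolution, which is pixel-wise
    what the crop path produces but much faster.  Returns
    ``(dataset, collection)``.
    """
    cc = config.collection
    if config.use_group_scans:
        collection = simulate_collection(cc, config.seed)
        imgs, hires = [], []
        for scan in collection.scans:
            tiles, circles, htiles = extract_dishes(
                scan.image, layout=scan.layout, target_side=config.image_side,
                hires_side=config.hires_side,
            )
            if len(tiles) != len(scan.records):
                raise RuntimeError(
                    f"detected {len(tiles)} dishes but scan holds {len(scan.records)}"
                )
            imgs.append(tiles)
            hires.append(htiles)
        images = np.concatenate(imgs)
        images_hires = np.concatenate(hires)
        records = [rec for scan in collection.scans for rec in scan.records]
    else:
        from .synthetic import attach_morphology, generate_taxonomy, sample_isolates
        from .synthetic import SimulatedCollection

        tree = generate_taxonomy(cc.n_per_rank, cc.skew, config.seed)
        records = sample_isolates(tree, cc.n_isolates, cc.missing_rates, config.seed + 1)
        attach_morphology(tree, records, cc.inheritance_decay, config.seed + 2,
                          cc.hue_min_separation)
        images, images_hires = render_isolate_images(
            records, config.image_side, config.seed + 3,
            hires_size=config.hires_side, confounder_prob=cc.confounder_prob,
        )
        collection = SimulatedCollection(cc, config.seed, tree, records, [],
                                         {r.isolate_id: r.true_path for r in records})

    table = impute_missing_labels(records_to_table(records).reset_index(drop=True))
    partition = split_train_test(
        table[config.stratify_rank].to_numpy(), config.split_ratio,
        seed=cell_seed(config.seed, "split"),
    )
    ds = ColonyDataset(images=images, labels=table, partition=partition,
                       images_hires=images_hires, records=records)
    return ds, collection


def variant_for(ds: ColonyDataset, name: str, rank: str, seed: int,
                spec: AugmentationSpec | None = None) -> DatasetVariant:
    """The requested treatment of ``ds`` balanced at ``rank``."""
    if name == "original":
        return DatasetVariant(name="original", dataset=ds)
    if name == "naive":
        return naive_oversample(ds, rank, seed, spec)
    if name == "augmented":
        base = spec or AugmentationSpec(variant="augmented")
        pre = ds.images_hires.shape[1] if ds.images_hires is not None else base.pre_crop_side
        spec_fit = dataclasses.replace(base, variant="augmented",
                                       pre_crop_side=pre, crop_side=ds.side)
        return augmented_oversample(ds, rank, seed, spec_fit)
    raise ValueError(f"unknown variant {name!r}")


# ---------------------------------------------------------------------------
# the grid
# ---------------------------------------------------------------------------


def _run_cell(arch: str, vname: str, ds: ColonyDataset, config: ExperimentConfig,
              outdir: Path | None = None):
    """Train one (architecture, variant) cell; returns (rows, histories)."""
    rows, histories, models_by_rank = [], {}, {}
    bspec, tcfg = config.backbone, config.training
    if arch == "sl":
        for rank in config.ranks:
            seed = cell_seed(config.seed, arch, vname, rank)
            var = variant_for(ds, vname, rank, seed)
            model, hist = mdl.train_sl(var, rank, bspec,
                                       dataclasses.replace(tcfg, seed=seed))
            histories[rank] = hist
            models_by_rank[rank] = model
    elif arch == "ml":
        seed = cell_seed(config.seed, arch, vname)
        var = variant_for(ds, vname, "species", seed)
        model, hist = mdl.train_ml(var, bspec, dataclasses.replace(tcfg, seed=seed))
        histories = {r: hist for r in config.ranks}
        models_by_rank = {r: model for r in config.ranks}
    elif arch == "hc":
        variants = {
            rank: variant_for(ds, vname, rank, cell_seed(config.seed, arch, vname, rank))
            for rank in RANKS
        }
        models, hists = mdl.train_hc_staged(variants, bspec, tcfg,
                                            seed=cell_seed(config.seed, arch, vname))
        histories = {r: hists[r] for r in config.ranks}
        models_by_rank = {r: models[r] for r in config.ranks}
    else:
        raise ValueError(f"unknown architecture {arch!r}")

    if outdir is not None:
        cdir = outdir / "confusion"
        cdir.mkdir(exist_ok=True)
        test_idx = ds.test_indices()
        for rank in config.ranks:
            model = models_by_rank[rank]
            y_true = ds.labels_at(rank, test_idx)
            y_pred = model.predict_labels(ds.images[test_idx])[rank]
            cm = ev.confusion(y_true, y_pred,
                              sorted(set(y_true) | set(model.classes[rank])))
            ev.confusion_to_csv(cm, cdir / f"{arch}_{vname}_{rank}.csv")

    for rank in config.ranks:
        best = ev.evaluate_history(histories[rank])[rank]
        entry = next(e for e in histories[rank] if e["epoch"] == best.epoch)
        m = entry["metrics"][rank]
        rows.append({
            "architecture": arch, "variant": vname, "rank": rank,
            "best_epoch": best.epoch,
            "test_accuracy": m["test_accuracy"], "test_mcc": m["test_mcc"],
            "train_accuracy": m["train_accuracy"], "train_mcc": m["train_mcc"],
        })
    return rows, histories


def run_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Execute every (architecture, variant) cell and write the archive.

    A failing cell is logged and skipped; the other cells proceed.  Returns
    the tidy summary table (one row per architecture, variant and rank).
    """
    outdir = Path(config.outdir)
    (outdir / "histories").mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    ds, collection = build_dataset(config)

    all_rows = []
    for arch in config.architectures:
        for vname in config.variants:
            try:
                rows, histories = _run_cell(arch, vname, ds, config, outdir)
            except Exception:
                log.exception("cell (%s, %s) failed; continuing", arch, vname)
                continue
            all_rows.extend(rows)
            hist_path = outdir / "histories" / f"{arch}_{vname}.json"
            hist_path.write_text(json.dumps(histories, indent=1))
    summary = pd.DataFrame(all_rows)
    summary.to_csv(outdir / "summary.csv", index=False)
    manifest = {
        "seed": config.seed,
        "n_isolates": len(ds.images),
        "image_side": config.image_side,
        "cells": sorted({(r["architecture"], r["variant"]) for r in all_rows}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return summary


def report(outdir) -> list[Path]:
    """Render figures and a markdown summary from a grid archive.

    Produces per-cell MCC/accuracy curves, a best-test-MCC bar panel and a
    short markdown digest; incomplete archives yield a partial report with
    warnings.  Returns the paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: list[Path] = []
    summary_path = outdir / "summary.csv"
    if not summary_path.exists():
        log.warning("no summary.csv in %s; nothing to report", outdir)
        return written
    summary = pd.read_csv(summary_path)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    for hist_path in sorted((outdir / "histories").glob("*.json")):
        histories = json.loads(hist_path.read_text())
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for rank, hist in histories.items():
            epochs = [e["epoch"] for e in hist]
            axes[0].plot(epochs, [e["metrics"][rank]["test_mcc"] for e in hist], label=rank)
            axes[1].plot(epochs, [e["metrics"][rank]["test_accuracy"] for e in hist], label=rank)
        axes[0].set(xlabel="epoch", ylabel="test MCC", title=hist_path.stem)
        axes[1].set(xlabel="epoch", ylabel="test accuracy", title=hist_path.stem)
        axes[0].legend(fontsize=6)
        fig.tight_layout()
        path = figdir / f"curves_{hist_path.stem}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    cm_paths = sorted((outdir / "confusion").glob("*.csv")) if (outdir / "confusion").is_dir() else []
    for cm_path in cm_paths:
        cm = ev.confusion_from_csv(cm_path)
        fig, ax = plt.subplots(figsize=(5, 4.5))
        im = ax.imshow(cm.counts, cmap="viridis")
        ax.set(xlabel="predicted", ylabel="observed", title=cm_path.stem)
        if len(cm.labels) <= 15:
            ax.set_xticks(range(len(cm.labels)), cm.labels, rotation=90, fontsize=5)
            ax.set_yticks(range(len(cm.labels)), cm.labels, fontsize=5)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        path = figdir / f"heatmap_{cm_path.stem}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    if not summary.empty:
        fig, ax = plt.subplots(figsize=(8, 4))
        piv = summary.pivot_table(index="rank", columns=["architecture", "variant"],
                                  values="test_mcc")
        piv = piv.reindex([r for r in RANKS if r in piv.index])
        piv.plot.bar(ax=ax, legend=True)
        ax.set_ylabel("best test MCC")
        ax.legend(fontsize=6)
        fig.tight_layout()
        path = figdir / "best_mcc.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    md = ["# Grid summary", "", "```", summary.to_string(index=False), "```"]
    md_path = outdir / "report.md"
    md_path.write_text("\n".join(md))
    written.append(md_path)
    return written
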