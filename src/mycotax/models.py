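"""Per-rank, multi-label and hierarchically chained colony classifiers.

Three architectures address the nested taxonomy:

* **SL** (separate local): one independently trained classifier per rank.
* **ML** (multi-label): one shared backbone with six independent output
  heads trained jointly under the unweighted sum of the per-rank softmax
  cross-entropies.  Because the heads are independent, predicted labels
  may form a biologically inconsistent path; that rate is measured, not
  forced to zero.
* **HC** (hierarchically chained): six stacked classifiers
  C_phylum < C_class < ... < C_species.  Each stage trains on its own
  rank's loss and hands its learned backbone parameters to the next stage
  (transfer down the hierarchy).  An optional joint mode additionally
  keeps the earlier ranks' losses in each stage's objective (the
  compositional reading of the nested-loss chain).

Training uses SGD with momentum ``m = 0.8``, L2 weight decay ``wd = 0.01``
and learning rate ``lr = 0.001`` for 20 epochs of fine-tuning, with Xavier
initialization — the reference settings for this task.  The default
backbone is a small four-block CNN trained from scratch (desk-scale,
dependency-free); a DenseNet-169 transfer-learning backbone is part of the
interface but requires a locally cached weight bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import evaluation as ev
from . import nn
from .data import DatasetVariant
from .synthetic import RANKS

DENSENET_CACHE = "~/.cache/mycotax/densenet169.npz"


@dataclass
class BackboneSpec:
    """Feature-extractor choice.  ``small_cnn`` is always available;
    ``densenet169`` needs a locally cached pretrained weight bundle."""

    name: str = "small_cnn"
    pretrained: bool = False
    channels: tuple[int, ...] = (8, 16, 32, 64)
    feature_gain: float = 8.0

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]


@dataclass
class TrainingConfig:
    """Optimization settings; defaults are the reference hyperparameters."""

    lr: float = 0.001
    momentum: float = 0.8
    weight_decay: float = 0.01
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.momentum, self.weight_decay) < 0 or self.lr == 0:
            raise ValueError("lr must be positive; momentum/weight_decay nonnegative")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")


def build_backbone(spec: BackboneSpec, seed: int) -> nn.Sequential:
    """Build the feature extractor mapping NCHW image batches to feature
    vectors.  Untrained layers are Xavier-initialized deterministically per
    seed."""
    if spec.name == "small_cnn":
        rng = np.random.default_rng(seed)
        layers = []
        c_prev = 3
        for c in spec.channels:
            layers += [nn.Conv2d(c_prev, c, rng), nn.ChannelNorm(), nn.ReLU(), nn.MaxPool2()]
            c_prev = c
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.FeatureScale(spec.feature_gain))
        return nn.Sequential(layers)
    if spec.name == "densenet169":
        raise FileNotFoundError(
            "densenet169 backbone requires a locally cached pretrained weight "
            f"bundle at {DENSENET_CACHE} (no download is attempted), and no "
            "cache was found; use the small_cnn backbone instead"
        )
    raise ValueError(f"unknown backbone {spec.name!r}")


@dataclass
class RankModel:
    """A trained classifier exposing per-rank class-probability outputs."""

    backbone: nn.Sequential
    heads: dict[str, nn.Linear]
    classes: dict[str, list[str]]
    architecture: str = "sl"
    #: backbone parameters at epoch 0, before any update (hand-off audit)
    initial_backbone_state: dict | None = None

    @property
    def ranks(self) -> tuple[str, ...]:
        return tuple(r for r in RANKS if r in self.heads)

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> dict[str, np.ndarray]:
        """Softmax class probabilities per covered rank for uint8 NHWC images."""
        if images.ndim != 4 or images.shape[3] != 3:
            raise ValueError("expected a batch of H x W x 3 images")
        outs: dict[str, list[np.ndarray]] = {r: [] for r in self.ranks}
        for s in range(0, len(images), batch_size):
            feats = self.backbone.forward(nn.to_batch(images[s : s + batch_size]))
            for r in self.ranks:
                outs[r].append(nn.softmax(self.heads[r].forward(feats)))
        return {r: np.concatenate(v) for r, v in outs.items()}

    def predict_labels(self, images: np.ndarray, batch_size: int = 64) -> dict[str, np.ndarray]:
        probs = self.predict_proba(images, batch_size)
        return {
            r: np.asarray(self.classes[r])[p.argmax(axis=1)] for r, p in probs.items()
        }


def predict(model: RankModel, images: np.ndarray) -> dict[str, np.ndarray]:
    """Per-rank probability vectors for a batch (order preserving)."""
    return model.predict_proba(images)


# ---------------------------------------------------------------------------
# training internals
# ---------------------------------------------------------------------------


def _class_index(labels: np.ndarray):
    classes = sorted(set(labels.tolist()))
    lut = {c: i for i, c in enumerate(classes)}
    return classes, lut


def _epoch_metrics(model: RankModel, ds, idx, rank) -> dict[str, float]:
    y_true = ds.labels_at(rank, idx)
    y_pred = model.predict_labels(ds.images[idx])[rank]
    labels = sorted(set(y_true.tolist()) | set(model.classes[rank]))
    cm = ev.confusion(y_true, y_pred, labels)
    return {"accuracy": ev.accuracy(cm), "mcc": ev.mcc(cm)}


def _record_epoch(history, epoch, loss, model, ds, ranks):
    train_idx, test_idx = ds.train_indices(), ds.test_indices()
    entry = {"epoch": epoch, "loss": loss, "metrics": {}}
    for r in ranks:
        m_tr = _epoch_metrics(model, ds, train_idx, r)
        m_te = _epoch_metrics(model, ds, test_idx, r)
        entry["metrics"][r] = {
            "train_accuracy": m_tr["accuracy"],
            "train_mcc": m_tr["mcc"],
            "test_accuracy": m_te["accuracy"],
            "test_mcc": m_te["mcc"],
        }
    history.append(entry)


def _train_multihead(
    variant: DatasetVariant,
    ranks: list[str],
    backbone: nn.Sequential,
    config: TrainingConfig,
    architecture: str,
):
    """Shared loop: one backbone, one head per requested rank, loss summed."""
    ds = variant.dataset
    train_idx = ds.train_indices()
    if train_idx.size == 0:
        raise ValueError("empty training partition")
    rng = np.random.default_rng(config.seed)
    head_rng = np.random.default_rng(config.seed + 1)

    heads, classes, y_enc = {}, {}, {}
    for r in ranks:
        labels = ds.labels_at(r, train_idx)
        cls, lut = _class_index(labels)
        if len(cls) < 2:
            raise ValueError(f"training data has a single class at rank {r!r}")
        classes[r] = cls
        y_enc[r] = np.array([lut[v] for v in labels])
    # probe feature dim with a single forward pass
    feature_dim = backbone.forward(nn.to_batch(ds.images[train_idx[:1]])).shape[1]
    for r in ranks:
        heads[r] = nn.Linear(feature_dim, len(classes[r]), head_rng)

    model = RankModel(backbone, heads, classes, architecture,
                      initial_backbone_state=backbone.state_dict())
    opt = nn.SGD([backbone, *heads.values()], config.lr, config.momentum, config.weight_decay)
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        total, nb = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            sel = order[s : s + config.batch_size]
            x = nn.to_batch(ds.images[train_idx[sel]])
            feats = backbone.forward(x, train=True)
            dfeat = np.zeros_like(feats)
            loss = 0.0
            for r in ranks:
                logits = heads[r].forward(feats)
                lr_loss, dlog = nn.cross_entropy_grad(logits, y_enc[r][sel])
                loss += lr_loss
                dfeat += heads[r].backward(dlog)
            backbone.backward(dfeat)
            opt.step()
            total += loss
            nb += 1
        _record_epoch(history, epoch, total / max(nb, 1), model, ds, ranks)
    return model, history


# ---------------------------------------------------------------------------
# public training entry points
# ---------------------------------------------------------------------------


def train_sl(variant: DatasetVariant, rank: str, backbone_spec: BackboneSpec,
             config: TrainingConfig):
    """Train one independent classifier for a single taxonomic rank."""
    backbone = build_backbone(backbone_spec, config.seed)
    return _train_multihead(variant, [rank], backbone, config, architecture="sl")


def train_ml(variant: DatasetVariant, backbone_spec: BackboneSpec, config: TrainingConfig):
    """Train the multi-label model: shared backbone, six independent heads,
    unweighted sum of per-rank cross-entropies."""
    backbone = build_backbone(backbone_spec, config.seed)
    return _train_multihead(variant, list(RANKS), backbone, config, architecture="ml")


def train_hc(variant: DatasetVariant, backbone_spec: BackboneSpec, config: TrainingConfig,
             joint: bool = False):
    """Train the hierarchically chained classifiers phylum -> species.

    The backbone of stage r+1 is initialized from stage r's trained
    backbone (fresh head).  With ``joint=True`` each stage keeps the
    earlier ranks' losses in its objective (compositional chain); by
    default each stage optimizes only its own rank's cross-entropy.

    Returns ``(models, histories)`` keyed by rank, in rank order.
    """
    models: dict[str, RankModel] = {}
    histories: dict[str, list[dict]] = {}
    state = None
    for depth, rank in enumerate(RANKS):
        backbone = build_backbone(backbone_spec, config.seed)
        if state is not None:
            backbone.load_state_dict(state)
        ranks = list(RANKS[: depth + 1]) if joint else [rank]
        stage_cfg = replace(config, seed=config.seed + depth)
        model, hist = _train_multihead(variant, ranks, backbone, stage_cfg, architecture="hc")
        models[rank] = model
        histories[rank] = hist
        state = backbone.state_dict()
    return models, histories


def save_model(model: RankModel, path) -> None:
    """Checkpoint a trained model to a single ``.npz`` (arrays + JSON meta)."""
    import json

    arrays = {f"backbone/{k}": v for k, v in model.backbone.state_dict().items()}
    for r, head in model.heads.items():
        for k, v in head.state_dict().items():
            arrays[f"head/{r}/{k}"] = v
    meta = {
        "architecture": model.architecture,
        "classes": model.classes,
        "head_dims": {r: list(model.heads[r].W.shape) for r in model.heads},
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path, backbone_spec: BackboneSpec | None = None) -> RankModel:
    """Restore a checkpoint written by :func:`save_model`."""
    import json

    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    backbone = build_backbone(backbone_spec or BackboneSpec(), seed=0)
    backbone.load_state_dict(
        {k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("backbone/")}
    )
    rng = np.random.default_rng(0)
    heads = {}
    for r, (d_out, d_in) in meta["head_dims"].items():
        head = nn.Linear(d_in, d_out, rng)
        head.load_state_dict(
            {k.rsplit("/", 1)[1]: data[k] for k in data.files
             if k.startswith(f"head/{r}/")}
        )
        heads[r] = head
    return RankModel(backbone, heads, meta["classes"], meta["architecture"])


def train_hc_staged(variants: dict[str, DatasetVariant], backbone_spec: BackboneSpec,
                    config: TrainingConfig, seed: int | None = None):
    """Chained training where every stage gets its own dataset variant.

    Used when each rank's stage trains on data balanced at that rank (the
    per-classifier loss-exposure convention); otherwise identical to
    :func:`train_hc` with ``joint=False``.
    """
    missing = [r for r in RANKS if r not in variants]
    if missing:
        raise ValueError(f"variants missing for ranks {missing}")
    base_seed = config.seed if seed is None else seed
    models: dict[str, RankModel] = {}
    histories: dict[str, list[dict]] = {}
    state = None
    for depth, rank in enumerate(RANKS):
        backbone = build_backbone(backbone_spec, base_seed)
        if state is not None:
            backbone.load_state_dict(state)
        stage_cfg = replace(config, seed=base_seed + depth)
        model, hist = _train_multihead(variants[rank], [rank], backbone, stage_cfg,
                                       architecture="hc")
        models[rank] = model
        histories[rank] = hist
        state = backbone.state_dict()
    return models, histories
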