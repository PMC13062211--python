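"""Experiment harness: data handling, splitting, training and evaluation.

A run is described by a :class:`RunConfig` (serialisable to YAML): the data
source (a synthetic scene family or an on-disk dataset directory), the
7:1:2 train/val/test split, preprocessing (resize to a fixed square size,
per-channel standardisation with dataset-computed statistics), the model
and loss configurations, and Adam optimiser settings.  Training logs one
history row per epoch and retains the checkpoint with the best validation
IoU; the encoder of a frozen-backbone model is verified untouched via a
probe-image checksum.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize as _sk_resize

from . import nn
from .autograd import Tensor
from .losses import LossConfig, total_loss_on_logits
from .metrics import MetricReport, evaluate_masks, lesion_geometry_rmse
from .model import (DinoUnet, ModelConfig, UnetBaseline, encoder_probe_checksum,
                    load_checkpoint, save_checkpoint)
from .synthetic import ImageSample, SceneConfig, generate_dataset, load_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig", "TrainResult", "split_dataset", "preprocess", "preprocess_mask",
    "train", "evaluate", "compare_models", "noise_coupling_experiment",
    "per_sample_lesion_iou", "setup_logging",
]


def setup_logging(log_file: str | Path | None = None, level=logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    n_images: int = 200
    data_dir: str | None = None              # overrides `scene` when set
    split_ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    split_seed: int = 0
    image_size: int = 256
    normalization: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    model_kind: str = "dinounet"             # dinounet | unet
    loss: LossConfig = field(default_factory=LossConfig)
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 50
    out_dir: str = "runs"
    run_seed: int = 0

    def validate(self) -> None:
        r = np.asarray(self.split_ratios, dtype=float)
        if (r <= 0).any() or abs(r.sum() - 1.0) > 1e-9:
            raise ValueError(f"split ratios must be positive and sum to 1, got {tuple(r)}")
        if self.model_kind not in ("dinounet", "unet"):
            raise ValueError(f"model_kind must be dinounet|unet, got {self.model_kind!r}")
        if self.optimizer != "adam":
            raise ValueError(f"only the adam optimizer is supported, got {self.optimizer!r}")
        if self.image_size % 16:
            raise ValueError(f"image_size must be divisible by 16, got {self.image_size}")
        self.model.validate()

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(_plainify(payload), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "scene" in kwargs and isinstance(kwargs["scene"], dict):
            sc = dict(kwargs["scene"])
            for key in ("class_set", "lesion_count_range", "lesion_area_fraction_range",
                        "lesion_radius_range", "illumination_jitter"):
                if key in sc and sc[key] is not None:
                    sc[key] = tuple(sc[key])
            kwargs["scene"] = SceneConfig(**sc)
        if "model" in kwargs and isinstance(kwargs["model"], dict):
            kwargs["model"] = ModelConfig(**kwargs["model"])
        if "loss" in kwargs and isinstance(kwargs["loss"], dict):
            ls = dict(kwargs["loss"])
            if ls.get("alpha") is not None:
                ls["alpha"] = tuple(ls["alpha"])
            kwargs["loss"] = LossConfig(**ls)
        for key in ("split_ratios", "normalization"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                                    for v in kwargs[key]) if key == "normalization" \
                    else tuple(kwargs[key])
        return cls(**kwargs)


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# splitting and preprocessing
# --------------------------------------------------------------------------

def split_dataset(n_samples: int, ratios=(0.7, 0.1, 0.2), seed: int = 0
                  ) -> tuple[list[int], list[int], list[int]]:
    """Disjoint, covering train/val/test index lists.

    Sizes follow an explicit rounding rule: ``test = round(r_test * n)``,
    ``val = round(r_val * n)``, train takes the remainder.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples to split")
    r = np.asarray(ratios, dtype=float)
    if (r <= 0).any() or abs(r.sum() - 1.0) > 1e-9:
        raise ValueError(f"ratios must be positive and sum to 1, got {tuple(r)}")
    n_test = int(round(r[2] * n_samples))
    n_val = int(round(r[1] * n_samples))
    n_train = n_samples - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n_samples} with ratios {tuple(r)} leaves an empty subset "
            f"({n_train}/{n_val}/{n_test})")
    perm = np.random.default_rng(seed).permutation(n_samples)
    train = sorted(int(i) for i in perm[:n_train])
    val = sorted(int(i) for i in perm[n_train:n_train + n_val])
    test = sorted(int(i) for i in perm[n_train + n_val:])
    return train, val, test


def preprocess(image: np.ndarray, size: int,
               normalization: tuple | None = None) -> np.ndarray:
    """Bilinear-resize an RGB image and standardise per channel -> (3, S, S)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {image.shape}")
    if image.shape[:2] != (size, size):
        image = _sk_resize(image, (size, size), order=1, mode="reflect",
                           anti_aliasing=False, preserve_range=True)
    if normalization is not None:
        mean, std = (np.asarray(v, dtype=np.float64) for v in normalization)
        image = (image - mean) / std
    return np.ascontiguousarray(image.transpose(2, 0, 1).astype(nn.DTYPE))


def preprocess_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resize of a class mask (labels preserved exactly)."""
    mask = np.asarray(mask)
    if mask.shape == (size, size):
        return mask.astype(np.int64)
    out = _sk_resize(mask.astype(np.float64), (size, size), order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return np.round(out).astype(np.int64)


def _dataset_normalization(images: list[np.ndarray]) -> tuple[tuple, tuple]:
    stack = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    mean = stack.mean(axis=(0, 1, 2))
    std = stack.std(axis=(0, 1, 2))
    std = np.where(std < 1e-6, 1.0, std)
    return tuple(mean.tolist()), tuple(std.tolist())


def _load_samples(run: RunConfig) -> list[ImageSample]:
    if run.data_dir is not None:
        samples = load_dataset(run.data_dir)
        if not samples:
            raise FileNotFoundError(f"no samples found under {run.data_dir}")
        return samples
    samples, _ = generate_dataset(run.scene, run.n_images)
    return samples


def _build_model(run: RunConfig):
    if run.model_kind == "dinounet":
        return DinoUnet(run.model)
    return UnetBaseline(run.model)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: object
    history: pd.DataFrame
    checkpoint_path: Path | None
    normalization: tuple
    split: tuple[list[int], list[int], list[int]]
    encoder_checksum_before: str | None
    encoder_checksum_after: str | None


def _predict_mask(model, x: np.ndarray) -> np.ndarray:
    logits = model.forward_logits(Tensor(x[None]))
    return logits.data[0].argmax(axis=0)


def _val_metrics(model, xs, masks, class_ids) -> dict[str, float]:
    preds = [_predict_mask(model, x) for x in xs]
    rep = evaluate_masks(preds, masks, class_ids)
    return {"dice": rep.macro["dice"], "iou": rep.macro["iou"],
            "pixel_accuracy": rep.macro["pixel_accuracy"]}


def train(run: RunConfig, samples: list[ImageSample] | None = None,
          out_dir: str | Path | None = None) -> TrainResult:
    """Seeded end-to-end training; returns history and the best-IoU model."""
    run.validate()
    t_start = time.time()
    if samples is None:
        samples = _load_samples(run)
    n_classes = run.model.n_classes
    max_id = max(int(s.mask.max()) for s in samples)
    if max_id >= n_classes:
        raise ValueError(f"data contains class id {max_id} but the model has "
                         f"{n_classes} classes")
    tr_idx, va_idx, te_idx = split_dataset(len(samples), run.split_ratios, run.split_seed)
    norm = run.normalization or _dataset_normalization(
        [samples[i].image for i in tr_idx])
    xs = [preprocess(s.image, run.image_size, norm) for s in samples]
    ms = [preprocess_mask(s.mask, run.image_size) for s in samples]
    class_ids = list(range(n_classes))

    model = _build_model(run)
    probe = xs[tr_idx[0]]
    ck_before = (encoder_probe_checksum(model, probe)
                 if isinstance(model, DinoUnet) else None)
    opt = nn.Adam(model.trainable_parameters(), lr=run.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([run.run_seed, 0x7121]))

    rows = []
    best_iou, best_state = -1.0, None
    for epoch in range(run.epochs):
        order = rng.permutation(len(tr_idx))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), run.batch_size):
            batch = [tr_idx[i] for i in order[start:start + run.batch_size]]
            xb = np.stack([xs[i] for i in batch])
            tb = np.stack([ms[i] for i in batch])
            logits = model.forward_logits(Tensor(xb))
            loss = total_loss_on_logits(logits, tb, run.loss)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {n_batches} (lr={run.learning_rate}, "
                    f"batch_size={run.batch_size})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += lval
            n_batches += 1
        val = _val_metrics(model, [xs[i] for i in va_idx],
                           [ms[i] for i in va_idx], class_ids)
        rows.append({"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
                     "val_dice": val["dice"], "val_iou": val["iou"],
                     "val_pixel_accuracy": val["pixel_accuracy"]})
        logger.info("epoch %d loss %.4f val_iou %.4f", epoch,
                    rows[-1]["train_loss"], val["iou"])
        if val["iou"] > best_iou:
            best_iou = val["iou"]
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    if best_state is not None:
        model.load_state_dict(best_state)
    ck_after = (encoder_probe_checksum(model, probe)
                if isinstance(model, DinoUnet) else None)
    if ck_before is not None and run.model.encoder_frozen and ck_before != ck_after:
        raise RuntimeError("frozen encoder changed during training")

    history = pd.DataFrame(rows)
    ckpt_path = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        history.to_csv(out / "history.csv", index=False)
        ckpt_path = save_checkpoint(model, out / "checkpoint.npz")
        run_with_norm = dataclasses.replace(run, normalization=norm)
        run_with_norm.to_yaml(out / "run_config.yaml")
    logger.info("training finished in %.1fs (best val IoU %.4f)",
                time.time() - t_start, best_iou)
    return TrainResult(model=model, history=history, checkpoint_path=ckpt_path,
                       normalization=norm, split=(tr_idx, va_idx, te_idx),
                       encoder_checksum_before=ck_before,
                       encoder_checksum_after=ck_after)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def per_sample_lesion_iou(pred: np.ndarray, gt: np.ndarray,
                          lesion_ids: list[int]) -> float:
    """Micro IoU over lesion classes within one image (pooled counts)."""
    tp = fp = fn = 0
    for cid in lesion_ids:
        p = pred == cid
        g = gt == cid
        tp += int((p & g).sum())
        fp += int((p & ~g).sum())
        fn += int((~p & g).sum())
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def evaluate(model_or_ckpt, samples: list[ImageSample], run: RunConfig,
             geometry_modes=("diameter", "circumference")
             ) -> tuple[MetricReport, pd.DataFrame]:
    """Full metric report plus a per-sample lesion-IoU table."""
    model = (load_checkpoint(model_or_ckpt)
             if isinstance(model_or_ckpt, (str, Path)) else model_or_ckpt)
    n_classes = model.cfg.n_classes
    max_id = max(int(s.mask.max()) for s in samples)
    if max_id >= n_classes:
        raise ValueError(f"data contains class id {max_id} but the checkpoint has "
                         f"{n_classes} classes")
    norm = run.normalization or _dataset_normalization([s.image for s in samples])
    preds, gts = [], []
    for s in samples:
        x = preprocess(s.image, run.image_size, norm)
        preds.append(_predict_mask(model, x))
        gts.append(preprocess_mask(s.mask, run.image_size))
    class_ids = list(range(n_classes))
    lesion_ids = [c for c in class_ids if c >= 2]
    report = evaluate_masks(preds, gts, class_ids)
    for cid in lesion_ids:
        report.geometry[cid] = {
            mode: lesion_geometry_rmse(preds, gts, cid, mode=mode)
            for mode in geometry_modes}
    table = pd.DataFrame({
        "sample": range(len(samples)),
        "iou": [per_sample_lesion_iou(p, g, lesion_ids) for p, g in zip(preds, gts)],
    })
    return report, table


def compare_models(runs: dict[str, RunConfig],
                   out_dir: str | Path | None = None) -> pd.DataFrame:
    """Train and evaluate several configurations on identical data and splits.

    All runs must share the same data source, split settings and image size;
    the comparison is over the model architecture, seeded identically.
    """
    if not runs:
        raise ValueError("no run configurations given")
    first = next(iter(runs.values()))
    for name, r in runs.items():
        if (r.scene, r.n_images, r.data_dir, r.split_ratios, r.split_seed,
                r.image_size) != (first.scene, first.n_images, first.data_dir,
                                  first.split_ratios, first.split_seed,
                                  first.image_size):
            raise ValueError(f"run {name!r} uses different data/split settings")
    samples = _load_samples(first)
    rows = []
    histories = {}
    for name, r in runs.items():
        sub = Path(out_dir) / name if out_dir is not None else None
        result = train(r, samples=samples, out_dir=sub)
        te_idx = result.split[2]
        run_eval = dataclasses.replace(r, normalization=result.normalization)
        report, per_sample = evaluate(result.model, [samples[i] for i in te_idx],
                                      run_eval)
        histories[name] = result.history
        row = {"model": name, "kind": r.model_kind,
               "test_dice": report.macro["dice"], "test_iou": report.macro["iou"],
               "test_pixel_accuracy": report.macro["pixel_accuracy"],
               "test_precision": report.macro["precision"],
               "test_recall": report.macro["recall"], "test_f1": report.macro["f1"]}
        for cid, modes in report.geometry.items():
            for mode, geo in modes.items():
                row[f"rmse_{mode}_class{cid}"] = geo.rmse
        rows.append(row)
        if sub is not None:
            report.save(sub / "metrics")
            per_sample.to_csv(sub / "per_sample_iou.csv", index=False)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "comparison.csv", index=False)
        _history_plot(histories, out / "history.png")
    return table


def _history_plot(histories: dict[str, pd.DataFrame], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for name, h in histories.items():
        axes[0].plot(h["epoch"], h["train_loss"], label=name)
        axes[1].plot(h["epoch"], h["val_iou"], label=name)
    axes[0].set_xlabel("epoch"); axes[0].set_ylabel("train loss")
    axes[1].set_xlabel("epoch"); axes[1].set_ylabel("val IoU")
    axes[1].legend()
    fig.tight_layout(); fig.savefig(path, dpi=120); plt.close(fig)


# --------------------------------------------------------------------------
# constructed embedding-vs-IoU coupling experiment
# --------------------------------------------------------------------------

def noise_coupling_experiment(n: int = 80, seed: int = 0, size: int = 64,
                              out_dir: str | Path | None = None):
    """Validation experiment coupling embedding quality to segmentation IoU.

    Each synthetic sample is corrupted with additive Gaussian noise of a
    per-sample level sigma_i; the same sigma_i also corrupts a copy of the
    ground-truth mask (random pixels reassigned), standing in for a
    prediction that degrades with image quality.  Embedding distances are
    computed from the frozen encoder on the noisy images, IoU from the
    degraded masks; a negative distance-IoU correlation is expected.
    """
    from .interpret import run_interpretability
    from .synthetic import simple_scene, generate_dataset as _gen

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    scene = simple_scene(size=size, seed=seed)
    samples, _ = _gen(scene, n)
    sigmas = rng.uniform(0.0, 0.8, size=n)
    lesion_ids = [c for c in range(len(scene.class_set)) if c >= 2]
    noisy, ious = [], []
    for s, sigma in zip(samples, sigmas):
        img = np.clip(s.image + rng.normal(0, sigma, size=s.image.shape), 0, 1)
        noisy.append(ImageSample(image=img, mask=s.mask, meta=dict(s.meta)))
        degraded = s.mask.copy()
        flip = rng.uniform(size=degraded.shape) < 0.6 * sigma
        degraded[flip] = rng.integers(0, len(scene.class_set), size=int(flip.sum()))
        ious.append(per_sample_lesion_iou(degraded, s.mask, lesion_ids))
    model = DinoUnet(ModelConfig(n_classes=len(scene.class_set), seed=seed))
    records, corr = run_interpretability(model, noisy, ious, k=1, seed=seed,
                                         out_dir=out_dir)
    return records, corr
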