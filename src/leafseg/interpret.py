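"""Embedding-space interpretability: does encoder-feature quality predict IoU?

Pipeline: pool each sample's encoder feature grid to a vector, project the
vectors to a low-dimensional space with UMAP, cluster with k-means to obtain
class centers, measure each sample's Euclidean distance to its own center,
and correlate that distance with the sample's segmentation IoU (Pearson r
with a two-sided t-test p-value).  A negative r means samples whose
embeddings sit close to their cluster center are segmented better.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .model import FeatureGrid

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingRecord", "CorrelationResult", "pool_features", "reduce_embedding",
    "assign_clusters_and_distances", "correlate_distance_iou", "run_interpretability",
]

_MIN_SAMPLES_UMAP = 10


@dataclass
class EmbeddingRecord:
    sample_id: int
    z: np.ndarray            # low-dimensional embedding
    cluster_label: int
    distance: float          # ||z - C_label||_2
    iou: float | None = None


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pool_features(grid: FeatureGrid | np.ndarray) -> np.ndarray:
    """Global average pool of an (H', W', C) grid to a C-vector."""
    values = grid.values if isinstance(grid, FeatureGrid) else np.asarray(grid)
    if values.ndim != 3:
        raise ValueError(f"expected (H', W', C) grid, got {values.shape}")
    return values.mean(axis=(0, 1))


def reduce_embedding(vectors: np.ndarray, d_low: int = 2, seed: int = 0) -> np.ndarray:
    """UMAP projection of n feature vectors to d_low dimensions (seeded)."""
    vectors = np.asarray(vectors, dtype=np.float64)
    n = vectors.shape[0]
    if n < _MIN_SAMPLES_UMAP:
        raise ValueError(
            f"UMAP reduction needs at least {_MIN_SAMPLES_UMAP} samples, got {n}")
    import umap  # deferred: numba-jitted import is slow

    reducer = umap.UMAP(n_components=d_low, random_state=int(seed),
                        n_neighbors=min(15, n - 1), n_jobs=1)
    return np.asarray(reducer.fit_transform(vectors), dtype=np.float64)


def assign_clusters_and_distances(z: np.ndarray, k: int, seed: int = 0,
                                  ious: np.ndarray | None = None
                                  ) -> tuple[list[EmbeddingRecord], np.ndarray]:
    """Seeded k-means (10 restarts); distances are to the sample's own center."""
    z = np.asarray(z, dtype=np.float64)
    n = z.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if np.unique(z, axis=0).shape[0] < k:
        raise ValueError(f"only {np.unique(z, axis=0).shape[0]} distinct points; "
                         f"cannot form k={k} clusters")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    labels = km.fit_predict(z)
    centers = km.cluster_centers_
    records = []
    for i in range(n):
        d = float(np.linalg.norm(z[i] - centers[labels[i]]))
        records.append(EmbeddingRecord(
            sample_id=i, z=z[i], cluster_label=int(labels[i]), distance=d,
            iou=float(ious[i]) if ious is not None else None))
    return records, centers


def correlate_distance_iou(records: list[EmbeddingRecord]) -> CorrelationResult:
    """Pearson r (with two-sided t-test p, n-2 df) between distance and IoU."""
    d = np.array([r.distance for r in records], dtype=float)
    i = np.array([r.iou for r in records], dtype=float)
    if np.any(np.isnan(i)):
        raise ValueError("all records need an IoU for correlation")
    if d.size < 3:
        raise ValueError("correlation needs at least 3 samples")
    if np.ptp(d) == 0 or np.ptp(i) == 0:
        raise ValueError("correlation undefined: distance or IoU is constant")
    res = stats.pearsonr(d, i)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=d.size)


def run_interpretability(model, samples, per_sample_ious, k: int, seed: int = 0,
                         out_dir: str | Path | None = None,
                         distance_space: str = "feature"
                         ) -> tuple[list[EmbeddingRecord], CorrelationResult]:
    """Full analysis over a test set; optionally writes CSV/JSON/PNG outputs.

    ``model`` must expose ``encode_tensor``/``cfg`` (a DinoUnet); features
    are its frozen encoder outputs, pooled per sample.  The 2-D UMAP
    embedding is always computed for visualisation; cluster centers and the
    distances ``D_i`` are measured in the original pooled-feature space by
    default (``distance_space='feature'``), because a 2-D neighbourhood
    embedding does not reliably preserve distance-to-center ordering.  Pass
    ``distance_space='umap'`` to cluster in the reduced space instead.
    """
    from .autograd import Tensor
    from .model import _to_nchw

    if distance_space not in ("feature", "umap"):
        raise ValueError(f"distance_space must be feature|umap, got {distance_space!r}")
    ious = np.asarray(per_sample_ious, dtype=float)
    if len(samples) != ious.size:
        raise ValueError(f"{len(samples)} samples but {ious.size} IoU values")
    vectors = []
    for s in samples:
        image = s.image if hasattr(s, "image") else np.asarray(s)
        grid = model.encode_tensor(Tensor(_to_nchw(image))).data[0].transpose(1, 2, 0)
        vectors.append(pool_features(FeatureGrid(values=grid, stride=model.cfg.patch_size)))
    vectors = np.stack(vectors)
    z = reduce_embedding(vectors, d_low=2, seed=seed)
    cluster_input = vectors if distance_space == "feature" else z
    records, centers = assign_clusters_and_distances(cluster_input, k=k, seed=seed,
                                                     ious=ious)
    corr = correlate_distance_iou(records)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = records_frame(records)
        df.to_csv(out / "embedding_records.csv", index=False)
        pd.DataFrame(z, columns=[f"z{j}" for j in range(z.shape[1])]).to_csv(
            out / "embeddings.csv", index=False)
        with open(out / "correlation.json", "w") as fh:
            json.dump(asdict(corr), fh, indent=2)
        _plots(z, records, centers, corr, out)
        logger.info("interpretability outputs written to %s", out)
    return records, corr


def records_frame(records: list[EmbeddingRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "cluster_label": r.cluster_label,
               "distance": r.distance, "iou": r.iou}
        for j, v in enumerate(np.asarray(r.z).ravel()):
            row[f"z{j}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)


def _plots(z, records, centers, corr, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.array([r.cluster_label for r in records])
    d = np.array([r.distance for r in records])
    i = np.array([r.iou for r in records], dtype=float)

    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(z[:, 0], z[:, 1], c=labels, cmap="tab10", s=18)
    if centers.shape[1] == z.shape[1]:
        ax.scatter(centers[:, 0], centers[:, 1], marker="x", c="k", s=80)
    ax.set_xlabel("UMAP-1"); ax.set_ylabel("UMAP-2")
    ax.set_title("Embedding clusters")
    fig.colorbar(sc, label="cluster")
    fig.tight_layout(); fig.savefig(out / "embedding_scatter.png", dpi=120); plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(d, i, s=18)
    ax.set_xlabel("distance to cluster center"); ax.set_ylabel("per-sample IoU")
    ax.set_title(f"r = {corr.r:.3f}, p = {corr.p:.2e} (n = {corr.n})")
    fig.tight_layout(); fig.savefig(out / "distance_vs_iou.png", dpi=120); plt.close(fig)
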