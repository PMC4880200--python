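"""Bundle post-processing: endpoint clustering, reorientation, resampling,
mean-skeleton outlier rejection and per-node metric extraction.

The processing chain is fixed: cluster endpoints -> orient/filter ->
resample to c equidistant nodes -> mean skeleton -> outlier removal ->
metric sampling.  After it, a bundle is an m x c grid of nodes, each node
carrying a world position and one metric value per time-point, which is the
unit every downstream cross-section model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.cluster import KMeans

from .bundle_io import RawBundle, ScalarVolume

__all__ = [
    "OrientedBundle",
    "ProcessedBundle",
    "MeanSkeleton",
    "cluster_endpoints",
    "orient_and_filter",
    "resample_fiber",
    "resample_bundle",
    "compute_mean_skeleton",
    "remove_outliers",
    "sample_metric",
    "process_bundle",
]

#: floor (mm) applied to per-node spread so identical-fiber bundles are not
#: self-rejected by the k-sigma rule
SPREAD_FLOOR = 1e-6


@dataclass
class EndpointClustering:
    r1_centroid: np.ndarray
    r2_centroid: np.ndarray
    #: (m, 2) array: cluster (0 = R1, 1 = R2) of each fiber's first/last point
    end_labels: np.ndarray


@dataclass
class OrientedBundle:
    fibers: list[np.ndarray]
    ids: np.ndarray
    r1_centroid: np.ndarray
    r2_centroid: np.ndarray
    removed_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.fibers)


@dataclass
class ProcessedBundle:
    """m fibers x c nodes, consistently oriented R1 -> R2.

    ``values[t]`` is the (m, c) matrix of metric values at time-point ``t``;
    NaN marks nodes whose world position fell outside the sampled volume.
    """

    positions: np.ndarray              # (m, c, 3) world mm
    ids: np.ndarray                    # (m,)
    values: dict[Any, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (m, c, 3)")

    @property
    def n_fibers(self) -> int:
        return self.positions.shape[0]

    @property
    def node_count(self) -> int:
        return self.positions.shape[1]

    def subset(self, fiber_ids: np.ndarray) -> "ProcessedBundle":
        """Restrict to the given fiber ids (order preserved)."""
        mask = np.isin(self.ids, fiber_ids)
        return ProcessedBundle(
            positions=self.positions[mask],
            ids=self.ids[mask],
            values={t: v[mask] for t, v in self.values.items()},
        )


@dataclass
class MeanSkeleton:
    """Per-node mean position with the spread of fibers around it.

    ``mean_distance[i]`` and ``spread[i]`` are the mean and SD of the
    Euclidean distances from each fiber's i-th node to ``mean_points[i]``.
    With ``method='coordinate'`` the spread is instead the norm of the
    per-axis coordinate SDs (mean_distance is then 0 and the outlier rule
    reduces to distance > k * spread).
    """

    mean_points: np.ndarray     # (c, 3)
    spread: np.ndarray          # (c,)
    mean_distance: np.ndarray   # (c,)
    method: str = "distance"


def cluster_endpoints(bundle: RawBundle, seed: int) -> EndpointClustering:
    """K-means (k=2, best of 10 restarts) on all fiber start/end points.

    Cluster R1 is the one with the lexicographically smaller centroid so the
    labelling is deterministic across seeds.
    """
    if len(bundle) < 2:
        raise ValueError("need at least 2 fibers to cluster endpoints")
    starts = np.array([f[0] for f in bundle.fibers])
    ends = np.array([f[-1] for f in bundle.fibers])
    pts = np.vstack([starts, ends])
    if np.allclose(pts, pts[0], atol=1e-12):
        raise ValueError("all fiber endpoints are coincident; "
                         "endpoint clusters are degenerate")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(pts)
    centroids = km.cluster_centers_
    order = np.lexsort(centroids.T[::-1])   # row-lexicographic
    r1, r2 = order[0], order[1]
    relabel = np.where(labels == r1, 0, 1)
    m = len(bundle)
    end_labels = np.column_stack([relabel[:m], relabel[m:]])
    return EndpointClustering(
        r1_centroid=centroids[r1].copy(),
        r2_centroid=centroids[r2].copy(),
        end_labels=end_labels,
    )


def orient_and_filter(bundle: RawBundle,
                      clustering: EndpointClustering) -> OrientedBundle:
    """Keep fibers linking R1 to R2, reversed if needed to run R1 -> R2.

    Fibers with both endpoints in the same cluster do not link the two
    regions and are removed (their ids are recorded).
    """
    kept: list[np.ndarray] = []
    kept_ids: list[Any] = []
    removed: list[Any] = []
    for fiber, fid, (lab_start, lab_end) in zip(
            bundle.fibers, bundle.ids, clustering.end_labels):
        if lab_start == lab_end:
            removed.append(fid)
            continue
        kept.append(fiber if lab_start == 0 else fiber[::-1].copy())
        kept_ids.append(fid)
    if not kept:
        raise ValueError("link filtering removed every fiber")
    return OrientedBundle(
        fibers=kept,
        ids=np.asarray(kept_ids),
        r1_centroid=clustering.r1_centroid,
        r2_centroid=clustering.r2_centroid,
        removed_ids=np.asarray(removed),
    )


def resample_fiber(fiber: np.ndarray, c: int = 100) -> np.ndarray:
    """Resample a polyline to ``c`` points equidistant in arc length.

    Linear interpolation between input vertices; the original first and last
    points are preserved exactly.
    """
    fiber = np.asarray(fiber, dtype=np.float64)
    if c < 2:
        raise ValueError("c must be >= 2")
    seg = np.linalg.norm(np.diff(fiber, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise ValueError("zero-length fiber cannot be resampled")
    targets = np.linspace(0.0, total, c)
    out = np.column_stack([np.interp(targets, arc, fiber[:, ax])
                           for ax in range(3)])
    out[0] = fiber[0]
    out[-1] = fiber[-1]
    return out


def resample_bundle(bundle: OrientedBundle, c: int = 100) -> ProcessedBundle:
    positions = np.stack([resample_fiber(f, c) for f in bundle.fibers])
    return ProcessedBundle(positions=positions, ids=bundle.ids.copy())


def compute_mean_skeleton(bundle: ProcessedBundle,
                          method: str = "distance") -> MeanSkeleton:
    """Mean node positions and the spread of fibers around each of them."""
    if bundle.n_fibers < 2:
        raise ValueError("need at least 2 fibers for a mean skeleton")
    mean_points = bundle.positions.mean(axis=0)                     # (c, 3)
    if method == "distance":
        dists = np.linalg.norm(bundle.positions - mean_points, axis=2)
        spread = dists.std(axis=0)
        mean_distance = dists.mean(axis=0)
    elif method == "coordinate":
        per_axis_sd = bundle.positions.std(axis=0)                  # (c, 3)
        spread = np.linalg.norm(per_axis_sd, axis=1)
        mean_distance = np.zeros(bundle.node_count)
    else:
        raise ValueError(f"unknown skeleton method {method!r}")
    return MeanSkeleton(mean_points=mean_points, spread=spread,
                        mean_distance=mean_distance, method=method)


def remove_outliers(bundle: ProcessedBundle, skeleton: MeanSkeleton,
                    k: float = 3.0) -> tuple[ProcessedBundle, np.ndarray]:
    """Drop fibers straying more than k spreads from the mean skeleton.

    Single pass: the skeleton is NOT recomputed after removal.  A fiber is an
    outlier if at ANY node its distance to the node mean exceeds
    mean_distance + k * spread (spread floored at SPREAD_FLOOR mm).
    Returns the filtered bundle and the dropped fiber ids.
    """
    dists = np.linalg.norm(bundle.positions - skeleton.mean_points, axis=2)
    threshold = skeleton.mean_distance + k * np.maximum(skeleton.spread,
                                                        SPREAD_FLOOR)
    outlier = (dists > threshold).any(axis=1)
    if outlier.all():
        raise ValueError("outlier removal would drop every fiber")
    dropped = bundle.ids[outlier]
    filtered = ProcessedBundle(
        positions=bundle.positions[~outlier],
        ids=bundle.ids[~outlier],
        values={t: v[~outlier] for t, v in bundle.values.items()},
    )
    return filtered, dropped


def sample_metric(bundle: ProcessedBundle, volume: ScalarVolume,
                  timepoint: Any) -> ProcessedBundle:
    """Fill ``bundle.values[timepoint]`` with nearest-voxel metric values.

    Out-of-volume nodes get NaN; downstream cross-section statistics skip
    them at the affected nodes only.
    """
    flat = bundle.positions.reshape(-1, 3)
    vals = volume.sample_nearest(flat).reshape(bundle.n_fibers,
                                               bundle.node_count)
    bundle.values[timepoint] = vals
    return bundle


def process_bundle(raw: RawBundle, volumes: dict[Any, ScalarVolume],
                   c: int = 100, sd_k: float = 3.0, seed: int = 0,
                   skeleton_method: str = "distance") -> ProcessedBundle:
    """Run the full chain on a raw bundle and sample every time-point."""
    clustering = cluster_endpoints(raw, seed=seed)
    oriented = orient_and_filter(raw, clustering)
    resampled = resample_bundle(oriented, c=c)
    skeleton = compute_mean_skeleton(resampled, method=skeleton_method)
    filtered, _ = remove_outliers(resampled, skeleton, k=sd_k)
    for tp, vol in volumes.items():
        sample_metric(filtered, vol, tp)
    return filtered
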