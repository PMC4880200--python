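"""Scoring of detections against simulated ground truth.

Counting unit is the lesion-event: a planted lesion is a true positive when
at least one detected cross-section contains at least one changed-fiber
point whose nearest voxel lies inside the lesion; detected cross-sections
touching no lesion are grouped into maximal runs of consecutive nodes, each
run costing one false positive.  True negatives are nodes with neither a
detection nor lesion overlap.  An alternative node-level tally (every node
scored independently) is available via ``unit='node'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .bundle_processing import ProcessedBundle, process_bundle, sample_metric
from .change_detection import (LABEL_CHANGED, DetectionInterval,
                               detect_change, label_fibers,
                               mean_method_detect, mean_method_profile)
from .cross_section_model import select_components_nodes
from .bundle_io import ScalarVolume
from .lesion_simulation import PhantomSpec, ValidationCase, build_validation_set

__all__ = [
    "ConfusionCounts",
    "MetricRow",
    "classify_detections",
    "classify_mean_detections",
    "compute_metrics",
    "f_measure",
    "sweep",
    "run_validation_study",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricRow:
    zeta: float
    alpha: float
    sensitivity: float
    precision: float
    f_measure: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


def _node_voxel_labels(bundle: ProcessedBundle, volume: ScalarVolume,
                       mask: np.ndarray) -> np.ndarray:
    """(m, c) array of lesion labels (0 = none) at each fiber node."""
    idx = volume.nearest_voxel(bundle.positions.reshape(-1, 3))
    inside = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=1)
    labels = np.zeros(len(idx), dtype=np.int32)
    ii = idx[inside]
    labels[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    return labels.reshape(bundle.n_fibers, bundle.node_count)


def _run_fp_count(fp_nodes: np.ndarray) -> int:
    """Number of maximal runs of consecutive True entries."""
    padded = np.concatenate([[False], fp_nodes, [False]])
    return int((np.diff(padded.astype(int)) == 1).sum())


def classify_detections(intervals: Sequence[DetectionInterval],
                        labels: np.ndarray,
                        bundle: ProcessedBundle,
                        volume: ScalarVolume,
                        lesion_mask: np.ndarray,
                        n_lesions: int,
                        unit: str = "lesion") -> ConfusionCounts:
    """Score one detection run against the planted-lesion mask.

    ``labels`` is the (m, c) per-fiber/per-node label table; ``lesion_mask``
    labels lesion voxels with 1-based lesion ids; ``n_lesions`` is the
    number of planted lesions (ids 1..n_lesions).  Only lesions whose mask
    is actually traversed by the bundle enter tp + fn.
    """
    node_labels = _node_voxel_labels(bundle, volume, lesion_mask)
    detected = np.array([iv.feasible for iv in intervals])
    changed = labels == LABEL_CHANGED

    intersecting = np.unique(node_labels[node_labels > 0])
    hit_ids: set[int] = set()
    node_hits_lesion = np.zeros(len(intervals), dtype=bool)
    for i in np.nonzero(detected)[0]:
        ids_here = np.unique(node_labels[changed[:, i], i])
        ids_here = ids_here[ids_here > 0]
        if len(ids_here):
            node_hits_lesion[i] = True
            hit_ids.update(int(v) for v in ids_here)

    node_overlap = (node_labels > 0).any(axis=0)
    if unit == "lesion":
        tp = len(hit_ids)
        fn = len(intersecting) - tp
        fp = _run_fp_count(detected & ~node_hits_lesion)
        tn = int((~detected & ~node_overlap).sum())
    elif unit == "node":
        tp = int((detected & node_hits_lesion).sum())
        fp = int((detected & ~node_hits_lesion).sum())
        fn = int((~detected & node_overlap).sum())
        tn = int((~detected & ~node_overlap).sum())
    else:
        raise ValueError(f"unknown counting unit {unit!r}")
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def classify_mean_detections(detected_nodes: np.ndarray,
                             bundle: ProcessedBundle,
                             volume: ScalarVolume,
                             lesion_mask: np.ndarray) -> ConfusionCounts:
    """Lesion-event scoring for the mean-method baseline (no fiber labels:
    a lesion is hit when any flagged node overlaps its mask)."""
    node_labels = _node_voxel_labels(bundle, volume, lesion_mask)
    detected = np.zeros(bundle.node_count, dtype=bool)
    detected[np.asarray(detected_nodes, dtype=int)] = True
    node_overlap = (node_labels > 0).any(axis=0)
    hit_ids: set[int] = set()
    for i in np.nonzero(detected)[0]:
        ids_here = np.unique(node_labels[:, i])
        hit_ids.update(int(v) for v in ids_here if v > 0)
    intersecting = np.unique(node_labels[node_labels > 0])
    tp = len(hit_ids)
    fn = len(intersecting) - tp
    fp = _run_fp_count(detected & ~(detected & node_overlap))
    tn = int((~detected & ~node_overlap).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def f_measure(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision, in percent."""
    if np.isnan(sensitivity) or np.isnan(precision):
        return float("nan")
    if sensitivity + precision == 0:
        return 0.0
    return 2 * sensitivity * precision / (sensitivity + precision)


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, precision and F-Measure in percent.

    Undefined ratios (empty denominators) are NaN, never coerced to 0.
    """
    sens = (100.0 * counts.tp / (counts.tp + counts.fn)
            if counts.tp + counts.fn > 0 else float("nan"))
    prec = (100.0 * counts.tp / (counts.tp + counts.fp)
            if counts.tp + counts.fp > 0 else float("nan"))
    return {"sensitivity": sens, "precision": prec,
            "f_measure": f_measure(sens, prec)}


def _case_models(bundle: ProcessedBundle, n_max: int, seed: int,
                 selection: str, restarts: int,
                 ref_fits: dict | None = None
                 ) -> list[tuple[Any, Any] | None]:
    """Fit per-node mixture pairs once; detection can then be replayed for
    any number of zeta values without refitting.  ``ref_fits`` caches the
    baseline-side fits across follow-up cases sharing one baseline."""
    _, models_ref, models_new = select_components_nodes(
        bundle.values["ref"], bundle.values["new"], n_max=n_max, seed=seed,
        objective=selection, restarts=restarts, ref_fits=ref_fits)
    return [None if mr is None else (mr, mn)
            for mr, mn in zip(models_ref, models_new)]


def run_validation_study(cases: Sequence[ValidationCase],
                         zetas: Sequence[float], *,
                         beta_mode: str = "fixed_zero",
                         n_max: int = 5, selection: str = "bic",
                         margin_z: float = 1.645, pair_alpha: float = 0.01,
                         restarts: int = 5,
                         node_count: int = 100, sd_k: float = 3.0,
                         seed: int = 0, unit: str = "lesion",
                         ) -> tuple[dict[float, ConfusionCounts],
                                    ConfusionCounts]:
    """Run the full pipeline on each simulated case and tally detections.

    All cases are assumed to share one phantom geometry (as produced by
    :func:`~tractdelta.lesion_simulation.build_validation_set`), so the
    bundle is processed once.  Returns per-zeta histogram-method counts and
    the mean-method counts on the same runs.
    """
    first = cases[0]
    geometry = process_bundle(first.bundle, {}, c=node_count, sd_k=sd_k,
                              seed=seed)
    sample_metric(geometry, first.w1, "ref")
    ref_profile = mean_method_profile(geometry.values["ref"])

    hist_counts = {z: ConfusionCounts() for z in zetas}
    mean_counts = ConfusionCounts()
    ref_fits: dict = {}
    for case_idx, case in enumerate(cases):
        sample_metric(geometry, case.w2, "new")
        models = _case_models(geometry, n_max=n_max,
                              seed=(seed + 7919 * (case_idx + 1))
                              % (2**31 - 1),
                              selection=selection, restarts=restarts,
                              ref_fits=ref_fits)
        for zeta in zetas:
            intervals = []
            labels = np.full((geometry.n_fibers, geometry.node_count),
                             "unchanged", dtype=object)
            for i, pair in enumerate(models):
                if pair is None:
                    iv = DetectionInterval.infeasible(
                        zeta, note="insufficient samples")
                else:
                    iv = detect_change(pair[0], pair[1], zeta,
                                       beta_mode=beta_mode,
                                       margin_z=margin_z,
                                       pair_alpha=pair_alpha,
                                       samples=(geometry.values["ref"][:, i],
                                                geometry.values["new"][:, i]))
                intervals.append(iv)
                labels[:, i] = label_fibers(geometry.values["new"][:, i], iv)
            hist_counts[zeta] += classify_detections(
                intervals, labels, geometry, case.w2, case.mask,
                n_lesions=1, unit=unit)
        new_profile = mean_method_profile(geometry.values["new"])
        mean_counts += classify_mean_detections(
            mean_method_detect(ref_profile, new_profile), geometry, case.w2,
            case.mask)
    return hist_counts, mean_counts


def sweep(zetas: Sequence[float], alphas: Sequence[float],
          spec: PhantomSpec, n_lesions: int, seeds: Sequence[int],
          **study_kwargs: Any) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sensitivity / precision / F-Measure grid over (zeta, alpha).

    For each seed and alpha a validation set of ``n_lesions`` single-lesion
    follow-ups is simulated and the full pipeline is run with beta fixed at
    0; counts are pooled over seeds.  Returns the per-(zeta, alpha) table
    (F to 2 decimals) and the per-zeta average F-Measure used to pick the
    operating zeta.
    """
    pooled: dict[tuple[float, float], ConfusionCounts] = {
        (z, a): ConfusionCounts() for z in zetas for a in alphas}
    for seed in seeds:
        for alpha in alphas:
            case_spec = replace_seed(spec, seed)
            cases = build_validation_set(n_lesions, [alpha], case_spec,
                                         seed=seed)
            hist_counts, _ = run_validation_study(cases, zetas,
                                                  seed=seed, **study_kwargs)
            for z in zetas:
                pooled[(z, alpha)] += hist_counts[z]
    rows = []
    for (z, a), counts in pooled.items():
        metrics = compute_metrics(counts)
        rows.append(MetricRow(zeta=z, alpha=a,
                              sensitivity=round(metrics["sensitivity"], 2),
                              precision=round(metrics["precision"], 2),
                              f_measure=round(metrics["f_measure"], 2),
                              tp=counts.tp, fp=counts.fp, fn=counts.fn,
                              tn=counts.tn))
    table = pd.DataFrame([r.__dict__ for r in rows])
    per_zeta = (table.groupby("zeta")["f_measure"].mean().round(2)
                .reset_index().rename(columns={"f_measure": "avg_f_measure"}))
    return table, per_zeta


def replace_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    from dataclasses import replace as _replace
    return _replace(spec, seed=seed)
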