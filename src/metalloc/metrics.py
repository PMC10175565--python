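"""Benchmark protocol for metal-location predictions.

Matching is binary and clustered at a 5 A radius: a true site with any
prediction within the radius counts once as a true positive, a true
site with none is a false negative, and leftover predictions are
agglomeratively clustered at the same radius with each cluster counted
as a single false positive.  Spatial accuracy is summarized by the MAD
(mean Euclidean distance over *all* matched predictions, not only the
best per site), and voxel densities are compared with a discretized
Jaccard index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .sites import PredictedSite

__all__ = [
    "MatchResult",
    "EvaluationReport",
    "UndefinedMetricError",
    "match_predictions",
    "precision_recall",
    "mad_statistics",
    "discretized_jaccard",
    "evaluate",
]


class UndefinedMetricError(ValueError):
    """Raised when a statistic's denominator or sample is empty."""


def _positions(items) -> np.ndarray:
    if len(items) == 0:
        return np.zeros((0, 3))
    rows = []
    for item in items:
        if isinstance(item, PredictedSite):
            rows.append(item.position)
        elif hasattr(item, "position"):
            rows.append(np.asarray(item.position, dtype=float))
        else:
            rows.append(np.asarray(item, dtype=float))
    return np.asarray(rows, dtype=float).reshape(-1, 3)


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[np.ndarray, np.ndarray, float]] = field(default_factory=list)
    fp_cluster_centers: list[np.ndarray] = field(default_factory=list)


def match_predictions(predictions: Sequence, true_sites: Sequence,
                      radius: float = 5.0) -> MatchResult:
    """Clustered binary matching of predictions against true sites.

    Every prediction within ``radius`` of any true site is consumed as
    matched and contributes its distance to the *nearest* true site; a
    prediction near two sites credits both.  Unmatched predictions are
    clustered (average linkage, ``radius`` threshold) and each cluster
    is one false positive.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    preds = _positions(predictions)
    truths = _positions(true_sites)

    matched_pairs = []
    if len(preds) and len(truths):
        d = np.linalg.norm(preds[:, None, :] - truths[None, :, :], axis=2)
        pred_matched = (d <= radius).any(axis=1)
        site_found = (d <= radius).any(axis=0)
        for i in np.flatnonzero(pred_matched):
            j = int(np.argmin(d[i]))
            matched_pairs.append((preds[i], truths[j], float(d[i, j])))
    else:
        pred_matched = np.zeros(len(preds), dtype=bool)
        site_found = np.zeros(len(truths), dtype=bool)

    tp = int(site_found.sum())
    fn = int(len(truths) - tp)

    strays = preds[~pred_matched]
    fp_centers: list[np.ndarray] = []
    if len(strays) == 1:
        fp_centers = [strays[0]]
    elif len(strays) > 1:
        labels = AgglomerativeClustering(
            n_clusters=None, distance_threshold=radius, linkage="average",
        ).fit_predict(strays)
        fp_centers = [strays[labels == lab].mean(axis=0) for lab in np.unique(labels)]
    return MatchResult(tp=tp, fp=len(fp_centers), fn=fn,
                       matched_pairs=matched_pairs,
                       fp_cluster_centers=fp_centers)


def precision_recall(match: MatchResult) -> tuple[Optional[float], Optional[float]]:
    """(TP/(TP+FP), TP/(TP+FN)); ``None`` where the denominator is zero."""
    precision = match.tp / (match.tp + match.fp) if (match.tp + match.fp) else None
    recall = match.tp / (match.tp + match.fn) if (match.tp + match.fn) else None
    return precision, recall


def mad_statistics(predictions: Sequence, true_sites: Sequence,
                   radius: float = 5.0) -> tuple[float, float, float]:
    """(mean, population std, median) distance of all matched predictions."""
    match = match_predictions(predictions, true_sites, radius)
    if not match.matched_pairs:
        raise UndefinedMetricError("no prediction within radius of a true site")
    dists = np.array([d for _, _, d in match.matched_pairs])
    return float(dists.mean()), float(dists.std(ddof=0)), float(np.median(dists))


def _as_grid(grid) -> np.ndarray:
    values = getattr(grid, "values", grid)
    return np.squeeze(np.asarray(values, dtype=float))


def discretized_jaccard(predicted, true, threshold: float = 0.5,
                        trim_voxels: int = 0) -> float:
    """Intersection-over-union of two binarized voxel grids.

    Both grids are thresholded (strictly above) and the outer
    ``trim_voxels`` shells are zeroed in both, discarding spurious
    density at the box edges.  An empty union counts as perfect
    agreement (1.0).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    vp = _as_grid(predicted) > threshold
    vt = _as_grid(true) > threshold
    if vp.shape != vt.shape:
        raise ValueError(f"grid shapes differ: {vp.shape} vs {vt.shape}")
    if trim_voxels:
        core = np.zeros(vp.shape, dtype=bool)
        sl = tuple(slice(trim_voxels, s - trim_voxels) for s in vp.shape)
        core[sl] = True
        vp &= core
        vt &= core
    union = np.count_nonzero(vp | vt)
    if union == 0:
        return 1.0
    return np.count_nonzero(vp & vt) / union


@dataclass
class EvaluationReport:
    precision: Optional[float]
    recall: Optional[float]
    mad_mean: Optional[float]
    mad_std: Optional[float]
    mad_median: Optional[float]
    n_distances: int
    match: MatchResult

    def to_dict(self) -> dict:
        return {
            "tp": self.match.tp, "fp": self.match.fp, "fn": self.match.fn,
            "precision": self.precision, "recall": self.recall,
            "mad_mean": self.mad_mean, "mad_std": self.mad_std,
            "mad_median": self.mad_median, "n_distances": self.n_distances,
        }


def evaluate(predictions: Sequence, true_sites: Sequence,
             radius: float = 5.0) -> EvaluationReport:
    """Full report: counts, precision/recall, and MAD statistics."""
    match = match_predictions(predictions, true_sites, radius)
    precision, recall = precision_recall(match)
    if match.matched_pairs:
        dists = np.array([d for _, _, d in match.matched_pairs])
        mad = (float(dists.mean()), float(dists.std(ddof=0)), float(np.median(dists)))
    else:
        mad = (None, None, None)
    return EvaluationReport(precision=precision, recall=recall,
                            mad_mean=mad[0], mad_std=mad[1], mad_median=mad[2],
                            n_distances=len(match.matched_pairs), match=match)
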