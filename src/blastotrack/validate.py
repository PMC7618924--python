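"""Comparison of tracked results against generator ground truth."""

from __future__ import annotations

import numpy as np

from .core import LabelVolume
from .lineage import LineageForest


def match_labels(pred: LabelVolume, truth: LabelVolume, min_iou: float = 0.5
                 ) -> dict[int, int]:
    """Greedy IoU matching of predicted to truth instances (best IoU first)."""
    pairs = []
    for p in pred.ids():
        pm = pred.labels == p
        overl = np.bincount(truth.labels[pm].ravel())
        for t in np.nonzero(overl)[0]:
            if t == 0:
                continue
            inter = overl[t]
            union = pm.sum() + (truth.labels == t).sum() - inter
            iou = inter / union
            if iou >= min_iou:
                pairs.append((iou, int(p), int(t)))
    pairs.sort(reverse=True)
    mapping: dict[int, int] = {}
    used_t: set[int] = set()
    for iou, p, t in pairs:
        if p not in mapping and t not in used_t:
            mapping[p] = t
            used_t.add(t)
    return mapping


def edge_accuracy(pred: LineageForest, truth: LineageForest,
                  label_maps: list[dict[int, int]] | None = None) -> float:
    """Fraction of ground-truth parentage edges recovered by the tracker.

    ``label_maps`` (optional, per frame) translates predicted labels to
    truth ids before comparison; identity when omitted (e.g. when tracking
    rendered ground-truth label volumes).
    """
    truth_edges = truth.edge_set()
    if not truth_edges:
        return 1.0

    def translate(node):
        f, lab = node
        if label_maps is None:
            return node
        return (f, label_maps[f].get(lab, -1))

    pred_edges = {(translate(u), translate(v)) for u, v in pred.edge_set()}
    return len(truth_edges & pred_edges) / len(truth_edges)


def division_recall(pred: LineageForest, truth: LineageForest) -> float:
    """Fraction of truth division branch points found as divisions."""
    truth_div = set(truth.division_nodes())
    if not truth_div:
        return 1.0
    return len(truth_div & set(pred.division_nodes())) / len(truth_div)
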