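"""Temporal-receptive-window maps from per-condition significance masks.

A voxel's TRW label is the lowest-coherence condition in which its
inter-subject correlation is significant — the shortest temporal structure
that still evokes reliable responses. Voxels significant nowhere are labeled
"none". The map is purely a function of the masks; non-nested significance
patterns (significant at some level but not at a higher-coherence one) are
kept, labeled by the same shortest-significant rule, and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CONDITIONS, TruthMap


@dataclass(frozen=True)
class TrwMap:
    """Per-voxel TRW labels over a condition hierarchy.

    ``labels`` holds integer codes: index into ``hierarchy`` for labeled
    voxels, ``len(hierarchy)`` for "none". ``violation`` flags voxels whose
    significance pattern is not nested (a gap above the assigned label).
    """

    labels: np.ndarray
    hierarchy: tuple
    violation: np.ndarray

    NONE_LABEL = "none"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int16)
        violation = np.asarray(self.violation, dtype=bool)
        if labels.shape != violation.shape:
            raise ValueError("labels and violation flags must share a shape")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "violation", violation)

    @property
    def legend(self) -> tuple:
        return self.hierarchy + (self.NONE_LABEL,)

    def labels_flat(self) -> np.ndarray:
        return np.array(self.legend, dtype=object)[self.labels.ravel()]


def classify_trw(masks: dict, hierarchy: tuple = CONDITIONS) -> TrwMap:
    """Label each voxel by its shortest significantly reliable condition.

    Parameters
    ----------
    masks : dict
        Condition name -> boolean significance array; all same shape. The
        hierarchy must cover every mask key.
    hierarchy : tuple
        Conditions ordered by increasing coherence.

    Returns
    -------
    TrwMap
        The violation flag marks voxels non-significant in some condition
        above their label (e.g. significant for measures and sections but
        not phrases).
    """
    missing = set(masks) - set(hierarchy)
    if missing:
        raise ValueError(f"masks for conditions outside hierarchy: {sorted(missing)}")
    conds = [c for c in hierarchy if c in masks]
    if not conds:
        raise ValueError("no masks supplied")
    shapes = {np.asarray(masks[c]).shape for c in conds}
    if len(shapes) != 1:
        raise ValueError(f"masks have mismatched shapes: {shapes}")
    stack = np.stack([np.asarray(masks[c], dtype=bool) for c in conds])  # (C, ...)

    n_cond = len(conds)
    none_code = len(hierarchy)
    # first significant condition in coherence order; none_code if no hit
    first = np.where(stack.any(axis=0), np.argmax(stack, axis=0), n_cond)
    # any non-significant condition at or above the label
    n_sig_above = stack.sum(axis=0)
    expected_above = np.where(first < n_cond, n_cond - first, 0)
    violation = (first < n_cond) & (n_sig_above < expected_above)

    # map position among supplied conds back to hierarchy codes
    code_of = np.array([hierarchy.index(c) for c in conds] + [none_code])
    labels = code_of[first]
    return TrwMap(labels=labels, hierarchy=tuple(hierarchy), violation=violation)


def trw_summary(trw: TrwMap) -> dict:
    """Counts per label plus the nesting-violation count/rate."""
    counts = {
        name: int(np.sum(trw.labels == code)) for code, name in enumerate(trw.legend)
    }
    n = int(trw.labels.size)
    return {
        "counts": counts,
        "n_voxels": n,
        "n_violations": int(trw.violation.sum()),
        "violation_rate": float(trw.violation.sum() / n) if n else 0.0,
    }


def score_against_truth(trw: TrwMap, truth: TruthMap) -> dict:
    """Score a recovered TRW map against ground truth.

    Returns exact-label accuracy, adjacent accuracy (correct to within one
    hierarchy step; "none" matches only itself), and a per-label confusion
    matrix as a nested dict truth_label -> predicted_label -> count.
    """
    if trw.labels.shape != truth.shape:
        raise ValueError(
            f"grid mismatch: map {trw.labels.shape} vs truth {truth.shape}"
        )
    pred = trw.labels_flat()
    true = truth.labels_flat()
    legend = list(trw.legend)
    rank = {name: i for i, name in enumerate(trw.hierarchy)}

    exact = pred == true
    adjacent = exact.copy()
    both_level = np.array([p in rank and t in rank for p, t in zip(pred, true)])
    if both_level.any():
        pr = np.array([rank.get(p, -99) for p in pred])
        tr = np.array([rank.get(t, 99) for t in true])
        adjacent |= both_level & (np.abs(pr - tr) <= 1)

    confusion = {t: {p: 0 for p in legend} for t in legend}
    for t, p in zip(true, pred):
        confusion[t][p] += 1
    return {
        "accuracy": float(exact.mean()),
        "adjacent_accuracy": float(adjacent.mean()),
        "confusion": confusion,
        "n_voxels": int(pred.size),
    }
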