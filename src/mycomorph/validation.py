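"""Validation against generator ground truth: label matching and recall.

Used by the test-bench to score the pipeline on synthetic scenes where every
object's true mask is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MatchResult:
    """Per-truth-object match table plus summary rates."""

    table: pd.DataFrame  # truth_label, pred_label (0 = unmatched), overlap_frac, true_area_px, pred_area_px
    recall: float
    mean_area_error: float  # mean relative |pred - true| / true over matched objects


def match_labels(pred: np.ndarray, truth: np.ndarray, min_overlap: float = 0.5) -> MatchResult:
    """Match predicted labels to truth labels by >= ``min_overlap`` pixel overlap.

    A truth object is recovered when a single predicted label covers at least
    ``min_overlap`` of its pixels; the predicted object's full pixel count is
    then compared with the truth pixel count for the area error.
    """
    truth_ids = np.unique(truth)
    truth_ids = truth_ids[truth_ids > 0]
    rows = []
    pred_areas = {int(p): int((pred == p).sum()) for p in np.unique(pred) if p > 0}
    for t_id in truth_ids:
        t_mask = truth == t_id
        t_area = int(t_mask.sum())
        overlap_labels, counts = np.unique(pred[t_mask], return_counts=True)
        keep = overlap_labels > 0
        overlap_labels, counts = overlap_labels[keep], counts[keep]
        if overlap_labels.size:
            best = int(np.argmax(counts))
            frac = counts[best] / t_area
            p_id = int(overlap_labels[best])
        else:
            frac, p_id = 0.0, 0
        matched = frac >= min_overlap
        rows.append(
            {
                "truth_label": int(t_id),
                "pred_label": p_id if matched else 0,
                "overlap_frac": float(frac),
                "true_area_px": t_area,
                "pred_area_px": pred_areas.get(p_id, 0) if matched else 0,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return MatchResult(table, float("nan"), float("nan"))
    matched = table[table["pred_label"] > 0]
    recall = len(matched) / len(table)
    if len(matched):
        err = np.abs(matched["pred_area_px"] - matched["true_area_px"]) / matched["true_area_px"]
        mean_err = float(err.mean())
    else:
        mean_err = float("nan")
    return MatchResult(table, float(recall), mean_err)
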