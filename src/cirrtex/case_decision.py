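"""Majority-vote aggregation of ROI stage predictions into case stages.

A case contributes several ROIs per MR sequence, each classified
independently; the case-level stage for that sequence is decided by
vote.  When every ROI agrees, the case takes that stage outright; when
they disagree, the minority is subordinate to the majority.  The vote
rule is deliberately silent on ties in the source method, so the tie
policy here is explicit and documented: among count-tied stages the one
whose votes carry the smallest mean nearest-neighbor chi-square
distance wins (use the available confidence), and a residual tie falls
to the more severe stage (clinical conservatism: normal < early <
mid_advanced).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_textures import STAGES


@dataclass(frozen=True)
class CaseRecord:
    """One case-sequence decision with its supporting ROI votes."""

    case_id: str
    sequence_name: str
    roi_predictions: list[tuple[int, str, float]]  # (roi_index, stage, distance)
    final_stage: str

    def __post_init__(self) -> None:
        if not self.roi_predictions:
            raise ValueError("a case record needs at least one ROI prediction")
        stages_present = {s for _, s, _ in self.roi_predictions}
        if self.final_stage not in stages_present:
            raise ValueError(
                "final_stage must be one of the stages voted by the ROIs")


def decide_case(roi_predictions: Sequence[tuple[str, float]],
                severity_order: Sequence[str] = STAGES) -> str:
    """Vote over (stage, nearest-distance) ROI predictions.

    Unanimous -> that stage.  Otherwise the modal stage; a count tie is
    broken by the smallest mean chi-square distance among the tied
    stages, and a residual tie by the most severe stage.
    """
    if not roi_predictions:
        raise ValueError("cannot decide a case from an empty prediction list")
    counts = Counter(stage for stage, _ in roi_predictions)
    if len(counts) == 1:
        return next(iter(counts))
    top = max(counts.values())
    tied = [s for s, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    mean_dist = {
        s: float(np.mean([d for stage, d in roi_predictions if stage == s]))
        for s in tied}
    best = min(mean_dist.values())
    closest = [s for s in tied if mean_dist[s] == best]
    if len(closest) == 1:
        return closest[0]
    return max(closest, key=lambda s: severity_order.index(s))


def make_case_record(case_id: str, sequence_name: str,
                     roi_predictions: Sequence[tuple[str, float]]) -> CaseRecord:
    """Bundle ROI votes and the voted stage into a CaseRecord."""
    final = decide_case(roi_predictions)
    preds = [(i, s, d) for i, (s, d) in enumerate(roi_predictions)]
    return CaseRecord(case_id=case_id, sequence_name=sequence_name,
                      roi_predictions=preds, final_stage=final)


def decide_patient(case_records: Sequence[CaseRecord]) -> str:
    """Optional cross-sequence fusion: vote over the per-sequence stages.

    Off the main path — each sequence is normally evaluated on its own.
    """
    votes = [(rec.final_stage,
              float(np.mean([d for _, _, d in rec.roi_predictions])))
             for rec in case_records]
    return decide_case(votes)


def evaluate(predictions: Sequence[CaseRecord],
             truth: Mapping[str, str],
             stage_order: Sequence[str] = STAGES) -> pd.DataFrame:
    """Per-stage ROI and case accuracy table for one sequence's run.

    ROI accuracy of stage c = correctly classified ROIs / all ROIs
    among cases whose true stage is c; case accuracy likewise at the
    case level.  Accuracies are percentages.
    """
    roi_correct = Counter()
    roi_total = Counter()
    case_correct = Counter()
    case_total = Counter()
    for rec in predictions:
        if rec.case_id not in truth:
            raise ValueError(f"no ground-truth stage for case {rec.case_id!r}")
        true_stage = truth[rec.case_id]
        case_total[true_stage] += 1
        case_correct[true_stage] += int(rec.final_stage == true_stage)
        for _, pred_stage, _ in rec.roi_predictions:
            roi_total[true_stage] += 1
            roi_correct[true_stage] += int(pred_stage == true_stage)
    rows = []
    for stage in stage_order:
        rows.append({
            "stage": stage,
            "roi_accuracy": 100.0 * roi_correct[stage] / roi_total[stage]
            if roi_total[stage] else np.nan,
            "case_accuracy": 100.0 * case_correct[stage] / case_total[stage]
            if case_total[stage] else np.nan,
            "n_rois": roi_total[stage],
            "n_cases": case_total[stage],
        })
    return pd.DataFrame(rows).set_index("stage")
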