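"""Validation against manual / ground-truth annotations.

Automated cycles are matched one-to-one to annotation intervals by greedy
maximal temporal overlap (at least half of the shorter interval must
overlap). Unmatched annotation cycles count as predicted "none" (missed)
and unmatched automated cycles as true "none" (falsely detected), exactly
as in a video-validated confusion matrix. The threshold-sensitivity sweep
re-labels a fixed set of detected cycles over a grid of (T_G5, T_turn)
values; the peak-prominence threshold is deliberately excluded, since
changing it would change the set of detected cycles and invalidate the
matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig, Thresholds
from .containers import MERGED_LABELS, TrajectorySeries, merge_label
from .classifier import NNCModel, TimelineResult, classify_cycle, classify_timeline

EVAL_LABELS = tuple(MERGED_LABELS) + ("none",)


def _check_annotations(truth: pd.DataFrame) -> pd.DataFrame:
    required = {"t_start_s", "t_end_s", "label"}
    if not required.issubset(truth.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    truth = truth.sort_values("t_start_s", ignore_index=True)
    ends = truth["t_end_s"].to_numpy()
    starts = truth["t_start_s"].to_numpy()
    if np.any(ends <= starts):
        raise ValueError("annotations must have positive duration")
    if np.any(starts[1:] < ends[:-1] - 1e-9):
        raise ValueError("overlapping annotations in truth table")
    return truth


def match_cycles(auto: pd.DataFrame, truth: pd.DataFrame,
                 min_overlap: float = 0.5) -> List[Tuple[str, str]]:
    """(true_label, predicted_label) pairs from greedy overlap matching.

    ``auto`` and ``truth`` are interval tables with columns
    t_start_s, t_end_s, label; labels are merged (G2L -> G2) on the fly.
    The overlap fraction is relative to the shorter interval.
    """
    truth = _check_annotations(truth)
    auto = auto.sort_values("t_start_s", ignore_index=True)

    cand = []
    for i, (a0, a1) in enumerate(zip(auto["t_start_s"], auto["t_end_s"])):
        for j, (b0, b1) in enumerate(zip(truth["t_start_s"],
                                         truth["t_end_s"])):
            ov = max(0.0, min(a1, b1) - max(a0, b0))
            denom = min(a1 - a0, b1 - b0)
            if denom > 0 and ov / denom >= min_overlap:
                cand.append((ov, i, j))
    cand.sort(key=lambda c: (-c[0], c[2], c[1]))
    used_a: set = set()
    used_t: set = set()
    pairs: List[Tuple[str, str]] = []
    for ov, i, j in cand:
        if i in used_a or j in used_t:
            continue
        used_a.add(i)
        used_t.add(j)
        pairs.append((merge_label(str(truth["label"][j])),
                      merge_label(str(auto["label"][i]))))
    for j in range(len(truth)):
        if j not in used_t:
            pairs.append((merge_label(str(truth["label"][j])), "none"))
    for i in range(len(auto)):
        if i not in used_a:
            pairs.append(("none", merge_label(str(auto["label"][i]))))
    return pairs


@dataclass
class ConfusionMatrix:
    """Aligned automated-vs-manual counts including "none" rows/columns."""

    counts: pd.DataFrame      # rows = true, columns = predicted
    normalized: pd.DataFrame  # rows divided by row sums (NaN for empty rows)
    sensitivities: pd.Series  # diagonal of the normalized matrix

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def accuracy(self) -> float:
        """Fraction of pairs on the diagonal (correct classifications)."""
        return float(np.trace(self.counts.to_numpy()) / max(self.total, 1))

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.counts.index),
            "counts": self.counts.to_numpy().tolist(),
            "sensitivities": {k: (None if np.isnan(v) else float(v))
                              for k, v in self.sensitivities.items()},
        }


def confusion(pairs: Sequence[Tuple[str, str]],
              labels: Iterable[str] = EVAL_LABELS) -> ConfusionMatrix:
    """Confusion matrix over (true, predicted) label pairs."""
    if not pairs:
        raise ValueError("no pairs to tabulate")
    labels = list(labels)
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for true, pred in pairs:
        if true not in labels or pred not in labels:
            raise ValueError(f"label pair ({true!r}, {pred!r}) outside "
                             f"{labels}")
        counts.loc[true, pred] += 1
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = counts.div(row_sums.replace(0, np.nan), axis=0)
    sens = pd.Series(np.diag(normalized), index=labels)
    return ConfusionMatrix(counts=counts, normalized=normalized,
                           sensitivities=sens)


def relabel_records(result: TimelineResult, thr: Thresholds,
                    model: Optional[NNCModel]) -> pd.DataFrame:
    """Re-run only the per-cycle decision rules on an existing detection."""
    rows = []
    for rec, feat in zip(result.records, result.features):
        rows.append({
            "t_start_s": rec.t_start, "t_end_s": rec.t_end,
            "label": classify_cycle(rec, feat, thr, model),
        })
    return pd.DataFrame(rows, columns=["t_start_s", "t_end_s", "label"])


def threshold_sweep(traj: TrajectorySeries, truth: pd.DataFrame,
                    model: Optional[NNCModel],
                    grid_g5: Sequence[float], grid_turn: Sequence[float],
                    config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Classification accuracy over a (T_G5, T_turn) grid.

    Cycle detection runs once; only the hard rules and NNC routing are
    re-evaluated per grid point. Returns a tidy frame with columns
    t_g5, t_turn, accuracy.
    """
    if not len(grid_g5) or not len(grid_turn):
        raise ValueError("threshold grids must be nonempty")
    cfg = config or PipelineConfig()
    result = classify_timeline(traj, model, cfg)
    return sweep_from_result(result, truth, model, grid_g5, grid_turn, cfg)


def sweep_from_result(result: TimelineResult, truth: pd.DataFrame,
                      model: Optional[NNCModel],
                      grid_g5: Sequence[float], grid_turn: Sequence[float],
                      config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    cfg = config or PipelineConfig()
    rows = []
    for tg5 in grid_g5:
        for tturn in grid_turn:
            thr = Thresholds(t_tuck=cfg.thresholds.t_tuck, t_g5=float(tg5),
                             t_turn=float(tturn))
            auto = relabel_records(result, thr, model)
            cm = confusion(match_cycles(auto, truth,
                                        min_overlap=cfg.min_overlap))
            rows.append({"t_g5": float(tg5), "t_turn": float(tturn),
                         "accuracy": cm.accuracy()})
    return pd.DataFrame(rows, columns=["t_g5", "t_turn", "accuracy"])


__all__ = ["EVAL_LABELS", "match_cycles", "ConfusionMatrix", "confusion",
           "relabel_records", "threshold_sweep", "sweep_from_result"]
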