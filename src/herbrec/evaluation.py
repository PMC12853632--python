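"""Micro-averaged top-K ranking metrics for multi-label prescriptions.

Precision@K and Recall@K pool hits over all test samples before dividing
(micro averaging): P = sum_i |R(i) ∩ T(i)| / sum_i |R(i)| and
R = sum_i |R(i) ∩ T(i)| / sum_i |T(i)|, with F1 the harmonic mean of the
pooled P and R.  Predicted lists shorter than K are allowed; the precision
denominator uses the actual list sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

__all__ = ["TopKReport", "topk_metrics", "f1_from_pr", "relative_improvement",
           "write_reports"]


@dataclass(frozen=True)
class TopKReport:
    K: int
    precision: float
    recall: float
    f1: float
    n_samples: int


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def topk_metrics(
    predicted: Sequence[Sequence[str]],
    truth: Sequence[Sequence[str]],
    K: int,
) -> TopKReport:
    """Pooled-sum precision/recall/F1 at K over all samples."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal lengths")
    if len(predicted) == 0:
        raise ValueError("at least one sample is required")
    hits = pred_total = truth_total = 0
    for i, (r, t) in enumerate(zip(predicted, truth)):
        r_set, t_set = set(r), set(t)
        if len(r_set) > K:
            raise ValueError(f"sample {i}: predicted set larger than K={K}")
        if not t_set:
            raise ValueError(f"sample {i}: empty truth set (recall undefined)")
        hits += len(r_set & t_set)
        pred_total += len(r_set)
        truth_total += len(t_set)
    precision = hits / pred_total if pred_total else 0.0
    recall = hits / truth_total
    return TopKReport(K=K, precision=precision, recall=recall,
                      f1=f1_from_pr(precision, recall), n_samples=len(predicted))


def relative_improvement(candidate: float, reference: float) -> float:
    """Percent change of candidate over reference: 100 (c - r) / r."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (candidate - reference) / reference


def write_reports(reports: Sequence[TopKReport], directory: str | Path,
                  model_name: str = "model", stem: str = "topk") -> dict[str, Path]:
    """TSV (model, K, P, R, F1) plus a JSON twin."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tsv = directory / f"{stem}.tsv"
    with open(tsv, "w", encoding="utf-8") as fh:
        fh.write("model\tK\tprecision\trecall\tf1\n")
        for rep in reports:
            fh.write(f"{model_name}\t{rep.K}\t{rep.precision:.6f}\t{rep.recall:.6f}\t{rep.f1:.6f}\n")
    js = directory / f"{stem}.json"
    js.write_text(json.dumps([{"model": model_name, **asdict(r)} for r in reports], indent=1),
                  encoding="utf-8")
    return {"tsv": tsv, "json": js}
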