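"""Scoring of predicted profiles against gold standards.

SGB-level detection is scored with set-based TP/FP/FN (a predicted SGB
containing — or overlapping — a community genome is a true positive),
quantification with Bray-Curtis dissimilarity and RMSE over the union of
SGBs after normalising both profiles to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


def _as_abundances(obj) -> dict[str, float]:
    if isinstance(obj, Mapping):
        return dict(obj)
    if hasattr(obj, "sgb_abundances"):  # TaxonomicProfile
        return obj.sgb_abundances()
    if hasattr(obj, "sgb_abundance"):  # GoldStandard
        return dict(obj.sgb_abundance)
    raise TypeError(f"cannot interpret {type(obj)} as SGB abundances")


def confusion_counts(
    predicted,
    gold,
    overlaps: Mapping[str, set[str]] | None = None,
) -> ConfusionCounts:
    """SGB-level TP/FP/FN.

    tp: predicted SGBs containing a community genome (or overlapping one via
    the ``overlaps`` map); fp: predicted SGBs with no community genome;
    fn: gold SGBs not predicted.
    """
    pred = set(_as_abundances(predicted))
    gold_sgbs = set(_as_abundances(gold))
    overlaps = overlaps or {}
    tp = fp = 0
    matched: set[str] = set()
    for p in pred:
        targets = {p} | set(overlaps.get(p, ()))
        hit = targets & gold_sgbs
        if hit:
            tp += 1
            matched |= hit
        else:
            fp += 1
    fn = len(gold_sgbs - matched)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def profile_metrics(
    counts: ConfusionCounts,
    predicted,
    gold,
) -> dict[str, float]:
    """Precision, recall, F1, Bray-Curtis and RMSE for one sample.

    F1 = 2PR/(P+R) (0 when P+R=0); BC = sum|p-g| / sum(p+g); RMSE over the
    union of SGBs with both profiles normalised to 1 (absent = 0).
    """
    p_den = counts.tp + counts.fp
    r_den = counts.tp + counts.fn
    precision = counts.tp / p_den if p_den else 0.0
    recall = counts.tp / r_den if r_den else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )

    pred = _as_abundances(predicted)
    gld = _as_abundances(gold)
    ps = sum(pred.values())
    gs = sum(gld.values())
    union = sorted(set(pred) | set(gld))
    p = [pred.get(k, 0.0) / ps if ps else 0.0 for k in union]
    g = [gld.get(k, 0.0) / gs if gs else 0.0 for k in union]
    num = sum(abs(a - b) for a, b in zip(p, g))
    den = sum(a + b for a, b in zip(p, g))
    bc = num / den if den else 0.0
    rmse = (
        math.sqrt(sum((a - b) ** 2 for a, b in zip(p, g)) / len(union))
        if union
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "bray_curtis": bc,
        "rmse": rmse,
    }


def metrics_table(per_sample: list[dict[str, float]]) -> pd.DataFrame:
    """Stack per-sample metric dicts into a DataFrame with a mean row handy."""
    return pd.DataFrame(per_sample)
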