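"""Confidence/accuracy statistics for fold-confidence-guided model selection.

Ranking confidence (RC) is the weighted predicted-TM-score combination
``0.8*iptm + 0.2*ptm``. A prediction counts as a *success* when its accuracy
score (MMscore from structural alignment to the reference, consumed here as
an input) exceeds 0.75 AND its RC exceeds 0.8; a *hidden failure* is a
high-confidence model (RC > 0.8) that is nevertheless inaccurate. Both
thresholds are strict inequalities and configurable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

MM_THRESHOLD = 0.75
RC_THRESHOLD = 0.8

#: Number of predictions per target drawn by the noise-injection sampling
#: protocol this method is benchmarked against, vs. the default 100-step
#: gradient budget here — the source of the >= 60-fold speedup.
AFSAMPLE_N_SAMPLES = 6000
DEFAULT_MAX_ITERS = 100


class Outcome(str, Enum):
    SUCCESS = "success"
    HIDDEN_FAILURE = "hidden_failure"
    MISSED_SUCCESS = "missed_success"
    TRUE_NEGATIVE = "true_negative"


@dataclass
class TargetResult:
    """Per-target accuracy before/after optimization plus the selection score."""

    target_id: str
    mmscore_initial: float
    mmscore_final: float
    ranking_confidence: float
    msa_depth: int | None = None

    def __post_init__(self) -> None:
        for name in ("mmscore_initial", "mmscore_final", "ranking_confidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.msa_depth is not None and self.msa_depth < 1:
            raise ValueError("msa_depth must be >= 1")

    @property
    def delta_mmscore(self) -> float:
        return self.mmscore_final - self.mmscore_initial


def ranking_confidence(iptm: float, ptm: float) -> float:
    """RC = 0.8*iptm + 0.2*ptm; both inputs must lie in [0, 1]."""
    if not (0.0 <= iptm <= 1.0 and 0.0 <= ptm <= 1.0):
        raise ValueError("iptm and ptm must lie in [0, 1]")
    return 0.8 * iptm + 0.2 * ptm


def classify_outcome(
    mmscore: float,
    rc: float,
    mm_thr: float = MM_THRESHOLD,
    rc_thr: float = RC_THRESHOLD,
) -> Outcome:
    """Partition the (accuracy, confidence) unit square into four outcomes.

    Thresholds are strict: a model sitting exactly at mm_thr or rc_thr does
    not clear that threshold.
    """
    if not (0.0 <= mmscore <= 1.0 and 0.0 <= rc <= 1.0):
        raise ValueError("mmscore and rc must lie in [0, 1]")
    accurate = mmscore > mm_thr
    confident = rc > rc_thr
    if accurate and confident:
        return Outcome.SUCCESS
    if confident:
        return Outcome.HIDDEN_FAILURE
    if accurate:
        return Outcome.MISSED_SUCCESS
    return Outcome.TRUE_NEGATIVE


def success_rate(
    results: list[TargetResult],
    mm_thr: float = MM_THRESHOLD,
    rc_thr: float = RC_THRESHOLD,
) -> float:
    """Fraction of targets whose selected model is both accurate and confident."""
    if not results:
        raise ValueError("success_rate of an empty result list is undefined")
    n = sum(
        classify_outcome(r.mmscore_final, r.ranking_confidence, mm_thr, rc_thr)
        is Outcome.SUCCESS
        for r in results
    )
    return n / len(results)


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (average ties). NaN if either input is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve of ``scores`` as a selector for ``labels``.

    Equals the Mann-Whitney concordance probability
    P(score+ > score-) + 0.5*P(tie).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def running_mean(x, y, step: float) -> list[tuple[float, float]]:
    """Mean of ``y`` within consecutive half-open bins ``[k*step, (k+1)*step)``
    over ``x``; empty bins are omitted. Returns (bin_center, mean) pairs."""
    if step <= 0:
        raise ValueError("step must be positive")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    k = np.floor(x / step).astype(np.int64)
    out = []
    for kk in np.unique(k):
        out.append((float((kk + 0.5) * step), float(y[k == kk].mean())))
    return out


def load_scores(path) -> list[TargetResult]:
    """Read a per-target score table (TSV).

    Required columns: target_id, mmscore_initial, mmscore_final and either
    ranking_confidence or the pair (iptm, ptm); optional msa_depth.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"target_id", "mmscore_initial", "mmscore_final"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scores table missing columns: {sorted(missing)}")
    if "ranking_confidence" not in df.columns:
        if not {"iptm", "ptm"} <= set(df.columns):
            raise ValueError("need ranking_confidence or iptm+ptm columns")
        df["ranking_confidence"] = [
            ranking_confidence(i, p) for i, p in zip(df["iptm"], df["ptm"])
        ]
    results = []
    for row in df.itertuples():
        depth = getattr(row, "msa_depth", None)
        results.append(
            TargetResult(
                target_id=str(row.target_id),
                mmscore_initial=float(row.mmscore_initial),
                mmscore_final=float(row.mmscore_final),
                ranking_confidence=float(row.ranking_confidence),
                msa_depth=None if depth is None or pd.isna(depth) else int(depth),
            )
        )
    return results


def evaluate_results(
    results: list[TargetResult],
    mm_thr: float = MM_THRESHOLD,
    rc_thr: float = RC_THRESHOLD,
    rc_step: float = 0.05,
) -> dict:
    """Full selection report: outcome counts, success rate, ROC-AUC of RC as
    an accuracy selector, Spearman(RC, final MMscore), delta-MMscore summary
    and the RC-binned running mean of final MMscore."""
    if not results:
        raise ValueError("no results to evaluate")
    counts = {o.value: 0 for o in Outcome}
    for r in results:
        counts[classify_outcome(r.mmscore_final, r.ranking_confidence, mm_thr, rc_thr).value] += 1
    rc = [r.ranking_confidence for r in results]
    mm = [r.mmscore_final for r in results]
    accurate = [int(r.mmscore_final > mm_thr) for r in results]
    report = {
        "n_targets": len(results),
        "success_rate": success_rate(results, mm_thr, rc_thr),
        "counts": counts,
        "spearman_rc_mmscore": spearman_correlation(rc, mm),
        "mean_delta_mmscore": float(np.mean([r.delta_mmscore for r in results])),
        "median_mmscore_final": float(np.median(mm)),
        "running_mean_rc_mmscore": running_mean(rc, mm, rc_step),
    }
    if len(set(accurate)) == 2:
        report["roc_auc_rc"] = roc_auc(rc, accurate)
    else:
        report["roc_auc_rc"] = None
    return report


def write_report(report: dict, path) -> None:
    def _clean(v):
        if isinstance(v, float) and math.isnan(v):
            return None
        return v

    with open(path, "w") as fh:
        json.dump({k: _clean(v) for k, v in report.items()}, fh, indent=2)
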