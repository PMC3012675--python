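"""Scoring of structure and concentration recovery on simulated data.

Structure prediction is scored cell-by-cell against the true binary matrix
(after transcript-column matching): true/false positives and negatives over
all probe × transcript cells give

* Hamming distance   HD = (FP + FN) / N,
* sensitivity        SN = TP / (TP + FN),
* specificity        SP = TN / (TN + FP).

Sweeping the binarization threshold over the continuous structure produces a
pooled ROC across genes; two scalar summaries are used: the threshold
minimizing pooled HD, and the crossing point where pooled SN equals pooled SP
(the operating point at which spurious inclusion and exclusion of a probe are
equally unreliable).

Rank estimation is scored as splicing-call rates: the false positive rate is
the fraction of single-transcript genes called alternatively spliced, the
false negative rate the fraction of multi-transcript genes called single.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import ValidationError

DEFAULT_THRESHOLDS = np.round(np.arange(0.05, 1.0, 0.05), 10)


@dataclass
class StructureMetrics:
    TP: int
    TN: int
    FP: int
    FN: int
    HD: float
    SN: float | None
    SP: float | None
    threshold: float | None = None


def confusion_counts(G_true, G_pred):
    """Entrywise (TP, TN, FP, FN) between matched binary structures."""
    A = np.asarray(G_true, dtype=float)
    B = np.asarray(G_pred, dtype=float)
    if A.shape != B.shape:
        raise ValidationError(f"shape mismatch after matching: {A.shape} vs {B.shape}")
    tp = int(np.sum((A == 1) & (B == 1)))
    tn = int(np.sum((A == 0) & (B == 0)))
    fp = int(np.sum((A == 0) & (B == 1)))
    fn = int(np.sum((A == 1) & (B == 0)))
    return tp, tn, fp, fn


def structure_metrics(counts, threshold: float | None = None) -> StructureMetrics:
    """HD/SN/SP from confusion counts; SN or SP is None when undefined."""
    tp, tn, fp, fn = counts
    n = tp + tn + fp + fn
    if n == 0:
        raise ValidationError("no cells to compare")
    hd = (fp + fn) / n
    sn = tp / (tp + fn) if (tp + fn) > 0 else None
    sp = tn / (tn + fp) if (tn + fp) > 0 else None
    return StructureMetrics(tp, tn, fp, fn, hd, sn, sp, threshold)


def pooled_roc(pairs, thresholds=DEFAULT_THRESHOLDS):
    """Pooled per-threshold metrics over matched (G_true, G_tilde) pairs.

    Counts are summed over all genes at each threshold, then converted to
    SN/SP/HD.  Returns a list of :class:`StructureMetrics`, one per threshold
    in increasing order.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    counts = np.zeros((len(thresholds), 4), dtype=np.int64)
    for G_true, G_cont in pairs:
        A = np.asarray(G_true, dtype=float)
        C = np.asarray(G_cont, dtype=float)
        if A.shape != C.shape:
            raise ValidationError("pair shapes differ; match columns first")
        for i, th in enumerate(thresholds):
            B = (C > th).astype(float)
            counts[i] += confusion_counts(A, B)
    return [structure_metrics(tuple(c), threshold=th) for c, th in zip(counts, thresholds)]


def _monotone_sn_sp(curve):
    th = np.array([m.threshold for m in curve])
    sn = np.array([m.SN if m.SN is not None else np.nan for m in curve])
    sp = np.array([m.SP if m.SP is not None else np.nan for m in curve])
    # isotonic cleanup: SN non-increasing, SP non-decreasing in threshold
    sn = np.minimum.accumulate(sn)
    sp = np.maximum.accumulate(sp)
    return th, sn, sp


def crossing_point(curve):
    """Threshold (and common value) where pooled SN equals pooled SP.

    Linear interpolation between grid points after an isotonic cleanup.  If
    the curves never cross inside the grid, the nearest boundary point is
    returned with a warning; if they coincide everywhere, the grid midpoint
    is returned.
    """
    th, sn, sp = _monotone_sn_sp(curve)
    diff = sn - sp
    if np.allclose(diff, 0.0):
        mid = len(th) // 2
        warnings.warn("SN and SP coincide on the whole grid; returning midpoint")
        return float(th[mid]), float(sn[mid])
    sign = np.sign(diff)
    crossings = np.nonzero(np.diff(sign < 0))[0]
    if len(crossings) == 0:
        idx = 0 if diff[0] < 0 else len(th) - 1
        warnings.warn("SN and SP do not cross inside the threshold grid")
        return float(th[idx]), float((sn[idx] + sp[idx]) / 2)
    i = crossings[0]
    if diff[i] == 0:
        return float(th[i]), float(sn[i])
    w = diff[i] / (diff[i] - diff[i + 1])
    th_star = th[i] + w * (th[i + 1] - th[i])
    value = sn[i] + w * (sn[i + 1] - sn[i])
    return float(th_star), float(value)


def hamming_optimal_threshold(curve):
    """Grid threshold minimizing pooled Hamming distance; ``(th, HD)``."""
    hds = np.array([m.HD for m in curve])
    i = int(np.argmin(hds))
    return float(curve[i].threshold), float(hds[i])


def splicing_call_rates(true_k, est_k):
    """(FPR, FNR) of the alternative-splicing call from rank estimates.

    FPR: fraction of single-transcript genes predicted to have several
    transcripts.  FNR: fraction of multi-transcript genes predicted to have a
    single transcript.  A rate is None when its gene class is empty.
    """
    t = np.asarray(true_k, dtype=float)
    e = np.asarray(est_k, dtype=float)
    if t.shape != e.shape:
        raise ValidationError("true_k and est_k must be paired vectors")
    singles = t == 1
    multis = t > 1
    fpr = float(np.mean(e[singles] > 1)) if singles.any() else None
    fnr = float(np.mean(e[multis] == 1)) if multis.any() else None
    return fpr, fnr


def concentration_mae(T_true, T_est, scale: str | None = "lstsq") -> float:
    """Mean absolute concentration error as a percentage of the truth's mean.

    Because estimated concentrations are in relative units, ``T_est`` is first
    rescaled by the least-squares scalar ``s = <T_true, T_est>/<T_est, T_est>``
    (pass ``scale=None`` to skip the alignment).

    ``MAE% = 100 · mean(|T_true − s·T_est|) / mean(T_true)``
    """
    A = np.asarray(T_true, dtype=float)
    B = np.asarray(T_est, dtype=float)
    if A.shape != B.shape:
        raise ValidationError("concentration matrices must be matched in shape")
    denom = A.mean()
    if denom <= 0:
        raise ValidationError("true concentrations have non-positive mean")
    if scale == "lstsq":
        bb = float(np.sum(B * B))
        s = float(np.sum(A * B)) / bb if bb > 0 else 1.0
        s = max(s, 0.0)
    elif scale is None:
        s = 1.0
    else:
        raise ValidationError(f"unknown scale mode: {scale!r}")
    return float(100.0 * np.mean(np.abs(A - s * B)) / denom)
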