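"""Method-evaluation harness: read subsampling, prediction-to-reference
matching, and ROC/AUC truncated at a specificity of 0.8.

Sensitivity without reasonable specificity is of little value for a
nucleosome caller, so ROC curves are cut at specificity 0.8: the maximum
attainable truncated AUC is 0.2 and chance performance is 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import StrandedReadSet


def subsample_reads(reads: StrandedReadSet, fraction: float,
                    seed: int | None = None) -> StrandedReadSet:
    """Simple random sample (without replacement) of ``floor(fraction * n)``
    reads, drawn jointly from the pooled forward+reverse list so strand
    proportions are random. Deterministic given ``seed``."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = reads.n_total
    k = int(np.floor(fraction * n))
    if k >= n:
        return reads
    rng = np.random.default_rng(seed)
    pick = rng.choice(n, size=k, replace=False)
    fwd_mask = pick < reads.n_fwd
    fwd = reads.fwd[pick[fwd_mask]]
    rev = reads.rev[pick[~fwd_mask] - reads.n_fwd]
    return StrandedReadSet(reads.chrom, fwd, rev)


@dataclass
class MatchResult:
    """Outcome of matching scored predictions to reference centres."""

    detected: np.ndarray  #: per-reference: some prediction within dist
    is_tp: np.ndarray  #: per-prediction: greedily matched one-to-one
    match_of: np.ndarray  #: per-prediction: matched reference index or -1

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())


def match_to_reference(pred_centers, ref_centers, dist: float) -> MatchResult:
    """Match predictions to reference nucleosomes within ``dist`` bp.

    A reference is *detected* if any prediction lies within ``dist`` of it.
    Prediction labels are one-to-one: candidate pairs are sorted by
    increasing distance (ties broken by leftmost reference, then leftmost
    prediction) and assigned greedily, so one prediction cannot claim
    several references; unmatched predictions are false positives.
    """
    if dist <= 0:
        raise ValueError("dist must be positive")
    preds = np.asarray(pred_centers, dtype=float)
    refs = np.asarray(ref_centers, dtype=float)
    detected = np.zeros(refs.size, dtype=bool)
    is_tp = np.zeros(preds.size, dtype=bool)
    match_of = np.full(preds.size, -1, dtype=int)
    if preds.size == 0 or refs.size == 0:
        return MatchResult(detected, is_tp, match_of)
    order_r = np.argsort(refs, kind="stable")
    refs_sorted = refs[order_r]
    pairs = []
    for pi, p in enumerate(preds):
        lo = np.searchsorted(refs_sorted, p - dist, side="left")
        hi = np.searchsorted(refs_sorted, p + dist, side="right")
        for rj in order_r[lo:hi]:
            d = abs(p - refs[rj])
            if d <= dist:
                detected[rj] = True
                pairs.append((d, refs[rj], p, rj, pi))
    pairs.sort()
    used_ref = np.zeros(refs.size, dtype=bool)
    used_pred = np.zeros(preds.size, dtype=bool)
    for d, _r, _p, rj, pi in pairs:
        if used_ref[rj] or used_pred[pi]:
            continue
        used_ref[rj] = used_pred[pi] = True
        is_tp[pi] = True
        match_of[pi] = rj
    return MatchResult(detected, is_tp, match_of)


def truncated_roc_auc(scores, labels, spec_min: float = 0.8) -> float:
    """Area under the ROC curve for 1 - specificity in [0, 1 - spec_min].

    Thresholds sweep from high to low score (tied scores move together);
    the curve is linearly interpolated at the truncation point and
    integrated by the trapezoid rule. A perfect ranking attains
    ``1 - spec_min`` exactly; a reversed ranking attains 0.
    """
    if not (0.0 < spec_min < 1.0):
        raise ValueError("spec_min must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # collapse tied scores into single threshold steps
    distinct = np.r_[np.diff(s) != 0, True]
    cum_tp = np.cumsum(y)[distinct]
    cum_fp = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    fpr_max = 1.0 - spec_min
    if fpr[-1] <= fpr_max:
        return float(np.trapezoid(tpr, fpr))
    # linear interpolation at the truncation point
    idx = int(np.searchsorted(fpr, fpr_max, side="right"))
    f0, f1 = fpr[idx - 1], fpr[idx]
    t0, t1 = tpr[idx - 1], tpr[idx]
    t_cut = t0 if f1 == f0 else t0 + (t1 - t0) * (fpr_max - f0) / (f1 - f0)
    fpr_t = np.r_[fpr[:idx], fpr_max]
    tpr_t = np.r_[tpr[:idx], t_cut]
    return float(np.trapezoid(tpr_t, fpr_t))


def evaluation_report(pred_centers, pred_scores, ref_centers, dist: float,
                      spec_min: float = 0.8) -> dict:
    """Match predictions to references and summarize detection + truncated AUC."""
    match = match_to_reference(pred_centers, ref_centers, dist)
    report = {
        "n_ref": int(np.asarray(ref_centers).size),
        "n_pred": int(np.asarray(pred_centers).size),
        "detected": match.n_detected,
        "detection_rate": (match.n_detected / max(1, np.asarray(ref_centers).size)),
    }
    labels = match.is_tp
    if labels.any() and (~labels).any():
        report["auc"] = truncated_roc_auc(np.asarray(pred_scores, dtype=float),
                                          labels, spec_min)
    else:
        report["auc"] = None
    return report
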