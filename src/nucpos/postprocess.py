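"""Scoring and filtering of nucleosome calls.

A call's enrichment score is its core read count divided by its total peak
width (reads/bp): reads are counted inside the two-sided 90% contour of each
strand's fitted t(4) read-position density, which trims outlier reads before
density is measured. With a control sample the same contours yield a
depth-normalized relative score and an empirical FDR. Finally, calls whose
read count is significantly lower than any neighbouring call's — under a
negative binomial that accounts for the two calls' peak widths — are removed
as likely false positives.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import nbinom
from scipy.stats import t as t_dist

from .config import Config
from .types import CORE_BP, NucleosomePrediction, StrandedReadSet


def core_interval(center: float, sd: float, q: float) -> tuple[float, float]:
    """The two-sided ``q`` contour of a t(4) read-position density:
    ``center +/- t4_quantile((1+q)/2) * sd``."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    mult = t_dist.ppf((1.0 + q) / 2.0, df=4)
    return center - mult * sd, center + mult * sd


def _count_interval(pos: np.ndarray, lo: float, hi: float) -> int:
    return int(np.searchsorted(pos, hi, side="right")
               - np.searchsorted(pos, lo, side="left"))


def count_core_reads(pred: NucleosomePrediction, fwd: np.ndarray,
                     rev: np.ndarray, q: float = 0.90) -> tuple[int, int]:
    """Count forward/reverse reads inside the ``q`` contours around the
    fitted strand centres ``mu -/+ delta/2``."""
    lo_f, hi_f = core_interval(pred.mu - pred.delta / 2.0, pred.sigma_f, q)
    lo_r, hi_r = core_interval(pred.mu + pred.delta / 2.0, pred.sigma_r, q)
    return (_count_interval(np.asarray(fwd), lo_f, hi_f),
            _count_interval(np.asarray(rev), lo_r, hi_r))


def score(pred: NucleosomePrediction) -> float:
    """Width-normalized enrichment score ``(n_f + n_r) / (sigma_f + sigma_r)``
    in reads/bp."""
    return (pred.n_f + pred.n_r) / (pred.sigma_f + pred.sigma_r)


def score_relative(pred: NucleosomePrediction, control: StrandedReadSet,
                   n_chip: int, n_ctrl: int, q: float = 0.90) -> float:
    """Depth-normalized enrichment relative to a control sample.

    Control reads are counted in the *same* contours derived from the ChIP
    fit; the +1 in the denominator guards against empty control intervals:
    ``[(n_f + n_r) / (n_f^c + n_r^c + 1)] * (N_ctrl / N_chip)``.
    """
    if n_chip <= 0:
        raise ValueError("ChIP sample must contain reads")
    nc_f, nc_r = count_core_reads(pred, control.fwd, control.rev, q)
    return (pred.n_f + pred.n_r) / (nc_f + nc_r + 1.0) * (n_ctrl / n_chip)


def estimate_fdr(chip_scores, ctrl_scores, n_chip: int, n_ctrl: int):
    """Empirical FDR at each ChIP call's score.

    ``FDR(s) = min(1, [#{ctrl >= s} / #{chip >= s}] * (N_chip / N_ctrl))``,
    made monotone nonincreasing in ``s`` by a cumulative minimum over
    thresholds up to ``s`` (a call keeps the best FDR of any threshold that
    still includes it).

    Returns ``(per_call_fdr, thresholds, fdr_at_threshold)``: the per-call
    values aligned with ``chip_scores`` plus the full score -> FDR table at
    the unique attained scores (ascending).
    """
    chip = np.asarray(chip_scores, dtype=float)
    if chip.size == 0:
        raise ValueError("need at least one ChIP score")
    ctrl = np.sort(np.asarray(ctrl_scores, dtype=float))
    chip_sorted = np.sort(chip)
    thresholds = np.unique(chip_sorted)
    n_chip_ge = chip.size - np.searchsorted(chip_sorted, thresholds, side="left")
    n_ctrl_ge = ctrl.size - np.searchsorted(ctrl, thresholds, side="left")
    depth = n_chip / max(n_ctrl, 1)
    raw = np.minimum(1.0, n_ctrl_ge / n_chip_ge * depth)
    adjusted = np.minimum.accumulate(raw)  # min over thresholds <= s
    per_call = adjusted[np.searchsorted(thresholds, chip)]
    return per_call, thresholds, adjusted


def nb_threshold(n_nb: int, s_ref: float, s_nb: float, alpha: float) -> int:
    """Adaptive minimum acceptable read count for a reference call, given a
    neighbour with count ``n_nb`` and the two calls' peak widths.

    Under equal read density the reference expects
    ``m = n_nb * s_ref / s_nb`` reads; the threshold is the ``alpha``
    quantile of a negative binomial with mean ``m`` and size ``n_nb``
    (variance ``m + m^2 / n_nb``), so wider peaks are held to
    proportionally higher counts.
    """
    if n_nb < 1:
        raise ValueError("neighbour count must be >= 1")
    if s_ref <= 0 or s_nb <= 0:
        raise ValueError("widths must be positive")
    if not (0.0 < alpha <= 0.5):
        raise ValueError("alpha must be in (0, 0.5]")
    m = n_nb * s_ref / s_nb
    p = n_nb / (n_nb + m)
    return int(nbinom.ppf(alpha, n_nb, p))


def remove_low_density(preds: list[NucleosomePrediction],
                       cfg: Config) -> list[NucleosomePrediction]:
    """Drop calls whose read count is significantly below any neighbour's.

    The neighbourhood of a reference call is every call within
    ``nb_radius`` bp of it, stopping at nucleosome-free gaps: a pair of
    adjacent calls whose centre distance minus the 147-bp core exceeds
    ``nb_gap_threshold`` breaks the neighbourhood in that direction. Flags
    are computed against the unfiltered set in a single pass (no cascade),
    so the result does not depend on removal order.
    """
    if not preds:
        return []
    mus = np.array([p.mu for p in preds], dtype=float)
    if np.any(np.diff(mus) < 0):
        raise ValueError("predictions must be sorted by mu")
    counts = np.array([p.n_f + p.n_r for p in preds], dtype=float)
    widths = np.array([p.width for p in preds], dtype=float)
    gaps = np.diff(mus) - CORE_BP  # nucleosome-free span between adjacent calls
    n = len(preds)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        # scan left then right, stopping at radius or a blocking gap
        for direction in (-1, 1):
            j = i
            while True:
                nxt = j + direction
                if nxt < 0 or nxt >= n:
                    break
                gap = gaps[min(j, nxt)]
                if gap > cfg.nb_gap_threshold:
                    break
                if abs(mus[nxt] - mus[i]) > cfg.nb_radius:
                    break
                j = nxt
                n_nb = int(counts[j])
                if n_nb >= 1:
                    thr = nb_threshold(n_nb, widths[i], widths[j], cfg.nb_alpha)
                    if counts[i] < thr:
                        keep[i] = False
                        break
            if not keep[i]:
                break
    return [p for p, k in zip(preds, keep) if k]
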