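"""End-to-end nucleosome calling: preprocessing, per-region model fitting,
scoring, and density filtering, with optional control-sample annotation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import Config
from .model import fit_region_auto
from .postprocess import (count_core_reads, estimate_fdr, remove_low_density,
                          score, score_relative)
from .preprocess import make_candidate_regions
from .types import CandidateRegion, MixtureFit, NucleosomePrediction, StrandedReadSet

logger = logging.getLogger(__name__)


@dataclass
class ChromResult:
    """Calls and intermediates for one chromosome."""

    chrom: str
    predictions: list[NucleosomePrediction]
    regions: list[CandidateRegion] = field(default_factory=list)
    fits: list[MixtureFit] = field(default_factory=list)


def call_chromosome(reads: StrandedReadSet, cfg: Config,
                    seed: int | None = None,
                    density_filter: bool = True,
                    keep_intermediates: bool = False) -> ChromResult:
    """Call nucleosomes on one chromosome's reads.

    Duplicate-caps and segments the reads, fits a mixture per candidate
    region with K selection and post-fit correction, and scores each
    surviving component inside its region. With ``density_filter`` (the
    default) calls whose read count is significantly below a neighbour's are
    additionally removed; benchmarking against reference positions uses the
    unfiltered scored calls, since the density filter is a
    pre-classification cleanup whose job is to discard weak calls, not part
    of the positional model.
    """
    regions = make_candidate_regions(reads, cfg)
    preds: list[NucleosomePrediction] = []
    fits: list[MixtureFit] = []
    for i, region in enumerate(regions):
        fit = fit_region_auto(region, cfg, seed=seed)
        if fit is None or fit.K == 0:
            continue
        if keep_intermediates:
            fits.append(fit)
        for c in fit.components:
            p = NucleosomePrediction(
                chrom=reads.chrom, mu=c.mu, delta=c.delta,
                sigma_f=c.sigma_f, sigma_r=c.sigma_r, w=c.w)
            p.n_f, p.n_r = count_core_reads(p, region.fwd, region.rev,
                                            cfg.core_quantile)
            p.score = score(p)
            preds.append(p)
        logger.debug("region %d/%d %s:%d-%d -> K=%d",
                     i + 1, len(regions), region.chrom, region.start,
                     region.end, fit.K)
    preds.sort(key=lambda p: p.mu)
    if density_filter:
        preds = remove_low_density(preds, cfg)
    return ChromResult(chrom=reads.chrom, predictions=preds,
                       regions=regions if keep_intermediates else [],
                       fits=fits)


def predict_scored(reads: StrandedReadSet, cfg: Config) -> list[NucleosomePrediction]:
    """Scored nucleosome calls without the low-density cleanup: the
    prediction set used when benchmarking positions against a reference."""
    return call_chromosome(reads, cfg, density_filter=False).predictions


def depth_benchmark(cfg: Config, n_regions: int, k_range: tuple[int, int],
                    fractions, seeds, reference_fraction: float = 0.5) -> dict:
    """Detection and truncated AUC as a function of sequencing depth.

    For each seed, simulates a multi-region dataset, subsamples the reads at
    each fraction, recalls nucleosomes, and matches them to ground truth at
    ``cfg.match_dist``; calls are pooled over seeds per fraction.

    Reference nucleosomes for the ROC are the top ``reference_fraction`` of
    truths by read density (core count over total peak width) — mirroring
    benchmark designs that rank against the best-supported reference
    positions — so calls at genuine but weaker nucleosomes populate the
    false-positive axis. The ROC sweeps the score threshold with
    sensitivity over the reference set: matched calls are positives at
    their score, missed references are positives no threshold recovers, and
    unmatched calls are negatives. A fraction with no unmatched calls at
    all yields the rectangle ``(1 - spec_min) * sensitivity``.

    Detection (``detection_rate_full``) is reported at full depth against
    *all* truth nucleosomes.
    """
    from .evaluate import match_to_reference, subsample_reads, truncated_roc_auc
    from .simulate import make_dataset, truth_centers

    fractions = list(fractions)
    scores = [[] for _ in fractions]
    labels = [[] for _ in fractions]
    ref_total = [0 for _ in fractions]
    detected = 0
    n_refs = 0
    for seed in seeds:
        reads, truths, _ = make_dataset(n_regions, k_range, cfg, seed=seed)
        all_refs = truth_centers(truths)
        density = np.concatenate([
            2.0 * t.reads_per_nucleosome / (t.sigma_f + t.sigma_r)
            for t in truths])
        centers = np.concatenate([t.centers for t in truths])
        n_top = max(1, int(round(reference_fraction * centers.size)))
        top = np.argsort(-density, kind="stable")[:n_top]
        roc_refs = np.sort(centers[top])
        for j, frac in enumerate(fractions):
            sub = subsample_reads(reads, frac, seed=(seed * 97 + j) % 2**31)
            preds = predict_scored(sub, cfg)
            mus = np.array([p.mu for p in preds])
            m = match_to_reference(mus, roc_refs, cfg.match_dist)
            scores[j].extend(p.score for p in preds)
            labels[j].extend(m.is_tp.tolist())
            ref_total[j] += roc_refs.size
            if frac == 1.0:
                m_all = match_to_reference(mus, all_refs, cfg.match_dist)
                detected += m_all.n_detected
                n_refs += all_refs.size
    aucs = []
    sens = []
    for s, l, n_ref in zip(scores, labels, ref_total):
        l = np.asarray(l, dtype=bool)
        s = np.asarray(s, dtype=float)
        n_tp = int(l.sum())
        n_miss = n_ref - n_tp
        sens.append(n_tp / n_ref if n_ref else 0.0)
        if not (~l).any() or n_tp == 0:
            # no negatives (or no signal): rectangular curve up to the ceiling
            aucs.append((1.0 - cfg.spec_min) * (n_tp / n_ref if n_ref else 0.0))
            continue
        # missed references: positives below every attained score
        sentinel = (s.min() if s.size else 0.0) - 1.0
        s_aug = np.r_[s, np.full(n_miss, sentinel)]
        l_aug = np.r_[l, np.ones(n_miss, dtype=bool)]
        aucs.append(truncated_roc_auc(s_aug, l_aug, cfg.spec_min))
    out = {"fractions": fractions, "auc_by_fraction": aucs,
           "sensitivity_by_fraction": sens}
    if n_refs:
        out["detection_rate_full"] = detected / n_refs
        out["n_ref"] = n_refs
    return out


def call_sample(reads_by_chrom: dict[str, StrandedReadSet], cfg: Config,
                control_by_chrom: dict[str, StrandedReadSet] | None = None,
                seed: int | None = None):
    """Call nucleosomes over all chromosomes of a treatment sample.

    With a control sample, each call additionally gets a depth-normalized
    relative score, and an empirical FDR computed from the score
    distribution of calls made by running the identical pipeline on the
    control reads.

    Returns ``(predictions, fdr_table)`` where ``fdr_table`` is
    ``(thresholds, fdr)`` or ``None`` without a control.
    """
    all_preds: list[NucleosomePrediction] = []
    for chrom in sorted(reads_by_chrom):
        result = call_chromosome(reads_by_chrom[chrom], cfg, seed=seed)
        all_preds.extend(result.predictions)
    fdr_table = None
    if control_by_chrom is not None:
        n_chip = sum(r.n_total for r in reads_by_chrom.values())
        n_ctrl = sum(r.n_total for r in control_by_chrom.values())
        for chrom in sorted(reads_by_chrom):
            ctrl = control_by_chrom.get(
                chrom, StrandedReadSet(chrom, [], []))
            for p in all_preds:
                if p.chrom != chrom:
                    continue
                p.score_rel = score_relative(p, ctrl, n_chip, n_ctrl,
                                             cfg.core_quantile)
        ctrl_preds: list[NucleosomePrediction] = []
        for chrom in sorted(control_by_chrom):
            ctrl_preds.extend(
                call_chromosome(control_by_chrom[chrom], cfg, seed=seed).predictions)
        if all_preds and ctrl_preds:
            chip_scores = np.array([p.score for p in all_preds])
            ctrl_scores = np.array([p.score for p in ctrl_preds])
            per_call, thr, fdr = estimate_fdr(chip_scores, ctrl_scores,
                                              n_chip, n_ctrl)
            for p, f in zip(all_preds, per_call):
                p.fdr = float(f)
            fdr_table = (thr, fdr)
        elif all_preds and not ctrl_preds:
            # no control calls at all: every score threshold is clean
            for p in all_preds:
                p.fdr = 0.0
            fdr_table = (np.array([p.score for p in all_preds]),
                         np.zeros(len(all_preds)))
    return all_preds, fdr_table
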