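"""Duplicate-read capping and segmentation into bounded candidate regions.

Segmentation slides a window along the chromosome and keeps windows whose
left half holds enough forward reads and whose right half holds enough
reverse reads — the bidirectional signature of fragment ends flanking
nucleosomal DNA. Overlapping retained windows merge into disjoint candidate
regions, which are then recursively split at read-sparse points so no region
exceeds the configured mixture-size bound.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .config import Config
from .types import CandidateRegion, StrandedReadSet

logger = logging.getLogger(__name__)


def _cap_strand(pos: np.ndarray, cap: int) -> np.ndarray:
    if pos.size == 0:
        return pos
    uniq, counts = np.unique(pos, return_counts=True)
    kept = np.minimum(counts, cap)
    return np.repeat(uniq, kept)


def duplicate_cap(reads: StrandedReadSet, quantile: float) -> int:
    """The per-position duplicate cap: ceil of the ``quantile``-quantile of
    per-position duplicate counts (positions with >= 1 read, both strands
    pooled), never below 1."""
    counts = []
    for pos in (reads.fwd, reads.rev):
        if pos.size:
            counts.append(np.unique(pos, return_counts=True)[1])
    if not counts:
        return 1
    all_counts = np.concatenate(counts)
    return max(1, math.ceil(np.quantile(all_counts, quantile)))


def filter_duplicates(reads: StrandedReadSet, quantile: float) -> StrandedReadSet:
    """Cap per-position read multiplicity at an empirical-quantile threshold.

    Library construction and PCR can pile artifactual duplicates on single
    positions; MNase data legitimately concentrates fragment starts, so the
    cap quantile is protocol-dependent (see :class:`~nucpos.config.Config`).
    Idempotent; empty input is returned unchanged.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must be in (0, 1]")
    if reads.n_total == 0:
        return reads
    cap = duplicate_cap(reads, quantile)
    return StrandedReadSet(reads.chrom,
                           _cap_strand(reads.fwd, cap),
                           _cap_strand(reads.rev, cap))


def _count_in(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Count positions p with lo <= p < hi for vectorized interval bounds."""
    return np.searchsorted(pos, hi, side="left") - np.searchsorted(pos, lo, side="left")


def segment_genome(reads: StrandedReadSet, cfg: Config) -> list[CandidateRegion]:
    """Slide a w-bp window by s bp; keep windows with >= min_reads forward
    reads in the left half-window ``[start, center - c)`` and >= min_reads
    reverse reads in the right half-window ``[center + c, start + w]``
    (reads within ``center_exclusion`` bp of the centre not counted); merge
    overlapping retained windows left to right into disjoint regions."""
    if reads.n_total == 0:
        return []
    w, s, c = cfg.window_width, cfg.window_step, cfg.center_exclusion
    half = w / 2.0
    lo = int(min(reads.fwd[0] if reads.n_fwd else np.inf,
                 reads.rev[0] if reads.n_rev else np.inf))
    hi = int(max(reads.fwd[-1] if reads.n_fwd else -np.inf,
                 reads.rev[-1] if reads.n_rev else -np.inf))
    starts = np.arange(max(0, lo - w), hi + s, s, dtype=np.int64)
    centers = starts + half
    nf = _count_in(reads.fwd, starts, np.maximum(starts, centers - c))
    # right half-window includes its right edge (count center+c <= p <= start+w)
    nr = (np.searchsorted(reads.rev, starts + w, side="right")
          - np.searchsorted(reads.rev, np.minimum(starts + w, centers + c),
                            side="left"))
    keep = (nf >= cfg.min_reads) & (nr >= cfg.min_reads)
    if not keep.any():
        return []
    regions: list[CandidateRegion] = []
    kept_starts = starts[keep]
    block_start = int(kept_starts[0])
    block_end = block_start + w
    merged: list[tuple[int, int]] = []
    for st in kept_starts[1:]:
        st = int(st)
        if st <= block_end:  # overlapping or abutting window extends the block
            block_end = st + w
        else:
            merged.append((block_start, block_end))
            block_start, block_end = st, st + w
    merged.append((block_start, block_end))
    for rs, re in merged:
        re += 1  # half-open region interval covering the closed window edge
        if re - rs < cfg.min_region_length:
            continue
        member = reads.subset(rs, re)
        if member.n_fwd < cfg.min_reads or member.n_rev < cfg.min_reads:
            continue
        regions.append(CandidateRegion(reads.chrom, rs, re, member.fwd, member.rev))
    return regions


def _central_gap_splits(region: CandidateRegion) -> list[int]:
    """Candidate split points: midpoints of gaps between consecutive pooled
    read positions whose midpoint lies in the central third of the region,
    widest gap first."""
    pooled = np.sort(np.concatenate([region.fwd, region.rev]))
    if pooled.size < 2:
        return []
    gaps = np.diff(pooled)
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    lo = region.start + region.length / 3.0
    hi = region.start + 2.0 * region.length / 3.0
    ok = (mids >= lo) & (mids <= hi) & (gaps > 0)
    if not ok.any():
        return []
    idx = np.flatnonzero(ok)
    order = idx[np.argsort(-gaps[idx], kind="stable")]
    return [int(round(m)) for m in mids[order]]


def split_long_regions(region: CandidateRegion, cfg: Config) -> list[CandidateRegion]:
    """Recursively split regions longer than ``max_region_length`` at the
    midpoint of the widest central-third read gap.

    Restricting split points to the central third guarantees geometric
    shrinkage (hence termination). If no candidate split leaves at least
    ``min_reads`` per strand on both sides, the region is returned unsplit
    with a warning.
    """
    if region.length <= cfg.max_region_length:
        return [region]
    for split in _central_gap_splits(region):
        lf = region.fwd[region.fwd < split]
        lr = region.rev[region.rev < split]
        rf = region.fwd[region.fwd >= split]
        rr = region.rev[region.rev >= split]
        if (lf.size < cfg.min_reads or lr.size < cfg.min_reads
                or rf.size < cfg.min_reads or rr.size < cfg.min_reads):
            continue
        left = CandidateRegion(region.chrom, region.start, split, lf, lr)
        right = CandidateRegion(region.chrom, split, region.end, rf, rr)
        return split_long_regions(left, cfg) + split_long_regions(right, cfg)
    logger.warning(
        "region %s:%d-%d (%d bp) exceeds max_region_length but cannot be "
        "split without starving a strand; kept unsplit",
        region.chrom, region.start, region.end, region.length)
    return [region]


def make_candidate_regions(reads: StrandedReadSet, cfg: Config) -> list[CandidateRegion]:
    """Full preprocessing: duplicate capping, segmentation, recursive splitting."""
    capped = filter_duplicates(reads, cfg.dup_quantile)
    out: list[CandidateRegion] = []
    for region in segment_genome(capped, cfg):
        out.extend(split_long_regions(region, cfg))
    return out
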