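"""Seeded generator of synthetic stranded read data from the caller's own
generative model.

Nucleosome centres follow the chain spacing prior (successive gaps
``delta0 + Normal(0, 1/sqrt(2 rho_s))``, rejection-sampled into the
configured spacing bounds); each nucleosome has a fragment length ``delta``
around the protocol's prior mean and strand scales from the protocol's
typical range; forward/reverse 5' read positions are Student-t(4) draws
around ``mu -/+ delta/2``, rounded to integer coordinates. Every stage of
the pipeline can therefore be tested against known ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import Config
from .model import PriorSpec
from .types import CORE_BP, SimTruth, StrandedReadSet

_READ_LEN = 25  # bp; only used to render BED intervals, the model sees 5' ends


def sample_centers(K: int, start: float, spec: PriorSpec,
                   rng: np.random.Generator,
                   spacing_bounds: tuple[float, float] = (150.0, 250.0)) -> np.ndarray:
    """Sample K centres sequentially from the chain spacing prior.

    ``mu_1 = start``; each subsequent gap is ``delta0 + Normal(0, sd)`` with
    ``sd = 1 / sqrt(2 rho_s)`` (the chain-conditional distribution of the
    spacing prior), redrawn until it lies within ``spacing_bounds``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    sd = 1.0 / np.sqrt(2.0 * spec.rho_s)
    centers = [float(start)]
    lo, hi = spacing_bounds
    for _ in range(K - 1):
        while True:
            gap = spec.delta0 + rng.normal(0.0, sd)
            if lo <= gap <= hi:
                break
        centers.append(centers[-1] + gap)
    return np.asarray(centers)


def sample_truth(K: int, start: float, cfg: Config,
                 rng: np.random.Generator, chrom: str = "chrSim") -> SimTruth:
    """Draw one nucleosome array's full ground-truth parameter set."""
    spec = PriorSpec.from_config(cfg)
    centers = sample_centers(K, start, spec, rng, cfg.spacing_bounds)
    d_lo = max(cfg.delta_bounds[0], cfg.xi - 3.0 * cfg.sim_delta_sd)
    d_hi = min(cfg.delta_bounds[1], cfg.xi + 3.0 * cfg.sim_delta_sd)
    deltas = np.clip(rng.normal(cfg.xi, cfg.sim_delta_sd, size=K), d_lo, d_hi)
    s_lo, s_hi = cfg.sim_sigma_range
    sigma_f = rng.uniform(s_lo, s_hi, size=K)
    sigma_r = rng.uniform(s_lo, s_hi, size=K)
    return SimTruth(chrom=chrom, centers=centers, deltas=deltas,
                    sigma_f=sigma_f, sigma_r=sigma_r,
                    reads_per_nucleosome=cfg.reads_per_nucleosome,
                    preset=cfg.preset_name)


def sample_reads(truth: SimTruth, rng: np.random.Generator) -> StrandedReadSet:
    """Draw reads for one truth array: per nucleosome, n forward positions
    ``mu - delta/2 + sigma_f * T4`` and n reverse ``mu + delta/2 + sigma_r * T4``
    (T4 standard t, nu=4), rounded to integers and clipped at 0."""
    n = truth.reads_per_nucleosome
    fwd_parts, rev_parts = [], []
    for k in range(truth.K):
        cf = truth.centers[k] - truth.deltas[k] / 2.0
        cr = truth.centers[k] + truth.deltas[k] / 2.0
        fwd_parts.append(cf + truth.sigma_f[k] * rng.standard_t(4, size=n))
        rev_parts.append(cr + truth.sigma_r[k] * rng.standard_t(4, size=n))
    fwd = np.clip(np.rint(np.concatenate(fwd_parts) if fwd_parts else []), 0, None)
    rev = np.clip(np.rint(np.concatenate(rev_parts) if rev_parts else []), 0, None)
    return StrandedReadSet(truth.chrom, fwd.astype(np.int64), rev.astype(np.int64))


def make_dataset(n_regions: int, k_range: tuple[int, int], cfg: Config,
                 seed: int, out_dir: str | Path | None = None,
                 chrom: str = "chrSim"):
    """Simulate a multi-region synthetic chromosome.

    Regions are separated by read-free gaps wider than ``max_region_length``
    so segmentation recovers them as distinct candidate regions. Returns
    ``(reads, truths, manifest)``; with ``out_dir`` also writes ``reads.bed``
    (BED6), ``truth.bed`` (147-bp footprints), and ``manifest.json`` from
    which the dataset regenerates bit-exactly.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    k_lo, k_hi = k_range
    if not (1 <= k_lo <= k_hi):
        raise ValueError("k_range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    gap = cfg.max_region_length + 1000
    pos = 1000.0
    truths: list[SimTruth] = []
    fwd_all, rev_all = [], []
    for _ in range(n_regions):
        K = int(rng.integers(k_lo, k_hi + 1))
        truth = sample_truth(K, pos, cfg, rng, chrom=chrom)
        reads = sample_reads(truth, rng)
        truths.append(truth)
        fwd_all.append(reads.fwd)
        rev_all.append(reads.rev)
        pos = float(truth.centers[-1]) + gap
    reads = StrandedReadSet(chrom, np.concatenate(fwd_all), np.concatenate(rev_all))
    manifest = {
        "seed": int(seed),
        "n_regions": int(n_regions),
        "k_range": [int(k_lo), int(k_hi)],
        "chrom": chrom,
        "preset": cfg.preset_name,
        "reads_per_nucleosome": int(cfg.reads_per_nucleosome),
        "delta0": cfg.delta0,
        "rho_s": cfg.rho_s,
        "spacing_bounds": list(cfg.spacing_bounds),
        "xi": cfg.xi,
        "sim_delta_sd": cfg.sim_delta_sd,
        "sim_sigma_range": list(cfg.sim_sigma_range),
        "n_fwd": reads.n_fwd,
        "n_rev": reads.n_rev,
        "n_nucleosomes": int(sum(t.K for t in truths)),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_reads_bed(reads, out_dir / "reads.bed")
        _write_truth_bed(truths, out_dir / "truth.bed")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return reads, truths, manifest


def dataset_from_manifest(path: str | Path):
    """Regenerate a dataset bit-exactly from its manifest."""
    with open(path) as fh:
        m = json.load(fh)
    cfg = Config.preset(
        m["preset"],
        reads_per_nucleosome=m["reads_per_nucleosome"],
        delta0=m["delta0"], rho_s=m["rho_s"],
        spacing_bounds=tuple(m["spacing_bounds"]),
        xi=m["xi"], sim_delta_sd=m["sim_delta_sd"],
        sim_sigma_range=tuple(m["sim_sigma_range"]),
    )
    return make_dataset(m["n_regions"], tuple(m["k_range"]), cfg,
                        seed=m["seed"], chrom=m["chrom"])


def truth_centers(truths: list[SimTruth]) -> np.ndarray:
    """All ground-truth centres pooled and sorted."""
    return np.sort(np.concatenate([t.centers for t in truths]))


def _write_reads_bed(reads: StrandedReadSet, path: Path) -> None:
    with open(path, "w") as fh:
        i = 0
        for p in reads.fwd:  # 5' = chromStart
            i += 1
            fh.write(f"{reads.chrom}\t{p}\t{p + _READ_LEN}\tread_{i}\t0\t+\n")
        for p in reads.rev:  # 5' = chromEnd - 1
            i += 1
            start = max(0, p + 1 - _READ_LEN)
            fh.write(f"{reads.chrom}\t{start}\t{p + 1}\tread_{i}\t0\t-\n")


def _write_truth_bed(truths: list[SimTruth], path: Path) -> None:
    with open(path, "w") as fh:
        i = 0
        for t in truths:
            for mu in t.centers:
                i += 1
                center = int(round(mu))
                fh.write(f"{t.chrom}\t{center - CORE_BP // 2}\t"
                         f"{center - CORE_BP // 2 + CORE_BP}\tnuc_{i}\t0\t.\n")
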