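"""Readers and writers for the standard formats the tool touches.

Reads come in as BED6 or coordinate-sorted indexed BAM; predictions go out as
a tab-delimited table (lossless round trip) plus a BED6 companion with the
canonical 147-bp footprint; occupancy profiles are written as fixedStep
wiggle.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

import numpy as np
import pandas as pd

from .types import NucleosomePrediction, StrandedReadSet

PREDICTION_COLUMNS = [
    "chrom", "start", "end", "mu", "delta", "sigma_f", "sigma_r",
    "w", "n_f", "n_r", "score", "score_rel", "fdr",
]


class BedParseError(ValueError):
    """A malformed line in a BED file, annotated with its line number."""


def read_reads_bed(path) -> dict[str, StrandedReadSet]:
    """Read single-end aligned reads from BED6 into per-chromosome read sets.

    Forward reads contribute ``chromStart`` as the 5' position; reverse reads
    contribute ``chromEnd - 1`` (BED ``end`` is exclusive).
    """
    fwd: dict[str, list[int]] = defaultdict(list)
    rev: dict[str, list[int]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: need 6 BED fields (strand required), got {len(parts)}"
                )
            chrom, start_s, end_s, _name, _score, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if strand == "+":
                fwd[chrom].append(start)
            elif strand == "-":
                rev[chrom].append(end - 1)
            else:
                raise BedParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
    chroms = sorted(set(fwd) | set(rev))
    return {c: StrandedReadSet(c, fwd.get(c, []), rev.get(c, [])) for c in chroms}


def read_reads_bam(path) -> dict[str, StrandedReadSet]:
    """Read aligned reads from a coordinate-sorted, indexed BAM file.

    Same contract as :func:`read_reads_bed` on equivalent alignments:
    unmapped, secondary and supplementary records are skipped.
    """
    import pysam

    with pysam.AlignmentFile(str(path), "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(
                f"{path}: BAM index (.bai) required; run `samtools index` first"
            )
        fwd: dict[str, list[int]] = defaultdict(list)
        rev: dict[str, list[int]] = defaultdict(list)
        for aln in bam.fetch():
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            chrom = aln.reference_name
            if aln.is_reverse:
                rev[chrom].append(aln.reference_end - 1)
            else:
                fwd[chrom].append(aln.reference_start)
    chroms = sorted(set(fwd) | set(rev))
    return {c: StrandedReadSet(c, fwd.get(c, []), rev.get(c, [])) for c in chroms}


def predictions_to_frame(preds: Iterable[NucleosomePrediction]) -> pd.DataFrame:
    rows = []
    for p in preds:
        rows.append({
            "chrom": p.chrom, "start": p.start, "end": p.end,
            "mu": p.mu, "delta": p.delta,
            "sigma_f": p.sigma_f, "sigma_r": p.sigma_r, "w": p.w,
            "n_f": p.n_f, "n_r": p.n_r, "score": p.score,
            "score_rel": np.nan if p.score_rel is None else p.score_rel,
            "fdr": np.nan if p.fdr is None else p.fdr,
        })
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def write_predictions(preds: list[NucleosomePrediction], path,
                      bed_path=None) -> None:
    """Write the tab-delimited prediction table and a BED6 companion.

    The table round-trips losslessly through :func:`read_predictions`
    (fractional ``mu`` preserved). The BED companion reports the canonical
    147-bp footprint centred on ``round(mu)`` with a rank-scaled score in
    [0, 1000] (best score -> 1000).
    """
    frame = predictions_to_frame(preds)
    # %.17g keeps the float round trip exact
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
    if bed_path is None:
        return
    with open(bed_path, "w") as fh:
        if len(frame):
            order = frame["score"].rank(method="min", ascending=True)
            denom = max(len(frame), 1)
            bed_scores = (order / denom * 1000).round().astype(int)
            for i, (row, bs) in enumerate(zip(frame.itertuples(index=False), bed_scores)):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"nuc_{i + 1}\t{bs}\t.\n")


def read_predictions(path) -> list[NucleosomePrediction]:
    """Read a prediction table written by :func:`write_predictions`."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"],
                        float_precision="round_trip")
    preds = []
    for row in frame.itertuples(index=False):
        preds.append(NucleosomePrediction(
            chrom=str(row.chrom), mu=float(row.mu), delta=float(row.delta),
            sigma_f=float(row.sigma_f), sigma_r=float(row.sigma_r),
            w=float(row.w), n_f=int(row.n_f), n_r=int(row.n_r),
            score=float(row.score),
            score_rel=None if pd.isna(row.score_rel) else float(row.score_rel),
            fdr=None if pd.isna(row.fdr) else float(row.fdr),
        ))
    return preds


def read_summits_bed(path) -> dict[str, np.ndarray]:
    """Read TF binding-site summits from BED; returns sorted positions per chrom.

    Single-base records are taken at ``start``; wider intervals at their
    midpoint.
    """
    out: dict[str, list[int]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: need >= 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            out[chrom].append(start if end - start <= 1 else (start + end) // 2)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in sorted(out.items())}


def read_gene_map(path) -> dict[str, list[str]]:
    """Read a tab-delimited site-to-gene association table (site, gene)."""
    mapping: dict[str, list[str]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: need site<TAB>gene")
            site, gene = parts[0], parts[1]
            if lineno == 1 and site.lower() in {"site", "site_id", "summit"}:
                continue  # header
            mapping[gene].append(site)
    return dict(mapping)


def write_wiggle(profile: np.ndarray, chrom: str, start: int, path,
                 step: int = 1) -> None:
    """Write a per-bp profile as a fixedStep wiggle track."""
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={chrom} start={start + 1} step={step}\n")
        for v in np.asarray(profile, dtype=float):
            fh.write(f"{v:.6g}\n")
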