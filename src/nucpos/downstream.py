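"""Biological-inference utilities on top of nucleosome calls.

Transcription-factor binding-site summits are classified by their distance
to the nearest called nucleosome centre: sites with a centre essentially on
top of the summit sit within nucleosomal DNA ("monomodal", the pattern of
pioneer-factor binding), sites with no marked nucleosome within 1 kb are
"NoNuc", and the remainder — typically flanked by a pair of nucleosomes —
are "bimodal". Gene-level labels follow the functional precedence
bimodal > monomodal > NoNuc. Occupancy and summit-versus-dyad profiles
support the corresponding positional analyses.
"""

from __future__ import annotations

import numpy as np

from .types import CORE_BP, NucleosomePrediction

#: half the canonical core: reference marks for dyad-relative profiles
HALF_CORE_BP = CORE_BP // 2  # 73

LABELS = ("bimodal", "monomodal", "NoNuc")
_PRECEDENCE = {"bimodal": 0, "monomodal": 1, "NoNuc": 2}


def nearest_center_distance(summits, centers) -> np.ndarray:
    """Absolute distance from each summit to its nearest centre (inf if none)."""
    summits = np.asarray(summits, dtype=float)
    centers = np.sort(np.asarray(centers, dtype=float))
    if centers.size == 0:
        return np.full(summits.shape, np.inf)
    idx = np.searchsorted(centers, summits)
    left = np.abs(summits - centers[np.clip(idx - 1, 0, centers.size - 1)])
    right = np.abs(summits - centers[np.clip(idx, 0, centers.size - 1)])
    return np.minimum(left, right)


def classify_sites(summits, centers, mono_dist: float = 50.0,
                   none_dist: float = 1000.0) -> list[str]:
    """Label each summit bimodal / monomodal / NoNuc.

    NoNuc: no nucleosome centre within ``none_dist`` (default 1 kb);
    monomodal: at least one centre within ``mono_dist`` (default 50 bp) of
    the summit; bimodal: everything else. Callers should pass centres of
    confidently called nucleosomes only (weak calls already removed).
    """
    if mono_dist > none_dist:
        raise ValueError("mono_dist must not exceed none_dist")
    dist = nearest_center_distance(summits, centers)
    labels = []
    for d in dist:
        if d > none_dist:
            labels.append("NoNuc")
        elif d <= mono_dist:
            labels.append("monomodal")
        else:
            labels.append("bimodal")
    return labels


def gene_modality(gene_to_labels: dict[str, list[str]]) -> dict[str, str]:
    """Collapse per-site labels to one label per gene.

    A bimodal site anywhere makes the gene bimodal; otherwise any monomodal
    site makes it monomodal; only all-NoNuc genes are NoNuc. Genes with no
    sites are absent from the output.
    """
    out = {}
    for gene, labels in gene_to_labels.items():
        if not labels:
            continue
        bad = set(labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown site labels {sorted(bad)} for gene {gene}")
        out[gene] = min(labels, key=_PRECEDENCE.__getitem__)
    return out


def occupancy_profile(nucs: list[NucleosomePrediction], anchors,
                      halfwidth: int, kernel_sd: float = 30.0) -> np.ndarray:
    """Average nucleosome-occupancy profile in anchor-relative coordinates.

    Each nucleosome contributes a Gaussian kernel at its centre (sd 30 bp)
    scaled by its score normalized to the set's maximum; contributions are
    summed per anchor and averaged over anchors (anchor strand ignored).
    Output covers offsets ``-halfwidth .. +halfwidth`` (length
    ``2 * halfwidth + 1``).
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size == 0:
        raise ValueError("need at least one anchor")
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    offsets = np.arange(-halfwidth, halfwidth + 1, dtype=float)
    profile = np.zeros_like(offsets)
    if not nucs:
        return profile
    mus = np.array([p.mu for p in nucs], dtype=float)
    scores = np.array([p.score for p in nucs], dtype=float)
    max_score = scores.max()
    weights = scores / max_score if max_score > 0 else np.ones_like(scores)
    reach = halfwidth + 5.0 * kernel_sd
    order = np.argsort(mus)
    mus, weights = mus[order], weights[order]
    for a in anchors:
        lo = np.searchsorted(mus, a - reach)
        hi = np.searchsorted(mus, a + reach)
        for m, wt in zip(mus[lo:hi], weights[lo:hi]):
            profile += wt * np.exp(-0.5 * ((offsets - (m - a)) / kernel_sd) ** 2)
    return profile / anchors.size


def site_vs_dyad_profile(summits, nucs: list[NucleosomePrediction],
                         truncate: int = 100, top_n: int | None = None):
    """Histogram of signed distances summit - nearest nucleosome centre.

    Bins are 1 bp over ``[-truncate, +truncate]``; distances beyond the
    truncation window are excluded from the histogram but counted in the
    overflow tally. ``top_n`` restricts the nucleosome set to the top-N
    calls by score before pairing. Reference marks for plotting sit at
    +/- 73 bp (half the 147-bp core).

    Returns ``(offsets, counts, overflow)``.
    """
    if truncate <= 0:
        raise ValueError("truncate must be positive")
    summits = np.asarray(summits, dtype=float)
    offsets = np.arange(-truncate, truncate + 1)
    counts = np.zeros(offsets.size, dtype=int)
    if not nucs or summits.size == 0:
        return offsets, counts, int(summits.size if nucs else 0)
    if top_n is not None:
        ranked = sorted(nucs, key=lambda p: -p.score)[:top_n]
    else:
        ranked = nucs
    centers = np.sort(np.array([p.mu for p in ranked], dtype=float))
    idx = np.searchsorted(centers, summits)
    left = centers[np.clip(idx - 1, 0, centers.size - 1)]
    right = centers[np.clip(idx, 0, centers.size - 1)]
    nearest = np.where(np.abs(summits - left) <= np.abs(summits - right),
                       left, right)
    dist = np.rint(summits - nearest).astype(int)
    inside = np.abs(dist) <= truncate
    overflow = int((~inside).sum())
    np.add.at(counts, dist[inside] + truncate, 1)
    return offsets, counts, overflow


def elbow_score_cutoff(scores) -> float:
    """Score at the elbow of the sorted-score curve.

    Scores are sorted descending and scaled to the unit square; the elbow is
    the point with maximum perpendicular distance to the chord joining the
    first and last points. Used to separate confident calls from the weak
    tail before site classification.
    """
    s = np.sort(np.asarray(scores, dtype=float))[::-1]
    if s.size < 3 or s[0] == s[-1]:
        return float(s[-1]) if s.size else 0.0
    x = np.linspace(0.0, 1.0, s.size)
    y = (s - s[-1]) / (s[0] - s[-1])
    # chord from (0, 1) to (1, 0); distance ~ |x + y - 1|
    dist = np.abs(x + y - 1.0)
    return float(s[int(np.argmax(dist))])
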