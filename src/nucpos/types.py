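"""Core data containers: stranded reads, candidate regions, fitted models,
and scored nucleosome calls.

Coordinate convention is 0-based half-open everywhere. A read contributes a
single integer 5' position: its leftmost aligned base on the forward strand,
its rightmost aligned base (BED ``end - 1``) on the reverse strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Canonical nucleosome-core DNA length (bp); used only for output footprints
#: and for measuring nucleosome-free gaps between adjacent calls.
CORE_BP = 147


def _positions(x, name: str) -> np.ndarray:
    arr = np.sort(np.asarray(x, dtype=np.int64).ravel())
    if arr.size and arr[0] < 0:
        raise ValueError(f"{name} read positions must be >= 0")
    return arr


@dataclass(frozen=True)
class StrandedReadSet:
    """Sorted 5' read positions of one chromosome, split by strand.

    This is the only evidence the model sees: the bidirectional offset of the
    two strand distributions around each nucleosome centre carries the
    fragment-length information.
    """

    chrom: str
    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "fwd", _positions(self.fwd, "forward"))
        object.__setattr__(self, "rev", _positions(self.rev, "reverse"))

    @property
    def n_fwd(self) -> int:
        return int(self.fwd.size)

    @property
    def n_rev(self) -> int:
        return int(self.rev.size)

    @property
    def n_total(self) -> int:
        return self.n_fwd + self.n_rev

    def shift(self, offset: int) -> "StrandedReadSet":
        """Translate every read by ``offset`` bp (must stay non-negative)."""
        return StrandedReadSet(self.chrom, self.fwd + offset, self.rev + offset)

    def subset(self, start: int, end: int) -> "StrandedReadSet":
        """Reads with 5' position in the half-open window [start, end)."""
        f = self.fwd[np.searchsorted(self.fwd, start): np.searchsorted(self.fwd, end)]
        r = self.rev[np.searchsorted(self.rev, start): np.searchsorted(self.rev, end)]
        return StrandedReadSet(self.chrom, f, r)


@dataclass(frozen=True)
class CandidateRegion:
    """A read-supported genomic interval; the unit of model fitting."""

    chrom: str
    start: int
    end: int
    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "fwd", _positions(self.fwd, "forward"))
        object.__setattr__(self, "rev", _positions(self.rev, "reverse"))
        if not self.start < self.end:
            raise ValueError("region must satisfy start < end")
        for arr in (self.fwd, self.rev):
            if arr.size and (arr[0] < self.start or arr[-1] >= self.end):
                raise ValueError("member reads must lie in [start, end)")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_fwd(self) -> int:
        return int(self.fwd.size)

    @property
    def n_rev(self) -> int:
        return int(self.rev.size)

    def shift(self, offset: int) -> "CandidateRegion":
        return CandidateRegion(self.chrom, self.start + offset, self.end + offset,
                               self.fwd + offset, self.rev + offset)


@dataclass
class NucleosomeComponent:
    """Per-nucleosome mixture parameters.

    ``w``
        shared forward/reverse mixture weight (a fragment contributes either
        read end with equal probability).
    ``mu``
        nucleosome centre (bp, fractional).
    ``delta``
        mean DNA fragment length: the offset between the forward and reverse
        read-density maxima, which sit at ``mu - delta/2`` and
        ``mu + delta/2``.
    ``var_f``, ``var_r``
        strand-specific read-position variances (bp^2); not constrained to be
        equal, to absorb mappability/sequencing asymmetries.
    """

    w: float
    mu: float
    delta: float
    var_f: float
    var_r: float

    @property
    def sigma_f(self) -> float:
        return float(np.sqrt(self.var_f))

    @property
    def sigma_r(self) -> float:
        return float(np.sqrt(self.var_r))


@dataclass
class MixtureFit:
    """A fitted per-region mixture with its selection objective.

    ``logpost_pen`` is the model-selection objective: the data log-likelihood
    penalized by the spacing prior over the fitted centres. ``objective_trace``
    records the full MAP objective (likelihood + all priors) at each EM
    iteration; it is nondecreasing for a correct EM implementation.
    """

    K: int
    components: list[NucleosomeComponent]
    loglik: float
    logpost_pen: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        mus = [c.mu for c in self.components]
        if any(b <= a for a, b in zip(mus, mus[1:])):
            raise ValueError("components must be strictly increasing in mu")

    @property
    def mus(self) -> np.ndarray:
        return np.array([c.mu for c in self.components], dtype=float)


@dataclass
class NucleosomePrediction:
    """A scored nucleosome call.

    ``score`` is core-read count divided by total peak width (reads/bp);
    ``score_rel`` is the depth-normalized ratio to a control sample and
    ``fdr`` the empirical false discovery rate at this call's score — both
    are ``None`` when no control sample was provided.
    """

    chrom: str
    mu: float
    delta: float
    sigma_f: float
    sigma_r: float
    w: float
    n_f: int = 0
    n_r: int = 0
    score: float = 0.0
    score_rel: Optional[float] = None
    fdr: Optional[float] = None

    @property
    def start(self) -> int:
        """Left edge of the canonical 147-bp footprint."""
        return int(round(self.mu)) - CORE_BP // 2

    @property
    def end(self) -> int:
        """Right edge (exclusive) of the canonical 147-bp footprint."""
        return self.start + CORE_BP

    @property
    def width(self) -> float:
        """Total peak width sigma_f + sigma_r (bp), the score denominator."""
        return self.sigma_f + self.sigma_r


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters of one simulated nucleosome array."""

    chrom: str
    centers: np.ndarray
    deltas: np.ndarray
    sigma_f: np.ndarray
    sigma_r: np.ndarray
    reads_per_nucleosome: int
    preset: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "deltas", np.asarray(self.deltas, dtype=float))
        object.__setattr__(self, "sigma_f", np.asarray(self.sigma_f, dtype=float))
        object.__setattr__(self, "sigma_r", np.asarray(self.sigma_r, dtype=float))
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("truth centers must be strictly increasing")
        for arr in (self.deltas, self.sigma_f, self.sigma_r):
            if np.any(arr <= 0):
                raise ValueError("scales must be positive")

    @property
    def K(self) -> int:
        return int(self.centers.size)
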