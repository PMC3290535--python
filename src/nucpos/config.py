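"""Run configuration with protocol presets.

Every tunable of the pipeline lives here: segmentation window geometry,
duplicate-cap quantile, the spacing (GMRF) and fragment-length priors, the
model-selection search margin, post-fit sanity bounds, scoring and filtering
thresholds, classification distances, and simulator settings.

Two presets reflect the two library-construction protocols:

``mnase``
    MNase digestion yields a tight mononucleosomal fragment-length
    distribution; the fragment prior is centred at 150 bp and is tight, more
    genuine duplicate reads are tolerated, and reference matching is strict.
``sonicated``
    Sonication yields broad fragment lengths; the prior is centred at 200 bp
    and loose, the duplicate cap is stricter, and matching is looser.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import yaml

_PRESET_OVERRIDES = {
    "mnase": dict(
        dup_quantile=0.999,
        xi=150.0,
        kappa=5.0,
        alpha=2.0,
        beta=800.0,
        match_dist=50.0,
        sim_sigma_range=(15.0, 25.0),
        sim_delta_sd=10.0,
    ),
    "sonicated": dict(
        dup_quantile=0.99,
        xi=200.0,
        kappa=3.0,
        alpha=2.0,
        beta=1800.0,
        match_dist=100.0,
        sim_sigma_range=(25.0, 40.0),
        sim_delta_sd=20.0,
    ),
}


@dataclass
class Config:
    """All tunables of the nucleosome caller.

    Defaults are the ``sonicated`` preset; use :meth:`preset` to build either
    protocol preset, then override individual fields via
    :func:`dataclasses.replace` or a YAML file (:meth:`with_yaml_overrides`).
    """

    preset_name: str = "sonicated"

    # -- duplicate filtering ------------------------------------------------
    #: per-position duplicate cap = ceil of this quantile of the per-position
    #: duplicate-count distribution
    dup_quantile: float = 0.99

    # -- segmentation -------------------------------------------------------
    window_width: int = 150  #: sliding-window width w (bp)
    window_step: int = 10  #: step size s (bp)
    center_exclusion: int = 0  #: half-width c around the window centre (bp)
    min_reads: int = 2  #: minimum forward AND reverse reads per window/region
    max_region_length: int = 1200  #: recursive-split bound (bp)
    min_region_length: int = 100  #: regions shorter than this are dropped (bp)

    # -- spacing (GMRF) prior ----------------------------------------------
    delta0: float = 200.0  #: target centre-to-centre spacing (bp)
    rho_s: float = 1.0 / (2.0 * 25.0**2)  #: penalty strength (bp^-2)
    spacing_bounds: tuple[float, float] = (150.0, 250.0)  #: simulator rejection bounds

    # -- fragment-length / precision prior ---------------------------------
    xi: float = 200.0  #: prior mean fragment length (bp)
    kappa: float = 3.0  #: pseudo-count shrinking delta toward xi
    alpha: float = 2.0  #: Gamma shape for read-position precision
    beta: float = 1800.0  #: Gamma rate for read-position precision (bp^2)
    nu: int = 4  #: Student-t degrees of freedom (fixed)

    # -- model search / EM --------------------------------------------------
    k_margin: int = 2  #: K searched in [E - margin, E + margin]
    tol: float = 1e-6  #: relative objective change declaring convergence
    max_iter: int = 500
    restarts: int = 0  #: extra seeded jittered restarts (best objective kept)

    # -- post-fit sanity bounds ---------------------------------------------
    delta_bounds: tuple[float, float] = (80.0, 250.0)
    sigma_bounds: tuple[float, float] = (5.0, 150.0)
    merge_distance: float = 60.0  #: components closer than this are merged (bp)
    min_weight_factor: float = 0.05  #: per-fit weight floor = factor / K

    # -- scoring and density filtering --------------------------------------
    core_quantile: float = 0.90  #: two-sided t contour for core-read counting
    nb_radius: float = 500.0  #: neighbourhood radius for the NB filter (bp)
    nb_gap_threshold: float = 250.0  #: nucleosome-free gap breaking a neighbourhood (bp)
    nb_alpha: float = 0.01  #: NB lower-quantile significance level

    # -- TF-site classification ---------------------------------------------
    mono_dist: float = 50.0  #: centre within this of a summit -> monomodal (bp)
    none_dist: float = 1000.0  #: no centre within this -> NoNuc (bp)

    # -- evaluation ----------------------------------------------------------
    match_dist: float = 100.0  #: detection distance for reference matching (bp)
    spec_min: float = 0.8  #: ROC truncation specificity

    # -- simulation -----------------------------------------------------------
    sim_sigma_range: tuple[float, float] = (25.0, 40.0)  #: per-nucleosome read sd (bp)
    sim_delta_sd: float = 20.0  #: sd of simulated fragment lengths around xi (bp)
    reads_per_nucleosome: int = 150  #: reads per strand per nucleosome

    seed: Optional[int] = None

    # ------------------------------------------------------------------

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def preset(cls, name: str = "sonicated", **overrides) -> "Config":
        """Build the named protocol preset, optionally overriding fields."""
        if name not in _PRESET_OVERRIDES:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(_PRESET_OVERRIDES)}"
            )
        kwargs = dict(_PRESET_OVERRIDES[name])
        kwargs.update(overrides)
        return cls(preset_name=name, **kwargs)

    def with_yaml_overrides(self, path) -> "Config":
        """Return a copy with fields overridden from a YAML mapping."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(self)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        tuple_fields = {"spacing_bounds", "delta_bounds", "sigma_bounds", "sim_sigma_range"}
        data = {
            k: tuple(v) if k in tuple_fields and v is not None else v
            for k, v in data.items()
        }
        return replace(self, **data)

    def validate(self) -> None:
        if not (0.0 < self.dup_quantile <= 1.0):
            raise ValueError("dup_quantile must be in (0, 1]")
        for name in ("window_width", "window_step", "min_reads",
                     "max_region_length", "min_region_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.center_exclusion < 0:
            raise ValueError("center_exclusion must be >= 0")
        if self.nu != 4:
            raise ValueError("nu is fixed at 4")
        if self.rho_s <= 0 or self.delta0 <= 0 or self.xi <= 0:
            raise ValueError("spacing/fragment prior parameters must be positive")
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1 (finite prior mean variance)")
        if self.beta <= 0 or self.kappa < 0:
            raise ValueError("beta must be positive and kappa non-negative")
        if not (0.0 < self.core_quantile < 1.0):
            raise ValueError("core_quantile must be in (0, 1)")
        for name in ("spacing_bounds", "delta_bounds", "sigma_bounds", "sim_sigma_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lo < hi")
        if not (0.0 < self.nb_alpha <= 0.5):
            raise ValueError("nb_alpha must be in (0, 0.5]")
        if not (0.0 < self.spec_min < 1.0):
            raise ValueError("spec_min must be in (0, 1)")

    @property
    def min_weight(self) -> float:
        """Weight floor for a fit with K components is min_weight_factor / K."""
        return self.min_weight_factor

    @property
    def prior_delta_sd(self) -> float:
        """Implied prior standard deviation of the fragment length delta.

        The delta prior is Normal(xi, beta / (kappa * (alpha - 1))): the prior
        mean read-position variance beta/(alpha-1) divided by the pseudo-count
        kappa.
        """
        return (self.beta / (self.kappa * (self.alpha - 1.0))) ** 0.5
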