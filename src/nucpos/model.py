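"""Bidirectional Student-t mixture model with a spacing prior.

Each candidate region is modelled as a K-component mixture: nucleosome k has
centre ``mu_k`` and mean fragment length ``delta_k``, and its forward and
reverse 5' read positions are Student-t(4) distributed around
``mu_k - delta_k/2`` and ``mu_k + delta_k/2`` with strand-specific scales.
Centres carry a one-dimensional Gaussian Markov random field prior that pulls
successive spacings toward ``delta0``; fragment lengths and read-position
precisions carry a Normal/Gamma prior.

Fitting is an EM/MAP algorithm using the normal scale-mixture representation
of the t distribution (latent weights ``u = (nu+1)/(nu + d^2)``), with the
spacing prior incorporated exactly in the centre M-step as a symmetric
tridiagonal linear system. The number of components K is chosen by the
penalized log-likelihood (likelihood plus spacing prior) over a search range
bracketing the expected count ``region_length / delta0``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.special import logsumexp

from .config import Config
from .types import CandidateRegion, MixtureFit, NucleosomeComponent

logger = logging.getLogger(__name__)

#: log density of the standard t(4) at 0: Gamma(5/2) / (sqrt(4 pi) Gamma(2)) = 3/8
_LOG_T4_PEAK = math.log(3.0 / 8.0)
_NU = 4.0


class FitError(RuntimeError):
    """A mixture fit could not be completed for this K."""


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the spacing and fragment-length priors."""

    nu: int = 4
    delta0: float = 200.0
    rho_s: float = 1.0 / 1250.0
    xi: float = 200.0
    kappa: float = 3.0
    alpha: float = 2.0
    beta: float = 1800.0

    def __post_init__(self) -> None:
        if self.nu != 4:
            raise ValueError("nu is fixed at 4")
        if self.rho_s <= 0 or self.delta0 <= 0 or self.xi <= 0:
            raise ValueError("delta0, rho_s, xi must be positive")
        if self.alpha <= 1 or self.beta <= 0 or self.kappa < 0:
            raise ValueError("require alpha > 1, beta > 0, kappa >= 0")

    @classmethod
    def from_config(cls, cfg: Config) -> "PriorSpec":
        return cls(nu=cfg.nu, delta0=cfg.delta0, rho_s=cfg.rho_s, xi=cfg.xi,
                   kappa=cfg.kappa, alpha=cfg.alpha, beta=cfg.beta)

    @property
    def delta_prior_precision(self) -> float:
        """Precision of the Normal prior on delta: kappa / (beta/(alpha-1))."""
        return self.kappa * (self.alpha - 1.0) / self.beta


@dataclass
class ParamSet:
    """Mixture parameters as parallel arrays, ordered by mu."""

    w: np.ndarray
    mu: np.ndarray
    delta: np.ndarray
    var_f: np.ndarray
    var_r: np.ndarray

    @property
    def K(self) -> int:
        return int(self.mu.size)

    def sort_by_mu(self) -> "ParamSet":
        order = np.argsort(self.mu, kind="stable")
        return ParamSet(self.w[order], self.mu[order], self.delta[order],
                        self.var_f[order], self.var_r[order])

    def copy(self) -> "ParamSet":
        return ParamSet(self.w.copy(), self.mu.copy(), self.delta.copy(),
                        self.var_f.copy(), self.var_r.copy())


@dataclass
class EStep:
    """Responsibilities and t latent scale weights for one region."""

    z_f: np.ndarray  # (n_f, K)
    u_f: np.ndarray
    z_r: np.ndarray  # (n_r, K)
    u_r: np.ndarray
    loglik: float


# ---------------------------------------------------------------------------
# densities and priors


def _log_t4_std(x: np.ndarray) -> np.ndarray:
    """log pdf of the standard Student t with 4 degrees of freedom."""
    return _LOG_T4_PEAK - 2.5 * np.log1p(np.square(x) / _NU)


def t4_density(x, center, sd):
    """Location-scale t(4) density: f((x - center)/sd) / sd."""
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    x = np.asarray(x, dtype=float)
    return np.exp(_log_t4_std((x - center) / sd)) / sd


def mixture_density(x, strand: str, fit: MixtureFit):
    """Mixture read-position density on one strand.

    Forward reads sit delta/2 upstream of the centre, reverse reads delta/2
    downstream; the mixture weights are shared between strands.
    """
    if strand not in ("fwd", "rev"):
        raise ValueError("strand must be 'fwd' or 'rev'")
    sign = -1.0 if strand == "fwd" else 1.0
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x, dtype=float)
    for c in fit.components:
        center = c.mu + sign * c.delta / 2.0
        sd = c.sigma_f if strand == "fwd" else c.sigma_r
        out += c.w * t4_density(x, center, sd)
    return out


def gmrf_logprior(mus, spec: PriorSpec) -> float:
    """Unnormalized log density of the chain spacing prior.

    ``-rho_s * sum_k (mu_k - mu_{k-1} - delta0)^2``; zero for K = 1.
    """
    mus = np.asarray(mus, dtype=float)
    if mus.size <= 1:
        return 0.0
    gaps = np.diff(mus)
    if np.any(gaps < 0):
        raise ValueError("mus must be sorted nondecreasing")
    return float(-spec.rho_s * np.sum((gaps - spec.delta0) ** 2))


def _log_param_priors(params: ParamSet, spec: PriorSpec) -> float:
    """Log prior terms for delta and the strand precisions (constants dropped).

    delta_k ~ Normal(xi, beta / (kappa (alpha-1))); precisions
    lambda = 1/var ~ Gamma(alpha, beta), contributing
    (alpha-1) log lambda - beta lambda each.
    """
    out = -0.5 * spec.delta_prior_precision * float(np.sum((params.delta - spec.xi) ** 2))
    for var in (params.var_f, params.var_r):
        lam = 1.0 / var
        out += float(np.sum((spec.alpha - 1.0) * np.log(lam) - spec.beta * lam))
    return out


def penalized_objective(region: CandidateRegion, params: ParamSet,
                        spec: PriorSpec) -> float:
    """Full MAP objective: log-likelihood plus all log priors."""
    est = _e_step_arrays(region, params)
    return est.loglik + gmrf_logprior(params.mu, spec) + _log_param_priors(params, spec)


# ---------------------------------------------------------------------------
# E-step


def _strand_estep(x: np.ndarray, centers: np.ndarray, sd: np.ndarray,
                  w: np.ndarray):
    """Responsibilities, latent weights, standardized residuals, row log-evidence."""
    d = (x[:, None] - centers[None, :]) / sd[None, :]
    logp = np.log(w)[None, :] + _log_t4_std(d) - np.log(sd)[None, :]
    row_lse = logsumexp(logp, axis=1)
    bad = ~np.isfinite(row_lse)
    z = np.exp(logp - row_lse[:, None])
    if bad.any():
        logger.warning("%d read(s) underflowed all components; "
                       "uniform responsibilities assigned", int(bad.sum()))
        z[bad] = 1.0 / centers.size
        row_lse = np.where(bad, np.max(logp, axis=1), row_lse)
    u = (_NU + 1.0) / (_NU + np.square(d))
    return z, u, row_lse


def _e_step_arrays(region: CandidateRegion, params: ParamSet) -> EStep:
    f = region.fwd.astype(float)
    r = region.rev.astype(float)
    sd_f = np.sqrt(params.var_f)
    sd_r = np.sqrt(params.var_r)
    z_f, u_f, lse_f = _strand_estep(f, params.mu - params.delta / 2.0, sd_f, params.w)
    z_r, u_r, lse_r = _strand_estep(r, params.mu + params.delta / 2.0, sd_r, params.w)
    return EStep(z_f, u_f, z_r, u_r, float(lse_f.sum() + lse_r.sum()))


def e_step(region: CandidateRegion, fit: MixtureFit) -> EStep:
    """E-step quantities for a fitted model (public wrapper on components)."""
    params = params_from_components(fit.components)
    return _e_step_arrays(region, params)


def params_from_components(components: list[NucleosomeComponent]) -> ParamSet:
    return ParamSet(
        w=np.array([c.w for c in components], dtype=float),
        mu=np.array([c.mu for c in components], dtype=float),
        delta=np.array([c.delta for c in components], dtype=float),
        var_f=np.array([c.var_f for c in components], dtype=float),
        var_r=np.array([c.var_r for c in components], dtype=float),
    )


def components_from_params(params: ParamSet) -> list[NucleosomeComponent]:
    return [NucleosomeComponent(w=float(params.w[k]), mu=float(params.mu[k]),
                                delta=float(params.delta[k]),
                                var_f=float(params.var_f[k]),
                                var_r=float(params.var_r[k]))
            for k in range(params.K)]


# ---------------------------------------------------------------------------
# M-steps


def _solve_centers(region: CandidateRegion, est: EStep, params: ParamSet,
                   spec: PriorSpec) -> np.ndarray:
    """Raw tridiagonal solution of the centre stationarity system, in the
    current component labelling (not sorted)."""
    K = params.K
    f = region.fwd.astype(float)
    r = region.rev.astype(float)
    Wf = est.z_f * est.u_f
    Wr = est.z_r * est.u_r
    SWf = Wf.sum(axis=0)
    SWr = Wr.sum(axis=0)
    # data precision and recentred-read weighted sums per component
    A = SWf / params.var_f + SWr / params.var_r
    b = ((Wf.T @ f) + SWf * params.delta / 2.0) / params.var_f \
        + ((Wr.T @ r) - SWr * params.delta / 2.0) / params.var_r
    rho = spec.rho_s
    if K == 1:
        if A[0] <= 0:
            raise FitError("no effective reads for the single component")
        return np.array([b[0] / A[0]])
    n_nb = np.full(K, 2.0)
    n_nb[0] = n_nb[-1] = 1.0
    diag = A + 2.0 * rho * n_nb
    c = b.copy()
    c[1:] += 2.0 * rho * spec.delta0   # has a lower neighbour
    c[:-1] -= 2.0 * rho * spec.delta0  # has an upper neighbour
    ab = np.zeros((2, K))
    ab[0, 1:] = -2.0 * rho
    ab[1, :] = diag
    try:
        mu = solveh_banded(ab, c, lower=False)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular centre-update system") from exc
    if not np.all(np.isfinite(mu)):
        raise FitError("non-finite centre update")
    return mu


def m_step_centers(region: CandidateRegion, est: EStep, params: ParamSet,
                   spec: PriorSpec) -> np.ndarray:
    """Joint MAP update of all centres.

    Each centre has a quadratic data term (forward reads inform
    ``mu_k - delta_k/2``, reverse reads ``mu_k + delta_k/2``, weighted by
    ``z * u / var``) plus the spacing prior coupling adjacent centres; the
    stationarity conditions form a symmetric tridiagonal system solved
    exactly. Output is sorted (components relabel if the solution crosses).
    """
    return np.sort(_solve_centers(region, est, params, spec))


def m_step_rest(region: CandidateRegion, est: EStep, params: ParamSet,
                spec: PriorSpec,
                delta_bounds: tuple[float, float] = (1.0, np.inf),
                sigma_bounds: tuple[float, float] = (1e-3, np.inf)) -> ParamSet:
    """MAP updates of weights, fragment lengths and strand variances.

    ``delta`` blends the data's forward/reverse offset estimate with the
    prior mean ``xi`` (pseudo-count ``kappa``); variances are the Gamma-prior
    MAP ``(2 beta + weighted SSE) / (2 alpha + eff_count - 2)``. Bounds are
    enforced by clipping, which is the exact constrained maximizer of each
    concave conditional objective.
    """
    f = region.fwd.astype(float)
    r = region.rev.astype(float)
    Wf = est.z_f * est.u_f
    Wr = est.z_r * est.u_r
    SWf = Wf.sum(axis=0)
    SWr = Wr.sum(axis=0)
    Tf = Wf.T @ f
    Tr = Wr.T @ r
    Nf = est.z_f.sum(axis=0)
    Nr = est.z_r.sum(axis=0)
    n_total = region.n_fwd + region.n_rev
    w = (Nf + Nr) / n_total
    w = np.maximum(w, 1e-12)
    w = w / w.sum()

    prior_prec = spec.delta_prior_precision
    num = (SWf * params.mu - Tf) / (2.0 * params.var_f) \
        + (Tr - SWr * params.mu) / (2.0 * params.var_r) \
        + prior_prec * spec.xi
    den = SWf / (4.0 * params.var_f) + SWr / (4.0 * params.var_r) + prior_prec
    delta = np.where(den > 0, num / np.where(den > 0, den, 1.0), params.delta)
    delta = np.clip(delta, delta_bounds[0], delta_bounds[1])

    cf = params.mu - delta / 2.0
    cr = params.mu + delta / 2.0
    sse_f = np.einsum("ik,ik->k", Wf, np.square(f[:, None] - cf[None, :]))
    sse_r = np.einsum("ik,ik->k", Wr, np.square(r[:, None] - cr[None, :]))
    var_f = (2.0 * spec.beta + sse_f) / (2.0 * spec.alpha + Nf - 2.0)
    var_r = (2.0 * spec.beta + sse_r) / (2.0 * spec.alpha + Nr - 2.0)
    lo, hi = sigma_bounds[0] ** 2, sigma_bounds[1] ** 2
    var_f = np.clip(var_f, lo, hi)
    var_r = np.clip(var_r, lo, hi)
    return ParamSet(w=w, mu=params.mu.copy(), delta=delta, var_f=var_f, var_r=var_r)


# ---------------------------------------------------------------------------
# full fit


def _initial_params(region: CandidateRegion, K: int, cfg: Config,
                    rng: np.random.Generator | None = None) -> ParamSet:
    spec = PriorSpec.from_config(cfg)
    pooled = np.concatenate([region.fwd + spec.xi / 2.0,
                             region.rev - spec.xi / 2.0]).astype(float)
    qs = (np.arange(K) + 0.5) / K
    mu = np.quantile(pooled, qs)
    if rng is not None:
        mu = mu + rng.normal(0.0, spec.delta0 / 8.0, size=K)
    mu = np.sort(mu)
    # break exact ties so components start distinct
    for k in range(1, K):
        if mu[k] <= mu[k - 1]:
            mu[k] = mu[k - 1] + 1.0
    sd0 = float(np.clip(np.std(pooled) / max(K, 1),
                        cfg.sigma_bounds[0], cfg.sigma_bounds[1]))
    return ParamSet(
        w=np.full(K, 1.0 / K),
        mu=mu,
        delta=np.full(K, spec.xi),
        var_f=np.full(K, sd0 ** 2),
        var_r=np.full(K, sd0 ** 2),
    )


def _run_em(region: CandidateRegion, params: ParamSet, cfg: Config) -> MixtureFit:
    spec = PriorSpec.from_config(cfg)
    trace: list[float] = []
    prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        est = _e_step_arrays(region, params)
        obj = est.loglik + gmrf_logprior(params.mu, spec) + _log_param_priors(params, spec)
        if not np.isfinite(obj):
            raise FitError("non-finite penalized objective")
        trace.append(obj)
        if abs(obj - prev) < cfg.tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = obj
        # raw (label-consistent) centre update, so est columns still match
        mu = _solve_centers(region, est, params, spec)
        params = ParamSet(params.w, mu, params.delta, params.var_f, params.var_r)
        params = m_step_rest(region, est, params, spec,
                             delta_bounds=cfg.delta_bounds,
                             sigma_bounds=cfg.sigma_bounds)
        params = params.sort_by_mu()
    est = _e_step_arrays(region, params)
    final_obj = est.loglik + gmrf_logprior(params.mu, spec) + _log_param_priors(params, spec)
    trace.append(final_obj)
    # strictly increasing mus required downstream; nudge exact ties
    for k in range(1, params.K):
        if params.mu[k] <= params.mu[k - 1]:
            params.mu[k] = params.mu[k - 1] + 1e-6
    return MixtureFit(
        K=params.K,
        components=components_from_params(params),
        loglik=est.loglik,
        logpost_pen=est.loglik + gmrf_logprior(params.mu, spec),
        n_iter=n_iter,
        converged=converged,
        objective_trace=np.asarray(trace),
    )


def fit_region(region: CandidateRegion, K: int, cfg: Config,
               seed: int | None = None) -> MixtureFit:
    """Fit a K-component mixture to one region by EM/MAP.

    Deterministic given the data: centres initialize at evenly spaced
    quantiles of the pooled recentred reads. ``cfg.restarts`` adds seeded
    jittered restarts, keeping the best penalized objective.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if region.n_fwd < 1 or region.n_rev < 1:
        raise FitError("region needs at least one read per strand")
    best = _run_em(region, _initial_params(region, K, cfg), cfg)
    if cfg.restarts > 0:
        rng = np.random.default_rng(seed if seed is not None else cfg.seed)
        for _ in range(cfg.restarts):
            try:
                cand = _run_em(region, _initial_params(region, K, cfg, rng), cfg)
            except FitError:
                continue
            if cand.logpost_pen > best.logpost_pen:
                best = cand
    return best


def k_search_range(region: CandidateRegion, cfg: Config) -> range:
    """Integer K values to try: a margin around the expected count
    ``region_length / delta0``, capped at one read per strand per component."""
    expected = max(1, round(region.length / cfg.delta0))
    lo = max(1, expected - cfg.k_margin)
    hi = expected + cfg.k_margin
    cap = max(1, min(region.n_fwd, region.n_rev))
    hi = min(hi, cap)
    lo = min(lo, hi)
    return range(lo, hi + 1)


def select_K(fits: list[MixtureFit], spec: PriorSpec) -> MixtureFit:
    """Pick the fit with the largest penalized log-likelihood
    (log-likelihood + spacing prior); ties go to the smaller K."""
    if not fits:
        raise ValueError("need at least one candidate fit")
    best = None
    best_obj = -np.inf
    for fit in sorted(fits, key=lambda f: f.K):
        obj = fit.loglik + gmrf_logprior(fit.mus, spec)
        if obj > best_obj:
            best, best_obj = fit, obj
    return best


def postfit_filter(fit: MixtureFit, cfg: Config,
                   n_reads: int | None = None) -> MixtureFit:
    """Remove noisy components and merge near-duplicates.

    Drops components with weight below ``min_weight_factor / K``, fragment
    length or scale outside the configured bounds, or (when ``n_reads`` is
    given) effective read support below one. Pairs of components closer than
    ``merge_distance`` merge into the higher-weight member's shape with
    summed weight. Weights renormalize to one.
    """
    min_w = cfg.min_weight_factor / max(fit.K, 1)
    comps = []
    for c in fit.components:
        if c.w < min_w:
            continue
        if not (cfg.delta_bounds[0] <= c.delta <= cfg.delta_bounds[1]):
            continue
        if not (cfg.sigma_bounds[0] <= c.sigma_f <= cfg.sigma_bounds[1]):
            continue
        if not (cfg.sigma_bounds[0] <= c.sigma_r <= cfg.sigma_bounds[1]):
            continue
        if n_reads is not None and c.w * n_reads < 1.0:
            continue
        comps.append(NucleosomeComponent(c.w, c.mu, c.delta, c.var_f, c.var_r))
    comps.sort(key=lambda c: c.mu)
    merged = True
    while merged and len(comps) > 1:
        merged = False
        for i in range(len(comps) - 1):
            a, b = comps[i], comps[i + 1]
            if abs(b.mu - a.mu) < cfg.merge_distance:
                keep = a if a.w >= b.w else b
                comps[i] = NucleosomeComponent(a.w + b.w, keep.mu, keep.delta,
                                               keep.var_f, keep.var_r)
                del comps[i + 1]
                merged = True
                break
    total = sum(c.w for c in comps)
    if total > 0:
        for c in comps:
            c.w /= total
    spec_gmrf = PriorSpec.from_config(cfg)
    mus = np.array([c.mu for c in comps])
    return MixtureFit(
        K=len(comps), components=comps, loglik=fit.loglik,
        logpost_pen=fit.loglik + gmrf_logprior(mus, spec_gmrf),
        n_iter=fit.n_iter, converged=fit.converged,
        objective_trace=fit.objective_trace,
    )


def fit_region_auto(region: CandidateRegion, cfg: Config,
                    seed: int | None = None) -> MixtureFit | None:
    """Search K, fit each candidate, select by penalized likelihood, and
    apply the post-fit filter. Returns None when every candidate K fails."""
    spec = PriorSpec.from_config(cfg)
    fits = []
    for K in k_search_range(region, cfg):
        try:
            fits.append(fit_region(region, K, cfg, seed=seed))
        except FitError as exc:
            logger.debug("region %s:%d-%d K=%d failed: %s",
                         region.chrom, region.start, region.end, K, exc)
    if not fits:
        logger.warning("region %s:%d-%d: all candidate fits failed",
                       region.chrom, region.start, region.end)
        return None
    best = select_K(fits, spec)
    return postfit_filter(best, cfg, n_reads=region.n_fwd + region.n_rev)
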