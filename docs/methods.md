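# Methods

This note documents the statistical model behind `nucpos`, the defaults and
why they were chosen, the numerical details of the fitting algorithm, what
the built-in simulator does and does not emulate, and known limitations.

## Data model

The unit of evidence is the 5' position of a single-end aligned read:
`chromStart` on the forward strand, `chromEnd − 1` on the reverse strand
(BED `end` is exclusive; all coordinates are 0-based half-open). A
nucleosome protects ~147 bp; sequencing its flanking fragment ends places
forward reads upstream and reverse reads downstream of the dyad, offset by
the library's fragment length. The bidirectional geometry — not a single
pile-up — is what the model exploits.

### Preprocessing

- **Duplicate capping.** Per-position read multiplicities are capped at the
  ceiling of the `dup_quantile` empirical quantile of the per-position
  duplicate-count distribution (never below 1). MNase concentrates genuine
  fragment starts at nucleosome edges, so its cap is looser (0.999) than
  the sonicated preset's (0.99). The operation is idempotent.
- **Segmentation.** A `w = 150` bp window slides by `s = 10` bp; a window
  is retained when its left half holds ≥ `min_reads = 2` forward reads and
  its right half ≥ 2 reverse reads (an optional exclusion radius `c` around
  the centre is off by default). The right half-window includes its right
  edge, so a forward/reverse pair separated by exactly `w` is still
  detected. Overlapping retained windows merge into disjoint candidate
  regions.
- **Recursive splitting.** Regions longer than `max_region_length =
  1200` bp (≈ six nucleosome repeats, bounding the mixture size) are split
  at the midpoint of the widest read gap whose midpoint lies in the central
  third of the region; restricting splits to the central third guarantees
  geometric shrinkage and hence termination. A split that would leave a
  strand with fewer than `min_reads` on either side is skipped in favour of
  the next-widest gap; if none works the region is kept whole with a
  warning.

### Mixture model

Within a region with `K` nucleosomes, forward positions `f_i` and reverse
positions `r_j` are i.i.d. from

    f ~ Σ_k w_k t4(μ_k − δ_k/2, σ²_fk),    r ~ Σ_k w_k t4(μ_k + δ_k/2, σ²_rk).

- `t4` is the location-scale Student t with ν = 4: heavy enough tails to
  absorb stray reads, light enough to keep the centre estimate efficient.
- The mixture weight `w_k` is shared between strands because a fragment is
  equally likely to be sequenced from either end.
- `σ_fk` and `σ_rk` are *not* constrained equal; mappability and library
  biases routinely skew one strand's spread.

### Priors

- **Spacing (centres).** `log p(μ) = −ρ_s Σ (μ_k − μ_{k−1} − δ0)²` with
  `δ0 = 200` bp and `ρ_s = 1/(2·25²) bp⁻²`, i.e. a chain-conditional spacing
  standard deviation of 25 bp, putting ±2 sd at roughly 150–250 bp —
  permissive enough for closely spaced alternative positioning and short
  linkers. The form is the standard unnormalized pairwise 1-D Gaussian
  Markov random field; no boundary term is added for the first/last
  nucleosome.
- **Fragment length.** `δ_k ~ Normal(ξ, β/(κ(α−1)))`. The prior scale is
  fixed at the prior-mean read-position variance `β/(α−1)` divided by the
  pseudo-count `κ`, rather than coupled to the per-component precision;
  this keeps every conditional M-step an exact closed form (see below)
  while preserving the two limits that define the prior's role: `κ → 0`
  gives the pure data estimate, `κ → ∞` pins `δ = ξ`.
- **Precisions.** `1/σ² ~ Gamma(α, β)` per strand.

Preset hyperparameters:

| preset | ξ (bp) | κ | α | β (bp²) | implied δ range (±2 sd) | duplicate cap |
|---|---|---|---|---|---|---|
| mnase | 150 | 5 | 2 | 800 | ≈ 125–175 | 0.999 |
| sonicated | 200 | 3 | 2 | 1800 | ≈ 150–250 | 0.99 |

β was set from a typical read-position spread (prior mean variance
`β/(α−1)` ≈ 28² bp² for MNase, ≈ 42² for sonication) and κ chosen so the
implied δ ranges match the tight-MNase / broad-sonication regimes above.
All are user-tunable.

## Fitting

EM/MAP with the normal scale-mixture representation of the t distribution:
the E-step computes responsibilities `z_ik` and latent scale weights
`u_ik = (ν+1)/(ν + d²_ik)` with `d` the standardized residual.

The M-step is expectation–conditional-maximization, each step an exact
maximizer given the others:

1. **Centres, jointly.** Each `μ_k` has a quadratic data term (forward
   reads inform `μ_k − δ_k/2`, reverse reads `μ_k + δ_k/2`, weights
   `z·u/σ²`) plus the spacing prior coupling neighbours. The stationarity
   conditions form a symmetric positive-definite tridiagonal system, solved
   with a banded Cholesky solve. Components are relabelled in centre order
   afterwards.
2. **Fragment lengths.** The quadratic MAP blend of the two strands' offset
   estimates with the prior mean ξ at pseudo-precision `κ(α−1)/β`.
3. **Variances.** `σ² = (2β + SSE_w) / (2α + n_eff − 2)` per strand, the
   Gamma-prior MAP in the precision, with `SSE_w` the `z·u`-weighted squared
   residuals and `n_eff` the responsibility mass.
4. **Weights.** Normalized responsibility masses over both strands.

Bounds (`delta_bounds = (80, 250)` bp, `sigma_bounds = (5, 150)` bp) are
enforced by clipping inside the M-step; because each conditional objective
is concave in the clipped scalar, the clip is the exact constrained
maximizer and the MAP objective (likelihood + all priors) remains monotone
nondecreasing across iterations — asserted in the test suite to a relative
1e−8.

**Initialization** is deterministic: centres at evenly spaced quantiles of
the pooled recentred reads (forward + ξ/2, reverse − ξ/2), `δ = ξ`, equal
weights, variances from the pooled spread. A `restarts` knob adds seeded
jittered restarts keeping the best objective. **Convergence**: relative
objective change < 1e−6, cap 500 iterations.

**Model selection.** K runs over `[E − 2, E + 2] ∩ [1, min(n_fwd, n_rev)]`
with `E = max(1, round(length/δ0))`; the fit maximizing the
likelihood-plus-spacing-prior objective wins, ties to the smaller K.
Degenerate or singular fits for a particular K are skipped.

**Post-fit correction.** Components with weight below `0.05/K`, effective
read support below one, or δ/σ outside the bounds are dropped; pairs of
centres closer than 60 bp merge into the higher-weight member's shape with
summed weight; weights renormalize.

## Scoring and filtering

- **Core reads**: counts inside the two-sided 90% contour of each strand's
  fitted t density (`centre ± t4⁻¹(0.95)·σ`), trimming outliers before
  density is measured.
- **Score** = `(n_f + n_r)/(σ_f + σ_r)` in reads/bp — width-normalized so
  diffuse fits do not outrank sharp ones.
- **Control-relative score** counts control reads in the *same* contours:
  `[(n_f + n_r)/(n_f^c + n_r^c + 1)]·(N_ctrl/N_chip)`; the +1 guards empty
  control windows.
- **Empirical FDR** at score s:
  `min(1, #{control calls ≥ s}/#{treatment calls ≥ s} · N_chip/N_ctrl)`,
  made monotone by a cumulative minimum over thresholds ≤ s; control calls
  come from running the identical pipeline on the control sample.
- **Low-density removal.** Each call is compared to neighbours within
  500 bp (neighbourhoods break at nucleosome-free gaps > 250 bp, the δ
  upper bound). Given a neighbour with count `N` and the width ratio
  `s_ref/s_nb` of the two calls, the reference's count is expected
  `m = N·s_ref/s_nb` under equal density; the call is removed when its
  count falls below the α = 0.01 quantile of a negative binomial with mean
  m and size N (variance `m + m²/N`). Flags are computed against the
  unfiltered set in one pass, so the outcome is order-independent. This
  screen is a pre-classification cleanup: positional benchmarking uses the
  scored calls before it (see below).

## Downstream classification

Summits with a confident nucleosome centre within 50 bp are **monomodal**
(binding within nucleosomal DNA); summits with no centre within 1 kb are
**NoNuc**; the rest are **bimodal**. "Confident" means surviving the
low-density screen plus a score cutoff at the elbow of the sorted-score
curve (the point of maximum distance to the chord in the unit square, an
explicit form of the usual elbow heuristic). Gene labels take the best site:
bimodal > monomodal > NoNuc. Occupancy profiles place a 30-bp-sd Gaussian
kernel at each centre, weighted by score relative to the set maximum;
summit-versus-dyad histograms use 1-bp bins truncated at ±100 bp with
reference marks at ±73 bp (half the core).

## Evaluation harness

`subsample_reads` draws without replacement from the pooled read list;
`match_to_reference` marks a reference *detected* if any call is within the
matching distance (100 bp sonicated, 50 bp MNase) and labels calls
one-to-one by greedy ascending distance; `truncated_roc_auc` integrates the
ROC over 1 − specificity ∈ [0, 0.2] with linear interpolation at the cut,
ceiling 0.2, chance level 0.02.

The depth benchmark (`pipeline.depth_benchmark`) designates the top half of
simulated truths by read density as the reference set, mirroring benchmark
designs that rank against the best-supported positions: calls at genuine
but weaker nucleosomes then populate the negative axis, and sensitivity is
measured over the reference set (missed references enter the ROC as
positives below every attained score). Without this, a precise caller
yields almost no negatives and the truncated AUC is undefined or unstable.
The default problem size is 20 regions × 10 seeds (≈ 500 nucleosomes per
fraction), enough for a stable four-point depth curve.

## Simulator

`simulate.make_dataset` draws nucleosome arrays from the model itself:
spacings `δ0 + Normal(0, 1/√(2ρ_s))` rejection-sampled into 150–250 bp;
per-nucleosome fragment lengths `Normal(ξ, sd)` (sd 10 bp MNase / 20 bp
sonicated, clipped to ±3 sd within the δ bounds); strand scales drawn
uniformly from 15–25 bp (MNase) or 25–40 bp (sonicated); 150 reads per
strand per nucleosome by default, positions `μ ∓ δ/2 + σ·t4` rounded to
integers; regions separated by read-free gaps wider than the split bound.
Datasets regenerate bit-exactly from their JSON manifest.

What it deliberately does **not** emulate: background/unstructured reads,
sequencing errors, mappability gaps, GC bias, copy-number variation, or
correlated occupancy between neighbouring nucleosomes. Consequently the
caller's precision on simulated data (essentially no false calls at any
depth) overstates what real data allows, and tests passing here certify the
estimation machinery, not robustness to artefacts. One visible consequence:
because every simulated nucleosome has the same read count while widths
vary, the negative-binomial screen removes a ~10% tail of genuinely wider,
hence lower-density, calls — on real data those would be the weak calls it
exists to remove.

## Numerical choices and tie-breaks

- Hot-loop t4 log-density is the closed form `log(3/8) − 2.5·log1p(x²/4)`
  (checked against `scipy.stats.t`).
- NB quantiles via `scipy.stats.nbinom.ppf`; the test oracle inverts the
  CDF in exact rational arithmetic so boundary cases (CDF exactly α)
  resolve unambiguously.
- Reads whose density underflows every component get uniform
  responsibilities and a warning.
- Ties: model selection prefers the smaller K; merging keeps the
  higher-weight member; matching breaks distance ties by leftmost
  reference, then leftmost prediction; duplicate caps never drop a
  position's first read.
- Empty strands, empty regions, and all-components-filtered fits yield
  empty results, never errors, except where a contract explicitly demands
  an error (e.g. zero ChIP depth).

## Limitations

- Single-end 5' positions only; no paired-end fragment reconstruction.
- MAP point estimates; no posterior sampling or interval reporting.
- No mappability-aware read imputation; unmappable stretches simply look
  read-free.
- The empirical FDR needs a control whose read geometry resembles
  nucleosomal data; input DNA controls yield very few calls and hence
  uninformative FDRs.
- Genome-scale parallelism is left to the caller (regions are independent;
  a process pool over chromosomes suffices).
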