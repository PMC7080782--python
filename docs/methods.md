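# Methods

This note documents the models implemented in `assemblage`, the
assumptions behind them, the defaults of the synthetic-experiment
generator, and the numerical choices made where the design was open.

## Time coordinate

Days are integers; transfer index `t = day / transfer_interval_days`
(default interval 3 days), so Day 0 is transfer 0 — the pre-transfer
inoculum — and Day 63 is transfer 21. The extinction clock starts at
**transfer 1 (Day 3)**, not Day 0: losses between Day 0 and Day 3 are
initial adjustment to the laboratory environment (inactive or
non-growing organisms washing out), not part of the assembly process the
extinction model describes. ASVs detected only at Day 0 are therefore
excluded from extinction records, and richness-decay curves are
normalized by the transfer-1 value.

## Detection-limit back-fill

Amplicon sampling misses rare ASVs, so raw absence is not extinction.
Richness and extinction records use back-filled presence: an ASV
detected at any later timepoint of a microcosm counts as present now.
Back-filled richness is non-increasing by construction, and an
"extinction" is a **permanent** absence. ASVs detected at the final
transfer are right-censored — their extinction time is unobserved.

## Geometric extinction model

For ASVs destined to go extinct, a constant per-transfer hazard *p*
gives `P(T = t) = p(1 − p)^(t−1)` on t = 1, 2, …, with MLE
`p̂ = 1/mean(t)`. Censored (surviving) ASVs never enter the likelihood:
the model is explicitly conditional on eventual extinction. This is a
deliberate modeling stance, not an approximation — the alternative
(one distribution with censoring contributions) would conflate the
survival fraction with the rate.

Model comparison uses the criterion `B_k = ln(n)·k − 𝓛` with *n* = the
number of microcosms and *k* the number of rate parameters (1 shared, or
one per microcosm); smaller wins, and `exp(ΔB/2)` is the relative
likelihood. Note two departures from the textbook BIC: the penalty uses
the number of *groups* rather than observations, and the likelihood
enters on the 𝓛 scale rather than 2𝓛. `compare_extinction_models(...,
conventional=True)` provides the textbook form (`ln(N)k − 2𝓛`, *N* =
pooled observations); both select the same model in all regimes we
simulate, because the likelihood term dominates whenever rates genuinely
differ.

Goodness of fit is a Pearson chi-squared over per-transfer bins with an
explicit open tail bin carrying the remaining geometric mass; the right
tail is pooled until every expected count is ≥ 5 (standard practice —
no binning rule is canonical here) and df = bins − 2 for the one
estimated parameter (floored at 1 when an external rate leaves only two
bins).

The expected richness-decay curve combines both estimates:
`E[relative richness](t) = s + (1 − s)(1 − p)^t`, with *s* the censored
fraction of the pooled baseline pool.

## CLR and trajectory correlations

Per microcosm, ASVs never observed there are removed (they carry no
information about that community), one pseudo-read is added to every
retained count (accounting for abundances below the detection
threshold), and each timepoint is centered on its mean log count. With
`pseudocount=0` the transform is exactly scale-invariant per timepoint;
with the default pseudo-read it is approximately so at realistic depths.

Correlations of the same ASV's CLR series are computed for every
microcosm pair sharing ≥ 3 sampled days, categorized as
same-inoculum (replicate pair), different-inoculum, or random-pair
(distinct ASVs in different microcosms, count-matched and seeded).
Zero-variance series are skipped, not scored 0 — Pearson is undefined
there and silent zeros would bias the density. The summary "mode" is the
argmax of a Silverman-bandwidth Gaussian KDE on a fixed 512-point grid
over [−1, 1] (the estimator is unspecified in the literature this
mirrors; any reasonable KDE gives the same peak to grid resolution).

**Persistence filter.** Only ASVs detected past the equilibration day
(default Day 21) in *both* series of a pair are compared. Early-extinct
ASVs all share one near-deterministic trajectory — a decline to the
detection floor followed by a constant-at-zero segment whose CLR value
drifts with community richness — and including them drives every
category's density toward the same spurious positive mass, erasing the
category structure the analysis is meant to expose. The filter is a
parameter (`persistence_day=None` disables it).

## Composition–trajectory coupling

Per microcosm pair: *x* = mean Bray–Curtis between post-equilibration
compositions (days > 21, configurable to final-day-only; "final
composition" is otherwise undefined), *y* = mean cosine distance between
the pair's shared-ASV relative-abundance series (cosine similarity is
scale-free and timepoints where one series is zero contribute nothing to
the inner product — which is why it is used on the untransformed
series). The fit is `y = βx` with no intercept, and R² is computed
against the uncentered total sum of squares (with no intercept the
centered R² can be negative and is not comparable).

## Shared-fate null

If an ASV's fate were redrawn fairly in every community, the chance of
one fate across all *n* occupied microcosms is `f^(n−1)` with f = 0.5.
Observed all-same-fate fractions per occupancy level are compared with
an exact one-sided binomial test.

## Mantel and PROTEST

Both permutation tests are one-tailed for positive association and use
the add-one rule `p = (1 + #{permuted ≥ observed}) / (n_perm + 1)`, so
the attainable minimum is `1/(n_perm + 1)` — defaults of 9999 (Mantel)
and 999 (Procrustes) make p = 10⁻⁴ and 10⁻³ reachable. Mantel r is the
Pearson correlation of strictly-lower-triangle entries (Spearman
available behind a flag); the implementation exploits the fact that a
joint row/column permutation merely permutes the triangle entries, so
the permuted correlation reduces to a gather plus a dot product.
Procrustes configurations are centered and scaled to unit sum of
squares; `m12² = 1 − (Σ singular values)²` of the cross-product, and
correlation = √(1 − m12²). Two-point configurations superimpose
trivially and are flagged with a warning. Cross-checks against
scikit-bio's Mantel and scipy's Procrustes disparity are part of the
test suite.

## Ordination

The default is classical scaling (PCoA): deterministic and exact on
Euclidean input, which makes downstream Procrustes tests reproducible
without seeds. Negative eigenvalues (Bray–Curtis is non-Euclidean) are
dropped and counted in the result — no Cailliez correction, the
simplest defensible default. Non-metric MDS (Kruskal stress-1, seeded
random restarts, best of `n_restarts`) is available via
`ordinate(..., method="nmds")` for parity with vegan-style workflows.

## Synthetic-experiment generator

The generator emulates the study design so every stage has a recovery
test. Defaults (all overridable in `SyntheticConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `n_inocula` / `paired_treatments` | 10 / true | 10 source communities, each as a filtered/unfiltered replicate pair |
| `n_transfers` / `transfer_interval_days` | 21 / 3 | Day 0 plus 21 transfers, 3-day cadence |
| `pool_size` | 300 | regional ASV pool |
| `initial_richness_range` | 20–80 | per-microcosm richness at transfer 1 |
| `day0_transient_fraction` | 1.0 | extra Day-0-only ASVs, as a fraction of initial richness |
| `survival_fraction` (s) | 0.5 | probability an ASV persists indefinitely |
| `extinction_rate` (p) | 0.3 | shared geometric hazard for doomed ASVs |
| `replicate_fate_agreement` | 0.9 | replicate redraws its fate with prob 0.1 |
| `fate_identity_correlation` | 0.3 | correlation of one ASV's fates across inocula (Beta propensity) |
| `replicate_correlation` / `context_correlation` | 0.95 / 0.3 | innovation correlation within replicate pairs / across inocula |
| `walk_reversion` / `walk_noise` | 0.4 / 0.5 | mean-reverting latent log-abundance walk |
| `read_depth` | 50 000 | multinomial reads per sample |
| `n_substrates` / `substrate_sparsity` / `function_noise` | 31 / 0.3 / 0.05 | sparse per-ASV substrate vectors; Gaussian profile noise (OD units) |
| `co2_level` / `co2_sd_day0` / `co2_sd_later` | 2.0 / 0.8 / 0.1 %CO₂ | respiration converges after Day 0 |

Construction, in order: heavy-tailed (lognormal σ = 1.5) occupancy
weights make most ASVs occur in ≤ 2 microcosms while a few core ASVs
occur in most, and (optionally) couple occupancy to mean abundance;
fates come from a per-ASV Beta survival propensity with mean *s* and
variance `c·s(1−s)` so the same ASV's fates correlate at *c* across
inocula while the marginal stays exactly *s*; doomed ASVs draw a
truncated-geometric extinction transfer (redraw above `n_transfers` —
truncation, not censoring, keeps ground-truth fates binary); survivors
follow `l(t+1) = l(t) + θ(μ − l) + σε` with innovations mixed as
`√ρ·shared + √(1−ρ)·own` at the inoculum and replicate level, so the
stated ρ values *are* the innovation correlations; doomed ASVs ramp
log-linearly from their initial latent to a floor four log-units below
the community mean at their extinction transfer and are absent after —
the floor keeps the last pre-extinction abundance well above the
detection limit at the default depth, so recovered extinction times
match ground truth essentially exactly; compositions close by softmax
over present ASVs; reads are multinomial; substrate profiles are
`relative abundance × sparse ASV substrate matrix + noise, clipped at 0`;
enzyme activities are zero for most ASVs and lognormal for a
20% "hydrolytic" minority. One `numpy.random.Generator`, seeded once per
experiment, drives everything.

**What the generator does not emulate** — and what passing recovery
tests therefore do not establish about real data: no ecological
interactions (no consumer–resource or Lotka–Volterra dynamics, no
priority effects beyond the statistical fate correlations), no
protozoan predation or evolution, no taxonomic or phylogenetic
structure, no primer/copy-number bias, and survivor trajectories follow
a statistical stand-in walk whose only purpose is tunable correlation
structure. Absolute correlation levels in the synthetic data sit higher
than in real experiments because all survivors share the richness-decay
drift; the *ordering* of categories, not the levels, is the designed
target.

## Pipeline and seeds

`run_pipeline` expands the top-level seed via
`numpy.random.SeedSequence(seed).generate_state(4)` into sub-seeds for
(simulate, context, mantel, procrustes) — documented, collision-free,
and each below 2³¹. Reports are JSON with sorted keys; identical seeds
give byte-identical files. Headline statistics are computed on the
filtered arm (falling back to all series if no treatment labels match),
while trajectory correlations always use both arms — the replicate
category needs them.

## Problem sizes

Tests and the acceptance script run the full default design (10 inocula
× 2 treatments × 22 timepoints, pool 300, depth 50 000) — the design is
small by construction, so no down-scaling is needed; calibration tests
use 100–500 replicates at the sizes stated in their docstrings.

## Known limitations

* The conditional-on-extinction likelihood discards censoring-time
  information; a survival-analysis treatment (e.g. cure models) could
  use it but is out of scope.
* The BIC with *n* = number of microcosms is unusual; the conventional
  variant is provided, and conclusions agree in everything we simulate.
* PCoA drops negative eigenvalues; for strongly non-Euclidean
  dissimilarities the retained axes understate distances.
* The random-pair correlation null shares community-level drift with the
  same-ASV categories; it is a null for *ASV identity*, not for all
  temporal structure.
* `process_function_profiles` clips negative water-subtracted responses
  at 0 (count recorded); heavy clipping indicates assay problems the
  pipeline cannot fix.
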