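# assemblage

Analysis pipeline for **serially transferred microbial community time
series** — the kind of experiment in which ~10 natural communities
(e.g. from *Sarracenia purpurea* pitcher-plant fluid) are grown in
microcosms and diluted 1:1 into fresh medium every 3 days for 21
transfers, with 16S ASV composition, substrate-use fingerprints
(31-substrate EcoPlate assays), CO₂ respiration and per-strain enzyme
activities measured along the way.

It is written for microbial ecologists who want to ask, quantitatively:

* **How is diversity lost?** Is extinction a memoryless process with a
  single community-independent rate, or does each community need its own?
* **How contingent are trajectories on history?** Does an ASV behave the
  same way in every community it lands in, or does community context
  dominate?
* **Does composition predict function?** Are substrate-use profiles and
  enzyme activities coupled to who is there?

## The models at the core

**Geometric extinction null model.** For an ASV destined to go extinct,
assume a constant per-transfer extinction probability *p*, so its
extinction transfer *T* (counted from the first post-inoculation
transfer) is geometric:

    P(T = t) = p (1 − p)^(t−1),   t = 1, 2, …

with MLE *p̂* = 1 / t̄. ASVs still present at the final transfer are
right-censored and excluded from the likelihood (the model conditions on
eventual extinction); their fraction *s* is the survival fraction.
Whether one shared rate describes all microcosms is decided with a BIC
written on the log-likelihood scale,

    B_k = ln(n)·k − 𝓛(data | {p}_k),

with *k* rate parameters and *n* microcosms; the smaller *B* wins and
exp(ΔB/2) is the relative likelihood of the winner. The expected
richness-decay curve is then `s + (1 − s)(1 − p)^t`, compared against
back-filled richness (an ASV detected at any later timepoint counts as
present, correcting for the sequencing detection limit).

**Context dependence.** Count series are CLR-transformed per microcosm
(never-observed ASVs removed, one pseudo-read added), and Pearson
correlations of the same ASV's trajectory are compared across three
categories: replicate pairs started from the same inoculum, pairs from
different inocula, and a count-matched random-ASV null. Compositional
divergence (Bray–Curtis between equilibrated communities) is regressed —
intercept-free — against trajectory divergence (mean cosine distance of
shared-ASV abundance series). A shared-fate null model
`P(n) = f^(n−1)` tests whether an ASV found in *n* microcosms shares one
fate (survive vs go extinct) more often than coin-flipping predicts.

**Composition–function coupling.** Bray–Curtis matrices of composition
and of water-subtracted substrate profiles are compared with a seeded
one-tailed Mantel permutation test; ordinations of the final-day
communities are compared with Procrustes superposition (PROTEST
row-permutation significance); projected community enzyme activity is
Σₐ activity(a) × frequencyₐ(t).

**Synthetic experiments.** `assemblage.synthetic` generates full
experiments with known ground truth (fates, extinction transfers,
substrate vectors, activities): heavy-tailed ASV occupancy, Day-0
transients, geometric extinction times with a common rate,
mean-reverting latent walks whose innovations are correlated within
replicate pairs (0.95) and across inocula (0.3), multinomial read
sampling, and function profiles linear in composition. Every analysis
stage has a recovery test against this generator.

## Worked example

```python
from assemblage.pipeline import PipelineConfig, run_pipeline
from assemblage.synthetic import SyntheticConfig

summary = run_pipeline(PipelineConfig(simulate=SyntheticConfig(), seed=1))
```

selected output (deterministic for `seed=1`):

```
p_hat_common: 0.2860                  # pooled extinction rate (truth: 0.3)
survival_fraction: 0.5                # censored fraction (truth: 0.5)
equilibrium_relative_richness: 0.503  # ~50% of transfer-1 richness survives
bic_winner: common                    # one shared rate beats ten rates
relative_likelihood: 8915.0           # evidence ratio for the shared rate
richness_regression_r_squared: 0.937  # transfer-1 richness predicts final
correlation_mean_same_inoculum: 0.981 # replicate trajectories nearly identical
correlation_mean_different_inoculum: 0.735
correlation_mean_random_pair: 0.596   # context beats identity
coupling_r_squared: 0.987             # divergence in composition tracks
                                      # divergence in ASV dynamics
mantel_r: 0.628 (p = 1e-4)            # composition-function coupling
procrustes_correlation: 0.653 (p = 0.001)
```

Reading it: the pooled extinction-rate estimate and survival fraction
recover the generator's truth; the BIC comparison correctly prefers a
single shared extinction rate; trajectory correlations are ordered
replicate-pair > same-ASV-across-inocula > random, i.e. community
context, not ASV identity, drives dynamics; and function stays coupled
to composition.

The same stages are available from a shell:

```
assemblage simulate --seed 1 --out-dir data/
assemblage extinction --in data/abundance.tsv --out results/ext
assemblage run-all --seed 1 --out results/summary.json
```

## Layout

| module | contents |
| --- | --- |
| `assemblage.io` | domain types, long-TSV/CSV readers and writers, validation |
| `assemblage.synthetic` | seeded experiment generator with ground truth |
| `assemblage.extinction` | geometric model, BIC comparison, richness decay |
| `assemblage.diversity` | back-filled richness, Bray–Curtis, PCoA/NMDS |
| `assemblage.context` | CLR, trajectory correlations, coupling, shared fates |
| `assemblage.functional` | EcoPlate processing, Mantel, PROTEST, activity projection |
| `assemblage.pipeline` / `assemblage.cli` | orchestration and the `assemblage` command |

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
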