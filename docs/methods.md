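# Methods

## Model

Gene lengths are assumed to evolve by a multiplicative stochastic process:
at each elementary update a gene is chosen uniformly at random and its
length is multiplied by an independent draw of a positive random factor
ζ.  One *sweep* is N elementary updates for a population of N genes, so a
gene is updated once per sweep on average.  With time t counted in sweeps
the process implies, in expectation,

* exponential growth of the mean length, ⟨L(t)⟩ = L₀·exp((⟨ζ⟩−1)·t);
* linear growth of the mean log-length, ⟨log L(t)⟩ = G₀ + ⟨log ζ⟩·t;
* lognormal within-species length distributions (central limit theorem on
  log-length increments).

Here L₀ and G₀ are the mean and mean natural-log gene length of the
ancestral (LUCA) genome.  For lognormal species the moment identity
⟨L²⟩ = ⟨L⟩⁴·exp(−2⟨log L⟩) holds exactly; substituting the two growth
laws and eliminating t yields a Taylor fluctuation-scaling law

    ⟨L²⟩ = σ² + ⟨L⟩² = a·⟨L⟩^β,
    β = 4 − 2⟨log ζ⟩/(⟨ζ⟩−1),
    a = L₀^(4−β)·exp(−2·G₀).

The prefactor carries exp(2G₀) in the *denominator*: that is what the
lognormal moment algebra forces, and it is the only reading that
reproduces a = 0.21 from (L₀ = 554, G₀ = 6.18, β = 2.29).  The package
uses the reference constants L₀ = 554 bp, G₀ = 6.18, ⟨ζ⟩ = 1.00101,
⟨log ζ⟩ = 0.00087 (fitted against time in My, hence the calendar mapping
1 sweep = 1 My) and always reports them side by side with data-derived
estimates, never substituting one for the other.

Protein lengths track gene lengths at the 3:1 nucleotide-per-codon ratio
until a critical mean gene length L_c, beyond which the mean protein
length saturates at L_c/3 and genes grow by accumulating noncoding
sequence.  The noncoding fraction ρ = 1 − 3⟨Lp⟩/⟨L⟩ is then 0 below L_c
and 1 − L_c/⟨L⟩ above it — continuous at L_c with discontinuous slope
(0 vs 1/L_c), i.e. a second-order transition.  Interpreting evolution as a
search algorithm, the cost per unit of problem size is
τ(L) = t(L)/L = ln(L/L₀)/((⟨ζ⟩−1)·L); dτ/dL = 0 gives L_c = e·L₀ and,
inverting the mean growth law, t_c = 1/(⟨ζ⟩−1) ≈ 990 My after LUCA,
i.e. ≈ 2,600 My ago for a LUCA age of 3,600 My.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| L₀ | 554 | bp | ancestral mean gene length; sets L_c = e·L₀ |
| G₀ | 6.18 | — | ancestral mean log-length; sets the Taylor prefactor |
| ⟨ζ⟩ | 1.00101 | per sweep | mean growth factor; sets t_c = 1/(⟨ζ⟩−1) |
| ⟨log ζ⟩ | 0.00087 | per sweep | mean log growth factor; sets β |
| L_c | 1,500 | bp | protein plateau threshold (e·L₀ ≈ 1,506, quoted as 1,500) |
| LUCA age | 3,600 | My | calendar anchor for dates |
| ⟨L⟩_human | 68,287 | bp | two-stage simulation stopping mean |

The ζ distribution family is not dictated by the model; the default is
lognormal with m = ⟨log ζ⟩ and s² = 2(ln⟨ζ⟩ − ⟨log ζ⟩), the unique
lognormal matching both prescribed moments.  Fixed and uniform families
are available for controlled tests.

## Synthetic ensemble

A synthetic species at time t draws its gene lengths i.i.d. from
LogNormal(μ(t), s(t)) with μ(t) = G₀ + ⟨log ζ⟩·t and
s²(t) = 2[(ln L₀ − G₀) + ((⟨ζ⟩−1) − ⟨log ζ⟩)·t].  This schedule is
*derived*, not assumed: it is the unique log-variance trajectory under
which lognormal species satisfy both growth laws simultaneously, and it
makes the ensemble's population moments obey the Taylor law with exactly
the bridge (a, β).  It requires ln L₀ ≥ G₀ and ⟨ζ⟩−1 ≥ ⟨log ζ⟩ (both are
Jensen-consistent and hold for the reference constants; s²(0) ≈ 0.274).

Ensemble defaults, chosen once as the study conditions: 2,000 species,
times uniform on [0, 3,600] My, 1,000 genes per species, ρ noise sd 0.01,
critical bump amplitude 0.15 and width 0.02 (natural-log length units).
Proteomes are generated from the threshold model: the target ρ is the
threshold value plus Gaussian noise whose sd is the baseline plus a
Gaussian kernel in log⟨L⟩ centred at L_c (the *critical bump*, emulating
metastable-state scatter near a second-order critical point; amplitude 0
recovers the pure threshold relations).  Protein draws are rescaled so
the realized sample mean equals the intended (1−ρ)⟨L⟩/3 exactly, which
enforces 3⟨Lp⟩ ≤ ⟨L⟩ by construction.  The bump width is deliberately
narrow (≈2% in length) so that the excess scatter is confined to the
critical bin and peak-location recovery is well posed.

What the generator does *not* emulate: annotation artifacts, fragmented
assemblies, pseudogenes, phylogenetic correlation between species, or
unequal species counts per clade.  Passing recovery tests therefore shows
that the estimators are correct and well calibrated under the model's own
assumptions — not that real annotation corpora satisfy those assumptions.

## Estimators and numerical choices

* **Distribution comparison.**  Six right-skewed families (lognormal,
  gamma, Weibull, exponential, log-logistic, Gumbel) are fitted by maximum
  likelihood and compared on raw total log-likelihood (no information
  criteria).  The lognormal and exponential MLEs are closed form; gamma,
  Weibull and log-logistic are fitted with location pinned at 0 (lengths
  are positive); the Gumbel is fitted on raw lengths with free location.
  Degenerate inputs (zero variance) and failed optimizations return a
  flagged result with log-likelihood −∞.  Ties break by the fixed family
  order above.  Because gamma and Weibull nest the exponential at shape 1,
  raw-likelihood comparison can never strictly prefer the exponential;
  exponential data lands in the nesting families with shape ≈ 1.
  The per-species fitting floor is n ≥ 20 (configurable); below it only
  moment summaries are produced.
* **Taylor fit.**  Ordinary least squares on log–log axes (standard
  practice for fluctuation scaling), in either the second-raw-moment or
  the variance form; a = exp(intercept).  Zero-variance species are
  excluded from the variance form with a warning.
* **Growth-law fit.**  OLS of ln(group mean length) and of group mean
  log-length on time; groups need ≥ 20 species and a divergence time.
  Non-growth fits (slope ≤ 0) are flagged, not raised.
* **Trajectory slopes.**  A simulated trajectory is a random walk around
  its trend, so OLS residual standard errors are severely anticonservative;
  slopes and their uncertainties are instead estimated from the
  differenced series (mean and standard error of per-sweep increments).
* **Simulators.**  Lengths are tracked in log space (no overflow on long
  runs); trajectory means use log-sum-exp.  Lengths are continuous reals —
  the model is continuous — with an integer-rounding toggle only in the
  fixture writers.  The additive-process variant applies log-domain
  addition sequentially for repeated hits within a sweep, and leaves the
  random stream untouched when the additive probability is 0 so it reduces
  exactly to the multiplicative simulator at equal seed.
* **Critical-length estimator.**  Grid-search least squares of observed ρ
  against the threshold model; the estimate is flagged unidentifiable
  when the optimum sits on the grid boundary (single-phase data).
* **State grid.**  100 log-uniform mean-length bins over the data range ×
  100 linear ρ bins on [0, 1] (the ρ bin count follows the canonical
  procedure; the length-axis count is symmetric by choice and
  configurable).  Entropy is Shannon entropy in bits over species counts
  per ρ bin (occupancy-based entropy available as a toggle; the peak
  location does not depend on the base).  The bootstrap keeps at most 10
  species per length bin, uniformly without replacement, and records the
  argmax column per replicate (ties to the first index).
* **ρ clamping.**  ρ is clamped to 0 only when 3⟨Lp⟩ exceeds ⟨L⟩ within
  floating tolerance (10⁻⁹ relative); genuine violations raise an error
  naming the species, since they signal unfiltered input.

## Quality filters (ingestion)

Applied in order: (i) 3⟨Lp⟩ ≤ ⟨L⟩; (ii) ≥ 500 genes and ≥ 500 proteins;
(iii) gene/protein counts agree within 5%, with the larger count as the
denominator (the conservative symmetric choice).  Assembly-status
filtering keeps "Complete genome" and "Chromosome".  GTF gene records
carrying a `gene_biotype` attribute are kept only when protein-coding;
records without the attribute are kept (some prokaryote annotations omit
it), and the toggle is exposed because either reading of the corpus
construction is defensible.  Duplicate taxa keep their first occurrence,
deterministically, with a warning.

## Problem sizes

Defaults used by the test suite and analysis scripts: growth-law recovery
with 1,000 genes × 2,000 sweeps; lognormality across 100 species of 2,000
genes grown for 1,000 sweeps (enough accumulated log-variance, ≈ 0.28, to
separate the six families decisively); Taylor recovery on 500 species ×
2,000 genes; transition diagnostics on the 2,000-species ensemble with
100 bootstrap replicates; two-stage run with 5,000 genes from a
bacterium-like start (lognormal, mean 1,000 bp, log-variance from the
ensemble schedule).  Distribution-family recovery is checked at n = 2,000
with 20 replicates per family.

## Known limitations

* The model aggregates all multiplicative mechanisms (duplication,
  elongation, genome doubling) into a single i.i.d. factor; speciation,
  selection and mechanism-specific dynamics are out of scope.
* The empirical corpus-scale fits (β = 2.29 on 33,627 genomes, the merged
  6,519-species set, corpus R² values) require external Ensembl/Uniprot
  data and are not reproduced here; the synthetic end-to-end recovery
  covers the same logic at desk scale.
* β from the reference ⟨ζ⟩, ⟨log ζ⟩ is 2.277, while the corpus-fitted
  exponent is 2.29; both are exposed (`beta_from_growth` vs the
  `REFERENCE_TAYLOR` constant) and no reconciliation is attempted.
  Likewise the variance-form exponent differs from the raw-moment form at
  finite lengths (they agree only asymptotically); both forms are
  implemented.
* Exponential-family recovery in model selection is structurally
  impossible under raw-likelihood comparison (see above); this is a
  property of the comparison rule, not a defect of the optimizer.
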