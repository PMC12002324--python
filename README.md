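# genegrowth

Gene-length evolution as a multiplicative stochastic process: growth laws,
Taylor's law, and the noncoding-fraction phase transition marking the
prokaryote→eukaryote boundary.

## The problem

Across the tree of life, within-species gene-length distributions are
lognormal — the signature of multiplicative growth (duplication,
elongation, genome doubling).  Modelling gene growth as a process in which
a random gene's length is multiplied by a random factor ζ per update
yields two growth laws for a genome evolving from an ancestral (LUCA)
state with mean gene length L₀ and mean log-length G₀,

    ⟨L(t)⟩     = L₀ · exp((⟨ζ⟩ − 1) · t)
    ⟨log L(t)⟩ = G₀ + ⟨log ζ⟩ · t

and, through the lognormal moment identity, a Taylor fluctuation-scaling
law ⟨L²⟩ = σ² + ⟨L⟩² = a·⟨L⟩^β whose parameters are fixed by the growth
laws:

    β = 4 − 2⟨log ζ⟩/(⟨ζ⟩ − 1)        a = L₀^(4−β) · exp(−2G₀)

Mean protein length tracks mean gene length at the 3:1 codon ratio only up
to a critical mean gene length L_c ≈ 1,500 bp, beyond which proteins
plateau at L_c/3 and genes grow by accumulating noncoding sequence.  The
noncoding fraction ρ = 1 − 3⟨Lp⟩/⟨L⟩ then rises continuously from zero —
a second-order phase transition.  Treating evolution as a search
algorithm, the time spent per nucleotide, τ(L) = ln(L/L₀)/((⟨ζ⟩−1)·L),
peaks exactly at L_c = e·L₀; inverting the mean growth law dates the
transition at t_c = 1/(⟨ζ⟩−1) ≈ 990 My after LUCA, i.e. ≈ 2,600 My ago —
the era of eukaryogenesis.

The package is aimed at researchers in molecular evolution and
statistical genomics who want these quantities as tested, composable
building blocks: GTF/FASTA ingestion with the corpus quality filters,
six-family distribution comparison, the stochastic simulators, the
Taylor/growth-law fits with the parameter bridge, the transition
diagnostics (fraction of states, ρ entropy, bootstrap), and a synthetic
ensemble generator whose population moments satisfy the model exactly.

## Layout

```
src/genegrowth/        library: annotations, lengthstats, growth, scaling,
                       transition, synth, pipeline
analysis/01..06_*.py   numbered narrative drivers writing tables to results/
scripts/acceptance.py  recomputes the headline constants as JSON
docs/methods.md        model, estimators, numerical choices, limitations
```

## Worked example

Simulate growth at the reference parameters (⟨ζ⟩ = 1.00101,
⟨log ζ⟩ = 0.00087, fitted with time in My; one sweep = 1 My) and check
the growth laws:

```bash
$ python analysis/01_simulate_growth.py
mean-log slope  0.000889 ± 0.000012  (growth law predicts 0.00087)
log-mean slope  0.001035 ± 0.000014  (growth law predicts 0.00101)
```

Both realized slopes agree with the predicted drift within uncertainty.
Derive the critical point from the same parameters:

```bash
$ python analysis/04_critical_point.py
critical length Lc = e*L0 = 1505.9 bp (~1,500 bp)
critical epoch  tc = 1/(<zeta>-1) = 990.1 My after LUCA (~1,000 My)
calendar date      = 3,600 - tc = 2609.9 My ago (~2,600 My ago)
tau-profile argmax on the numeric grid: 1505.4 bp (confirms Lc)
```

The numeric argmax of the τ profile lands on e·L₀ to grid resolution,
confirming the closed form.  The remaining drivers show the lognormality
of simulated length distributions (`02`, lognormal wins the six-family
comparison for 100/100 species), the Taylor fit and bridge on a synthetic
ensemble (`03`, β = 2.274 fitted vs 2.277 predicted, R² = 0.999), the
transition diagnostics (`05`, least-squares L̂_c = 1,509 bp against a
generator value of 1,500, fraction-of-states and entropy peaks one
log-bin from L_c, bootstrap peak stable in 86% of replicates), and the
two-stage coding/noncoding simulation to the modern human mean of
68,287 bp (`06`, final ρ = 0.978, all length components lognormal).

Library use mirrors the scripts:

```python
from genegrowth import REFERENCE_PARAMS, critical_length, critical_time, calendar_date

Lc = critical_length(REFERENCE_PARAMS.L0)   # 1505.9 bp
tc = critical_time(REFERENCE_PARAMS, Lc)    # 990.1 My after LUCA
calendar_date(tc)                           # 2609.9 My ago
```

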