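"""Synthetic species ensembles with the exact moment structure of the model.

A synthetic species at time ``t`` (My after LUCA) draws its gene lengths
i.i.d. from ``LogNormal(mu(t), s(t))`` with

    mu(t)  = G0 + <log zeta> * t
    s2(t)  = 2 [ (ln L0 - G0) + ((<zeta> - 1) - <log zeta>) * t ].

This log-variance schedule is the unique one for which lognormal species
satisfy *both* growth laws simultaneously: the population mean
``exp(mu + s2/2)`` then equals ``L0 exp((<zeta>-1) t)`` identically, and
population moments follow Taylor's law with exponent and prefactor given
exactly by the bridge relations.  Requires ``ln L0 >= G0`` and
``<zeta> - 1 >= <log zeta>`` so the schedule is non-negative and
non-decreasing.

Proteomes are generated from the threshold model with optional Gaussian
noise on the realized noncoding fraction plus a *critical bump*: extra
scatter localized (Gaussian kernel in log mean length) at the critical
length, emulating the metastable-state scatter expected near a
second-order critical point.  Amplitude 0 reproduces the pure threshold
relations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from genegrowth.annotations import LengthSample
from genegrowth.lengthstats import SpeciesSummary
from genegrowth.scaling import GrowthParams, REFERENCE_PARAMS
from genegrowth.transition import rho_model


@dataclass
class CriticalBump:
    """Extra rho scatter near the critical length.

    ``amplitude`` is the added rho standard deviation at ``Lc``;
    ``width`` is the Gaussian kernel width in natural-log length units.
    """

    amplitude: float = 0.15
    width: float = 0.02


@dataclass
class EnsembleSpec:
    """Study conditions for a synthetic species ensemble."""

    growth: GrowthParams = field(default_factory=lambda: REFERENCE_PARAMS)
    n_species: int = 2000
    t_range: tuple[float, float] = (0.0, 3600.0)
    genes_per_species: int = 1000
    Lc: float = 1500.0
    rho_noise_sd: float = 0.01
    critical_bump: CriticalBump = field(default_factory=CriticalBump)
    seed: int | None = None

    def validate(self) -> "EnsembleSpec":
        g = self.growth
        if math.log(g.L0) < g.G0:
            raise ValueError("need ln L0 >= G0 (non-negative initial log-variance)")
        if (g.mean_zeta - 1.0) < g.meanlog_zeta:
            raise ValueError("need <zeta> - 1 >= <log zeta> (non-decreasing log-variance)")
        if self.n_species < 1 or self.genes_per_species < 1:
            raise ValueError("counts must be >= 1")
        if not (self.t_range[0] <= self.t_range[1]):
            raise ValueError("t_range must be ordered")
        if self.rho_noise_sd < 0 or self.critical_bump.amplitude < 0:
            raise ValueError("noise scales must be non-negative")
        return self


def sigma2_schedule(growth: GrowthParams, t: float | np.ndarray) -> float | np.ndarray:
    """Log-variance of the species length distribution at time t."""
    t = np.asarray(t, dtype=float)
    s2 = 2.0 * (
        (math.log(growth.L0) - growth.G0)
        + ((growth.mean_zeta - 1.0) - growth.meanlog_zeta) * t
    )
    return s2 if s2.ndim else float(s2)


def population_moments(growth: GrowthParams, t: float | np.ndarray) -> pd.DataFrame:
    """Exact lognormal population moments of species at times t.

    Columns: t, mu, sigma2, mean (``e^{mu+s2/2}``), second_raw_moment
    (``e^{2mu+2s2}``), var, mean_log (= mu).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    mu = growth.G0 + growth.meanlog_zeta * t
    s2 = np.asarray(sigma2_schedule(growth, t))
    mean = np.exp(mu + 0.5 * s2)
    m2 = np.exp(2.0 * mu + 2.0 * s2)
    return pd.DataFrame(
        {
            "t": t,
            "mu": mu,
            "sigma2": s2,
            "mean": mean,
            "second_raw_moment": m2,
            "var": m2 - mean**2,
            "mean_log": mu,
        }
    )


def generate_species_ensemble(
    spec: EnsembleSpec,
    t_grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[LengthSample], pd.DataFrame]:
    """Draw a species ensemble along the growth trajectory.

    Species times are uniform over ``spec.t_range`` (or taken from
    ``t_grid``); each species draws ``genes_per_species`` i.i.d. lognormal
    gene lengths from the schedule above.  A spec in which every species
    has zero log-variance (``<log zeta> = <zeta> - 1`` and ``G0 = ln L0``)
    is degenerate and rejected.  Returns the samples and a truth table
    holding each species' time and exact population moments.
    """
    spec.validate()
    g = spec.growth
    if (
        math.isclose(g.meanlog_zeta, g.mean_zeta - 1.0)
        and math.isclose(g.G0, math.log(g.L0))
    ):
        raise ValueError("degenerate spec: all species would have zero log-variance")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if t_grid is not None:
        t = np.asarray(t_grid, dtype=float)
        if t.size != spec.n_species:
            raise ValueError("t_grid length must equal n_species")
    else:
        t = rng.uniform(spec.t_range[0], spec.t_range[1], spec.n_species)
    truth = population_moments(g, t)
    truth.insert(0, "species_id", [f"S{i:05d}" for i in range(spec.n_species)])
    samples = []
    for i in range(spec.n_species):
        lens = rng.lognormal(truth["mu"].iat[i], math.sqrt(truth["sigma2"].iat[i]),
                             spec.genes_per_species)
        samples.append(
            LengthSample(truth["species_id"].iat[i], truth["species_id"].iat[i],
                         "gene", list(lens))
        )
    return samples, truth


def generate_proteomes(
    gene_summaries: list[SpeciesSummary],
    Lc: float = 1500.0,
    rho_noise_sd: float = 0.01,
    critical_bump: CriticalBump | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    proteins_per_species: int | None = None,
) -> list[LengthSample]:
    """Generate protein length samples consistent with the threshold model.

    Per species with mean gene length ``<L>``: the target noncoding
    fraction is ``rho_model(<L>, Lc)`` plus Gaussian noise whose standard
    deviation is ``rho_noise_sd`` plus the critical bump evaluated at
    ``<L>``; the realized rho is clipped to [0, 1).  Protein lengths are
    drawn lognormal with log-variance proportional to the species' gene
    log-variance (proteins inherit the genes' multiplicative history) and
    then rescaled so the sample mean protein length equals
    ``(1 - rho) <L> / 3`` exactly — the realized rho is the intended one
    and ``3 <Lp> <= <L>`` holds by construction.
    """
    bump = critical_bump if critical_bump is not None else CriticalBump()
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = []
    for s in gene_summaries:
        L = s.mean
        sd = rho_noise_sd
        if bump.amplitude > 0:
            sd = sd + bump.amplitude * math.exp(
                -((math.log(L) - math.log(Lc)) ** 2) / (2.0 * bump.width**2)
            )
        rho = float(rho_model(L, Lc))
        if sd > 0:
            rho = rho + rng.normal(0.0, sd)
        rho = min(max(rho, 0.0), 1.0 - 1e-6)
        target_mean = (1.0 - rho) * L / 3.0
        n = proteins_per_species if proteins_per_species is not None else s.n
        # gene log-variance from the moment identity s2 = 2(ln<L> - <logL>)
        s2_gene = max(2.0 * (math.log(s.mean) - s.mean_log), 0.0)
        sp = math.sqrt(s2_gene)
        lens = rng.lognormal(math.log(target_mean) - 0.5 * s2_gene, sp, n)
        lens *= target_mean / lens.mean()
        lens = np.maximum(lens, 1.0)  # floor rare sub-residue draws at high log-variance
        out.append(LengthSample(s.taxon_id, s.taxon_id, "protein", list(lens)))
    return out


def generate_group_table(
    growth: GrowthParams,
    group_times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Group-averaged growth-law inputs (t, mean_len, mean_log_len).

    Noiseless rows satisfy both growth laws exactly.  With ``noise_sd > 0``
    the mean lengths get multiplicative lognormal noise
    (``* exp(N(0, noise_sd))``) and the mean log-lengths additive normal
    noise of the same scale (the natural counterpart on the log axis).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    t = np.asarray(group_times, dtype=float)
    mean_len = growth.L0 * np.exp((growth.mean_zeta - 1.0) * t)
    mean_log = growth.G0 + growth.meanlog_zeta * t
    if noise_sd > 0:
        mean_len = mean_len * np.exp(rng.normal(0.0, noise_sd, t.size))
        mean_log = mean_log + rng.normal(0.0, noise_sd, t.size)
    return pd.DataFrame({"t": t, "mean_len": mean_len, "mean_log_len": mean_log})


def write_fixture_gtf(sample: LengthSample, path: str | Path, round_lengths: bool = False) -> None:
    """Write a minimal GTF fixture: one ``gene`` row per length, start=1, end=length.

    Lengths must be positive integers (or pass ``round_lengths`` to round
    real-valued model lengths).  An empty sample yields a header-only file.
    """
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for k, ln in enumerate(sample.lengths):
            end = int(round(ln)) if round_lengths else ln
            if not float(end).is_integer() or end < 1:
                raise ValueError(f"length {ln!r} is not a positive integer (use round_lengths)")
            end = int(end)
            attrs = f'gene_id "g{k}"; gene_biotype "protein_coding";'
            fh.write(
                f"{sample.species_id or 'chr1'}\tgenegrowth\tgene\t1\t{end}\t.\t+\t.\t{attrs}\n"
            )


def write_fixture_fasta(sample: LengthSample, path: str | Path, round_lengths: bool = False) -> None:
    """Write a protein FASTA fixture: each record is ``length`` 'M' residues."""
    with open(path, "w") as fh:
        for k, ln in enumerate(sample.lengths):
            n = int(round(ln)) if round_lengths else ln
            if not float(n).is_integer() or n < 1:
                raise ValueError(f"length {ln!r} is not a positive integer (use round_lengths)")
            fh.write(f">p{k} synthetic\n")
            seq = "M" * int(n)
            for off in range(0, len(seq), 60):
                fh.write(seq[off : off + 60] + "\n")
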