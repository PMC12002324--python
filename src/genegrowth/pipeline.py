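"""End-to-end orchestration of the gene-length analysis.

Sequence: ingest (or synthesize) gene/protein length corpora ->
per-species summaries -> distribution comparison -> Taylor and growth-law
fits -> parameter bridge -> critical point -> noncoding-fraction
transition diagnostics.  Stages communicate through plain TSV/JSON
artifacts when an output directory is given, so any stage can be re-run
from its inputs.  Reports always carry the reference corpus constants
(L0=554, G0=6.18, <zeta>=1.00101, <log zeta>=0.00087) next to the
data-derived estimates; one is never silently substituted for the other.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from genegrowth import annotations as ann
from genegrowth import lengthstats as ls
from genegrowth import scaling, synth, transition

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage name."""


@dataclass
class AnalysisConfig:
    """Configuration for :func:`run_full_analysis`."""

    mode: str = "synthetic"  # "synthetic" | "real"
    ensemble: synth.EnsembleSpec = field(default_factory=synth.EnsembleSpec)
    # real-mode paths
    gtf_dir: str | None = None
    fasta_dir: str | None = None
    metadata_tsv: str | None = None
    # filters
    min_count: int = 500
    max_disagreement: float = 0.05
    allowed_statuses: frozenset = ann.BEST_ASSEMBLY_STATUSES
    # model constants
    Lc: float = 1500.0
    luca_age: float = scaling.LUCA_AGE_MY
    # diagnostics
    n_L_bins: int = 100
    n_rho_bins: int = 100
    n_fit_species: int = 20
    n_growth_groups: int = 12
    bootstrap_reps: int = 100
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> "AnalysisConfig":
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.min_count <= 0 or self.max_disagreement <= 0:
            raise ValueError("filter thresholds must be positive")
        if self.Lc <= 0 or self.luca_age <= 0:
            raise ValueError("Lc and luca_age must be positive")
        return self


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("ingest")
def _ingest_real(config: AnalysisConfig):
    gtf_dir, fasta_dir = Path(config.gtf_dir or ""), Path(config.fasta_dir or "")
    gtfs = sorted(gtf_dir.glob("*.gtf")) if gtf_dir.is_dir() else []
    fastas = sorted(fasta_dir.glob("*.fasta")) if fasta_dir.is_dir() else []
    if not gtfs or not fastas:
        raise FileNotFoundError(
            f"no input annotations found (gtf_dir={config.gtf_dir!r} has {len(gtfs)} "
            f".gtf files, fasta_dir={config.fasta_dir!r} has {len(fastas)} .fasta files)"
        )
    meta: dict[str, dict] = {}
    if config.metadata_tsv:
        with open(config.metadata_tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                meta[row["taxon_id"]] = row
    genes = [
        ann.gene_lengths_from_gtf(
            p, species_id=p.stem, taxon_id=p.stem,
            group_label=meta.get(p.stem, {}).get("group_label", "unknown"),
        )
        for p in gtfs
    ]
    proteins = [
        ann.protein_lengths_from_fasta(p, species_id=p.stem, taxon_id=p.stem)
        for p in fastas
    ]
    logger.info("ingest: %d gene samples, %d protein samples", len(genes), len(proteins))
    return genes, proteins, meta


@_stage("synthesize")
def _synthesize(config: AnalysisConfig):
    spec = config.ensemble
    rng = np.random.default_rng(config.seed)
    genes, truth = synth.generate_species_ensemble(spec, rng=rng)
    gene_summaries = [ls.summarize(s) for s in genes]
    proteins = synth.generate_proteomes(
        gene_summaries, Lc=spec.Lc, rho_noise_sd=spec.rho_noise_sd,
        critical_bump=spec.critical_bump, rng=rng,
    )
    return genes, proteins, gene_summaries, truth


@_stage("distribution_comparison")
def _compare_distributions(genes, n_fit_species: int):
    tally: dict[str, int] = {}
    for s in genes[:n_fit_species]:
        fam = ls.best_fit(ls.fit_all_families(np.asarray(s.lengths)))
        tally[fam] = tally.get(fam, 0) + 1
    return tally


@_stage("transition_diagnostics")
def _transition_diagnostics(points, config: AnalysisConfig):
    L = np.array([p.mean_gene_len for p in points])
    grid = np.geomspace(max(L.min(), 200.0), min(L.max(), 20000.0), 121)
    lc_est = transition.estimate_Lc(points, grid)
    frac, sgrid = transition.fraction_of_states(points, config.n_L_bins, config.n_rho_bins)
    ent, _ = transition.rho_entropy(points, config.n_L_bins, config.n_rho_bins)
    peaks, _ = transition.bootstrap_fraction_of_states(
        points, max_per_bin=10, reps=config.bootstrap_reps, seed=config.seed + 1,
        n_L_bins=config.n_L_bins, n_rho_bins=config.n_rho_bins,
    )
    centers = sgrid.L_bin_centers
    peak_lengths = centers[peaks]
    return {
        "Lc_hat": lc_est.Lc_hat,
        "Lc_identifiable": bool(lc_est.identifiable),
        "fraction_peak_bin": int(np.argmax(frac)),
        "fraction_peak_length": float(centers[int(np.argmax(frac))]),
        "entropy_peak_bin": int(np.argmax(ent)),
        "entropy_peak_length": float(centers[int(np.argmax(ent))]),
        "bootstrap_peak_quantiles": {
            q: float(np.quantile(peak_lengths, float(q))) for q in ("0.05", "0.5", "0.95")
        },
    }, frac, ent, sgrid


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and return the report bundle (a JSON-serializable dict).

    Deterministic for a fixed ``config.seed``.  When ``config.out_dir`` is
    set, per-stage TSVs and the final ``report.json`` are written there.
    """
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        genes, proteins, gene_summaries, truth = _synthesize(config)
    else:
        genes, proteins, _meta = _ingest_real(config)
        gene_summaries = [ls.summarize(s) for s in genes]
        truth = None

    protein_summaries = [ls.summarize(s) for s in proteins]
    logger.info("summaries: %d gene, %d protein species", len(gene_summaries), len(protein_summaries))

    fit_tally = _compare_distributions(genes, config.n_fit_species)

    merged = ann.apply_quality_filters(
        ann.merge_by_taxon(genes, proteins),
        min_count=config.min_count,
        max_disagreement=config.max_disagreement,
    )
    points = [
        transition.SpeciesPoint(
            m.taxon_id, m.mean_gene_len, m.mean_protein_len,
            transition.noncoding_fraction(m.mean_gene_len, m.mean_protein_len, m.taxon_id),
            m.group_label,
        )
        for m in merged
    ]
    if not points:
        raise PipelineError("stage 'merge' failed: no species survived merging/filters")

    taylor_raw = scaling.fit_taylor(gene_summaries, form="raw_moment")
    taylor_var = scaling.fit_taylor(gene_summaries, form="variance")

    report: dict = {
        "reference": {
            "L0": scaling.REFERENCE_PARAMS.L0,
            "G0": scaling.REFERENCE_PARAMS.G0,
            "mean_zeta": scaling.REFERENCE_PARAMS.mean_zeta,
            "meanlog_zeta": scaling.REFERENCE_PARAMS.meanlog_zeta,
            "taylor": dict(scaling.REFERENCE_TAYLOR),
        },
        "n_species": len(points),
        "best_fit_tally": fit_tally,
        "taylor": {
            "raw_moment": asdict(taylor_raw),
            "variance": asdict(taylor_var),
        },
    }

    if truth is not None:
        # growth-law fit from time-binned group averages of the truth table times
        t = truth["t"].to_numpy()
        order = np.argsort(t)
        bins = np.array_split(order, config.n_growth_groups)
        rows = []
        for b in bins:
            if b.size == 0:
                continue
            rows.append(
                (
                    float(t[b].mean()),
                    float(np.mean([gene_summaries[i].mean for i in b])),
                    float(np.mean([gene_summaries[i].mean_log for i in b])),
                )
            )
        params, diag = scaling.fit_growth_laws(rows)
        beta_bridge = scaling.beta_from_growth(params)
        a_bridge = scaling.a_from_growth(params.L0, params.G0, beta_bridge)
        Lc_theory = scaling.critical_length(params.L0)
        tc = scaling.critical_time(params, Lc_theory)
        report["growth_fit"] = {**asdict(params), **diag}
        report["bridge"] = {
            "beta_from_growth": beta_bridge,
            "a_from_growth": a_bridge,
            "invert_from_taylor": scaling.invert_eq5(
                taylor_raw.a, taylor_raw.beta, G0=params.G0, mean_zeta=params.mean_zeta
            ),
        }
        report["critical_point"] = {
            "Lc": Lc_theory,
            "tc": tc,
            "date_mya": scaling.calendar_date(tc, config.luca_age),
            "luca_age": config.luca_age,
        }

    diag_report, frac, ent, sgrid = _transition_diagnostics(points, config)
    report["transition"] = diag_report

    if out_dir:
        _write_artifacts(out_dir, report, gene_summaries, points, frac, ent, sgrid)
    return report


def _write_artifacts(out_dir: Path, report, gene_summaries, points, frac, ent, sgrid):
    with open(out_dir / "species_summaries.tsv", "w") as fh:
        fh.write("taxon_id\tn\tmean\tvar\tsecond_raw_moment\tmean_log\n")
        for s in gene_summaries:
            fh.write(f"{s.taxon_id}\t{s.n}\t{s.mean!r}\t{s.var!r}\t{s.second_raw_moment!r}\t{s.mean_log!r}\n")
    with open(out_dir / "species_points.tsv", "w") as fh:
        fh.write("taxon_id\tmean_gene_len\tmean_protein_len\trho\tgroup_label\n")
        for p in points:
            fh.write(f"{p.taxon_id}\t{p.mean_gene_len!r}\t{p.mean_protein_len!r}\t{p.rho!r}\t{p.group_label}\n")
    with open(out_dir / "state_profile.tsv", "w") as fh:
        fh.write("L_bin_center\tfraction_of_states\trho_entropy_bits\n")
        for c, f, h in zip(sgrid.L_bin_centers, frac, ent):
            fh.write(f"{c!r}\t{f!r}\t{h!r}\n")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
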