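"""Noncoding-fraction threshold and phase-transition diagnostics.

A species is characterized by the pair ``(<L>, rho)`` with
``rho = 1 - 3 <Lp> / <L>`` the mean fraction of intragenic noncoding
sequence (the factor 3 converts amino acids to coding base pairs).  The
threshold model for mean protein length,

    <Lp> = <L>/3        for <L> <= Lc
    <Lp> = Lc/3         for <L> >  Lc,

implies a continuous, second-order transition in the noncoding fraction:

    rho(<L>) = 0             for <L> <= Lc
    rho(<L>) = 1 - Lc/<L>    for <L> >  Lc.

Criticality diagnostics discretize the (mean length, rho) plane into a
grid of *states* — log-uniform bins in mean length, linear bins on [0, 1]
for rho — and measure, per mean-length bin, the fraction of occupied rho
states and the Shannon entropy of rho.  Both peak at the critical length
when metastable scatter concentrates there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance for clamping a numerically-negative noncoding fraction to 0
RHO_CLAMP_TOL = 1e-9


@dataclass
class SpeciesPoint:
    """One species in the (mean gene length, noncoding fraction) plane."""

    taxon_id: str
    mean_gene_len: float
    mean_protein_len: float
    rho: float
    group_label: str = "unknown"


@dataclass
class StateGrid:
    """Binned occupancy of the (mean length, rho) plane.

    ``occupancy[i, j]`` is True when at least one species falls in mean-
    length bin i and rho bin j; ``counts`` holds the species counts.
    """

    L_bin_edges: np.ndarray
    rho_bin_edges: np.ndarray
    occupancy: np.ndarray
    counts: np.ndarray

    @property
    def n_L_bins(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_rho_bins(self) -> int:
        return self.occupancy.shape[1]

    @property
    def L_bin_centers(self) -> np.ndarray:
        e = self.L_bin_edges
        return np.sqrt(e[:-1] * e[1:])  # geometric centers of log-uniform bins


@dataclass
class GroupComplexity:
    """Empirical algorithmic complexity of one phyletic group."""

    group_label: str
    tdiv: float  # divergence time from H. sapiens, My
    Lgr: float  # group-average mean gene length, bp
    tau_exp: float  # My per bp


def noncoding_fraction(
    mean_gene_len: float, mean_protein_len: float, taxon_id: str = "?"
) -> float:
    """Noncoding fraction ``rho = 1 - 3 <Lp> / <L>``.

    Values negative beyond floating tolerance indicate unfiltered input
    (coding sequence longer than the gene) and raise, naming the species.
    """
    if mean_gene_len <= 0 or mean_protein_len <= 0:
        raise ValueError("mean lengths must be positive")
    rho = 1.0 - 3.0 * mean_protein_len / mean_gene_len
    if rho < 0:
        if 3.0 * mean_protein_len - mean_gene_len <= RHO_CLAMP_TOL * mean_gene_len:
            return 0.0
        raise ValueError(
            f"species {taxon_id}: 3<Lp> = {3 * mean_protein_len:g} exceeds "
            f"<L> = {mean_gene_len:g}; apply the coding-consistency filter first"
        )
    return rho


def protein_plateau_model(
    mean_gene_len: float | np.ndarray, Lc: float = 1500.0
) -> float | np.ndarray:
    """Threshold model for mean protein length: ``<L>/3`` below ``Lc``, ``Lc/3`` above."""
    L = np.asarray(mean_gene_len, dtype=float)
    out = np.where(L <= Lc, L / 3.0, Lc / 3.0)
    return float(out) if np.isscalar(mean_gene_len) else out


def rho_model(mean_gene_len: float | np.ndarray, Lc: float = 1500.0) -> float | np.ndarray:
    """Threshold model for the noncoding fraction: 0 below ``Lc``, ``1 - Lc/<L>`` above.

    Continuous at ``Lc`` (second-order transition); the left/right
    derivatives there are 0 and ``1/Lc``.
    """
    L = np.asarray(mean_gene_len, dtype=float)
    out = np.where(L <= Lc, 0.0, 1.0 - Lc / L)
    return float(out) if np.isscalar(mean_gene_len) else out


@dataclass
class LcEstimate:
    """Grid-search estimate of the critical length from (L, rho) data."""

    Lc_hat: float
    grid: np.ndarray
    ssr: np.ndarray
    identifiable: bool


def estimate_Lc(points: list[SpeciesPoint], grid: np.ndarray) -> LcEstimate:
    """Least-squares critical length over a candidate grid.

    Minimizes the sum of squared residuals of observed rho values against
    the threshold model.  Flagged unidentifiable when the minimum sits on
    the grid boundary (data on one side of every candidate — e.g. a
    prokaryote-only sample — produces a flat or monotone profile).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("need a grid of at least two candidate values")
    L = np.array([p.mean_gene_len for p in points], dtype=float)
    rho = np.array([p.rho for p in points], dtype=float)
    if L.size == 0:
        raise ValueError("no points")
    ssr = np.array([float(((rho - rho_model(L, c)) ** 2).sum()) for c in grid])
    imin = int(np.argmin(ssr))
    tol = 1e-12 * (1.0 + ssr[imin])
    tied = np.flatnonzero(ssr <= ssr[imin] + tol)
    identifiable = not (0 in tied or (grid.size - 1) in tied)
    if not identifiable:
        logger.warning("estimate_Lc: minimum on grid boundary; Lc unidentifiable")
    return LcEstimate(Lc_hat=float(grid[imin]), grid=grid, ssr=ssr, identifiable=identifiable)


def build_state_grid(
    points: list[SpeciesPoint],
    n_L_bins: int = 100,
    n_rho_bins: int = 100,
    L_bin_edges: np.ndarray | None = None,
) -> StateGrid:
    """Discretize species into the (mean length, rho) state grid.

    Mean-length bins are log-uniform over the data range (or the supplied
    edges); rho bins are linear on [0, 1].  Species exactly on the upper
    edge fall in the last bin.
    """
    if not points:
        raise ValueError("need at least one point")
    L = np.array([p.mean_gene_len for p in points], dtype=float)
    rho = np.array([p.rho for p in points], dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho values must lie in [0, 1]")
    if L_bin_edges is None:
        lo, hi = L.min(), L.max()
        if lo == hi:
            hi = lo * (1.0 + 1e-9)
        L_bin_edges = np.geomspace(lo, hi, n_L_bins + 1)
    else:
        L_bin_edges = np.asarray(L_bin_edges, dtype=float)
        n_L_bins = L_bin_edges.size - 1
    rho_edges = np.linspace(0.0, 1.0, n_rho_bins + 1)
    i = np.clip(np.searchsorted(L_bin_edges, L, side="right") - 1, 0, n_L_bins - 1)
    j = np.clip(np.searchsorted(rho_edges, rho, side="right") - 1, 0, n_rho_bins - 1)
    counts = np.zeros((n_L_bins, n_rho_bins), dtype=int)
    np.add.at(counts, (i, j), 1)
    return StateGrid(L_bin_edges, rho_edges, occupancy=counts > 0, counts=counts)


def fraction_of_states(
    points: list[SpeciesPoint],
    n_L_bins: int = 100,
    n_rho_bins: int = 100,
    L_bin_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, StateGrid]:
    """Fraction of occupied rho states per mean-length bin.

    For each column of the state grid: number of rho bins holding at least
    one species, divided by the total number of rho bins.  Invariant under
    permutation and duplication of the input points.
    """
    grid = build_state_grid(points, n_L_bins, n_rho_bins, L_bin_edges)
    frac = grid.occupancy.sum(axis=1) / grid.n_rho_bins
    return frac, grid


def rho_entropy(
    points: list[SpeciesPoint],
    n_L_bins: int = 100,
    n_rho_bins: int = 100,
    L_bin_edges: np.ndarray | None = None,
    use_counts: bool = True,
) -> tuple[np.ndarray, StateGrid]:
    """Shannon entropy (bits) of rho within each mean-length bin.

    With ``use_counts`` (default) the entropy is over the distribution of
    species counts across rho bins; otherwise over the 0/1 occupancy
    pattern (all occupied bins weighted equally).  Empty columns score 0.
    """
    grid = build_state_grid(points, n_L_bins, n_rho_bins, L_bin_edges)
    mat = grid.counts if use_counts else grid.occupancy.astype(float)
    totals = mat.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, mat / np.maximum(totals, 1), 0.0)
        h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=1)
    return h, grid


def bootstrap_fraction_of_states(
    points: list[SpeciesPoint],
    max_per_bin: int = 10,
    reps: int = 100,
    seed: int | None = None,
    n_L_bins: int = 100,
    n_rho_bins: int = 100,
) -> tuple[np.ndarray, StateGrid]:
    """Bootstrap robustness of the fraction-of-states peak.

    Guards against the peak being a sample-size artifact: each replicate
    keeps at most ``max_per_bin`` species per mean-length bin (uniformly,
    without replacement), recomputes the fraction of states on the same
    bin edges, and records the argmax column.  Returns the sample of peak
    bin indices and the full-data grid (for mapping indices to lengths).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    frac_full, grid = fraction_of_states(points, n_L_bins, n_rho_bins)
    L = np.array([p.mean_gene_len for p in points], dtype=float)
    col = np.clip(
        np.searchsorted(grid.L_bin_edges, L, side="right") - 1, 0, grid.n_L_bins - 1
    )
    by_col = [np.flatnonzero(col == i) for i in range(grid.n_L_bins)]
    peaks = np.empty(reps, dtype=int)
    for r in range(reps):
        chosen: list[np.ndarray] = []
        for members in by_col:
            if members.size == 0:
                continue
            if members.size <= max_per_bin:
                chosen.append(members)
            else:
                chosen.append(rng.choice(members, size=max_per_bin, replace=False))
        sub = [points[k] for k in np.concatenate(chosen)]
        frac, _ = fraction_of_states(
            sub, n_rho_bins=grid.n_rho_bins, L_bin_edges=grid.L_bin_edges
        )
        peaks[r] = int(np.argmax(frac))
    return peaks, grid


def algorithmic_complexity_empirical(
    groups: list[tuple[str, float, float]], luca_age: float = 3600.0
) -> list[GroupComplexity]:
    """Empirical complexity ``tau_exp = (luca_age - tdiv) / Lgr`` per group.

    ``groups`` rows are ``(label, tdiv, Lgr)`` with ``tdiv`` the divergence
    time from H. sapiens in My and ``Lgr`` the group-average mean gene
    length in bp.
    """
    out = []
    for label, tdiv, Lgr in groups:
        if not (0 <= tdiv <= luca_age):
            raise ValueError(f"group {label}: tdiv must lie in [0, {luca_age}]")
        if Lgr <= 0:
            raise ValueError(f"group {label}: Lgr must be positive")
        out.append(GroupComplexity(label, tdiv, Lgr, (luca_age - tdiv) / Lgr))
    return out


def group_summaries(
    summaries: list,
    taxonomy: dict[str, str],
    divergence: dict[str, float],
    min_size: int = 20,
    luca_age: float = 3600.0,
) -> pd.DataFrame:
    """Group-averaged growth-law inputs.

    Averages the per-species mean and mean-log lengths within each phyletic
    group (arithmetic mean of the per-species values), assigning the group
    the time ``t = luca_age - tdiv`` after LUCA.  Groups with fewer than
    ``min_size`` species, or absent from the divergence table, are dropped
    with a warning.  Returns a table (group, t, n, mean_len, mean_log_len).
    """
    buckets: dict[str, list] = {}
    for s in summaries:
        grp = taxonomy.get(s.taxon_id)
        if grp is None:
            continue
        buckets.setdefault(grp, []).append(s)
    rows = []
    for grp, members in sorted(buckets.items()):
        if len(members) < min_size:
            logger.warning("group %s has %d < %d species; dropped", grp, len(members), min_size)
            continue
        if grp not in divergence:
            logger.warning("group %s missing from divergence table; dropped", grp)
            continue
        rows.append(
            {
                "group": grp,
                "t": luca_age - divergence[grp],
                "n": len(members),
                "mean_len": float(np.mean([m.mean for m in members])),
                "mean_log_len": float(np.mean([m.mean_log for m in members])),
            }
        )
    return pd.DataFrame(rows, columns=["group", "t", "n", "mean_len", "mean_log_len"])
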