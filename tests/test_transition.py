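"""Noncoding-fraction threshold model and criticality diagnostics."""

import math

import numpy as np
import pytest

from genegrowth import transition as tr


def _pt(L, rho, taxon="s"):
    # mean_protein_len consistent with rho by construction
    return tr.SpeciesPoint(taxon, L, (1.0 - rho) * L / 3.0, rho)


class TestNoncodingFraction:
    def test_prokaryote_case_is_zero(self):
        assert tr.noncoding_fraction(900.0, 300.0) == 0.0

    def test_half_noncoding(self):
        assert tr.noncoding_fraction(3000.0, 500.0) == pytest.approx(0.5)

    def test_one_minus_inverse_e(self):
        assert tr.noncoding_fraction(math.e * 1500.0, 500.0) == pytest.approx(1 - 1 / math.e)

    def test_tiny_negative_clamped(self):
        assert tr.noncoding_fraction(900.0, 300.0 * (1 + 1e-12)) == 0.0

    def test_violation_names_species(self):
        with pytest.raises(ValueError, match="taxonX"):
            tr.noncoding_fraction(900.0, 400.0, taxon_id="taxonX")


class TestThresholdModels:
    def test_plateau_below_and_above(self):
        assert tr.protein_plateau_model(900.0) == 300.0
        assert tr.protein_plateau_model(1e6) == 500.0

    def test_plateau_continuous_at_Lc(self):
        assert tr.protein_plateau_model(1500.0) == tr.protein_plateau_model(1500.0 + 1e-9) == pytest.approx(500.0)

    def test_rho_model_values(self):
        assert tr.rho_model(1500.0) == 0.0
        assert tr.rho_model(3000.0) == pytest.approx(0.5)
        assert tr.rho_model(1e12) == pytest.approx(1.0, abs=1e-8)

    def test_rho_model_second_order(self):
        """Continuous at Lc with distinct one-sided derivatives (0 vs 1/Lc)."""
        Lc, h = 1500.0, 1e-6
        assert tr.rho_model(Lc - h) == pytest.approx(tr.rho_model(Lc + h), abs=1e-8)
        left = (tr.rho_model(Lc) - tr.rho_model(Lc - h)) / h
        right = (tr.rho_model(Lc + h) - tr.rho_model(Lc)) / h
        assert left == pytest.approx(0.0, abs=1e-12)
        assert right == pytest.approx(1.0 / Lc, rel=1e-3)

    def test_models_agree_through_noncoding_fraction(self):
        for L in (500.0, 1500.0, 4000.0, 40000.0):
            rho = tr.noncoding_fraction(L, tr.protein_plateau_model(L))
            assert rho == pytest.approx(tr.rho_model(L), abs=1e-12)


class TestEstimateLc:
    GRID = np.geomspace(500.0, 8000.0, 161)

    def test_noiseless_self_consistency(self):
        L = np.geomspace(300.0, 30000.0, 400)
        grid = np.unique(np.append(self.GRID, 1500.0))
        points = [_pt(x, float(tr.rho_model(x, 1500.0))) for x in L]
        est = tr.estimate_Lc(points, grid)
        assert est.Lc_hat == 1500.0 and est.identifiable

    def test_noisy_recovery(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(900 + rep)
            L = np.exp(rng.uniform(math.log(300.0), math.log(30000.0), 2000))
            rho = np.clip(tr.rho_model(L, 1500.0) + rng.normal(0, 0.05, L.size), 0, 1)
            est = tr.estimate_Lc([_pt(x, r) for x, r in zip(L, rho)], self.GRID)
            if abs(est.Lc_hat - 1500.0) / 1500.0 <= 0.10:
                hits += 1
        assert hits >= 18

    def test_single_phase_unidentifiable(self):
        points = [_pt(x, 0.0) for x in np.geomspace(300.0, 1200.0, 50)]
        est = tr.estimate_Lc(points, self.GRID)
        assert not est.identifiable


class TestStateGrid:
    def test_identical_rho_single_state_per_column(self):
        points = [_pt(L, 0.25) for L in np.geomspace(100, 10000, 57)]
        frac, grid = tr.fraction_of_states(points)
        nonzero = frac[frac > 0]
        assert np.allclose(nonzero, 1 / 100)

    def test_two_states_in_one_column(self):
        points = [_pt(1000.0, 0.005), _pt(1000.0, 0.995)]
        frac, _ = tr.fraction_of_states(points, n_L_bins=5)
        assert frac.max() == pytest.approx(2 / 100)

    def test_empty_columns_are_zero(self):
        points = [_pt(100.0, 0.1), _pt(10000.0, 0.5)]
        frac, _ = tr.fraction_of_states(points, n_L_bins=10)
        assert (frac == 0).sum() == 8

    def test_invariant_under_permutation_and_duplication(self, rng):
        L = np.exp(rng.uniform(5, 10, 200))
        rho = rng.uniform(0, 1, 200)
        points = [_pt(x, r) for x, r in zip(L, rho)]
        frac1, _ = tr.fraction_of_states(points)
        shuffled = [points[i] for i in rng.permutation(200)]
        frac2, _ = tr.fraction_of_states(shuffled)
        frac3, _ = tr.fraction_of_states(points + points[:50])
        assert np.array_equal(frac1, frac2) and np.array_equal(frac1, frac3)


class TestRhoEntropy:
    def test_single_occupied_bin_zero_entropy(self):
        points = [_pt(1000.0, 0.205, f"s{i}") for i in range(8)]
        h, _ = tr.rho_entropy(points, n_L_bins=3)
        assert np.all(h == 0.0)

    def test_uniform_four_bins_two_bits(self):
        rhos = [0.105, 0.205, 0.305, 0.405]
        points = [_pt(1000.0, r, f"s{i}") for i, r in enumerate(rhos)]
        h, _ = tr.rho_entropy(points, n_L_bins=3)
        assert h.max() == pytest.approx(2.0)

    def test_entropy_bounded_by_log_bins(self, rng):
        points = [_pt(1000.0, r, f"s{i}") for i, r in enumerate(rng.uniform(0, 1, 500))]
        h, _ = tr.rho_entropy(points, n_L_bins=3)
        assert np.all(h <= math.log2(100) + 1e-12)


class TestBootstrap:
    def test_single_column_peak_is_that_column(self):
        points = [_pt(1000.0, r, f"s{i}") for i, r in enumerate(np.linspace(0.1, 0.9, 30))]
        peaks, grid = tr.bootstrap_fraction_of_states(points, reps=10, seed=1, n_L_bins=7)
        L = 1000.0
        col = np.searchsorted(grid.L_bin_edges, L, side="right") - 1
        col = min(col, grid.n_L_bins - 1)
        assert np.all(peaks == col)

    def test_deterministic_for_fixed_seed(self, rng):
        L = np.exp(rng.uniform(5, 10, 300))
        rho = rng.uniform(0, 1, 300)
        points = [_pt(x, r, f"s{i}") for i, (x, r) in enumerate(zip(L, rho))]
        p1, _ = tr.bootstrap_fraction_of_states(points, reps=20, seed=77)
        p2, _ = tr.bootstrap_fraction_of_states(points, reps=20, seed=77)
        assert np.array_equal(p1, p2)


class TestGroupComplexity:
    def test_zero_at_luca(self):
        (g,) = tr.algorithmic_complexity_empirical([("LUCA", 3600.0, 554.0)])
        assert g.tau_exp == 0.0

    def test_aves_value(self):
        (g,) = tr.algorithmic_complexity_empirical([("Aves", 319.0, 30000.0)])
        assert g.tau_exp == pytest.approx(3281.0 / 30000.0)

    def test_inverse_proportionality_in_Lgr(self):
        a, b = tr.algorithmic_complexity_empirical([("x", 319.0, 30000.0), ("y", 319.0, 60000.0)])
        assert a.tau_exp == pytest.approx(2 * b.tau_exp)

    def test_tdiv_beyond_luca_rejected(self):
        with pytest.raises(ValueError):
            tr.algorithmic_complexity_empirical([("x", 4000.0, 1000.0)])


class TestGroupSummaries:
    def _summaries(self, specs):
        from genegrowth.lengthstats import SpeciesSummary

        return [
            SpeciesSummary(tid, "gene", 100, mean, 1.0, mean**2 + 1.0, math.log(mean))
            for tid, mean in specs
        ]

    def test_small_groups_dropped(self):
        summ = self._summaries([(f"s{i}", 1000.0) for i in range(19)])
        table = tr.group_summaries(summ, {s.taxon_id: "G" for s in summ}, {"G": 300.0})
        assert table.empty

    def test_group_mean_of_identical_species(self):
        summ = self._summaries([(f"s{i}", 1000.0) for i in range(25)])
        table = tr.group_summaries(summ, {s.taxon_id: "G" for s in summ}, {"G": 300.0})
        assert table.loc[0, "mean_len"] == 1000.0
        assert table.loc[0, "t"] == 3300.0

    def test_arithmetic_average_of_means(self):
        summ = self._summaries([("a", 1000.0), ("b", 3000.0)])
        table = tr.group_summaries(summ, {"a": "G", "b": "G"}, {"G": 0.0}, min_size=2)
        assert table.loc[0, "mean_len"] == 2000.0

    def test_missing_divergence_dropped(self):
        summ = self._summaries([(f"s{i}", 1000.0) for i in range(25)])
        table = tr.group_summaries(summ, {s.taxon_id: "G" for s in summ}, {})
        assert table.empty
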