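"""LD r^2, pruning, PCA and Hill-Weir decay fitting."""

import numpy as np
import pytest

import rohmap as rm
from rohmap.panel import MISSING
from rohmap.structure import fit_hill_weir, pairwise_r2_matrix
from conftest import make_panel


class TestLdR2:
    def test_duplicated_marker_gives_one(self):
        panel = make_panel([[0, 0], [1, 1], [2, 2], [1, 1]])
        assert rm.ld_r2(panel, 0, 1) == pytest.approx(1.0)

    def test_orthogonal_dosages_give_zero(self):
        panel = make_panel([[0, 0], [0, 2], [2, 0], [2, 2]])
        assert rm.ld_r2(panel, 0, 1) == pytest.approx(0.0)

    def test_matches_direct_pearson_formula(self):
        x = np.array([0, 1, 2, 2, 0, 1], dtype=float)
        y = np.array([0, 0, 2, 1, 1, 2], dtype=float)
        panel = make_panel(np.column_stack([x, y]).astype(np.int8))
        r = np.corrcoef(x, y)[0, 1]
        assert rm.ld_r2(panel, 0, 1) == pytest.approx(r**2)

    def test_pairwise_complete_on_missing(self):
        x = np.array([0, 1, 2, MISSING, 0], dtype=np.int8)
        y = np.array([0, 1, MISSING, 2, 2], dtype=np.int8)
        panel = make_panel(np.column_stack([x, y]))
        shared = [0, 1, 4]
        r = np.corrcoef(x[shared].astype(float), y[shared].astype(float))[0, 1]
        assert rm.ld_r2(panel, 0, 1) == pytest.approx(r**2)

    def test_zero_variance_undefined(self):
        panel = make_panel([[0, 0], [0, 1], [0, 2]])
        assert np.isnan(rm.ld_r2(panel, 0, 1))


class TestLdPrune:
    def test_identical_window_keeps_exactly_one(self):
        col = np.array([0, 1, 2, 0, 1, 2, 0, 2], dtype=np.int8)
        panel = make_panel(np.tile(col[:, None], (1, 5)))
        pruned = rm.ld_prune(panel, window=5, step=2, r2_max=0.5)
        assert pruned.n_markers == 1

    def test_uncorrelated_panel_unchanged(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.integers(0, 3, size=(200, 12)).astype(np.int8))
        pruned = rm.ld_prune(panel)
        assert pruned.n_markers == 12

    def test_output_subset_preserves_order_and_ld_bound(self, midsize_panel):
        panel, _ = midsize_panel
        pruned = rm.ld_prune(panel, window=50, step=5, r2_max=0.5)
        pos = list(zip(pruned.markers["chrom"], pruned.markers["pos"]))
        all_pos = list(zip(panel.markers["chrom"], panel.markers["pos"]))
        assert pos == [p for p in all_pos if p in set(pos)]  # order-preserving subset
        # oracle: no retained within-window pair exceeds the threshold
        for chrom, sub in pruned.markers.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            for ws in range(0, len(idx), 5):
                win = idx[ws:ws + 50]
                if len(win) < 2:
                    continue
                r2 = pairwise_r2_matrix(pruned, win)
                iu = np.triu_indices(len(win), k=1)
                vals = r2[iu]
                assert np.nanmax(vals) <= 0.5 + 1e-12


class TestPCA:
    def test_separates_balding_nichols_subpopulations(self):
        cfg = rm.SimConfig(seed=3, n_founders=60, n_subpops=2, fst=0.1,
                           markers_per_chrom=375, n_parent_offspring=0,
                           n_full_sib_pairs=0, selfing_generations=(),
                           clone_group_sizes=(), missing_rate=0.05)
        panel, truth = rm.simulate_panel(cfg)
        res = rm.pca(panel, n_components=2)
        labels = truth.samples.set_index("id").loc[panel.sample_ids, "subpop"].to_numpy()
        pc1 = res.scores[:, 0]
        a, b = pc1[labels == 0], pc1[labels == 1]
        pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert abs(a.mean() - b.mean()) > 4 * pooled_sd

    def test_duplicate_samples_get_identical_scores(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(20, 100)).astype(np.int8)
        d[1] = d[0]
        res = rm.pca(make_panel(d), n_components=3)
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-8)

    def test_scores_centered_and_variances_monotone(self, midsize_panel):
        panel, _ = midsize_panel
        res = rm.pca(panel, n_components=5)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-8)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all() and evr.sum() <= 1 + 1e-12

    def test_too_many_components_rejected(self, tiny_panel):
        panel, _ = tiny_panel
        with pytest.raises(ValueError):
            rm.pca(panel, n_components=panel.n_samples)


class TestHillWeir:
    def test_formula_value_at_origin(self):
        # C=0, n=50: (10/22) * (1 + 36/1100)
        assert rm.hill_weir_r2(0.0, 1.0, 50) == pytest.approx(0.46942, abs=1e-4)

    def test_curve_monotone_nonincreasing(self):
        d = np.linspace(0, 1e6, 500)
        vals = rm.hill_weir_r2(d, 0.01, 30)
        assert (np.diff(vals) <= 1e-12).all()

    def test_rho_recovery_from_simulated_curve(self):
        rng = np.random.default_rng(4)
        rho_true, n = 0.05, 50
        d = rng.uniform(1, 2000, size=4000)
        r2 = np.clip(rm.hill_weir_r2(d, rho_true, n)
                     + rng.normal(0, 0.05, size=d.size), 0, 1)
        rho_hat = fit_hill_weir(d, r2, n)
        assert rho_hat == pytest.approx(rho_true, rel=0.2)


class TestLdDecay:
    def test_fit_on_simulated_panel(self, midsize_panel):
        panel, _ = midsize_panel
        fit = rm.ld_decay(panel, max_dist=2_000_000, pair_cap_per_chrom=3000,
                          threshold_pairs=5000, seed=0)
        assert fit.rho > 0
        assert 0 < fit.threshold_r2 < 1
        assert set(fit.per_chrom_mean_r2.index) == set(panel.markers["chrom"])

    def test_per_chrom_mean_matches_direct_loop(self):
        rng = np.random.default_rng(5)
        panel = make_panel(rng.integers(0, 3, size=(40, 8)).astype(np.int8))
        from rohmap.structure import per_chromosome_mean_r2
        got = per_chromosome_mean_r2(panel)["1"]
        vals = [rm.ld_r2(panel, i, j) for i in range(8) for j in range(i + 1, 8)]
        assert got == pytest.approx(np.nanmean(vals))
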