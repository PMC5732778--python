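"""Residual pooling, screen resampling and the omnibus decision logic."""

import numpy as np
import pytest

from combostat import AnalysisConfig, ConcentrationGrid, PlateBatch
from combostat.bootstrap_stats import (
    BootstrapResult,
    bootstrap_indices,
    build_pools,
    compute_residuals,
    joint_call,
    omnibus_call,
    per_well_calls,
    simulate_batch,
    simulate_batches,
)
from combostat.errors import ConfigError

from conftest import make_manual_batch


class TestResiduals:
    def test_two_replicates(self):
        S = np.full((3, 3, 2), 0.5)
        S[1, 1, :] = [0.4, 0.6]
        resid = compute_residuals(make_manual_batch(S))
        np.testing.assert_allclose(resid.e[1, 1, :], [-0.1, 0.1])

    def test_constant_replicates_zero_residuals(self):
        S = np.full((3, 3, 4), 0.8)
        resid = compute_residuals(make_manual_batch(S))
        np.testing.assert_allclose(resid.e, 0.0, atol=1e-15)

    def test_missing_replicate_excluded(self):
        S = np.full((3, 3, 3), 0.5)
        S[1, 1, :] = [0.4, 0.6, np.nan]
        resid = compute_residuals(make_manual_batch(S))
        assert resid.well_means[1, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(resid.e[1, 1, :2], [-0.1, 0.1])
        assert np.isnan(resid.e[1, 1, 2])

    def test_residuals_sum_to_zero_per_cell(self, null_batch):
        resid = compute_residuals(null_batch)
        sums = np.nansum(resid.e, axis=2)
        np.testing.assert_allclose(sums, 0.0, atol=1e-12)


class TestPools:
    def _resid_for_cells(self, n_rows, n_cols, K=4, seed=0):
        rng = np.random.default_rng(seed)
        S = rng.uniform(0, 1, size=(n_rows, n_cols, K))
        return compute_residuals(make_manual_batch(S))

    def test_eighty_wells_give_window_of_eight(self):
        # 5 x 16 = 80 cells with defined means, 10% window
        resid = self._resid_for_cells(5, 16)
        pools = build_pools(resid, window_fraction=0.10)
        assert pools.n_wells == 80
        assert pools.window_size == 8
        assert all(len(m) == 8 for m in pools.members.values())

    def test_sixty_three_wells_round_to_six(self):
        # the 7 x 9 checkerboard grid: round(6.3) = 6
        resid = self._resid_for_cells(7, 9)
        pools = build_pools(resid, window_fraction=0.10)
        assert pools.n_wells == 63
        assert pools.window_size == 6

    def test_self_always_member(self):
        resid = self._resid_for_cells(4, 5)
        pools = build_pools(resid)
        for cell, members in pools.members.items():
            assert cell in members

    def test_identical_means_are_mutual_neighbors(self):
        S = np.empty((3, 3, 2))
        base = [0.1, 0.5, 0.5, 0.8, 0.81, 0.3, 0.95, 0.05, 0.65]
        for idx, m in enumerate(base):
            j, i = divmod(idx, 3)
            S[j, i, :] = [m - 0.01, m + 0.01]
        pools = build_pools(compute_residuals(make_manual_batch(S)), window_fraction=0.25)
        # cells with means 0.5 (idx 1 and 2) must contain each other
        assert (0, 2) in pools.members[(0, 1)]
        assert (0, 1) in pools.members[(0, 2)]

    def test_invalid_fraction_rejected(self):
        resid = self._resid_for_cells(3, 3)
        with pytest.raises(ConfigError):
            build_pools(resid, window_fraction=1.5)

    def test_rescaling_restores_variance(self):
        resid = self._resid_for_cells(7, 9, K=4, seed=5)
        raw = build_pools(resid, rescale=False)
        scaled = build_pools(resid, rescale=True)
        for cell in raw.values:
            np.testing.assert_allclose(
                scaled.values[cell], raw.values[cell] * np.sqrt(4 / 3)
            )


class TestSimulateBatches:
    def test_zero_residuals_reproduce_mean_surface(self):
        S = np.repeat(np.random.default_rng(0).uniform(0, 1, (3, 4))[:, :, None], 4, axis=2)
        resid = compute_residuals(make_manual_batch(S))
        pools = build_pools(resid)
        sims = simulate_batches(resid, pools, 20, np.random.default_rng(1))
        np.testing.assert_allclose(
            sims, np.broadcast_to(S[None], sims.shape), atol=1e-14
        )

    def test_seeded_reproducibility(self, null_batch):
        resid = compute_residuals(null_batch)
        pools = build_pools(resid)
        s1 = simulate_batch(resid, pools, 123)
        s2 = simulate_batch(resid, pools, 123)
        np.testing.assert_array_equal(s1, s2)

    def test_simulated_sd_matches_pool_rms(self):
        """Across many batches the draw SD equals the pooled-residual RMS."""
        rng = np.random.default_rng(8)
        S = 0.5 + rng.normal(0, 0.08, size=(3, 4, 4))
        resid = compute_residuals(make_manual_batch(S))
        pools = build_pools(resid, window_fraction=0.2)
        sims = simulate_batches(resid, pools, 10_000, np.random.default_rng(9))
        for (j, i), pool in pools.values.items():
            emp_sd = np.std(sims[:, j, i, :] - resid.well_means[j, i])
            rms = np.sqrt(np.mean(pool**2))
            assert emp_sd == pytest.approx(rms, rel=0.05)


def _dummy_result(**overrides):
    base = dict(
        model="bliss",
        B=4,
        indices=np.zeros((4, 2, 2)),
        observed=np.zeros((2, 2)),
        combo_mask=np.array([[False, False], [False, True]]),
        per_well_lower=np.zeros((2, 2)),
        per_well_upper=np.zeros((2, 2)),
        Imax_dist=np.zeros(4),
        Imin_dist=np.zeros(4),
        observed_Imax=0.0,
        observed_Imin=0.0,
        Imax_upper=0.0,
        Imin_lower=0.0,
        alpha_tail=0.025,
    )
    base.update(overrides)
    return BootstrapResult(**base)


class TestDecisions:
    def test_omnibus_strict_inequality_at_boundary(self):
        res = _dummy_result(observed_Imax=0.12, Imax_upper=0.12)
        assert omnibus_call(res) == {"synergy": False, "antagonism": False}

    def test_omnibus_dual_flags(self):
        res = _dummy_result(
            observed_Imax=0.30, Imax_upper=0.2, observed_Imin=-0.28, Imin_lower=-0.2
        )
        assert omnibus_call(res) == {"synergy": True, "antagonism": True}

    @pytest.mark.parametrize(
        "lower, upper, expected",
        [(-0.05, 0.08, "none"), (0.02, 0.09, "synergy"), (-0.09, -0.01, "antagonism")],
    )
    def test_per_well_interval_rules(self, lower, upper, expected):
        res = _dummy_result(
            per_well_lower=np.full((2, 2), lower),
            per_well_upper=np.full((2, 2), upper),
        )
        calls = per_well_calls(res)
        assert calls[1, 1] == expected

    def test_joint_symbols(self):
        syn = {"synergy": True, "antagonism": False}
        ant = {"synergy": False, "antagonism": True}
        none = {"synergy": False, "antagonism": False}
        both = {"synergy": True, "antagonism": True}
        assert joint_call(syn, syn) == "X"
        assert joint_call(ant, ant) == "O"
        assert joint_call(syn, none) == "--"
        assert joint_call(syn, None) == "NA"
        assert joint_call(both, both) == "XO"


class TestBootstrapIndices:
    def test_zero_noise_degenerate_intervals(self):
        means = np.random.default_rng(2).uniform(0.2, 1.0, (3, 4))
        S = np.repeat(means[:, :, None], 4, axis=2)
        batch = make_manual_batch(S)
        res = bootstrap_indices(batch, "bliss", B=50, rng=0)
        np.testing.assert_allclose(res.per_well_lower, res.observed, atol=1e-12)
        np.testing.assert_allclose(res.per_well_upper, res.observed, atol=1e-12)
        np.testing.assert_allclose(res.Imax_dist, 0.0, atol=1e-12)

    def test_seed_determinism(self, null_batch, fast_config):
        r1 = bootstrap_indices(null_batch, "bliss", B=100, rng=5, config=fast_config)
        r2 = bootstrap_indices(null_batch, "bliss", B=100, rng=5, config=fast_config)
        np.testing.assert_array_equal(r1.indices, r2.indices)
        assert r1.Imax_upper == r2.Imax_upper

    def test_max_property_per_batch(self, null_batch, fast_config):
        res = bootstrap_indices(null_batch, "bliss", B=100, rng=5, config=fast_config)
        centered = res.indices - res.observed[None]
        centered = np.where(res.combo_mask[None], centered, np.nan)
        for b in range(res.B):
            assert res.Imax_dist[b] >= np.nanmax(centered[b]) - 1e-12
            assert res.Imax_dist[b] == pytest.approx(np.nanmax(centered[b]))

    def test_interval_brackets_median(self, null_batch, fast_config):
        res = bootstrap_indices(null_batch, "bliss", B=200, rng=6, config=fast_config)
        med = np.nanmedian(res.indices, axis=0)
        ok = np.isfinite(res.per_well_lower)
        assert np.all(res.per_well_lower[ok] <= med[ok] + 1e-12)
        assert np.all(res.per_well_upper[ok] >= med[ok] - 1e-12)

    def test_heteroscedastic_strata_widths(self):
        """High-variance wells must receive wider intervals than quiet wells."""
        rng = np.random.default_rng(11)
        J1, I1, K = 4, 6, 4
        means = np.where(np.arange(J1)[:, None] < 2, 0.9, 0.2) * np.ones((J1, I1))
        sd = np.where(means > 0.5, 0.10, 0.01)
        S = means[:, :, None] + rng.normal(0, 1, (J1, I1, K)) * sd[:, :, None]
        batch = make_manual_batch(S)
        res = bootstrap_indices(batch, "bliss", B=400, rng=12)
        width = res.per_well_upper - res.per_well_lower
        wide = width[1, 1:].mean()    # high-survival, noisy stratum
        narrow = width[2:, 1:].mean()  # low-survival, quiet stratum
        assert wide > 2 * narrow
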