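"""Bliss and Loewe interaction indices and the isobole inversion."""

import numpy as np
import pytest

from combostat import (
    DoseResponseCurve,
    SynergyIndexMatrix,
    bliss_index_matrix,
    bliss_prediction,
    hill_response,
    loewe_index_matrix,
    loewe_response,
    total_interaction_weight,
)
from combostat.plate_io import ConcentrationGrid
from combostat.synergy_models import loewe_response_grid


class TestBliss:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(1.0, 0.37, 0.37), (0.5, 0.5, 0.25), (0.0, 0.9, 0.0)],
    )
    def test_prediction_is_product(self, a, b, expected):
        assert bliss_prediction(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "mA, mB, mAB, expected",
        [(0.5, 0.5, 0.25, 0.0), (0.8, 0.9, 0.60, 0.12), (0.8, 0.9, 0.85, -0.13)],
    )
    def test_index_sign_convention(self, mA, mB, mAB, expected):
        means = np.ones((2, 2))
        means[0, 1] = mA  # single drug A
        means[1, 0] = mB  # single drug B
        means[1, 1] = mAB
        I = bliss_index_matrix(means)
        assert I[1, 1] == pytest.approx(expected)

    def test_single_drug_rows_zero_when_control_is_one(self):
        rng = np.random.default_rng(3)
        means = rng.uniform(0.2, 0.9, size=(4, 5))
        means[0, 0] = 1.0
        I = bliss_index_matrix(means)
        np.testing.assert_allclose(I[0, :], 0.0, atol=1e-12)
        np.testing.assert_allclose(I[:, 0], 0.0, atol=1e-12)


class TestLoeweResponse:
    def test_single_drug_limits(self):
        cA = DoseResponseCurve(1.0, 2.0)
        cB = DoseResponseCurve(10.0, 1.0)
        assert loewe_response(0.0, 0.0, cA, cB) == 1.0
        assert loewe_response(0.7, 0.0, cA, cB) == pytest.approx(
            hill_response(0.7, cA), abs=1e-8
        )
        assert loewe_response(0.0, 3.0, cA, cB) == pytest.approx(
            hill_response(3.0, cB), abs=1e-8
        )

    @pytest.mark.parametrize("c", [0.1, 0.5, 1.0, 4.0, 20.0])
    def test_sham_combination(self, c):
        """A drug mixed with itself: half + half equals the full dose."""
        curve = DoseResponseCurve(2.0, 1.5)
        s = loewe_response(c / 2, c / 2, curve, curve)
        assert s == pytest.approx(hill_response(c, curve), abs=1e-8)

    def test_monotone_in_each_concentration(self):
        cA = DoseResponseCurve(1.0, 2.0)
        cB = DoseResponseCurve(5.0, 0.8)
        grid_a = np.linspace(0.0, 5.0, 25)
        s_a = loewe_response_grid(grid_a, np.full_like(grid_a, 1.0), cA, cB)
        assert np.all(np.diff(s_a) < 1e-12)
        s_b = loewe_response_grid(np.full_like(grid_a, 0.5), grid_a, cA, cB)
        assert np.all(np.diff(s_b) < 1e-12)

    def test_grid_search_oracle_single_pair(self):
        cA = DoseResponseCurve(1.0, 1.0)
        cB = DoseResponseCurve(10.0, 1.0)
        s_bis = loewe_response(0.5, 5.0, cA, cB)
        s_grid = np.arange(1e-6, 1.0, 1e-6)
        lhs = 0.5 / ((1 - s_grid) / s_grid * 1.0) + 5.0 / ((1 - s_grid) / s_grid * 10.0)
        s_oracle = s_grid[np.argmin(np.abs(lhs - 1.0))]
        assert s_bis == pytest.approx(s_oracle, abs=1e-5)

    def test_non_computable_curve_gives_nan(self):
        flat = DoseResponseCurve(None, None, computable=False)
        ok = DoseResponseCurve(1.0, 1.0)
        assert np.isnan(loewe_response(0.5, 0.5, flat, ok))


class TestLoeweIndex:
    def _sham_grid(self):
        curve = DoseResponseCurve(1.0, 2.0)
        concs = np.geomspace(0.125, 8.0, 7)
        grid = ConcentrationGrid(concs, concs)
        cA = np.concatenate([[0.0], concs])[None, :]
        cB = np.concatenate([[0.0], concs])[:, None]
        surface = loewe_response_grid(cA, cB, curve, curve, tol=1e-12)
        return curve, grid, surface

    def test_zero_on_exact_additive_surface(self):
        curve, grid, surface = self._sham_grid()
        I = loewe_index_matrix(surface, grid, curve, curve)
        np.testing.assert_allclose(I[1:, 1:], 0.0, atol=1e-7)

    def test_perturbed_well_shows_as_index(self):
        curve, grid, surface = self._sham_grid()
        surface = surface.copy()
        surface[3, 2] -= 0.1
        I = loewe_index_matrix(surface, grid, curve, curve)
        assert I[3, 2] == pytest.approx(0.1, abs=1e-7)

    def test_all_na_when_curve_flat(self):
        _, grid, surface = self._sham_grid()
        flat = DoseResponseCurve(None, None, computable=False)
        ok = DoseResponseCurve(1.0, 2.0)
        I = loewe_index_matrix(surface, grid, flat, ok)
        assert np.all(np.isnan(I))


class TestInteractionWeight:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        mask = np.zeros_like(values, dtype=bool)
        mask[1:, 1:] = True
        return SynergyIndexMatrix("bliss", values, mask)

    def test_all_zero(self):
        m = self._matrix(np.zeros((3, 3)))
        assert total_interaction_weight(m, "synergy") == 0.0
        assert total_interaction_weight(m, "antagonism") == 0.0

    def test_signed_sums(self):
        vals = np.zeros((3, 3))
        vals[1, 1], vals[1, 2], vals[2, 1] = 0.1, -0.2, 0.3
        m = self._matrix(vals)
        assert total_interaction_weight(m, "synergy") == pytest.approx(0.4)
        assert total_interaction_weight(m, "antagonism") == pytest.approx(0.2)

    def test_nan_wells_skipped(self):
        vals = np.zeros((3, 3))
        vals[1, 1], vals[2, 2] = 0.25, np.nan
        m = self._matrix(vals)
        assert total_interaction_weight(m, "synergy") == pytest.approx(0.25)
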