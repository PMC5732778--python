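"""Per-well Bliss and Loewe interaction indices.

Both indices share one sign convention: *predicted* survival under the null
interaction model minus *observed* mean survival, so a positive index means
the combination killed more cells than the null model expects (synergy
direction) and a negative index means antagonism.

Bliss independence predicts the combination survival as the product of the
single-drug survivals.  Loewe additivity predicts it through the linear
isobole equation

    cA / R_A^{-1}(s) + cB / R_B^{-1}(s) = 1,

whose unique root s in (0, 1) is the predicted survival: for decreasing
Hill curves the left-hand side is strictly increasing in s, running from 0
(as s -> 0, inverse concentrations diverge) to +inf (as s -> 1), so the
printed "argmin of |LHS - 1|" is exactly a root-finding problem and is
solved here by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .doseresponse import DoseResponseCurve, hill_inverse, hill_response


@dataclass
class SynergyIndexMatrix:
    """Observed per-well interaction indices for one model."""

    model: str  # "bliss" or "loewe"
    values: np.ndarray  # (J+1, I+1), NaN where undefined
    combo_mask: np.ndarray  # cells with i >= 1 and j >= 1


def bliss_prediction(mean_A: float, mean_B: float) -> float:
    """Bliss independence: combined survival = product of single-drug survivals."""
    return mean_A * mean_B


def bliss_index_matrix(means: np.ndarray) -> np.ndarray:
    """I_Bliss(i,j) = <S(i,0)> * <S(0,j)> - <S(i,j)> for a full mean matrix.

    ``means`` is the (J+1, I+1) matrix of per-cell replicate means (rows =
    j, columns = i); NaN propagates wherever a required cell is undefined.
    """
    means = np.asarray(means, dtype=float)
    return means[0:1, :] * means[:, 0:1] - means


def bliss_index(batch, i: int, j: int) -> float:
    """Observed Bliss index at one well of a batch (NaN if inputs missing)."""
    means = batch.well_means()
    return float(means[0, i] * means[j, 0] - means[j, i])


def _isobole_lhs(s, cA, cB, curveA, curveB):
    return cA / hill_inverse(s, curveA) + cB / hill_inverse(s, curveB)


def loewe_response_grid(
    cA,
    cB,
    curveA: DoseResponseCurve,
    curveB: DoseResponseCurve,
    tol: float = 1e-9,
    eps: float = 1e-9,
) -> np.ndarray:
    """Vectorized Loewe-additive survival prediction on concentration arrays.

    Boundary cases: (0, 0) -> 1; one drug absent -> that drug's own Hill
    response.  Returns NaN everywhere if either curve is not computable.
    """
    cA = np.asarray(cA, dtype=float)
    cB = np.asarray(cB, dtype=float)
    cA, cB = np.broadcast_arrays(cA, cB)
    out = np.full(cA.shape, np.nan)
    if not (curveA.computable and curveB.computable):
        return out
    both_zero = (cA == 0) & (cB == 0)
    only_A = (cA > 0) & (cB == 0)
    only_B = (cA == 0) & (cB > 0)
    interior = (cA > 0) & (cB > 0)
    out[both_zero] = 1.0
    if np.any(only_A):
        out[only_A] = hill_response(cA[only_A], curveA)
    if np.any(only_B):
        out[only_B] = hill_response(cB[only_B], curveB)
    if np.any(interior):
        a, b = cA[interior], cB[interior]
        lo = np.full(a.shape, eps)
        hi = np.full(a.shape, 1.0 - eps)
        # the LHS is strictly increasing in s, so plain bisection converges
        while np.max(hi - lo) > tol:
            mid = 0.5 * (lo + hi)
            below = _isobole_lhs(mid, a, b, curveA, curveB) < 1.0
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        out[interior] = 0.5 * (lo + hi)
    return out


def loewe_response(
    cA: float,
    cB: float,
    curveA: DoseResponseCurve,
    curveB: DoseResponseCurve,
    tol: float = 1e-9,
) -> float:
    """Predicted Loewe-additive survival at one concentration pair (or NaN)."""
    return float(loewe_response_grid(np.array(cA), np.array(cB), curveA, curveB, tol=tol))


def loewe_index_matrix(
    means: np.ndarray,
    grid,
    curveA: DoseResponseCurve,
    curveB: DoseResponseCurve,
    tol: float = 1e-9,
) -> np.ndarray:
    """I_Loewe(i,j) = Loewe-predicted survival - observed mean, full matrix.

    All-NaN when either single-drug curve is not computable (the Loewe
    model is then undefined for this screen).
    """
    means = np.asarray(means, dtype=float)
    concA = np.concatenate([[0.0], grid.concs_A])[None, :]
    concB = np.concatenate([[0.0], grid.concs_B])[:, None]
    pred = loewe_response_grid(concA, concB, curveA, curveB, tol=tol)
    return pred - means


def loewe_index(batch, curveA, curveB, i: int, j: int, tol: float = 1e-9) -> float:
    """Observed Loewe index at one combination well (NaN where undefined)."""
    means = batch.well_means()
    cA = batch.grid.conc_A_at(i)
    cB = batch.grid.conc_B_at(j)
    pred = loewe_response(cA, cB, curveA, curveB, tol=tol)
    return float(pred - means[j, i])


def total_interaction_weight(indices: SynergyIndexMatrix, direction: str) -> float:
    """Summed index magnitude in one direction over the combination wells.

    ``direction`` is ``"synergy"`` (sum of positive parts) or
    ``"antagonism"`` (sum of absolute negative parts); NaN wells are
    skipped.  Used as the edge width in the network figures.
    """
    vals = indices.values[indices.combo_mask]
    vals = vals[np.isfinite(vals)]
    if direction == "synergy":
        return float(np.sum(np.clip(vals, 0, None)))
    if direction == "antagonism":
        return float(np.sum(np.clip(-vals, 0, None)))
    raise ValueError(f"direction must be 'synergy' or 'antagonism', got {direction!r}")
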