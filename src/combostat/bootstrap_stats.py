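"""Heteroscedasticity-aware residual bootstrap and omnibus testing.

Experimental error in viability screens depends on the survival level
(heteroscedasticity), so each well resamples residuals only from wells with
a *similar mean survival*: for every cell, the 10% of all wells (single-drug
and control wells included) whose means are closest to its own form a
sliding window, and the cell's simulated errors are drawn from the pooled
residuals of that window, with a random sign flip (the error distribution is
assumed symmetric but otherwise arbitrary).

Each bootstrap batch b rebuilds a full K-replicate screen

    S_b(i,j,k) = <S(i,j,k)>_k + e_b(i,j,k)

and recomputes the entire interaction index matrix from it -- for the Loewe
model this includes refitting both Hill curves to that batch's simulated
single-drug rows.  Two summaries come out:

* per-well bootstrap intervals [a_ij, b_ij] (2.5/97.5 percentiles of the
  uncentered per-well index distribution), read as "synergy at this well if
  the interval excludes zero" -- descriptive, not multiplicity-corrected;
* a global (omnibus) test on the extremal index.  The null distribution of
  the maximum is the per-batch maximum of the *null-centered* indices
  I(b,i,j) - I(i,j) over the combination wells; global synergy is declared
  when the observed I_max strictly exceeds its 97.5-percentile, and global
  antagonism when the observed I_min falls strictly below the
  2.5-percentile of the corresponding minimum distribution.  Centering is
  what makes the resampled surface obey the null ("assuming the model to be
  true"): without it the bootstrap maxima would straddle the observed
  maximum by construction and the test could never reject.  A single max
  statistic replaces per-well multiple testing, avoiding a Bonferroni-style
  correction.

Residuals about a mean of K replicates have expected mean square
((K-1)/K) * sigma^2; by default they are rescaled by sqrt(K/(K-1)) per cell
before pooling so the simulated errors match the sampling noise of the
observed statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .doseresponse import DoseResponseCurve, _hill
from .errors import AnalysisError, ConfigError
from .synergy_models import bliss_index_matrix, loewe_index_matrix

logger = logging.getLogger(__name__)

Cell = Tuple[int, int]  # (j, i)


@dataclass
class ResidualSet:
    """Replicate residuals e(i,j,k) = S(i,j,k) - <S(i,j,k)>_k per cell."""

    e: np.ndarray  # (J+1, I+1, K), NaN where replicate missing/removed
    well_means: np.ndarray  # (J+1, I+1)
    counts: np.ndarray  # (J+1, I+1) surviving replicates


@dataclass
class ResidualPool:
    """Sliding-window residual pools, one per cell with a defined mean."""

    members: Dict[Cell, List[Cell]] = field(default_factory=dict)
    values: Dict[Cell, np.ndarray] = field(default_factory=dict)
    window_size: int = 0
    n_wells: int = 0


@dataclass
class BootstrapResult:
    """Everything the omnibus and per-well decisions need, for one model."""

    model: str
    B: int
    indices: np.ndarray  # (B, J+1, I+1) uncentered bootstrap indices
    observed: np.ndarray  # (J+1, I+1) observed index matrix
    combo_mask: np.ndarray  # wells entering I_max / I_min
    per_well_lower: np.ndarray
    per_well_upper: np.ndarray
    Imax_dist: np.ndarray  # (B,) null-centered per-batch maxima
    Imin_dist: np.ndarray  # (B,) null-centered per-batch minima
    observed_Imax: float
    observed_Imin: float
    Imax_upper: float  # (1 - alpha_tail) percentile of Imax_dist
    Imin_lower: float  # alpha_tail percentile of Imin_dist
    alpha_tail: float
    n_failed_batches: int = 0
    seed: Optional[int] = None


def compute_residuals(batch) -> ResidualSet:
    """Residuals about the per-cell mean over surviving replicates."""
    means = batch.well_means()
    e = batch.S - means[:, :, None]
    return ResidualSet(e=e, well_means=means, counts=batch.counts())


def build_pools(
    resid: ResidualSet,
    window_fraction: float = 0.10,
    rescale: bool = True,
) -> ResidualPool:
    """Assemble each cell's sliding window of similar-mean wells.

    The window size is w = round(window_fraction * N) with N the number of
    wells having a defined mean, never below 2; the cell itself is always a
    member (distance zero).  With ``rescale`` each contributing cell's
    residuals are multiplied by sqrt(K_c / (K_c - 1)) to undo the variance
    shrinkage of mean-centering.
    """
    if not (0.0 < window_fraction <= 1.0):
        raise ConfigError(f"window_fraction must be in (0, 1], got {window_fraction}")
    cells = [
        (j, i)
        for j in range(resid.e.shape[0])
        for i in range(resid.e.shape[1])
        if resid.counts[j, i] >= 2
    ]
    N = len(cells)
    if N < 2:
        raise AnalysisError("need at least 2 wells with defined means to build pools")
    w = int(np.round(window_fraction * N))
    w = max(2, min(w, N))
    means = np.array([resid.well_means[c] for c in cells])

    scaled: Dict[Cell, np.ndarray] = {}
    for c in cells:
        vals = resid.e[c[0], c[1], :]
        vals = vals[np.isfinite(vals)]
        if rescale:
            k = len(vals)
            vals = vals * np.sqrt(k / (k - 1.0))
        scaled[c] = vals

    pool = ResidualPool(window_size=w, n_wells=N)
    for idx, c in enumerate(cells):
        d = np.abs(means - means[idx])
        d[idx] = -1.0  # the cell itself always ranks first
        order = np.argsort(d, kind="stable")[:w]
        member_cells = [cells[m] for m in order]
        pool.members[c] = member_cells
        pool.values[c] = np.concatenate([scaled[m] for m in member_cells])
    return pool


def simulate_batches(
    resid: ResidualSet,
    pools: ResidualPool,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate B bootstrap screens S_b = well mean + resampled error.

    For every cell and replicate slot an error is drawn with replacement
    from the cell's pooled window residuals and its sign is flipped with
    probability 1/2.  Draws are independent across wells, replicates and
    batches; missing replicate slots stay NaN.
    """
    J1, I1, K = resid.e.shape
    S_b = np.full((B, J1, I1, K), np.nan)
    for j in range(J1):
        for i in range(I1):
            cell = (j, i)
            if cell not in pools.values:
                continue
            pool = pools.values[cell]
            if pool.size == 0:
                raise AnalysisError(f"empty residual pool at cell (i={i}, j={j})")
            slots = np.flatnonzero(np.isfinite(resid.e[j, i, :]))
            draws = pool[rng.integers(0, pool.size, size=(B, slots.size))]
            signs = np.where(rng.random((B, slots.size)) < 0.5, -1.0, 1.0)
            S_b[:, j, i, slots] = resid.well_means[j, i] + draws * signs
    return S_b


def simulate_batch(resid: ResidualSet, pools: ResidualPool, rng) -> np.ndarray:
    """One simulated screen (convenience wrapper around the batched path)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return simulate_batches(resid, pools, 1, rng)[0]


def _refit_hill(
    concs: np.ndarray,
    resp: np.ndarray,
    start: DoseResponseCurve,
    flat_range_min: float = 0.1,
) -> Optional[Tuple[float, float]]:
    """Fast per-batch Hill refit starting from the observed-data fit."""
    ok = np.isfinite(resp)
    concs, resp = concs[ok], resp[ok]
    if len(concs) < 2 or (np.max(resp) - np.min(resp)) < flat_range_min:
        return None

    def f(theta):
        return _hill(concs, np.exp(theta[0]), np.exp(theta[1])) - resp

    try:
        sol = least_squares(f, np.log([start.c50, start.H]), method="lm", max_nfev=500)
    except Exception:  # pragma: no cover
        return None
    c50, H = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
    cmin, cmax = float(np.min(concs)), float(np.max(concs))
    dyn = float(_hill(cmin, c50, H) - _hill(cmax, c50, H))
    if dyn < flat_range_min or not (cmin / 100.0 <= c50 <= cmax * 100.0):
        return None
    return c50, H


def _nanpercentile(a: np.ndarray, q: float, axis=None) -> np.ndarray:
    """np.nanpercentile (linear interpolation) without all-NaN warnings."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanpercentile(a, q, axis=axis)


def bootstrap_indices(
    batch,
    model: str = "bliss",
    B: int = 1000,
    rng=None,
    curves: Optional[Tuple[DoseResponseCurve, DoseResponseCurve]] = None,
    config=None,
    max_failed_fraction: float = 0.20,
) -> BootstrapResult:
    """Full bootstrap analysis of one batch under one interaction model.

    ``rng`` may be an integer seed or a Generator; passing the same seed for
    the Bliss and the Loewe run reproduces the identical stream of simulated
    screens, so both models are judged against the same resampled noise.
    For the Loewe model ``curves`` must hold the observed-data Hill fits
    (both computable); each batch refits both curves to its own simulated
    single-drug rows, and batches whose refit degenerates are dropped
    (aborting if more than ``max_failed_fraction`` of them fail).
    """
    from .config import AnalysisConfig

    config = config or AnalysisConfig()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if model not in ("bliss", "loewe"):
        raise ConfigError(f"model must be 'bliss' or 'loewe', got {model!r}")

    resid = compute_residuals(batch)
    pools = build_pools(
        resid,
        window_fraction=config.window_fraction,
        rescale=config.rescale_residuals,
    )
    S_b = simulate_batches(resid, pools, B, rng)
    with np.errstate(invalid="ignore"):
        M_b = np.nansum(np.nan_to_num(S_b, nan=0.0), axis=3)
    cnt = np.sum(np.isfinite(S_b), axis=3)
    M_b = np.where(cnt > 0, M_b / np.maximum(cnt, 1), np.nan)

    grid = batch.grid
    concA = grid.concs_A
    concB = grid.concs_B
    if model == "bliss":
        observed = bliss_index_matrix(resid.well_means)
        indices = M_b[:, 0:1, :] * M_b[:, :, 0:1] - M_b
        n_failed = 0
    else:
        if curves is None or not (curves[0].computable and curves[1].computable):
            raise AnalysisError("Loewe bootstrap requires two computable observed curves")
        curveA, curveB = curves
        observed = loewe_index_matrix(
            resid.well_means, grid, curveA, curveB, tol=config.loewe_bisection_tol
        )
        indices = np.full(M_b.shape, np.nan)
        n_failed = 0
        for b in range(B):
            fitA = _refit_hill(concA, M_b[b, 0, 1:], curveA, config.flat_curve_range_min)
            fitB = _refit_hill(concB, M_b[b, 1:, 0], curveB, config.flat_curve_range_min)
            if fitA is None or fitB is None:
                n_failed += 1
                continue
            cA = DoseResponseCurve(c50=fitA[0], H=fitA[1])
            cB = DoseResponseCurve(c50=fitB[0], H=fitB[1])
            indices[b] = loewe_index_matrix(
                M_b[b], grid, cA, cB, tol=config.loewe_bisection_tol
            )
        if n_failed > max_failed_fraction * B:
            raise AnalysisError(
                f"{n_failed}/{B} Loewe bootstrap batches failed to refit; "
                "the concentration-response data are too unstable for Loewe analysis"
            )

    combo = batch.combo_mask() & np.isfinite(observed) & (resid.counts >= 2)
    if not np.any(combo):
        raise AnalysisError("no combination wells with a defined index")

    per_well_lower = _nanpercentile(indices, 100 * config.alpha_tail, axis=0)
    per_well_upper = _nanpercentile(indices, 100 * (1 - config.alpha_tail), axis=0)

    centered = indices - observed[None, :, :]
    cvals = np.where(combo[None, :, :], centered, np.nan)
    flat = cvals.reshape(B, -1)
    any_valid = np.any(np.isfinite(flat), axis=1)
    Imax_dist = np.full(B, np.nan)
    Imin_dist = np.full(B, np.nan)
    Imax_dist[any_valid] = _nanpercentile(flat[any_valid], 100.0, axis=1)  # = nanmax
    Imin_dist[any_valid] = _nanpercentile(flat[any_valid], 0.0, axis=1)

    observed_Imax = float(np.nanmax(np.where(combo, observed, np.nan)))
    observed_Imin = float(np.nanmin(np.where(combo, observed, np.nan)))
    valid = np.isfinite(Imax_dist)
    Imax_upper = float(np.percentile(Imax_dist[valid], 100 * (1 - config.alpha_tail)))
    Imin_lower = float(np.percentile(Imin_dist[valid], 100 * config.alpha_tail))

    return BootstrapResult(
        model=model,
        B=B,
        indices=indices,
        observed=observed,
        combo_mask=combo,
        per_well_lower=per_well_lower,
        per_well_upper=per_well_upper,
        Imax_dist=Imax_dist,
        Imin_dist=Imin_dist,
        observed_Imax=observed_Imax,
        observed_Imin=observed_Imin,
        Imax_upper=Imax_upper,
        Imin_lower=Imin_lower,
        alpha_tail=config.alpha_tail,
        n_failed_batches=n_failed,
        seed=seed,
    )


def omnibus_call(result: BootstrapResult) -> Dict[str, bool]:
    """Global synergy/antagonism decision from the extremal-index test.

    Strict inequalities: synergy iff the observed I_max exceeds the upper
    percentile of its null distribution, antagonism iff the observed I_min
    falls below the lower percentile.  Both can hold at once (synergy and
    antagonism at different concentration ranges).
    """
    return {
        "synergy": bool(result.observed_Imax > result.Imax_upper),
        "antagonism": bool(result.observed_Imin < result.Imin_lower),
    }


def per_well_calls(result: BootstrapResult) -> np.ndarray:
    """Descriptive per-well verdicts from the uncentered bootstrap intervals.

    ``synergy`` where the interval lies entirely above zero, ``antagonism``
    entirely below, ``none`` otherwise (``""`` outside the evaluable wells).
    These are not multiplicity-corrected; the omnibus test is the headline
    inference.
    """
    calls = np.full(result.observed.shape, "", dtype=object)
    evaluable = np.isfinite(result.per_well_lower) & np.isfinite(result.per_well_upper)
    calls[evaluable] = "none"
    calls[evaluable & (result.per_well_lower > 0)] = "synergy"
    calls[evaluable & (result.per_well_upper < 0)] = "antagonism"
    return calls


def joint_call(bliss: Dict[str, bool], loewe: Optional[Dict[str, bool]]) -> str:
    """Combine the two omnibus calls into the summary symbol.

    ``X`` = joint synergy under both models, ``O`` = joint antagonism,
    ``--`` = neither, ``NA`` = Loewe analysis was not possible.  If a screen
    shows joint synergy *and* joint antagonism (at different wells) both
    symbols are reported as ``XO``.
    """
    if loewe is None:
        return "NA"
    symbol = ""
    if bliss["synergy"] and loewe["synergy"]:
        symbol += "X"
    if bliss["antagonism"] and loewe["antagonism"]:
        symbol += "O"
    return symbol or "--"
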