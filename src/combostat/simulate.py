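"""Synthetic checkerboard screens with known ground truth.

Every stage of the pipeline is testable without external data: the
generator builds K replicate (J+1) x (I+1) survival matrices from a chosen
truth model, adds symmetric level-dependent noise, and can inject outliers
and localized synergy/antagonism.

Truth models
------------
``bliss_null``
    Combination survival is the product of two Hill single-drug curves --
    no interaction under the Bliss definition.
``loewe_null``
    The combination surface solves the linear isobole equation for the two
    Hill curves -- no interaction under the Loewe definition.
``exponential``
    S = exp(alpha*cA + beta*cB) with alpha, beta < 0.  Two drugs acting
    independently with exponential single-drug responses multiply into
    exactly this surface, whose isoboles are straight lines: the one case
    that is simultaneously Bliss-independent and Loewe-additive.

Defaults mirror the reference screen layout: I = 8 non-zero concentrations
of drug A, J = 6 of drug B, K = 4 replicate plates (matrices of dimension
7 x 9).  The default noise is Gaussian with a piecewise SD of 0.03 / 0.06 /
0.09 for true survival below 0.3, between 0.3 and 0.7, and above 0.7 --
the level-dependent variability the bootstrap's sliding window is built
for.  A scaled-t option (df = 4, unit variance) exercises the
non-parametric claim with heavier tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .doseresponse import DoseResponseCurve, _hill
from .plate_io import ConcentrationGrid, PlateBatch
from .synergy_models import loewe_response_grid

DEFAULT_NOISE_STRATA = ((0.3, 0.03), (0.7, 0.06), (None, 0.09))


def default_grid() -> ConcentrationGrid:
    """Two-fold dilution ladders centered on the default c50s (1 and 5)."""
    return ConcentrationGrid(
        concs_A=1.0 * 2.0 ** np.arange(-3, 5),  # 0.125 .. 16, I = 8
        concs_B=5.0 * 2.0 ** np.arange(-3, 3),  # 0.625 .. 20, J = 6
    )


@dataclass
class SimSpec:
    """Specification of one synthetic screen.

    ``interaction_map`` maps (i, j) cells to an additive survival shift
    delta; delta > 0 lowers the true combination survival by delta, i.e.
    pushes the well in the synergy direction of the index sign convention.
    """

    grid: ConcentrationGrid = field(default_factory=default_grid)
    K: int = 4
    truth_model: str = "bliss_null"
    curve_A: Tuple[float, float] = (1.0, 2.0)  # (c50, H)
    curve_B: Tuple[float, float] = (5.0, 1.0)
    alpha: float = -1.0  # exponential truth rate constants (alpha, beta < 0)
    beta: float = -0.2
    interaction_map: Dict[Tuple[int, int], float] = field(default_factory=dict)
    noise_strata: tuple = DEFAULT_NOISE_STRATA
    noise_dist: str = "gaussian"  # or "t" (scaled to unit variance, df=t_df)
    t_df: float = 4.0
    outlier_rate: float = 0.0
    outlier_factor_range: Tuple[float, float] = (2.0, 5.0)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.truth_model not in ("bliss_null", "loewe_null", "exponential"):
            raise ValueError(f"unknown truth_model {self.truth_model!r}")
        if self.truth_model == "exponential" and (self.alpha >= 0 or self.beta >= 0):
            raise ValueError("exponential truth requires alpha < 0 and beta < 0")
        if self.noise_dist not in ("gaussian", "t"):
            raise ValueError(f"unknown noise_dist {self.noise_dist!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid" in raw:
            g = raw.pop("grid")
            raw["grid"] = ConcentrationGrid(
                np.asarray(g["concs_A"], dtype=float),
                np.asarray(g["concs_B"], dtype=float),
                g.get("drug_A_name", "drug_A"),
                g.get("drug_B_name", "drug_B"),
            )
        if "interaction_map" in raw:
            raw["interaction_map"] = {
                (int(k.split(",")[0]), int(k.split(",")[1])): float(v)
                for k, v in raw["interaction_map"].items()
            }
        for key in ("curve_A", "curve_B", "outlier_factor_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "noise_strata" in raw:
            raw["noise_strata"] = tuple(
                (None if u is None else float(u), float(s)) for u, s in raw["noise_strata"]
            )
        return cls(**raw)


def noise_sd(true_s: np.ndarray, strata=DEFAULT_NOISE_STRATA) -> np.ndarray:
    """Piecewise-constant residual SD as a function of the true survival."""
    true_s = np.asarray(true_s, dtype=float)
    sd = np.full(true_s.shape, strata[-1][1])
    for upper, s in reversed(strata):
        if upper is not None:
            sd = np.where(true_s < upper, s, sd)
    return sd


def make_truth_surface(spec: SimSpec) -> np.ndarray:
    """Noise-free (J+1) x (I+1) survival surface implied by the spec."""
    cA = np.concatenate([[0.0], spec.grid.concs_A])[None, :]
    cB = np.concatenate([[0.0], spec.grid.concs_B])[:, None]
    if spec.truth_model == "bliss_null":
        sA = _hill(cA, *spec.curve_A)
        sB = _hill(cB, *spec.curve_B)
        surface = sA * sB
    elif spec.truth_model == "loewe_null":
        curveA = DoseResponseCurve(*spec.curve_A)
        curveB = DoseResponseCurve(*spec.curve_B)
        surface = loewe_response_grid(cA, cB, curveA, curveB, tol=1e-12)
    else:  # exponential
        surface = np.exp(spec.alpha * cA + spec.beta * cB)
    surface = np.broadcast_to(surface, (spec.grid.J + 1, spec.grid.I + 1)).copy()
    for (i, j), delta in spec.interaction_map.items():
        surface[j, i] -= delta
    return np.clip(surface, 0.0, None)


def make_batch(spec: SimSpec, rng=None) -> PlateBatch:
    """Simulate one K-replicate screen; bit-reproducible given a seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    truth = make_truth_surface(spec)
    sd = noise_sd(truth, spec.noise_strata)
    shape = truth.shape + (spec.K,)
    if spec.noise_dist == "gaussian":
        noise = rng.normal(0.0, 1.0, size=shape)
    else:
        scale = np.sqrt(spec.t_df / (spec.t_df - 2.0))
        noise = rng.standard_t(spec.t_df, size=shape) / scale
    S = truth[:, :, None] + sd[:, :, None] * noise
    if spec.outlier_rate > 0:
        hit = rng.random(shape) < spec.outlier_rate
        lo, hi = spec.outlier_factor_range
        factors = rng.uniform(lo, hi, size=shape)
        S = np.where(hit, S * factors, S)
    return PlateBatch(grid=spec.grid, S=S)


def batch_to_fluorescence_records(
    batch: PlateBatch,
    f_blank: float = 200.0,
    f_control: float = 2000.0,
    n_blank: int = 4,
    n_control: int = 4,
    rng=None,
    well_noise_sd: float = 0.0,
):
    """Back-transform a survival batch to raw-fluorescence rows.

    Uses f = f_blank + S * (f_control - f_blank) so plate reading, QC and
    survival conversion can be exercised end to end; choosing
    f_control / f_blank <= 5 produces a screen that fails assay QC.
    Returns a pandas DataFrame in the canonical CSV schema.
    """
    import pandas as pd

    from .plate_io import _role_for

    rng = np.random.default_rng(rng)
    span = f_control - f_blank
    rows = []
    for k in range(batch.K):
        pid = f"plate{k + 1}"
        for n in range(n_blank):
            rows.append(
                dict(plate_id=pid, well_role="blank", i=0, j=0, conc_A=0.0, conc_B=0.0,
                     fluorescence=f_blank + rng.normal(0, well_noise_sd) if well_noise_sd else f_blank)
            )
        for n in range(n_control):
            rows.append(
                dict(plate_id=pid, well_role="control", i=0, j=0, conc_A=0.0, conc_B=0.0,
                     fluorescence=f_control + rng.normal(0, well_noise_sd) if well_noise_sd else f_control)
            )
        for j in range(batch.grid.J + 1):
            for i in range(batch.grid.I + 1):
                if i == 0 and j == 0:
                    continue
                v = batch.S[j, i, k]
                if not np.isfinite(v):
                    continue
                rows.append(
                    dict(
                        plate_id=pid,
                        well_role=_role_for(i, j),
                        i=i,
                        j=j,
                        conc_A=batch.grid.conc_A_at(i),
                        conc_B=batch.grid.conc_B_at(j),
                        fluorescence=f_blank + v * span,
                    )
                )
    return pd.DataFrame(rows)
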