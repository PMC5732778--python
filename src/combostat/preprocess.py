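"""Fluorescence-to-survival conversion, assay QC and outlier screening.

The viability readout is a fluorometric microculture cytotoxicity assay:
hydrolysis of fluorescein diacetate in intact cells yields fluorescence
proportional to the number of surviving cells.  Each plate carries blank
wells (medium only) and growth-control wells (cells, no drug); the survival
index of an exposed well is its background-corrected, control-normalized
fluorescence.  An assay is accepted only if the control/blank ratio exceeds
5 and the control-well coefficient of variation stays below 30%.

Replicate survival values for each concentration pair are screened for
outliers with the same 30% CV rule: while the sample CV exceeds the
threshold and more than ``min_keep`` replicates remain, the single value
contributing most to the CV (largest absolute deviation from the current
mean) is removed and the statistics are recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .errors import DegenerateAssayError, InsufficientControlsError

logger = logging.getLogger(__name__)


def survival_index(f_exposed, f_blank: float, f_control: float):
    """Survival index S = (f_exposed - f_blank) / (f_control - f_blank).

    ``f_blank`` and ``f_control`` are the plate's mean blank and mean
    control fluorescence.  The result is not clamped; values below 0 or
    above 1 are legitimate noisy observations.
    """
    if f_control <= f_blank:
        raise DegenerateAssayError(
            f"mean control fluorescence ({f_control}) must exceed mean blank ({f_blank})"
        )
    return (np.asarray(f_exposed, dtype=float) - f_blank) / (f_control - f_blank)


def _cv(values: np.ndarray) -> float:
    """Sample (n-1) coefficient of variation; inf when the mean is ~0."""
    m = np.mean(values)
    sd = np.std(values, ddof=1)
    if abs(m) < 1e-12:
        return np.inf if sd > 0 else 0.0
    return float(sd / abs(m))


@dataclass
class QCReport:
    """Assay-level QC summary for one plate."""

    plate_id: str
    control_blank_ratio: float
    control_cv: float
    replicate_cv_violations: List[Tuple[int, int]] = field(default_factory=list)
    passed: bool = False


def qc_assay(plate, config=None) -> "QCReport":
    """Evaluate assay acceptance criteria on one plate of raw records.

    ``plate`` is a DataFrame slice of the canonical CSV for a single
    ``plate_id`` with a ``fluorescence`` column.  The plate passes iff the
    control/blank mean ratio is strictly greater than ``qc_ratio_min`` and
    the control CV is strictly below ``qc_cv_max``.  Cells whose replicate
    wells within the plate violate the CV bound are reported for
    information; replicate-level cleanup across plates is handled by
    :func:`remove_outliers`.
    """
    from .config import AnalysisConfig

    config = config or AnalysisConfig()
    blanks = plate[plate["well_role"] == "blank"]["fluorescence"].astype(float)
    controls = plate[plate["well_role"] == "control"]["fluorescence"].astype(float)
    if len(blanks) < 1:
        raise InsufficientControlsError("plate has no blank wells")
    if len(controls) < 2:
        raise InsufficientControlsError(
            f"plate has {len(controls)} control wells; at least 2 required for QC"
        )
    ratio = float(controls.mean() / blanks.mean())
    control_cv = _cv(controls.to_numpy())

    violations: List[Tuple[int, int]] = []
    exposed = plate[~plate["well_role"].isin(["blank", "control"])]
    for (i, j), sub in exposed.groupby(["i", "j"]):
        vals = sub["fluorescence"].to_numpy(dtype=float)
        if len(vals) >= 2 and _cv(vals) >= config.qc_cv_max:
            violations.append((int(i), int(j)))

    passed = (ratio > config.qc_ratio_min) and (control_cv < config.qc_cv_max)
    pid = str(plate["plate_id"].iloc[0]) if len(plate) else "?"
    if not passed:
        logger.warning(
            "plate %s fails assay QC (control/blank ratio %.3g, control CV %.3g)",
            pid,
            ratio,
            control_cv,
        )
    return QCReport(
        plate_id=pid,
        control_blank_ratio=ratio,
        control_cv=control_cv,
        replicate_cv_violations=violations,
        passed=passed,
    )


def remove_outliers(
    values: Sequence[float],
    cv_threshold: float = 0.30,
    min_keep: int = 2,
) -> Tuple[np.ndarray, List[int]]:
    """Iterative CV-based outlier removal for one cell's replicates.

    While the sample CV exceeds ``cv_threshold`` and more than ``min_keep``
    values remain, the value with the largest absolute deviation from the
    current mean is removed; mean and CV are recomputed after every single
    removal.  Ties in deviation are broken by removing the larger value
    (high outliers are the common plate artifact).  Returns the surviving
    values and the original indices of the removed ones.

    Cells whose mean is ~0 with non-zero spread have an undefined CV; they
    are flagged with a warning and left untouched.
    """
    vals = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(vals)) < 2:
        raise ValueError("need at least 2 finite replicate values")
    keep = [idx for idx in range(len(vals)) if np.isfinite(vals[idx])]
    removed: List[int] = []
    while len(keep) > min_keep:
        current = vals[keep]
        m = np.mean(current)
        sd = np.std(current, ddof=1)
        if abs(m) < 1e-12:
            if sd > 0:
                logger.warning(
                    "replicate mean ~0 with non-zero spread; CV undefined, no removal"
                )
            break
        if sd / abs(m) <= cv_threshold:
            break
        dev = np.abs(current - m)
        worst = np.flatnonzero(dev == dev.max())
        if len(worst) > 1:  # tie: drop the larger value
            worst = worst[np.argmax(current[worst])]
        else:
            worst = worst[0]
        removed_idx = keep.pop(int(worst))
        removed.append(removed_idx)
        logger.debug("removed replicate %d (value %.4g)", removed_idx, vals[removed_idx])
    return vals[keep], removed


def clean_batch(batch, config=None):
    """Apply per-cell outlier removal to a whole batch.

    Returns a new :class:`~combostat.plate_io.PlateBatch` with removed
    replicates set to NaN and an audit trail in ``provenance``.  Cells left
    with fewer than ``min_replicates_keep`` finite replicates (possible only
    through missing input wells) are blanked entirely and recorded, since no
    interaction index can be estimated there.
    """
    from .config import AnalysisConfig

    config = config or AnalysisConfig()
    out = batch.copy()
    J1, I1, K = out.S.shape
    for j in range(J1):
        for i in range(I1):
            finite = np.flatnonzero(np.isfinite(out.S[j, i, :]))
            if len(finite) < config.min_replicates_keep:
                if len(finite) > 0:
                    out.S[j, i, :] = np.nan
                    out.provenance[(i, j)] = {
                        "removed": finite.tolist(),
                        "reason": "fewer than min replicates present",
                    }
                    logger.warning(
                        "cell (i=%d, j=%d) has <%d replicates; excluded from analysis",
                        i,
                        j,
                        config.min_replicates_keep,
                    )
                continue
            kept, removed_local = remove_outliers(
                out.S[j, i, :],
                cv_threshold=config.cv_threshold,
                min_keep=config.min_replicates_keep,
            )
            if removed_local:
                out.S[j, i, removed_local] = np.nan
                out.provenance[(i, j)] = {
                    "removed": [int(r) for r in removed_local],
                    "reason": "cv_outlier",
                }
    return out
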