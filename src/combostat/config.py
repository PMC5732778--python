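"""Analysis configuration.

All tunable parameters of the pipeline live in one dataclass so a run can be
serialized alongside its results for provenance.  Defaults follow the
method's reference settings: a 30% coefficient-of-variation threshold for
outlier screening, a control/blank fluorescence ratio of 5 for assay
acceptance, B = 1000 bootstrap batches, a 10% sliding residual window and
2.5% tails for the bootstrap intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigError

VALID_MODELS = ("bliss", "loewe")


@dataclass
class AnalysisConfig:
    """Container for every knob the pipeline exposes.

    Parameters
    ----------
    cv_threshold:
        Replicate coefficient of variation above which outlier removal
        iterates (fraction, default 0.30).
    min_replicates_keep:
        Outlier removal never leaves fewer than this many replicates.
    qc_ratio_min:
        Minimum control/blank mean-fluorescence ratio (strict inequality).
    qc_cv_max:
        Maximum control-well coefficient of variation (strict inequality).
    force_qc:
        Proceed even if assay QC fails (an in-silico run cannot "repeat the
        assay", so the default is a hard stop).
    hill_multistart:
        Number of start points for the Hill least-squares fit.
    flat_curve_range_min:
        Minimum fitted dynamic range below which a concentration-response
        curve is declared not computable (Loewe analysis then yields NA).
    loewe_bisection_tol:
        Absolute tolerance on the survival level when inverting the linear
        isobole equation.
    B:
        Number of bootstrap batches.
    window_fraction:
        Fraction of all wells pooled into each cell's residual window.
    alpha_tail:
        Tail mass on each side of the bootstrap interval (0.025 gives the
        2.5/97.5 percentile interval).
    rescale_residuals:
        Restore residual variance by sqrt(K/(K-1)) per cell before pooling,
        compensating for the shrinkage of residuals about a K-replicate mean.
    seed:
        Seed for all randomness in the run.
    models:
        Which interaction models to run.
    figures:
        Emit network figures when writing results.
    """

    cv_threshold: float = 0.30
    min_replicates_keep: int = 2
    qc_ratio_min: float = 5.0
    qc_cv_max: float = 0.30
    force_qc: bool = False
    hill_multistart: int = 3
    flat_curve_range_min: float = 0.1
    loewe_bisection_tol: float = 1e-9
    B: int = 1000
    window_fraction: float = 0.10
    alpha_tail: float = 0.025
    rescale_residuals: bool = True
    seed: Optional[int] = None
    models: Sequence[str] = ("bliss", "loewe")
    figures: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.window_fraction <= 1.0):
            raise ConfigError(
                f"window_fraction must be in (0, 1], got {self.window_fraction}"
            )
        if self.cv_threshold <= 0:
            raise ConfigError("cv_threshold must be positive")
        if self.min_replicates_keep < 2:
            raise ConfigError("min_replicates_keep must be at least 2")
        if not (0.0 < self.alpha_tail < 0.5):
            raise ConfigError("alpha_tail must be in (0, 0.5)")
        if self.B < 1:
            raise ConfigError("B must be a positive integer")
        for m in self.models:
            if m not in VALID_MODELS:
                raise ConfigError(f"unknown model {m!r}; valid: {VALID_MODELS}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
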