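"""Reading and writing checkerboard combination-screen data.

The canonical on-disk format is a long-format CSV with one row per well and
the columns

    plate_id, well_role, i, j, conc_A, conc_B, fluorescence, survival

``well_role`` is one of ``blank``, ``control``, ``single_A``, ``single_B``
or ``combo``.  Concentration indices are 0-based; index 0 means the drug is
absent, so a screen with I non-zero concentrations of drug A and J of drug B
occupies a (J+1) x (I+1) grid of cells.  Replicates are separate plates that
share one concentration grid.  Either every row carries ``fluorescence``
(raw plate-reader mode, blanks and growth controls required) or every
non-blank row carries ``survival`` (precomputed survival indices; blank rows
are then unnecessary).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import GridMismatchError, SchemaError

logger = logging.getLogger(__name__)

WELL_ROLES = ("blank", "control", "single_A", "single_B", "combo")
REQUIRED_COLUMNS = ("plate_id", "well_role", "i", "j", "conc_A", "conc_B")


@dataclass
class ConcentrationGrid:
    """The two non-zero concentration ladders of a checkerboard screen.

    Only ratios of concentrations on the same ladder enter the mathematics;
    units are opaque labels carried through for reporting.
    """

    concs_A: np.ndarray
    concs_B: np.ndarray
    drug_A_name: str = "drug_A"
    drug_B_name: str = "drug_B"

    def __post_init__(self) -> None:
        self.concs_A = np.asarray(self.concs_A, dtype=float)
        self.concs_B = np.asarray(self.concs_B, dtype=float)
        for name, c in (("concs_A", self.concs_A), ("concs_B", self.concs_B)):
            if c.ndim != 1 or c.size < 2:
                raise ValueError(f"{name} must be a vector with at least 2 entries")
            if np.any(c <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if np.any(np.diff(c) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return self.concs_A.size

    @property
    def J(self) -> int:
        return self.concs_B.size

    def conc_A_at(self, i: int) -> float:
        return 0.0 if i == 0 else float(self.concs_A[i - 1])

    def conc_B_at(self, j: int) -> float:
        return 0.0 if j == 0 else float(self.concs_B[j - 1])


@dataclass
class PlateBatch:
    """K replicate survival-index matrices on a shared concentration grid.

    ``S`` has shape (J+1, I+1, K) with NaN marking missing or removed
    replicates; cell (0, 0) holds the growth controls whose mean is ~1 by
    construction of the survival index.  ``provenance`` records, per cell,
    which replicates were dropped and why.
    """

    grid: ConcentrationGrid
    S: np.ndarray
    provenance: Dict[Tuple[int, int], dict] = field(default_factory=dict)
    qc_reports: List = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        expected = (self.grid.J + 1, self.grid.I + 1)
        if self.S.ndim != 3 or self.S.shape[:2] != expected:
            raise ValueError(
                f"S has shape {self.S.shape}, expected ({expected[0]}, {expected[1]}, K)"
            )

    @property
    def K(self) -> int:
        return self.S.shape[2]

    def well_means(self) -> np.ndarray:
        """Per-cell mean over non-missing replicates (NaN if none)."""
        cnt = self.counts()
        with np.errstate(invalid="ignore"):
            total = np.nansum(self.S, axis=2)
        means = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
        return means

    def counts(self) -> np.ndarray:
        return np.sum(np.isfinite(self.S), axis=2)

    def combo_mask(self) -> np.ndarray:
        """Cells where both drugs are present (i >= 1 and j >= 1)."""
        mask = np.zeros(self.S.shape[:2], dtype=bool)
        mask[1:, 1:] = True
        return mask

    def copy(self) -> "PlateBatch":
        return PlateBatch(
            grid=self.grid,
            S=self.S.copy(),
            provenance={k: dict(v) for k, v in self.provenance.items()},
            qc_reports=list(self.qc_reports),
        )


def _role_for(i: int, j: int) -> str:
    if i == 0 and j == 0:
        return "control"
    if j == 0:
        return "single_A"
    if i == 0:
        return "single_B"
    return "combo"


def _validate_roles(df: pd.DataFrame) -> None:
    bad = set(df["well_role"]) - set(WELL_ROLES)
    if bad:
        raise SchemaError(f"unknown well_role values: {sorted(bad)}")
    for role, sub in df.groupby("well_role"):
        if role in ("blank", "control"):
            if (sub["i"] != 0).any() or (sub["j"] != 0).any():
                raise SchemaError(f"{role} wells must have i = j = 0")
            if (sub["conc_A"] != 0).any() or (sub["conc_B"] != 0).any():
                raise SchemaError(f"{role} wells must have zero concentrations")
        elif role == "single_A":
            if (sub["j"] != 0).any() or (sub["conc_B"] != 0).any() or (sub["i"] < 1).any():
                raise SchemaError("single_A wells require i >= 1 and j = 0")
        elif role == "single_B":
            if (sub["i"] != 0).any() or (sub["conc_A"] != 0).any() or (sub["j"] < 1).any():
                raise SchemaError("single_B wells require j >= 1 and i = 0")
        elif role == "combo":
            if (sub["i"] < 1).any() or (sub["j"] < 1).any():
                raise SchemaError("combo wells require i >= 1 and j >= 1")


def _ladder_from(df: pd.DataFrame, idx_col: str, conc_col: str, label: str) -> np.ndarray:
    """Extract the index -> concentration mapping and check monotonicity."""
    sub = df[df[idx_col] >= 1][[idx_col, conc_col]].drop_duplicates()
    if sub.empty:
        raise SchemaError(f"no non-zero concentrations found for {label}")
    by_idx = sub.groupby(idx_col)[conc_col].nunique()
    if (by_idx > 1).any():
        bad = by_idx[by_idx > 1].index.tolist()
        raise GridMismatchError(f"{label}: conflicting concentrations at indices {bad}")
    mapping = sub.groupby(idx_col)[conc_col].first().sort_index()
    indices = mapping.index.to_numpy()
    if not np.array_equal(indices, np.arange(1, indices.max() + 1)):
        raise SchemaError(f"{label}: concentration indices must be contiguous from 1")
    ladder = mapping.to_numpy(dtype=float)
    if np.any(ladder <= 0) or np.any(np.diff(ladder) <= 0):
        raise GridMismatchError(
            f"{label}: concentrations must be strictly positive and increasing in the index"
        )
    return ladder


def read_plate_csv(
    path: str | Path,
    config=None,
    drug_A_name: str = "drug_A",
    drug_B_name: str = "drug_B",
) -> PlateBatch:
    """Read a long-format checkerboard CSV into a :class:`PlateBatch`.

    If the file carries raw fluorescence, survival indices are computed per
    plate from its blank and control wells and an assay QC report is
    attached for each plate (enforcement is left to the caller).  Cells
    absent on some plate become missing values with a logged warning.
    """
    from . import preprocess  # deferred to avoid an import cycle
    from .config import AnalysisConfig

    config = config or AnalysisConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    has_flu = "fluorescence" in df.columns and df["fluorescence"].notna().all()
    nonblank = df[df["well_role"] != "blank"]
    has_surv = "survival" in df.columns and nonblank["survival"].notna().all()
    if not has_flu and not has_surv:
        raise SchemaError(
            "need either a complete 'fluorescence' column or a 'survival' "
            "column complete on all non-blank rows"
        )
    df = df.copy()
    df["i"] = df["i"].astype(int)
    df["j"] = df["j"].astype(int)
    _validate_roles(df)

    ladder_A = _ladder_from(nonblank, "i", "conc_A", "drug A")
    ladder_B = _ladder_from(nonblank, "j", "conc_B", "drug B")
    # every plate must agree with the global ladders
    for pid, sub in nonblank.groupby("plate_id"):
        for idx_col, conc_col, ladder, label in (
            ("i", "conc_A", ladder_A, "drug A"),
            ("j", "conc_B", ladder_B, "drug B"),
        ):
            s = sub[sub[idx_col] >= 1]
            expect = ladder[s[idx_col].to_numpy() - 1]
            if not np.allclose(s[conc_col].to_numpy(dtype=float), expect, rtol=1e-9, atol=0):
                raise GridMismatchError(
                    f"plate {pid}: {label} concentrations disagree with the common ladder"
                )
    grid = ConcentrationGrid(ladder_A, ladder_B, drug_A_name, drug_B_name)

    plate_ids = list(dict.fromkeys(df["plate_id"]))  # stable order of appearance
    K = len(plate_ids)
    S = np.full((grid.J + 1, grid.I + 1, K), np.nan)
    qc_reports = []
    if has_surv:
        work = df[df["well_role"] != "blank"].copy()
        work["_value"] = work["survival"].astype(float)
    else:
        work = df.copy()

    for k, pid in enumerate(plate_ids):
        plate = work[work["plate_id"] == pid]
        if not has_surv:
            report = preprocess.qc_assay(plate, config)
            qc_reports.append(report)
            blanks = plate[plate["well_role"] == "blank"]["fluorescence"].astype(float)
            controls = plate[plate["well_role"] == "control"]["fluorescence"].astype(float)
            if blanks.empty:
                raise SchemaError(f"plate {pid}: fluorescence mode requires blank wells")
            f_blank = float(blanks.mean())
            f_control = float(controls.mean())
            plate = plate[plate["well_role"] != "blank"].copy()
            plate["_value"] = preprocess.survival_index(
                plate["fluorescence"].to_numpy(dtype=float), f_blank, f_control
            )
        cell_means = plate.groupby(["j", "i"])["_value"].mean()
        for (j, i), val in cell_means.items():
            S[j, i, k] = val

    # warn about cells missing on some plates
    for j in range(grid.J + 1):
        for i in range(grid.I + 1):
            n_missing = int(np.sum(~np.isfinite(S[j, i, :])))
            if 0 < n_missing < K:
                logger.warning(
                    "cell (i=%d, j=%d) missing on %d of %d plates", i, j, n_missing, K
                )

    return PlateBatch(grid=grid, S=S, qc_reports=qc_reports)


def write_plate_csv(batch: PlateBatch, path: str | Path) -> None:
    """Write a batch back to the canonical long CSV (survival mode)."""
    rows = []
    for k in range(batch.K):
        for j in range(batch.grid.J + 1):
            for i in range(batch.grid.I + 1):
                v = batch.S[j, i, k]
                if not np.isfinite(v):
                    continue
                rows.append(
                    {
                        "plate_id": f"plate{k + 1}",
                        "well_role": _role_for(i, j),
                        "i": i,
                        "j": j,
                        "conc_A": batch.grid.conc_A_at(i),
                        "conc_B": batch.grid.conc_B_at(j),
                        "survival": v,
                    }
                )
    # %.17g guarantees a lossless float round trip
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def _matrix_frame(values: np.ndarray, grid: ConcentrationGrid) -> pd.DataFrame:
    cols = [0.0] + list(grid.concs_A)
    idx = [0.0] + list(grid.concs_B)
    return pd.DataFrame(values, index=pd.Index(idx, name="conc_B"), columns=cols)


def write_results(result, out_dir: str | Path) -> List[Path]:
    """Write a completed analysis to ``out_dir``.

    Emits per-well index matrices and bootstrap interval bounds as CSV
    (rows = drug-B concentration, columns = drug-A concentration), a
    machine-readable ``summary.json``, the run configuration, and optional
    figures.  Returns the list of files written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: List[Path] = []

    grid = result.batch.grid
    for model, boot in result.bootstrap.items():
        if boot is None:
            continue
        for name, arr in (
            ("index", boot.observed),
            ("bi_lower", boot.per_well_lower),
            ("bi_upper", boot.per_well_upper),
        ):
            p = out_dir / f"{model}_{name}.csv"
            _matrix_frame(arr, grid).to_csv(p)
            written.append(p)

    p = out_dir / "summary.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)

    p = out_dir / "config.yaml"
    result.config.to_yaml(p)
    written.append(p)

    if result.config.figures:
        from .cli_report import save_figures

        written.extend(save_figures(result, out_dir))
    return written
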