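"""Balanced longitudinal binary panels and the partitioned (lagged) design matrix.

A marginal logistic model for a binary outcome measured at waves t = 1..T can
let each time-dependent covariate act on the outcome at every later wave as
well as contemporaneously.  Splitting a covariate's effect by the wave
separation t - s yields one coefficient per lag; the design matrix that
carries this partition stacks, per subject, a lower-triangular block per
covariate: the lag-k column holds the covariate's value k waves before the
outcome row, and structural zeros where no such measurement exists.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import BalanceError, ConfigurationError, DataError, ParameterError

logger = logging.getLogger(__name__)

ColumnLabel = tuple[str, Optional[int]]

INTERCEPT_NAME = "(Intercept)"


def _as_2d(a, name):
    a = np.asarray(a)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ParameterError(f"{name} must be 2-dimensional, got shape {a.shape}")
    return a


@dataclasses.dataclass
class PanelDataset:
    """A balanced panel: N subjects observed at each of T waves.

    Parameters
    ----------
    subject_ids : sequence of length N
        Identifiers, kept in the order subjects appear.
    y : ndarray (N, T)
        Binary outcome, y[i, t-1] is subject i's outcome at wave t.
    x_td : ndarray (N, T, J)
        Time-dependent covariates, re-measured at every wave.
    td_names : sequence of J names
    x_fixed : ndarray (N, F)
        Time-independent covariates (constant within subject).
    fixed_names : sequence of F names
    wave_labels : sequence of T original wave labels (e.g. calendar years),
        ascending; internally waves are always 1..T.
    """

    subject_ids: np.ndarray
    y: np.ndarray
    x_td: np.ndarray
    td_names: Sequence[str]
    x_fixed: np.ndarray
    fixed_names: Sequence[str]
    wave_labels: Optional[Sequence] = None
    outcome_name: str = "y"

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.y = np.asarray(self.y, dtype=float)
        self.x_td = np.asarray(self.x_td, dtype=float)
        self.x_fixed = _as_2d(self.x_fixed, "x_fixed").astype(float)
        self.td_names = list(self.td_names)
        self.fixed_names = list(self.fixed_names)
        if self.y.ndim != 2:
            raise ParameterError(f"y must have shape (N, T), got {self.y.shape}")
        n, t = self.y.shape
        if n < 1 or t < 1:
            raise DataError("need N >= 1 subjects and T >= 1 waves")
        if self.x_td.ndim != 3 or self.x_td.shape[:2] != (n, t):
            raise ParameterError(
                f"x_td must have shape (N, T, J) = ({n}, {t}, J), got {self.x_td.shape}"
            )
        if self.x_td.shape[2] < 1:
            raise DataError("need at least one time-dependent covariate (J >= 1)")
        if self.subject_ids.shape[0] != n:
            raise ParameterError("subject_ids length must equal N")
        if len(np.unique(self.subject_ids)) != n:
            raise DataError("subject ids must be unique")
        if self.x_fixed.shape[0] != n:
            raise ParameterError("x_fixed must have N rows")
        if len(self.td_names) != self.x_td.shape[2]:
            raise ParameterError("td_names length must equal J")
        if len(self.fixed_names) != self.x_fixed.shape[1]:
            raise ParameterError("fixed_names length must equal F")
        if np.isnan(self.y).any() or np.isnan(self.x_td).any() or np.isnan(self.x_fixed).any():
            raise DataError("missing values are not supported; no imputation is performed")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise DataError("outcome must be binary (0/1) at every (subject, wave)")
        if self.wave_labels is None:
            self.wave_labels = list(range(1, t + 1))
        else:
            self.wave_labels = list(self.wave_labels)
            if len(self.wave_labels) != t:
                raise ParameterError("wave_labels length must equal T")

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_waves(self) -> int:
        return self.y.shape[1]

    @property
    def n_td(self) -> int:
        return self.x_td.shape[2]

    @property
    def n_fixed(self) -> int:
        return self.x_fixed.shape[1]

    def to_long_frame(self, id_col="id", wave_col="wave") -> pd.DataFrame:
        """One row per (subject, wave), covariates in columns."""
        n, t = self.n_subjects, self.n_waves
        frame = {
            id_col: np.repeat(self.subject_ids, t),
            wave_col: np.tile(np.asarray(self.wave_labels, dtype=object), n),
            self.outcome_name: self.y.reshape(-1),
        }
        for f, name in enumerate(self.fixed_names):
            frame[name] = np.repeat(self.x_fixed[:, f], t)
        for j, name in enumerate(self.td_names):
            frame[name] = self.x_td[:, :, j].reshape(-1)
        return pd.DataFrame(frame)

    def write_long_csv(self, path, id_col="id", wave_col="wave") -> None:
        self.to_long_frame(id_col=id_col, wave_col=wave_col).to_csv(path, index=False)


def _load_mapping(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    path = Path(config)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def from_long_frame(df: pd.DataFrame, config) -> PanelDataset:
    """Build a validated :class:`PanelDataset` from a long-format frame.

    ``config`` is a mapping (or a YAML/JSON file path) with keys ``id``,
    ``wave``, ``outcome``, ``time_dependent`` (list) and optionally ``fixed``
    (list) and ``drop_incomplete`` (bool, default False).
    """
    cfg = _load_mapping(config)
    for key in ("id", "wave", "outcome", "time_dependent"):
        if key not in cfg:
            raise ConfigurationError(f"column mapping is missing required key '{key}'")
    id_col, wave_col, y_col = cfg["id"], cfg["wave"], cfg["outcome"]
    td_cols = list(cfg["time_dependent"])
    fixed_cols = list(cfg.get("fixed", []))
    drop_incomplete = bool(cfg.get("drop_incomplete", False))
    if not td_cols:
        raise ConfigurationError("'time_dependent' must list at least one column")

    needed = [id_col, wave_col, y_col] + fixed_cols + td_cols
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigurationError(f"input is missing mapped columns: {missing}")

    wave_labels = sorted(df[wave_col].unique())
    t = len(wave_labels)
    wave_rank = {w: k for k, w in enumerate(wave_labels)}

    counts = df.groupby(id_col)[wave_col].agg(["size", "nunique"])
    complete = counts[(counts["size"] == t) & (counts["nunique"] == t)].index
    incomplete = counts.index.difference(complete)
    if len(incomplete) > 0:
        if not drop_incomplete:
            sid = incomplete[0]
            raise BalanceError(
                f"subject {sid!r} does not have exactly one record per wave "
                f"(expected waves {wave_labels}); set drop_incomplete to discard"
            )
        logger.warning("dropping %d incomplete subject(s)", len(incomplete))
        df = df[df[id_col].isin(complete)]
    if df.empty:
        raise DataError("no complete subjects remain")

    df = df.copy()
    df["_rank"] = df[wave_col].map(wave_rank)
    df = df.sort_values([id_col, "_rank"], kind="stable")

    subject_ids = df[id_col].to_numpy()[::t]
    n = len(subject_ids)

    def grid(col):
        vals = df[col].to_numpy()
        if np.issubdtype(np.asarray(vals).dtype, np.number):
            vals = vals.astype(float)
        else:
            raise DataError(f"column '{col}' is not numeric")
        return vals.reshape(n, t)

    y = grid(y_col)
    if not np.isin(y[~np.isnan(y)], (0.0, 1.0)).all():
        raise DataError(f"outcome column '{y_col}' is not binary 0/1")
    x_td = np.stack([grid(c) for c in td_cols], axis=2)
    if fixed_cols:
        fixed_grid = np.stack([grid(c) for c in fixed_cols], axis=2)
        if np.nanmax(np.abs(fixed_grid - fixed_grid[:, :1, :])) > 0:
            raise DataError("a 'fixed' column varies within subject")
        x_fixed = fixed_grid[:, 0, :]
    else:
        x_fixed = np.empty((n, 0))

    return PanelDataset(
        subject_ids=subject_ids,
        y=y,
        x_td=x_td,
        td_names=td_cols,
        x_fixed=x_fixed,
        fixed_names=fixed_cols,
        wave_labels=wave_labels,
        outcome_name=y_col,
    )


def read_long_csv(path, config) -> PanelDataset:
    """Read a long-format CSV (one row per subject-wave) into a PanelDataset."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    return from_long_frame(pd.read_csv(path), config)


@dataclasses.dataclass
class PartitionedDesign:
    """The N*T-row design matrix with labeled (covariate, lag) columns.

    ``column_labels`` pairs each column with its lag: ``None`` for the
    intercept, wave indicators and time-independent covariates; k for the
    lag-k block of a time-dependent covariate.  Rows are grouped by subject,
    waves ascending within subject.
    """

    Z: np.ndarray
    column_labels: list[ColumnLabel]
    row_subjects: np.ndarray
    row_waves: np.ndarray  # 1..T

    @property
    def n_rows(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [format_label(lbl) for lbl in self.column_labels]

    @property
    def max_lag(self) -> int:
        lags = [lag for _, lag in self.column_labels if lag is not None]
        return max(lags) if lags else 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Z, columns=self.column_names)
        df.insert(0, "wave", self.row_waves)
        df.insert(0, "subject", self.row_subjects)
        return df

    def select_columns(self, indices: Sequence[int]) -> "PartitionedDesign":
        indices = list(indices)
        return PartitionedDesign(
            Z=self.Z[:, indices],
            column_labels=[self.column_labels[i] for i in indices],
            row_subjects=self.row_subjects,
            row_waves=self.row_waves,
        )


def format_label(label: ColumnLabel) -> str:
    name, lag = label
    return name if lag is None else f"{name}.lag{lag}"


def build_partitioned_design(
    data: PanelDataset,
    max_lag: Optional[int] = None,
    include_fixed: bool = True,
    wave_effects: bool = False,
) -> PartitionedDesign:
    """Build the lower-triangular partitioned design matrix.

    Column order: intercept, optional wave indicators (waves 2..T), the
    time-independent covariates, then per time-dependent covariate its
    lag-0 .. lag-``max_lag`` block.  The lag-k column of covariate j holds
    x_{ij(t-k)} in the row for wave t when t > k, and 0 when t <= k.  No
    column is dropped here even if all-zero; rank screening happens at fit
    time.
    """
    n, t, j = data.n_subjects, data.n_waves, data.n_td
    if max_lag is None:
        max_lag = t - 1
    if not (0 <= max_lag <= t - 1):
        raise ParameterError(f"max_lag must be in [0, T-1] = [0, {t - 1}], got {max_lag}")

    labels: list[ColumnLabel] = [(INTERCEPT_NAME, None)]
    blocks = [np.ones((n, t, 1))]
    if wave_effects:
        for w in range(2, t + 1):
            ind = np.zeros((n, t, 1))
            ind[:, w - 1, 0] = 1.0
            blocks.append(ind)
            labels.append((f"wave_{data.wave_labels[w - 1]}", None))
    if include_fixed:
        for f, name in enumerate(data.fixed_names):
            blocks.append(np.repeat(data.x_fixed[:, f][:, None, None], t, axis=1))
            labels.append((name, None))
    for jj, name in enumerate(data.td_names):
        for k in range(max_lag + 1):
            col = np.zeros((n, t, 1))
            col[:, k:, 0] = data.x_td[:, : t - k, jj]
            blocks.append(col)
            labels.append((name, k))

    z = np.concatenate(blocks, axis=2).reshape(n * t, -1)
    return PartitionedDesign(
        Z=z,
        column_labels=labels,
        row_subjects=np.repeat(data.subject_ids, t),
        row_waves=np.tile(np.arange(1, t + 1), n),
    )


def marginal_mean(beta, design: Union[PartitionedDesign, np.ndarray]) -> np.ndarray:
    """Row-wise marginal success probability: inverse-logit of Z @ beta."""
    z = design.Z if isinstance(design, PartitionedDesign) else np.asarray(design, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (z.shape[1],):
        raise ParameterError(
            f"beta has length {beta.shape}, design has {z.shape[1]} columns"
        )
    return expit(z @ beta)
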