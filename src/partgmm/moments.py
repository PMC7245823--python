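"""Moment-condition screening for lagged time-dependent covariates.

Estimation rests on product-moments E[x * (y - mu)] = 0.  Pairings in which
the covariate enters the same design row as the outcome (the lower-triangular
columns, including all cross-sectional terms) identify the coefficients and
are taken as valid.  Every remaining (covariate wave s, outcome wave t) pair
is a *candidate* over-identifying moment whose validity is an empirical
question: if the covariate responds to past outcomes (feedback), moments that
pair a later covariate measurement with an earlier residual fail.  Each
candidate is screened with a bivariate correlation test — Pearson correlation
across subjects between x_{ijs} and the standardized residual at wave t,
referred to a Fisher-z null.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import DegenerateFitError, ParameterError
from .panel import ColumnLabel, PanelDataset, PartitionedDesign, marginal_mean

_MEAN_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class ExtraMoment:
    """One over-identifying product-moment: covariate j at wave s vs outcome at wave t."""

    cov_index: int
    cov_name: str
    cov_wave: int
    outcome_wave: int

    @property
    def separation(self) -> int:
        """Wave separation t - s (negative when the covariate is measured later)."""
        return self.outcome_wave - self.cov_wave

    @property
    def label(self) -> str:
        return f"{self.cov_name}[s={self.cov_wave},t={self.outcome_wave}]"


@dataclasses.dataclass
class MomentSet:
    """Moments entering GMM estimation.

    ``baseline_labels`` lists the (name, lag) design columns; each contributes
    one identifying moment (the column paired row-wise with the residual,
    summed over a subject's rows).  ``extras`` are test-selected
    over-identifying moments.
    """

    baseline_labels: list[ColumnLabel]
    extras: list[ExtraMoment] = dataclasses.field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.baseline_labels)

    @property
    def m(self) -> int:
        return self.p + len(self.extras)


def candidate_moments(data: PanelDataset, max_lag: int) -> list[ExtraMoment]:
    """All (covariate, wave-pair) product-moments not already identifying.

    Pairs with 0 <= t - s <= max_lag are components of the baseline
    lower-triangular pairings and are excluded (cross-sectional moments are
    valid by assumption; in-model lagged pairings identify coefficients).
    Remaining candidates have t < s, or t - s > max_lag when the partition is
    truncated.
    """
    t_waves = data.n_waves
    out = []
    for j, name in enumerate(data.td_names):
        for s in range(1, t_waves + 1):
            for t in range(1, t_waves + 1):
                if 0 <= t - s <= max_lag:
                    continue
                out.append(ExtraMoment(j, name, s, t))
    return out


def standardized_residuals(
    data: PanelDataset, design: PartitionedDesign, beta
) -> np.ndarray:
    """Pearson residuals e_it = (y_it - mu_it) / sqrt(mu_it (1 - mu_it)), shape (N, T)."""
    mu = marginal_mean(beta, design).reshape(data.n_subjects, data.n_waves)
    var = mu * (1.0 - mu)
    if np.min(var) < _MEAN_EPS:
        raise DegenerateFitError(
            "a fitted mean is 0 or 1; residuals are undefined (possible separation)"
        )
    return (data.y - mu) / np.sqrt(var)


def fisher_z_test(r: float, n: int) -> tuple[float, float]:
    """Fisher-z statistic and two-sided p-value for H0: rho = 0."""
    if n <= 3:
        raise ParameterError("Fisher z test requires n > 3")
    r = float(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    z = np.arctanh(r) * np.sqrt(n - 3.0)
    p = 2.0 * (1.0 - ndtr(abs(z)))
    return z, p


def test_moment_validity(
    data: PanelDataset,
    design: PartitionedDesign,
    beta0,
    alpha: float = 0.05,
    adjust: Optional[str] = None,
    max_lag: Optional[int] = None,
) -> tuple[pd.DataFrame, MomentSet]:
    """Screen candidate moments; return the per-candidate table and the MomentSet.

    Residuals are evaluated once at ``beta0`` (the just-identified
    working-independence estimate; screening is not iterated with
    re-estimation).  A candidate is declared valid when the Fisher-z test
    does not reject rho = 0 at level ``alpha``; ``adjust='bonferroni'``
    multiplies p-values by the number of tested candidates first.  Zero
    variance in a candidate's covariate or residual excludes it with a
    warning.

    The returned MomentSet is baseline (one moment per design column) plus
    the valid extras.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    if adjust not in (None, "bonferroni"):
        raise ParameterError(f"unknown multiplicity adjustment {adjust!r}")
    if max_lag is None:
        max_lag = design.max_lag
    resid = standardized_residuals(data, design, beta0)
    cands = candidate_moments(data, max_lag)
    n = data.n_subjects

    rows = []
    testable = []
    for cand in cands:
        x = data.x_td[:, cand.cov_wave - 1, cand.cov_index]
        e = resid[:, cand.outcome_wave - 1]
        if n <= 3 or np.std(x) == 0.0 or np.std(e) == 0.0:
            warnings.warn(
                f"candidate {cand.label} excluded: zero variance or too few subjects",
                stacklevel=2,
            )
            rows.append((cand, np.nan, np.nan, np.nan, "excluded"))
            continue
        r = float(np.corrcoef(x, e)[0, 1])
        z, p = fisher_z_test(r, n)
        rows.append((cand, r, z, p, None))
        testable.append(len(rows) - 1)

    k = len(testable)
    records = []
    extras = []
    for idx, (cand, r, z, p, verdict) in enumerate(rows):
        p_adj = p
        if verdict is None:
            if adjust == "bonferroni":
                p_adj = min(1.0, p * k)
            verdict = "valid" if p_adj >= alpha else "invalid"
            if verdict == "valid":
                extras.append(cand)
        records.append(
            {
                "covariate": cand.cov_name,
                "cov_wave": cand.cov_wave,
                "outcome_wave": cand.outcome_wave,
                "separation": cand.separation,
                "n": n,
                "r": r,
                "z": z,
                "p_value": p,
                "p_adjusted": p_adj,
                "verdict": verdict,
                "alpha": alpha,
            }
        )
    table = pd.DataFrame.from_records(records)
    moment_set = MomentSet(baseline_labels=list(design.column_labels), extras=extras)
    return table, moment_set
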