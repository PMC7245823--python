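"""Two-step GMM estimation of the partitioned marginal logistic model.

Step 1 solves the just-identified baseline moments — one per design column,
sum over a subject's rows of z * (y - mu) — which is exactly pooled logistic
regression under working independence.  The optimal weight matrix W is the
inverse sample second-moment matrix of the per-subject moment vectors at the
step-1 estimate; step 2 minimizes Q(beta) = gbar' W gbar over the full
moment set (baseline plus any test-selected over-identifying moments) by
Gauss-Newton with a backtracking line search.  The covariance of the
estimate is (G' W G)^{-1} / N with G = d gbar / d beta, the J statistic is
N * Q at the optimum with m - p degrees of freedom, and per-coefficient
odds ratios carry normal-reference 95% intervals (critical value 1.96).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from scipy.special import expit, ndtr
from scipy.stats import chi2

from .errors import ConvergenceError, ParameterError, SeparationError
from .moments import MomentSet
from .panel import ColumnLabel, PanelDataset, PartitionedDesign, format_label

Z_CRIT = 1.96  # normal 97.5% point, fixed for 95% intervals

_COND_MAX = 1e12


def lag_sort_key(label: ColumnLabel, position: int) -> tuple[int, int]:
    lag = label[1]
    return (-1 if lag is None else lag, position)


def screen_columns(
    design: PartitionedDesign, tol: float = 1e-8
) -> tuple[list[int], list[ColumnLabel]]:
    """Greedy rank screen: keep a maximal independent column subset.

    Columns are considered in order of (lag, position) so that when a linear
    dependency exists the later-lag column is the one dropped; all-zero
    columns are always dropped.  Returns kept indices (original order) and
    the dropped labels.
    """
    z = design.Z
    order = sorted(range(design.p), key=lambda i: lag_sort_key(design.column_labels[i], i))
    basis = np.empty((z.shape[0], 0))
    kept: list[int] = []
    dropped: list[ColumnLabel] = []
    for i in order:
        v = z[:, i].astype(float)
        resid = v - basis @ (basis.T @ v)
        nrm = np.linalg.norm(resid)
        if nrm > tol * max(1.0, np.linalg.norm(v)):
            kept.append(i)
            basis = np.hstack([basis, (resid / nrm)[:, None]])
        else:
            dropped.append(design.column_labels[i])
    kept.sort()
    return kept, dropped


def fit_independence(y_rows: np.ndarray, z: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, int]:
    """Pooled logistic regression by iteratively reweighted least squares.

    Solves sum_rows z * (y - mu(beta)) = 0.  ``z`` must be full column rank
    (run :func:`screen_columns` first).  Raises :class:`SeparationError`
    when the iterates diverge, naming the runaway column.
    """
    y = np.asarray(y_rows, dtype=float).reshape(-1)
    if z.shape[0] != y.shape[0]:
        raise ParameterError("design and outcome row counts differ")
    p = z.shape[1]
    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        mu = expit(z @ beta)
        w = mu * (1.0 - mu)
        grad = z.T @ (y - mu)
        h = z.T @ (z * w[:, None]) + 1e-10 * np.eye(p)
        delta = np.linalg.solve(h, grad)
        # dampen huge Newton steps (near-separation)
        step_norm = np.max(np.abs(delta))
        if step_norm > 5.0:
            delta *= 5.0 / step_norm
        beta = beta + delta
        if np.max(np.abs(beta)) > 30.0 and np.min(w) < 1e-10:
            worst = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"complete or quasi-complete separation detected (column index {worst})"
            )
        if np.max(np.abs(delta)) < 1e-10:
            return beta, it
    return beta, max_iter


def moment_vector(
    beta,
    data: PanelDataset,
    design: PartitionedDesign,
    moments: MomentSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject moment vectors g_i (N, m) and their mean gbar.

    Baseline component c: sum over the subject's rows of z_c * (y - mu).
    Extra (j, s, t): x_{ijs} * (y_it - mu_it).
    """
    beta = np.asarray(beta, dtype=float)
    n, t = data.n_subjects, data.n_waves
    p = design.p
    if beta.shape != (p,):
        raise ParameterError("beta length must equal the design column count")
    if moments.p != p:
        raise ParameterError("MomentSet baseline does not match the design columns")
    mu = expit(design.Z @ beta)
    resid = (data.y.reshape(-1) - mu).reshape(n, t)
    zr = design.Z.reshape(n, t, p)
    g_base = np.einsum("ntp,nt->np", zr, resid)
    if moments.extras:
        g_extra = np.column_stack(
            [
                data.x_td[:, e.cov_wave - 1, e.cov_index] * resid[:, e.outcome_wave - 1]
                for e in moments.extras
            ]
        )
        g = np.hstack([g_base, g_extra])
    else:
        g = g_base
    return g, g.mean(axis=0)


def moment_jacobian(
    beta,
    data: PanelDataset,
    design: PartitionedDesign,
    moments: MomentSet,
) -> np.ndarray:
    """G = d gbar / d beta, shape (m, p), computed analytically."""
    beta = np.asarray(beta, dtype=float)
    n, t = data.n_subjects, data.n_waves
    p = design.p
    mu = expit(design.Z @ beta)
    w = mu * (1.0 - mu)
    g_base = -(design.Z * w[:, None]).T @ design.Z / n
    if not moments.extras:
        return g_base
    zr = design.Z.reshape(n, t, p)
    wr = w.reshape(n, t)
    g_extra = np.empty((len(moments.extras), p))
    for k, e in enumerate(moments.extras):
        x = data.x_td[:, e.cov_wave - 1, e.cov_index]
        wt = wr[:, e.outcome_wave - 1]
        g_extra[k] = -(x * wt) @ zr[:, e.outcome_wave - 1, :] / n
    return np.vstack([g_base, g_extra])


def weight_matrix(g_i: np.ndarray, cond_max: float = _COND_MAX) -> np.ndarray:
    """Optimal GMM weight: inverse of S = (1/N) sum g_i g_i'.

    Uses the symmetric pseudo-inverse; when S is ill-conditioned
    (condition number above ``cond_max``) a ridge lambda = 1e-8 * tr(S)/m
    is added first.  Zero-variance components are flagged with a warning
    and handled by the pseudo-inverse, never a hard failure.
    """
    g = np.asarray(g_i, dtype=float)
    n, m = g.shape
    if n <= m:
        warnings.warn(
            f"only {n} subjects for {m} moments; weight matrix may be unstable",
            stacklevel=2,
        )
    s = g.T @ g / n
    s = (s + s.T) / 2.0
    if np.any(np.diag(s) == 0.0):
        warnings.warn("a moment component has zero sample variance", stacklevel=2)
    evals = np.linalg.eigvalsh(s)
    emax = float(evals[-1])
    emin = float(evals[0])
    if emax <= 0.0 or emin <= 0.0 or emax / emin > cond_max:
        lam = 1e-8 * max(np.trace(s), 1e-300) / m
        s = s + lam * np.eye(m)
    w = pinvh(s)
    return (w + w.T) / 2.0


@dataclasses.dataclass
class GmmFit:
    """Result of a (two-step) GMM fit of the partitioned model."""

    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    column_labels: list[ColumnLabel]
    dropped_labels: list[ColumnLabel]
    moments: MomentSet
    objective: float
    j_stat: float
    j_df: int
    j_pvalue: float
    n_subjects: int
    n_iter: int
    grad_norm: float
    converged: bool
    gbar: np.ndarray

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def m(self) -> int:
        return self.moments.m

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def conf_int(self) -> np.ndarray:
        lo = np.exp(self.beta - Z_CRIT * self.se)
        hi = np.exp(self.beta + Z_CRIT * self.se)
        return np.column_stack([lo, hi])

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * (1.0 - ndtr(np.abs(self.zvalues)))

    def params_frame(self, include_dropped: bool = True) -> pd.DataFrame:
        ci = self.conf_int
        rows = []
        for i, lbl in enumerate(self.column_labels):
            rows.append(
                {
                    "name": lbl[0],
                    "lag": lbl[1],
                    "label": format_label(lbl),
                    "estimate": self.beta[i],
                    "se": self.se[i],
                    "or": self.odds_ratios[i],
                    "ci_low": ci[i, 0],
                    "ci_high": ci[i, 1],
                    "z": self.zvalues[i],
                    "p_value": self.pvalues[i],
                    "status": "kept",
                }
            )
        if include_dropped:
            for lbl in self.dropped_labels:
                rows.append(
                    {
                        "name": lbl[0],
                        "lag": lbl[1],
                        "label": format_label(lbl),
                        "estimate": np.nan,
                        "se": np.nan,
                        "or": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "z": np.nan,
                        "p_value": np.nan,
                        "status": "dropped",
                    }
                )
        return pd.DataFrame(rows)


def fit_two_step(
    data: PanelDataset,
    design: PartitionedDesign,
    moments: MomentSet,
    beta0: Optional[np.ndarray] = None,
    dropped_labels: Optional[list[ColumnLabel]] = None,
    max_iter: int = 200,
    gtol: float = 1e-8,
    step_tol: float = 1e-10,
) -> GmmFit:
    """Two-step GMM: weight from the step-1 estimate, then minimize Q.

    ``design`` must already be rank-screened; ``beta0`` defaults to the
    working-independence (step 1) estimate.  With a just-identified moment
    set the optimum reproduces step 1 and the objective is ~0.
    """
    if beta0 is None:
        beta0, _ = fit_independence(data.y.reshape(-1), design.Z)
    beta = np.asarray(beta0, dtype=float).copy()
    n = data.n_subjects

    g_i, _ = moment_vector(beta, data, design, moments)
    w = weight_matrix(g_i)

    def objective(b):
        _, gbar = moment_vector(b, data, design, moments)
        return float(gbar @ w @ gbar), gbar

    q, gbar = objective(beta)
    n_iter = 0
    converged = False
    grad_norm = np.inf
    for n_iter in range(1, max_iter + 1):
        big_g = moment_jacobian(beta, data, design, moments)
        grad = 2.0 * big_g.T @ (w @ gbar)
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < gtol:
            converged = True
            break
        h = big_g.T @ w @ big_g
        try:
            delta = -np.linalg.solve(h, big_g.T @ (w @ gbar))
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular G'WG; a degenerate column may need to be dropped",
                last_beta=beta,
                diagnostics={"iteration": n_iter, "objective": q},
            ) from exc
        step = 1.0
        accepted = False
        for _ in range(50):
            beta_new = beta + step * delta
            q_new, gbar_new = objective(beta_new)
            if q_new < q or q_new <= q + 1e-16:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = grad_norm < 1e-6  # flat to numerical precision
            break
        moved = float(np.linalg.norm(step * delta))
        beta, q, gbar = beta_new, q_new, gbar_new
        if moved < step_tol:
            converged = True
            break
    if not converged and grad_norm >= gtol:
        # a final gradient check at the last accepted iterate
        big_g = moment_jacobian(beta, data, design, moments)
        grad_norm = float(np.linalg.norm(2.0 * big_g.T @ (w @ gbar)))
        if grad_norm >= 1e-6:
            raise ConvergenceError(
                f"GMM optimizer did not converge in {max_iter} iterations "
                f"(gradient norm {grad_norm:.3e})",
                last_beta=beta,
                diagnostics={"objective": q, "grad_norm": grad_norm},
            )
        converged = True

    big_g = moment_jacobian(beta, data, design, moments)
    h = big_g.T @ w @ big_g
    try:
        vcov = np.linalg.inv(h) / n
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            "singular G'WG at the optimum; consider dropping a column"
        ) from exc
    vcov = (vcov + vcov.T) / 2.0
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    j_df = moments.m - moments.p
    j_stat = float(n * q)
    j_pvalue = float(chi2.sf(j_stat, j_df)) if j_df > 0 else float("nan")
    return GmmFit(
        beta=beta,
        se=se,
        vcov=vcov,
        column_labels=list(design.column_labels),
        dropped_labels=list(dropped_labels or []),
        moments=moments,
        objective=q,
        j_stat=j_stat,
        j_df=j_df,
        j_pvalue=j_pvalue,
        n_subjects=n,
        n_iter=n_iter,
        grad_norm=grad_norm,
        converged=converged,
        gbar=gbar,
    )


def lag_group_name(lag: Optional[int]) -> str:
    if lag is None or (isinstance(lag, float) and np.isnan(lag)) or lag == 0:
        return "Cross sectional"
    lag = int(lag)
    words = {1: "One", 2: "Two", 3: "Three"}
    return f"{words.get(lag, str(lag))} time period lag"


def wald_table(fit: GmmFit, include_dropped: bool = True) -> pd.DataFrame:
    """Per-coefficient OR / CI / p rows grouped by lag block.

    Groups follow the conventional presentation: cross-sectional (including
    time-independent covariates), then one / two / three ... time period
    lags.  Dropped coefficients appear with NaN statistics.
    """
    df = fit.params_frame(include_dropped=include_dropped)
    df["group"] = [lag_group_name(lag) for lag in df["lag"]]
    df["_lagkey"] = [
        -1 if (lag is None or (isinstance(lag, float) and np.isnan(lag))) else int(lag)
        for lag in df["lag"]
    ]
    df = df.sort_values("_lagkey", kind="stable").drop(columns="_lagkey")
    cols = ["group", "name", "lag", "estimate", "se", "or", "ci_low", "ci_high", "z", "p_value", "status"]
    return df[cols].reset_index(drop=True)
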