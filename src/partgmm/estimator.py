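"""Scikit-learn style front end for the partitioned GMM marginal model."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .gmm import fit_two_step, fit_independence, screen_columns, wald_table
from .moments import MomentSet, test_moment_validity
from .panel import (
    PanelDataset,
    PartitionedDesign,
    build_partitioned_design,
    from_long_frame,
    marginal_mean,
)


def _as_panel(data, column_config=None) -> PanelDataset:
    if isinstance(data, PanelDataset):
        return data
    if isinstance(data, pd.DataFrame):
        if column_config is None:
            raise ValueError("a long-format DataFrame needs a column_config mapping")
        return from_long_frame(data, column_config)
    raise TypeError(f"expected PanelDataset or DataFrame, got {type(data).__name__}")


class PartitionedDesignBuilder(TransformerMixin, BaseEstimator):
    """Transformer: PanelDataset -> partitioned (lagged) design matrix.

    ``transform`` returns the N*T x p matrix; ``get_feature_names_out``
    exposes the "name.lagK" column labels, so the builder composes with
    sklearn pipelines.
    """

    def __init__(self, max_lag=None, include_fixed=True, wave_effects=False):
        self.max_lag = max_lag
        self.include_fixed = include_fixed
        self.wave_effects = wave_effects

    def fit(self, data, y=None):
        design = self._build(_as_panel(data))
        self.feature_names_out_ = np.asarray(design.column_names, dtype=object)
        self.n_features_out_ = design.p
        return self

    def _build(self, panel: PanelDataset) -> PartitionedDesign:
        return build_partitioned_design(
            panel,
            max_lag=self.max_lag,
            include_fixed=self.include_fixed,
            wave_effects=self.wave_effects,
        )

    def transform(self, data) -> np.ndarray:
        check_is_fitted(self, "feature_names_out_")
        return self._build(_as_panel(data)).Z

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return self.feature_names_out_


class PartitionedGMM(BaseEstimator):
    """Marginal logistic regression with partitioned lagged coefficients, fit by GMM.

    The effect of each time-dependent covariate on a binary outcome is split
    into a cross-sectional coefficient and one coefficient per lag, via a
    lower-triangular design.  Estimation is two-step GMM: a
    working-independence (pooled logistic) step identifies the coefficients;
    candidate over-identifying moments are screened with a Fisher-z
    correlation test on standardized residuals; the second step minimizes
    the optimally weighted quadratic form over the selected moment set.

    Parameters
    ----------
    max_lag : int or None
        Largest lag in the partition; None means T - 1.
    include_fixed : bool
        Include the time-independent covariates.
    wave_effects : bool
        Add wave-indicator intercept shifts (waves 2..T).
    select_moments : bool
        Screen and add valid over-identifying moments; False fits
        just-identified (baseline moments only).
    alpha : float
        Level of the per-candidate moment-validity test.
    adjust : None or "bonferroni"
        Multiplicity adjustment for the validity screen.
    max_iter, gtol, step_tol :
        Gauss-Newton budget and tolerances for the step-2 minimization.
    column_config : mapping or None
        Column mapping used when ``fit`` receives a long-format DataFrame.

    Attributes
    ----------
    coef_ : ndarray of the kept coefficients (model scale, log odds)
    bse_, pvalues_, odds_ratios_, conf_int_ : per-coefficient inference
    column_labels_ : kept (name, lag) pairs aligned with ``coef_``
    dropped_columns_ : labels dropped as degenerate/collinear
    moment_test_ : per-candidate screening table (None if not screened)
    j_stat_, j_df_, j_pvalue_ : over-identification test
    results_ : tidy per-coefficient frame grouped by lag block
    """

    def __init__(
        self,
        max_lag: Optional[int] = None,
        include_fixed: bool = True,
        wave_effects: bool = False,
        select_moments: bool = True,
        alpha: float = 0.05,
        adjust: Optional[str] = None,
        max_iter: int = 200,
        gtol: float = 1e-8,
        step_tol: float = 1e-10,
        column_config=None,
    ):
        self.max_lag = max_lag
        self.include_fixed = include_fixed
        self.wave_effects = wave_effects
        self.select_moments = select_moments
        self.alpha = alpha
        self.adjust = adjust
        self.max_iter = max_iter
        self.gtol = gtol
        self.step_tol = step_tol
        self.column_config = column_config

    def fit(self, data, y=None):
        panel = _as_panel(data, self.column_config)
        design_full = build_partitioned_design(
            panel,
            max_lag=self.max_lag,
            include_fixed=self.include_fixed,
            wave_effects=self.wave_effects,
        )
        kept_idx, dropped = screen_columns(design_full)
        design = design_full.select_columns(kept_idx)
        beta1, _ = fit_independence(panel.y.reshape(-1), design.Z)

        if self.select_moments and panel.n_waves > 1:
            moment_test, moment_set = test_moment_validity(
                panel, design, beta1, alpha=self.alpha, adjust=self.adjust
            )
        else:
            moment_test = None
            moment_set = MomentSet(baseline_labels=list(design.column_labels))

        fit = fit_two_step(
            panel,
            design,
            moment_set,
            beta0=beta1,
            dropped_labels=dropped,
            max_iter=self.max_iter,
            gtol=self.gtol,
            step_tol=self.step_tol,
        )

        self.panel_shape_ = (panel.n_subjects, panel.n_waves, panel.n_td)
        self.design_ = design
        self.fit_ = fit
        self.coef_ = fit.beta
        self.bse_ = fit.se
        self.vcov_ = fit.vcov
        self.pvalues_ = fit.pvalues
        self.odds_ratios_ = fit.odds_ratios
        self.conf_int_ = fit.conf_int
        self.column_labels_ = fit.column_labels
        self.feature_names_in_ = np.asarray(design.column_names, dtype=object)
        self.dropped_columns_ = fit.dropped_labels
        self.independence_coef_ = beta1
        self.moment_test_ = moment_test
        self.moment_set_ = moment_set
        self.n_moments_ = fit.m
        self.objective_ = fit.objective
        self.j_stat_ = fit.j_stat
        self.j_df_ = fit.j_df
        self.j_pvalue_ = fit.j_pvalue
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.results_ = wald_table(fit)
        return self

    def _design_for(self, data) -> PartitionedDesign:
        panel = _as_panel(data, self.column_config)
        design_full = build_partitioned_design(
            panel,
            max_lag=self.max_lag,
            include_fixed=self.include_fixed,
            wave_effects=self.wave_effects,
        )
        wanted = {lbl: i for i, lbl in enumerate(design_full.column_labels)}
        idx = [wanted[lbl] for lbl in self.column_labels_]
        return design_full.select_columns(idx)

    def predict_proba(self, data) -> np.ndarray:
        """Per-row [P(y=0), P(y=1)] for every (subject, wave) row."""
        check_is_fitted(self, "coef_")
        mu = marginal_mean(self.coef_, self._design_for(data))
        return np.column_stack([1.0 - mu, mu])

    def predict(self, data) -> np.ndarray:
        return (self.predict_proba(data)[:, 1] >= 0.5).astype(int)

    def summary(self) -> str:
        """Rendered per-coefficient table grouped by lag block."""
        check_is_fitted(self, "results_")
        from .reporting import render_results_table

        return render_results_table(self.fit_)


def fit_partitioned_gmm(data, **params) -> PartitionedGMM:
    """Convenience wrapper: construct, fit and return a :class:`PartitionedGMM`."""
    return PartitionedGMM(**params).fit(data)
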