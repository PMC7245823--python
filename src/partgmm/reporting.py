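"""Human-readable tables: per-coefficient OR/CI/p, descriptives, sign summary."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gmm import GmmFit, wald_table
from .panel import PanelDataset


def format_pvalue(p: float, threshold: float = 0.001) -> str:
    if np.isnan(p):
        return "–"
    if p < threshold:
        return "<0.001"
    return f"{p:.2f}"


def format_or_row(or_value: float, ci_low: float, ci_high: float, p: float) -> str:
    """Render one coefficient as ``OR [lo, hi] p`` with dashes when dropped."""
    if np.isnan(or_value):
        return "– – –"
    return f"{or_value:.2f} [{ci_low:.2f}, {ci_high:.2f}] {format_pvalue(p)}"


def render_results_table(fit: GmmFit) -> str:
    """Text table of odds ratios grouped by lag block."""
    df = wald_table(fit)
    lines = []
    width = max(len(str(n)) for n in df["name"]) + 2
    header = f"{'Covariate':<{width}}  {'OR':>6}  {'95% CI':>16}  {'p':>7}"
    for group, block in df.groupby("group", sort=False):
        lines.append(group)
        lines.append(header)
        for _, row in block.iterrows():
            if np.isnan(row["or"]):
                lines.append(f"{row['name']:<{width}}  {'–':>6}  {'–':>16}  {'–':>7}")
            else:
                ci = f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]"
                lines.append(
                    f"{row['name']:<{width}}  {row['or']:>6.2f}  {ci:>16}  "
                    f"{format_pvalue(row['p_value']):>7}"
                )
        lines.append("")
    meta = (
        f"N = {fit.n_subjects}, p = {fit.p}, m = {fit.m}, "
        f"J = {fit.j_stat:.3f} (df {fit.j_df}), objective = {fit.objective:.3e}"
    )
    lines.append(meta)
    return "\n".join(lines)


def descriptive_table(data: PanelDataset) -> pd.DataFrame:
    """Percentage of ones per wave for the outcome and each time-dependent covariate."""
    cols = {str(lbl): None for lbl in data.wave_labels}
    rows = {}
    rows[data.outcome_name] = 100.0 * data.y.mean(axis=0)
    for j, name in enumerate(data.td_names):
        rows[name] = 100.0 * data.x_td[:, :, j].mean(axis=0)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(cols))
    return df.round(2)


def sign_summary(fit: GmmFit, alpha: float = 0.05) -> pd.DataFrame:
    """'+' / '-' where a coefficient is significant at ``alpha`` and OR above/below 1."""
    df = wald_table(fit)
    marks = []
    for _, row in df.iterrows():
        if np.isnan(row["p_value"]) or row["p_value"] >= alpha:
            marks.append("")
        else:
            marks.append("+" if row["or"] > 1.0 else "-")
    df = df.assign(sign=marks)
    return df.pivot_table(
        index="name", columns="group", values="sign", aggfunc="first", sort=False
    ).fillna("")
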