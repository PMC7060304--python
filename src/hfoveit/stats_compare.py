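"""Cohort summaries and Bland-Altman method-agreement analysis.

Small-animal titration cohorts (here: ten subjects) are summarized as
median (Q1-Q3). Quartiles use the exclusive *rank p.(n+1)* convention:
the p-quantile sits at order-statistic rank ``p * (n + 1)``, linearly
interpolated and clamped to the extreme order statistics. This is
``numpy.quantile(..., method="weibull")`` and matches the convention of
several clinical statistics packages; the more common ``linear`` default
interpolates at ``1 + p*(n-1)`` and yields different upper quartiles on
small samples.

Agreement between two titration strategies is quantified the Bland-Altman
way: bias = mean of paired differences, limits of agreement =
bias +/- 1.96 x SD of the differences (sample SD, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AnalysisError

METHOD_COLUMNS = ("oxygenation", "cov", "regions")


def median_iqr(values: Sequence[float]) -> Tuple[float, float, float]:
    """Median and quartiles by the rank ``p*(n+1)`` convention.

    Returns ``(median, q1, q3)`` at full precision; use
    :func:`format_median_iqr` for the one-decimal report form.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise AnalysisError("median_iqr: empty sample")
    med, q1, q3 = np.quantile(x, [0.5, 0.25, 0.75], method="weibull")
    return float(med), float(q1), float(q3)


def format_median_iqr(values: Sequence[float]) -> str:
    """One-decimal report string, e.g. ``"19.5 (18.0-21.8)"``."""
    med, q1, q3 = median_iqr(values)
    return f"{round(med, 1):g} ({q1:.1f}-{q3:.1f})"


@dataclass
class AgreementSummary:
    """Bland-Altman agreement between two paired measurement series."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    diffs: np.ndarray
    means: np.ndarray

    @property
    def loa_width(self) -> float:
        return self.loa_upper - self.loa_lower


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementSummary:
    """Bland-Altman summary of paired samples ``a`` and ``b`` (diffs a - b)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AnalysisError(
            f"bland_altman: paired samples differ in length ({a.shape} vs {b.shape})"
        )
    if a.size < 2:
        raise AnalysisError("bland_altman: need n >= 2 pairs for limits")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementSummary(
        bias=bias,
        sd=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        diffs=diffs,
        means=(a + b) / 2.0,
    )


def plot_bland_altman(summary: AgreementSummary, ax=None, title: str = ""):
    """Scatter of pairwise means vs differences with bias and LoA lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(summary.means, summary.diffs, color="k", zorder=3)
    ax.axhline(summary.bias, color="tab:blue", label=f"bias {summary.bias:.1f}")
    for y in (summary.loa_lower, summary.loa_upper):
        ax.axhline(y, color="tab:blue", linestyle="--")
    ax.set_xlabel("mean of methods (cmH2O)")
    ax.set_ylabel("difference (cmH2O)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    return ax


def _check_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METHOD_COLUMNS if c not in cohort.columns]
    if missing:
        raise AnalysisError(f"cohort table missing method columns {missing}")
    if len(cohort) < 1:
        raise AnalysisError("cohort table is empty")
    for c in METHOD_COLUMNS:
        if (pd.to_numeric(cohort[c], errors="coerce") <= 0).any():
            raise AnalysisError(f"cohort column '{c}' must be positive pressures")
    return cohort


def max_abs_disagreement(cohort: pd.DataFrame) -> Dict[str, float]:
    """Largest per-subject |difference| in selected mPaw per method pair."""
    cohort = _check_cohort(cohort)
    out = {}
    for a, b in combinations(METHOD_COLUMNS, 2):
        d = cohort[a].to_numpy(dtype=float) - cohort[b].to_numpy(dtype=float)
        out[f"{a}_vs_{b}"] = float(np.max(np.abs(d)))
    return out


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Medians/IQRs, pairwise Bland-Altman and maximal disagreements."""
    cohort = _check_cohort(cohort)
    summary: dict = {"n_subjects": int(len(cohort)), "methods": {}}
    for c in METHOD_COLUMNS:
        med, q1, q3 = median_iqr(cohort[c])
        summary["methods"][c] = {
            "median": med,
            "q1": q1,
            "q3": q3,
            "report": format_median_iqr(cohort[c]),
        }
    summary["agreement"] = {}
    if len(cohort) >= 2:
        for a, b in combinations(METHOD_COLUMNS, 2):
            ba = bland_altman(cohort[a], cohort[b])
            summary["agreement"][f"{a}_vs_{b}"] = {
                "bias": ba.bias,
                "loa_lower": ba.loa_lower,
                "loa_upper": ba.loa_upper,
            }
    summary["max_abs_disagreement"] = max_abs_disagreement(cohort)
    return summary
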