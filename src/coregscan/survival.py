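"""Quartile-stratified Kaplan-Meier estimation and log-rank gene screening.

For each gene, tumors are split into the lower and upper quartile of its
expression (middle half excluded), the two groups' time-to-progression
curves are compared with a two-group log-rank test, and p-values are
BH-adjusted across the screened gene set within the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

__all__ = [
    "quartile_groups",
    "KmCurve",
    "km_estimate",
    "logrank_screen",
]


def quartile_groups(
    expr: pd.Series,
    inclusive: bool = True,
) -> pd.Series:
    """Label samples 'lower' (<= Q1), 'upper' (>= Q3) or 'excluded'.

    Q1 and Q3 are linear-interpolation quantiles over the non-missing
    values. Boundary ties are included in the group by default
    (``inclusive``); with ``inclusive=False`` the comparisons are strict,
    which can make boundary groups smaller than n/4.
    """
    values = expr.dropna()
    if len(values) < 8:
        raise ValueError("quartile grouping needs at least 8 samples with expression")
    q1, q3 = np.quantile(values.to_numpy(dtype=float), [0.25, 0.75])
    if q1 == q3:
        raise ValueError("expression is constant across the quartile boundaries")
    if inclusive:
        lower, upper = values <= q1, values >= q3
    else:
        lower, upper = values < q1, values > q3
    labels = pd.Series("excluded", index=expr.index, name="group")
    labels[values.index[lower]] = "lower"
    labels[values.index[upper]] = "upper"
    return labels


@dataclass
class KmCurve:
    """Product-limit survival curve with at-risk counts at each event time."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """Survival probability at time t (right-continuous step function)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimate; censor-only data stay at 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no survival records")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
    )
    return KmCurve(timeline=timeline, survival=survival, at_risk=at_risk)


def logrank_screen(
    expr_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    genes=None,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Per-gene lower-vs-upper-quartile log-rank screen with BH FDR.

    ``clinical`` needs 'sample', 'time' and 'event' columns; expression
    columns are matched to clinical samples. Genes whose quartile split is
    undefined (constant expression) are reported with NA statistics and
    kept out of both numerator and denominator of the FDR correction.
    """
    for col in ("sample", "time", "event"):
        if col not in clinical.columns:
            raise KeyError(f"clinical table lacks required column {col!r}")
    clin = clinical.set_index("sample")
    samples = [s for s in expr_matrix.columns if s in clin.index]
    if len(samples) < 8:
        raise ValueError("fewer than 8 tumors shared between expression and clinical")
    genes = list(genes) if genes is not None else list(expr_matrix.index)
    missing = sorted(set(genes) - set(expr_matrix.index))
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")

    rows = []
    for gene in genes:
        try:
            groups = quartile_groups(expr_matrix.loc[gene, samples], inclusive=inclusive)
        except ValueError:
            rows.append({"gene": gene, "statistic": np.nan, "p": np.nan})
            continue
        lo = groups.index[groups == "lower"]
        hi = groups.index[groups == "upper"]
        res = logrank_test(
            clin.loc[lo, "time"],
            clin.loc[hi, "time"],
            event_observed_A=clin.loc[lo, "event"],
            event_observed_B=clin.loc[hi, "event"],
        )
        rows.append(
            {"gene": gene, "statistic": float(res.test_statistic), "p": float(res.p_value)}
        )
    out = pd.DataFrame(rows).set_index("gene")
    if out["p"].notna().sum() == 0:
        raise ValueError("no gene produced a usable quartile split")
    usable = out["p"].notna()
    out["q"] = np.nan
    out.loc[usable, "q"] = multipletests(out.loc[usable, "p"], method="fdr_bh")[1]
    return out.reset_index()
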