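"""Goodness-of-fit diagnostics: observed-vs-simulated regression.

Observed counts (y) are regressed on the simulated totals (x) by ordinary
least squares; a fit consistent with the 1:1 line (intercept CI covering 0
and slope CI covering 1) indicates agreement between model and data.  The
report carries the slope, intercept, R^2, the regression F-test p-value and
a Gaussian-likelihood AIC, n*ln(RSS/n) + 2p with p = 3 (slope, intercept,
error variance).  The AIC omits the additive normalisation constant, so it
compares fits within this package only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohorts import StageSeries
from .timeseries import MonitoringSeries

_AIC_N_PARAMS = 3


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    f_pvalue: float
    aic: float
    n: int
    residuals: np.ndarray
    slope_ci: tuple
    intercept_ci: tuple
    consistent_with_identity: bool
    stage: Optional[str] = None

    def to_text(self) -> str:
        lines = [
            "observed ~ simulated regression" + (f" ({self.stage})" if self.stage else ""),
            f"  n                 {self.n}",
            f"  slope             {self.slope:.6g}  (95% CI {self.slope_ci[0]:.6g} .. {self.slope_ci[1]:.6g})",
            f"  intercept         {self.intercept:.6g}  (95% CI {self.intercept_ci[0]:.6g} .. {self.intercept_ci[1]:.6g})",
            f"  R^2               {self.r_squared:.4f}",
            f"  F                 {self.f_statistic:.4g} (p = {self.f_pvalue:.4g})",
            f"  AIC               {self.aic:.2f}",
            f"  1:1-consistent    {'yes' if self.consistent_with_identity else 'no'}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue, "aic": self.aic,
            "consistent_with_identity": self.consistent_with_identity,
        }


def matched_pairs(observed: MonitoringSeries, simulated: StageSeries,
                  stage: Optional[str] = None) -> pd.DataFrame:
    """Observation/simulation pairs matched by calendar date and stage."""
    records = observed.records if stage is None else observed.counts_for(stage)
    col = {"adult": "adult_total", "nymph": "nymph"}
    rows = [(r.date, r.stage, r.count, simulated.total_on(r.date, col[r.stage]))
            for r in records.itertuples(index=False)]
    return pd.DataFrame(rows, columns=["date", "stage", "observed", "simulated"])


def regress(observed_values, simulated_values,
            stage: Optional[str] = None) -> RegressionReport:
    """OLS of observed on simulated with 1:1-line consistency check."""
    y = np.asarray(observed_values, dtype=float)
    x = np.asarray(simulated_values, dtype=float)
    if len(y) != len(x):
        raise ValueError("observed and simulated lengths differ")
    n = len(y)
    if n < 3:
        raise ValueError(f"need >= 3 matched pairs for inference, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("simulated values have zero variance; regression is degenerate")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    ci = model.conf_int(alpha=0.05)
    rss_reg = float(np.sum(model.resid ** 2))
    # Gaussian AIC without the additive constant; guard perfect fits
    aic = n * np.log(max(rss_reg, np.finfo(float).tiny) / n) + 2 * _AIC_N_PARAMS
    consistent = (ci[0][0] <= 0.0 <= ci[0][1]) and (ci[1][0] <= 1.0 <= ci[1][1])
    return RegressionReport(
        slope=float(slope), intercept=float(intercept),
        r_squared=float(model.rsquared), f_statistic=float(model.fvalue),
        f_pvalue=float(model.f_pvalue), aic=float(aic), n=n,
        residuals=np.asarray(model.resid),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        consistent_with_identity=bool(consistent), stage=stage)


def evaluate_fit(observed: MonitoringSeries, simulated: StageSeries,
                 stage: Optional[str] = None) -> RegressionReport:
    """Regression diagnostics for one stage (or all records pooled)."""
    pairs = matched_pairs(observed, simulated, stage=stage)
    return regress(pairs["observed"], pairs["simulated"], stage=stage)


def plot_fit(report: RegressionReport, pairs: pd.DataFrame, path: str) -> None:
    """Scatter of observed vs simulated with the fitted and 1:1 lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs["simulated"], pairs["observed"], s=18, alpha=0.7)
    grid = np.linspace(pairs["simulated"].min(), pairs["simulated"].max(), 50)
    ax.plot(grid, report.intercept + report.slope * grid, "k-", label="OLS fit")
    ax.plot(grid, grid, "r--", label="1:1 line")
    ax.set_xlabel("simulated")
    ax.set_ylabel("observed")
    ax.legend()
    ax.set_title(f"R$^2$={report.r_squared:.2f}, AIC={report.aic:.1f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
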