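"""Validation statistics: correlations, percent agreement, calibration fit.

The method is validated the way organ-morphometry methods usually are:

* Pearson product-moment ``r`` and Spearman's rho ``r_s`` between each
  calculated quantity and its measured counterpart, with two-sided
  significance from the t-transform ``t = r * sqrt(n-2) / sqrt(1-r^2)``
  against Student's t with ``n - 2`` degrees of freedom.  The same
  transform is applied to ``r_s`` — an approximation that is adequate at
  the cohort sizes used here (n ~ 30).
* Percent agreement: the per-kidney ratio ``100 * calculated /
  measured``, summarized as mean ± SEM (sample sd with the n-1
  denominator over sqrt(n)) and tested two-sided against 100%.
* Ordinary least squares for the collagen ~ A_e calibration line.

Sample size ``n`` is always taken from the data passed in, never
assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SchemaError, SingularFitError, UndefinedCorrelationError
from .geometry import CollagenModel

__all__ = [
    "CorrelationResult",
    "AgreementResult",
    "FitDiagnostics",
    "correlate",
    "correlation_p",
    "percent_agreement",
    "fit_collagen_line",
    "validation_report",
    "ALPHA",
]

#: significance threshold used when *reporting* results; never gates computation
ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r, Spearman rho, sample size and their two-sided p-values."""

    r: float
    r_s: float
    n: int
    p_r: float
    p_rs: float


@dataclass(frozen=True)
class AgreementResult:
    """Mean ± SEM of the per-item calculated/measured ratio, in %."""

    mean_pct: float
    sem_pct: float
    p_diff: float
    n: int


@dataclass(frozen=True)
class FitDiagnostics:
    """OLS diagnostics for the calibration line."""

    slope_se: float
    intercept_se: float
    r_squared: float
    n: int


def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value of a correlation coefficient at sample size ``n``.

    Uses the Student-t transform ``t = |r| * sqrt(n-2) / sqrt(1-r^2)``
    with ``n - 2`` degrees of freedom — the standard significance
    calculation for a product-moment correlation, also applied (as an
    approximation) to Spearman's rho.  ``|r| = 1`` returns 0.
    """
    if n < 3:
        raise UndefinedCorrelationError(f"need n >= 3, got n={n}")
    if not -1.0 <= r <= 1.0:
        raise UndefinedCorrelationError(f"correlation r={r} outside [-1, 1]")
    if 1.0 - r * r <= 0.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(t, df=n - 2))


_p_from_r = correlation_p


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson and Spearman correlation of two vectors with significance.

    Pearson r uses the product-moment formula; Spearman r_s is Pearson
    applied to mid-ranks (ties averaged).  Both p-values come from the
    t-transform with ``n - 2`` degrees of freedom, two-sided.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or len(xa) != len(ya):
        raise UndefinedCorrelationError(
            f"need two equal-length 1-D vectors, got lengths {xa.shape} and {ya.shape}"
        )
    n = len(xa)
    if n < 3:
        raise UndefinedCorrelationError(f"need n >= 3 observations, got n={n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r = float(np.corrcoef(xa, ya)[0, 1])
    rx, ry = sps.rankdata(xa), sps.rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("ranks are constant; Spearman undefined")
    r_s = float(np.corrcoef(rx, ry)[0, 1])
    return CorrelationResult(
        r=r, r_s=r_s, n=n, p_r=_p_from_r(r, n), p_rs=_p_from_r(r_s, n)
    )


def percent_agreement(
    calculated: Sequence[float],
    measured: Sequence[float],
    mode: Literal["ratio", "paired"] = "ratio",
) -> AgreementResult:
    """Agreement of a calculated area with its measured counterpart.

    Each kidney contributes the ratio ``100 * calculated / measured``;
    the result is the mean of those ratios, its SEM, and a two-sided
    p-value that calculated differs from measured.  ``mode="ratio"``
    (default) is a one-sample t-test of the ratios against 100%;
    ``mode="paired"`` is a paired t-test of the raw values.  With zero
    ratio variance the t statistic is undefined and the p-value is
    reported as 1.0 when the mean is exactly on target, else 0.0.
    """
    calc = np.asarray(calculated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if calc.shape != meas.shape or calc.ndim != 1 or len(calc) == 0:
        raise SchemaError("need two equal-length non-empty 1-D vectors")
    if np.any(meas <= 0):
        raise SchemaError("all measured areas must be positive")
    ratios = 100.0 * calc / meas
    n = len(ratios)
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1)) if n > 1 else 0.0
    sem = sd / np.sqrt(n)
    if mode == "ratio":
        if sd == 0.0:
            p = 1.0 if mean == 100.0 else 0.0
        else:
            p = float(sps.ttest_1samp(ratios, 100.0).pvalue)
    elif mode == "paired":
        diff = calc - meas
        sd_diff = float(np.std(diff, ddof=1)) if n > 1 else 0.0
        if sd_diff == 0.0:
            p = 1.0 if np.allclose(diff, 0.0) else 0.0
        else:
            p = float(sps.ttest_rel(calc, meas).pvalue)
    else:
        raise ValueError(f"unknown agreement mode {mode!r}")
    return AgreementResult(mean_pct=mean, sem_pct=float(sem), p_diff=p, n=n)


def fit_collagen_line(
    A_e: Sequence[float], collagen: Sequence[float]
) -> tuple[CollagenModel, FitDiagnostics]:
    """Ordinary-least-squares calibration of collagen (μg) on A_e (mm²)."""
    x = np.asarray(A_e, dtype=float)
    y = np.asarray(collagen, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SchemaError("need two equal-length 1-D vectors")
    if len(x) < 3:
        raise SingularFitError(f"need n >= 3 points to fit, got n={len(x)}")
    if np.ptp(x) == 0:
        raise SingularFitError("constant predictor: calibration fit is singular")
    fit = sps.linregress(x, y)
    model = CollagenModel(slope=float(fit.slope), intercept=float(fit.intercept))
    diag = FitDiagnostics(
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
        r_squared=float(fit.rvalue) ** 2,
        n=len(x),
    )
    return model, diag


# ---------------------------------------------------------------------------
# cohort-level validation report

_COMPARISONS = [
    ("A_vs_Am", "A_mm2", "Am_mm2"),
    ("Ae_vs_Am", "Ae_mm2", "Am_mm2"),
    ("collagen_vs_Am", "collagen_ug", "Am_mm2"),
    ("collagen_vs_Ae", "collagen_ug", "Ae_mm2"),
]


def validation_report(table: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Run the standard method-validation comparisons on a cohort table.

    Expects the measurement-table columns ``A_mm2``, ``Ae_mm2``,
    ``Am_mm2`` and optionally ``collagen_ug``.  For each available
    comparison reports r, r_s and their p-values; for the two
    area-vs-area comparisons additionally the percent agreement with
    measured area.  Returns a tidy DataFrame plus a plain-text summary
    (r to 2 decimals, percentages to 1, matching standard reporting).
    """
    required = {"A_mm2", "Ae_mm2", "Am_mm2"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"table is missing required columns: {sorted(missing)}")
    rows = []
    lines = []
    for name, xcol, ycol in _COMPARISONS:
        if xcol not in table.columns:
            continue
        sub = table[[xcol, ycol]].dropna()
        if len(sub) < 3:
            continue
        corr = correlate(sub[xcol], sub[ycol])
        row = {
            "comparison": name,
            "n": corr.n,
            "r": corr.r,
            "p_r": corr.p_r,
            "r_s": corr.r_s,
            "p_rs": corr.p_rs,
            "mean_pct": np.nan,
            "sem_pct": np.nan,
            "p_diff": np.nan,
        }
        text = (
            f"{name}: n={corr.n}, r={corr.r:.2f} (p={corr.p_r:.2g}), "
            f"r_s={corr.r_s:.2f} (p={corr.p_rs:.2g})"
        )
        if ycol == "Am_mm2" and xcol in ("A_mm2", "Ae_mm2"):
            agree = percent_agreement(sub[xcol], sub[ycol])
            row.update(
                mean_pct=agree.mean_pct, sem_pct=agree.sem_pct, p_diff=agree.p_diff
            )
            verdict = "significant" if agree.p_diff < ALPHA else "not significant"
            text += (
                f"; agreement {agree.mean_pct:.1f} ± {agree.sem_pct:.1f}% of measured "
                f"(difference {verdict}, p={agree.p_diff:.2g})"
            )
        rows.append(row)
        lines.append(text)
    if not rows:
        raise SchemaError("no comparison had at least 3 complete rows")
    return pd.DataFrame(rows), "\n".join(lines)
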