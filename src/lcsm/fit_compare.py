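"""Fit indices, nested-model tests, and coupling-model selection.

Implements the likelihood-ratio chi-square against the saturated model,
chi-square/df, CFI against the independence model, RMSEA with its 90%
confidence interval by inverting the noncentral chi-square distribution,
and the sample-size-adjusted BIC (Sclove/Yang effective sample size
(n + 2) / 24).  Model comparison uses the plain chi-square difference
test for nested models (alpha 0.01 by convention here) and the adjusted
BIC for selection among coupling models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy import optimize, stats

from .estimation import FitResult

__all__ = [
    "FitIndices",
    "ComparisonRow",
    "fit_indices",
    "chisq_difference",
    "delta_cfi_decision",
    "select_coupling_model",
    "format_fit",
]


@dataclass(frozen=True)
class FitIndices:
    """Global fit summary of one fitted model."""

    chi_square: float
    df: int
    chi_over_df: float
    cfi: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    bic_adjusted: float
    n: int

    def good_fit(self) -> bool:
        """chi2/df <= 2, CFI > 0.97, RMSEA <= 0.05."""
        return self.chi_over_df <= 2.0 and self.cfi > 0.97 and self.rmsea <= 0.05

    def adequate_fit(self) -> bool:
        """chi2/df <= 3, CFI > 0.95, RMSEA <= 0.08."""
        return self.chi_over_df <= 3.0 and self.cfi > 0.95 and self.rmsea <= 0.08


@dataclass
class ComparisonRow:
    """One line of a model-comparison table."""

    label: str
    indices: FitIndices
    delta_chi_square: float | None = None
    delta_df: int | None = None
    p_value: float | None = None
    selected: bool = False


def fit_indices(
    model_fit: FitResult, saturated: FitResult, null: FitResult
) -> FitIndices:
    """Compute chi-square-based fit indices for a fitted model.

    All three fits must be on the same data and variables.  The RMSEA
    confidence interval inverts the noncentral chi-square CDF; with
    df = 0 the RMSEA is undefined and reported as NaN.
    """
    if not (model_fit.converged and saturated.converged and null.converged):
        raise ValueError("fit indices require converged fits")
    if not (model_fit.n_used == saturated.n_used == null.n_used):
        raise ValueError("fits disagree on the analysis sample")
    n = model_fit.n_used
    chi2 = 2.0 * (saturated.log_likelihood - model_fit.log_likelihood)
    if chi2 < 0:
        if chi2 < -1e-4:
            warnings.warn(
                f"model log-likelihood exceeds saturated by {-chi2 / 2:.3g}; "
                "flooring chi-square at 0",
                stacklevel=2,
            )
        chi2 = 0.0
    df = model_fit.df
    chi0 = 2.0 * (saturated.log_likelihood - null.log_likelihood)
    df0 = null.df

    num = max(chi2 - df, 0.0)
    den = max(chi0 - df0, chi2 - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)

    if df > 0:
        rmsea = math.sqrt(max(0.0, (chi2 - df) / (df * n)))
        ci = _rmsea_ci(chi2, df, n)
        chi_over_df = chi2 / df
    else:
        rmsea = float("nan")
        ci = (float("nan"), float("nan"))
        chi_over_df = float("nan")
    k = model_fit.n_params
    bic_adj = -2.0 * model_fit.log_likelihood + k * math.log((n + 2.0) / 24.0)
    return FitIndices(
        chi_square=chi2,
        df=df,
        chi_over_df=chi_over_df,
        cfi=cfi,
        rmsea=rmsea,
        rmsea_ci90=ci,
        bic_adjusted=bic_adj,
        n=n,
    )


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90):
    """90% RMSEA interval from the noncentrality parameter bounds."""
    lo_q, hi_q = (1.0 + level) / 2.0, (1.0 - level) / 2.0  # 0.95, 0.05

    def ncp_for(q: float) -> float:
        # largest lambda with P(X_{df,lambda} <= chi2) >= q  (monotone in lambda)
        if stats.chi2.cdf(chi2, df) < q:
            return 0.0
        f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - q
        hi = max(chi2 * 2.0, 10.0)
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e8:
                break
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-8))

    lam_lo = ncp_for(lo_q)
    lam_hi = ncp_for(hi_q)
    return (
        math.sqrt(lam_lo / (df * n)),
        math.sqrt(lam_hi / (df * n)),
    )


def chisq_difference(
    restricted: FitIndices, general: FitIndices
) -> tuple[float, int, float]:
    """Chi-square difference test for nested models.

    Returns (delta, delta_df, p).  The restricted model must have more
    df; a (numerically) negative difference is floored at zero with a
    warning, as can happen under FIML when convergence differs.
    """
    if restricted.df <= general.df:
        raise ValueError(
            "restricted model must have more df than the general model"
        )
    delta = restricted.chi_square - general.chi_square
    delta_df = restricted.df - general.df
    if delta < 0:
        warnings.warn(
            f"negative chi-square difference ({delta:.4g}) floored at 0",
            stacklevel=2,
        )
        delta = 0.0
    p = float(stats.chi2.sf(delta, delta_df)) if delta > 0 else 1.0
    return delta, delta_df, p


def delta_cfi_decision(
    lower_invariance: FitIndices, higher_invariance: FitIndices,
    threshold: float = 0.01,
) -> str:
    """Accept the more constrained model iff the CFI drop is <= 0.01."""
    drop = lower_invariance.cfi - higher_invariance.cfi
    return "accept" if drop <= threshold + 1e-12 else "reject"


def select_coupling_model(
    rows: Sequence[ComparisonRow],
    override: str | None = None,
    alpha: float = 0.01,
) -> ComparisonRow:
    """Select among baseline and coupling models.

    Coupling models that beat the baseline at the chi-square-difference
    threshold compete on the adjusted BIC (lowest wins); with no
    significant improvement the baseline is retained.  ``override``
    forces a named model (used when a substantive reason trumps a small
    BIC difference).
    """
    if not rows:
        raise ValueError("no comparison rows supplied")
    for r in rows:
        r.selected = False
    if override is not None:
        for r in rows:
            if r.label == override:
                r.selected = True
                return r
        raise KeyError(f"override model {override!r} not among rows")
    baseline = rows[0]
    candidates = [
        r
        for r in rows[1:]
        if r.p_value is not None and r.p_value < alpha
    ]
    chosen = (
        min(candidates, key=lambda r: r.indices.bic_adjusted)
        if candidates
        else baseline
    )
    chosen.selected = True
    return chosen


def format_fit(fi: FitIndices) -> str:
    """Render indices in the conventional table style."""
    lo, hi = fi.rmsea_ci90
    return (
        f"chi2({fi.df}) = {fi.chi_square:,.3f}, chi2/df = {fi.chi_over_df:.2f}, "
        f"RMSEA = {fi.rmsea:.3f} ({lo:.3f}-{hi:.3f}), CFI = {fi.cfi:.3f}, "
        f"BIC = {fi.bic_adjusted:,.3f}"
    )
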