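"""Builders for univariate and bivariate latent change score models.

The latent change score (LCS) model decomposes a latent true score
``eta_t`` at each occasion into the previous true score plus a latent
change, ``eta_t = eta_{t-1} + d_t``, with every change loading with a
fixed weight of 1 on a constant-change slope factor ``S`` and the first
true score identified with an intercept factor ``I``.  With all slope
loadings fixed to 1 and the time grid in years, the slope mean is annual
change.  A *phantom* occasion is a latent time point with no indicators,
inserted so that the annual grid stays equally spaced when a wave was
skipped (here, year 3).

Two measurement variants are supported:

* **first-order** (one indicator per occasion): the indicator loads 1 on
  ``eta_t`` with intercept 0 and a free occasion-specific residual
  variance; time-varying covariates (head motion) regress on the
  indicator at the matching occasion.
* **second-order** (>= 3 indicators): indicators load on ``eta_t`` with
  the first loading fixed to 1 and the first intercept fixed to 0 per
  occasion; remaining loadings/intercepts are equality-constrained over
  occasions according to the requested measurement-invariance level, and
  residuals of the same indicator are freely correlated across every
  occasion pair.

Time-invariant covariates regress on ``I`` and ``S``.  All exogenous
observed covariates — time-invariant and time-varying alike — enter the
model as stochastic variables with free means and a fully free covariance
block, so that full-information maximum likelihood can absorb missing
covariate values.

Change-score means and residual variances are fixed to 0 so that change
is carried entirely by the slope factor; the *retest* option frees the
mean (and optionally the variance) of the first change score to absorb
the practice gain between the first two waves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .model import PathModel

__all__ = [
    "BuilderConfig",
    "CouplingSpec",
    "build_univariate_lcs",
    "build_bivariate_lcs",
]

_INVARIANCE_LEVELS = ("configural", "weak", "strong", "partial")


@dataclass(frozen=True)
class BuilderConfig:
    """Recipe for one domain's univariate LCS model.

    Parameters
    ----------
    domain:
        Short name used in latent-variable and parameter labels.
    indicators:
        Observed indicator base names; columns are ``{name}_t{year}``.
        One name builds a first-order model, three or more a second-order
        model.
    occasions:
        Time grid in years.
    phantom:
        Subset of ``occasions`` with no observed indicators.
    invariance_level:
        "configural" | "weak" | "strong" | "partial".
    freed_intercepts:
        For "partial": indicator base names whose intercepts are freed at
        every non-reference occasion.
    retest:
        "none" | "free_mean" | "free_mean_and_variance" applied to the
        first latent change score.
    covariates:
        Time-invariant covariates regressed on intercept and slope.
    time_varying_covariates:
        Mapping occasion-year -> covariate base name regressed on that
        occasion's manifest indicator(s) (columns ``{name}_t{year}``).
    tvc_equal_over_time:
        Share one regression weight across occasions (default) or free it
        per occasion.
    slope_variance_fixed_zero:
        Fix the slope variance (and intercept-slope covariance) to 0.
    proportional_change:
        Add self-feedback paths ``eta_{t-1} -> d_t`` with one shared
        coefficient, allowing accelerating/decelerating change.
    """

    domain: str
    indicators: tuple[str, ...]
    occasions: tuple[float, ...] = (0, 1, 2, 3, 4)
    phantom: tuple[float, ...] = (3,)
    invariance_level: str = "strong"
    freed_intercepts: tuple[str, ...] = ()
    retest: str = "none"
    covariates: tuple[str, ...] = ("age_base", "education", "gender")
    time_varying_covariates: Mapping[float, str] | None = None
    tvc_equal_over_time: bool = True
    slope_variance_fixed_zero: bool = False
    proportional_change: bool = False

    def __post_init__(self):
        if self.invariance_level not in _INVARIANCE_LEVELS:
            raise ValueError(f"unknown invariance level {self.invariance_level!r}")
        if self.retest not in ("none", "free_mean", "free_mean_and_variance"):
            raise ValueError(f"unknown retest option {self.retest!r}")
        if not set(self.phantom) <= set(self.occasions):
            raise ValueError("phantom occasions must be on the occasion grid")
        if len(self.measured_occasions) < 2:
            raise ValueError("need at least two measured occasions")
        n_ind = len(self.indicators)
        if n_ind == 0:
            raise ValueError("at least one indicator required")
        if 1 < n_ind < 3 and self.invariance_level != "configural":
            raise ValueError(
                "a second-order model needs >= 3 indicators for invariance "
                "levels above configural"
            )
        if self.retest != "none" and n_ind == 1:
            warnings.warn(
                "retest effect requested for a single-indicator model; the "
                "retest mean is then weakly separable from residual structure",
                stacklevel=2,
            )

    @property
    def measured_occasions(self) -> tuple[float, ...]:
        return tuple(t for t in self.occasions if t not in self.phantom)

    @property
    def second_order(self) -> bool:
        return len(self.indicators) > 1

    def column(self, indicator: str, occasion: float) -> str:
        return f"{indicator}_t{_fmt(occasion)}"

    def with_invariance(self, level: str, freed: Sequence[str] = ()) -> "BuilderConfig":
        return replace(
            self, invariance_level=level, freed_intercepts=tuple(freed)
        )


@dataclass(frozen=True)
class CouplingSpec:
    """Lagged change-to-change coupling between two domains.

    ``lag_years`` separates the leading change from the lagging change on
    the annual grid; couplings of the same direction share one free
    parameter when ``equal_over_time``.  Direction "a_to_b" makes domain
    A lead (paths from A's changes to B's later changes).
    """

    lag_years: int = 1
    direction: str = "bidirectional"
    equal_over_time: bool = True

    def __post_init__(self):
        if self.direction not in ("a_to_b", "b_to_a", "bidirectional"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.lag_years < 1:
            raise ValueError("lag must be at least one interval")


def _fmt(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


class _Assembler:
    """Accumulates cells by variable *name*, then materializes arrays."""

    def __init__(self):
        self.observed: list[str] = []
        self.latent: list[str] = []
        self.A: dict[tuple[str, str], object] = {}
        self.S: dict[tuple[str, str], object] = {}
        self.M: dict[str, object] = {}
        self.hints: dict[str, tuple] = {}

    def add_observed(self, name: str):
        if name not in self.observed:
            self.observed.append(name)

    def add_latent(self, name: str):
        if name not in self.latent:
            self.latent.append(name)

    def path(self, dst: str, src: str, entry):
        self.A[(dst, src)] = entry

    def cov(self, a: str, b: str, entry):
        self.S[(a, b)] = entry

    def mean(self, v: str, entry):
        self.M[v] = entry

    def hint(self, label: str, recipe: tuple):
        self.hints[label] = recipe

    def build(self) -> PathModel:
        names = self.observed + self.latent
        idx = {v: i for i, v in enumerate(names)}
        n = len(names)
        A = np.full((n, n), 0.0, dtype=object)
        S = np.full((n, n), 0.0, dtype=object)
        M = np.full(n, 0.0, dtype=object)
        for (dst, src), e in self.A.items():
            A[idx[dst], idx[src]] = e
        for (a, b), e in self.S.items():
            S[idx[a], idx[b]] = e
            S[idx[b], idx[a]] = e
        for v, e in self.M.items():
            M[idx[v]] = e
        model = PathModel(names, len(self.observed), A, S, M, dict(self.hints))
        model.validate()
        return model


# ----------------------------------------------------------------------
# domain structure
# ----------------------------------------------------------------------
def _add_domain(asm: _Assembler, cfg: BuilderConfig) -> None:
    d = cfg.domain
    years = tuple(cfg.occasions)
    measured = cfg.measured_occasions
    eta = {t: f"eta_{d}_t{_fmt(t)}" for t in years}
    chg = {t: f"d_{d}_t{_fmt(t)}" for t in years[1:]}
    I_, S_ = f"I_{d}", f"S_{d}"

    # observed indicator columns, occasion-major
    for t in measured:
        for ind in cfg.indicators:
            asm.add_observed(cfg.column(ind, t))
    for t in years:
        asm.add_latent(eta[t])
    for t in years[1:]:
        asm.add_latent(chg[t])
    asm.add_latent(I_)
    asm.add_latent(S_)

    # --- latent change structure -------------------------------------
    asm.path(eta[years[0]], I_, 1.0)
    for prev, t in zip(years, years[1:]):
        asm.path(eta[t], eta[prev], 1.0)
        asm.path(eta[t], chg[t], 1.0)
        asm.path(chg[t], S_, 1.0)  # alpha fixed to 1: constant change
        if cfg.proportional_change:
            asm.path(chg[t], eta[prev], f"beta:{d}")
    if cfg.proportional_change:
        asm.hint(f"beta:{d}", ("value", 0.0))

    ref = cfg.indicators[0]
    ref0 = cfg.column(ref, measured[0])

    # latent moments
    asm.mean(I_, f"mu_I:{d}")
    asm.mean(S_, f"mu_S:{d}")
    asm.cov(I_, I_, f"var_I:{d}")
    asm.hint(f"mu_I:{d}", ("mean", ref0))
    asm.hint(
        f"mu_S:{d}",
        ("ols_slope", [cfg.column(ref, t) for t in measured], list(measured)),
    )
    asm.hint(f"var_I:{d}", ("var", ref0, 0.5))
    if cfg.slope_variance_fixed_zero:
        asm.cov(S_, S_, 0.0)
        asm.cov(I_, S_, 0.0)
    else:
        asm.cov(S_, S_, f"var_S:{d}")
        asm.cov(I_, S_, f"cov_IS:{d}")
        asm.hint(f"var_S:{d}", ("var", ref0, 0.02))
        asm.hint(f"cov_IS:{d}", ("value", 0.0))

    # retest: free mean (and variance) of the first change score
    first_chg_year = min(chg)  # first interval on the grid
    if cfg.retest in ("free_mean", "free_mean_and_variance"):
        asm.mean(chg[first_chg_year], f"retest_mu:{d}")
        asm.hint(f"retest_mu:{d}", ("value", 0.0))
    if cfg.retest == "free_mean_and_variance":
        asm.cov(chg[first_chg_year], chg[first_chg_year], f"retest_var:{d}")
        asm.hint(f"retest_var:{d}", ("var", ref0, 0.05))

    # --- measurement model -------------------------------------------
    tvc = dict(cfg.time_varying_covariates or {})
    for t in measured:
        ref_col_t = cfg.column(ref, t)
        for j, ind in enumerate(cfg.indicators):
            col = cfg.column(ind, t)
            # loading
            if j == 0:
                asm.path(col, eta[t], 1.0)
            else:
                if cfg.invariance_level == "configural":
                    lab = f"lam:{d}:{ind}:t{_fmt(t)}"
                else:
                    lab = f"lam:{d}:{ind}"
                asm.path(col, eta[t], lab)
                asm.hint(lab, ("value", 1.0))
            # intercept
            if j == 0:
                asm.mean(col, 0.0)
            else:
                lab = _intercept_label(cfg, ind, t)
                asm.mean(col, lab)
                asm.hint(lab, ("mean_diff", col, ref_col_t))
            # residual variance
            evar = f"evar:{d}:{ind}:t{_fmt(t)}"
            asm.cov(col, col, evar)
            asm.hint(evar, ("var", col, 0.5))
        # time-varying covariate on this occasion's indicators
        if t in tvc:
            cov_col = f"{tvc[t]}_t{_fmt(t)}"
            for ind in cfg.indicators:
                lab = (
                    f"b_tvc:{d}" if cfg.tvc_equal_over_time
                    else f"b_tvc:{d}:t{_fmt(t)}"
                )
                asm.path(cfg.column(ind, t), cov_col, lab)
                asm.hint(lab, ("value", 0.0))

    # cross-occasion correlated residuals (second-order only)
    if cfg.second_order:
        for ind in cfg.indicators:
            for i, t1 in enumerate(measured):
                for t2 in measured[i + 1:]:
                    lab = f"ecov:{d}:{ind}:t{_fmt(t1)}:t{_fmt(t2)}"
                    asm.cov(cfg.column(ind, t1), cfg.column(ind, t2), lab)
                    asm.hint(
                        lab,
                        ("covfrac", cfg.column(ind, t1), cfg.column(ind, t2), 0.2),
                    )

    # covariate regressions on intercept and slope
    for cov in cfg.covariates:
        for lat, tag in ((I_, "I"), (S_, "S")):
            lab = f"b:{d}:{tag}:{cov}"
            asm.path(lat, cov, lab)
            asm.hint(lab, ("value", 0.0))


def _intercept_label(cfg: BuilderConfig, ind: str, t: float) -> str:
    d = cfg.domain
    level = cfg.invariance_level
    first = cfg.measured_occasions[0]
    if level in ("configural", "weak"):
        return f"nu:{d}:{ind}:t{_fmt(t)}"
    if level == "partial" and ind in cfg.freed_intercepts and t != first:
        return f"nu:{d}:{ind}:t{_fmt(t)}"
    return f"nu:{d}:{ind}"


def _exogenous_names(cfgs: Sequence[BuilderConfig]) -> list[str]:
    """Time-varying covariate columns first, then shared covariates."""
    out: list[str] = []
    for cfg in cfgs:
        for t, name in sorted((cfg.time_varying_covariates or {}).items()):
            col = f"{name}_t{_fmt(t)}"
            if col not in out:
                out.append(col)
    for cfg in cfgs:
        for cov in cfg.covariates:
            if cov not in out:
                out.append(cov)
    return out


def _add_exogenous_block(asm: _Assembler, exog: Sequence[str]) -> None:
    """Saturated stochastic block over all exogenous covariates."""
    for v in exog:
        asm.add_observed(v)
    for i, v in enumerate(exog):
        lab = f"mean:{v}"
        asm.mean(v, lab)
        asm.hint(lab, ("mean", v))
        for w in exog[i:]:
            lab = f"vcov:{v}:{w}"
            asm.cov(v, w, lab)
            asm.hint(lab, ("cov", v, w))


# ----------------------------------------------------------------------
# public builders
# ----------------------------------------------------------------------
def build_univariate_lcs(config: BuilderConfig) -> PathModel:
    """Build a univariate (first- or second-order) LCS model."""
    asm = _Assembler()
    _add_domain(asm, config)
    _add_exogenous_block(asm, _exogenous_names([config]))
    return asm.build()


def build_bivariate_lcs(
    config_a: BuilderConfig,
    config_b: BuilderConfig,
    coupling: CouplingSpec | None = None,
) -> PathModel:
    """Join two univariate LCS models into a bivariate model.

    The *baseline* model (``coupling=None``) adds only the four free
    cross-domain covariances between the intercept and slope factors;
    a :class:`CouplingSpec` additionally adds lagged directed paths
    between the two domains' change scores.
    """
    if config_a.occasions != config_b.occasions or config_a.phantom != config_b.phantom:
        raise ValueError("bivariate domains must share the occasion grid")
    if config_a.covariates != config_b.covariates:
        raise ValueError("bivariate domains must share the covariate set")
    if config_a.domain == config_b.domain:
        raise ValueError("domains must have distinct names")

    asm = _Assembler()
    _add_domain(asm, config_a)
    _add_domain(asm, config_b)
    _add_exogenous_block(asm, _exogenous_names([config_a, config_b]))

    a, b = config_a.domain, config_b.domain
    # four cross-domain covariances among intercepts and slopes
    pairs = [
        (f"I_{a}", f"I_{b}", f"xcov:I_{a}:I_{b}"),
        (f"S_{a}", f"S_{b}", f"xcov:S_{a}:S_{b}"),
        (f"I_{a}", f"S_{b}", f"xcov:I_{a}:S_{b}"),
        (f"I_{b}", f"S_{a}", f"xcov:I_{b}:S_{a}"),
    ]
    for u, v, lab in pairs:
        if (
            config_a.slope_variance_fixed_zero and "S_" + a in (u, v)
        ) or (
            config_b.slope_variance_fixed_zero and "S_" + b in (u, v)
        ):
            continue  # no covariance with a zero-variance slope
        asm.cov(u, v, lab)
        asm.hint(lab, ("value", 0.0))

    if coupling is not None:
        _add_couplings(asm, config_a, config_b, coupling)
    return asm.build()


def _add_couplings(
    asm: _Assembler,
    config_a: BuilderConfig,
    config_b: BuilderConfig,
    spec: CouplingSpec,
) -> None:
    years = tuple(config_a.occasions)
    chg_years = years[1:]
    directions = []
    if spec.direction in ("a_to_b", "bidirectional"):
        directions.append((config_a.domain, config_b.domain))
    if spec.direction in ("b_to_a", "bidirectional"):
        directions.append((config_b.domain, config_a.domain))
    for src, dst in directions:
        placed = 0
        for t in chg_years:
            t_to = t + spec.lag_years
            if t_to in chg_years:
                lab = (
                    f"gamma:{src}->{dst}" if spec.equal_over_time
                    else f"gamma:{src}->{dst}:t{_fmt(t_to)}"
                )
                asm.path(f"d_{dst}_t{_fmt(t_to)}", f"d_{src}_t{_fmt(t)}", lab)
                asm.hint(lab, ("value", 0.0))
                placed += 1
        if placed == 0:
            raise ValueError(
                f"lag {spec.lag_years} leaves no coupling path on grid {years}"
            )
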