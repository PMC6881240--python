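"""Synthetic longitudinal cohorts with known generative parameters.

The generator mirrors the structure the change-score models assume: per
participant, intercept and slope factors (conditioned on covariates)
drive latent true-score trajectories on an annual grid with a phantom
year; indicators add measurement error with cross-occasion correlated
residuals; head motion contaminates the white-matter indicators; change
scores can be coupled across domains with a lag; attrition is monotone
and (by default) weakly age-dependent, and element-wise missingness is
missing-at-random.  Every generated table comes with a ground-truth
manifest so that parameter-recovery experiments can compare estimates to
truth label by label.

The default presets emulate the qualitative regimes of a healthy-aging
cohort followed at years 0, 1, 2 and 4 (n 232 declining to 173):
processing speed measured by four tasks with a retest bump after the
first wave, and fractional-anisotropy (FA, scaled x100) tract series
that decline, stay stable, or show no slope variance.  They are scenario
templates, not estimates of any particular cohort.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .builders import BuilderConfig, CouplingSpec, build_bivariate_lcs, build_univariate_lcs
from .data import LongitudinalTable
from .model import PathModel

__all__ = [
    "DomainTruth",
    "CrossDomain",
    "Coupling",
    "AttritionSchedule",
    "TrueParameters",
    "simulate_dataset",
    "recovery_experiment",
    "true_estimates",
    "speed_truth",
    "tract_truth",
    "bivariate_truth",
    "cohort_truth",
]

_OCCASIONS = (0, 1, 2, 3, 4)
_PHANTOM = (3,)


# ----------------------------------------------------------------------
# covariate generating distributions (model scale: age - 70, education - 2)
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class _Covariate:
    name: str
    kind: str  # "normal" | "discrete" | "bernoulli"
    a: float = 0.0
    b: float = 1.0
    levels: tuple[float, ...] = ()
    probs: tuple[float, ...] = ()

    @property
    def mean(self) -> float:
        if self.kind == "normal":
            return self.a
        if self.kind == "bernoulli":
            return self.a
        return float(np.dot(self.levels, self.probs))

    @property
    def var(self) -> float:
        if self.kind == "normal":
            return self.b ** 2
        if self.kind == "bernoulli":
            return self.a * (1 - self.a)
        m = self.mean
        return float(np.dot((np.array(self.levels) - m) ** 2, self.probs))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "normal":
            return self.a + self.b * rng.standard_normal(n)
        if self.kind == "bernoulli":
            return (rng.random(n) < self.a).astype(float)
        return rng.choice(np.array(self.levels), size=n, p=np.array(self.probs))


_DEFAULT_COVARIATES = {
    # age centered at 70: cohort mean ~70.8, sd ~5.1
    "age_base": _Covariate("age_base", "normal", 0.84, 5.08),
    # education 1-3 centered at 2
    "education": _Covariate(
        "education", "discrete", levels=(-1.0, 0.0, 1.0), probs=(0.22, 0.33, 0.45)
    ),
    # gender: 0 = female, 1 = male; cohort ~49% female
    "gender": _Covariate("gender", "bernoulli", 0.51),
}

# head motion: right-skewed (lognormal), median ~0.2, uncentered
_HM_MU, _HM_SIGMA = math.log(0.2), 0.55


def _hm_mean() -> float:
    return math.exp(_HM_MU + 0.5 * _HM_SIGMA ** 2)


def _hm_var() -> float:
    return (math.exp(_HM_SIGMA ** 2) - 1.0) * math.exp(2 * _HM_MU + _HM_SIGMA ** 2)


# ----------------------------------------------------------------------
# truth dataclasses
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class DomainTruth:
    """Generative parameters for one domain's change process."""

    domain: str
    indicators: tuple[str, ...]
    loadings: tuple[float, ...]
    intercepts: tuple[float, ...]
    residual_sd: tuple[float, ...]
    residual_corr: float = 0.3
    icept_mean: float = 0.0
    icept_sd: float = 1.0
    slope_mean: float = 0.0
    slope_sd: float = 0.0
    icept_slope_cov: float = 0.0
    retest_mean: float = 0.0
    retest_sd: float = 0.0
    intercept_drift: tuple[tuple[str, float, float], ...] = ()  # (indicator, year, offset)
    covariate_effects_icept: tuple[tuple[str, float], ...] = ()
    covariate_effects_slope: tuple[tuple[str, float], ...] = ()
    tvc_name: str | None = None  # e.g. head motion "hm"
    tvc_effect: float = 0.0
    proportional: float = 0.0
    scale100: bool = False  # raw output divides indicators by 100 (FA)

    def __post_init__(self):
        k = len(self.indicators)
        if not (len(self.loadings) == len(self.intercepts) == len(self.residual_sd) == k):
            raise ValueError("per-indicator truth vectors must share length")
        if self.loadings[0] != 1.0 or self.intercepts[0] != 0.0:
            raise ValueError("reference indicator must have loading 1, intercept 0")

    def drift(self, indicator: str, year: float) -> float:
        for ind, y, off in self.intercept_drift:
            if ind == indicator and y == year:
                return off
        return 0.0

    def builder_config(
        self,
        occasions: tuple[float, ...] = _OCCASIONS,
        phantom: tuple[float, ...] = _PHANTOM,
        covariates: tuple[str, ...] = ("age_base", "education", "gender"),
        invariance: str = "strong",
    ) -> BuilderConfig:
        measured = tuple(t for t in occasions if t not in phantom)
        tvc = (
            {t: self.tvc_name for t in measured} if self.tvc_name else None
        )
        return BuilderConfig(
            domain=self.domain,
            indicators=self.indicators,
            occasions=occasions,
            phantom=phantom,
            invariance_level=invariance,
            retest="free_mean" if self.retest_mean or self.retest_sd else "none",
            covariates=covariates,
            time_varying_covariates=tvc,
            proportional_change=self.proportional != 0.0,
        )


@dataclass(frozen=True)
class CrossDomain:
    """Cross-domain intercept/slope covariances between two domains (a, b)."""

    icept_icept: float = 0.0
    slope_slope: float = 0.0
    icept_a_slope_b: float = 0.0
    icept_b_slope_a: float = 0.0


@dataclass(frozen=True)
class Coupling:
    """Lagged change-to-change regression: source leads, target lags."""

    source: str
    target: str
    lag_years: int
    gamma: float


@dataclass(frozen=True)
class AttritionSchedule:
    """Monotone dropout: retained counts (or probabilities) per measured
    occasion; optionally missing-at-random in baseline age."""

    counts: tuple[int, ...] | None = (232, 210, 197, 173)
    probs: tuple[float, ...] | None = None
    age_dependent: bool = True
    age_log_odds: float = 0.06  # dropout log-odds per year above the center

    def retained(self, n: int, n_occ: int) -> list[int]:
        if self.counts is not None:
            if len(self.counts) != n_occ:
                raise ValueError("schedule length must match measured occasions")
            if any(b > a for a, b in zip(self.counts, self.counts[1:])):
                raise ValueError("retained counts must be non-increasing")
            base = self.counts[0]
            return [max(1, round(n * c / base)) for c in self.counts]
        if self.probs is not None:
            if len(self.probs) != n_occ:
                raise ValueError("schedule length must match measured occasions")
            out = [n]
            for p in self.probs[1:]:
                out.append(max(1, round(out[-1] * p)))
            return out
        return [n] * n_occ


@dataclass(frozen=True)
class TrueParameters:
    """Full generative manifest: domains, cross-links, covariates, missingness."""

    domains: tuple[DomainTruth, ...]
    cross: tuple[tuple[str, str, CrossDomain], ...] = ()
    couplings: tuple[Coupling, ...] = ()
    occasions: tuple[float, ...] = _OCCASIONS
    phantom: tuple[float, ...] = _PHANTOM
    covariates: tuple[str, ...] = ("age_base", "education", "gender")
    cell_missing_rate: float = 0.01
    covariate_missing_rate: float = 0.03  # education-style incompleteness

    @property
    def measured_occasions(self) -> tuple[float, ...]:
        return tuple(t for t in self.occasions if t not in self.phantom)

    def domain(self, name: str) -> DomainTruth:
        for d in self.domains:
            if d.domain == name:
                return d
        raise KeyError(name)

    def cross_for(self, a: str, b: str) -> CrossDomain | None:
        for x, y, c in self.cross:
            if (x, y) == (a, b):
                return c
            if (x, y) == (b, a):
                return CrossDomain(
                    c.icept_icept, c.slope_slope, c.icept_b_slope_a, c.icept_a_slope_b
                )
        return None

    # -- model construction -------------------------------------------
    def builder_config(self, name: str, **kw) -> BuilderConfig:
        return self.domain(name).builder_config(
            occasions=self.occasions, phantom=self.phantom,
            covariates=self.covariates, **kw,
        )

    def model(self) -> PathModel:
        """The analysis model matching this truth (1 or 2 domains)."""
        if len(self.domains) == 1:
            return build_univariate_lcs(self.builder_config(self.domains[0].domain))
        if len(self.domains) == 2:
            a, b = self.domains
            coupling = None
            if self.couplings:
                lags = {c.lag_years for c in self.couplings}
                if len(lags) != 1:
                    raise ValueError("mixed coupling lags have no single model")
                srcs = {c.source for c in self.couplings}
                if srcs == {a.domain}:
                    direction = "a_to_b"
                elif srcs == {b.domain}:
                    direction = "b_to_a"
                else:
                    direction = "bidirectional"
                coupling = CouplingSpec(lag_years=lags.pop(), direction=direction)
            return build_bivariate_lcs(
                self.builder_config(a.domain), self.builder_config(b.domain), coupling
            )
        raise ValueError("model() supports one or two domains")

    def manifest(self, n: int, seed: int, schedule: AttritionSchedule) -> dict:
        return {
            "truth": dataclasses.asdict(self),
            "n": n,
            "seed": seed,
            "schedule": dataclasses.asdict(schedule),
        }


# ----------------------------------------------------------------------
# truth -> model-parameter mapping
# ----------------------------------------------------------------------
def true_estimates(truth: TrueParameters, model: PathModel) -> dict[str, float]:
    """Ground-truth value for every free label of ``model``.

    Labels follow the builders' naming scheme; covariate moments come
    from the generating distributions in closed form.
    """
    out: dict[str, float] = {}
    for lab in model.labels():
        out[lab] = _true_value(truth, lab)
    return out


def _cov_moments(name: str) -> tuple[float, float]:
    if name.startswith("hm_t"):
        return _hm_mean(), _hm_var()
    c = _DEFAULT_COVARIATES[name]
    return c.mean, c.var


def _true_value(truth: TrueParameters, lab: str) -> float:
    parts = lab.split(":")
    head = parts[0]
    if head == "lam":
        d = truth.domain(parts[1])
        return d.loadings[d.indicators.index(parts[2])]
    if head == "nu":
        d = truth.domain(parts[1])
        base = d.intercepts[d.indicators.index(parts[2])]
        if len(parts) == 4:  # occasion-specific
            year = float(parts[3][1:])
            base += d.drift(parts[2], year)
        return base
    if head == "evar":
        d = truth.domain(parts[1])
        return d.residual_sd[d.indicators.index(parts[2])] ** 2
    if head == "ecov":
        d = truth.domain(parts[1])
        s = d.residual_sd[d.indicators.index(parts[2])]
        return d.residual_corr * s * s
    if head == "mu_I":
        return truth.domain(parts[1]).icept_mean
    if head == "mu_S":
        return truth.domain(parts[1]).slope_mean
    if head == "var_I":
        return truth.domain(parts[1]).icept_sd ** 2
    if head == "var_S":
        return truth.domain(parts[1]).slope_sd ** 2
    if head == "cov_IS":
        return truth.domain(parts[1]).icept_slope_cov
    if head == "retest_mu":
        return truth.domain(parts[1]).retest_mean
    if head == "retest_var":
        return truth.domain(parts[1]).retest_sd ** 2
    if head == "beta":
        return truth.domain(parts[1]).proportional
    if head == "b":
        d = truth.domain(parts[1])
        effects = (
            d.covariate_effects_icept if parts[2] == "I" else d.covariate_effects_slope
        )
        return dict(effects).get(parts[3], 0.0)
    if head == "b_tvc":
        return truth.domain(parts[1]).tvc_effect
    if head == "gamma":
        src, dst = lab[len("gamma:"):].split("->")
        for c in truth.couplings:
            if c.source == src and c.target == dst:
                return c.gamma
        return 0.0
    if head == "xcov":
        (k1, d1), (k2, d2) = (p.split("_", 1) for p in parts[1:3])
        c = truth.cross_for(d1, d2)
        if c is None:
            return 0.0
        if k1 == "I" and k2 == "I":
            return c.icept_icept
        if k1 == "S" and k2 == "S":
            return c.slope_slope
        if k1 == "I" and k2 == "S":
            return c.icept_a_slope_b
        return c.icept_b_slope_a
    if head == "mean":
        return _cov_moments(parts[1])[0]
    if head == "vcov":
        if parts[1] == parts[2]:
            return _cov_moments(parts[1])[1]
        return 0.0  # covariates generated independently
    raise KeyError(f"no truth mapping for label {lab!r}")


# ----------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------
def _latent_cov(truth: TrueParameters) -> np.ndarray:
    """Joint covariance of (I, S) across all domains, domain-major."""
    k = len(truth.domains)
    V = np.zeros((2 * k, 2 * k))
    for i, d in enumerate(truth.domains):
        V[2 * i, 2 * i] = d.icept_sd ** 2
        V[2 * i + 1, 2 * i + 1] = d.slope_sd ** 2
        V[2 * i, 2 * i + 1] = V[2 * i + 1, 2 * i] = d.icept_slope_cov
    for i, a in enumerate(truth.domains):
        for j, b in enumerate(truth.domains):
            if j <= i:
                continue
            c = truth.cross_for(a.domain, b.domain)
            if c is None:
                continue
            V[2 * i, 2 * j] = V[2 * j, 2 * i] = c.icept_icept
            V[2 * i + 1, 2 * j + 1] = V[2 * j + 1, 2 * i + 1] = c.slope_slope
            V[2 * i, 2 * j + 1] = V[2 * j + 1, 2 * i] = c.icept_a_slope_b
            V[2 * i + 1, 2 * j] = V[2 * j, 2 * i + 1] = c.icept_b_slope_a
    return V


def _psd_factor(V: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    w, Q = np.linalg.eigh(0.5 * (V + V.T))
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValueError(f"infeasible latent covariance (min eigenvalue {w.min():.3g})")
    return Q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_dataset(
    truth: TrueParameters,
    n: int,
    schedule: AttritionSchedule | None = None,
    seed: int = 0,
    *,
    raw_scale: bool = False,
    hemispheres: bool = False,
) -> tuple[LongitudinalTable, dict]:
    """Draw a synthetic cohort; returns (table, ground-truth manifest).

    ``raw_scale`` emits pre-preprocessing units (FA in 0-1, reaction
    times positive, age in years, education 1-3); the default is the
    model scale the estimators consume.  ``hemispheres`` additionally
    emits left/right FA and voxel-count columns for single-indicator
    domains flagged ``scale100`` so that hemispheric averaging has work
    to do.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if schedule is None:
        # cohort-style attrition on the canonical 4-wave grid; no
        # attrition on other grids unless a schedule is supplied
        if len(truth.measured_occasions) == 4:
            schedule = AttritionSchedule()
        else:
            schedule = AttritionSchedule(counts=None)
    rng = np.random.default_rng(seed)
    years = truth.occasions
    measured = truth.measured_occasions
    chg_years = years[1:]

    cols: dict[str, np.ndarray] = {}
    # covariates
    for name in truth.covariates:
        cols[name] = _DEFAULT_COVARIATES[name].sample(rng, n)
    needs_hm = any(d.tvc_name for d in truth.domains)
    if needs_hm:
        for t in measured:
            cols[f"hm_t{_fmt(t)}"] = np.exp(
                _HM_MU + _HM_SIGMA * rng.standard_normal(n)
            )

    # latent intercepts and slopes
    V = _latent_cov(truth)
    L = _psd_factor(V)
    u = rng.standard_normal((n, V.shape[0])) @ L.T
    I = {}
    S = {}
    for i, d in enumerate(truth.domains):
        mi = np.full(n, d.icept_mean)
        ms = np.full(n, d.slope_mean)
        for cov, b in d.covariate_effects_icept:
            mi = mi + b * cols[cov]
        for cov, b in d.covariate_effects_slope:
            ms = ms + b * cols[cov]
        I[d.domain] = mi + u[:, 2 * i]
        S[d.domain] = ms + u[:, 2 * i + 1]

    # trajectories with lagged couplings
    eta = {d.domain: {years[0]: I[d.domain].copy()} for d in truth.domains}
    chg: dict[str, dict[float, np.ndarray]] = {d.domain: {} for d in truth.domains}
    first_chg = chg_years[0]
    for t_prev, t in zip(years, chg_years):
        for d in truth.domains:
            dd = S[d.domain].copy()
            if t == first_chg and (d.retest_mean or d.retest_sd):
                dd += d.retest_mean + d.retest_sd * rng.standard_normal(n)
            if d.proportional:
                dd += d.proportional * eta[d.domain][t_prev]
            for c in truth.couplings:
                if c.target == d.domain:
                    t_src = t - c.lag_years
                    if t_src in chg[c.source]:
                        dd += c.gamma * chg[c.source][t_src]
            chg[d.domain][t] = dd
            eta[d.domain][t] = eta[d.domain][t_prev] + dd

    # indicators
    for d in truth.domains:
        k_occ = len(measured)
        R = d.residual_corr * np.ones((k_occ, k_occ))
        np.fill_diagonal(R, 1.0)
        Lr = _psd_factor(R)
        for j, ind in enumerate(d.indicators):
            eps = (rng.standard_normal((n, k_occ)) @ Lr.T) * d.residual_sd[j]
            for a, t in enumerate(measured):
                y = (
                    d.intercepts[j]
                    + d.drift(ind, t)
                    + d.loadings[j] * eta[d.domain][t]
                    + eps[:, a]
                )
                if d.tvc_name:
                    y = y + d.tvc_effect * cols[f"{d.tvc_name}_t{_fmt(t)}"]
                cols[f"{ind}_t{_fmt(t)}"] = y

    df = pd.DataFrame(cols)
    df.index.name = "participant_id"

    # --- attrition (monotone, optionally age-dependent) ----------------
    retained = schedule.retained(n, len(measured))
    age = cols.get("age_base", np.zeros(n))
    active = np.ones(n, dtype=bool)
    occ_cols = {
        t: [c for c in df.columns if c.endswith(f"_t{_fmt(t)}")] for t in measured
    }
    for a, t in enumerate(measured):
        target = retained[a]
        n_drop = int(active.sum()) - target
        if n_drop > 0:
            cand = np.nonzero(active)[0]
            if schedule.age_dependent:
                w = np.exp(schedule.age_log_odds * (age[cand] - age.mean()))
                w = w / w.sum()
            else:
                w = None
            drop = rng.choice(cand, size=n_drop, replace=False, p=w)
            active[drop] = False
        df.loc[~active, occ_cols[t]] = np.nan

    # --- element-wise MAR missingness ----------------------------------
    if truth.cell_missing_rate > 0:
        # rate modulated by (always-observed) baseline age: MAR
        z = (age - age.mean()) / (age.std() + 1e-12)
        rate = np.clip(truth.cell_missing_rate * (1.0 + 0.4 * z), 0.0, 0.5)
        for t in measured[1:]:
            for c in occ_cols[t]:
                hit = rng.random(n) < rate
                df.loc[hit, c] = np.nan
    if truth.covariate_missing_rate > 0 and "education" in df.columns:
        hit = rng.random(n) < truth.covariate_missing_rate
        df.loc[hit, "education"] = np.nan

    if hemispheres:
        df = _emit_hemispheres(df, truth, measured, rng)
    if raw_scale:
        df = _to_raw_scale(df, truth, measured)

    return LongitudinalTable(df), truth.manifest(n, seed, schedule)


def _fmt(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


def _emit_hemispheres(df, truth, measured, rng):
    for d in truth.domains:
        if not (d.scale100 and len(d.indicators) == 1):
            continue
        ind = d.indicators[0]
        v_left = int(rng.integers(150, 400))
        v_right = int(rng.integers(150, 400))
        for t in measured:
            col = f"{ind}_t{_fmt(t)}"
            delta = 0.5 * rng.standard_normal(len(df))
            left = df[col] + delta
            right = df[col] - delta * v_left / v_right
            df[f"{ind}_left_t{_fmt(t)}"] = left
            df[f"{ind}_right_t{_fmt(t)}"] = right
            df[f"{ind}_left_voxels_t{_fmt(t)}"] = v_left
            df[f"{ind}_right_voxels_t{_fmt(t)}"] = v_right
    return df


def _to_raw_scale(df, truth, measured):
    df = df.copy()
    for d in truth.domains:
        for ind in d.indicators:
            for t in measured:
                for prefix in ("", "_left", "_right"):
                    col = f"{ind}{prefix}_t{_fmt(t)}"
                    if col in df.columns:
                        if d.scale100:
                            df[col] = df[col] / 100.0
                        if "tmta" in ind:
                            df[col] = -df[col]
    if "age_base" in df.columns:
        df["age_base"] = df["age_base"] + 70.0
    if "education" in df.columns:
        df["education"] = df["education"] + 2.0
    return df


def save_dataset(table: LongitudinalTable, manifest: dict, path_stem: str) -> None:
    """Write the table as CSV with its truth manifest as JSON alongside."""
    table.df.to_csv(f"{path_stem}.csv")
    with open(f"{path_stem}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------
def speed_truth(retest: float = 2.0) -> DomainTruth:
    """Processing speed: 4 tasks on a common factor, practice gain ~+2."""
    return DomainTruth(
        domain="ps",
        indicators=("speed_ipt", "speed_digsy", "speed_tmta", "speed_lps14"),
        loadings=(1.0, 0.9, 0.7, 1.1),
        intercepts=(0.0, 6.0, -88.0, -12.0),
        residual_sd=(5.0, 5.5, 7.0, 5.0),
        residual_corr=0.35,
        icept_mean=48.5,
        icept_sd=9.0,
        slope_mean=-0.55,
        slope_sd=1.0,
        icept_slope_cov=-0.5,
        retest_mean=retest,
        covariate_effects_icept=(("age_base", -0.6), ("education", 2.0), ("gender", 1.0)),
        covariate_effects_slope=(("age_base", -0.03),),
    )


def tract_truth(name: str, regime: str = "declining") -> DomainTruth:
    """FA tract (x100 scale) in one of three slope regimes.

    "declining": negative mean slope with real slope variance;
    "stable": no mean change but slope variance;
    "zero_slope_var": boundary case with no between-person slope variance.
    """
    regimes = {
        "declining": (-0.30, 0.28),
        "stable": (0.00, 0.25),
        "zero_slope_var": (-0.20, 0.0),
    }
    if regime not in regimes:
        raise ValueError(f"unknown regime {regime!r}")
    mu_s, sd_s = regimes[regime]
    return DomainTruth(
        domain=name,
        indicators=(f"fa_{name}",),
        loadings=(1.0,),
        intercepts=(0.0,),
        residual_sd=(0.8,),
        residual_corr=0.0,
        icept_mean=44.0,
        icept_sd=2.6,
        slope_mean=mu_s,
        slope_sd=sd_s,
        icept_slope_cov=0.0,
        covariate_effects_icept=(("age_base", -0.12), ("gender", -0.3)),
        covariate_effects_slope=(("age_base", -0.01),),
        tvc_name="hm",
        tvc_effect=-2.0,
        scale100=True,
    )


def bivariate_truth(
    lag_years: int = 2,
    gamma_fa_ps: float = 2.5,
    gamma_ps_fa: float = 0.6,
    tract: str = "slf",
) -> TrueParameters:
    """FA tract + processing speed with (optionally null) lagged coupling."""
    fa = tract_truth(tract, "declining")
    ps = speed_truth()
    couplings = []
    if gamma_fa_ps:
        couplings.append(Coupling(fa.domain, ps.domain, lag_years, gamma_fa_ps))
    if gamma_ps_fa:
        couplings.append(Coupling(ps.domain, fa.domain, lag_years, gamma_ps_fa))
    return TrueParameters(
        domains=(fa, ps),
        cross=((fa.domain, ps.domain, CrossDomain(1.75, 0.06, 0.17, 0.2)),),
        couplings=tuple(couplings),
    )


def cohort_truth(
    tracts: Mapping[str, str] | None = None,
    coupled_tract: str = "slf",
    lag_years: int = 2,
    gamma_fa_ps: float = 2.5,
    gamma_ps_fa: float = 0.6,
) -> TrueParameters:
    """Multi-tract cohort: speed plus several FA tracts, one coupled.

    ``tracts`` maps tract name -> slope regime; the default mirrors a
    cohort where half the tracts carry real slope variance.
    """
    if tracts is None:
        tracts = {
            "fmin": "declining",
            "slf": "declining",
            "ifof": "declining",
            "atr": "declining",
            "unc": "stable",
            "fmaj": "zero_slope_var",
            "ilf": "zero_slope_var",
            "ccg": "zero_slope_var",
            "chc": "zero_slope_var",
            "cst": "zero_slope_var",
        }
    ps = speed_truth()
    domains = [ps]
    cross = []
    couplings = []
    for name, regime in tracts.items():
        fa = tract_truth(name, regime)
        domains.append(fa)
        if name == coupled_tract:
            cross.append((fa.domain, ps.domain, CrossDomain(1.75, 0.06, 0.17, 0.2)))
            if gamma_fa_ps:
                couplings.append(Coupling(fa.domain, ps.domain, lag_years, gamma_fa_ps))
            if gamma_ps_fa:
                couplings.append(Coupling(ps.domain, fa.domain, lag_years, gamma_ps_fa))
    return TrueParameters(
        domains=tuple(domains), cross=tuple(cross), couplings=tuple(couplings)
    )


# ----------------------------------------------------------------------
# parameter recovery
# ----------------------------------------------------------------------
@dataclass
class RecoveryResult:
    """Per-parameter bias/RMSE/coverage over simulate-fit replicates."""

    table: pd.DataFrame
    n_replicates: int
    n_converged: int
    valid: bool

    def parameter(self, label: str) -> pd.Series:
        return self.table.loc[label]


def recovery_experiment(
    truth: TrueParameters,
    n: int,
    replicates: int,
    seed: int = 0,
    *,
    schedule: AttritionSchedule | None = None,
    compute_se: bool = True,
    heywood_fix: bool = True,
) -> RecoveryResult:
    """Simulate-and-fit loop reporting bias, RMSE and Wald coverage.

    Non-converged replicates are counted and excluded; the experiment is
    flagged invalid when more than 20% fail to converge.
    """
    from .estimation import fit  # local import to avoid cycle

    if replicates < 2:
        raise ValueError("need at least two replicates")
    model = truth.model()
    target = true_estimates(truth, model)
    labels = sorted(target)
    ests: list[dict] = []
    ses: list[dict] = []
    n_conv = 0
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(replicates)
    for r in range(replicates):
        tab, _ = simulate_dataset(
            truth, n, schedule, seed=int(child_seeds[r]) % (2 ** 31)
        )
        res = fit(model, tab, compute_se=compute_se, heywood_fix=heywood_fix)
        if not res.converged:
            continue
        n_conv += 1
        ests.append(res.estimates)
        ses.append(res.standard_errors)

    rows = {}
    for lab in labels:
        e = np.array([d[lab] for d in ests])
        tv = target[lab]
        emp_sd = float(e.std(ddof=1)) if len(e) > 1 else float("nan")
        se_vals = np.array(
            [d.get(lab, float("nan")) for d in ses], dtype=float
        )
        with np.errstate(invalid="ignore"):
            cover = np.abs(e - tv) <= 1.959963984540054 * se_vals
        ok = np.isfinite(se_vals)
        rows[lab] = {
            "true": tv,
            "mean_est": float(e.mean()),
            "bias": float(e.mean() - tv),
            "mc_se": emp_sd / math.sqrt(max(len(e), 1)),
            "emp_sd": emp_sd,
            "rmse": float(np.sqrt(np.mean((e - tv) ** 2))),
            "mean_se": float(np.nanmean(se_vals)) if ok.any() else float("nan"),
            "coverage": float(cover[ok].mean()) if ok.any() else float("nan"),
        }
    table = pd.DataFrame(rows).T
    table.index.name = "label"
    return RecoveryResult(
        table=table,
        n_replicates=replicates,
        n_converged=n_conv,
        valid=(replicates - n_conv) <= 0.2 * replicates,
    )
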