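"""Full published-analysis orchestration on a conforming wide table.

Stages: outlier screening -> univariate tract models (with negative
slope variances fixed to zero where triggered) -> global-factor
invariance evaluation -> speed invariance cascade and retest comparison
-> shortlist of tracts with reliable slope variance -> bivariate
baseline and lagged-coupling series per shortlisted tract -> model
selection.  Any stage's non-convergence is recorded in the run log and
its dependents skipped; nothing is silently imputed.

Input tables are wide, one row per participant, columns
``{variable}_t{occasion}`` for occasion-indexed variables plus
``age_base``, ``education``, ``gender``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .builders import BuilderConfig, CouplingSpec, build_bivariate_lcs, build_univariate_lcs
from .data import LongitudinalTable, as_table
from .estimation import FitResult, fit, saturated_and_null_fits
from .fit_compare import (
    ComparisonRow,
    FitIndices,
    chisq_difference,
    fit_indices,
    format_fit,
    select_coupling_model,
)
from .invariance import InvarianceReport, mi_cascade
from .preprocessing import ExclusionSpec, OutlierPolicy, apply_exclusions

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis",
           "marginal_significance_label"]


def marginal_significance_label(p: float) -> str:
    """Annotation used in result tables: significant / marginal / ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "marginal"
    return "ns"


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the full analysis run."""

    speed_indicators: tuple[str, ...] = (
        "speed_ipt", "speed_digsy", "speed_tmta", "speed_lps14",
    )
    tracts: tuple[str, ...] = (
        "fa_fmaj", "fa_fmin", "fa_slf", "fa_ilf", "fa_ifof",
        "fa_atr", "fa_unc", "fa_ccg", "fa_chc", "fa_cst",
    )
    covariates: tuple[str, ...] = ("age_base", "education", "gender")
    hm_variable: str = "hm"
    occasions: tuple[float, ...] = (0, 1, 2, 3, 4)
    phantom: tuple[float, ...] = (3,)
    coupling_lags: tuple[int, ...] = (1, 2)
    alpha: float = 0.01  # chi-square difference threshold
    slope_var_p_threshold: float = 0.10  # significant-or-marginal rule
    heywood_fix: bool = True
    run_global_factor: bool = True
    probe_retest_variance: bool = False
    max_freed: int = 3
    screen_outliers: bool = True

    @property
    def measured_occasions(self) -> tuple[float, ...]:
        return tuple(t for t in self.occasions if t not in self.phantom)

    def tract_config(self, tract: str) -> BuilderConfig:
        return BuilderConfig(
            domain=tract.removeprefix("fa_"),
            indicators=(tract,),
            occasions=self.occasions,
            phantom=self.phantom,
            covariates=self.covariates,
            time_varying_covariates={
                t: self.hm_variable for t in self.measured_occasions
            },
        )

    def speed_config(self, retest: str = "none", invariance: str = "strong") -> BuilderConfig:
        return BuilderConfig(
            domain="ps",
            indicators=self.speed_indicators,
            occasions=self.occasions,
            phantom=self.phantom,
            invariance_level=invariance,
            retest=retest,
            covariates=self.covariates,
        )

    def global_fa_config(self) -> BuilderConfig:
        return BuilderConfig(
            domain="fa_glob",
            indicators=self.tracts,
            occasions=self.occasions,
            phantom=self.phantom,
            covariates=self.covariates,
        )


@dataclass
class AnalysisReport:
    """Everything the full run produced, plus a plain-text run log."""

    exclusion_counts: dict[str, int] = field(default_factory=dict)
    univariate_tracts: dict[str, dict] = field(default_factory=dict)
    global_factor: InvarianceReport | None = None
    global_factor_tenable: bool | None = None
    speed_invariance: InvarianceReport | None = None
    retest_comparison: dict | None = None
    shortlist: list[str] = field(default_factory=list)
    bivariate: dict[tuple[str, int], list[ComparisonRow]] = field(default_factory=dict)
    selected: dict[tuple[str, int], str] = field(default_factory=dict)
    parameter_tables: dict[tuple[str, int], pd.DataFrame] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def comparison_table(self, tract: str, lag: int) -> pd.DataFrame:
        rows = self.bivariate[(tract, lag)]
        recs = []
        for r in rows:
            fi = r.indices
            recs.append(
                {
                    "model": r.label,
                    "chi2": fi.chi_square,
                    "df": fi.df,
                    "chi2_df": fi.chi_over_df,
                    "rmsea": fi.rmsea,
                    "cfi": fi.cfi,
                    "bic_adj": fi.bic_adjusted,
                    "delta_chi2": r.delta_chi_square,
                    "delta_df": r.delta_df,
                    "p": r.p_value,
                    "selected": r.selected,
                }
            )
        return pd.DataFrame(recs)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")
        for (tract, lag), _ in self.bivariate.items():
            self.comparison_table(tract, lag).to_csv(
                out / f"comparison_{tract}_lag{lag}.csv", index=False
            )
        for (tract, lag), tab in self.parameter_tables.items():
            tab.to_csv(out / f"parameters_{tract}_lag{lag}.csv")
        summary = {
            "shortlist": self.shortlist,
            "selected": {f"{t}_lag{l}": m for (t, l), m in self.selected.items()},
            "exclusions": self.exclusion_counts,
            "global_factor_tenable": self.global_factor_tenable,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))


def run_full_analysis(data, config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Execute the complete longitudinal coupling analysis."""
    report = AnalysisReport()
    log = report.log
    table = as_table(data)
    _validate_schema(table, config)

    # -- screening ------------------------------------------------------
    if config.screen_outliers:
        spec = ExclusionSpec(
            per_variable={v: OutlierPolicy() for v in config.speed_indicators},
            head_motion=(config.hm_variable, tuple(config.tracts)),
        )
        table, exc_log = apply_exclusions(table, spec)
        report.exclusion_counts = dict(exc_log.removed)
        for k, v in exc_log.removed.items():
            log.append(f"screening: removed {v} values for {k}")
        n_rows = table.n_rows
        n_occ = len(config.measured_occasions)
        hm_cols = [
            table.column(config.hm_variable, t) for t in config.measured_occasions
        ]
        n_hm_obs = int(table.df[hm_cols].notna().sum().sum())
        log.append(
            "head-motion screening pool: "
            f"{n_rows * n_occ} cells ({n_rows} rows x {n_occ} occasions); "
            f"{n_hm_obs} observed motion values"
        )

    # -- univariate tract models ---------------------------------------
    for tract in config.tracts:
        cfg = config.tract_config(tract)
        model = build_univariate_lcs(cfg)
        res = fit(model, table, heywood_fix=config.heywood_fix)
        entry: dict = {"fit": res}
        if not res.converged:
            log.append(f"univariate {tract}: NOT CONVERGED; skipping downstream")
            entry["indices"] = None
            report.univariate_tracts[tract] = entry
            continue
        sat, null = saturated_and_null_fits(table, model.observed_names)
        fi = fit_indices(res, sat, null)
        entry["indices"] = fi
        d = cfg.domain
        pvals = res.p_values()
        slope_var_label = f"var_S:{d}"
        fixed_zero = slope_var_label in res.heywood_flags
        entry["slope_variance"] = res.estimates.get(slope_var_label, 0.0)
        entry["slope_variance_p"] = pvals.get(slope_var_label, float("nan"))
        entry["slope_mean"] = res.estimates.get(f"mu_S:{d}")
        entry["slope_mean_p"] = pvals.get(f"mu_S:{d}", float("nan"))
        entry["heywood_fixed"] = fixed_zero
        report.univariate_tracts[tract] = entry
        log.append(
            f"univariate {tract}: {format_fit(fi)}"
            + (" [slope variance fixed to 0]" if fixed_zero else "")
        )

    # -- global FA factor -----------------------------------------------
    if config.run_global_factor and len(config.tracts) >= 3:
        try:
            rep = mi_cascade(table, config.global_fa_config(), config.max_freed)
            report.global_factor = rep
            last = rep.steps[-1].indices
            tenable = rep.final_level in ("strong", "partial") and last.adequate_fit()
            report.global_factor_tenable = tenable
            log.append(
                f"global FA factor: final invariance {rep.final_level}, "
                f"{format_fit(last)} -> {'tenable' if tenable else 'not tenable'}"
            )
        except RuntimeError as err:
            log.append(f"global FA factor: {err}")
            report.global_factor_tenable = None

    # -- speed invariance and retest -------------------------------------
    speed_rep = mi_cascade(table, config.speed_config(), config.max_freed)
    report.speed_invariance = speed_rep
    log.append(f"speed invariance: final level {speed_rep.final_level}")

    # the retest contrast is a likelihood-ratio test between the stated
    # models, so both are fit without boundary fixes; Heywood flags are
    # logged rather than refit here
    retest_choice = "none"
    base_fit = fit(
        build_univariate_lcs(config.speed_config("none")), table,
        heywood_fix=False,
    )
    retest_fit = fit(
        build_univariate_lcs(config.speed_config("free_mean")), table,
        heywood_fix=False,
    )
    for name, f in (("no-retest", base_fit), ("retest", retest_fit)):
        if f.heywood_flags:
            log.append(f"speed {name} model: negative variances {f.heywood_flags}")
    if base_fit.converged and retest_fit.converged:
        sat, null = saturated_and_null_fits(
            table, base_fit.model.observed_names
        )
        fi_base = fit_indices(base_fit, sat, null)
        fi_re = fit_indices(retest_fit, sat, null)
        delta, ddf, p = chisq_difference(fi_base, fi_re)
        report.retest_comparison = {
            "no_retest": fi_base,
            "retest": fi_re,
            "delta_chi2": delta,
            "delta_df": ddf,
            "p": p,
        }
        if p < config.alpha:
            retest_choice = "free_mean"
        log.append(
            f"retest: delta chi2 {delta:.3f} ({ddf}), p = {p:.4g} -> "
            f"{'retest mean retained' if retest_choice != 'none' else 'no retest'}"
        )
        if retest_choice == "free_mean" and config.probe_retest_variance:
            var_fit = fit(
                build_univariate_lcs(config.speed_config("free_mean_and_variance")),
                table, heywood_fix=False,
            )
            if var_fit.converged and not var_fit.heywood_flags:
                retest_choice = "free_mean_and_variance"
                log.append("retest variance admissible; freeing it")
            else:
                log.append(
                    "retest variance inadmissible (negative estimate); kept fixed at 0"
                )
    else:
        log.append("retest comparison skipped: speed model did not converge")

    # -- shortlist --------------------------------------------------------
    for tract, entry in report.univariate_tracts.items():
        if entry.get("indices") is None or entry.get("heywood_fixed"):
            continue
        p = entry.get("slope_variance_p", float("nan"))
        if np.isfinite(p) and p < config.slope_var_p_threshold:
            report.shortlist.append(tract)
    log.append(
        f"tracts with reliable slope variance: {report.shortlist or 'none'}"
    )

    # -- bivariate series -------------------------------------------------
    # bivariate comparisons are likelihood-ratio tests over a nested
    # chain, so the chain is fit without boundary refits (which would
    # change df mid-chain); negative variances are logged instead
    speed_cfg = config.speed_config(retest_choice)
    for tract in report.shortlist:
        tract_cfg = config.tract_config(tract)
        base_model = build_bivariate_lcs(tract_cfg, speed_cfg, None)
        base_res = fit(base_model, table, heywood_fix=False)
        if not base_res.converged:
            log.append(f"bivariate {tract}: baseline NOT CONVERGED; skipped")
            continue
        if base_res.heywood_flags:
            log.append(
                f"bivariate {tract}: baseline negative variances "
                f"{base_res.heywood_flags}"
            )
        sat, null = saturated_and_null_fits(table, base_model.observed_names)
        fi_base = fit_indices(base_res, sat, null)
        fits = {"baseline": base_res}
        for lag in config.coupling_lags:
            rows = [ComparisonRow("baseline", fi_base)]
            for direction, name in (
                ("a_to_b", "fa->ps"),
                ("b_to_a", "ps->fa"),
                ("bidirectional", "full"),
            ):
                model = build_bivariate_lcs(
                    tract_cfg, speed_cfg,
                    CouplingSpec(lag_years=lag, direction=direction),
                )
                res = fit(model, table, heywood_fix=False)
                if not res.converged:
                    log.append(
                        f"bivariate {tract} lag {lag} {name}: NOT CONVERGED; "
                        "left out of comparison"
                    )
                    continue
                fi = fit_indices(res, sat, null)
                delta, ddf, p = chisq_difference(fi_base, fi)
                rows.append(ComparisonRow(name, fi, delta, ddf, p))
                fits[name] = res
            chosen = select_coupling_model(rows, alpha=config.alpha)
            report.bivariate[(tract, lag)] = rows
            report.selected[(tract, lag)] = chosen.label
            report.parameter_tables[(tract, lag)] = _parameter_table(
                fits.get(chosen.label, base_res), tract_cfg.domain, "ps"
            )
            log.append(
                f"bivariate {tract} lag {lag}: selected {chosen.label} "
                f"({format_fit(chosen.indices)})"
            )
    return report


def _parameter_table(res: FitResult, dom_a: str, dom_b: str) -> pd.DataFrame:
    """Cross-domain covariances and couplings of the selected model."""
    pvals = res.p_values()
    rows = []
    for lab, est in sorted(res.estimates.items()):
        if lab.startswith(("xcov:", "gamma:")) or lab.startswith(
            (f"mu_S:{dom_a}", f"mu_S:{dom_b}", f"retest_mu:{dom_b}")
        ):
            p = pvals.get(lab, float("nan"))
            rows.append(
                {
                    "parameter": lab,
                    "estimate": est,
                    "se": res.standard_errors.get(lab, float("nan")),
                    "p": p,
                    "label": (
                        marginal_significance_label(p) if np.isfinite(p) else "n/a"
                    ),
                }
            )
    return pd.DataFrame(rows).set_index("parameter")


def _validate_schema(table: LongitudinalTable, config: AnalysisConfig) -> None:
    required = list(config.covariates)
    for t in config.measured_occasions:
        for v in (*config.speed_indicators, *config.tracts, config.hm_variable):
            required.append(f"{v}_t{int(t) if float(t).is_integer() else t}")
    missing = [c for c in required if c not in table.df.columns]
    if missing:
        raise KeyError(f"input table missing required columns: {missing[:8]}")
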