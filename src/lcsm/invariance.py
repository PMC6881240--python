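"""Step-wise longitudinal measurement-invariance testing.

The cascade fits the same second-order change-score model under
increasingly constrained measurement structures — configural (pattern
only), weak (equal loadings over occasions), strong (equal loadings and
intercepts) — and accepts each step if the CFI drops by at most 0.01.
When strong invariance fails, intercepts are freed one indicator at a
time, highest modification index first (ties broken by earliest occasion
then indicator order), each freeing releasing that indicator's intercept
at every non-reference occasion, until the CFI rule passes
(partial-strong) or the freeing budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builders import BuilderConfig, build_univariate_lcs
from .data import as_table
from .estimation import FitResult, fit, modification_indices, saturated_and_null_fits
from .fit_compare import FitIndices, delta_cfi_decision, fit_indices

__all__ = ["InvarianceStep", "InvarianceReport", "mi_cascade"]


@dataclass
class InvarianceStep:
    level: str
    indices: FitIndices
    delta_cfi: float | None
    decision: str  # "baseline" | "accept" | "reject"
    freed: tuple[str, ...] = ()


@dataclass
class InvarianceReport:
    steps: list[InvarianceStep] = field(default_factory=list)
    freed_cells: list[str] = field(default_factory=list)
    final_level: str = "configural"

    def step(self, level: str) -> InvarianceStep:
        for s in self.steps:
            if s.level == level:
                return s
        raise KeyError(level)


def mi_cascade(
    data,
    config: BuilderConfig,
    max_freed: int = 3,
    *,
    delta_cfi_threshold: float = 0.01,
) -> InvarianceReport:
    """Run configural -> weak -> strong (-> partial) invariance testing.

    Requires a second-order configuration (>= 3 indicators).  Returns a
    report with one step per fitted level; ``final_level`` is the most
    constrained accepted level, with freed intercepts listed when the
    outcome is partial-strong.
    """
    if len(config.indicators) < 3:
        raise ValueError("invariance testing needs >= 3 indicators")
    table = as_table(data)

    report = InvarianceReport()

    def fit_level(cfg: BuilderConfig) -> tuple[FitResult, FitIndices]:
        model = build_univariate_lcs(cfg)
        res = fit(model, table, heywood_fix=True)
        if not res.converged:
            raise RuntimeError(
                f"{cfg.invariance_level} model did not converge; "
                "cannot continue the cascade"
            )
        sat, null = _baselines(table, model, _cache)
        return res, fit_indices(res, sat, null)

    _cache: dict = {}

    conf_fit, conf_ix = fit_level(config.with_invariance("configural"))
    report.steps.append(InvarianceStep("configural", conf_ix, None, "baseline"))
    report.final_level = "configural"

    weak_fit, weak_ix = fit_level(config.with_invariance("weak"))
    decision = delta_cfi_decision(conf_ix, weak_ix, delta_cfi_threshold)
    report.steps.append(
        InvarianceStep("weak", weak_ix, conf_ix.cfi - weak_ix.cfi, decision)
    )
    if decision == "reject":
        return report
    report.final_level = "weak"

    strong_fit, strong_ix = fit_level(config.with_invariance("strong"))
    decision = delta_cfi_decision(weak_ix, strong_ix, delta_cfi_threshold)
    report.steps.append(
        InvarianceStep("strong", strong_ix, weak_ix.cfi - strong_ix.cfi, decision)
    )
    if decision == "accept":
        report.final_level = "strong"
        return report

    # partial-strong: free intercepts by modification index
    freed: list[str] = []
    current_fit = strong_fit
    for _ in range(max_freed):
        indicator = _top_intercept_indicator(current_fit, config, exclude=freed)
        if indicator is None:
            break
        freed.append(indicator)
        part_fit, part_ix = fit_level(
            config.with_invariance("partial", freed=tuple(freed))
        )
        decision = delta_cfi_decision(weak_ix, part_ix, delta_cfi_threshold)
        report.steps.append(
            InvarianceStep(
                f"partial({','.join(freed)})",
                part_ix,
                weak_ix.cfi - part_ix.cfi,
                decision,
                freed=tuple(freed),
            )
        )
        if decision == "accept":
            report.final_level = "partial"
            report.freed_cells = list(freed)
            return report
        current_fit = part_fit
    return report


def _baselines(table, model, cache):
    key = tuple(model.observed_names)
    if key not in cache:
        cache[key] = saturated_and_null_fits(table, model.observed_names)
    return cache[key]


def _top_intercept_indicator(
    fit_result: FitResult, config: BuilderConfig, exclude: list[str]
) -> str | None:
    """Indicator whose constrained intercept has the largest modification
    index; ties break to the earliest occasion, then indicator order."""
    model = fit_result.model
    candidates = []
    order = {}
    occasions = config.measured_occasions
    for j, ind in enumerate(config.indicators):
        if j == 0 or ind in exclude:
            continue  # reference indicator stays fixed
        for a, t in enumerate(occasions):
            col = config.column(ind, t)
            cell = ("M", model.index(col), model.index(col))
            candidates.append(cell)
            order[cell] = (a, j, ind)
    if not candidates:
        return None
    mi_table = modification_indices(fit_result, candidates)
    best = None
    best_key = None
    for _, row in mi_table.iterrows():
        if not np.isfinite(row["mi"]):
            continue
        cell = ("M", model.index(row["row"]), model.index(row["row"]))
        occ_rank, ind_rank, ind = order[cell]
        key = (-row["mi"], occ_rank, ind_rank)
        if best_key is None or key < best_key:
            best_key = key
            best = ind
    return best
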