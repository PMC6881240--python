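"""Lagged coupled-change inference between white matter and speed.

Simulates a cohort in which FA changes in one tract lead processing-speed
changes two years later (and weakly vice versa), fits the baseline,
unidirectional and full-coupling bivariate models, and selects among
them by chi-square difference and adjusted BIC.
"""

import warnings

from lcsm import (
    ComparisonRow,
    CouplingSpec,
    bivariate_truth,
    build_bivariate_lcs,
    chisq_difference,
    fit,
    fit_indices,
    saturated_and_null_fits,
    select_coupling_model,
    simulate_dataset,
)

truth = bivariate_truth(lag_years=2, gamma_fa_ps=2.5, gamma_ps_fa=0.6)
table, _ = simulate_dataset(truth, 230, seed=13)
fa_cfg = truth.builder_config("slf")
ps_cfg = truth.builder_config("ps")

series = [
    ("baseline", None),
    ("fa->ps", CouplingSpec(2, "a_to_b")),
    ("ps->fa", CouplingSpec(2, "b_to_a")),
    ("full", CouplingSpec(2, "bidirectional")),
]
rows, fits, sat = [], {}, None
for label, coupling in series:
    model = build_bivariate_lcs(fa_cfg, ps_cfg, coupling)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit(model, table)
    if sat is None:
        sat, null = saturated_and_null_fits(table, model.observed_names)
    fi = fit_indices(res, sat, null)
    if label == "baseline":
        rows.append(ComparisonRow(label, fi))
    else:
        delta, ddf, p = chisq_difference(rows[0].indices, fi)
        rows.append(ComparisonRow(label, fi, delta, ddf, p))
    fits[label] = res

print(f"{'model':>10} {'chi2(df)':>16} {'BIC_adj':>12} {'dchi2 (ddf)':>14} {'p':>8}")
for r in rows:
    d = "-" if r.delta_chi_square is None else f"{r.delta_chi_square:.3f} ({r.delta_df})"
    p = "-" if r.p_value is None else f"{r.p_value:.4f}"
    print(f"{r.label:>10} {r.indices.chi_square:>10.3f} ({r.indices.df}) "
          f"{r.indices.bic_adjusted:>12.3f} {d:>14} {p:>8}")

chosen = select_coupling_model(rows)
print(f"selected: {chosen.label}")
best = fits[chosen.label]
pv = best.p_values()
for lab in sorted(best.estimates):
    if lab.startswith("gamma:"):
        print(f"  {lab} = {best.estimates[lab]:.3f} "
              f"(SE {best.standard_errors[lab]:.3f}, p = {pv[lab]:.4f})")
print("truth: gamma slf->ps = 2.5, gamma ps->slf = 0.6; a positive "
      "fa->ps coupling means smaller FA declines precede smaller speed "
      "declines two years later")
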