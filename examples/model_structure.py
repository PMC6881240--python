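"""Build the core latent change score model variants and show their size.

A second-order LCS model for processing speed (4 indicators at years
0, 1, 2, 4 plus a phantom year 3), a first-order single-tract FA model
with occasion-wise head-motion covariates, and the bivariate series that
joins them with lagged change-to-change couplings.
"""

import dataclasses

from lcsm import BuilderConfig, CouplingSpec, build_bivariate_lcs, build_univariate_lcs

speed = BuilderConfig(
    domain="ps",
    indicators=("speed_ipt", "speed_digsy", "speed_tmta", "speed_lps14"),
)
tract = BuilderConfig(
    domain="slf",
    indicators=("fa_slf",),
    time_varying_covariates={0: "hm", 1: "hm", 2: "hm", 4: "hm"},
)

for name, model in [
    ("speed, strong invariance", build_univariate_lcs(speed)),
    ("speed + retest mean",
     build_univariate_lcs(dataclasses.replace(speed, retest="free_mean"))),
    ("single tract + head motion", build_univariate_lcs(tract)),
]:
    free, moments, df = model.count_df()
    print(f"{name}: {model.n_observed} observed variables, "
          f"{moments} moments, {free} free parameters -> df {df}")

speed_retest = BuilderConfig(
    domain="ps",
    indicators=("speed_ipt", "speed_digsy", "speed_tmta", "speed_lps14"),
    retest="free_mean",
)
for label, coupling in [
    ("baseline (correlations only)", None),
    ("FA -> speed, 2-year lag", CouplingSpec(2, "a_to_b")),
    ("bidirectional, 2-year lag", CouplingSpec(2, "bidirectional")),
]:
    model = build_bivariate_lcs(tract, speed_retest, coupling)
    print(f"bivariate {label}: df {model.count_df()[2]}")

# each free coupling parameter costs exactly one degree of freedom;
# the df chain 292 -> 291 -> 290 identifies the nested comparison series
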