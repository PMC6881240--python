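"""The data-preparation rules between raw measures and model input.

MAD-based outlier screening pooled across occasions, head-motion-driven
blanking of FA cells, voxel-weighted hemispheric averaging, model-scale
transforms, and the attrition selectivity index.
"""

import numpy as np
import pandas as pd

from lcsm import (
    ExclusionSpec,
    OutlierPolicy,
    apply_exclusions,
    hemispheric_average,
    mad_flags,
    prepare_model_inputs,
    selectivity_index,
)

# --- MAD screening ----------------------------------------------------
values = [1, 2, 3, 4, 100]
flags = mad_flags(values, OutlierPolicy(k_mads=3, side="upper"))
print(f"values {values} -> flagged: {list(np.array(values)[flags])}")
print("  (median 3, MAD 1, upper threshold 3 + 3 x 1.4826 = 7.45)")

# --- head-motion exclusion blanks FA cells, keeps the row -------------
df = pd.DataFrame({
    "fa_slf_t0": [0.40, 0.41], "fa_slf_t1": [0.39, 0.40],
    "speed_ipt_t0": [30.0, 31.0], "speed_ipt_t1": [29.0, 30.0],
    "hm_t0": [0.20, 0.21], "hm_t1": [0.22, 4.0],
})
cleaned, log = apply_exclusions(df, ExclusionSpec(head_motion=("hm", ("fa_slf",))))
print(f"head-motion flags blanked {log.removed['hm->dependents']} FA cell(s); "
      f"speed cells kept: {cleaned.df.loc[1, 'speed_ipt_t1']}")

# --- hemispheric averaging --------------------------------------------
v = hemispheric_average(0.40, 0.50, 300, 100)
print(f"left 0.40 (300 voxels) + right 0.50 (100 voxels) -> {float(v):.3f}")

# --- model-scale transforms --------------------------------------------
raw = pd.DataFrame({
    "fa_slf_t0": [0.35796], "speed_tmta_t0": [40.0],
    "age_base": [70.0], "education": [2.0],
})
prepared = prepare_model_inputs(
    raw, fa_variables=("fa_slf",), reverse_variables=("speed_tmta",)
).df
print(f"FA 0.35796 -> {prepared.loc[0, 'fa_slf_t0']:.3f} (x100); "
      f"TMTA 40 s -> {prepared.loc[0, 'speed_tmta_t0']:.0f} (sign flip); "
      f"age 70 -> {prepared.loc[0, 'age_base']:.0f}; "
      f"education 2 -> {prepared.loc[0, 'education']:.0f}")

# --- selectivity of attrition -----------------------------------------
for name, (m0, sd0, m1) in {
    "baseline age": (70.84, 5.08, 70.15),
    "education": (2.23, 0.86, 2.29),
    "head motion": (0.24, 0.15, 0.26),
}.items():
    s = selectivity_index(m0, sd0, m1)
    print(f"selectivity {name}: {s:+.2f} "
          f"({'weak' if abs(s) < 0.20 else 'substantial'} attrition effect)")
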