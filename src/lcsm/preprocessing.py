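"""Data preparation between raw measures and model input.

Covers robust outlier screening (median absolute deviation rule, pooled
across occasions), exclusion application that blanks cells rather than
dropping rows, voxel-weighted hemispheric averaging of tract FA,
model-scale transforms (FA x100, reaction-time sign flip, covariate
centering), and the attrition selectivity index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import LongitudinalTable, as_table

__all__ = [
    "OutlierPolicy",
    "ExclusionSpec",
    "ExclusionLog",
    "mad_flags",
    "apply_exclusions",
    "hemispheric_average",
    "prepare_model_inputs",
    "selectivity_index",
]


@dataclass(frozen=True)
class OutlierPolicy:
    """Median +/- k * MAD screening rule.

    ``scope`` pools all occasions of one variable into a single
    distribution before computing the median and MAD.  The consistency
    constant 1.4826 rescales the MAD to a normal-sd-equivalent; set it
    to 1.0 for the unscaled convention.
    """

    k_mads: float = 3.0
    side: str = "two_sided"  # "two_sided" | "upper"
    mad_constant: float = 1.4826

    def __post_init__(self):
        if self.k_mads <= 0:
            raise ValueError("k_mads must be positive")
        if self.side not in ("two_sided", "upper"):
            raise ValueError(f"unknown side {self.side!r}")


def mad_flags(values, policy: OutlierPolicy = OutlierPolicy()) -> np.ndarray:
    """Boolean flags for values beyond median +/- k * (constant * MAD).

    Missing values are never flagged.  A zero MAD (degenerate scale)
    flags every value different from the median, with a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    obs = x[~np.isnan(x)]
    if obs.size == 0:
        raise ValueError("need at least one non-missing value")
    med = float(np.median(obs))
    mad = float(np.median(np.abs(obs - med)))
    if mad == 0.0:
        import warnings

        warnings.warn(
            "MAD is zero (degenerate scale); flagging values != median",
            stacklevel=2,
        )
        with np.errstate(invalid="ignore"):
            flags = x != med
        flags[np.isnan(x)] = False
        return flags
    cut = policy.k_mads * policy.mad_constant * mad
    with np.errstate(invalid="ignore"):
        if policy.side == "upper":
            flags = x > med + cut
        else:
            flags = (x > med + cut) | (x < med - cut)
    flags[np.isnan(x)] = False
    return flags


@dataclass(frozen=True)
class ExclusionSpec:
    """Which variables to screen and how.

    ``per_variable``: variable base name -> OutlierPolicy; flagged cells
    are blanked.  ``head_motion``: (motion variable, dependent variable
    bases) — a flagged motion value blanks every dependent cell at that
    occasion for that participant (the motion value itself is kept).
    """

    per_variable: Mapping[str, OutlierPolicy] = field(default_factory=dict)
    head_motion: tuple[str, tuple[str, ...]] | None = None
    head_motion_policy: OutlierPolicy = OutlierPolicy(side="upper")


@dataclass
class ExclusionLog:
    """Removal bookkeeping: variable base name -> number of blanked cells."""

    removed: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.removed.values())


def _occasion_columns(df: pd.DataFrame, base: str) -> list[str]:
    cols = [c for c in df.columns if c == base or c.startswith(base + "_t")]
    if not cols:
        raise KeyError(f"unknown variable {base!r}")
    return cols


def apply_exclusions(
    data, spec: ExclusionSpec
) -> tuple[LongitudinalTable, ExclusionLog]:
    """Blank outlying cells; never drop rows.

    Screened distributions pool all occasions of a variable.  Head-motion
    flags blank the dependent (FA) cells of the same occasion, leaving
    other domains untouched so FIML retains the row.
    """
    table = as_table(data)
    df = table.df.copy()
    log = ExclusionLog()

    for base, policy in spec.per_variable.items():
        cols = _occasion_columns(df, base)
        pooled = df[cols].to_numpy(dtype=float)
        flags = mad_flags(pooled.ravel(), policy).reshape(pooled.shape)
        n_flagged = int(flags.sum())
        if n_flagged:
            arr = df[cols].to_numpy(dtype=float)
            arr[flags] = np.nan
            df[cols] = arr
        log.removed[base] = n_flagged

    if spec.head_motion is not None:
        motion, dependents = spec.head_motion
        mcols = _occasion_columns(df, motion)
        pooled = df[mcols].to_numpy(dtype=float)
        flags = mad_flags(pooled.ravel(), spec.head_motion_policy).reshape(
            pooled.shape
        )
        n_dep = 0
        for k, mcol in enumerate(mcols):
            suffix = mcol[len(motion):]  # "_t<occ>"
            hit = flags[:, k]
            if not hit.any():
                continue
            for dep in dependents:
                dcol = dep + suffix
                if dcol in df.columns:
                    present = hit & df[dcol].notna().to_numpy()
                    n_dep += int(present.sum())
                    df.loc[hit, dcol] = np.nan
        log.removed[f"{motion}->dependents"] = n_dep
    return LongitudinalTable(df), log


def hemispheric_average(
    left_fa, right_fa, left_voxels, right_voxels
) -> np.ndarray:
    """Voxel-weighted mean of left/right homologous tract FA.

    ``(L * vL + R * vR) / (vL + vR)`` elementwise; when one side is
    missing the other side is returned unchanged; both sides missing
    yields missing.  Voxel counts must be positive wherever the
    corresponding FA is present.
    """
    L = np.asarray(left_fa, dtype=float)
    R = np.asarray(right_fa, dtype=float)
    vL = np.asarray(left_voxels, dtype=float)
    vR = np.asarray(right_voxels, dtype=float)
    if np.any((~np.isnan(L)) & ~(vL > 0)):
        raise ValueError("left voxel counts must be positive where FA present")
    if np.any((~np.isnan(R)) & ~(vR > 0)):
        raise ValueError("right voxel counts must be positive where FA present")
    both = ~np.isnan(L) & ~np.isnan(R)
    out = np.full(np.broadcast(L, R).shape, np.nan)
    out = np.where(both, (L * vL + R * vR) / np.where(both, vL + vR, 1.0), out)
    out = np.where(np.isnan(L) & ~np.isnan(R), R, out)
    out = np.where(np.isnan(R) & ~np.isnan(L), L, out)
    return out


def prepare_model_inputs(
    data,
    fa_variables: Sequence[str] = (),
    reverse_variables: Sequence[str] = (),
    age_center: float = 70.0,
    education_center: float = 2.0,
) -> LongitudinalTable:
    """Apply the model-scale transforms.

    FA columns x100 (avoids estimation artifacts from scale mismatch with
    the cognitive scores); reversed timing scores x(-1) so higher =
    better; age centered (median 70), education centered at level 2;
    gender and head motion untouched (zero motion is meaningful).
    """
    table = as_table(data)
    df = table.df.copy()
    for base in fa_variables:
        for col in _occasion_columns(df, base):
            df[col] = df[col] * 100.0
    for base in reverse_variables:
        for col in _occasion_columns(df, base):
            df[col] = -df[col]
    if "age_base" in df.columns:
        df["age_base"] = df["age_base"] - age_center
    if "education" in df.columns:
        df["education"] = df["education"] - education_center
    return LongitudinalTable(df)


def selectivity_index(
    baseline_mean: float, baseline_sd: float, followup_mean: float
) -> float:
    """Attrition effect size: (followup_mean - baseline_mean) / baseline_sd.

    Standardizes the difference between the follow-up sample's baseline
    mean and the full baseline sample's mean on the baseline SD; values
    below 0.20 in magnitude are conventionally a weak attrition effect.
    """
    if not baseline_sd > 0:
        raise ValueError("baseline SD must be positive")
    return (followup_mean - baseline_mean) / baseline_sd
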