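"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from lcsm.builders import BuilderConfig
from lcsm.data import LongitudinalTable
from lcsm.model import PathModel

SPEED_INDICATORS = ("speed_ipt", "speed_digsy", "speed_tmta", "speed_lps14")


def symbolic_df_count(model: PathModel) -> tuple[int, int, int]:
    """Independent df oracle: enumerate cells from the JSON export.

    Walks the serialized document (not the in-memory matrices), collects
    distinct labels, and counts observed moments from first principles.
    """
    doc = json.loads(model.to_json())
    labels = set()
    seen_sym = set()
    for mat in ("A", "S", "M"):
        for rec in doc[mat]:
            if "label" not in rec:
                continue
            if mat == "S":
                key = frozenset((rec["row"], rec["col"]))
                if key in seen_sym:
                    continue
                seen_sym.add(key)
            labels.add(rec["label"])
    p = doc["n_observed"]
    moments = p * (p + 1) // 2 + p
    return len(labels), moments, moments - len(labels)


@pytest.fixture(scope="session")
def speed_config() -> BuilderConfig:
    """Second-order processing-speed configuration (strong invariance)."""
    return BuilderConfig(domain="ps", indicators=SPEED_INDICATORS)


@pytest.fixture(scope="session")
def tract_config() -> BuilderConfig:
    """First-order tract configuration with occasion-wise head motion."""
    return BuilderConfig(
        domain="slf",
        indicators=("fa_slf",),
        time_varying_covariates={0: "hm", 1: "hm", 2: "hm", 4: "hm"},
    )


@pytest.fixture(scope="session")
def small_lcs_config() -> BuilderConfig:
    """Minimal first-order model: 4 annual occasions, no phantom, no covariates."""
    return BuilderConfig(
        domain="g", indicators=("y",), occasions=(0, 1, 2, 3), phantom=(),
        covariates=(),
    )


def simulate_small_lcs(
    n: int,
    seed: int,
    *,
    mu_i: float = 50.0,
    mu_s: float = -0.5,
    sd_i: float = 2.0,
    sd_s: float = 0.3,
    cov_is: float = 0.0,
    resid_sd: float = 1.0,
    missing: float = 0.0,
) -> pd.DataFrame:
    """Hand-rolled generator for the minimal first-order model.

    Independent of lcsm.simulate so estimation tests have an oracle data
    source that shares no code with the module under test.
    """
    rng = np.random.default_rng(seed)
    cov = np.array([[sd_i ** 2, cov_is], [cov_is, sd_s ** 2]])
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    u = rng.standard_normal((n, 2)) @ L.T
    I = mu_i + u[:, 0]
    S = mu_s + u[:, 1]
    data = {}
    for t in range(4):
        data[f"y_t{t}"] = I + S * t + resid_sd * rng.standard_normal(n)
    df = pd.DataFrame(data)
    if missing > 0:
        mask = rng.random((n, 4)) < missing
        arr = df.to_numpy()
        arr[mask] = np.nan
        keep = ~np.isnan(arr).all(axis=1)
        df = pd.DataFrame(arr[keep], columns=df.columns)
    return df


@pytest.fixture(scope="session")
def small_lcs_data() -> LongitudinalTable:
    return LongitudinalTable(simulate_small_lcs(400, seed=7, missing=0.1))
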