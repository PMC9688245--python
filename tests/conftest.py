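import numpy as np
import pandas as pd
import pytest

from fallfs.cohort import CohortSpec, FeatureTable, generate_cohort


def make_table(values: dict, scales: dict | None = None, roles: dict | None = None,
               levels: dict | None = None, block: str = "B") -> FeatureTable:
    """Small hand-built FeatureTable; NaN cells become masked."""
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()})
    mask = df.isna()
    meta = pd.DataFrame(
        {
            "block": [block] * df.shape[1],
            "scale": [(scales or {}).get(f, "metric") for f in df.columns],
            "levels": [(levels or {}).get(f, np.nan) for f in df.columns],
            "role": [(roles or {}).get(f, "") for f in df.columns],
        },
        index=pd.Index(df.columns, name="feature"),
    )
    return FeatureTable(df, mask, meta)


@pytest.fixture(scope="session")
def default_cohort():
    """One default cohort shared across tests (n=1240, 428 features)."""
    spec = CohortSpec(seed=20240901)
    blocks, y = generate_cohort(spec)
    return spec, blocks, y


def slim_spec(**kw) -> CohortSpec:
    """A one-block cohort spec for cheap targeted simulations."""
    defaults = dict(
        n_samples=500,
        block_widths={"GR_N": 10},
        informative_features={},
        missingness={"GR_N": (0.0, 0.0)},
        seed=0,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)
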