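"""Synthetic multi-block gait/questionnaire cohort generator.

The generator emulates the statistical structure of a clinical fall-risk
cohort assessed with eleven overlapping data sets: two pressure-mat gait
recordings (normal and dual-task walking), two wearable-sensor gait
recordings, two postural-sway recordings (eyes open / eyes closed), a
rater-based disability block (EDSS functional-system scores with a derived
total plus two timed walking tests), and two Likert questionnaires (MSWS-12,
5-level items; EMIQ, 4-level items).

The model is a single latent severity factor: each subject carries
``s_i ~ N(0, 1)``; the binary faller label is ``Bernoulli(sigmoid(a + b*s_i))``
with the intercept ``a`` solved numerically so the marginal prevalence matches
the requested value; an informative feature with loading ``lambda_j`` is
``lambda_j * s_i + e`` with unit-variance Gaussian noise ``e`` (ordinal
features cut the same latent at equiprobable thresholds); all other features
are pure noise. Missingness has two parts, applied blockwise: a per-block
missing-completely-at-random cell rate (system errors) and an optional
severity-linked component that removes a subject's entire block (an
assessment the patient could not complete), so more severely affected
subjects lose whole sensor recordings — and each analysis data set keeps its
own complete-case n.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

DEFAULT_BLOCK_WIDTHS: dict[str, int] = {
    "Basic": 11,
    "EDSS": 9,
    "GR_N": 82,
    "GR_D": 82,
    "ML_N": 84,
    "ML_D": 84,
    "ML_S_EO": 32,
    "ML_S_EC": 32,
    "MSWS-12": 12,
    "EMIQ": 9,
}

#: Physical blocks actually generated; the EDSS data set is the 9 disability
#: features inside Basic, and the "All" data set concatenates everything
#: except that duplicate view (428 columns at the default widths).
PHYSICAL_BLOCKS = ("Basic", "GR_N", "GR_D", "ML_N", "ML_D", "ML_S_EO", "ML_S_EC", "MSWS-12", "EMIQ")

DATASET_NAMES = ("All",) + ("Basic", "EDSS") + PHYSICAL_BLOCKS[1:]

EDSS_FUNCTIONAL = (
    "EDSS_Visual",
    "EDSS_Brainstem",
    "EDSS_Pyramidal",
    "EDSS_Cerebellar",
    "EDSS_Sensory",
    "EDSS_Bowel_Bladder",
    "EDSS_Cognition_Fatigue",
    "EDSS_Ambulation",
)
EDSS_TOTAL = "EDSS_Score"

#: Default planted informative features: nine questionnaire items spread over
#: the two patient-reported blocks, mirroring the kind of subset a
#: feature-selection ensemble is expected to recover.
DEFAULT_INFORMATIVE = (
    "Q1_EMIQ",
    "Q4_EMIQ",
    "Q8_EMIQ",
    "Q1_MSWS-12",
    "Q2_MSWS-12",
    "Q3_MSWS-12",
    "Q7_MSWS-12",
    "Q11_MSWS-12",
    "Q12_MSWS-12",
)

DEFAULT_LOADING = 1.2


def _default_missingness() -> dict[str, tuple[float, float]]:
    """Per-block (mcar_rate, severity_slope).

    Sensor blocks carry a positive slope: subjects with higher latent severity
    are less able to complete instrumented walking/balance tests, so their
    cells go missing more often.
    """
    out: dict[str, tuple[float, float]] = {}
    for b in PHYSICAL_BLOCKS:
        if b in ("Basic", "MSWS-12", "EMIQ"):
            out[b] = (0.01, 0.0)
        else:
            out[b] = (0.02, 0.75)
    return out


@dataclass
class FeatureTable:
    """Samples x features matrix with a missingness mask and per-feature metadata.

    ``values`` holds floats (ordinal features as their integer codes); cells
    with ``mask`` True are missing and stored as NaN so they carry no
    information. ``meta`` is indexed by feature name with columns
    ``block``, ``scale`` ('metric' | 'ordinal'), ``levels`` (level count for
    Likert-type ordinals, NaN otherwise) and ``role`` ('' |
    'edss_functional' | 'edss_total').
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.mask.columns):
            raise ValueError("values and mask must share columns")
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("meta must be indexed by the value columns")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate feature name: {dup}")

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.mask.copy(), self.meta.copy())

    def select(self, features: list[str]) -> "FeatureTable":
        """Column subset, preserving the requested order."""
        return FeatureTable(
            self.values[features].copy(), self.mask[features].copy(), self.meta.loc[features].copy()
        )

    def take_rows(self, idx) -> "FeatureTable":
        return FeatureTable(
            self.values.iloc[idx].reset_index(drop=True),
            self.mask.iloc[idx].reset_index(drop=True),
            self.meta.copy(),
        )


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort."""

    n_samples: int = 1240
    faller_prevalence: float = 0.139
    block_widths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BLOCK_WIDTHS))
    informative_features: dict[str, float] = field(
        default_factory=lambda: {f: DEFAULT_LOADING for f in DEFAULT_INFORMATIVE}
    )
    ordinal_levels: dict[str, int] = field(default_factory=dict)
    missingness: dict[str, tuple[float, float]] = field(default_factory=_default_missingness)
    label_slope: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.faller_prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.faller_prevalence}")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        for b, w in self.block_widths.items():
            if w <= 0:
                raise ValueError(f"block width must be positive: {b}={w}")
        non_edss = [b for b in self.block_widths if b != "EDSS"]
        total = sum(self.block_widths[b] for b in non_edss)
        if set(self.block_widths) == set(DEFAULT_BLOCK_WIDTHS) and total != 428:
            raise ValueError(f"non-EDSS block widths must sum to 428, got {total}")
        if "EDSS" in self.block_widths and "Basic" in self.block_widths:
            if self.block_widths["EDSS"] > self.block_widths["Basic"]:
                raise ValueError("EDSS block must be a subset of Basic")
        for f, lam in self.informative_features.items():
            if not np.isfinite(lam):
                raise ValueError(f"non-finite loading for {f}")
        for b, (mcar, slope) in self.missingness.items():
            if not 0.0 <= mcar < 1.0:
                raise ValueError(f"MCAR rate for {b} must be in [0,1)")


def _feature_names(block: str, width: int) -> list[str]:
    """Deterministic feature naming per block."""
    if block == "Basic":
        if width != 11:
            raise ValueError("Basic block is fixed at 11 features (2 timed tests + 9 EDSS)")
        return ["T25FW", "2MWT", *EDSS_FUNCTIONAL, EDSS_TOTAL]
    if block == "MSWS-12":
        return [f"Q{i}_MSWS-12" for i in range(1, width + 1)]
    if block == "EMIQ":
        return [f"Q{i}_EMIQ" for i in range(1, width + 1)]
    return [f"{block}_f{i:03d}" for i in range(1, width + 1)]


def solve_label_intercept(beta: float, prevalence: float) -> float:
    """Intercept a with E_s[sigmoid(a + beta*s)] = prevalence for s ~ N(0,1).

    Solved by bracketed root finding on a Gauss-Hermite quadrature of the
    marginal; raises if the bracket fails (it cannot for prevalence in (0,1)).
    """
    nodes, wts = np.polynomial.hermite_e.hermegauss(61)
    wts = wts / wts.sum()

    def marginal(a: float) -> float:
        return float(np.sum(wts * expit(a + beta * nodes)) - prevalence)

    lo, hi = -40.0, 40.0
    if marginal(lo) > 0 or marginal(hi) < 0:
        raise ValueError(f"cannot solve intercept for prevalence={prevalence}, beta={beta}")
    return float(brentq(marginal, lo, hi, xtol=1e-12))


def edss_total_from_functional(scores: np.ndarray) -> np.ndarray:
    """Deterministic monotone surrogate for the EDSS total.

    ``total = max(f) + 0.5 * max(0, #(f >= 2) - 1)`` over the 8 functional
    scores ``f``. This is a documented stand-in for the real Neurostatus
    scoring rules (which are rater-administered and out of scope); it is
    monotone in every functional score and is the same rule the
    knowledge-based imputer inverts.
    """
    scores = np.asarray(scores, dtype=float)
    mx = scores.max(axis=-1)
    n_ge2 = (scores >= 2).sum(axis=-1)
    return mx + 0.5 * np.maximum(0, n_ge2 - 1)


def _ordinal_levels_for(spec: CohortSpec, name: str, block: str) -> int | None:
    if name in spec.ordinal_levels:
        return spec.ordinal_levels[name]
    if block == "MSWS-12":
        return 5
    if block == "EMIQ":
        return 4
    if name in EDSS_FUNCTIONAL:
        return 5
    return None  # metric


def generate_cohort(spec: CohortSpec) -> tuple[dict[str, FeatureTable], np.ndarray]:
    """Draw a synthetic cohort: per-block feature tables and the binary labels.

    Deterministic given (spec, spec.seed). The returned dict holds the nine
    physical blocks; use :func:`dataset_table` to assemble any of the eleven
    analysis data sets (including the EDSS view of Basic and the concatenated
    "All" set).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    s = rng.standard_normal(n)
    alpha = solve_label_intercept(spec.label_slope, spec.faller_prevalence)
    y = (rng.random(n) < expit(alpha + spec.label_slope * s)).astype(int)
    if y.min() == y.max():
        warnings.warn(
            f"cohort of n={n} drew a single class; increase n or prevalence",
            stacklevel=2,
        )

    blocks: dict[str, FeatureTable] = {}
    for block in (b for b in spec.block_widths if b != "EDSS"):
        width = spec.block_widths[block]
        names = _feature_names(block, width)
        cols: dict[str, np.ndarray] = {}
        meta_rows = []
        for name in names:
            if name == EDSS_TOTAL:
                # derived after the functional scores; placeholder
                cols[name] = np.zeros(n)
                meta_rows.append((name, block, "ordinal", np.nan, "edss_total"))
                continue
            lam = spec.informative_features.get(name, 0.0)
            latent = lam * s + rng.standard_normal(n)
            levels = _ordinal_levels_for(spec, name, block)
            if levels is None:
                cols[name] = latent
                meta_rows.append((name, block, "metric", np.nan, ""))
            else:
                sd = float(np.sqrt(1.0 + lam * lam))
                cuts = sd * norm.ppf(np.arange(1, levels) / levels)
                cols[name] = (1.0 + np.searchsorted(cuts, latent)).astype(float)
                role = "edss_functional" if name in EDSS_FUNCTIONAL else ""
                meta_rows.append((name, block, "ordinal", float(levels), role))
        if block == "Basic":
            func = np.column_stack([cols[f] for f in EDSS_FUNCTIONAL])
            cols[EDSS_TOTAL] = edss_total_from_functional(func)

        values = pd.DataFrame(cols, columns=names)
        # Missingness, applied blockwise: the severity-linked (MAR) term drops
        # the subject's whole block — an assessment the patient could not
        # complete — while the MCAR rate knocks out individual cells (system
        # errors). At slope=0 the MAR term vanishes exactly.
        mcar, slope = spec.missingness.get(block, (0.0, 0.0))
        p_out = np.clip(expit(slope * s) - 0.5, 0.0, 0.99)
        block_out = rng.random(n) < p_out
        mask = pd.DataFrame(
            block_out[:, None] | (rng.random((n, width)) < mcar), columns=names
        )
        values = values.mask(mask.to_numpy())  # masked cells carry no information
        meta = pd.DataFrame(
            meta_rows, columns=["feature", "block", "scale", "levels", "role"]
        ).set_index("feature")
        blocks[block] = FeatureTable(values, mask, meta)

    return blocks, y


_DATASET_BLOCKS: dict[str, tuple[str, ...]] = {
    "All": PHYSICAL_BLOCKS,
    "Basic": ("Basic",),
    "EDSS": ("Basic",),
    **{b: (b,) for b in PHYSICAL_BLOCKS[1:]},
}


def dataset_table(blocks: dict[str, FeatureTable], name: str) -> FeatureTable:
    """Assemble one of the eleven analysis data sets from the physical blocks.

    "EDSS" is the nine disability features inside Basic; "All" concatenates
    every physical block (428 columns at the default widths).
    """
    if name not in _DATASET_BLOCKS:
        raise KeyError(f"unknown data set {name!r}; expected one of {DATASET_NAMES}")
    needed = _DATASET_BLOCKS[name]
    missing = [b for b in needed if b not in blocks]
    if missing:
        raise KeyError(f"data set {name!r} needs missing block(s): {missing}")
    if name == "EDSS":
        basic = blocks["Basic"]
        edss_cols = [f for f in basic.features if basic.meta.loc[f, "role"].startswith("edss")]
        return basic.select(edss_cols)
    if len(needed) == 1:
        return blocks[needed[0]].copy()
    values = pd.concat([blocks[b].values for b in needed], axis=1)
    mask = pd.concat([blocks[b].mask for b in needed], axis=1)
    meta = pd.concat([blocks[b].meta for b in needed], axis=0)
    return FeatureTable(values, mask, meta)


# ---------------------------------------------------------------------------
# on-disk dialect: one CSV per block (empty cell = missing), labels.csv,
# a tabular metadata sidecar, and a machine-readable spec echo.


def write_cohort(blocks: dict[str, FeatureTable], y: np.ndarray, directory, spec: CohortSpec | None = None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta_all = []
    for name, tab in blocks.items():
        tab.values.to_csv(d / f"block_{name}.csv", index=False)
        meta_all.append(tab.meta.assign(block=tab.meta["block"]))
    pd.concat(meta_all).to_csv(d / "features.tsv", sep="\t", index_label="feature")
    pd.DataFrame({"faller": np.asarray(y, dtype=int)}).to_csv(d / "labels.csv", index=False)
    if spec is not None:
        echo = {
            "n_samples": spec.n_samples,
            "faller_prevalence": spec.faller_prevalence,
            "block_widths": spec.block_widths,
            "informative_features": spec.informative_features,
            "label_slope": spec.label_slope,
            "missingness": {k: list(v) for k, v in spec.missingness.items()},
            "seed": spec.seed,
        }
        (d / "spec.json").write_text(json.dumps(echo, indent=2))


def read_cohort(directory) -> tuple[dict[str, FeatureTable], np.ndarray]:
    """Inverse of :func:`write_cohort`; round-trips values, masks and metadata."""
    d = Path(directory)
    sidecar = d / "features.tsv"
    if not sidecar.exists():
        raise FileNotFoundError(f"no cohort found in {d}: missing features.tsv")
    meta_all = pd.read_csv(sidecar, sep="\t", index_col="feature")
    meta_all["role"] = meta_all["role"].fillna("")
    blocks: dict[str, FeatureTable] = {}
    for path in sorted(d.glob("block_*.csv")):
        name = path.stem[len("block_"):]
        values = pd.read_csv(path)
        missing_meta = [f for f in values.columns if f not in meta_all.index]
        if missing_meta:
            raise ValueError(f"sidecar lacks metadata for feature {missing_meta[0]!r}")
        meta = meta_all.loc[list(values.columns)].copy()
        if meta["scale"].isna().any():
            bad = meta.index[meta["scale"].isna()][0]
            raise ValueError(f"sidecar missing scale for feature {bad!r}")
        if len(meta) != values.shape[1]:
            raise ValueError(f"width/metadata mismatch for block {name}")
        mask = values.isna()
        blocks[name] = FeatureTable(values, mask, meta)
    if not blocks:
        raise FileNotFoundError(f"no block CSVs found in {d}")
    y = pd.read_csv(d / "labels.csv")["faller"].to_numpy(dtype=int)
    for tab in blocks.values():
        if tab.n_samples != len(y):
            raise ValueError("label length does not match block rows")
    return blocks, y
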