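"""Type-aware imputation, EDSS knowledge-based handling, and standardization.

Metric features are imputed with the reference median, ordinal features with
the reference mode (ties broken toward the smaller code, for determinism).
The EDSS total is special-cased: a missing total is recomputed from complete
functional scores through the documented surrogate scoring rule
(:func:`fallfs.cohort.edss_total_from_functional`); a missing functional
score with an observed total takes the mode of that score among reference
subjects sharing the same total; when neither route applies the plain mode is
used. Ordinal features have a natural order and are treated as quasi-metric
downstream, so standardization z-scores every retained feature; constant
features are dropped with a warning.

All statistics are fitted on reference rows only and applied unchanged to new
rows, so the pipeline can request leakage-free per-fold fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fallfs.cohort import FeatureTable, edss_total_from_functional


def _median(x: np.ndarray) -> float:
    # even count -> mean of the two central order statistics
    return float(np.median(x))


def _mode_smallest(x: np.ndarray) -> float:
    """Mode with ties broken toward the smaller code."""
    vals, counts = np.unique(x, return_counts=True)
    return float(vals[np.argmax(counts)])  # np.unique sorts, argmax takes first max


@dataclass
class ImputationPlan:
    """Per-feature imputation rule and the statistics fitted from reference rows."""

    rules: dict[str, str]  # feature -> 'median' | 'mode' | 'edss_knowledge'
    stats: dict[str, float]  # fallback fill value per feature
    edss_functional: list[str] = field(default_factory=list)
    edss_total: str | None = None
    #: mode of each functional score among reference rows sharing a total value
    edss_strata: dict[str, dict[float, float]] = field(default_factory=dict)


def fit_impute(table: FeatureTable, reference_rows=None) -> ImputationPlan:
    """Learn imputation statistics from the reference rows (default: all rows)."""
    ref = table if reference_rows is None else table.take_rows(reference_rows)
    rules: dict[str, str] = {}
    stats: dict[str, float] = {}
    functional: list[str] = []
    total: str | None = None

    for f in table.features:
        role = table.meta.loc[f, "role"]
        scale = table.meta.loc[f, "scale"]
        obs = ref.values[f].to_numpy()[~ref.mask[f].to_numpy()]
        if role == "edss_total":
            # may be fully missing: the knowledge rule recomputes it from the
            # functional scores before any mode fallback is needed
            rules[f] = "edss_knowledge"
            stats[f] = _mode_smallest(obs) if obs.size else np.nan
            total = f
            continue
        if obs.size == 0:
            raise ValueError(f"feature {f!r} has no observed value in the reference rows")
        elif scale == "ordinal":
            rules[f] = "mode"
            stats[f] = _mode_smallest(obs)
            if role == "edss_functional":
                functional.append(f)
        else:
            rules[f] = "median"
            stats[f] = _median(obs)

    strata: dict[str, dict[float, float]] = {}
    if total is not None and functional:
        tot_obs = ~ref.mask[total].to_numpy()
        tot_vals = ref.values[total].to_numpy()
        for f in functional:
            f_obs = ~ref.mask[f].to_numpy()
            both = tot_obs & f_obs
            per_total: dict[float, float] = {}
            for t in np.unique(tot_vals[both]):
                per_total[float(t)] = _mode_smallest(ref.values[f].to_numpy()[both & (tot_vals == t)])
            strata[f] = per_total

    return ImputationPlan(rules, stats, functional, total, strata)


def apply_impute(plan: ImputationPlan, table: FeatureTable) -> FeatureTable:
    """Fill every masked cell; observed cells are preserved exactly."""
    out = table.copy()
    if plan.edss_total is not None and plan.edss_functional:
        out = impute_edss(out, plan)
    for f in out.features:
        miss = out.mask[f].to_numpy()
        if miss.any():
            fill = plan.stats[f]
            if not np.isfinite(fill):
                # total was unobserved at fit time; mode of the recomputed column
                recomputed = out.values[f].to_numpy()[~miss]
                if recomputed.size == 0:
                    raise ValueError(f"feature {f!r} cannot be imputed: no values at all")
                fill = _mode_smallest(recomputed)
            vals = out.values[f].to_numpy(copy=True)
            vals[miss] = fill
            out.values[f] = vals
            out.mask[f] = False
    return out


def impute_edss(table: FeatureTable, plan: ImputationPlan | None = None) -> FeatureTable:
    """Knowledge-based EDSS imputation on a table containing the EDSS features.

    Missing total with all 8 functional scores observed -> recomputed by the
    surrogate scoring rule. Missing functional score with an observed total ->
    mode of that score among reference subjects at the same total. Remaining
    holes are left for the plain mode pass of :func:`apply_impute` (or filled
    here when called through it).
    """
    if plan is None:
        plan = fit_impute(table)
    if plan.edss_total is None or not plan.edss_functional:
        raise ValueError("table carries no EDSS total/functional roles")
    out = table.copy()
    total, functional = plan.edss_total, plan.edss_functional

    func_mask = out.mask[functional].to_numpy()
    all_missing = func_mask.all(axis=1) & out.mask[total].to_numpy()
    if all_missing.any():
        raise ValueError(f"row {int(np.flatnonzero(all_missing)[0])}: entire EDSS block missing")

    # 1) recompute missing totals from complete functional rows
    tot_miss = out.mask[total].to_numpy()
    complete_f = ~func_mask.any(axis=1)
    fix = tot_miss & complete_f
    if fix.any():
        func_vals = out.values[functional].to_numpy()
        vals = out.values[total].to_numpy(copy=True)
        vals[fix] = edss_total_from_functional(func_vals[fix])
        out.values[total] = vals
        m = out.mask[total].to_numpy(copy=True)
        m[fix] = False
        out.mask[total] = m

    # 2) missing functional score, observed total -> stratified mode
    tot_obs = ~out.mask[total].to_numpy()
    tot_vals = out.values[total].to_numpy()
    for f in functional:
        miss = out.mask[f].to_numpy()
        fix = miss & tot_obs
        if not fix.any():
            continue
        vals = out.values[f].to_numpy(copy=True)
        strat = plan.edss_strata.get(f, {})
        filled = fix.copy()
        for i in np.flatnonzero(fix):
            t = float(tot_vals[i])
            if t in strat:
                vals[i] = strat[t]
            else:
                filled[i] = False  # fall through to the plain mode
        out.values[f] = vals
        m = out.mask[f].to_numpy(copy=True)
        m[filled] = False
        out.mask[f] = m

    return out


@dataclass
class Standardizer:
    """Fitted per-feature location/scale; transforms any table to z-scores."""

    mean: pd.Series
    std: pd.Series
    dropped: list[str]

    def transform(self, table: FeatureTable) -> FeatureTable:
        keep = [f for f in table.features if f in self.mean.index]
        out = table.select(keep)
        out.values = (out.values - self.mean[keep]) / self.std[keep]
        meta = out.meta.copy()
        return FeatureTable(out.values, out.mask, meta)


def standardize(table: FeatureTable, reference_rows=None) -> tuple[Standardizer, FeatureTable]:
    """Z-score each feature using reference-row statistics; drop constants.

    Requires an imputed table (no masked cells). Ordinals are quasi-metric and
    standardized like any metric feature.
    """
    if table.mask.to_numpy().any():
        raise ValueError("standardize expects an imputed table without missing cells")
    ref = table if reference_rows is None else table.take_rows(reference_rows)
    mean = ref.values.mean(axis=0)
    std = ref.values.std(axis=0, ddof=0)
    constant = std <= 1e-12
    dropped = list(std.index[constant])
    if dropped:
        warnings.warn(f"dropping constant feature(s): {dropped}", stacklevel=2)
    mean, std = mean[~constant], std[~constant]
    scaler = Standardizer(mean, std, dropped)
    return scaler, scaler.transform(table)
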