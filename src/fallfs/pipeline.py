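"""Orchestration: the full experiment grid over data sets, models and
ensemble configurations, best-model selection, and report rendering.

For every data set the pipeline drops subjects missing an entire constituent
block (complete-case per data set, so each data set keeps its own n), fits
the preprocessing (imputation + standardization), runs the feature-selection
ensemble at the requested threshold/combination, tunes each model family by
grid search, and scores it with repeated stratified cross-validation.
Infeasible cells (empty final subsets) are recorded as skipped. The winner
per data set maximizes mean F1; exact ties go to the row with fewer selected
features, then to the model-family order gnb, dt, knn, svm.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fallfs.cohort import DATASET_NAMES, FeatureTable, dataset_table
from fallfs.ensemble import (
    COMBINATIONS,
    THRESHOLDS,
    EnsembleConfig,
    ensemble_from_rankings,
    rank_all,
    run_fs_ensemble,
)
from fallfs.evaluate import (
    MODEL_FAMILIES,
    METRICS,
    grid_search_cv,
    permutation_test,
    repeated_cv_evaluate,
)
from fallfs.preprocess import apply_impute, fit_impute, standardize

logger = logging.getLogger(__name__)


@dataclass
class ExperimentGrid:
    """Axes and scale of one experiment run.

    Defaults are reduced-scale (3 repetitions, 99 permutations) so a full grid
    stays desk-sized; pass ``repetitions=10, permutations=1000`` for
    full-scale evaluation.
    """

    datasets: tuple[str, ...] = DATASET_NAMES
    models: tuple[str, ...] = MODEL_FAMILIES
    thresholds: tuple[float, ...] = THRESHOLDS
    combinations: tuple[str, ...] = COMBINATIONS
    seed: int = 0
    repetitions: int = 3
    folds: int = 5
    permutations: int = 99
    fit_scope: str = "global"  # 'global' (fit preprocessing once) | 'per_fold'
    nested: bool = False  # re-run feature selection inside each training fold
    relieff_kwargs: dict = field(default_factory=dict)

    def configs(self) -> list[EnsembleConfig]:
        out = []
        for t in self.thresholds:
            if t == 1.0:
                out.append(EnsembleConfig(1.0, None))
            else:
                out.extend(EnsembleConfig(t, c) for c in self.combinations)
        return out


class _FoldPreprocessor:
    """Per-fold imputation + standardization (+ optional nested selection).

    ``fit(rows)`` learns the statistics on the training rows only;
    ``transform(rows)`` returns the model matrix for any rows.
    """

    def __init__(self, table: FeatureTable, y, config: EnsembleConfig | None = None, relieff_kwargs=None):
        self.table = table
        self.y = np.asarray(y, dtype=int)
        self.config = config
        self.relieff_kwargs = relieff_kwargs or {}

    def fit(self, rows):
        ref = self.table.take_rows(rows)
        self.plan = fit_impute(self.table, rows)
        imputed = apply_impute(self.plan, self.table)
        self.scaler, scaled = standardize(imputed, rows)
        self._scaled = scaled
        if self.config is not None:
            sub = run_fs_ensemble(
                scaled.take_rows(rows), self.y[rows], self.config, self.relieff_kwargs
            )
            feats = sub.features if sub.features else scaled.features
            self._features = [f for f in scaled.features if f in set(feats)]
        else:
            self._features = scaled.features
        return self

    def transform(self, rows):
        return self._scaled.select(self._features).take_rows(rows).values.to_numpy(dtype=float)


def _complete_case(table: FeatureTable, y) -> tuple[FeatureTable, np.ndarray]:
    """Drop rows for which an entire constituent block is missing."""
    keep = np.ones(table.n_samples, dtype=bool)
    for block in table.meta["block"].unique():
        cols = [f for f in table.features if table.meta.loc[f, "block"] == block]
        keep &= ~table.mask[cols].to_numpy().all(axis=1)
    return table.take_rows(np.flatnonzero(keep)), np.asarray(y, dtype=int)[keep]


_RESULT_COLUMNS = (
    ["dataset", "n", "model", "threshold", "combination", "n_features", "skipped", "params", "features"]
    + [f"{m}_mean" for m in METRICS]
    + [f"{m}_sd" for m in METRICS]
)


def run_grid(blocks: dict[str, FeatureTable], y, grid: ExperimentGrid) -> pd.DataFrame:
    """One CVReport row per grid cell; deterministic given the grid seed."""
    rows = []
    for ds in grid.datasets:
        try:
            table = dataset_table(blocks, ds)
        except KeyError as err:
            logger.warning("data set %s unavailable: %s", ds, err)
            continue
        table_cc, y_cc = _complete_case(table, y)
        n_ds = table_cc.n_samples
        if grid.fit_scope == "global":
            plan = fit_impute(table_cc)
            _, scaled = standardize(apply_impute(plan, table_cc))
            rankings = rank_all(scaled, y_cc, grid.relieff_kwargs)
        for config in grid.configs():
            if grid.fit_scope == "global":
                subset = ensemble_from_rankings(rankings, config)
                if subset.infeasible:
                    rows.append(_skip_row(ds, n_ds, config))
                    continue
                X = scaled.select(subset.features).values.to_numpy(dtype=float)
                prep = None
                feats = subset.features
            else:
                prep = _FoldPreprocessor(table_cc, y_cc, config if grid.nested else None, grid.relieff_kwargs)
                if not grid.nested:
                    # selection still happens once, on globally preprocessed data
                    plan = fit_impute(table_cc)
                    _, scaled_all = standardize(apply_impute(plan, table_cc))
                    subset = run_fs_ensemble(scaled_all, y_cc, config, grid.relieff_kwargs)
                    if subset.infeasible:
                        rows.append(_skip_row(ds, n_ds, config))
                        continue
                    prep = _FoldPreprocessor(table_cc.select(subset.features), y_cc)
                    feats = subset.features
                else:
                    feats = table_cc.features
                X = None
            for family in grid.models:
                params, _ = grid_search_cv(family, X, y_cc, grid.folds, grid.seed, preprocessor=prep)
                rep = repeated_cv_evaluate(
                    family, params, X if X is not None else prep.table, y_cc,
                    grid.repetitions, grid.folds, grid.seed, preprocessor=prep,
                )
                row = {
                    "dataset": ds,
                    "n": n_ds,
                    "model": family,
                    "threshold": config.threshold,
                    "combination": config.combination or "-",
                    "n_features": len(feats) if not grid.nested else rep.n_features,
                    "skipped": False,
                    "params": repr(params),
                    "features": ";".join(feats) if not grid.nested else "(per-fold)",
                }
                row.update({f"{m}_mean": rep.means[m] for m in METRICS})
                row.update({f"{m}_sd": rep.sds[m] for m in METRICS})
                rows.append(row)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def _skip_row(ds: str, n: int, config: EnsembleConfig) -> dict:
    logger.info("%s %s: empty final subset, configuration skipped", ds, config.label)
    row = {
        "dataset": ds, "n": n, "model": "-", "threshold": config.threshold,
        "combination": config.combination or "-", "n_features": 0,
        "skipped": True, "params": "-", "features": "",
    }
    row.update({f"{m}_mean": np.nan for m in METRICS})
    row.update({f"{m}_sd": np.nan for m in METRICS})
    return row


_MODEL_ORDER = {m: i for i, m in enumerate(MODEL_FAMILIES)}


def select_best(results: pd.DataFrame) -> pd.DataFrame:
    """Winner per data set: max mean F1; ties -> fewer features -> family order."""
    winners = []
    for ds, sub in results.groupby("dataset", sort=False):
        live = sub[~sub["skipped"]]
        if live.empty:
            logger.warning("data set %s has no feasible rows; absent from the report", ds)
            continue
        ranked = sorted(
            live.to_dict("records"),
            key=lambda r: (
                -round(r["f1_mean"], 12),
                r["n_features"],
                _MODEL_ORDER.get(r["model"], 99),
                -r["threshold"],
                str(r["combination"]),
            ),
        )
        winners.append(ranked[0])
    return pd.DataFrame(winners, columns=results.columns)


def permutation_pvalues_for_winners(
    blocks: dict[str, FeatureTable], y, selection: pd.DataFrame, grid: ExperimentGrid
) -> pd.DataFrame:
    """Add the label-permutation p-value to each winning row.

    The already-chosen hyperparameters are reused across permutations (no
    re-tuning) and the scalar score is the repeated-CV mean F1 at the grid's
    repetition count.
    """
    selection = selection.copy()
    pvals = []
    for _, row in selection.iterrows():
        table_cc, y_cc = _complete_case(dataset_table(blocks, row["dataset"]), y)
        plan = fit_impute(table_cc)
        _, scaled = standardize(apply_impute(plan, table_cc))
        feats = [f for f in row["features"].split(";") if f]
        X = scaled.select(feats).values.to_numpy(dtype=float)
        params = ast.literal_eval(row["params"])  # repr of a plain dict from run_grid

        def score(Xa, ya):
            rep = repeated_cv_evaluate(
                row["model"], params, Xa, ya, grid.repetitions, grid.folds, grid.seed
            )
            return rep.means["f1"]

        res = permutation_test(score, X, y_cc, grid.permutations, grid.seed)
        pvals.append(res.p_value)
    selection["p_value"] = pvals
    return selection


def report(selection: pd.DataFrame, results: pd.DataFrame, out_dir=None) -> str:
    """Human-readable best-model table (+ TSVs when ``out_dir`` is given)."""
    lines = ["Best configuration per data set", "=" * 31]
    for _, r in selection.iterrows():
        pct = f"{r['threshold']:.0%}"
        p_txt = f"  p={r['p_value']:.4g}" if "p_value" in r and pd.notna(r.get("p_value")) else ""
        lines.append(
            f"{r['dataset']:<10} (n={r['n']:>5})  {r['model']:<4} {pct:>4} {r['combination']:<13}"
            f" k={r['n_features']:<4} F1={r['f1_mean']:.2f}+/-{r['f1_sd']:.2f}"
            f" recall={r['recall_mean']*100:.1f}% precision={r['precision_mean']*100:.1f}%"
            f" specificity={r['specificity_mean']*100:.1f}% kappa={r['kappa_mean']:.2f}{p_txt}"
        )
        feats = [f for f in str(r["features"]).split(";") if f]
        if feats and len(feats) <= 30:
            lines.append(f"{'':<12}features: {', '.join(feats)}")
    text = "\n".join(lines)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.tsv", sep="\t", index=False)
        selection.to_csv(out / "best.tsv", sep="\t", index=False)
        (out / "report.txt").write_text(text + "\n")
    return text
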