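"""Random-forest regression layer with the study's resampling design.

The response (official yield, t ha⁻¹) is predicted from the 89-column
design matrix with unpruned random-forest regression. Accuracy is
assessed over 100 unit-stratified bootstrap splits: per split, 25% of
each unit's seasons form the validation set (so with 16 seasons every
unit appears exactly four times in validation) and the calibration set
is a with-replacement bootstrap resample of the remaining pool.
Calibration-side metrics come from leave-one-out cross-validation over
the calibration rows; final metrics are the medians across splits.
Variable importance is %IncMSE — the percentage increase in out-of-bag
MSE after permuting one predictor — reported as the median across
splits. A per unit × season table of median percent prediction errors
closes the report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils import check_random_state

from .evaluation import MetricSet, metrics

__all__ = ["SplitPlan", "PredictionReport", "RFConfig", "encode_predictors",
           "make_splits", "train_rf", "evaluate_split", "oob_importance",
           "importance", "error_table", "run_prediction"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    """One stratified bootstrap split over the row positions of the table."""

    split_id: int
    calibration: np.ndarray   # positional row ids, with-replacement resample
    validation: np.ndarray    # positional row ids, without replacement


@dataclass
class RFConfig:
    """Random-forest hyperparameters (regression defaults, unpruned trees)."""

    n_trees: int = 500
    mtry_fraction: float = 1.0 / 3.0   # mtry = floor(p/3)
    min_node_size: int = 5
    loocv: bool = True                 # LOOCV calibration metrics
    tune_mtry: bool = False            # optionally select mtry by LOOCV
    mtry_grid: tuple = (0.2, 1.0 / 3.0, 0.5)


@dataclass
class PredictionReport:
    per_split_validation: pd.DataFrame      # one metric row per split
    per_split_calibration: pd.DataFrame     # LOOCV metrics per split (may be empty)
    median_validation: dict
    median_calibration: dict
    importance: pd.DataFrame                # predictor, median_pct_inc_mse, rank
    errors: pd.DataFrame                    # per unit x season percent error
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# encoding and splits
# ---------------------------------------------------------------------------

def encode_predictors(table: pd.DataFrame):
    """Split the feature table into integer-coded X and response y.

    Categorical columns (the three variety slots and the on/off label)
    are integer-coded against a vocabulary built from the whole table;
    the predictor count stays at the documented 89. Returns
    (X: DataFrame float, y: Series).
    """
    from .feature_builder import predictor_columns

    cols = predictor_columns()
    missing = [c for c in cols + ["yield_obs_t_ha"] if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    assert len(cols) == 89
    X = table[cols].copy()
    for col in ("variety_1", "variety_2", "variety_3", "onoff_label"):
        vocab = sorted(str(v) for v in X[col].dropna().unique())
        code = {v: i for i, v in enumerate(vocab)}
        X[col] = X[col].map(lambda v: code.get(str(v), -1)).astype(float)
    X = X.astype(float)
    y = table["yield_obs_t_ha"].astype(float)
    return X, y


def make_splits(table: pd.DataFrame, n_splits: int = 100,
                seed: int = 0) -> list:
    """Unit-stratified bootstrap splits.

    Per split and per unit, 25% of that unit's seasons (4 of 16; floor,
    with a warning for units holding fewer than 4 seasons) are drawn
    without replacement into validation. The calibration set is a
    with-replacement bootstrap resample, of equal size, of the pooled
    remaining rows. Deterministic given (table, n_splits, seed).
    """
    if "unit_id" not in table.index.names:
        raise ValueError("table index must carry a unit_id level")
    rng = np.random.default_rng(seed)
    units = table.index.get_level_values("unit_id")
    unit_rows = {u: np.flatnonzero(units == u) for u in units.unique()}
    for u, rows in unit_rows.items():
        if len(rows) < 4:
            warnings.warn(f"unit {u} has only {len(rows)} seasons; "
                          "validation share is floor(25%)")
    plans = []
    for s in range(n_splits):
        val, pool = [], []
        for u in sorted(unit_rows):
            rows = unit_rows[u]
            n_val = max(1, len(rows) // 4)
            chosen = rng.choice(rows, size=n_val, replace=False)
            val.append(chosen)
            pool.append(np.setdiff1d(rows, chosen))
        val = np.sort(np.concatenate(val))
        pool = np.concatenate(pool)
        cal = np.sort(rng.choice(pool, size=len(pool), replace=True))
        plans.append(SplitPlan(split_id=s + 1, calibration=cal,
                               validation=val))
    return plans


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def _impute_train_medians(X_tr: pd.DataFrame, *others):
    """Median-impute NaNs using training-fold medians only (no leakage)."""
    med = X_tr.median(numeric_only=True)
    med = med.fillna(0.0)  # all-NaN column in the fold
    out = [X_tr.fillna(med)]
    out.extend(o.fillna(med) for o in others)
    return out if len(out) > 1 else out[0]


def _mtry(p: int, fraction: float) -> int:
    return max(1, int(p * fraction))


def _fit_forest(X, y, config: RFConfig, seed: int,
                mtry_fraction: float | None = None) -> RandomForestRegressor:
    frac = config.mtry_fraction if mtry_fraction is None else mtry_fraction
    rf = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=_mtry(X.shape[1], frac),
        min_samples_leaf=config.min_node_size,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return rf


def _loocv_predictions(X, y, config: RFConfig, seed: int,
                       mtry_fraction: float | None = None) -> np.ndarray:
    """Leave-one-out predictions over the calibration rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        rf = _fit_forest(X[mask], y[mask], config, seed, mtry_fraction)
        preds[i] = rf.predict(X[i:i + 1])[0]
        mask[i] = True
    return preds


def train_rf(X_cal: pd.DataFrame, y_cal: pd.Series, config: RFConfig,
             seed: int = 0):
    """Fit the unpruned regression forest on the calibration rows.

    Returns (model, loocv_predictions or None, chosen mtry fraction).
    With ``config.tune_mtry`` the mtry grid is scored by LOOCV MSE;
    otherwise LOOCV only produces the calibration-side metrics.
    """
    if len(y_cal) < 2:
        raise ValueError("need at least 2 calibration rows")
    if float(np.std(y_cal)) == 0.0:
        warnings.warn("constant response in calibration set")
    frac = config.mtry_fraction
    loocv_pred = None
    if config.tune_mtry:
        best_mse = np.inf
        for cand in config.mtry_grid:
            pred = _loocv_predictions(X_cal, y_cal, config, seed, cand)
            mse = float(np.mean((pred - np.asarray(y_cal)) ** 2))
            if mse < best_mse:
                best_mse, frac, loocv_pred = mse, cand, pred
    elif config.loocv:
        loocv_pred = _loocv_predictions(X_cal, y_cal, config, seed, frac)
    model = _fit_forest(X_cal, y_cal, config, seed, frac)
    return model, loocv_pred, frac


def evaluate_split(model, X_val: pd.DataFrame, y_val: pd.Series):
    """Five-metric evaluation of a fitted model on the validation rows.

    Returns (MetricSet, DataFrame of (obs, pred) pairs indexed like y_val).
    """
    if len(y_val) == 0:
        raise ValueError("empty validation set")
    pred = model.predict(np.asarray(X_val, dtype=float))
    m = metrics(np.asarray(y_val, dtype=float), pred)
    pairs = pd.DataFrame({"obs": np.asarray(y_val, dtype=float),
                          "pred": pred}, index=y_val.index)
    return m, pairs


# ---------------------------------------------------------------------------
# %IncMSE permutation importance on out-of-bag samples
# ---------------------------------------------------------------------------

def oob_importance(model: RandomForestRegressor, X: pd.DataFrame,
                   y: pd.Series, seed: int = 0) -> pd.Series:
    """%IncMSE per predictor from out-of-bag permutation.

    For every sample, the OOB prediction averages the trees whose
    bootstrap draw excluded it. Permuting one predictor column (same
    permutation for all trees) and recomputing the OOB MSE measures how
    much the forest relied on it:
    %IncMSE = 100 · (MSE_oob_permuted − MSE_oob) / MSE_oob.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    # per-tree OOB membership: replay each tree's bootstrap draw, which
    # sklearn generates as randint(0, n) from the tree's random_state
    oob_masks = []
    for est in model.estimators_:
        rs = check_random_state(est.random_state)
        drawn = rs.randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[drawn] = False
        oob_masks.append(mask)

    # stack the unpermuted matrix and one column-permuted copy per
    # predictor, so each tree predicts once over all p+1 variants
    rng = np.random.default_rng(seed)
    p = Xa.shape[1]
    blocks = [Xa]
    for j in range(p):
        perm = rng.permutation(n)
        Xp = Xa.copy()
        Xp[:, j] = Xa[perm, j]
        blocks.append(Xp)
    Xstack = np.vstack(blocks)
    s = np.zeros((p + 1, n))
    c = np.zeros(n)
    for est, mask in zip(model.estimators_, oob_masks):
        if mask.any():
            pred = est.predict(Xstack).reshape(p + 1, n)
            s[:, mask] += pred[:, mask]
            c[mask] += 1
    ok = c > 0
    mse = np.mean((s[:, ok] / c[ok] - ya[ok]) ** 2, axis=1)
    base = mse[0]
    vals = np.zeros(p) if base == 0.0 else 100.0 * (mse[1:] - base) / base
    return pd.Series(vals, index=X.columns, name="pct_inc_mse")


def importance(per_split_importance: list) -> pd.DataFrame:
    """Median %IncMSE across splits, ranked descending."""
    mat = pd.concat(per_split_importance, axis=1)
    med = mat.median(axis=1).sort_values(ascending=False)
    return pd.DataFrame({
        "predictor": med.index,
        "median_pct_inc_mse": med.to_numpy(),
        "rank": np.arange(1, len(med) + 1),
    }).reset_index(drop=True)


def error_table(all_pairs: pd.DataFrame) -> pd.DataFrame:
    """Per unit × season median percent prediction error.

    percent error = 100·(pred − obs)/obs (positive = overestimation),
    median across the splits in which the row fell in validation. Rows
    with obs = 0 are flagged undefined. The returned frame carries
    attrs['share_within_10'] and attrs['share_within_20']: the share of
    cells with |error| within 10% and 20%.
    """
    if all_pairs.empty:
        raise ValueError("no validation pairs")
    rows = []
    for key, grp in all_pairs.groupby(level=["unit_id", "season"]):
        obs = grp["obs"].iloc[0]
        if obs == 0:
            rows.append({"unit_id": key[0], "season": key[1], "obs": obs,
                         "pred": float(grp["pred"].median()),
                         "pct_error": np.nan, "undefined": True,
                         "n_splits": len(grp)})
            continue
        pct = 100.0 * (grp["pred"] - grp["obs"]) / grp["obs"]
        rows.append({"unit_id": key[0], "season": key[1], "obs": float(obs),
                     "pred": float(grp["pred"].median()),
                     "pct_error": float(pct.median()), "undefined": False,
                     "n_splits": len(grp)})
    tab = pd.DataFrame(rows)
    ok = tab.loc[~tab["undefined"], "pct_error"].abs()
    tab.attrs["share_within_10"] = float((ok <= 10).mean()) if len(ok) else np.nan
    tab.attrs["share_within_20"] = float((ok <= 20).mean()) if len(ok) else np.nan
    return tab


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

_METRIC_KEYS = ["mae", "rrmse", "r2", "ef", "crm"]


def _metric_row(m: MetricSet, split_id: int) -> dict:
    d = {"split_id": split_id}
    d.update({k: getattr(m, k) for k in _METRIC_KEYS})
    return d


def run_prediction(table: pd.DataFrame, n_splits: int = 100, seed: int = 0,
                   config: RFConfig | None = None,
                   compute_importance: bool = True) -> PredictionReport:
    """The full resampling study over a feature table.

    Fully deterministic given (table, n_splits, seed, config).
    """
    config = config or RFConfig()
    X, y = encode_predictors(table)
    plans = make_splits(table, n_splits=n_splits, seed=seed)
    val_rows, cal_rows, imp_cols, pair_frames = [], [], [], []
    for plan in plans:
        split_seed = seed + plan.split_id
        X_cal, y_cal = X.iloc[plan.calibration], y.iloc[plan.calibration]
        X_val, y_val = X.iloc[plan.validation], y.iloc[plan.validation]
        X_cal, X_val = _impute_train_medians(X_cal, X_val)
        model, loocv_pred, _ = train_rf(X_cal, y_cal, config, seed=split_seed)
        m_val, pairs = evaluate_split(model, X_val, y_val)
        val_rows.append(_metric_row(m_val, plan.split_id))
        pairs["split_id"] = plan.split_id
        pair_frames.append(pairs)
        if loocv_pred is not None:
            m_cal = metrics(np.asarray(y_cal, dtype=float), loocv_pred)
            cal_rows.append(_metric_row(m_cal, plan.split_id))
        if compute_importance:
            imp_cols.append(oob_importance(model, X_cal, y_cal,
                                           seed=split_seed))
        logger.info("split %d/%d done", plan.split_id, n_splits)
    per_val = pd.DataFrame(val_rows).set_index("split_id")
    per_cal = (pd.DataFrame(cal_rows).set_index("split_id")
               if cal_rows else pd.DataFrame(columns=_METRIC_KEYS))
    all_pairs = pd.concat(pair_frames)
    imp = (importance(imp_cols) if imp_cols
           else pd.DataFrame(columns=["predictor", "median_pct_inc_mse",
                                      "rank"]))
    return PredictionReport(
        per_split_validation=per_val,
        per_split_calibration=per_cal,
        median_validation={k: float(per_val[k].median()) for k in _METRIC_KEYS},
        median_calibration={k: float(per_cal[k].median()) for k in _METRIC_KEYS}
        if len(per_cal) else {},
        importance=imp,
        errors=error_table(all_pairs),
        pairs=all_pairs,
    )
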