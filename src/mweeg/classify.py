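"""Per-subject RBF-SVM classification of mind-wandering from 25 EEG markers.

The feature vector for each labeled trial concatenates 5 single-trial ERP
amplitudes (P1 and N1 at A10/B7, P3 at A19), 8 band powers (alpha and theta
at the four sites) and 12 intersite phase-clustering values (alpha and theta
over the six site pairs), all from the after-stimulus-onset period. Features
are z-transformed, the training sample is balanced by random oversampling of
the minority class, and an RBF-kernel SVM with grid-searched (C, gamma) is
validated by leave-one-out cross-validation within a task, by across-task
transfer, and marker-by-marker on the pooled two-task data.

Mind-wandering is the positive class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import CHANNELS
from .evaluate import confusion_metrics
from .spectral import SITE_PAIRS
from .synth import MIND_WANDERING, ON_TASK

__all__ = ["FEATURE_COLUMNS", "ERP_COLUMNS", "POWER_COLUMNS", "ISPC_COLUMNS",
           "ModelSpec", "assemble_features", "zscore", "oversample",
           "grid_search", "loocv", "cross_task_predict", "single_marker_models"]

ERP_COLUMNS = ("st_P1_A10", "st_P1_B7", "st_N1_A10", "st_N1_B7", "st_P3_A19")
POWER_COLUMNS = tuple(f"pow_{band}_{ch}" for band in ("alpha", "theta")
                      for ch in CHANNELS)
ISPC_COLUMNS = tuple(f"ispc_{band}_{a}-{b}" for band in ("alpha", "theta")
                     for a, b in SITE_PAIRS)

#: the 25 classifier markers, in fixed documented order
FEATURE_COLUMNS = ERP_COLUMNS + POWER_COLUMNS + ISPC_COLUMNS

_DEF_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))
_DEF_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))


@dataclass(frozen=True)
class ModelSpec:
    """RBF-SVM hyperparameter search specification."""

    C_grid: tuple[float, ...] = _DEF_C_GRID
    gamma_grid: tuple[float, ...] = _DEF_GAMMA_GRID
    inner_folds: int = 5
    seed: int = 0
    #: "per_subject": one grid search on the full table, then LOOCV with the
    #: chosen point; "nested": a fresh grid search inside every LOOCV fold.
    grid_mode: str = "per_subject"

    def __post_init__(self):
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("empty grid")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")
        if self.grid_mode not in ("per_subject", "nested"):
            raise ValueError("grid_mode must be 'per_subject' or 'nested'")


def assemble_features(erp: pd.DataFrame, spectral: pd.DataFrame,
                      labels: pd.DataFrame, period: str = "ASO",
                      include_ispc: bool = True) -> pd.DataFrame:
    """Join ERP and spectral features into the per-trial marker table.

    Parameters
    ----------
    erp : long frame from :func:`mweeg.sterp.extract_erp_features`
    spectral : long frame from :func:`mweeg.spectral.extract_spectral_features`
    labels : frame with ``trial_id`` and ``state`` (labeled trials only)
    period : which spectral period feeds the classifier (default ASO)
    include_ispc : drop the 12 ISPC columns when False (13-marker table)

    Returns a frame with one row per labeled trial: ``trial_id``, ``state``,
    and the marker columns in :data:`FEATURE_COLUMNS` order. A labeled trial
    missing any feature raises.
    """
    erp_w = erp.pivot_table(index="trial_id", columns=["component", "channel"],
                            values="W", aggfunc="first")
    erp_w.columns = [f"st_{c}_{ch}" for c, ch in erp_w.columns]
    spec_p = spectral[spectral["period"] == period]
    spec_w = spec_p.pivot_table(index="trial_id", columns=["kind", "band", "site_or_pair"],
                                values="value", aggfunc="first")
    spec_w.columns = [("pow_" if k == "power" else "ispc_") + f"{b}_{s}"
                      for k, b, s in spec_w.columns]
    table = labels[["trial_id", "state"]].merge(
        erp_w, on="trial_id", how="left").merge(spec_w, on="trial_id", how="left")
    cols = list(FEATURE_COLUMNS if include_ispc
                else ERP_COLUMNS + POWER_COLUMNS)
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"features absent from inputs: {missing_cols}")
    out = table[["trial_id", "state"] + cols]
    if out[cols].isna().any().any():
        bad = out.loc[out[cols].isna().any(axis=1), "trial_id"].tolist()
        raise ValueError(f"labeled trials missing features: {bad[:10]}")
    return out


def zscore(table: pd.DataFrame, scope: str = "global") -> pd.DataFrame:
    """Standardize marker columns to zero mean and unit sd.

    ``scope="global"`` transforms using the whole table's statistics (the
    per-subject-and-task normalization the classifier defaults to);
    ``scope="train_fold_only"`` is handled inside the cross-validation loops
    (this function then returns the table untouched) so test rows are scaled
    with training statistics only. Zero-variance marker columns are dropped
    with a warning.
    """
    if scope == "train_fold_only":
        return table.copy()
    if scope != "global":
        raise ValueError("scope must be 'global' or 'train_fold_only'")
    out = table.copy()
    for col in _marker_cols(table):
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"dropping zero-variance marker column {col!r}")
            out = out.drop(columns=[col])
            continue
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def _marker_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith(("st_", "pow_", "ispc_"))]


def oversample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Balance classes by duplicating minority rows (with replacement).

    Majority rows are untouched; minority rows are resampled until the class
    counts are equal. Raises on single-class input.
    """
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("oversample requires both classes in the input")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    need = int(np.abs(counts[0] - counts[1]))
    pool = np.nonzero(y == minority)[0]
    extra = rng.choice(pool, size=need, replace=True)
    idx = np.concatenate([np.arange(y.size), extra])
    return X[idx], y[idx]


def _fit_svc(X, y, C, gamma):
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(X, y)
    return clf


def _train_scale(Xtr, Xte):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (Xtr - mu) / sd, (Xte - mu) / sd


def grid_search(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                rng: np.random.Generator | None = None,
                fold_scale: bool = False) -> tuple[float, float, float]:
    """Pick (C, gamma) maximizing stratified inner-CV accuracy on the grid.

    Oversampling is applied inside each inner training split. Ties are broken
    toward smaller C, then smaller gamma. Returns ``(C, gamma, accuracy)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("grid search needs >= 2 rows per class")
    n_folds = int(min(spec.inner_folds, counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    folds = list(skf.split(X, y))
    prepared = []
    for tr, te in folds:
        Xtr, ytr = oversample(X[tr], y[tr], rng)
        Xte = X[te]
        if fold_scale:
            Xtr, Xte = _train_scale(Xtr, Xte)
        prepared.append((Xtr, ytr, Xte, y[te]))
    best = (-1.0, None, None)
    for C in sorted(spec.C_grid):
        for gamma in sorted(spec.gamma_grid):
            hits = total = 0
            for Xtr, ytr, Xte, yte in prepared:
                clf = _fit_svc(Xtr, ytr, C, gamma)
                hits += int((clf.predict(Xte) == yte).sum())
                total += yte.size
            acc = hits / total
            if acc > best[0]:  # strict: first (smallest C, gamma) wins ties
                best = (acc, C, gamma)
    return best[1], best[2], best[0]


def _metrics_row(y_true, y_pred) -> dict:
    acc, sens, spec_ = confusion_metrics(y_true, y_pred)
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec_,
            "n": int(len(y_true)),
            "n_mw": int(np.sum(np.asarray(y_true) == MIND_WANDERING)),
            "n_ot": int(np.sum(np.asarray(y_true) == ON_TASK))}


def loocv(table: pd.DataFrame, spec: ModelSpec | None = None,
          scope: str = "global") -> tuple[pd.DataFrame, dict]:
    """Leave-one-out cross-validation of the per-subject SVM.

    Each trial is predicted by a model trained on all the others, with the
    minority class oversampled inside the training fold. Returns
    ``(predictions, metrics)``: a frame with ``trial_id, true, predicted`` and
    a dict with accuracy / sensitivity / specificity and the chosen
    hyperparameters.
    """
    spec = spec or ModelSpec()
    rng = np.random.default_rng(spec.seed)
    table = zscore(table, scope)
    cols = _marker_cols(table)
    X = table[cols].to_numpy(float)
    y = table["state"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("LOOCV needs both classes")
    fold_scale = scope == "train_fold_only"
    if spec.grid_mode == "per_subject":
        C, gamma, _ = grid_search(X, y, spec, rng, fold_scale=fold_scale)
    preds = np.empty(y.size, dtype=object)
    for i in range(y.size):
        keep = np.arange(y.size) != i
        Xtr, ytr = oversample(X[keep], y[keep], rng)
        Xte = X[i:i + 1]
        if fold_scale:
            Xtr, Xte = _train_scale(Xtr, Xte)
        if spec.grid_mode == "nested":
            C, gamma, _ = grid_search(X[keep], y[keep], spec, rng,
                                      fold_scale=fold_scale)
        preds[i] = _fit_svc(Xtr, ytr, C, gamma).predict(Xte)[0]
    predictions = pd.DataFrame({"trial_id": table["trial_id"], "true": y,
                                "predicted": preds, "scheme": "loocv"})
    metrics = _metrics_row(y, preds)
    metrics.update({"C": C, "gamma": gamma, "scheme": "loocv"})
    return predictions, metrics


def cross_task_predict(train_table: pd.DataFrame, test_table: pd.DataFrame,
                       spec: ModelSpec | None = None,
                       scope: str = "global") -> tuple[pd.DataFrame, dict]:
    """Train on all of one task, evaluate on all of the other.

    Both tables are normalized within themselves (the per-task z-transform),
    the model is fit once on the oversampled training task and applied to
    every trial of the test task.
    """
    spec = spec or ModelSpec()
    rng = np.random.default_rng(spec.seed)
    cols_tr = _marker_cols(train_table)
    if set(cols_tr) != set(_marker_cols(test_table)):
        raise ValueError("train/test marker columns differ")
    train_table = zscore(train_table, scope)
    test_table = zscore(test_table, scope)
    cols = [c for c in cols_tr if c in train_table.columns and c in test_table.columns]
    Xtr = train_table[cols].to_numpy(float)
    ytr = train_table["state"].to_numpy()
    Xte = test_table[cols].to_numpy(float)
    yte = test_table["state"].to_numpy()
    C, gamma, _ = grid_search(Xtr, ytr, spec, rng,
                              fold_scale=scope == "train_fold_only")
    Xtr_b, ytr_b = oversample(Xtr, ytr, rng)
    if scope == "train_fold_only":
        Xtr_b, Xte = _train_scale(Xtr_b, Xte)
    preds = _fit_svc(Xtr_b, ytr_b, C, gamma).predict(Xte)
    predictions = pd.DataFrame({"trial_id": test_table["trial_id"], "true": yte,
                                "predicted": preds, "scheme": "cross_task"})
    metrics = _metrics_row(yte, preds)
    metrics.update({"C": C, "gamma": gamma, "scheme": "cross_task"})
    return predictions, metrics


def single_marker_models(pooled: pd.DataFrame, spec: ModelSpec | None = None,
                         scope: str = "global") -> pd.DataFrame:
    """LOOCV one model per marker, plus the full model, on pooled-task data.

    ``pooled`` should contain the already-normalized per-task tables stacked
    together (normalize per task before pooling). Returns one metric row per
    marker and a final ``full_model`` row.
    """
    spec = spec or ModelSpec()
    rows = []
    for col in _marker_cols(pooled):
        sub = pooled[["trial_id", "state", col]]
        _, m = loocv(sub, spec, scope="train_fold_only" if scope == "train_fold_only"
                     else "global")
        m["marker"] = col
        rows.append(m)
    _, m = loocv(pooled, spec, scope)
    m["marker"] = "full_model"
    rows.append(m)
    return pd.DataFrame(rows)
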