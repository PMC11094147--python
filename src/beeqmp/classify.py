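"""Seeded supervised classification of hive winter survival.

Protocol: repeated stratified 80/20 train/test splits (one per seed);
hyperparameters chosen by cross-validated grid search on the training
portion only; feature standardization fit on training folds only (no
test-set leakage); performance summarized as the median test AUROC over
seeds.  Feature importance is read off either the logistic coefficients or
the AUROC drop when a feature is omitted.

Bees from one hive share a label, so a hive-grouped split mode is provided
alongside the default per-sample splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    GridSearchCV,
    GroupShuffleSplit,
    StratifiedKFold,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .datamodel import CountMatrix, SampleTable

__all__ = [
    "build_features",
    "run_models",
    "feature_importance",
    "summarize_auroc",
    "auroc",
    "MLRunResult",
    "MLSummary",
    "LOGISTIC_C_GRID",
    "RF_MAX_FEATURES_GRID",
]

LOGISTIC_C_GRID = tuple(10.0 ** np.arange(-3, 4))  # 1e-3 ... 1e3
RF_MAX_FEATURES_GRID = ("sqrt", 0.333, 1.0)
RF_N_ESTIMATORS = 500


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def build_features(
    genus_abund: CountMatrix,
    samples: SampleTable,
    include_location: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature table (genus abundances [+ one-hot locations]) and labels.

    Labels are 1 for bees from surviving hives.  Abundances are returned
    raw; standardization belongs to model fitting, where it is fit on
    training folds only.
    """
    ids = genus_abund.sample_ids
    meta = samples.data
    unknown = [s for s in ids if s not in meta.index or meta.loc[s, "role"] != "bee"]
    if unknown:
        raise ValueError(f"unlabeled (non-bee or unknown) sample(s): {unknown}")
    X = genus_abund.data.loc[ids].copy()
    if include_location:
        loc = pd.get_dummies(meta.loc[ids, "location"], prefix="location", dtype=float)
        X = pd.concat([X, loc], axis=1)
    y = (meta.loc[ids, "condition"] == "survived").astype(int).rename("survived")
    return X, y


@dataclass
class MLRunResult:
    seed: int
    model: str
    auroc: float
    best_params: dict
    coefficients: pd.Series | None = None

    def __post_init__(self):
        if not 0.0 <= self.auroc <= 1.0:
            raise ValueError("AUROC must lie in [0, 1]")


@dataclass
class MLSummary:
    mode: str
    median_auroc: dict
    coefficients: pd.DataFrame | None = None  # per-feature median (+spread)
    auroc_drop: pd.Series | None = None


def _make_search(model: str, rs: int, cv: int, standardize: bool) -> GridSearchCV:
    steps = [("scale", StandardScaler())] if standardize else []
    if model == "l2_logistic":
        # default penalty is ridge (L2); C grid below sets its strength
        steps.append(("clf", LogisticRegression(solver="lbfgs", max_iter=5000)))
        grid = {"clf__C": list(LOGISTIC_C_GRID)}
    elif model == "random_forest":
        steps.append(
            (
                "clf",
                RandomForestClassifier(
                    n_estimators=RF_N_ESTIMATORS, random_state=rs, n_jobs=1
                ),
            )
        )
        grid = {"clf__max_features": list(RF_MAX_FEATURES_GRID)}
    else:
        raise ValueError(f"unknown model {model!r}")
    return GridSearchCV(
        Pipeline(steps),
        grid,
        scoring="roc_auc",
        cv=StratifiedKFold(cv, shuffle=True, random_state=rs),
        n_jobs=1,
    )


def _split(X, y, groups, train_frac, rs):
    test_size = 1.0 - train_frac
    if groups is not None:
        for attempt in range(20):
            gss = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=rs + attempt)
            tr, te = next(gss.split(X, y, groups=groups))
            if y.iloc[tr].nunique() == 2 and y.iloc[te].nunique() == 2:
                if attempt:
                    warnings.warn("single-class grouped split resampled")
                return tr, te
        raise ValueError("could not produce a two-class grouped split")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_size, random_state=rs, stratify=y)
    return tr, te


def run_models(
    X: pd.DataFrame,
    y: pd.Series,
    n_seeds: int = 100,
    train_frac: float = 0.8,
    models: Sequence[str] = ("l2_logistic", "random_forest"),
    seed0: int = 0,
    cv: int = 5,
    standardize: bool = True,
    groups: pd.Series | None = None,
) -> list[MLRunResult]:
    """Repeated seeded train/test evaluation with in-split grid search.

    One stratified ``train_frac`` split per seed (or hive-grouped when
    ``groups`` is given); the hyperparameter grid is searched by ``cv``-fold
    cross-validation on the training portion; AUROC is measured on the
    held-out portion.
    """
    if y.nunique() < 2:
        raise ValueError("labels contain a single class")
    grp = groups.loc[X.index].to_numpy() if groups is not None else None
    results: list[MLRunResult] = []
    for s in range(int(n_seeds)):
        rs = int((seed0 + s) % (2**31 - 1))
        tr, te = _split(X, y, grp, train_frac, rs)
        X_tr, y_tr = X.iloc[tr], y.iloc[tr]
        X_te, y_te = X.iloc[te], y.iloc[te]
        for model in models:
            search = _make_search(model, rs, cv, standardize)
            search.fit(X_tr.to_numpy(), y_tr.to_numpy())
            scores = search.predict_proba(X_te.to_numpy())[:, 1]
            coef = None
            if model == "l2_logistic":
                clf = search.best_estimator_.named_steps["clf"]
                coef = pd.Series(clf.coef_[0], index=X.columns, name=f"seed{rs}")
            results.append(
                MLRunResult(
                    seed=rs,
                    model=model,
                    auroc=auroc(scores, y_te.to_numpy()),
                    best_params=dict(search.best_params_),
                    coefficients=coef,
                )
            )
    return results


def summarize_auroc(results: Sequence[MLRunResult]) -> dict:
    """Median test AUROC per model over seeds."""
    out: dict[str, float] = {}
    for model in sorted({r.model for r in results}):
        vals = [r.auroc for r in results if r.model == model]
        out[model] = float(np.median(vals))
    return out


def feature_importance(
    X: pd.DataFrame,
    y: pd.Series,
    results: Sequence[MLRunResult],
    mode: str = "coefficients",
    **run_kwargs,
) -> MLSummary:
    """Feature importance from a completed run.

    ``coefficients``: per-feature median (and IQR) of the logistic weights
    across seeds.  ``omission``: rerun the full protocol excluding one
    feature at a time and report the drop in median AUROC relative to the
    inclusive model (positive drop = feature helped).
    """
    if not results:
        raise ValueError("base run is empty")
    median_auroc = summarize_auroc(results)
    if mode == "coefficients":
        coefs = pd.DataFrame(
            [r.coefficients for r in results if r.coefficients is not None]
        )
        if coefs.empty:
            raise ValueError("coefficients mode requires l2_logistic results")
        table = pd.DataFrame(
            {
                "median": coefs.median(axis=0),
                "q25": coefs.quantile(0.25, axis=0),
                "q75": coefs.quantile(0.75, axis=0),
            }
        )
        return MLSummary(mode=mode, median_auroc=median_auroc, coefficients=table)
    if mode == "omission":
        if X.shape[1] < 2:
            raise ValueError("cannot omit features from a single-feature table")
        models = sorted({r.model for r in results})
        run_kwargs.setdefault("models", models)
        drops = {}
        base = summarize_auroc(results)
        for col in X.columns:
            sub = run_models(X.drop(columns=[col]), y, **run_kwargs)
            med = summarize_auroc(sub)
            drops[col] = float(np.mean([base[m] - med[m] for m in med]))
        return MLSummary(
            mode=mode, median_auroc=median_auroc, auroc_drop=pd.Series(drops)
        )
    raise ValueError(f"unknown mode {mode!r}")
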