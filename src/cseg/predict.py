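"""Supervised E/NE prediction with imbalance-aware validation.

Gene feature groups (bio/exp/orth/subloc/emb) are concatenated into one
design matrix, and a gradient-boosted decision-tree ensemble (LightGBM) is
validated under one of two schemes:

* ``stratified_cv`` — repeated stratified k-fold on the full, imbalanced
  label set;
* ``undersampled_cv`` — before each repeat the NE class is randomly
  undersampled to a 1:r E:NE ratio (all E genes kept), then stratified
  k-fold is run on the subsample.  This is the validation style used by
  DeepHE-like essential-gene predictors; the 1:4 ratio is the default.

Per-column standardisation is fitted inside each training fold only (an
sklearn Pipeline), so no statistics leak from held-out genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from cseg.io import FeatureTable, LabelTable

#: Default classifier contract: GBDT ensemble, 500 trees, learning rate 0.1,
#: class-balanced weights.  All entries can be overridden per call.
DEFAULT_MODEL_SPEC: dict = {
    "n_estimators": 500,
    "learning_rate": 0.1,
    "class_weight": "balanced",
    "n_jobs": 1,
    "verbose": -1,
}

METRIC_NAMES = ("roc_auc", "accuracy", "balanced_accuracy", "mcc", "sensitivity", "specificity")


@dataclass
class Dataset:
    """Aligned features + labels for a set of genes."""

    X: pd.DataFrame  # genes x features
    y: pd.Series  # "E"/"NE" aligned to X.index
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("features and labels are not aligned")
        if self.X.index.duplicated().any():
            raise ValueError("duplicate genes in dataset")

    @property
    def n_e(self) -> int:
        return int((self.y == "E").sum())

    @property
    def n_ne(self) -> int:
        return int((self.y == "NE").sum())


@dataclass
class ValidationConfig:
    scheme: str = "undersampled_cv"  # or "stratified_cv"
    folds: int = 5
    repeats: int = 10
    ratio: int = 4  # NE per E in undersampled_cv
    seed: int = 42

    def __post_init__(self) -> None:
        if self.scheme not in ("stratified_cv", "undersampled_cv"):
            raise ValueError(f"unknown validation scheme {self.scheme!r}")
        if self.folds < 2:
            raise ValueError("need k >= 2 folds")
        if self.ratio < 1:
            raise ValueError("undersample ratio must be 1:r with r >= 1")


@dataclass
class MetricsReport:
    """Mean and standard deviation of each metric over folds x repeats."""

    mean: pd.Series
    sd: pd.Series
    n_folds: int
    per_fold: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for name in ("accuracy", "balanced_accuracy", "sensitivity", "specificity", "roc_auc"):
            v = self.mean[name]
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} mean out of [0,1]: {v}")
        if not (-1.0 <= self.mean["mcc"] <= 1.0):
            raise ValueError(f"mcc mean out of [-1,1]: {self.mean['mcc']}")


# ---------------------------------------------------------------------------
# metric closed forms


def balanced_accuracy(tp: int, fp: int, fn: int, tn: int) -> float:
    """(sensitivity + specificity) / 2 from confusion-matrix counts."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("balanced accuracy needs both classes present")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 (with a warning) when any
    confusion-matrix marginal is empty."""
    marginals = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(m == 0 for m in marginals):
        warnings.warn("degenerate confusion matrix; MCC set to 0")
        return 0.0
    num = tp * tn - fp * fn
    den = math.sqrt(math.prod(marginals))
    return num / den


# ---------------------------------------------------------------------------
# dataset assembly


def assemble_features(
    tables: Sequence[FeatureTable],
    combination: Iterable[str],
    labels: LabelTable,
) -> Dataset:
    """Column-concatenate the requested feature groups and align to labels.

    The gene universe is the intersection of the labelled genes with every
    table contributing at least one requested column.  Values are kept raw;
    standardisation happens inside CV training folds.
    """
    wanted = list(combination)
    available = set()
    for t in tables:
        available |= set(t.groups.unique())
    unknown = set(wanted) - available
    if unknown:
        raise KeyError(f"requested feature group(s) not available: {sorted(unknown)}")

    blocks: list[pd.DataFrame] = []
    for t in tables:
        cols = t.columns_for(wanted)
        if cols:
            blocks.append(t.values[cols])
    genes = set(labels.labels.index)
    for b in blocks:
        genes &= set(b.index)
    if not genes:
        raise ValueError("no genes shared by the requested tables and the labels")
    order = [g for g in labels.labels.index if g in genes]
    X = pd.concat([b.loc[order] for b in blocks], axis=1)
    if X.columns.duplicated().any():
        raise ValueError("duplicate feature column names across tables")
    y = labels.labels.loc[order]
    tag = "+".join(wanted)
    return Dataset(X=X, y=y, tag=tag)


def undersample(d: Dataset, ratio_r: int = 4, seed: int = 42) -> Dataset:
    """Keep all E genes and a uniform sample of ratio_r * |E| NE genes."""
    e_genes = d.y.index[d.y == "E"]
    ne_genes = d.y.index[d.y == "NE"]
    want = ratio_r * len(e_genes)
    if len(ne_genes) < want:
        warnings.warn(
            f"only {len(ne_genes)} NE genes available for a 1:{ratio_r} "
            f"ratio ({want} wanted); keeping all"
        )
        chosen = ne_genes
    else:
        rng = np.random.default_rng(seed)
        chosen = ne_genes[rng.choice(len(ne_genes), size=want, replace=False)]
    keep = e_genes.append(pd.Index(chosen))
    keep = d.y.index[d.y.index.isin(keep)]  # preserve original gene order
    return Dataset(X=d.X.loc[keep], y=d.y.loc[keep], tag=d.tag)


# ---------------------------------------------------------------------------
# cross-validation


def _make_model(model_spec: dict | None, seed: int) -> Pipeline:
    params = dict(DEFAULT_MODEL_SPEC)
    if model_spec:
        params.update(model_spec)
    params["random_state"] = seed
    return Pipeline(
        [("scale", StandardScaler()), ("gbm", LGBMClassifier(**params))]
    )


def _fold_metrics(y_true: np.ndarray, prob_e: np.ndarray) -> dict:
    pred = prob_e >= 0.5
    tp = int((pred & y_true).sum())
    fp = int((pred & ~y_true).sum())
    fn = int((~pred & y_true).sum())
    tn = int((~pred & ~y_true).sum())
    n = tp + fp + fn + tn
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fold_mcc = mcc(tp, fp, fn, tn)
    return {
        "roc_auc": roc_auc_score(y_true, prob_e),
        "accuracy": (tp + tn) / n,
        "balanced_accuracy": balanced_accuracy(tp, fp, fn, tn),
        "mcc": fold_mcc,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }


def cross_validate(
    d: Dataset,
    cfg: ValidationConfig,
    model_spec: dict | None = None,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Repeated (optionally undersampled) stratified k-fold validation.

    Returns the aggregated metrics report and a per-gene table of mean
    out-of-fold E-probability, the number of out-of-fold evaluations, and
    the resulting label (E iff mean probability >= 0.5).  Under
    ``undersampled_cv`` the NE subsample is re-drawn for every repeat, so
    all E genes — and, over repeats, most NE genes — receive out-of-fold
    probabilities.
    """
    rows: list[dict] = []
    prob_sum = pd.Series(0.0, index=d.X.index)
    prob_cnt = pd.Series(0, index=d.X.index)

    for rep in range(cfg.repeats):
        rep_seed = cfg.seed + rep
        if cfg.scheme == "undersampled_cv":
            data = undersample(d, cfg.ratio, seed=rep_seed)
        else:
            data = d
        X_arr = data.X.to_numpy(dtype=float)
        y_bool = (data.y == "E").to_numpy()
        if y_bool.sum() == 0 or (~y_bool).sum() == 0:
            raise ValueError("both classes must be present")
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=rep_seed)
        for fold, (tr, te) in enumerate(skf.split(data.X, y_bool)):
            if len(np.unique(y_bool[te])) < 2:
                raise ValueError("single-class validation fold")
            model = _make_model(model_spec, seed=rep_seed * 100 + fold)
            with warnings.catch_warnings():
                # lightgbm's sklearn wrapper warns about its own auto feature
                # names when data flows through a scaler; harmless
                warnings.filterwarnings(
                    "ignore", message="X does not have valid feature names"
                )
                model.fit(X_arr[tr], y_bool[tr])
                prob = model.predict_proba(X_arr[te])[:, 1]
            rows.append(_fold_metrics(y_bool[te], prob))
            held = data.X.index[te]
            prob_sum.loc[held] += prob
            prob_cnt.loc[held] += 1

    per_fold = pd.DataFrame(rows)
    report = MetricsReport(
        mean=per_fold.mean(), sd=per_fold.std(ddof=1), n_folds=len(per_fold),
        per_fold=per_fold,
    )
    seen = prob_cnt > 0
    preds = pd.DataFrame(
        {
            "mean_prob_e": prob_sum[seen] / prob_cnt[seen],
            "n_oof": prob_cnt[seen],
        }
    )
    preds["label"] = np.where(preds["mean_prob_e"] >= 0.5, "E", "NE")
    preds.index.name = "gene"
    return report, preds
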