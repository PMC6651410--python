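"""Subject-wise cross-validation, accuracy metrics, and ANOVA contrasts.

Accuracy of each estimator is scored against the ground truth with the
Pearson correlation coefficient, the RMSE in degrees, and the relative RMSE
(rRMSE, % of the measured signal's range).  Splits are always by subject
identity (no individual contributes to both training and testing); with 24
subjects the learning/validation/test ratio 75/12.5/12.5 gives 18/3/3.
Because ten disjoint 3-subject test sets cannot partition 24 subjects, the
"10-fold" protocol is implemented as 10 repeated random subject-wise splits.
One-way ANOVA compares mean accuracy between estimators and between filter
cutoffs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldSplit:
    """One subject-wise train/validation/test split."""

    fold_id: int
    train_subjects: tuple
    val_subjects: tuple
    test_subjects: tuple
    seed: int = 0

    def __post_init__(self) -> None:
        tr, va, te = map(set, (self.train_subjects, self.val_subjects, self.test_subjects))
        if tr & va or tr & te or va & te:
            raise ValueError("train/val/test subject sets must be pairwise disjoint")
        if not (tr and va and te):
            raise ValueError("every partition must contain at least one subject")


@dataclass
class EvalMetrics:
    """Per-fold accuracy in one anatomical plane."""

    plane: str                  # "sagittal" | "frontal"
    r: float
    rmse: float                 # degrees
    rrmse: float                # percent of the measured range
    fold_id: int = 0
    model: str = ""
    cutoff: float = float("nan")

    def __post_init__(self) -> None:
        if not (np.isnan(self.r) or -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("r must lie in [-1, 1]")
        if self.rmse < 0 or (not np.isnan(self.rrmse) and self.rrmse < 0):
            raise ValueError("rmse and rrmse must be non-negative")


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA outcome."""

    F: float
    df_between: int
    df_within: int
    p: float

    def __post_init__(self) -> None:
        if self.F < 0 or not (0.0 <= self.p <= 1.0):
            raise ValueError("require F >= 0 and p in [0, 1]")
        if self.df_between < 1 or self.df_within < 1:
            raise ValueError("degrees of freedom must be positive")


def split_sizes(n_subjects: int) -> tuple[int, int, int]:
    """Train/val/test subject counts preserving the 75/12.5/12.5 ratio.

    24 -> (18, 3, 3).  For other counts the training share is rounded and the
    remainder split between validation and test, with test taking the larger
    half so held-out evaluation never starves.
    """
    if n_subjects < 8:
        raise ValueError(
            f"need at least 8 subjects to honour a 75/12.5/12.5 split, got {n_subjects}"
        )
    n_train = int(round(0.75 * n_subjects))
    rest = n_subjects - n_train
    n_val = rest // 2
    n_test = rest - n_val
    return n_train, n_val, n_test


def make_folds(subjects, n_folds: int = 10, seed: int = 0) -> list[FoldSplit]:
    """Seeded repeated random subject-wise splits (18/3/3 for 24 subjects)."""
    subjects = sorted(subjects)
    n_train, n_val, n_test = split_sizes(len(subjects))
    rng = np.random.default_rng(int(seed))
    folds = []
    for k in range(n_folds):
        perm = rng.permutation(len(subjects))
        ids = [subjects[i] for i in perm]
        folds.append(FoldSplit(
            fold_id=k,
            train_subjects=tuple(ids[:n_train]),
            val_subjects=tuple(ids[n_train:n_train + n_val]),
            test_subjects=tuple(ids[n_train + n_val:]),
            seed=int(seed),
        ))
    tested = set().union(*(f.test_subjects for f in folds))
    logger.info(
        "make_folds: %d folds over %d subjects; %d/%d subjects appear in a test set",
        n_folds, len(subjects), len(tested), len(subjects),
    )
    return folds


def metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    plane: str = "",
    rrmse_norm: str = "range",
    **tags,
) -> EvalMetrics:
    """Pearson r, RMSE (deg) and rRMSE (%) of a prediction against ground truth.

    rRMSE = 100 * RMSE / (max(y_true) - min(y_true)) by default; a
    mean-normalized variant is available with ``rrmse_norm='mean'``.  A
    constant ground-truth series has no defined correlation (reported NaN
    with a warning).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("series must have equal lengths >= 2")
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    if np.ptp(y_true) == 0:
        warnings.warn("constant ground truth: r and rRMSE undefined", stacklevel=2)
        r = float("nan")
        rrmse = float("nan")
    else:
        r = float(stats.pearsonr(y_true, y_pred).statistic) if np.ptp(y_pred) > 0 else float("nan")
        denom = np.ptp(y_true) if rrmse_norm == "range" else abs(np.mean(y_true))
        rrmse = float(100.0 * rmse / denom)
    return EvalMetrics(plane=plane, r=r, rmse=rmse, rrmse=rrmse, **tags)


def one_way_anova(groups: list) -> AnovaResult:
    """Classical one-way ANOVA across k groups of observations."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    res = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    f = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(f):  # all observations identical: no variance anywhere
        f, p = 0.0, 1.0
    return AnovaResult(F=max(f, 0.0), df_between=k - 1, df_within=n - k, p=p)


def summarize(results: list[EvalMetrics]) -> dict:
    """Aggregate fold metrics into the study's result tables.

    Returns a dict with:

    * ``long`` — one row per (fold, model, cutoff, plane) metric set;
    * ``table1`` — mean r and mean (SD) RMSE per plane x cutoff x model;
    * ``rrmse`` — mean (SD) rRMSE per plane x model and per plane x model x
      cutoff;
    * ``anova`` — model contrast (FFANN vs LSTM rRMSE, pooled over cutoffs)
      and cutoff contrast (per model), per plane.
    """
    if not results:
        raise ValueError("no results to summarize")
    long = pd.DataFrame([{
        "fold": m.fold_id, "model": m.model, "cutoff": m.cutoff, "plane": m.plane,
        "r": m.r, "rmse": m.rmse, "rrmse": m.rrmse,
    } for m in results])

    table1 = (
        long.groupby(["plane", "cutoff", "model"])
        .agg(r=("r", "mean"), rmse_mean=("rmse", "mean"), rmse_sd=("rmse", "std"))
        .reset_index()
    )
    rrmse_by_model = (
        long.groupby(["plane", "model"])
        .agg(rrmse_mean=("rrmse", "mean"), rrmse_sd=("rrmse", "std"))
        .reset_index()
    )
    rrmse_by_cutoff = (
        long.groupby(["plane", "model", "cutoff"])
        .agg(rrmse_mean=("rrmse", "mean"), rrmse_sd=("rrmse", "std"))
        .reset_index()
    )

    anova_rows = []
    for plane, sub in long.groupby("plane"):
        models = sorted(sub["model"].unique())
        if len(models) >= 2:
            groups = [sub.loc[sub["model"] == m, "rrmse"].dropna().to_numpy()
                      for m in models]
            if all(len(g) >= 2 for g in groups):
                a = one_way_anova(groups)
                anova_rows.append({
                    "plane": plane, "contrast": "model", "scope": "all",
                    "F": a.F, "df1": a.df_between, "df2": a.df_within, "p": a.p,
                })
        for m in models:
            subm = sub[sub["model"] == m]
            cuts = sorted(subm["cutoff"].unique())
            if len(cuts) >= 2:
                groups = [subm.loc[subm["cutoff"] == c, "rrmse"].dropna().to_numpy()
                          for c in cuts]
                if all(len(g) >= 2 for g in groups):
                    a = one_way_anova(groups)
                    anova_rows.append({
                        "plane": plane, "contrast": "cutoff", "scope": m,
                        "F": a.F, "df1": a.df_between, "df2": a.df_within, "p": a.p,
                    })
    return {
        "long": long,
        "table1": table1,
        "rrmse_by_model": rrmse_by_model,
        "rrmse_by_cutoff": rrmse_by_cutoff,
        "anova": pd.DataFrame(anova_rows),
    }
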