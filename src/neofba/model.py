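"""Functional brain age regression.

An ε-support-vector regression with a Gaussian kernel predicts
postmenstrual age (PMA, weeks) from the standardized qEEG features.
The hyperparameters follow a fixed recipe rather than a search:

* kernel scale σ = 10, i.e. K(x, x′) = exp(−‖x − x′‖² / σ²) on
  standardized features;
* box constraint C = IQR(training PMA) / 1.349 — the IQR of a normal
  divided by 1.349 is its SD, so C tracks the age spread of the cohort;
* ε = C / 10.

Evaluation uses leave-one-subject-out (LOSO) cross-validation: every
recording of one infant is held out per fold, so no subject's data can
leak between train and test.  Optional backward feature selection runs
*inside* each training fold (greedy single-removal, subject-grouped
4-fold CV, mean-squared FBA−PMA error as the cost).  The per-recording
FBA is the arithmetic mean of its epochs' predictions, and
PAD = FBA − PMA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .features import ID_COLUMNS
from .registry import feature_names

__all__ = ["FBAModel", "FBAResult", "fit_svr", "backward_select", "loso_cv", "apply_model"]

log = logging.getLogger(__name__)

KERNEL_SCALE = 10.0
SVR_TOL = 1e-6
SVR_MAX_ITER = 2_000_000


@dataclass
class FBAModel:
    """A fitted FBA regressor with its preprocessing state."""

    selected_features: list[str]
    center: np.ndarray
    scale: np.ndarray
    medians: np.ndarray
    svr: SVR
    C: float
    epsilon: float
    sigma: float = KERNEL_SCALE

    def _prepare(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.selected_features].to_numpy(dtype=float)
        for j in range(X.shape[1]):
            col = X[:, j]
            col[~np.isfinite(col)] = self.medians[j]
        return (X - self.center) / self.scale

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Per-epoch FBA (weeks) for rows of a feature table."""
        return self.svr.predict(self._prepare(table))


@dataclass
class FBAResult:
    """Per-epoch and per-recording predictions over a cohort."""

    epochs: pd.DataFrame      # subject_id, recording_id, start_s, pma_weeks, fba_weeks, fold
    recordings: pd.DataFrame  # subject_id, recording_id, pma_weeks, fba_weeks, pad_weeks, fold
    selected_features: dict = field(default_factory=dict)  # fold -> feature list

    @classmethod
    def from_epoch_predictions(cls, epochs: pd.DataFrame, selected=None) -> "FBAResult":
        recs = (
            epochs.groupby(["subject_id", "recording_id"], as_index=False)
            .agg(pma_weeks=("pma_weeks", "first"),
                 # np.mean on the raw array: the recording FBA must equal
                 # the arithmetic mean of its epoch FBAs bit-for-bit
                 fba_weeks=("fba_weeks", lambda s: float(np.mean(s.to_numpy()))),
                 fold=("fold", "first"))
        )
        recs["pad_weeks"] = recs["fba_weeks"] - recs["pma_weeks"]
        return cls(epochs=epochs, recordings=recs, selected_features=selected or {})


def _hyperparameters(pma: np.ndarray) -> tuple[float, float]:
    q75, q25 = np.percentile(pma, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("degenerate cohort: training PMA IQR is zero")
    C = iqr / 1.349
    return C, C / 10.0


def fit_svr(train: pd.DataFrame, features: list[str] | None = None) -> FBAModel:
    """Fit the Gaussian-kernel ε-SVR on a training feature table.

    Features are median-imputed then standardized with training means
    and SDs; zero-variance features are dropped with a warning.
    """
    if features is None:
        features = [c for c in feature_names() if c in train.columns]
    if not features:
        raise ValueError("no features to fit")
    if train["subject_id"].nunique() < 2:
        raise ValueError("need at least two training subjects")

    X = train[features].to_numpy(dtype=float)
    y = train["pma_weeks"].to_numpy(dtype=float)

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        medians = np.nanmedian(X, axis=0)
    medians = np.where(np.isfinite(medians), medians, 0.0)
    inds = np.where(~np.isfinite(X))
    X = X.copy()
    X[inds] = np.take(medians, inds[1])

    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(features, keep) if not k]
        log.info("dropping zero-variance features: %s", dropped)
        features = [f for f, k in zip(features, keep) if k]
        X, medians, sd = X[:, keep], medians[keep], sd[keep]
        if not features:
            raise ValueError("all features have zero variance")

    center = X.mean(axis=0)
    Xs = (X - center) / sd

    C, eps = _hyperparameters(y)
    svr = SVR(kernel="rbf", gamma=1.0 / KERNEL_SCALE**2, C=C, epsilon=eps,
              tol=SVR_TOL, max_iter=SVR_MAX_ITER)
    svr.fit(Xs, y)
    return FBAModel(selected_features=list(features), center=center, scale=sd,
                    medians=medians, svr=svr, C=C, epsilon=eps)


def _grouped_folds(subjects: np.ndarray, n_folds: int, seed: int) -> dict[str, int]:
    """Deterministic assignment of subjects to folds (balanced, seeded)."""
    uniq = np.array(sorted(set(subjects)))
    if len(uniq) < n_folds:
        raise ValueError(f"need >= {n_folds} subjects for {n_folds}-fold grouped CV, got {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    return {str(uniq[i]): int(k % n_folds) for k, i in enumerate(order)}


def _cv_mse(train: pd.DataFrame, features: list[str], fold_of: dict[str, int], n_folds: int) -> float:
    errs = []
    folds = np.array([fold_of[str(s)] for s in train["subject_id"]])
    for k in range(n_folds):
        tr, te = train[folds != k], train[folds == k]
        if len(te) == 0 or tr["subject_id"].nunique() < 2:
            continue
        try:
            model = fit_svr(tr, features)
        except ValueError:
            return np.inf
        pred = model.predict(te)
        errs.append((pred - te["pma_weeks"].to_numpy()) ** 2)
    if not errs:
        return np.inf
    return float(np.mean(np.concatenate(errs)))


def backward_select(train: pd.DataFrame, seed: int = 0, n_folds: int = 4,
                    features: list[str] | None = None) -> list[str]:
    """Greedy backward feature elimination under subject-grouped CV MSE.

    Each round tentatively removes every remaining feature, scores
    4-fold subject-grouped CV MSE of the FBA, and permanently removes
    the candidate whose removal gives the lowest MSE; stops at the first
    round where no removal strictly improves on the incumbent.  Ties
    break toward the lexicographically smaller feature name.
    """
    if features is None:
        features = [c for c in feature_names() if c in train.columns]
    if len(features) <= 1:
        return list(features)
    fold_of = _grouped_folds(train["subject_id"].to_numpy(), n_folds, seed)

    current = list(features)
    best_mse = _cv_mse(train, current, fold_of, n_folds)
    while len(current) > 1:
        candidates = []
        for f in sorted(current):
            trial = [g for g in current if g != f]
            candidates.append((_cv_mse(train, trial, fold_of, n_folds), f))
        mse, feat = min(candidates, key=lambda t: (t[0], t[1]))
        if mse < best_mse:
            best_mse = mse
            current = [g for g in current if g != feat]
        else:
            break
    return current


def loso_cv(cohort: pd.DataFrame, do_selection: bool = False, seed: int = 0,
            features: list[str] | None = None) -> FBAResult:
    """Leave-one-subject-out cross-validated FBA over a cohort table."""
    subjects = sorted(cohort["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    frames = []
    selected_by_fold: dict[int, list[str]] = {}
    for fold, subj in enumerate(subjects):
        train = cohort[cohort["subject_id"] != subj]
        test = cohort[cohort["subject_id"] == subj]
        if len(test) == 0:
            log.warning("subject %s has no kept epochs; excluded", subj)
            continue
        feats = features
        if do_selection:
            feats = backward_select(train, seed=seed, features=features)
        model = fit_svr(train, feats)
        selected_by_fold[fold] = model.selected_features
        out = test[ID_COLUMNS].copy()
        out["fba_weeks"] = model.predict(test)
        out["fold"] = fold
        frames.append(out)
    epochs = pd.concat(frames, ignore_index=True)
    return FBAResult.from_epoch_predictions(epochs, selected_by_fold)


def apply_model(model: FBAModel, external: pd.DataFrame,
                pma_range: tuple[float, float] | None = None) -> FBAResult:
    """Apply a fitted model to an external cohort, never refitting.

    All rows are predicted; when ``pma_range`` is given, recordings
    outside it are flagged ``in_range = False`` so evaluation can be
    restricted to the comparable PMA span while predictions remain
    available for every recording.  Epochs missing more than half of the
    selected features are skipped.
    """
    ext = external.copy()
    n_missing = ext[model.selected_features].isna().sum(axis=1)
    bad = n_missing > len(model.selected_features) / 2
    if bad.any():
        log.warning("skipping %d epochs with >50%% of selected features missing", int(bad.sum()))
        ext = ext[~bad]
    out = ext[ID_COLUMNS].copy()
    out["fba_weeks"] = model.predict(ext)
    out["fold"] = -1
    result = FBAResult.from_epoch_predictions(out)
    lo, hi = pma_range if pma_range is not None else (-np.inf, np.inf)
    result.recordings["in_range"] = result.recordings["pma_weeks"].between(lo, hi)
    return result
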