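"""Normative Gaussian-process brain-age models and bias-corrected BAGs.

Per-tract (bilateral pairs concatenated to 200 features, callosal tracts
100) and whole-brain (all tracts concatenated) GP regressors predict
chronological age from FA tract profiles. The brain-age gap (BAG) is
predicted minus chronological age; the well-known regression-dilution
age bias is removed by fitting BAG = alpha * age + beta in training data
and subtracting the fitted line everywhere. Model performance (Pearson R
and RMSE of uncorrected predictions) is evaluated by seeded, age-decile
stratified k-fold cross-validation and an age-permutation test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "assemble_features",
    "GaussianProcessBrainAge",
    "fit_gpr",
    "crossval_brain_age",
    "permutation_test_R",
    "fit_bias_correction",
    "apply_bias_correction",
    "bag_table",
    "ModelPerformance",
]


def assemble_features(profiles: pd.DataFrame, tracts=None) -> pd.DataFrame:
    """Assemble the feature matrix for one brain-age model.

    ``profiles`` carries a (tract, hemisphere, node) column MultiIndex.
    With ``tracts`` a single tract name, the bilateral pair is
    concatenated (left nodes 1..N then right nodes 1..N, 200 features for
    100-node tracts) or, for a midline/callosal tract, the single
    100-node profile is used. With ``tracts`` a list (or None = all
    tracts), all selected tracts are concatenated into a whole-brain
    assembly.
    """
    if not isinstance(profiles.columns, pd.MultiIndex):
        raise ValueError("profiles must have a (tract, hemisphere, node) MultiIndex")
    available = profiles.columns.get_level_values("tract").unique()
    if tracts is None:
        tracts = list(available)
    single = isinstance(tracts, str)
    names = [tracts] if single else list(tracts)
    blocks = []
    for name in names:
        if name not in available:
            raise KeyError(f"tract {name!r} not present in profiles")
        sub = profiles[name]
        hemis = list(sub.columns.get_level_values("hemisphere").unique())
        order = [h for h in ("L", "R", "M") if h in hemis]
        if set(hemis) - set(order):
            raise ValueError(f"unexpected hemisphere labels for {name!r}: {hemis}")
        for h in order:
            blk = sub[h].sort_index(axis=1)
            blk.columns = pd.Index(
                [f"{name}_{h}_{int(c):03d}" for c in blk.columns]
            )
            blocks.append(blk)
    return pd.concat(blocks, axis=1)


class GaussianProcessBrainAge(RegressorMixin, BaseEstimator):
    """GP regressor for chronological age from standardized FA features.

    Exact Gaussian-process regression with an (amplitude-scaled) RBF
    kernel plus a white-noise term; hyperparameters maximize the log
    marginal likelihood with ``n_restarts`` seeded restarts. Features are
    z-scored using training statistics only; predictions are posterior
    means.

    Attributes (after fit)
    ----------------------
    feature_mean_, feature_sd_ : training standardization
    gp_ : the fitted underlying GP
    kernel_params_ : dict with signal variance, length-scale and noise
        variance at the optimum
    """

    def __init__(
        self,
        n_restarts: int = 2,
        noise_floor: float = 1e-5,
        random_state: int | None = 0,
    ):
        self.n_restarts = n_restarts
        self.noise_floor = noise_floor
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite features or ages")
        if len(y) < 20:
            raise ValueError("need at least 20 training subjects")
        if np.std(y) == 0:
            raise ValueError("constant ages: nothing to learn")
        self.feature_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.feature_sd_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.feature_mean_) / self.feature_sd_

        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            length_scale=np.sqrt(X.shape[1]), length_scale_bounds=(1e-2, 1e5)
        ) + WhiteKernel(noise_level=0.1, noise_level_bounds=(self.noise_floor, 1e3))
        self.gp_ = GaussianProcessRegressor(
            kernel=kernel,
            alpha=0.0,
            normalize_y=True,
            n_restarts_optimizer=self.n_restarts,
            random_state=self.random_state,
        )
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # hyperparameters at a bound (e.g. noise floor on clean data)
            # are acceptable optima here
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.gp_.fit(Xs, y)
        k = self.gp_.kernel_
        self.kernel_params_ = {
            "signal_variance": float(k.k1.k1.constant_value),
            "length_scale": float(k.k1.k2.length_scale),
            "noise_variance": float(k.k2.noise_level),
        }
        self.train_X_ = Xs
        self.train_y_ = y
        return self

    def predict(self, X):
        check_is_fitted(self, "gp_")
        Xs = (np.asarray(X, dtype=float) - self.feature_mean_) / self.feature_sd_
        return self.gp_.predict(Xs)

    def posterior_mean_direct(self, X):
        """Posterior mean via direct linear algebra k*^T (K + sigma^2 I)^-1 y.

        Independent of the fitted GP's prediction path; used for
        cross-checking exactness of the GP solve.
        """
        check_is_fitted(self, "gp_")
        Xs = (np.asarray(X, dtype=float) - self.feature_mean_) / self.feature_sd_
        p = self.kernel_params_
        Xt, y = self.train_X_, self.train_y_
        ym, ys = y.mean(), y.std()
        ys = ys if ys > 0 else 1.0
        yn = (y - ym) / ys

        def rbf(A, B):
            d2 = (
                np.sum(A**2, axis=1)[:, None]
                + np.sum(B**2, axis=1)[None, :]
                - 2.0 * A @ B.T
            )
            return p["signal_variance"] * np.exp(-0.5 * d2 / p["length_scale"] ** 2)

        K = rbf(Xt, Xt) + p["noise_variance"] * np.eye(len(Xt))
        k_star = rbf(Xs, Xt)
        alpha = np.linalg.solve(K, yn)
        return ym + ys * (k_star @ alpha)


def fit_gpr(features, ages, **kwargs) -> GaussianProcessBrainAge:
    """Fit a GP age model (thin wrapper over :class:`GaussianProcessBrainAge`)."""
    return GaussianProcessBrainAge(**kwargs).fit(features, ages)


@dataclass
class ModelPerformance:
    """Cross-validated accuracy of one brain-age model (uncorrected predictions)."""

    R: float
    RMSE: float
    p_perm: float | None
    n_folds: int
    seed: int

    def to_dict(self):
        return {
            "R": self.R,
            "RMSE": self.RMSE,
            "p_perm": self.p_perm,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def _age_strata(ages: np.ndarray, n_bins: int = 10) -> np.ndarray:
    # decile bins; duplicate edges collapse for small/narrow samples
    qs = np.quantile(ages, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), ages)


def crossval_brain_age(
    features,
    ages,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 1,
    holdout: float | None = None,
):
    """Seeded age-decile-stratified k-fold CV of a GP brain-age model.

    Returns out-of-fold predictions (aligned with the input order) and a
    :class:`ModelPerformance` with Pearson R and RMSE computed on the
    concatenated out-of-fold predictions. With ``holdout`` set (e.g.
    0.2), that fraction is first split off; CV runs on the remainder and
    the returned dict also carries held-out predictions and performance.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(ages, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")

    out: dict = {"seed": seed, "k": k}
    if holdout is not None:
        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx, test_size=holdout, random_state=seed, stratify=_age_strata(y)
        )
        model = GaussianProcessBrainAge(n_restarts=n_restarts, random_state=seed).fit(
            X[tr], y[tr]
        )
        pred_te = model.predict(X[te])
        out["holdout_index"] = te
        out["holdout_pred"] = pred_te
        out["holdout_performance"] = ModelPerformance(
            R=float(pearsonr(y[te], pred_te)[0]),
            RMSE=float(np.sqrt(np.mean((pred_te - y[te]) ** 2))),
            p_perm=None,
            n_folds=1,
            seed=seed,
        )
        X, y, cv_index = X[tr], y[tr], tr
    else:
        cv_index = np.arange(len(y))

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    strata = _age_strata(y)
    preds = np.full(len(y), np.nan)
    folds = np.full(len(y), -1)
    for f, (tr_i, te_i) in enumerate(skf.split(X, strata)):
        if len(te_i) < 2:
            raise ValueError("fold with fewer than 2 subjects")
        model = GaussianProcessBrainAge(
            n_restarts=n_restarts, random_state=seed + f
        ).fit(X[tr_i], y[tr_i])
        preds[te_i] = model.predict(X[te_i])
        folds[te_i] = f
    perf = ModelPerformance(
        R=float(pearsonr(y, preds)[0]),
        RMSE=float(np.sqrt(np.mean((preds - y) ** 2))),
        p_perm=None,
        n_folds=k,
        seed=seed,
    )
    out.update(predictions=preds, folds=folds, performance=perf, ages=y,
               cv_index=np.asarray(cv_index))
    return out


def permutation_test_R(
    features,
    ages,
    n_perm: int = 1000,
    seed: int = 0,
    k: int = 5,
    n_restarts: int = 0,
    observed_R: float | None = None,
) -> float:
    """Age-permutation test of cross-validated prediction accuracy.

    Chronological ages are permuted across participants, the model
    re-established, and the null distribution of R collected; p = (count
    of permuted R >= observed R + 1) / (n_perm + 1). Benjamini-Hochberg
    correction across models is applied by the caller.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(ages, dtype=float)
    if observed_R is None:
        observed_R = crossval_brain_age(
            features, y, k=k, seed=seed, n_restarts=n_restarts
        )["performance"].R
    count = 0
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        r = crossval_brain_age(
            features, y_perm, k=k, seed=seed, n_restarts=n_restarts
        )["performance"].R
        if r >= observed_R:
            count += 1
    return (count + 1) / (n_perm + 1)


def crossval_bag_table(
    profiles: pd.DataFrame,
    ages,
    tract: str | None,
    subject_id=None,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 1,
) -> tuple[pd.DataFrame, ModelPerformance]:
    """Out-of-fold BAGs for one model, with per-fold age-bias correction.

    For each CV fold the GP and the bias line (alpha, beta) are estimated
    on the training subjects only and applied to the held-out fold, so
    every subject's corrected BAG is out-of-sample. ``tract=None`` builds
    the whole-brain assembly.
    """
    feats = assemble_features(profiles, tract)
    X = feats.to_numpy()
    y = np.asarray(ages, dtype=float)
    if subject_id is None:
        subject_id = np.asarray(profiles.index)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.full(len(y), np.nan)
    corrected = np.full(len(y), np.nan)
    for f, (tr_i, te_i) in enumerate(skf.split(X, _age_strata(y))):
        model = GaussianProcessBrainAge(
            n_restarts=n_restarts, random_state=seed + f
        ).fit(X[tr_i], y[tr_i])
        train_bag = model.predict(X[tr_i]) - y[tr_i]
        alpha, beta = fit_bias_correction(y[tr_i], train_bag)
        preds[te_i] = model.predict(X[te_i])
        corrected[te_i] = apply_bias_correction(
            alpha, beta, y[te_i], preds[te_i] - y[te_i]
        )
    perf = ModelPerformance(
        R=float(pearsonr(y, preds)[0]),
        RMSE=float(np.sqrt(np.mean((preds - y) ** 2))),
        p_perm=None,
        n_folds=k,
        seed=seed,
    )
    table = pd.DataFrame(
        {
            "subject_id": np.asarray(subject_id),
            "tract": tract if tract is not None else "whole-brain",
            "predicted_age": preds,
            "bag_raw": preds - y,
            "bag_corrected": corrected,
        }
    )
    return table, perf


def fit_bias_correction(train_ages, train_bags) -> tuple[float, float]:
    """OLS slope/intercept (alpha, beta) of BAG on chronological age (training set)."""
    age = np.asarray(train_ages, dtype=float)
    bag = np.asarray(train_bags, dtype=float)
    if len(age) < 3:
        raise ValueError("need at least 3 training subjects")
    if np.var(age) == 0:
        raise ValueError("degenerate age variance")
    alpha, beta = np.polyfit(age, bag, 1)
    return float(alpha), float(beta)


def apply_bias_correction(alpha, beta, age, bag_raw):
    """Corrected BAG = raw BAG - (alpha * age + beta)."""
    age = np.asarray(age, dtype=float)
    bag = np.asarray(bag_raw, dtype=float)
    if not (np.all(np.isfinite(age)) and np.all(np.isfinite(bag))
            and np.isfinite(alpha) and np.isfinite(beta)):
        raise ValueError("non-finite inputs")
    return bag - (alpha * age + beta)


def bag_table(
    subject_id, tract: str, predicted_age, chronological_age, alpha, beta
) -> pd.DataFrame:
    """Per-subject BAG table for one model: raw BAG = predicted - chronological."""
    pred = np.asarray(predicted_age, dtype=float)
    age = np.asarray(chronological_age, dtype=float)
    raw = pred - age
    return pd.DataFrame(
        {
            "subject_id": np.asarray(subject_id),
            "tract": tract,
            "predicted_age": pred,
            "bag_raw": raw,
            "bag_corrected": apply_bias_correction(alpha, beta, age, raw),
        }
    )


def save_model(model: GaussianProcessBrainAge, path_json, path_npz) -> None:
    """Persist hyperparameters/standardization as JSON plus training arrays."""
    with open(path_json, "w") as fh:
        json.dump(
            {
                "kernel_params": model.kernel_params_,
                "feature_mean": model.feature_mean_.tolist(),
                "feature_sd": model.feature_sd_.tolist(),
                "sidecar": str(path_npz),
            },
            fh,
        )
    np.savez(path_npz, train_X=model.train_X_, train_y=model.train_y_)
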