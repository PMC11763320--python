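"""Composite diagnostic INDEX: elastic-net logistic model over nine gene
methylation percentages plus one cf-DNA copy-number feature, benchmarked
against four comparator families over repeated stratified hold-out splits.

The INDEX is the fitted linear combination INDEX(x) = b0 + sum_j beta_j x_j;
predicted probability is the logistic transform of the INDEX and the status
call is case when probability exceeds the decision threshold (strictly).
Features are standardized with training-fold statistics only; the copy-number
feature is log10-transformed by default (its raw scale spans about three
decades).  The elastic net minimizes the mean logistic deviance plus
lambda * [alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2] with an unpenalized
intercept; hyperparameters are tuned by stratified k-fold cross-validated AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureTable",
    "SplitScheme",
    "BenchmarkResult",
    "IndexModel",
    "ElasticNetLogistic",
    "build_feature_table",
    "fit_elastic_net",
    "lambda_grid",
    "tune_hyperparameters",
    "repeated_holdout_benchmark",
    "average_roc",
    "finalize_index_model",
    "predict_index",
    "MODEL_FAMILIES",
]

COPY_FEATURE = "log10_copies"
POSITIVE_LABEL = "case"


# ---------------------------------------------------------------------------
# feature table


@dataclass
class FeatureTable:
    """Samples x features design with case/control labels.

    ``X`` is indexed by sample id with one ``meth_<gene>`` percent column per
    panel gene plus the copy-number feature; ``y`` is 1 for case.  Column
    order and applied transforms are recorded.  Standardization happens at
    fit time with training-fold statistics, never here.
    """

    X: pd.DataFrame
    y: np.ndarray
    feature_names: list[str]
    transforms: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.X.index)

    def subset(self, ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        loc = self.X.index.get_indexer(list(ids))
        return self.X.to_numpy(dtype=float)[loc], self.y[loc]


def build_feature_table(
    gene_percentages: pd.DataFrame,
    copies: pd.Series | Mapping[str, float],
    labels: pd.Series | Mapping[str, str],
    log_copies: bool = True,
    max_missing_frac: float = 1 / 3,
) -> FeatureTable:
    """Assemble gene methylation percentages and copy numbers into a design.

    ``gene_percentages`` is samples x genes (percent), ``copies`` per-sample
    copy numbers (> 0, log10-transformed by default), ``labels``
    "case"/"control" per sample.  Samples missing more than a third of their
    features are excluded with a warning; remaining missing values are left
    NaN and imputed at fit time with training-fold medians (recorded rule).
    """
    copies = pd.Series(dict(copies) if not isinstance(copies, pd.Series) else copies, dtype=float)
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    samples = [s for s in gene_percentages.index if s in labels.index]
    if len(samples) < len(gene_percentages):
        raise ValueError("every sample needs a label")
    if (copies[samples] <= 0).any():
        raise ValueError("every sample needs copies > 0")
    X = gene_percentages.loc[samples].copy()
    X.columns = [f"meth_{g}" for g in gene_percentages.columns]
    X[COPY_FEATURE] = np.log10(copies[samples]) if log_copies else copies[samples]

    frac_missing = X.isna().mean(axis=1)
    bad = frac_missing[frac_missing > max_missing_frac].index
    if len(bad):
        warnings.warn(f"excluding samples missing >1/3 of features: {list(bad)}", stacklevel=2)
        X = X.drop(index=bad)
    y = (labels[X.index] == POSITIVE_LABEL).to_numpy(dtype=int)
    return FeatureTable(
        X=X,
        y=y,
        feature_names=list(X.columns),
        transforms={
            COPY_FEATURE: "log10" if log_copies else "raw",
            "imputation": "train-fold median",
        },
    )


# ---------------------------------------------------------------------------
# elastic-net logistic regression


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


class ElasticNetLogistic:
    """Elastic-net penalized logistic regression with internal standardization.

    Minimizes mean logistic deviance + lam*[alpha_mix*||b||_1 +
    (1-alpha_mix)/2*||b||_2^2] over standardized slopes (intercept
    unpenalized).  Solved by FISTA proximal gradient with a per-iteration
    Newton update of the intercept; the smooth case (lam*alpha_mix == 0,
    i.e. ridge or unpenalized) uses L-BFGS.  ``lam=0`` is plain logistic
    regression.  Deterministic given data and hyperparameters.  Missing
    feature values are imputed with training medians.
    """

    def __init__(
        self,
        alpha_mix: float = 0.5,
        lam: float = 0.01,
        tol: float = 1e-7,
        max_iter: int = 20000,
    ):
        if not (0.0 <= alpha_mix <= 1.0):
            raise ValueError("alpha_mix must lie in [0, 1]")
        if lam < 0:
            raise ValueError("lam must be >= 0")
        self.alpha_mix = alpha_mix
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def _standardize(self, X: np.ndarray, fit: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if fit:
            self.medians_ = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), self.medians_, X)
        if fit:
            self.means_ = X.mean(axis=0)
            scales = X.std(axis=0)
            scales[scales == 0] = 1.0
            self.scales_ = scales
        return (X - self.means_) / self.scales_

    def _fit_smooth(self, Z: np.ndarray, y: np.ndarray, l2: float) -> np.ndarray:
        n = Z.shape[0]

        def obj_grad(w):
            b0, b = w[0], w[1:]
            eta = b0 + Z @ b
            val = float(np.mean(np.logaddexp(0.0, eta) - y * eta)) + 0.5 * l2 * b @ b
            r = (expit(eta) - y) / n
            return val, np.concatenate([[r.sum()], Z.T @ r + l2 * b])

        res = minimize(
            obj_grad,
            np.zeros(Z.shape[1] + 1),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": 1e-15, "gtol": self.tol},
        )
        return res.x

    def _fit_fista(self, Z: np.ndarray, y: np.ndarray) -> np.ndarray:
        n, p = Z.shape
        l1 = self.lam * self.alpha_mix
        l2 = self.lam * (1.0 - self.alpha_mix)
        # Lipschitz constant of the smooth slope gradient
        L = np.linalg.norm(Z, 2) ** 2 / (4.0 * n) + l2
        step = 1.0 / L
        b = np.zeros(p)
        v = b.copy()
        b0 = float(np.log(y.mean() / (1.0 - y.mean())))
        t = 1.0
        for _ in range(self.max_iter):
            pr = expit(b0 + Z @ v)
            grad = Z.T @ (pr - y) / n + l2 * v
            b_new = _soft_threshold(v - step * grad, step * l1)
            if np.dot(grad, b_new - b) > 0.0:  # adaptive restart
                t, v = 1.0, b.copy()
                pr = expit(b0 + Z @ v)
                grad = Z.T @ (pr - y) / n + l2 * v
                b_new = _soft_threshold(v - step * grad, step * l1)
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            v = b_new + ((t - 1.0) / t_new) * (b_new - b)
            # exact-curvature Newton step on the unpenalized intercept
            pr = expit(b0 + Z @ b_new)
            w_curv = max(float(np.mean(pr * (1.0 - pr))), 1e-10)
            b0_new = b0 - float(np.mean(pr - y)) / w_curv
            delta = max(np.max(np.abs(b_new - b)), abs(b0_new - b0))
            b, b0, t = b_new, b0_new, t_new
            if delta < self.tol:
                break
        return np.concatenate([[b0], b])

    def fit(self, X, y) -> "ElasticNetLogistic":
        y = np.asarray(y, dtype=float)
        if np.unique(y).size < 2:
            raise ValueError("training fold must contain both classes")
        Z = self._standardize(X, fit=True)
        if self.lam * self.alpha_mix == 0.0:
            w = self._fit_smooth(Z, y, l2=self.lam * (1.0 - self.alpha_mix))
        else:
            w = self._fit_fista(Z, y)
        self.intercept_ = float(w[0])
        self.coef_ = w[1:]
        return self

    @property
    def coef_raw_(self) -> np.ndarray:
        return self.coef_ / self.scales_

    @property
    def intercept_raw_(self) -> float:
        return self.intercept_ - float(np.sum(self.coef_ * self.means_ / self.scales_))

    def decision_function(self, X) -> np.ndarray:
        Z = self._standardize(X, fit=False)
        return Z @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > threshold).astype(int)


def fit_elastic_net(X, y, alpha_mix: float = 0.5, lam: float = 0.01) -> ElasticNetLogistic:
    """Fit an elastic-net logistic model; see :class:`ElasticNetLogistic`."""
    return ElasticNetLogistic(alpha_mix=alpha_mix, lam=lam).fit(X, y)


def lambda_grid(
    X, y, alpha_mix: float, n_lambda: int = 50, decades: float = 4.0
) -> np.ndarray:
    """Descending log-spaced lambda grid from lambda_max (the smallest
    penalty zeroing every slope at this mixing weight) down ``decades``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n = Z.shape[0]
    resid = y - y.mean()
    lam_max = np.max(np.abs(Z.T @ resid)) / (n * max(alpha_mix, 1e-3))
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_lambda)


def tune_hyperparameters(
    X,
    y,
    alphas: Sequence[float] | None = None,
    n_lambda: int = 50,
    k: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> tuple[float, float, pd.DataFrame]:
    """Stratified k-fold CV grid search maximizing mean AUC.

    Default grid: alpha_mix in {0, 0.1, ..., 1.0}, per-alpha lambda path of
    ``n_lambda`` points spanning four decades down from lambda_max.  Ties are
    broken toward larger lambda then larger alpha (more parsimonious).
    Returns (alpha_mix*, lambda*, cv_table).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if alphas is None:
        alphas = np.round(np.arange(0.0, 1.01, 0.1), 1)
    if k < 2:
        raise ValueError("k must be >= 2")
    min_class = int(np.bincount(y).min())
    if min_class < k:
        warnings.warn(f"reducing k from {k} to {min_class} for stratification", stacklevel=2)
        k = min_class
    folds = list(StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(X, y))
    rows = []
    for alpha in alphas:
        lams = lambda_grid(X, y, alpha, n_lambda=n_lambda)
        for lam in lams:
            aucs = []
            for tr, te in folds:
                # CV ranking tolerates loose fits; the final model refits tightly
                model = ElasticNetLogistic(
                    alpha_mix=float(alpha), lam=float(lam), tol=tol, max_iter=max_iter
                )
                model.fit(X[tr], y[tr])
                scores = model.decision_function(X[te])
                if np.unique(y[te]).size == 2:
                    aucs.append(roc_auc_score(y[te], scores))
            rows.append((float(alpha), float(lam), float(np.mean(aucs))))
    cv = pd.DataFrame(rows, columns=["alpha_mix", "lam", "mean_auc"])
    best = cv.sort_values(
        ["mean_auc", "lam", "alpha_mix"], ascending=[False, False, False], kind="stable"
    ).iloc[0]
    return float(best.alpha_mix), float(best.lam), cv


#: Coarse inner-tuning settings used by the repeated hold-out benchmark:
#: bracketing grid and loose solver (CV only ranks hyperparameters).
FAST_TUNE = {"alphas": (0.0, 0.5, 1.0), "n_lambda": 8, "k": 3,
             "tol": 1e-4, "max_iter": 250}


# ---------------------------------------------------------------------------
# repeated hold-out benchmark


@dataclass(frozen=True)
class SplitScheme:
    """Repeated randomized train/test hold-out partitions (id-keyed)."""

    n_splits: int = 5000
    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


def iter_splits(table: FeatureTable, scheme: SplitScheme):
    """Yield (train_ids, test_ids) for every split, seed-determined.

    Splitting is keyed on sorted sample ids so row order is irrelevant.
    Every split keeps at least 2 samples per class in train and 1 per class
    in test; non-stratified draws violating this are redrawn (counted via the
    generator's ``.redraws`` attribute on the wrapped function).
    """
    ids = np.array(sorted(table.sample_ids))
    y = pd.Series(table.y, index=table.sample_ids)[ids].to_numpy()
    rng = np.random.default_rng(scheme.seed)
    by_class = [ids[y == c] for c in (0, 1)]
    if min(len(g) for g in by_class) < 3:
        raise ValueError("need >= 3 samples per class to split")
    for _ in range(scheme.n_splits):
        if scheme.stratified:
            train: list[str] = []
            test: list[str] = []
            for g in by_class:
                n_train = int(round(scheme.train_fraction * len(g)))
                n_train = min(max(n_train, 2), len(g) - 1)
                perm = rng.permutation(len(g))
                train.extend(g[perm[:n_train]])
                test.extend(g[perm[n_train:]])
            yield train, test
        else:
            while True:
                perm = rng.permutation(len(ids))
                n_train = int(round(scheme.train_fraction * len(ids)))
                tr, te = ids[perm[:n_train]], ids[perm[n_train:]]
                y_tr = y[perm[:n_train]]
                y_te = y[perm[n_train:]]
                if (
                    min(np.count_nonzero(y_tr == c) for c in (0, 1)) >= 2
                    and min(np.count_nonzero(y_te == c) for c in (0, 1)) >= 1
                ):
                    yield list(tr), list(te)
                    break


def _make_family(name: str, seed: int, enet_params: tuple[float, float] | None):
    if name == "decision_tree":
        return DecisionTreeClassifier(max_depth=4, random_state=seed)
    if name == "logistic":
        return ElasticNetLogistic(lam=0.0, tol=1e-6)
    if name == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if name == "elastic_net":
        a, l = enet_params if enet_params else (0.5, 0.01)
        return ElasticNetLogistic(alpha_mix=a, lam=l)
    raise ValueError(f"unknown model family {name!r}")


MODEL_FAMILIES = ("decision_tree", "logistic", "svm_rbf", "random_forest", "elastic_net")

_NEEDS_SCALING = {"logistic", "svm_rbf"}  # ElasticNetLogistic standardizes itself


def _impute_scale(Xtr: np.ndarray, Xte: np.ndarray, scale: bool):
    """Train-fold median imputation and (optionally) z-scoring; the test fold
    is always transformed with train statistics only."""
    med = np.nanmedian(Xtr, axis=0)
    Xtr = np.where(np.isnan(Xtr), med, Xtr)
    Xte = np.where(np.isnan(Xte), med, Xte)
    if scale:
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
    return Xtr, Xte


@dataclass
class BenchmarkResult:
    """Per-family metrics over all hold-out splits (case = positive class)."""

    family: str
    auc: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    auc_of_mean_roc: float
    tuned: list[tuple[float, float]] | None = None

    @property
    def summary(self) -> dict:
        return {
            "family": self.family,
            "n_splits": int(self.auc.size),
            "mean_auc": float(self.auc.mean()),
            "sd_auc": float(self.auc.std(ddof=1)) if self.auc.size > 1 else 0.0,
            "mean_sensitivity": float(self.sensitivity.mean()),
            "mean_specificity": float(self.specificity.mean()),
            "mean_accuracy": float(self.accuracy.mean()),
            "auc_of_mean_roc": float(self.auc_of_mean_roc),
        }


def _split_metrics(y_true: np.ndarray, scores: np.ndarray, preds: np.ndarray):
    tp = int(np.sum((preds == 1) & (y_true == 1)))
    fn = int(np.sum((preds == 0) & (y_true == 1)))
    tn = int(np.sum((preds == 0) & (y_true == 0)))
    fp = int(np.sum((preds == 1) & (y_true == 0)))
    auc = roc_auc_score(y_true, scores)
    return (
        float(auc),
        tp / (tp + fn) if (tp + fn) else float("nan"),
        tn / (tn + fp) if (tn + fp) else float("nan"),
        (tp + tn) / y_true.size,
    )


def average_roc(
    score_label_pairs: Sequence[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Vertically averaged ROC: per split, TPR is interpolated on a fixed FPR
    grid, then averaged across splits.  Returns (fpr_grid, mean_tpr)."""
    if not score_label_pairs:
        raise ValueError("need at least one split with both classes")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for y_true, scores in score_label_pairs:
        fpr, tpr, _ = roc_curve(y_true, scores)
        tprs.append(np.interp(grid, fpr, tpr))
    return grid, np.mean(tprs, axis=0)


def repeated_holdout_benchmark(
    table: FeatureTable,
    scheme: SplitScheme,
    families: Sequence[str] = MODEL_FAMILIES,
    threshold: float = 0.5,
    tune_elastic_net: bool = True,
    tune_grid: dict | None = None,
    enet_params: tuple[float, float] | None = None,
) -> dict[str, BenchmarkResult]:
    """Benchmark model families over repeated stratified hold-out splits.

    Each family is re-fitted per split on the training fold (the elastic net
    with inner CV tuning unless fixed ``enet_params`` are given; comparators
    with fixed documented defaults) and evaluated on the held-out fold: AUC
    from continuous scores, and sensitivity/specificity/accuracy at the 0.5
    probability threshold with case as positive.  Fully seed-determined.
    """
    grid = dict(FAST_TUNE)
    if tune_grid:
        grid.update(tune_grid)
    splits = list(iter_splits(table, scheme))
    results: dict[str, BenchmarkResult] = {}
    for family in families:
        aucs, sens, spec, acc = [], [], [], []
        pairs = []
        tuned: list[tuple[float, float]] = []
        for si, (train_ids, test_ids) in enumerate(splits):
            Xtr, ytr = table.subset(train_ids)
            Xte, yte = table.subset(test_ids)
            params = enet_params
            if family == "elastic_net" and tune_elastic_net and enet_params is None:
                a, l, _ = tune_hyperparameters(
                    Xtr, ytr, alphas=grid["alphas"], n_lambda=grid["n_lambda"],
                    k=grid["k"], seed=scheme.seed + si,
                    tol=grid["tol"], max_iter=grid["max_iter"],
                )
                params = (a, l)
                tuned.append(params)
            model = _make_family(family, seed=scheme.seed + si, enet_params=params)
            if isinstance(model, ElasticNetLogistic):
                model.fit(Xtr, ytr)
                scores = model.decision_function(Xte)
                preds = model.predict(Xte, threshold=threshold)
            else:
                Xtr_p, Xte_p = _impute_scale(Xtr, Xte, scale=family in _NEEDS_SCALING)
                model.fit(Xtr_p, ytr)
                if hasattr(model, "predict_proba"):
                    scores = model.predict_proba(Xte_p)[:, 1]
                    preds = (scores > threshold).astype(int)
                else:
                    scores = model.decision_function(Xte_p)
                    preds = model.predict(Xte_p)
            a_, se, sp, ac = _split_metrics(yte, scores, preds)
            aucs.append(a_)
            sens.append(se)
            spec.append(sp)
            acc.append(ac)
            pairs.append((yte, scores))
        fpr_grid, mean_tpr = average_roc(pairs)
        results[family] = BenchmarkResult(
            family=family,
            auc=np.array(aucs),
            sensitivity=np.array(sens),
            specificity=np.array(spec),
            accuracy=np.array(acc),
            fpr_grid=fpr_grid,
            mean_tpr=mean_tpr,
            auc_of_mean_roc=float(np.trapezoid(mean_tpr, fpr_grid)),
            tuned=tuned or None,
        )
    return results


# ---------------------------------------------------------------------------
# final INDEX model


@dataclass
class IndexModel:
    """The final linear INDEX score: intercept + beta . x.

    Betas are stored on the standardized scale together with the back-
    transformed raw-scale equivalents (identical scores); prediction uses the
    raw-scale coefficients on features transformed as recorded.  Status is
    case when probability strictly exceeds ``threshold``.
    """

    feature_names: list[str]
    betas: list[float]  # standardized scale
    intercept: float
    betas_raw: list[float]
    intercept_raw: float
    means: list[float]
    scales: list[float]
    alpha_mix: float
    lam: float
    threshold: float = 0.5
    transforms: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "IndexModel":
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "IndexModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def finalize_index_model(
    table: FeatureTable,
    alpha_mix: float,
    lam: float,
    threshold: float = 0.5,
) -> IndexModel:
    """Fit the elastic net on the full table and package it as an IndexModel."""
    model = ElasticNetLogistic(alpha_mix=alpha_mix, lam=lam)
    model.fit(table.X.to_numpy(dtype=float), table.y)
    return IndexModel(
        feature_names=list(table.feature_names),
        betas=[float(b) for b in model.coef_],
        intercept=float(model.intercept_),
        betas_raw=[float(b) for b in model.coef_raw_],
        intercept_raw=float(model.intercept_raw_),
        means=[float(m) for m in model.means_],
        scales=[float(s) for s in model.scales_],
        alpha_mix=float(alpha_mix),
        lam=float(lam),
        threshold=float(threshold),
        transforms=dict(table.transforms),
    )


def predict_index(model: IndexModel, features) -> tuple[float, float, str]:
    """INDEX score, probability and status for one feature vector.

    ``features`` is a mapping or Series of raw feature values (transformed as
    recorded in the model, e.g. log10 copies).  Missing features raise a
    KeyError naming the column.  Status is "case" iff probability strictly
    exceeds the model threshold.
    """
    if isinstance(features, pd.Series):
        features = features.to_dict()
    x = []
    for name in model.feature_names:
        if name not in features or pd.isna(features[name]):
            raise KeyError(f"missing feature: {name}")
        x.append(float(features[name]))
    index = model.intercept_raw + float(np.dot(model.betas_raw, x))
    prob = 1.0 / (1.0 + np.exp(-index))
    status = "case" if prob > model.threshold else "control"
    return index, prob, status


def predict_index_frame(model: IndexModel, X: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`predict_index` over the rows of a feature table."""
    rows = [predict_index(model, X.loc[i]) for i in X.index]
    return pd.DataFrame(rows, columns=["index", "probability", "status"], index=X.index)
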