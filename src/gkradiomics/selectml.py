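"""Feature selection, class balancing, SVM training, and model comparison.

The modeling recipe, applied identically to the clinical, radiomics and
combined feature views of a labeled cohort table:

1. grouped, class-stratified 70/30 hold-out split (all lesions of a patient
   stay on one side);
2. Welch two-sample t-test per radiomic feature; keep the <=25 smallest
   p-values below alpha (clinical covariates bypass this step);
3. NearMiss-2 undersampling of the majority class on the training side;
4. sequential forward selection (SFS) over the candidates, wrapper
   criterion = stratified 5-fold CV AUC of an RBF SVM;
5. RBF SVM with Gaussian-process (expected-improvement) hyperparameter
   search over log-uniform (C, gamma), refit at the optimum;
6. test-set AUC/accuracy/sensitivity/specificity, and paired bootstrap
   comparison of models with Bonferroni-corrected paired t-tests.

Estimators follow sklearn conventions (fit/transform/predict, ``get_params``,
fitted attributes with trailing underscores) and compose with sklearn
pipelines; NearMiss-2 exposes the imblearn-style ``fit_resample`` because
undersampling changes the number of rows.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .cohort import CLINICAL_FEATURES, view_columns

logger = logging.getLogger(__name__)

METRICS = ("auc", "accuracy", "sensitivity", "specificity")
VIEWS = ("clinical", "radiomics", "combined")


def _stratified_cv(y, n_splits: int, seed: int) -> StratifiedKFold:
    """Stratified K-fold capped at the smallest class count (>= 2 folds)."""
    smallest = int(np.bincount(np.asarray(y)).min())
    if smallest < 2:
        raise ValueError(
            f"CV criterion undefined: smallest class has {smallest} row(s)"
        )
    return StratifiedKFold(n_splits=min(n_splits, smallest), shuffle=True, random_state=seed)


# ---------------------------------------------------------------------- #
# hold-out split
# ---------------------------------------------------------------------- #
@dataclass
class SplitSpec:
    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")


def holdout_split(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grouped, class-stratified hold-out split of a labeled cohort table.

    The split is drawn at patient level so that all lesions of one patient
    land on one side; patients are stratified by their majority label.
    """
    y = table["label"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present before splitting")
    if counts.min() < 2:
        raise ValueError("need >=2 rows per class to stratify the split")

    patients = table.groupby("patient_id")["label"].mean()
    pat_ids = patients.index.to_numpy()
    pat_y = (patients.to_numpy() > 0.5).astype(int)
    if spec.stratified and len(np.unique(pat_y)) == 2 and np.bincount(pat_y).min() >= 2:
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=spec.train_fraction, random_state=spec.seed
        )
        (train_idx, test_idx), = splitter.split(pat_ids.reshape(-1, 1), pat_y)
    else:
        rng = np.random.default_rng(spec.seed)
        perm = rng.permutation(len(pat_ids))
        n_train = int(round(spec.train_fraction * len(pat_ids)))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    train_pat = set(pat_ids[train_idx])
    is_train = table["patient_id"].isin(train_pat)
    train, test = table[is_train].copy(), table[~is_train].copy()
    train.attrs.update(table.attrs)
    test.attrs.update(table.attrs)
    return train, test


# ---------------------------------------------------------------------- #
# step 1: Welch t-test ranking
# ---------------------------------------------------------------------- #
class WelchTTestSelector(SelectorMixin, BaseEstimator):
    """Keep the <=k features with the smallest Welch t-test p-values < alpha.

    Features with zero variance in both classes get p = 1 and are never
    selected.  Fitted attributes: ``pvalues_`` (per input feature) and the
    boolean ``support_``.
    """

    def __init__(self, k: int = 25, alpha: float = 0.05):
        self.k = k
        self.alpha = alpha

    def fit(self, X, y):
        X = validate_data(self, X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {classes}")
        a, b = X[y == classes[0]], X[y == classes[1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, equal_var=False, axis=0)
            p = np.asarray(res.pvalue, dtype=np.float64)
        degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
        p = np.where(np.isnan(p) | degenerate, 1.0, p)
        self.pvalues_ = p
        order = np.argsort(p, kind="stable")
        chosen = [i for i in order[: self.k] if p[i] < self.alpha]
        support = np.zeros(X.shape[1], dtype=bool)
        support[chosen] = True
        self.support_ = support
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def ttest_rank(train: pd.DataFrame, columns, k: int = 25, alpha: float = 0.05) -> pd.DataFrame:
    """Candidate features of a labeled table: name + p-value, p ascending."""
    sel = WelchTTestSelector(k=k, alpha=alpha).fit(train[list(columns)].to_numpy(), train["label"])
    cols = np.asarray(list(columns))
    out = pd.DataFrame({"feature": cols, "pvalue": sel.pvalues_})
    out = out[sel.support_].sort_values("pvalue", kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------- #
# NearMiss-2 undersampling
# ---------------------------------------------------------------------- #
class NearMiss2(BaseEstimator):
    """NearMiss-2 majority undersampling.

    Majority rows are ranked by their average Euclidean distance (on
    per-feature standardized values) to their ``k`` *farthest* minority
    rows; the rows with the smallest average distance are kept until class
    counts equalize.  Minority rows are untouched.
    """

    def __init__(self, k: int = 3, standardize: bool = True):
        self.k = k
        self.standardize = standardize

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        idx = self.sample_indices(X, y)
        return X[idx], y[idx]

    def sample_indices(self, X, y) -> np.ndarray:
        """Sorted row indices retained by the undersampling rule."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("NearMiss-2 needs exactly two classes")
        if counts[0] == counts[1]:
            return np.arange(len(y))
        minority = classes[np.argmin(counts)]
        majority = classes[np.argmax(counts)]
        if self.standardize:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            Xs = (X - X.mean(axis=0)) / sd
        else:
            Xs = X
        maj_idx = np.flatnonzero(y == majority)
        min_idx = np.flatnonzero(y == minority)
        d = np.linalg.norm(Xs[maj_idx][:, None, :] - Xs[min_idx][None, :, :], axis=2)
        k = min(self.k, len(min_idx))
        # average distance to the k farthest minority samples
        far = np.sort(d, axis=1)[:, -k:]
        score = far.mean(axis=1)
        keep_maj = maj_idx[np.argsort(score, kind="stable")[: len(min_idx)]]
        return np.sort(np.concatenate([min_idx, keep_maj]))


def nearmiss2(train: pd.DataFrame, columns, k: int = 3) -> pd.DataFrame:
    """Balanced copy of a labeled table (distance computed on ``columns``)."""
    y = train["label"].to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    if counts.min() == counts.max():
        return train
    idx = NearMiss2(k=k).sample_indices(train[list(columns)].to_numpy(), y)
    out = train.iloc[idx].copy()
    out.attrs.update(train.attrs)
    return out


# ---------------------------------------------------------------------- #
# sequential forward selection
# ---------------------------------------------------------------------- #
class SequentialForwardSelector(SelectorMixin, BaseEstimator):
    """Greedy forward feature selection with a CV-AUC wrapper criterion.

    At each step the candidate whose addition maximizes stratified ``cv``-fold
    CV AUC of ``estimator`` is added; selection stops when the best addition
    improves the criterion by less than ``tol``.  ``base_mask`` marks columns
    that are always included (e.g. clinical covariates in the combined view)
    and never count as selections.

    Fitted attributes: ``selected_`` (column indices in selection order),
    ``trace_`` (criterion value after each addition), ``support_``.
    """

    def __init__(self, estimator=None, cv: int = 5, tol: float = 1e-4, seed: int = 0, base_mask=None):
        self.estimator = estimator
        self.cv = cv
        self.tol = tol
        self.seed = seed
        self.base_mask = base_mask

    def _criterion(self, X, y, cols):
        est = clone(self.estimator) if self.estimator is not None else SVC(kernel="rbf", C=1.0, gamma="scale")
        skf = _stratified_cv(y, self.cv, self.seed)
        scores = cross_val_score(est, X[:, cols], y, cv=skf, scoring="roc_auc", error_score="raise")
        return float(scores.mean())

    def fit(self, X, y):
        X = validate_data(self, X, dtype=np.float64)
        y = np.asarray(y)
        n = X.shape[1]
        base = np.zeros(n, dtype=bool) if self.base_mask is None else np.asarray(self.base_mask, dtype=bool)
        pool = [i for i in range(n) if not base[i]]
        selected: list[int] = []
        trace: list[float] = []
        current = self._criterion(X, y, np.flatnonzero(base).tolist()) if base.any() else 0.5
        while pool:
            scores = [
                (self._criterion(X, y, np.flatnonzero(base).tolist() + selected + [j]), j)
                for j in pool
            ]
            best_score, best_j = max(scores, key=lambda t: (t[0], -t[1]))
            if best_score - current <= self.tol:
                break
            selected.append(best_j)
            pool.remove(best_j)
            trace.append(best_score)
            current = best_score
        self.selected_ = selected
        self.trace_ = trace
        support = base.copy()
        support[selected] = True
        self.support_ = support
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def sfs_select(
    train: pd.DataFrame,
    candidates,
    base_features=(),
    cv: int = 5,
    tol: float = 1e-4,
    seed: int = 0,
) -> tuple[list[str], list[float]]:
    """Names selected by SFS from ``candidates`` (base features always kept).

    Works on per-feature standardized values of the (balanced) training table.
    Returns (selected names in order, criterion trace).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate feature")
    cols = list(base_features) + candidates
    X = StandardScaler().fit_transform(train[cols].to_numpy(dtype=np.float64))
    base_mask = np.array([c in set(base_features) for c in cols])
    sel = SequentialForwardSelector(cv=cv, tol=tol, seed=seed, base_mask=base_mask)
    sel.fit(X, train["label"].to_numpy())
    names = [cols[i] for i in sel.selected_]
    return names, sel.trace_


# ---------------------------------------------------------------------- #
# Bayesian-optimized RBF SVM
# ---------------------------------------------------------------------- #
class BayesSVMClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with GP/expected-improvement hyperparameter search.

    (log10 C, log10 gamma) are searched over a box by maximizing stratified
    ``cv``-fold CV AUC: ``n_initial`` quasi-random evaluations seed a
    Gaussian-process surrogate, then ``n_iter - n_initial`` proposals each
    maximize expected improvement over a random candidate set.  The final
    SVC is refit on the full training data at the best point.  Deterministic
    under a fixed ``seed``.
    """

    def __init__(
        self,
        n_iter: int = 30,
        n_initial: int = 8,
        c_bounds: tuple[float, float] = (1e-3, 1e3),
        gamma_bounds: tuple[float, float] = (1e-4, 1e1),
        cv: int = 5,
        seed: int = 0,
    ):
        self.n_iter = n_iter
        self.n_initial = n_initial
        self.c_bounds = c_bounds
        self.gamma_bounds = gamma_bounds
        self.cv = cv
        self.seed = seed

    def _cv_auc(self, X, y, log_c, log_g):
        svc = SVC(kernel="rbf", C=10.0**log_c, gamma=10.0**log_g)
        skf = _stratified_cv(y, self.cv, self.seed)
        try:
            return float(
                cross_val_score(svc, X, y, cv=skf, scoring="roc_auc", error_score="raise").mean()
            )
        except ValueError as exc:
            raise ValueError(f"CV criterion undefined: {exc}") from exc

    def fit(self, X, y):
        X = validate_data(self, X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly two classes, got {self.classes_}")
        rng = np.random.default_rng(self.seed)
        lo = np.log10([self.c_bounds[0], self.gamma_bounds[0]])
        hi = np.log10([self.c_bounds[1], self.gamma_bounds[1]])

        pts: list[np.ndarray] = []
        vals: list[float] = []
        n_init = min(self.n_initial, self.n_iter)
        init = lo + (hi - lo) * rng.random((n_init, 2))
        for p in init:
            pts.append(p)
            vals.append(self._cv_auc(X, y, *p))
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=[1.0, 1.0], length_scale_bounds=(1e-2, 1e2), nu=2.5
        )
        for _ in range(self.n_iter - n_init):
            gp = GaussianProcessRegressor(
                kernel=kernel, alpha=1e-4, normalize_y=True, random_state=int(rng.integers(2**31))
            )
            with warnings.catch_warnings():
                # surrogate hyperparameters hitting bounds is harmless here
                warnings.simplefilter("ignore")
                gp.fit(np.vstack(pts), np.asarray(vals))
            cand = lo + (hi - lo) * rng.random((256, 2))
            mu, sd = gp.predict(cand, return_std=True)
            best = max(vals)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (mu - best) / sd
                ei = (mu - best) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
            ei = np.where(sd > 0, ei, 0.0)
            p = cand[int(np.argmax(ei))]
            pts.append(p)
            vals.append(self._cv_auc(X, y, *p))

        best_idx = int(np.argmax(vals))
        log_c, log_g = pts[best_idx]
        self.C_, self.gamma_ = float(10.0**log_c), float(10.0**log_g)
        self.cv_best_score_ = float(vals[best_idx])
        self.search_points_ = np.vstack(pts)
        self.search_scores_ = np.asarray(vals)
        self.svc_ = SVC(kernel="rbf", C=self.C_, gamma=self.gamma_).fit(X, y)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        X = validate_data(self, X, dtype=np.float64, reset=False)
        return self.svc_.decision_function(X)

    def predict(self, X):
        check_is_fitted(self, "svc_")
        X = validate_data(self, X, dtype=np.float64, reset=False)
        return self.svc_.predict(X)


# ---------------------------------------------------------------------- #
# end-to-end view model
# ---------------------------------------------------------------------- #
@dataclass
class ModelSpec:
    k_candidates: int = 25
    alpha: float = 0.05
    nearmiss_k: int = 3
    sfs_cv: int = 5
    sfs_tol: float = 1e-4
    bayes_iter: int = 30
    bayes_initial: int = 8
    bayes_cv: int = 5
    seed: int = 0


@dataclass
class FittedOutcomeModel:
    view: str
    features: list[str]
    candidates: pd.DataFrame
    sfs_trace: list[float] = field(default_factory=list)
    pipeline: Pipeline | None = None

    def decision_scores(self, table: pd.DataFrame) -> np.ndarray:
        return self.pipeline.decision_function(table[self.features].to_numpy(dtype=np.float64))


def fit_outcome_model(train: pd.DataFrame, view: str, spec: ModelSpec | None = None) -> FittedOutcomeModel:
    """Fit one view's model: selection -> balancing -> SFS -> Bayes SVM.

    The clinical view skips radiomic selection but shares balancing,
    training and evaluation machinery with the other views.
    """
    spec = spec or ModelSpec()
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}")
    y = train["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: one class only")

    base = list(CLINICAL_FEATURES) if view in ("clinical", "combined") else []
    candidates = pd.DataFrame(columns=["feature", "pvalue"])
    pool: list[str] = []
    if view in ("radiomics", "combined"):
        radiomic_cols = view_columns(train, "radiomics")
        candidates = ttest_rank(train, radiomic_cols, k=spec.k_candidates, alpha=spec.alpha)
        pool = candidates["feature"].tolist()

    balance_cols = base + pool if (base or pool) else view_columns(train, view)
    balanced = nearmiss2(train, balance_cols, k=spec.nearmiss_k)

    trace: list[float] = []
    selected: list[str] = []
    if pool:
        selected, trace = sfs_select(
            balanced, pool, base_features=base, cv=spec.sfs_cv, tol=spec.sfs_tol, seed=spec.seed
        )
        if not selected and not base:
            # a model needs at least one feature; keep the top candidate
            selected = [pool[0]]
            logger.info("fit_outcome_model[%s]: SFS selected nothing; keeping top candidate", view)
    features = base + selected

    pipeline = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                BayesSVMClassifier(
                    n_iter=spec.bayes_iter,
                    n_initial=spec.bayes_initial,
                    cv=spec.bayes_cv,
                    seed=spec.seed,
                ),
            ),
        ]
    )
    pipeline.fit(balanced[features].to_numpy(dtype=np.float64), balanced["label"].to_numpy())
    return FittedOutcomeModel(
        view=view, features=features, candidates=candidates, sfs_trace=trace, pipeline=pipeline
    )


# ---------------------------------------------------------------------- #
# evaluation and bootstrap comparison
# ---------------------------------------------------------------------- #
def evaluate_scores(scores: np.ndarray, y: np.ndarray, threshold: float = 0.0) -> dict[str, float]:
    """AUC (rank statistic) + threshold metrics; positive class is poor=1."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    pred = (np.asarray(scores) > threshold).astype(int)
    return {
        "auc": float(roc_auc_score(y, scores)),
        "accuracy": float((pred == y).mean()),
        "sensitivity": float((pred[y == 1] == 1).mean()),
        "specificity": float((pred[y == 0] == 0).mean()),
    }


def evaluate(model: FittedOutcomeModel, test: pd.DataFrame) -> dict[str, float]:
    """Test-set metrics of a fitted view model."""
    if test.empty:
        raise ValueError("empty test set")
    return evaluate_scores(model.decision_scores(test), test["label"].to_numpy())


@dataclass
class EvalReport:
    """Point metrics, bootstrap distributions, and pairwise comparisons."""

    metrics: dict  # model -> metric -> float
    bootstrap: dict  # model -> metric -> np.ndarray (B,)
    comparisons: pd.DataFrame  # columns: metric, model_a, model_b, p, significant
    alpha: float
    n_comparisons: int
    resample_index_hash: str

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "bootstrap_mean": {
                m: {k: float(np.mean(v)) for k, v in d.items()} for m, d in self.bootstrap.items()
            },
            "bootstrap_std": {
                m: {k: float(np.std(v)) for k, v in d.items()} for m, d in self.bootstrap.items()
            },
            "comparisons": self.comparisons.to_dict(orient="records"),
            "alpha": self.alpha,
            "n_comparisons": self.n_comparisons,
            "resample_index_hash": self.resample_index_hash,
        }


def bootstrap_compare(
    models: dict[str, FittedOutcomeModel],
    test: pd.DataFrame,
    b: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    max_redraws: int = 1000,
) -> EvalReport:
    """Paired bootstrap comparison of fitted models on one test set.

    ``b`` resamples of the test rows (with replacement, shared indices
    across models) give per-metric distributions; each model pair is
    compared with a paired t-test at Bonferroni-adjusted alpha.  Resamples
    that lose a class are redrawn (bounded, logged).
    """
    if b < 2:
        raise ValueError("b must be >= 2")
    y = test["label"].to_numpy()
    scores = {name: m.decision_scores(test) for name, m in models.items()}
    point = {name: evaluate_scores(s, y) for name, s in scores.items()}

    rng = np.random.default_rng(seed)
    n = len(y)
    indices = []
    redraws = 0
    while len(indices) < b:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("could not draw two-class bootstrap resamples")
            continue
        indices.append(idx)
    if redraws:
        logger.info("bootstrap_compare: redrew %d single-class resamples", redraws)
    import hashlib

    h = hashlib.sha256(np.vstack(indices).tobytes()).hexdigest()[:16]

    boot: dict[str, dict[str, np.ndarray]] = {
        name: {m: np.empty(b) for m in METRICS} for name in models
    }
    for r, idx in enumerate(indices):
        for name in models:
            met = evaluate_scores(scores[name][idx], y[idx])
            for m in METRICS:
                boot[name][m][r] = met[m]

    pairs = list(itertools.combinations(sorted(models), 2))
    adj_alpha = alpha / max(len(pairs), 1)
    rows = []
    for metric in METRICS:
        for a_name, b_name in pairs:
            da, db = boot[a_name][metric], boot[b_name][metric]
            if np.allclose(da, db):
                p = 1.0
            else:
                p = float(stats.ttest_rel(da, db).pvalue)
                if np.isnan(p):
                    p = 1.0
            rows.append(
                {
                    "metric": metric,
                    "model_a": a_name,
                    "model_b": b_name,
                    "mean_a": float(da.mean()),
                    "mean_b": float(db.mean()),
                    "p": p,
                    "significant": bool(p < adj_alpha),
                }
            )
    comparisons = pd.DataFrame(rows)
    return EvalReport(
        metrics=point,
        bootstrap=boot,
        comparisons=comparisons,
        alpha=adj_alpha,
        n_comparisons=len(pairs),
        resample_index_hash=h,
    )
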