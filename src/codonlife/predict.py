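"""Cross-validated prediction harness for homeostasis parameters.

Design: the cohort is split 72% training / 8% cross-validation / 20% held-out
test, realised as a 20% test split plus balanced 10-fold cross-validation with
10 repeats (initializations) on the remaining 80% (each fold is 8% of the
total).  Hyperparameters minimise mean CV RMSE; the winner is refit on the
full train-cv set and scored once on the test set.  Three learner families are
supported: a random-forest regressor (captures non-linearity), an elastic-net
linear model, and a greedy forward-backward sparse linear model.  Feature
importances are scaled 0-100 (top feature = 100) and can be summed over
amino-acid classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression

from .codon_tables import standard_table

LEARNERS = ("ensemble_trees", "elastic_linear", "greedy_forward_backward")

#: Fig.-2e-style amino-acid classes used for grouped importances.
AA_GROUPS = {
    "small_hydrophobic": frozenset("AILV"),
    "negative_polar": frozenset("DENQ"),
    "positive": frozenset("KR"),
    "phospho": frozenset("ST"),
    "unusual": frozenset("PWC"),
}

DEFAULT_GRIDS = {
    "ensemble_trees": [
        {"max_features": "sqrt"},
        {"max_features": 0.33},
    ],
    "elastic_linear": [
        {"alpha": a, "l1_ratio": l}
        for a in (1e-4, 1e-3, 1e-2, 1e-1)
        for l in (0.2, 0.95)
    ],
    "greedy_forward_backward": [{"k_max": k} for k in (1, 2, 4, 8, 16, 32, 64)],
}


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitSpec:
    """72/8/20 split realised as 20% test + 10-fold x 10-repeat CV on the rest."""

    train_fraction: float = 0.72
    cv_fraction: float = 0.08
    test_fraction: float = 0.20
    folds: int = 10
    repeats: int = 10
    seed: int = 0

    def validate(self) -> None:
        if abs(self.train_fraction + self.cv_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


@dataclass(frozen=True)
class Split:
    """Disjoint, exhaustive partition plus per-repeat fold labels."""

    test_ids: tuple[str, ...]
    traincv_ids: tuple[str, ...]
    fold_labels: np.ndarray  # shape (repeats, n_traincv), values 0..folds-1
    spec: SplitSpec


def make_split(ids: list[str], spec: SplitSpec | None = None) -> Split:
    """Seeded 20% test split and balanced fold assignment per repeat."""
    spec = spec or SplitSpec()
    spec.validate()
    ids = list(ids)
    if len(ids) < spec.folds + 1:
        raise ValueError(f"need at least folds+1={spec.folds + 1} ids, got {len(ids)}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(ids))
    n_test = round(spec.test_fraction * len(ids))
    test = tuple(ids[i] for i in order[:n_test])
    traincv = tuple(ids[i] for i in order[n_test:])
    n = len(traincv)
    base = np.concatenate([np.full(n // spec.folds + (1 if f < n % spec.folds else 0),
                                   f, dtype=int)
                           for f in range(spec.folds)])
    fold_labels = np.empty((spec.repeats, n), dtype=int)
    for rep in range(spec.repeats):
        fold_labels[rep] = base[rng.permutation(n)]
    return Split(test_ids=test, traincv_ids=traincv, fold_labels=fold_labels, spec=spec)


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class Preprocessor:
    """Center/scale fitted on the training data, with optional redundancy filter.

    The filter removes near-zero-variance columns (frequency-ratio +
    unique-fraction rule), columns that are exact linear combinations of
    earlier columns, and one member of each highly collinear pair
    (|r| above ``corr_threshold``); removals are recorded.
    """

    filter: bool = True
    corr_threshold: float = 0.95
    freq_ratio: float = 19.0
    unique_fraction: float = 0.1
    kept_columns: list[str] = field(default_factory=list)
    removed: dict[str, list[str]] = field(default_factory=dict)
    means_: pd.Series | None = None
    sds_: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "Preprocessor":
        df = train.astype(float)
        sds = df.std(ddof=0)
        if (sds == 0).all():
            raise ValueError("all feature columns are constant")
        removed: dict[str, list[str]] = {"zero_variance": [], "near_zero_variance": [],
                                         "linear_combo": [], "collinear": []}
        keep = [c for c in df.columns if sds[c] > 0]
        removed["zero_variance"] = [c for c in df.columns if sds[c] == 0]
        if self.filter:
            keep2 = []
            for c in keep:
                col = df[c]
                counts = col.value_counts()
                ratio = counts.iloc[0] / counts.iloc[1] if len(counts) > 1 else np.inf
                uniq = len(counts) / len(col)
                if ratio > self.freq_ratio and uniq < self.unique_fraction:
                    removed["near_zero_variance"].append(c)
                else:
                    keep2.append(c)
            keep = keep2
            keep, combos = _drop_linear_combos(df[keep])
            removed["linear_combo"] = combos
            keep, collinear = _drop_collinear(df[keep], self.corr_threshold)
            removed["collinear"] = collinear
        if not keep:
            raise ValueError("no feature columns survive filtering")
        self.kept_columns = keep
        self.removed = removed
        self.means_ = df[keep].mean()
        self.sds_ = df[keep].std(ddof=0)
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        if self.means_ is None:
            raise RuntimeError("Preprocessor not fitted")
        return (data[self.kept_columns].astype(float) - self.means_) / self.sds_


def _drop_linear_combos(df: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Greedy rank check: drop columns exactly spanned by earlier ones."""
    x = df.to_numpy()
    keep_idx: list[int] = []
    dropped: list[str] = []
    for j in range(x.shape[1]):
        cand = x[:, keep_idx + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(cand).max())) == len(keep_idx) + 1:
            keep_idx.append(j)
        else:
            dropped.append(df.columns[j])
    return [df.columns[j] for j in keep_idx], dropped


def _drop_collinear(df: pd.DataFrame, threshold: float) -> tuple[list[str], list[str]]:
    """caret-style findCorrelation: for each |r|>threshold pair drop the member
    with the larger mean absolute correlation."""
    corr = df.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    cols = list(df.columns)
    mean_abs = corr.mean(axis=0)
    dropped_idx: set[int] = set()
    pairs = np.argwhere(np.triu(corr, 1) > threshold)
    for i, j in sorted(pairs, key=lambda p: -corr[p[0], p[1]]):
        if i in dropped_idx or j in dropped_idx:
            continue
        dropped_idx.add(i if mean_abs[i] >= mean_abs[j] else j)
    kept = [c for k, c in enumerate(cols) if k not in dropped_idx]
    dropped = [cols[k] for k in sorted(dropped_idx)]
    return kept, dropped


# ---------------------------------------------------------------------------
# learners


class GreedyForwardBackward(BaseEstimator, RegressorMixin):
    """Sparse linear regression by adaptive forward selection with backward
    deletion: features are added greedily by residual-sum-of-squares gain, and
    after each addition any feature whose removal costs less than ``nu`` times
    the last gain is deleted.  Capacity is controlled by ``k_max``.
    """

    def __init__(self, k_max: int = 8, nu: float = 0.5):
        self.k_max = k_max
        self.nu = nu

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        selected: list[int] = []
        ybar = y.mean()
        resid = y - ybar

        def rss_of(idx: list[int]) -> tuple[float, np.ndarray, float]:
            if not idx:
                return float(np.sum((y - ybar) ** 2)), np.empty(0), ybar
            lr = LinearRegression().fit(X[:, idx], y)
            pred = lr.predict(X[:, idx])
            return float(np.sum((y - pred) ** 2)), lr.coef_, float(lr.intercept_)

        current_rss, coef, intercept = rss_of(selected)
        while len(selected) < min(self.k_max, p):
            # forward: best single addition by correlation with residual
            gains = np.abs(X.T @ resid)
            gains[selected] = -np.inf
            j = int(np.argmax(gains))
            new_rss, coef, intercept = rss_of(selected + [j])
            gain = current_rss - new_rss
            if gain <= 1e-12:
                break
            selected.append(j)
            current_rss = new_rss
            # backward: delete features that cost less than nu * last gain
            improved = True
            while improved and len(selected) > 1:
                improved = False
                for k in list(selected):
                    trial = [s for s in selected if s != k]
                    trial_rss, tcoef, tint = rss_of(trial)
                    if trial_rss - current_rss < self.nu * gain:
                        selected = trial
                        current_rss, coef, intercept = trial_rss, tcoef, tint
                        improved = True
                        break
            _, coef, intercept = rss_of(selected)
            pred = X[:, selected] @ coef + intercept
            resid = y - pred
        self.selected_ = sorted(selected)
        _, coef_sel, self.intercept_ = rss_of(self.selected_)
        self.coef_ = np.zeros(p)
        if len(self.selected_):
            self.coef_[self.selected_] = coef_sel
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def build_learner(learner: str, params: dict, seed: int = 0,
                  n_estimators: int = 200):
    """Instantiate one of the three learner families."""
    if learner == "ensemble_trees":
        return RandomForestRegressor(n_estimators=n_estimators, random_state=seed,
                                     n_jobs=1, **params)
    if learner == "elastic_linear":
        # Gram precompute: feature counts here are small relative to n
        return ElasticNet(max_iter=5000, precompute=True, **params)
    if learner == "greedy_forward_backward":
        return GreedyForwardBackward(**params)
    raise ValueError(f"unknown learner {learner!r}; expected one of {LEARNERS}")


def _complexity(learner: str, params: dict) -> float:
    """Tie-break key: prefer the simpler model at (near-)equal CV RMSE."""
    if learner == "greedy_forward_backward":
        return params.get("k_max", 0)
    if learner == "elastic_linear":
        return -params.get("alpha", 0)  # stronger penalty = simpler
    return {"sqrt": 0}.get(params.get("max_features"), 1)


# ---------------------------------------------------------------------------
# tuning, evaluation, importances


@dataclass
class TunedModel:
    learner: str
    estimator: object  # refit on the full train-cv set
    best_params: dict
    rmse_cv: float
    cv_table: pd.DataFrame  # one row per grid point: params, mean/sd CV RMSE
    train_ids: tuple[str, ...]
    seed: int


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def tune_and_fit(matrix: pd.DataFrame, response: pd.Series, split: Split,
                 learner: str, grid: list[dict] | None = None,
                 one_se_rule: bool = False, n_estimators: int = 200) -> TunedModel:
    """Grid-search hyperparameters over the repeated CV folds, refit winner.

    ``matrix`` must be the preprocessed train-cv block indexed like
    ``split.traincv_ids``.  The default tie-break prefers the simpler model;
    ``one_se_rule`` instead picks the simplest model within one standard error
    of the best mean CV RMSE (the optional "tolerance model").
    """
    if response.std(ddof=0) == 0:
        raise ValueError("response is constant")
    grid = grid if grid is not None else DEFAULT_GRIDS[learner]
    X = matrix.loc[list(split.traincv_ids)].to_numpy(dtype=float)
    y = response.loc[list(split.traincv_ids)].to_numpy(dtype=float)
    results = []
    with warnings.catch_warnings():
        # weakly-penalized grid points may stop at max_iter; their CV RMSE
        # still ranks them correctly
        warnings.simplefilter("ignore", ConvergenceWarning)
        for params in grid:
            fold_rmses = []
            for rep in range(split.spec.repeats):
                labels = split.fold_labels[rep]
                for f in range(split.spec.folds):
                    val = labels == f
                    est = build_learner(learner, params, seed=split.spec.seed,
                                        n_estimators=n_estimators)
                    est.fit(X[~val], y[~val])
                    fold_rmses.append(_rmse(est.predict(X[val]), y[val]))
            results.append({"params": params,
                            "rmse_cv": float(np.mean(fold_rmses)),
                            "rmse_cv_sd": float(np.std(fold_rmses, ddof=1)),
                            "n_folds": len(fold_rmses)})
    table = pd.DataFrame(results)
    best_i = int(min(range(len(results)),
                     key=lambda i: (results[i]["rmse_cv"],
                                    _complexity(learner, results[i]["params"]))))
    if one_se_rule:
        se = results[best_i]["rmse_cv_sd"] / math.sqrt(results[best_i]["n_folds"])
        cutoff = results[best_i]["rmse_cv"] + se
        candidates = [i for i in range(len(results)) if results[i]["rmse_cv"] <= cutoff]
        best_i = min(candidates, key=lambda i: _complexity(learner, results[i]["params"]))
    best = results[best_i]
    final = build_learner(learner, best["params"], seed=split.spec.seed,
                          n_estimators=n_estimators)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        final.fit(X, y)
    return TunedModel(learner=learner, estimator=final, best_params=best["params"],
                      rmse_cv=best["rmse_cv"], cv_table=table,
                      train_ids=split.traincv_ids, seed=split.spec.seed)


@dataclass
class ImportanceTable:
    """Raw and 0-100-scaled feature importances plus amino-acid-class sums."""

    raw: pd.Series
    scaled: pd.Series  # max = 100; NaN-flagged when all raw are 0
    grouped: pd.Series
    defined: bool


def _aa_of_feature(name: str) -> str | None:
    """Amino acid behind a composition-derived feature name, else None."""
    table = standard_table()
    for marker in ("aa_", "codon_"):
        if marker in name:
            token = name.rsplit(marker, 1)[1]
            if marker == "aa_" and token in table.amino_acids:
                return token
            if marker == "codon_" and token in table.forward:
                return table.forward[token]
    return None


def group_of_feature(name: str) -> str:
    aa = _aa_of_feature(name)
    if aa is not None:
        for group, members in AA_GROUPS.items():
            if aa in members:
                return group
    return "other"


def importance_table(tuned: TunedModel, matrix: pd.DataFrame,
                     response: pd.Series, n_refits: int = 30) -> ImportanceTable:
    """Learner-appropriate raw importances, scaled to a 0-100 range.

    Random forest: mean decrease in node impurity.  Linear learners:
    |mean coefficient| / sd over ``n_refits`` cross-validation refits on the
    train-cv set (a t-statistic).  Scaled importances are 100 * raw / max(raw);
    grouped values sum the scaled importances over amino-acid classes.
    """
    X = matrix.loc[list(tuned.train_ids)]
    y = response.loc[list(tuned.train_ids)].to_numpy(dtype=float)
    names = list(matrix.columns)
    if tuned.learner == "ensemble_trees":
        raw = pd.Series(tuned.estimator.feature_importances_, index=names)
    else:
        rng = np.random.default_rng(tuned.seed)
        labels = np.arange(len(X)) % n_refits
        rng.shuffle(labels)
        coefs = np.empty((n_refits, len(names)))
        Xv = X.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for f in range(n_refits):
                est = clone(tuned.estimator)
                mask = labels != f
                est.fit(Xv[mask], y[mask])
                coefs[f] = est.coef_
        mean = coefs.mean(axis=0)
        sd = coefs.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.abs(mean) / sd
        t[np.abs(mean) < 1e-12] = 0.0
        t[np.isinf(t)] = np.nanmax(t[np.isfinite(t)], initial=1.0)
        raw = pd.Series(np.nan_to_num(t), index=names)
    max_raw = raw.max()
    if max_raw <= 0:
        scaled = pd.Series(math.nan, index=raw.index)
        defined = False
    else:
        scaled = 100.0 * (raw / max_raw)  # ratio first so the top feature is exactly 100
        defined = True
    grouped = scaled.groupby(scaled.index.map(group_of_feature)).sum() if defined \
        else pd.Series(dtype=float)
    return ImportanceTable(raw=raw, scaled=scaled, grouped=grouped, defined=defined)


@dataclass
class ModelReport:
    """Test-set performance of one tuned model."""

    learner: str
    tier: str
    rmse_cv: float
    rmse_test: float
    r_test: float
    r2_test: float  # squared Pearson of predicted vs observed
    percent_of_max: float | None
    best_params: dict
    seed: int
    predictions: pd.Series = field(repr=False, default=None)
    importances: ImportanceTable | None = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "learner": self.learner,
            "tier": self.tier,
            "rmse_cv": self.rmse_cv,
            "rmse_test": self.rmse_test,
            "r_test": self.r_test,
            "r2_test": self.r2_test,
            "percent_of_max": self.percent_of_max,
            "best_params": self.best_params,
            "seed": self.seed,
        }


def evaluate(tuned: TunedModel, test_matrix: pd.DataFrame, test_response: pd.Series,
             tier: str = "composition", r2_interstudy: float | None = None) -> ModelReport:
    """Score a tuned model on held-out ids (disjointness is asserted)."""
    overlap = set(test_matrix.index) & set(tuned.train_ids)
    if overlap:
        raise ValueError(f"test ids seen during tuning: {sorted(overlap)[:5]}")
    pred = np.asarray(tuned.estimator.predict(test_matrix.to_numpy(dtype=float)),
                      dtype=float)
    obs = test_response.loc[test_matrix.index].to_numpy(dtype=float)
    rmse_test = _rmse(pred, obs)
    if np.std(pred) == 0 or np.std(obs) == 0:
        r = math.nan
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
    r2 = r * r if not math.isnan(r) else math.nan
    pom = None
    if r2_interstudy is not None and not math.isnan(r2):
        pom = percent_of_max(r2, r2_interstudy).raw
    return ModelReport(learner=tuned.learner, tier=tier, rmse_cv=tuned.rmse_cv,
                       rmse_test=rmse_test, r_test=r, r2_test=r2,
                       percent_of_max=pom, best_params=tuned.best_params,
                       seed=tuned.seed,
                       predictions=pd.Series(pred, index=test_matrix.index))


@dataclass(frozen=True)
class PercentOfMax:
    raw: float
    percent: int  # rounded half away from zero


def percent_of_max(r2_model: float, r2_interstudy: float) -> PercentOfMax:
    """Model r-squared as a percentage of the inter-study (maximum expected)
    r-squared; e.g. (0.17, 0.48) -> ~35%."""
    if not 0 < r2_interstudy <= 1:
        raise ValueError("r2_interstudy must be in (0, 1]")
    raw = 100.0 * r2_model / r2_interstudy
    rounded = int(math.floor(raw + 0.5)) if raw >= 0 else -int(math.floor(-raw + 0.5))
    return PercentOfMax(raw=raw, percent=rounded)


def learning_curve(matrix: pd.DataFrame, response: pd.Series, split: Split,
                   learner: str, sizes: list[int], params: dict | None = None,
                   n_estimators: int = 100) -> pd.DataFrame:
    """Train and CV RMSE at increasing train-cv sizes (bias/variance diagnostic)."""
    if any(s < split.spec.folds for s in sizes):
        raise ValueError("every size must be >= the number of folds")
    if sorted(sizes) != list(sizes):
        raise ValueError("sizes must be increasing")
    params = params or DEFAULT_GRIDS[learner][0]
    rng = np.random.default_rng(split.spec.seed)
    all_ids = list(split.traincv_ids)
    rows = []
    for size in sizes:
        ids = [all_ids[i] for i in rng.permutation(len(all_ids))[:size]]
        X = matrix.loc[ids].to_numpy(dtype=float)
        y = response.loc[ids].to_numpy(dtype=float)
        labels = np.arange(size) % split.spec.folds
        rng.shuffle(labels)
        tr, cv = [], []
        for f in range(split.spec.folds):
            val = labels == f
            est = build_learner(learner, params, seed=split.spec.seed,
                                n_estimators=n_estimators)
            est.fit(X[~val], y[~val])
            tr.append(_rmse(est.predict(X[~val]), y[~val]))
            cv.append(_rmse(est.predict(X[val]), y[val]))
        rows.append({"size": size, "rmse_train": float(np.mean(tr)),
                     "rmse_cv": float(np.mean(cv))})
    return pd.DataFrame(rows)
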