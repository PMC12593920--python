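"""Interpretable APL screening over tabular features.

This stage assembles the feature table (20 scattergram parameters + 50
routine blood parameters for the RFC-S screener, routine parameters only
for the RFC-C baseline), standardizes it with training-split statistics,
selects features by recursive feature elimination scored with stratified
5-fold cross-validated ROC-AUC, tunes random-forest hyperparameters by
grid search, fits the forest with balanced-subsample class weights, tunes
the decision threshold for a screening-grade sensitivity floor, and
explains the fitted model with exact tree-Shapley attributions.

The modelling surface follows the Model/Results convention:
``ScreeningModel`` holds the training data and configuration, ``fit()``
returns a ``ScreeningResults`` carrying the fitted bundle, the RFE curve,
cross-validated scores and evaluation/attribution methods.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import treeshap
from .quant import FEATURE_NAMES as SCATTER_FEATURE_NAMES
from .synthgram import CLASS_NAMES, ROUTINE_PARAM_NAMES, ConfigurationError, ValidationError

MODES = {"rfc-s": 70, "rfc-c": 50}
POSITIVE_CLASS = "APL"


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureTable:
    """Samples x features matrix with binary APL labels."""

    X: pd.DataFrame                 # indexed by sample_id
    y: np.ndarray                   # 1 = APL, 0 = other
    mode: str
    class_names: np.ndarray | None = None  # original 4-way labels, if known

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.X.shape[1] != MODES[self.mode]:
            raise ValidationError(
                f"{self.mode} requires {MODES[self.mode]} columns, "
                f"got {self.X.shape[1]}")
        if self.X.index.has_duplicates:
            raise ValidationError("duplicate sample_ids")
        if not np.isfinite(self.X.to_numpy()).all():
            raise ValidationError("non-finite entries after cleaning")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        cls = None if self.class_names is None else self.class_names[idx]
        return FeatureTable(self.X.iloc[idx], self.y[idx], self.mode, cls)


@dataclass
class ScalerParams:
    """Train-split per-feature mean/sd; degenerate sd is replaced by 1."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: list[str]

    def transform(self, table: FeatureTable) -> FeatureTable:
        if list(table.X.columns) != self.feature_names:
            raise ValidationError("column mismatch in standardization")
        Z = (table.X - self.mean) / self.sd
        return FeatureTable(Z, table.y, table.mode, table.class_names)


@dataclass
class RfeCurve:
    """CV ROC-AUC as a function of retained feature count."""

    counts: np.ndarray              # descending: p, p-1, ..., 1
    scores: np.ndarray              # mean CV AUC at each count
    elimination_order: list[str]    # first-dropped first
    feature_names: list[str]        # original column order
    tol: float = 0.003
    estimator: str = "rfc"

    @property
    def selected_count(self) -> int:
        mx = self.scores.max()
        ok = self.scores >= (1.0 - self.tol) * mx
        return int(self.counts[ok].min())

    def features_at(self, k: int) -> list[str]:
        dropped = set(self.elimination_order[: len(self.feature_names) - k])
        return [f for f in self.feature_names if f not in dropped]

    @property
    def selected_features(self) -> list[str]:
        return self.features_at(self.selected_count)


@dataclass
class ModelBundle:
    """Everything needed to score new samples reproducibly."""

    classifier: str
    hyperparams: dict
    model: object
    selected_features: list[str]
    scaler: ScalerParams
    threshold: float
    seed: int
    mode: str
    metadata: dict = field(default_factory=dict)

    def scores(self, table: FeatureTable, standardized: bool = False) -> np.ndarray:
        t = table if standardized else self.scaler.transform(table)
        X = t.X[self.selected_features].to_numpy()
        return self.model.predict_proba(X)[:, 1]

    def to_bytes(self) -> bytes:
        return pickle.dumps(self, protocol=4)

    @staticmethod
    def from_bytes(raw: bytes) -> "ModelBundle":
        return pickle.loads(raw)


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    scores: np.ndarray | None = None

    @classmethod
    def from_confusion(cls, tp: int, fp: int, fn: int, tn: int, auc: float,
                       scores=None) -> "EvaluationReport":
        n = tp + fp + fn + tn
        return cls(
            tp, fp, fn, tn,
            accuracy=(tp + tn) / n if n else 0.0,
            sensitivity=tp / (tp + fn) if tp + fn else 0.0,
            specificity=tn / (tn + fp) if tn + fp else 0.0,
            ppv=tp / (tp + fp) if tp + fp else 0.0,
            npv=tn / (tn + fn) if tn + fn else 0.0,
            auc=auc, scores=scores,
        )

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("tp", "fp", "fn", "tn", "accuracy", "sensitivity", "specificity",
              "ppv", "npv", "auc")}
        return d


@dataclass
class AttributionMatrix:
    """Per-sample, per-feature Shapley attributions (probability scale)."""

    values: np.ndarray
    base_value: float
    feature_names: list[str]
    sample_ids: list

    def mean_abs(self) -> pd.Series:
        return pd.Series(np.abs(self.values).mean(axis=0),
                         index=self.feature_names).sort_values(ascending=False)

    def rank_of(self, feature: str) -> int:
        """1-based rank of a feature by mean |attribution|."""
        order = list(self.mean_abs().index)
        return order.index(feature) + 1


# ---------------------------------------------------------------------------
# table assembly and standardization


def _clean(df: pd.DataFrame) -> pd.DataFrame:
    if df["sample_id"].duplicated().any():
        warnings.warn("duplicate sample_ids dropped (first occurrence kept)")
        df = df.drop_duplicates(subset="sample_id", keep="first")
    num = df.drop(columns=[c for c in ("sample_id", "class") if c in df])
    finite = np.isfinite(num.to_numpy(dtype=float)).all(axis=1)
    if not finite.all():
        warnings.warn(f"dropped {int((~finite).sum())} rows with non-finite entries")
        df = df.loc[finite]
    return df


def assemble_features(scatter: pd.DataFrame | None, routine: pd.DataFrame,
                      mode: str = "rfc-s") -> FeatureTable:
    """Build the screening table.

    ``routine`` must carry sample_id, class and the 50 routine columns;
    ``scatter`` carries sample_id plus the 20 scattergram parameters and is
    required in rfc-s mode.  Rows are cleaned (dedupe, drop non-finite)
    before assembly.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}")
    routine = _clean(routine.copy())
    cols = list(ROUTINE_PARAM_NAMES)
    if mode == "rfc-s":
        if scatter is None:
            raise ValidationError("rfc-s mode requires the scattergram table")
        scatter = _clean(scatter.copy())
        merged = scatter.merge(routine, on="sample_id", how="inner",
                               validate="one_to_one")
        if len(merged) == 0 or len(merged) < max(len(scatter), len(routine)) / 2:
            raise ValidationError("sample_id mismatch between scatter and routine tables")
        cols = list(SCATTER_FEATURE_NAMES) + cols
    else:
        merged = routine
    X = merged.set_index("sample_id")[cols].astype(float)
    labels = merged.set_index("sample_id")["class"]
    y = (labels == POSITIVE_CLASS).to_numpy(dtype=int)
    return FeatureTable(X, y, mode, class_names=labels.to_numpy())


def standardize(train: FeatureTable, *others: FeatureTable
                ) -> tuple[list[FeatureTable], ScalerParams]:
    """Z-score all tables with statistics estimated on ``train`` only."""
    X = train.X.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    params = ScalerParams(mean, sd, list(train.X.columns))
    return [params.transform(t) for t in (train, *others)], params


# ---------------------------------------------------------------------------
# estimators


def make_estimator(name: str, seed: int, hyperparams: dict | None = None):
    hp = hyperparams or {}
    if name == "lr":
        return LogisticRegression(max_iter=2000, random_state=seed, **hp)
    if name == "svm":
        return SVC(kernel="linear", random_state=seed, **hp)
    if name == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if name == "rfc":
        defaults = dict(n_estimators=300, class_weight="balanced_subsample",
                        max_features="sqrt")
        defaults.update(hp)
        return RandomForestClassifier(random_state=seed, **defaults)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    raise ConfigurationError(f"unknown estimator {name!r}")


def _importance(est) -> np.ndarray:
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    if hasattr(est, "coef_"):
        return np.abs(np.asarray(est.coef_, dtype=float)).ravel()
    raise ConfigurationError(f"{type(est).__name__} exposes no importance")


def _scores_of(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def _cv_auc(estimator_name: str, X: np.ndarray, y: np.ndarray, folds: int,
            seed: int, hyperparams: dict | None = None) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        est = make_estimator(estimator_name, seed, hyperparams)
        est.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], _scores_of(est, X[te])))
    return float(np.mean(aucs))


def cv_out_of_fold_scores(estimator_name: str, table: FeatureTable, folds: int,
                          seed: int, hyperparams: dict | None = None,
                          features: list[str] | None = None) -> np.ndarray:
    """Out-of-fold predicted APL probabilities on the training table."""
    X = table.X[features or table.feature_names].to_numpy()
    y = table.y
    out = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        est = make_estimator(estimator_name, seed, hyperparams)
        est.fit(X[tr], y[tr])
        out[te] = _scores_of(est, X[te])
    return out


# ---------------------------------------------------------------------------
# feature selection and tuning


def rfe_cv(table: FeatureTable, estimator: str = "rfc", folds: int = 5,
           tol: float = 0.003, seed: int = 0,
           hyperparams: dict | None = None) -> RfeCurve:
    """Recursive feature elimination scored by stratified CV ROC-AUC.

    At each width the estimator is refit on the full training table to rank
    features by its native importance; the least important one (ties broken
    by column order) is dropped.  The curve records mean CV AUC at every
    width from the full table down to a single feature.
    """
    y = table.y
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ValidationError("need at least `folds` samples of each class")
    current = list(table.feature_names)
    counts, scores, dropped = [], [], []
    while current:
        X = table.X[current].to_numpy()
        counts.append(len(current))
        scores.append(_cv_auc(estimator, X, y, folds, seed, hyperparams))
        if len(current) == 1:
            break
        est = make_estimator(estimator, seed, hyperparams)
        est.fit(X, y)
        imp = _importance(est)
        drop = current[int(np.argmin(imp))]  # argmin keeps first on ties
        dropped.append(drop)
        current.remove(drop)
    return RfeCurve(np.asarray(counts), np.asarray(scores), dropped,
                    list(table.feature_names), tol, estimator)


def grid_search(table: FeatureTable, estimator: str, grid: list[dict],
                folds: int = 5, seed: int = 0,
                features: list[str] | None = None) -> tuple[dict, list[float]]:
    """Exhaustive CV-AUC grid search; ties keep the earliest grid point."""
    if not grid:
        raise ValidationError("empty hyperparameter grid")
    X = table.X[features or table.feature_names].to_numpy()
    best, best_score, all_scores = None, -np.inf, []
    for point in grid:
        score = _cv_auc(estimator, X, table.y, folds, seed, point)
        all_scores.append(score)
        if score > best_score:
            best, best_score = point, score
    return dict(best), all_scores


def expand_grid(param_grid: dict[str, list]) -> list[dict]:
    from itertools import product

    keys = list(param_grid)
    return [dict(zip(keys, vals)) for vals in product(*param_grid.values())]


def tune_threshold(scores: np.ndarray, labels: np.ndarray,
                   min_sensitivity: float = 0.95) -> float:
    """Highest threshold maximizing specificity subject to a sensitivity
    floor (positives are calls with score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if (labels == 1).sum() == 0:
        raise ValidationError("no positive samples to tune on")
    candidates = np.unique(scores)
    best_t, best_spec, best_sens = None, -1.0, -1.0
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = ((~pred) & (labels == 0)).sum() / n_neg if n_neg else 1.0
        if sens >= min_sensitivity and (spec > best_spec or
                                        (spec == best_spec and t > (best_t or -1))):
            best_t, best_spec, best_sens = float(t), spec, sens
    if best_t is None:  # floor unreachable: fall back to catching every positive
        best_t = float(scores[labels == 1].min())
    # probability thresholds live strictly inside (0, 1); clamping at the
    # float boundary leaves every score >= t decision unchanged
    return float(np.clip(best_t, 1e-12, 1.0 - 1e-12))


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Alternative rule: maximize sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best_t, best_j = float(scores.min()), -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / max((labels == 1).sum(), 1)
        spec = ((~pred) & (labels == 0)).sum() / max((labels == 0).sum(), 1)
        if sens + spec - 1 > best_j:
            best_j, best_t = sens + spec - 1, float(t)
    return best_t


# ---------------------------------------------------------------------------
# fitting, evaluation, explanation


def train_classifier(table: FeatureTable, selected_features: list[str],
                     scaler: ScalerParams, seed: int = 0,
                     hyperparams: dict | None = None,
                     threshold: float = 0.5) -> ModelBundle:
    """Fit the random-forest screener on a standardized training table."""
    if len(np.unique(table.y)) < 2:
        raise ValidationError("training labels are single-class")
    hp = dict(n_estimators=300 if table.mode == "rfc-s" else 150,
              class_weight="balanced_subsample", max_features="sqrt")
    hp.update(hyperparams or {})
    model = RandomForestClassifier(random_state=seed, **hp)
    model.fit(table.X[selected_features].to_numpy(), table.y)
    return ModelBundle("rfc", hp, model, list(selected_features), scaler,
                       threshold, seed, table.mode)


def evaluate(bundle: ModelBundle, table: FeatureTable,
             standardized: bool = False) -> EvaluationReport:
    """Confusion matrix at the bundle threshold plus rank-based ROC-AUC."""
    if len(table.y) == 0:
        raise ValidationError("empty evaluation table")
    scores = bundle.scores(table, standardized=standardized)
    pred = scores >= bundle.threshold
    y = table.y
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, scores))
    else:
        auc = float("nan")
    return EvaluationReport.from_confusion(tp, fp, fn, tn, auc, scores)


def shap_explain(bundle: ModelBundle, table: FeatureTable,
                 standardized: bool = False) -> AttributionMatrix:
    """Exact tree-Shapley attributions on the probability scale."""
    if not isinstance(bundle.model, RandomForestClassifier):
        raise ConfigurationError("attributions require a tree-ensemble model")
    t = table if standardized else bundle.scaler.transform(table)
    X = t.X[bundle.selected_features].to_numpy()
    phi, base = treeshap.forest_shap(bundle.model, X)
    return AttributionMatrix(phi, base, list(bundle.selected_features),
                             list(table.X.index))


def compare_classifiers(table: FeatureTable, seed: int = 0, folds: int = 5,
                        tol: float = 0.003,
                        estimators: tuple[str, ...] = ("lr", "svm", "lda", "rfc",
                                                       "adaboost"),
                        hyperparams: dict[str, dict] | None = None
                        ) -> dict[str, RfeCurve]:
    """RFE/CV curves for the five candidate classifier families under a
    shared fold structure."""
    hp = hyperparams or {}
    return {name: rfe_cv(table, name, folds, tol, seed, hp.get(name))
            for name in estimators}


def group_correlation(scatter: pd.DataFrame, class_names) -> pd.DataFrame:
    """Pearson correlation of each scattergram parameter with each study
    group's one-vs-rest indicator (20 x 4)."""
    labels = pd.Series(np.asarray(class_names))
    groups = [g for g in CLASS_NAMES if (labels == g).any()]
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValidationError(f"need >= 2 samples in group {g}")
    out = np.zeros((len(SCATTER_FEATURE_NAMES), len(groups)))
    for j, g in enumerate(groups):
        ind = (labels == g).to_numpy(dtype=float)
        for i, fname in enumerate(SCATTER_FEATURE_NAMES):
            v = scatter[fname].to_numpy(dtype=float)
            if v.std() == 0 or ind.std() == 0:
                warnings.warn(f"zero-variance parameter {fname}; correlation 0")
                out[i, j] = 0.0
            else:
                out[i, j] = float(np.corrcoef(v, ind)[0, 1])
    return pd.DataFrame(out, index=list(SCATTER_FEATURE_NAMES), columns=groups)


# ---------------------------------------------------------------------------
# Model / Results surface


def stratified_split(y: np.ndarray, test_fraction: float = 0.2, seed: int = 0,
                     strata=None) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test split (8:2 by default).

    Stratification uses ``strata`` when given (e.g. the 4-way class label)
    so every study group is represented in both splits.
    """
    rng = np.random.default_rng(seed)
    strata = np.asarray(strata if strata is not None else y)
    test_idx = []
    for g in np.unique(strata):
        idx = np.flatnonzero(strata == g)
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(len(idx) * test_fraction)))
        test_idx.extend(idx[:k])
    test = np.sort(np.asarray(test_idx))
    train = np.setdiff1d(np.arange(len(strata)), test)
    return train, test


@dataclass
class ScreenConfig:
    mode: str = "rfc-s"
    folds: int = 5
    rfe_tol: float = 0.003
    min_sensitivity: float = 0.95
    threshold_rule: str = "max_specificity"     # or "youden"
    grid: dict[str, list] = field(default_factory=lambda: {
        "n_estimators": [100, 150, 300], "max_features": ["sqrt", None]})
    run_rfe: bool = True
    run_grid: bool = True
    #: forest size used during RFE ranking/scoring only; the final model
    #: keeps the mode's tree count (selection is stable with fewer trees
    #: and the elimination loop refits at every width)
    rfe_trees: int = 100


class ScreeningModel:
    """Random-forest APL screener over a (training) feature table.

    Parameters
    ----------
    table : FeatureTable
        Raw (unstandardized) training table.
    config : ScreenConfig
        Pipeline settings; the mode decides the 70- vs 50-feature roster
        and the default forest size (300 vs 150 trees).
    """

    def __init__(self, table: FeatureTable, config: ScreenConfig | None = None):
        self.table = table
        self.config = config or ScreenConfig(mode=table.mode)
        if self.config.mode != table.mode:
            raise ConfigurationError("config mode does not match table mode")

    @classmethod
    def from_dataframe(cls, routine: pd.DataFrame,
                       scatter: pd.DataFrame | None = None,
                       mode: str = "rfc-s",
                       config: ScreenConfig | None = None) -> "ScreeningModel":
        table = assemble_features(scatter, routine, mode)
        if config is None:
            config = ScreenConfig(mode=mode)
        return cls(table, config)

    def fit(self, seed: int = 0) -> "ScreeningResults":
        cfg = self.config
        (train_z,), scaler = standardize(self.table)
        base_hp = dict(n_estimators=300 if cfg.mode == "rfc-s" else 150,
                       class_weight="balanced_subsample", max_features="sqrt")
        curve = None
        selected = list(train_z.feature_names)
        if cfg.run_rfe:
            rfe_hp = dict(base_hp, n_estimators=cfg.rfe_trees)
            curve = rfe_cv(train_z, "rfc", cfg.folds, cfg.rfe_tol, seed, rfe_hp)
            selected = curve.selected_features
        hp, grid_scores = dict(base_hp), []
        if cfg.run_grid:
            grid = expand_grid(cfg.grid)
            best, grid_scores = grid_search(train_z, "rfc", grid, cfg.folds,
                                            seed, selected)
            hp.update(best)
        oof = cv_out_of_fold_scores("rfc", train_z, cfg.folds, seed, hp, selected)
        if cfg.threshold_rule == "youden":
            threshold = youden_threshold(oof, train_z.y)
        else:
            threshold = tune_threshold(oof, train_z.y, cfg.min_sensitivity)
        bundle = train_classifier(train_z, selected, scaler, seed, hp, threshold)
        return ScreeningResults(self, bundle, curve, grid_scores, oof, seed)


class ScreeningResults:
    """Fitted screener: bundle + diagnostics + evaluation/attribution."""

    def __init__(self, model: ScreeningModel, bundle: ModelBundle,
                 rfe_curve: RfeCurve | None, grid_scores: list[float],
                 oof_scores: np.ndarray, seed: int):
        self.model = model
        self.bundle = bundle
        self.rfe_curve = rfe_curve
        self.grid_scores = grid_scores
        self.oof_scores = oof_scores
        self.seed = seed
        self.train_report = evaluate(bundle, model.table)

    def evaluate(self, table: FeatureTable) -> EvaluationReport:
        return evaluate(self.bundle, table)

    def explain(self, table: FeatureTable | None = None) -> AttributionMatrix:
        return shap_explain(self.bundle, table if table is not None
                            else self.model.table)

    def summary(self) -> str:
        b = self.bundle
        r = self.train_report
        lines = [
            f"APL screening model ({b.mode.upper()})",
            "=" * 46,
            f"training samples:    {len(self.model.table.y)} "
            f"({int(self.model.table.y.sum())} APL)",
            f"features offered:    {len(self.model.table.feature_names)}",
            f"features selected:   {len(b.selected_features)}",
            f"forest:              {b.hyperparams['n_estimators']} trees, "
            f"max_features={b.hyperparams['max_features']}, "
            f"class_weight={b.hyperparams['class_weight']}",
            f"decision threshold:  {b.threshold:.4f} "
            f"(rule: {self.model.config.threshold_rule})",
            f"train AUC:           {r.auc:.4f}",
            f"train sens/spec:     {r.sensitivity:.4f} / {r.specificity:.4f}",
            "selected features:",
        ]
        for f in b.selected_features:
            lines.append(f"  - {f}")
        return "\n".join(lines)
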