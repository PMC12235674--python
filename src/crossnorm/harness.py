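"""End-to-end experiment driver.

For each (normalization method, tau_ndeg, tau_deg, classifier family) cell:
select genes by ANOVA on the training platform's full labelled sample set,
partition 75/25 against the other platform with name-match overlap removal,
normalize each platform independently using the training-derived NDEG list,
restrict features to the DEG set, tune the classifier by exhaustive grid
search over stratified 10-fold CV scored with weighted F1, predict the
cross-platform test set, repeat with fresh partitions, and aggregate the
repeats into means/SDs and the Evalue.

No statistic of the test platform's values or labels enters selection,
normalization fitting, or tuning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from crossnorm.core_io import DataError, ExpressionMatrix, SubtypeLabels
from crossnorm.evaluate import MetricSet, RepeatedEvaluation, f1_weighted
from crossnorm.normalize import REFERENCE_METHODS, NormalizationSpec, normalize
from crossnorm.partition import assign_folds, split_cross_platform
from crossnorm.selection import GeneSelection, anova_table, select_genes

logger = logging.getLogger("crossnorm")

FAMILIES = ("MLP", "XGB", "LR", "SVM", "RF")

# hyperparameter search spaces per classifier family (full profile)
_FULL_GRIDS: dict[str, object] = {
    "LR": {"C": list(np.logspace(-2, 1, 5)), "solver": ["liblinear", "lbfgs"]},
    "SVM": [{"kernel": ["linear"]}, {"kernel": ["rbf"], "gamma": ["scale", 0.01, 0.1]}],
    "RF": {
        "n_estimators": [100, 200, 300],
        "max_depth": [3, 4, 6],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [2, 5, 10],
        "max_features": ["sqrt", "log2"],
    },
    "MLP": {
        "hidden_layer_sizes": [(100,), (100, 30), (100, 50)],
        "solver": ["adam", "sgd", "lbfgs"],
        "alpha": [1e-4, 1e-3],
    },
    "XGB": {
        "n_estimators": [100, 200, 300],
        "learning_rate": [0.05, 0.1, 0.3],
        "max_depth": [3, 4, 6],
        "subsample": [0.6, 0.8, 1.0],
        "colsample_bytree": [0.6, 0.8, 1.0],
        "gamma": [0, 0.1, 0.5],
    },
}

# desk-scale profile: one or two values per axis
_FAST_GRIDS: dict[str, object] = {
    "LR": {"C": [1.0], "solver": ["lbfgs"]},
    "SVM": [{"kernel": ["linear"]}],
    "RF": {"n_estimators": [100], "max_depth": [6]},
    "MLP": {"hidden_layer_sizes": [(100,)], "solver": ["adam"], "alpha": [1e-4]},
    "XGB": {"n_estimators": [100], "learning_rate": [0.1], "max_depth": [3]},
}

_ALLOWED_PARAMS = {
    "LR": {"C", "solver", "penalty"},
    "SVM": {"kernel", "gamma", "C"},
    "RF": {"n_estimators", "max_depth", "min_samples_split", "min_samples_leaf", "max_features"},
    "MLP": {"hidden_layer_sizes", "solver", "alpha"},
    "XGB": {"n_estimators", "learning_rate", "max_depth", "subsample", "colsample_bytree", "gamma"},
}


@dataclass
class ClassifierGrid:
    """A classifier family with its hyperparameter search space."""

    family: str
    grid: object  # dict of lists, or list of such dicts

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DataError(f"unknown classifier family {self.family!r}")
        configs = list(ParameterGrid(self.grid))
        if not configs:
            raise DataError("empty hyperparameter grid")
        allowed = _ALLOWED_PARAMS[self.family]
        for cfg in configs:
            bad = set(cfg) - allowed
            if bad:
                raise DataError(f"invalid {self.family} parameters: {sorted(bad)}")

    def configs(self) -> list[dict]:
        return list(ParameterGrid(self.grid))

    @classmethod
    def default(cls, family: str, fast: bool = False) -> "ClassifierGrid":
        grids = _FAST_GRIDS if fast else _FULL_GRIDS
        if family not in grids:
            raise DataError(f"unknown classifier family {family!r}")
        return cls(family, grids[family])


def make_estimator(family: str, params: dict, seed: int):
    """Instantiate one classifier configuration with a fixed random state."""
    if family == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed, **params)
    if family == "SVM":
        return SVC(probability=True, max_iter=1000, random_state=seed, **params)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "MLP":
        return MLPClassifier(early_stopping=True, max_iter=500, random_state=seed, **params)
    if family == "XGB":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="mlogloss", verbosity=0, **params
        )
    raise DataError(f"unknown classifier family {family!r}")


def _full_proba(est, x: np.ndarray, n_classes: int) -> np.ndarray:
    """Probability matrix over all classes, 0 for classes absent from training."""
    p = est.predict_proba(x)
    out = np.zeros((x.shape[0], n_classes))
    out[:, np.asarray(est.classes_, dtype=int)] = p
    return out


def tune_and_fit(x: np.ndarray, y: np.ndarray, folds: np.ndarray, grid: ClassifierGrid, seed: int):
    """Exhaustive grid search by mean weighted F1 over the given folds, then refit.

    Ties are broken by first-in-grid enumeration order (strict improvement
    wins).  A grid of size 1 skips cross-validation and refits directly.
    Returns (fitted estimator, chosen parameters, mean CV score or None).
    """
    configs = grid.configs()
    best_params, best_score = configs[0], None
    if len(configs) > 1:
        n_folds = int(folds.max()) + 1
        best_score = -np.inf
        for cfg in configs:
            scores = []
            for f in range(n_folds):
                te = folds == f
                if not te.any():
                    continue
                tr = ~te
                if len(np.unique(y[te])) < len(np.unique(y)):
                    warnings.warn(
                        f"fold {f} is missing classes; scored on present classes", stacklevel=2
                    )
                est = make_estimator(grid.family, cfg, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(x[tr], y[tr])
                    scores.append(f1_weighted(y[te], est.predict(x[te])))
            mean = float(np.mean(scores))
            if mean > best_score:
                best_score, best_params = mean, cfg
    final = make_estimator(grid.family, best_params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(x, y)
    return final, best_params, best_score


@dataclass
class ExperimentConfig:
    """Cartesian product of cells for one train->test direction."""

    direction: str = "Model-S"
    methods: tuple[str, ...] = ("RAW", "LOG", "QN", "LOG_RQN", "LOG_RQN_Z")
    tau_degs: tuple[float, ...] = (0.05,)
    tau_ndegs: tuple[float, ...] = (0.95,)
    families: tuple[str, ...] = ("SVM",)
    n_repeats: int = 5
    base_seed: int = 0
    frac: float = 0.75
    k_folds: int = 10
    fast: bool = False
    fdr: bool = False
    pseudo_count: float = 1.0


@dataclass
class CellResult:
    method: str
    tau_deg: float
    tau_ndeg: float
    family: str
    n_deg: int
    n_ndeg: int
    evaluation: RepeatedEvaluation
    chosen_params: list = field(default_factory=list)


def run_cell(
    train_x: ExpressionMatrix,
    test_x: ExpressionMatrix,
    labels: SubtypeLabels,
    method: str,
    tau_deg: float,
    tau_ndeg: float,
    family: str,
    grid: ClassifierGrid | None = None,
    n_repeats: int = 5,
    base_seed: int = 0,
    frac: float = 0.75,
    k_folds: int = 10,
    fast: bool = False,
    fdr: bool = False,
    pseudo_count: float = 1.0,
    selection: GeneSelection | None = None,
) -> CellResult:
    """Evaluate one experiment cell across repeated partitions.

    Gene selection uses the training platform's full labelled sample set and
    is computed once per cell (it does not depend on the repeat's draw).
    """
    spec = NormalizationSpec(method, pseudo_count=pseudo_count)
    grid = grid or ClassifierGrid.default(family, fast=fast)
    train_labels = labels.restrict(train_x.sample_ids)
    if selection is None:
        table = anova_table(train_x, train_labels, fdr=fdr)
        selection = select_genes(
            table, tau_deg, tau_ndeg, mode="q" if fdr else "p",
            require_ndeg=method in REFERENCE_METHODS,
        )
    if not selection.deg:
        raise DataError(f"no features: DEG set empty at tau_deg={tau_deg}")

    class_to_int = {c: i for i, c in enumerate(labels.class_order)}
    metric_sets, chosen = [], []
    for i in range(n_repeats):
        seed = base_seed + i
        plan = split_cross_platform(train_labels, test_x.sample_ids, frac=frac,
                                    seed=seed, repeat_index=i)
        plan = assign_folds(plan, labels, k=k_folds)

        tr_norm = normalize(train_x.subset_samples(plan.train_sample_ids), spec, selection)
        te_norm = normalize(test_x.subset_samples(plan.test_sample_ids), spec, selection)
        tr_deg = tr_norm.subset_genes(selection.deg)
        te_deg = te_norm.subset_genes(selection.deg)

        xtr = tr_deg.values.T
        ytr = np.array([class_to_int[c] for c in labels.y(plan.train_sample_ids)])
        folds = np.array([plan.fold_of[s] for s in plan.train_sample_ids])
        model, params, _ = tune_and_fit(xtr, ytr, folds, grid, seed)
        chosen.append(params)

        xte = te_deg.values.T
        yte = labels.y(plan.test_sample_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred_int = model.predict(xte)
            proba = _full_proba(model, xte, len(labels.class_order))
        ypred = np.array([labels.class_order[j] for j in pred_int], dtype=object)
        metric_sets.append(MetricSet.from_predictions(yte, ypred, proba, labels.class_order))
        logger.info(
            "cell %s tau=(%g,%g) %s repeat %d: kappa=%.3f BA=%.3f",
            method, tau_ndeg, tau_deg, family, i,
            metric_sets[-1].kappa, metric_sets[-1].balanced_accuracy,
        )
    return CellResult(
        method, tau_deg, tau_ndeg, family,
        len(selection.deg), len(selection.ndeg),
        RepeatedEvaluation.aggregate(metric_sets), chosen,
    )


def run_experiment(
    train_x: ExpressionMatrix,
    test_x: ExpressionMatrix,
    labels: SubtypeLabels,
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full Cartesian product of cells.

    Returns a per-repeat long-format table and an aggregate table (means,
    SDs, Evalue), both keyed by (direction, method, tau_ndeg, tau_deg,
    classifier).  ANOVA tables per tau pair are cached across methods.
    """
    train_labels = labels.restrict(train_x.sample_ids)
    table = anova_table(train_x, train_labels, fdr=config.fdr)
    mode = "q" if config.fdr else "p"

    repeat_rows, agg_rows = [], []
    for tau_ndeg in config.tau_ndegs:
        for tau_deg in config.tau_degs:
            sel = select_genes(table, tau_deg, tau_ndeg, mode=mode)
            for method in config.methods:
                if method in REFERENCE_METHODS and not sel.ndeg:
                    raise DataError(f"{method} needs NDEG but none at tau_ndeg={tau_ndeg}")
                for family in config.families:
                    logger.info("running cell: %s tau_ndeg=%g tau_deg=%g %s",
                                method, tau_ndeg, tau_deg, family)
                    res = run_cell(
                        train_x, test_x, labels, method, tau_deg, tau_ndeg, family,
                        n_repeats=config.n_repeats, base_seed=config.base_seed,
                        frac=config.frac, k_folds=config.k_folds, fast=config.fast,
                        pseudo_count=config.pseudo_count, selection=sel,
                    )
                    key = {
                        "direction": config.direction, "method": method,
                        "tau_ndeg": tau_ndeg, "tau_deg": tau_deg, "classifier": family,
                    }
                    for r, ms in enumerate(res.evaluation.repeats):
                        repeat_rows.append({**key, "repeat": r, **ms.as_dict()})
                    agg = dict(key)
                    agg.update({f"mean_{k}": v for k, v in res.evaluation.means.items()})
                    agg.update({f"sd_{k}": v for k, v in res.evaluation.sds.items()})
                    agg.update({
                        "evalue": res.evaluation.evalue,
                        "n_deg": res.n_deg, "n_ndeg": res.n_ndeg,
                    })
                    agg_rows.append(agg)
    return pd.DataFrame(repeat_rows), pd.DataFrame(agg_rows)
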