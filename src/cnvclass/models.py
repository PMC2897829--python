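"""Classifiers: published decision trees, trainable CART/forest, screen, evaluation.

The five published trees are the fixed rule sets reported for glioblastoma
training data under three segmentations (smoothed CBS, GLAD, unsmoothed CBS;
full predictor set or Database score alone).  They are hard-coded here so the
rules can be applied to any feature matrix without refitting.  Threshold
conventions: "at least" / "or more" splits are inclusive; "shorter than" /
"longer than" / "more than" / "less than" splits are strict; feature values
falling on no enumerated CNV path predict CNA.

Trainable counterparts use scikit-learn: CART is a Gini tree cost-complexity
pruned by 10-fold cross-validation under the 1-SE rule; the forest is a
standard bootstrap ensemble with sqrt-subset splits and total-Gini-decrease
importances.  The univariate screen fits one logistic regression per predictor
(statsmodels) with likelihood-ratio p-values.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .calling import CandidateCNV
from .genome_io import DGVRecord, ValidationError
from .truth_labeling import CNA, CNV

log = logging.getLogger(__name__)

PUBLISHED_TREES = (
    "cbs_smoothed_full",
    "glad_full",
    "cbs_unsmoothed_full",
    "cbs_smoothed_dgv_only",
    "glad_dgv_only",
)

_REQUIRED_FEATURES = {
    "cbs_smoothed_full": ("database_score", "length_bp"),
    "glad_full": ("database_score", "relative_height"),
    "cbs_unsmoothed_full": ("database_score", "length_bp", "matching_bkpt_pct"),
    "cbs_smoothed_dgv_only": ("database_score",),
    "glad_dgv_only": ("database_score",),
}


def predict_published_tree(
    fv: Mapping[str, float],
    tree: str,
    overlap_feature: str = "overlap_pct",
) -> str:
    """Classify one feature vector with a published tree; returns "CNV" or "CNA".

    ``overlap_feature`` selects which predictor stands behind the smoothed-CBS
    tree's "matching candidate segments in other patients" split and the GLAD
    tree's cohort-overlap split (default the overlap percentage; rebind to
    ``matching_bkpt_pct`` if preferred).
    """
    if tree not in PUBLISHED_TREES:
        raise ValidationError(f"unknown published tree {tree!r}; choose from {PUBLISHED_TREES}")
    required = _REQUIRED_FEATURES[tree] + (
        (overlap_feature,) if tree in ("cbs_smoothed_full", "glad_full") else ()
    )
    missing = [f for f in required if f not in fv or fv[f] is None or (
        isinstance(fv[f], float) and np.isnan(fv[f]))]
    if missing:
        raise ValidationError(f"tree {tree}: feature vector missing {missing}")

    ds = float(fv["database_score"])
    if tree == "cbs_smoothed_dgv_only":
        return CNV if ds >= 2.45 else CNA
    if tree == "glad_dgv_only":
        return CNV if ds >= 3.0 else CNA

    if tree == "cbs_smoothed_full":
        if ds >= 2.45:
            return CNV
        length = float(fv["length_bp"])
        if length < 30_000:
            return CNV
        if float(fv[overlap_feature]) >= 0.37:
            return CNV
        return CNA

    if tree == "glad_full":
        rel = float(fv["relative_height"])
        overlap = float(fv[overlap_feature])
        if ds >= 3.0 and rel > 1.5:
            return CNV
        if ds < 3.0 and overlap >= 0.38:
            return CNV
        return CNA

    # cbs_unsmoothed_full
    mb = float(fv["matching_bkpt_pct"])
    length = float(fv["length_bp"])
    if mb > 0.012:
        if length < 396_000:
            return CNV
        if length > 396_000 and ds >= 4.5:
            return CNV
        return CNA
    if mb < 0.012:
        if length < 22_000:
            return CNV
        if length < 77_000 and ds >= 1.3:
            return CNV
        if length > 77_000 and ds >= 3.1:
            return CNV
    return CNA


def predict_published_tree_frame(
    features: pd.DataFrame, tree: str, overlap_feature: str = "overlap_pct"
) -> np.ndarray:
    return np.array(
        [predict_published_tree(row, tree, overlap_feature)
         for row in features.to_dict("records")],
        dtype=object,
    )


def adhoc_dgv_rule(candidate: CandidateCNV, dgv: Sequence[DGVRecord]) -> str:
    """Literature rule of thumb: CNV iff overlapping variants from >= 2 distinct studies."""
    studies = {
        rec.study_id
        for rec in dgv
        if rec.chromosome == candidate.chromosome
        and rec.start < candidate.end
        and candidate.start < rec.end
    }
    return CNV if len(studies) >= 2 else CNA


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ConfusionCounts:
    """CNV is the positive class throughout."""

    tn: int
    fn: int
    fp: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fn + self.fp + self.tp


@dataclass
class EvaluationReport:
    counts: ConfusionCounts
    accuracy: float
    sensitivity_std: float  # tp / (tp + fn): recall on true CNVs
    specificity_std: float  # tn / (tn + fp): recall on true CNAs
    ppv: float  # tp / (tp + fp)
    npv: float  # tn / (tn + fn)
    per_tumor_accuracies: dict[str, float] = field(default_factory=dict)
    per_tumor_median: float = float("nan")

    @classmethod
    def from_counts(cls, counts: ConfusionCounts) -> "EvaluationReport":
        """Pooled metrics from confusion counts alone (no per-tumor breakdown)."""
        def safe(a, b):
            return a / b if b else float("nan")

        return cls(
            counts=counts,
            accuracy=safe(counts.tn + counts.tp, counts.total),
            sensitivity_std=safe(counts.tp, counts.tp + counts.fn),
            specificity_std=safe(counts.tn, counts.tn + counts.fp),
            ppv=safe(counts.tp, counts.tp + counts.fp),
            npv=safe(counts.tn, counts.tn + counts.fn),
        )


def evaluate(
    predictions: Sequence[str],
    truths: Sequence[str],
    sample_ids: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Pooled confusion counts and accuracies, plus per-tumor accuracy if ids given."""
    if len(predictions) == 0:
        raise ValidationError("evaluate: empty input")
    if len(predictions) != len(truths):
        raise ValidationError("evaluate: predictions and truths differ in length")
    pred = np.asarray(predictions, dtype=object)
    true = np.asarray(truths, dtype=object)
    counts = ConfusionCounts(
        tn=int(np.sum((pred == CNA) & (true == CNA))),
        fn=int(np.sum((pred == CNA) & (true == CNV))),
        fp=int(np.sum((pred == CNV) & (true == CNA))),
        tp=int(np.sum((pred == CNV) & (true == CNV))),
    )
    report = EvaluationReport.from_counts(counts)
    if sample_ids is not None:
        sids = np.asarray(sample_ids, dtype=object)
        per = {}
        for s in pd.unique(sids):
            mask = sids == s
            per[str(s)] = float(np.mean(pred[mask] == true[mask]))
        report.per_tumor_accuracies = per
        report.per_tumor_median = float(np.median(list(per.values())))
    return report


# ---------------------------------------------------------------------------
# trainable models


def _validate_training(y: np.ndarray):
    classes = set(y)
    if len(classes) < 2:
        raise ValidationError(f"training requires both classes; got only {classes}")


@dataclass
class CartModel:
    """A pruned classification tree with readable split structure."""

    tree: DecisionTreeClassifier
    feature_names: list[str]
    ccp_alpha: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.tree.predict(X[self.feature_names].to_numpy(dtype=float))

    @property
    def root_feature(self) -> Optional[str]:
        t = self.tree.tree_
        if t.node_count == 0 or t.children_left[0] == -1:
            return None
        return self.feature_names[t.feature[0]]

    def describe(self) -> str:
        from sklearn.tree import export_text

        return export_text(self.tree, feature_names=self.feature_names)


def train_cart(
    features: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    min_samples_leaf: int = 5,
    cv_folds: int = 10,
) -> CartModel:
    """Gini tree, cost-complexity pruned by cross-validated 1-SE rule.

    The pruning strength is the largest complexity penalty whose mean CV error
    is within one standard error of the minimum, i.e. the smallest adequate
    tree.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=object)
    _validate_training(y)
    base = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=min_samples_leaf, random_state=seed
    )
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))

    folds = min(cv_folds, int(np.min(np.unique(y, return_counts=True)[1])))
    if folds < 2:
        raise ValidationError("too few examples of one class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = np.zeros((len(alphas), folds))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        for a, alpha in enumerate(alphas):
            clf = DecisionTreeClassifier(
                criterion="gini",
                min_samples_leaf=min_samples_leaf,
                random_state=seed,
                ccp_alpha=alpha,
            ).fit(X[tr], y[tr])
            errors[a, f] = np.mean(clf.predict(X[te]) != y[te])
    mean_err = errors.mean(axis=1)
    se = errors.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_err))
    threshold = mean_err[best] + se[best]
    chosen = alphas[np.flatnonzero(mean_err <= threshold)[-1]]

    final = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
        ccp_alpha=chosen,
    ).fit(X, y)
    return CartModel(tree=final, feature_names=list(features.columns), ccp_alpha=float(chosen))


@dataclass
class ForestModel:
    forest: RandomForestClassifier
    feature_names: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(X[self.feature_names].to_numpy(dtype=float))

    @property
    def importances(self) -> pd.Series:
        """Per-feature mean decrease in Gini impurity, descending."""
        return pd.Series(
            self.forest.feature_importances_, index=self.feature_names
        ).sort_values(ascending=False)


def train_rf(
    features: pd.DataFrame,
    labels: Sequence[str],
    n_trees: int = 500,
    seed: int = 0,
    min_samples_leaf: int = 1,
) -> ForestModel:
    """Bootstrap forest with sqrt-feature splits and Gini importances."""
    y = np.asarray(labels, dtype=object)
    _validate_training(y)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    ).fit(features.to_numpy(dtype=float), y)
    return ForestModel(forest=forest, feature_names=list(features.columns))


def univariate_screen(features: pd.DataFrame, labels: Sequence[str]) -> pd.DataFrame:
    """One single-predictor logistic regression per feature.

    Multi-level string/categorical columns are expanded to indicator contrasts
    (baseline is ``None`` when present, else the first level) and share one
    likelihood-ratio p-value.  Non-convergence (e.g. perfect separation) is
    flagged, not raised; constant features get p = 1.
    """
    import statsmodels.api as sm

    y = (np.asarray(labels, dtype=object) == CNV).astype(float)
    rows = []
    for col in features.columns:
        series = features[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            levels = list(pd.unique(series))
            baseline = "None" if "None" in levels else levels[0]
            contrasts = [lv for lv in levels if lv != baseline]
            X = pd.DataFrame({f"{col}[{lv}]": (series == lv).astype(float) for lv in contrasts})
        else:
            X = pd.DataFrame({col: series.astype(float)})

        if X.shape[1] == 0 or (X.nunique() <= 1).all():
            rows.append(
                {"feature": col, "level": "", "beta": np.nan, "p_value": 1.0,
                 "converged": False, "note": "constant"}
            )
            continue

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True)) and np.isfinite(
                fit.params
            ).all()
            p = float(fit.llr_pvalue)
            params = fit.params.iloc[1:]
        except Exception as exc:  # separation / singular designs
            log.info("univariate fit failed for %s: %s", col, exc)
            converged, p, params = False, np.nan, pd.Series(np.nan, index=X.columns)
        for name, beta in params.items():
            level = name[len(col) + 1 : -1] if name.startswith(f"{col}[") else ""
            rows.append(
                {"feature": col, "level": level, "beta": float(beta), "p_value": p,
                 "converged": converged, "note": "" if converged else "non-convergence"}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# text serialization


def _tree_to_dict(tree: DecisionTreeClassifier, class_names=None) -> dict:
    # Forest sub-estimators see integer-encoded labels; the caller supplies the
    # decoded class names in matching column order.
    t = tree.tree_
    names = tree.classes_ if class_names is None else class_names
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value.tolist(),
        "classes": [str(c) for c in names],
        "n_features": int(tree.n_features_in_),
    }


class _FrozenTree:
    """Predict-only tree reconstructed from its explicit split lists."""

    def __init__(self, d: dict):
        self.left = d["children_left"]
        self.right = d["children_right"]
        self.feature = d["feature"]
        self.threshold = d["threshold"]
        self.value = d["value"]
        self.classes_ = np.array(d["classes"], dtype=object)

    def predict_row(self, x) -> str:
        node = 0
        while self.left[node] != -1:
            node = (
                self.left[node]
                if x[self.feature[node]] <= self.threshold[node]
                else self.right[node]
            )
        return str(self.classes_[int(np.argmax(self.value[node][0]))])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.predict_row(row) for row in X], dtype=object)


@dataclass
class FrozenModel:
    """A saved CART/forest in self-describing text form (splits listed explicitly)."""

    kind: str  # "cart" or "forest"
    feature_names: list[str]
    trees: list[_FrozenTree]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        arr = X[self.feature_names].to_numpy(dtype=float)
        if self.kind == "cart":
            return self.trees[0].predict(arr)
        votes = np.stack([t.predict(arr) for t in self.trees])
        out = []
        for j in range(arr.shape[0]):
            vals, counts = np.unique(votes[:, j], return_counts=True)
            out.append(vals[np.argmax(counts)])
        return np.array(out, dtype=object)


def save_model(model, path) -> None:
    if isinstance(model, CartModel):
        payload = {
            "format": "cnvclass-model/1",
            "kind": "cart",
            "feature_names": model.feature_names,
            "ccp_alpha": model.ccp_alpha,
            "trees": [_tree_to_dict(model.tree)],
        }
    elif isinstance(model, ForestModel):
        payload = {
            "format": "cnvclass-model/1",
            "kind": "forest",
            "feature_names": model.feature_names,
            "trees": [
                _tree_to_dict(est, model.forest.classes_)
                for est in model.forest.estimators_
            ],
        }
    else:
        raise ValidationError(f"cannot serialize model of type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> FrozenModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "cnvclass-model/1":
        raise ValidationError(f"{path}: not a recognised model file")
    return FrozenModel(
        kind=payload["kind"],
        feature_names=payload["feature_names"],
        trees=[_FrozenTree(d) for d in payload["trees"]],
    )
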