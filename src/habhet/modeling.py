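"""Staged feature selection, the seven-classifier suite, and evaluation.

Selection runs in three steps on the training split only:

1. reproducibility: drop features whose intra- or inter-observer ICC(2,1)
   under repeated segmentations falls below 0.800;
2. univariate screen: per feature, Shapiro-Wilk normality in both classes
   gates a Student t test vs a Mann-Whitney U test; keep P < .05 (no
   multiplicity correction);
3. importance: a single Gini decision tree ranks the survivors; keep the
   top 20 (ties broken by canonical name order).

Seven probabilistic classifiers (logistic regression, random forest,
decision tree, SVM, AdaBoost, k-NN, and a small MLP standing as the deep
neural network) are fitted on the selected features; evaluation reports AUC,
confusion-matrix metrics at the Youden-optimal training threshold (frozen
across splits), and a 10-bin expected calibration error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .heterogeneity import icc_2_1

logger = logging.getLogger(__name__)

ALGORITHMS = ("LG", "RF", "DT", "SVM", "Ada", "KNN", "DNN")
ICC_THRESHOLD = 0.800
ALPHA = 0.05
TOP_K = 20


# ---------------------------------------------------------------------------
# split

def stratified_split(
    labels: pd.Series,
    ratio: float = 0.7,
    seed: int = 0,
) -> pd.Series:
    """Assign ``train`` / ``test`` split labels, stratified by class.

    The test set receives ``ceil((1 - ratio) * N)`` cases, allocated across
    classes by largest remainder so class proportions are preserved as
    closely as integer counts allow. Deterministic given the seed.
    """
    y = pd.Series(labels)
    counts = y.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    n = len(y)
    # test size ceil((1-ratio)*n), guarded against float representation of the
    # ratio (e.g. 1-0.7) tipping an exact multiple over the next integer
    n_test = n - math.floor(ratio * n + 1e-9)

    classes = sorted(counts.index)
    exact = {c: (1.0 - ratio) * counts[c] for c in classes}
    base = {c: int(math.floor(exact[c])) for c in classes}
    short = n_test - sum(base.values())
    # distribute the remainder to the largest fractional parts
    for c in sorted(classes, key=lambda c: (-(exact[c] - base[c]), c))[:short]:
        base[c] += 1

    rng = np.random.default_rng(seed)
    assignment = pd.Series("train", index=y.index, name="split")
    for c in classes:
        members = y.index[y == c].to_numpy()
        picked = rng.permutation(members)[: base[c]]
        assignment.loc[picked] = "test"
    return assignment


# ---------------------------------------------------------------------------
# selection

def icc_filter(
    rating_sets: dict[str, list[pd.DataFrame]],
    threshold: float = ICC_THRESHOLD,
) -> tuple[list[str], pd.DataFrame]:
    """Step 1: keep features reproducible under repeated segmentations.

    Parameters
    ----------
    rating_sets : dict
        e.g. ``{"intra": [df_a1, df_a2], "inter": [df_a1, df_b]}`` where each
        DataFrame is cases x features computed from one mask variant. A
        feature is retained only if its ICC(2,1) is >= threshold in every
        rating set.

    Returns
    -------
    (retained names, per-feature ICC table)
    """
    iccs: dict[str, pd.Series] = {}
    for name, dfs in rating_sets.items():
        if len(dfs) < 2:
            raise ValueError(f"ICC requires repeats: rating set {name!r} has {len(dfs)}")
        cols = dfs[0].columns
        data = np.stack([d[cols].to_numpy() for d in dfs], axis=1)
        vals = np.full(len(cols), np.nan)
        finite = np.isfinite(data).all(axis=1)
        for fi in range(len(cols)):
            sub = data[finite[:, fi], :, fi]
            if sub.shape[0] >= 2 and np.ptp(sub) > 0:
                vals[fi] = icc_2_1(sub)
        iccs[name] = pd.Series(vals, index=cols)
    table = pd.DataFrame(iccs)
    keep = table.index[(table >= threshold).all(axis=1)].tolist()
    return keep, table


def univariate_filter(
    features: pd.DataFrame,
    labels: pd.Series,
    alpha: float = ALPHA,
) -> tuple[list[str], pd.Series]:
    """Step 2: class-difference screen, t test or Mann-Whitney per normality.

    Returns the retained names and the per-feature P values. Constant
    features are excluded with a logged reason.
    """
    y = np.asarray(labels).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("both classes need >= 3 cases")
    pvals: dict[str, float] = {}
    for col in features.columns:
        v = features[col].to_numpy(np.float64)
        ok = np.isfinite(v)
        a, b = v[ok & (y == 0)], v[ok & (y == 1)]
        if len(a) < 3 or len(b) < 3 or (np.ptp(v[ok]) == 0):
            logger.debug("feature %s excluded: constant or too few finite values", col)
            pvals[col] = np.nan
            continue
        normal = True
        for g in (a, b):
            if np.ptp(g) == 0:
                normal = False
                break
            if stats.shapiro(g if len(g) <= 5000 else g[:5000]).pvalue < ALPHA:
                normal = False
                break
        if normal:
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        pvals[col] = float(p)
    pser = pd.Series(pvals)
    keep = pser.index[pser < alpha].tolist()
    return keep, pser


def tree_topk(
    features: pd.DataFrame,
    labels: pd.Series,
    k: int = TOP_K,
    seed: int = 0,
    tiebreak: pd.Series | None = None,
) -> list[str]:
    """Step 3: top-k features by Gini impurity reduction of a decision tree.

    A single tree assigns nonzero importance only to features it actually
    splits on; on small cohorts that can be far fewer than k. Ties (notably
    the zero-importance mass) are therefore broken by ``tiebreak``
    (ascending; typically the univariate P values from step 2) and then by
    canonical name order, so the deterministic fill is evidence-ranked
    rather than alphabetical.
    """
    cols = list(features.columns)
    if len(cols) <= k:
        if len(cols) < k:
            logger.warning("only %d features available for top-%d selection", len(cols), k)
        return sorted(cols)
    X = features.to_numpy(np.float64)
    tree = DecisionTreeClassifier(criterion="gini", random_state=seed)
    tree.fit(X, np.asarray(labels).astype(int))
    imp = tree.feature_importances_
    tb = (tiebreak.reindex(cols).fillna(np.inf) if tiebreak is not None
          else pd.Series(0.0, index=cols))
    order = sorted(range(len(cols)), key=lambda i: (-imp[i], tb.iloc[i], cols[i]))
    return [cols[i] for i in order[:k]]


@dataclass
class SelectionReport:
    """Counts and names surviving each selection step."""

    n_input: int
    n_after_icc: int
    n_after_univariate: int
    n_final: int
    retained: list[str]
    icc_table: pd.DataFrame | None = None
    p_values: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_icc": self.n_after_icc,
            "n_after_univariate": self.n_after_univariate,
            "n_final": self.n_final,
            "retained": list(self.retained),
        }


def select_features(
    features: pd.DataFrame,
    labels: pd.Series,
    rating_sets: dict[str, list[pd.DataFrame]] | None = None,
    icc_threshold: float = ICC_THRESHOLD,
    alpha: float = ALPHA,
    top_k: int = TOP_K,
    seed: int = 0,
) -> SelectionReport:
    """Run the three selection steps on training data."""
    cols = list(features.columns)
    icc_table = None
    if rating_sets is not None:
        keep1, icc_table = icc_filter(rating_sets, icc_threshold)
        keep1 = [c for c in cols if c in set(keep1)]
    else:  # no repeated segmentations supplied: step 1 passes everything
        keep1 = cols
    keep2, pvals = univariate_filter(features[keep1], labels, alpha)
    final = tree_topk(features[keep2], labels, top_k, seed,
                      tiebreak=pvals) if keep2 else []
    report = SelectionReport(
        n_input=len(cols),
        n_after_icc=len(keep1),
        n_after_univariate=len(keep2),
        n_final=len(final),
        retained=final,
        icc_table=icc_table,
        p_values=pvals,
    )
    assert report.n_input >= report.n_after_icc >= report.n_after_univariate >= report.n_final
    return report


# ---------------------------------------------------------------------------
# model suite

def _make_estimator(algo: str, seed: int):
    if algo == "LG":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if algo == "RF":
        return RandomForestClassifier(random_state=seed)
    if algo == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if algo == "SVM":
        return SVC(probability=True, random_state=seed)
    if algo == "Ada":
        return AdaBoostClassifier(random_state=seed)
    if algo == "KNN":
        return KNeighborsClassifier()
    if algo == "DNN":
        # small MLP: 20-ish inputs, a few hundred cases; L2 + early stopping
        return MLPClassifier(
            hidden_layer_sizes=(64, 32),
            activation="relu",
            alpha=1e-2,
            early_stopping=True,
            validation_fraction=0.2,
            n_iter_no_change=20,
            max_iter=1000,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algo!r}")


@dataclass
class ModelSuite:
    """Classifier suite fitted on train-split statistics only.

    Imputation (train median) and standardization (train mean/SD) are frozen
    at fit time and re-applied verbatim to any evaluation split, so no test
    information leaks into preprocessing.
    """

    feature_names: list[str]
    seed: int = 0
    algorithms: tuple[str, ...] = ALGORITHMS
    models: dict = field(default_factory=dict)
    medians_: pd.Series | None = None
    mu_: np.ndarray | None = None
    sd_: np.ndarray | None = None
    thresholds_: dict = field(default_factory=dict)

    def _prepare(self, features: pd.DataFrame, fit: bool) -> np.ndarray:
        X = features[self.feature_names].copy()
        if fit:
            self.medians_ = X.median()
        X = X.fillna(self.medians_)
        arr = X.to_numpy(np.float64)
        if fit:
            self.mu_ = arr.mean(axis=0)
            sd = arr.std(axis=0)
            self.sd_ = np.where(sd > 0, sd, 1.0)
        arr = (arr - self.mu_) / self.sd_
        if not np.isfinite(arr).all():
            raise ValueError("non-finite feature values after imputation")
        return arr

    def fit(self, features: pd.DataFrame, labels: pd.Series) -> "ModelSuite":
        X = self._prepare(features, fit=True)
        y = np.asarray(labels).astype(int)
        for algo in self.algorithms:
            est = _make_estimator(algo, self.seed)
            if algo == "DNN" and len(y) < 60:
                # a 20% validation split of a few dozen cases cannot steer
                # early stopping; train for a fixed budget instead
                est.set_params(early_stopping=False, max_iter=300)
            est.fit(X, y)
            self.models[algo] = est
            # Youden-optimal operating point on the training ROC, frozen
            prob = est.predict_proba(X)[:, 1]
            fpr, tpr, thr = roc_curve(y, prob)
            self.thresholds_[algo] = float(thr[np.argmax(tpr - fpr)])
        return self

    def predict_proba(self, algo: str, features: pd.DataFrame) -> np.ndarray:
        X = self._prepare(features, fit=False)
        return self.models[algo].predict_proba(X)[:, 1]


def expected_calibration_error(y: np.ndarray, prob: np.ndarray, n_bins: int = 10) -> float:
    """ECE over equal-width probability bins: sum of |accuracy - confidence|
    gaps weighted by bin occupancy."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(prob, edges[1:-1]), 0, n_bins - 1)
    ece = 0.0
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            ece += sel.mean() * abs(y[sel].mean() - prob[sel].mean())
    return float(ece)


@dataclass
class ModelReport:
    """Evaluation of one model on one split."""

    algo: str
    auc: float
    threshold: float
    confusion: tuple[int, int, int, int]  # tn, fp, fn, tp
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    calibration_error: float
    roc_points: tuple[np.ndarray, np.ndarray]

    def to_dict(self) -> dict:
        tn, fp, fn, tp = self.confusion
        return {
            "algo": self.algo, "auc": self.auc, "threshold": self.threshold,
            "tn": tn, "fp": fp, "fn": fn, "tp": tp,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "calibration_error": self.calibration_error,
        }


def evaluate(
    suite: ModelSuite,
    algo: str,
    features: pd.DataFrame,
    labels: pd.Series,
) -> ModelReport:
    """Evaluate one fitted model on a split with the frozen training threshold."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined on a single-class split")
    prob = suite.predict_proba(algo, features)
    auc = float(roc_auc_score(y, prob))
    thr = suite.thresholds_[algo]
    pred = (prob >= thr).astype(int)
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    acc = (tp + tn) / len(y)
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else np.nan
    fpr, tpr, _ = roc_curve(y, prob)
    return ModelReport(
        algo=algo, auc=auc, threshold=thr,
        confusion=(int(tn), int(fp), int(fn), int(tp)),
        sensitivity=float(sens), specificity=float(spec), accuracy=float(acc),
        precision=float(prec), recall=float(sens), f1=float(f1),
        calibration_error=expected_calibration_error(y, prob),
        roc_points=(fpr, tpr),
    )


def metrics_from_confusion(tn: int, fp: int, fn: int, tp: int) -> dict[str, float]:
    """Confusion-matrix summary metrics (fractions, not percentages)."""
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp else float("nan")
    acc = (tp + tn) / (tn + fp + fn + tp)
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else float("nan")
    return {
        "sensitivity": sens, "specificity": spec, "accuracy": acc,
        "precision": prec, "recall": sens, "f1": f1,
    }
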