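"""Cause classification: stepwise selection, classifier menu, cross-validation.

Each of the four causes of a hazardous driver state is classified as
present/absent from any combination of the three feature sets (physiology,
driver characteristics, vehicle kinematics).  Before a classifier is
trained, stepwise forward feature selection with a partial F-test
(entry threshold p < 0.05, escalated to 0.1 when nothing enters) reduces
the candidate set.  Accuracy is estimated by leave-one-out
cross-validation with selection refit inside every training fold, so no
selection information leaks from the held-out sample; selection on the
full table (used for reported entry p-values, and optionally for the
optimistic "outside" validation variant) is also available.

The augmented scheme appends the other three causes' true presence bits
as extra candidate features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .design import CAUSES, WITHIN_SESSION_CAUSES
from .features import ALL_FEATURES, FEATURE_SETS
from .normalization import impute_session_median

P_ENTER = 0.05
P_FALLBACK = 0.10

#: Max number of split nodes per tree-complexity level.
TREE_MAX_SPLITS = {"simple": 4, "medium": 20, "complex": 100}

#: Table-3 ordering of the seven nonempty feature-set combinations.
FEATURE_SET_COMBOS = tuple(
    combo for r in (1, 2, 3)
    for combo in combinations(("physio", "characteristics", "kinematics"), r)
)


# ---------------------------------------------------------------------------
# Classifier menu
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its hyperparameters.

    ``kernel`` applies only to SVMs; ``tree_complexity`` only to (boosted)
    decision trees.
    """

    family: str                       # svm | logistic | tree | boosted_tree
    kernel: str | None = None         # linear | quadratic | gaussian_medium
    tree_complexity: str | None = None  # simple | medium | complex
    C: float = 1.0
    n_estimators: int = 30

    def __post_init__(self):
        if self.family not in ("svm", "logistic", "tree", "boosted_tree"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if (self.kernel is not None) != (self.family == "svm"):
            raise ValueError("kernel must be set iff family is 'svm'")
        tree_family = self.family in ("tree", "boosted_tree")
        if (self.tree_complexity is not None) != tree_family:
            raise ValueError("tree_complexity must be set iff family involves trees")
        if self.family == "svm" and self.kernel not in (
                "linear", "quadratic", "gaussian_medium"):
            raise ValueError(f"unknown SVM kernel {self.kernel!r}")
        if tree_family and self.tree_complexity not in TREE_MAX_SPLITS:
            raise ValueError(f"unknown tree complexity {self.tree_complexity!r}")

    @property
    def label(self) -> str:
        if self.family == "svm":
            return {"linear": "SVM linear kernel", "quadratic": "SVM quadratic kernel",
                    "gaussian_medium": "SVM medium Gaussian kernel"}[self.kernel]
        if self.family == "logistic":
            return "LR"
        if self.family == "tree":
            return f"DT ({self.tree_complexity})"
        return "Ensemble boosted DT"


def default_menu() -> list[ClassifierSpec]:
    """The classifier menu: three SVM kernels, logistic regression, three
    decision-tree complexities, and a boosted decision-tree ensemble."""
    return [
        ClassifierSpec("svm", kernel="linear"),
        ClassifierSpec("svm", kernel="quadratic"),
        ClassifierSpec("svm", kernel="gaussian_medium"),
        ClassifierSpec("logistic"),
        ClassifierSpec("tree", tree_complexity="simple"),
        ClassifierSpec("tree", tree_complexity="medium"),
        ClassifierSpec("tree", tree_complexity="complex"),
        ClassifierSpec("boosted_tree", tree_complexity="medium"),
    ]


def build_estimator(spec: ClassifierSpec, n_features: int, seed: int = 0):
    if spec.family == "svm":
        if spec.kernel == "linear":
            return SVC(kernel="linear", C=spec.C)
        if spec.kernel == "quadratic":
            return SVC(kernel="poly", degree=2, coef0=1.0, C=spec.C)
        # "medium" Gaussian: kernel scale sqrt(p)  =>  gamma = 1/p
        return SVC(kernel="rbf", C=spec.C, gamma=1.0 / max(n_features, 1))
    if spec.family == "logistic":
        return LogisticRegression(C=np.inf, max_iter=2000)
    if spec.family == "tree":
        return DecisionTreeClassifier(
            max_leaf_nodes=TREE_MAX_SPLITS[spec.tree_complexity] + 1,
            random_state=seed)
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=3),
        n_estimators=spec.n_estimators, random_state=seed)


def fit_predict(spec: ClassifierSpec, X_train, y_train, X_test, seed: int = 0
                ) -> np.ndarray:
    """Train one classifier and predict the test labels.

    Logistic regression follows the 0.5-output decision rule, with an
    output of exactly 0.5 assigned to the positive class.
    """
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train, int)
    est = build_estimator(spec, X_train.shape[1], seed)
    # class-balanced sample weights: the factorial design is balanced by
    # construction, so the training prior must not tilt with the held-out
    # sample (unchecked, that tilt drives leave-one-out below chance on
    # effect-free data)
    classes, counts = np.unique(y_train, return_counts=True)
    wmap = {c: y_train.size / (len(classes) * k) for c, k in zip(classes, counts)}
    sw = np.array([wmap[c] for c in y_train])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X_train, y_train, sample_weight=sw)
        if spec.family == "logistic":
            proba = est.predict_proba(X_test)[:, list(est.classes_).index(1)]
            return (proba >= 0.5).astype(int)
        return est.predict(X_test)


# ---------------------------------------------------------------------------
# Stepwise forward selection (partial F-test on nested linear models)
# ---------------------------------------------------------------------------

def stepwise_select(X, y, p_enter: float = P_ENTER, p_fallback: float = P_FALLBACK,
                    guarantee_nonempty: bool = False
                    ) -> tuple[list[int], list[float]]:
    """Greedy forward selection by partial F-test on nested linear models.

    At each step the candidate whose addition to the current linear model of
    ``y`` gives the smallest partial-F p-value enters, if p < the threshold;
    ties break toward the lower column index.  If the first step admits
    nothing at ``p_enter`` the whole run is retried at ``p_fallback``.  With
    ``guarantee_nonempty`` the single best candidate is returned when even
    the fallback threshold admits nothing.

    Returns (ordered column indices, entry p-values).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.unique(y).size < 2:
        raise ValueError("single-class labels")
    scale = np.sum((X - X.mean(axis=0)) ** 2, axis=0)

    def run(threshold: float) -> tuple[list[int], list[float]]:
        yr = y - y.mean()
        C = X - X.mean(axis=0)
        avail = np.ones(p, dtype=bool)
        selected: list[int] = []
        pvals: list[float] = []
        while True:
            df = n - len(selected) - 2
            if df <= 0 or not avail.any():
                break
            c2 = np.einsum("ij,ij->j", C, C)
            valid = avail & (c2 > 1e-10 * np.maximum(scale, 1e-30)) & (scale > 0)
            if not valid.any():
                break
            rss = float(yr @ yr)
            proj = C.T @ yr
            with np.errstate(divide="ignore", invalid="ignore"):
                red = np.where(valid, proj ** 2 / c2, 0.0)
            rss_new = np.maximum(rss - red, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = np.where(rss_new > 0, red / (rss_new / df), np.inf)
            pv = np.where(valid, stats.f.sf(F, 1, df), np.inf)
            j = int(np.argmin(pv))  # argmin takes the first (lowest index) on ties
            if not np.isfinite(pv[j]) or pv[j] >= threshold:
                break
            selected.append(j)
            pvals.append(float(pv[j]))
            q = C[:, j] / np.sqrt(c2[j])
            yr = yr - q * (q @ yr)
            C = C - np.outer(q, q @ C)
            avail[j] = False
        return selected, pvals

    selected, pvals = run(p_enter)
    if not selected and p_fallback > p_enter:
        selected, pvals = run(p_fallback)
    if not selected and guarantee_nonempty:
        selected, pvals = run(np.inf)
        selected, pvals = selected[:1], pvals[:1]
    return selected, pvals


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _folds(n: int, groups=None) -> list[tuple[np.ndarray, np.ndarray]]:
    idx = np.arange(n)
    if groups is None:
        return [(np.delete(idx, i), np.array([i])) for i in idx]
    groups = np.asarray(groups)
    return [(idx[groups != g], idx[groups == g]) for g in np.unique(groups)]


def fold_selections(X, y, folds, **kw) -> list[list[int]]:
    """Stepwise selection refit on every training fold (shared across the
    classifier menu, since selection does not depend on the classifier).

    A fold's selection may be empty: no candidate passed the entry
    thresholds, so that fold has no model and the prediction falls back to
    the tie rule.  (Forcing a best single feature instead makes near-tied
    noise candidates flip with the held-out sample, which systematically
    selects against it and drags effect-free accuracy far below chance.)
    """
    out = []
    for train, _ in folds:
        sel, _ = stepwise_select(X[train], y[train], **kw)
        out.append(sel)
    return out


def loocv(spec: ClassifierSpec, X, y, groups=None, seed: int = 0,
          selection: str = "inside", selections=None) -> float:
    """Leave-one-out (or leave-one-group-out) cross-validated accuracy.

    ``selection='inside'`` refits stepwise selection within each training
    fold (no leakage); ``'outside'`` selects once on the full data — the
    optimistic variant.  Precomputed per-fold ``selections`` may be passed
    to amortise selection across a classifier menu.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples for cross-validation")
    folds = _folds(X.shape[0], groups)
    if selections is None:
        if selection == "outside":
            sel, _ = stepwise_select(X, y, guarantee_nonempty=True)
            selections = [sel] * len(folds)
        else:
            selections = fold_selections(X, y, folds)
    correct = 0
    total = 0
    for (train, test), sel in zip(folds, selections):
        if len(sel) == 0:
            # no feature entered: featureless model at a balanced prior
            # falls to the tie rule (positive class)
            pred = np.ones(len(test), dtype=int)
        else:
            pred = fit_predict(spec, X[np.ix_(train, sel)], y[train],
                               X[np.ix_(test, sel)], seed=seed)
        correct += int(np.sum(pred == y[test]))
        total += len(test)
    return correct / total


# ---------------------------------------------------------------------------
# The experiment matrix
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Outcome of one (cause, feature-set combination, scheme) cell."""

    cause: str
    feature_sets: tuple[str, ...]
    scheme: str
    accuracy: float                      # NaN when not classifiable
    selected_features: list[str]
    p_values: list[float]
    best_spec: ClassifierSpec | None
    accuracies: dict[str, float] = field(default_factory=dict)
    note: str = ""


def _session_varying(table: pd.DataFrame, feature_names) -> set[str]:
    nun = table.groupby(["participant", "session"])[list(feature_names)].nunique()
    return set(nun.columns[(nun > 1).any()])


def prepare_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Impute missing feature values with the session median (global median
    then scale centre as fallbacks) ahead of selection."""
    return impute_session_median(table)


def run_matrix(table: pd.DataFrame, scheme: str = "independent",
               menu: list[ClassifierSpec] | None = None, cv: str = "loo",
               seed: int = 0, causes=CAUSES, combos=FEATURE_SET_COMBOS,
               selection: str = "inside") -> list[RunResult]:
    """Cross-validate every cause x feature-set-combination cell.

    For each cell, stepwise selection + every classifier in the menu are
    evaluated by leave-one-out (``cv='loo'``) or leave-one-participant-out
    (``cv='loso'``) cross-validation and the best classifier is kept.  In
    the augmented scheme the other three causes' true presence bits join
    the candidate features.  A cell whose selected features are all
    session-constant while the target label varies within sessions is
    reported as not classifiable (accuracy NaN), mirroring how
    session-level questionnaire scores cannot track scenario-level causes.
    """
    if scheme not in ("independent", "augmented"):
        raise ValueError(f"unknown scheme {scheme!r}")
    menu = menu if menu is not None else default_menu()
    table = prepare_matrix(table)
    varying = _session_varying(table, ALL_FEATURES)
    groups = table["participant"].to_numpy() if cv == "loso" else None
    results = []
    for cause in causes:
        y = table[cause].to_numpy(dtype=int)
        for combo in combos:
            feats = [f for s in combo for f in FEATURE_SETS[s]]
            indicator_cols = []
            if scheme == "augmented":
                for other in CAUSES:
                    if other != cause:
                        col = f"has_{other}"
                        table[col] = table[other].astype(float)
                        indicator_cols.append(col)
            cand = feats + indicator_cols
            X = table[cand].to_numpy(dtype=float)
            sel_full, pv_full = stepwise_select(X, y, guarantee_nonempty=True)
            sel_names = [cand[j] for j in sel_full]
            cause_within = cause in WITHIN_SESSION_CAUSES
            sel_varying = [f for f in sel_names
                           if f in varying or f.startswith("has_")]
            if cause_within and not sel_varying:
                results.append(RunResult(
                    cause=cause, feature_sets=combo, scheme=scheme,
                    accuracy=float("nan"), selected_features=sel_names,
                    p_values=pv_full, best_spec=None,
                    note="not classifiable: no session-varying feature selected"))
                continue
            folds = _folds(X.shape[0], groups)
            if selection == "outside":
                sels = [sel_full] * len(folds)
            else:
                sels = fold_selections(X, y, folds)
            accs = {}
            for spec in menu:
                accs[spec.label] = loocv(spec, X, y, groups=groups, seed=seed,
                                         selections=sels)
            best_label = max(accs, key=lambda k: accs[k])
            best = next(s for s in menu if s.label == best_label)
            results.append(RunResult(
                cause=cause, feature_sets=combo, scheme=scheme,
                accuracy=accs[best_label], selected_features=sel_names,
                p_values=pv_full, best_spec=best, accuracies=accs))
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_CAUSE_TITLES = {
    "phone": "Cell phone", "drowsy": "Alert vs. drowsy",
    "town": "Highway vs. town", "snowy": "Snowy vs. clear",
}
_COMBO_TITLES = {
    ("physio",): "Physiology",
    ("characteristics",): "Characteristics",
    ("kinematics",): "Vehicle kinematics",
    ("physio", "characteristics"): "Physiology, characteristics",
    ("physio", "kinematics"): "Physiology, vehicle kinematics",
    ("characteristics", "kinematics"): "Characteristics, vehicle kinematics",
    ("physio", "characteristics", "kinematics"): "All",
}


def format_p(p: float, floor: float = 0.001) -> str:
    return f"<{floor}" if p < floor else f"{p:.3f}"


def results_frame(results: list[RunResult]) -> pd.DataFrame:
    """One row per cell: accuracy, best classifier, selected features."""
    rows = []
    for r in results:
        rows.append(dict(
            cause=r.cause, feature_sets="+".join(r.feature_sets), scheme=r.scheme,
            accuracy=r.accuracy,
            best_classifier=r.best_spec.label if r.best_spec else "",
            selected_features=";".join(r.selected_features),
            p_values=";".join(format_p(p) for p in r.p_values),
            note=r.note,
        ))
    return pd.DataFrame(rows)


def accuracy_table(results: list[RunResult]) -> pd.DataFrame:
    """Accuracy grid, feature-set combinations x causes (percent; '-' cells
    are not classifiable)."""
    grid = {}
    for r in results:
        row = _COMBO_TITLES.get(r.feature_sets, "+".join(r.feature_sets))
        col = _CAUSE_TITLES.get(r.cause, r.cause)
        grid.setdefault(row, {})[col] = (
            "-" if np.isnan(r.accuracy) else f"{100 * r.accuracy:.1f}%")
    order = [t for c, t in _COMBO_TITLES.items()
             if any(r.feature_sets == c for r in results)]
    return pd.DataFrame(grid).T.reindex(order)


def best_features_table(results: list[RunResult], top: int = 3) -> pd.DataFrame:
    """Per cause (all-feature-set cells): best accuracy, best classifier and
    the top entry features with their selection p-values."""
    rows = []
    for r in results:
        if set(r.feature_sets) != {"physio", "characteristics", "kinematics"}:
            continue
        for k in range(min(top, len(r.selected_features))):
            rows.append(dict(
                cause=_CAUSE_TITLES.get(r.cause, r.cause),
                accuracy=f"{100 * r.accuracy:.1f}%" if k == 0 else "",
                best_classifier=r.best_spec.label if (r.best_spec and k == 0) else "",
                feature=r.selected_features[k],
                p_value=format_p(r.p_values[k]),
            ))
    return pd.DataFrame(rows)


def report(results: list[RunResult]) -> str:
    """Human-readable summary of an experiment matrix."""
    if not results:
        return "(no results)\n"
    parts = []
    for scheme in sorted({r.scheme for r in results}):
        sub = [r for r in results if r.scheme == scheme]
        parts.append(f"== Scheme: {scheme} ==\n")
        parts.append("Accuracy by feature-set combination:\n")
        parts.append(accuracy_table(sub).to_string())
        bf = best_features_table(sub)
        if len(bf):
            parts.append("\n\nBest classifier and top features (all feature sets):\n")
            parts.append(bf.to_string(index=False))
        parts.append("\n")
    return "\n".join(parts)
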