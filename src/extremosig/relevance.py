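"""Relevant k-mer discovery via Random Forest mean decrease in impurity (MDI).

For each environment category a one-vs-all Random Forest is cross-validated,
the per-fold MDI importances are averaged into a global ranking, and the
"most relevant subset" is the shortest prefix of that ranking that
classifies the data as accurately as the full feature set (within a declared
tolerance — cross-validated accuracy is stochastic, so exact equality would
be ill-posed).  Per-category deviation profiles express each canonical
3-mer's category mean frequency minus the dataset mean, in percentage
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .classify import ClassifierSpec, CVResult, run_cv
from .folds import FoldPlan, build_standard_folds
from .signatures import FCGRGrid, fcgr_map

__all__ = [
    "ImportanceRanking",
    "RelevantSubset",
    "DeviationProfile",
    "one_vs_all_importance",
    "minimal_relevant_subset",
    "deviation_profile",
    "importance_fcgr",
]


@dataclass
class ImportanceRanking:
    """Mean MDI importance per k-mer for one one-vs-all classification."""

    category: str
    k: int
    kmer_order: list[str]          # feature order of the signature matrix
    importances: np.ndarray        # mean MDI over folds, aligned to kmer_order
    ranking: list[str] = field(default=None)  # k-mers, descending importance
    plan: FoldPlan | None = field(default=None, repr=False)
    seed: int = 0

    def __post_init__(self):
        if self.ranking is None:
            order = np.argsort(-self.importances, kind="stable")
            self.ranking = [self.kmer_order[i] for i in order]


@dataclass
class RelevantSubset:
    """Shortest ranking prefix matching full-feature accuracy within tolerance."""

    category: str
    kmers: list[str]
    prefix_accuracy: float   # %
    full_accuracy: float     # %
    tolerance: float         # percentage points
    degenerate: bool = False  # classification no better than majority baseline


@dataclass
class DeviationProfile:
    """Per-category k-mer frequency deviations from the dataset mean (pp)."""

    categories: list[str]
    category_sizes: dict
    deviations: pd.DataFrame  # rows = categories, columns = canonical k-mers
    relevant: dict = field(default_factory=dict)  # category -> set of k-mers


def one_vs_all_importance(
    signatures: pd.DataFrame,
    env_labels: Sequence[str],
    category: str,
    n_folds: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
) -> tuple[CVResult, ImportanceRanking]:
    """One-vs-all Random Forest CV + fold-averaged MDI importance ranking."""
    y = np.asarray(env_labels)
    if category not in y:
        raise ValueError(f"category {category!r} absent from labels")
    binary = np.where(y == category, category, "rest")
    X = signatures.to_numpy(dtype=float)
    plan = build_standard_folds(binary, n_folds=n_folds, seed=seed)
    accs, imps = [], []
    for test_idx in plan.folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        rf = RandomForestClassifier(n_estimators=n_estimators, criterion="gini",
                                    random_state=seed, n_jobs=1)
        rf.fit(X[mask], binary[mask])
        accs.append(100.0 * float(np.mean(rf.predict(X[test_idx]) ==
                                          binary[test_idx])))
        imps.append(rf.feature_importances_)
    mean_imp = np.mean(imps, axis=0)
    k = len(signatures.columns[0])
    cv = CVResult(fold_accuracies=accs, fold_plan_mode=plan.mode,
                  label_scheme=f"one-vs-all:{category}", k=k,
                  backend="random_forest_gini")
    ranking = ImportanceRanking(category=category, k=k,
                                kmer_order=list(signatures.columns),
                                importances=mean_imp, plan=plan, seed=seed)
    return cv, ranking


def _prefix_accuracy(
    signatures: pd.DataFrame, binary: np.ndarray, ranking: ImportanceRanking,
    m: int, spec: ClassifierSpec,
) -> float:
    cols = ranking.ranking[:m]
    res = run_cv(signatures[cols].to_numpy(dtype=float), binary,
                 ranking.plan, spec)
    return res.mean_accuracy


def minimal_relevant_subset(
    ranking: ImportanceRanking,
    signatures: pd.DataFrame,
    env_labels: Sequence[str],
    tolerance: float = 0.5,
    spec: ClassifierSpec | None = None,
) -> RelevantSubset:
    """Shortest prefix of the ranking sufficient for full-feature accuracy.

    The search doubles the prefix length until the accuracy criterion is met,
    then bisects.  The same fold plan and seed as the full-feature run are
    reused so only the feature subset varies.
    """
    y = np.asarray(env_labels)
    binary = np.where(y == ranking.category, ranking.category, "rest")
    spec = spec or ClassifierSpec(backend="random_forest_gini", seed=ranking.seed)
    n_features = len(ranking.ranking)
    full_acc = _prefix_accuracy(signatures, binary, ranking, n_features, spec)
    target = full_acc - tolerance

    def ok(m: int) -> bool:
        return _prefix_accuracy(signatures, binary, ranking, m, spec) >= target

    m = 1
    while m < n_features and not ok(m):
        m = min(2 * m, n_features)
    # bisect in (m//2, m]: ok(m) holds (or m == n_features)
    lo, hi = m // 2, m
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    m = max(hi, 1)
    prefix_acc = _prefix_accuracy(signatures, binary, ranking, m, spec)
    baseline = 100.0 * max(np.mean(binary == ranking.category),
                           np.mean(binary == "rest"))
    return RelevantSubset(
        category=ranking.category,
        kmers=ranking.ranking[:m],
        prefix_accuracy=prefix_acc,
        full_accuracy=full_acc,
        tolerance=tolerance,
        degenerate=bool(full_acc <= baseline + tolerance),
    )


def minimal_relevant_subset_linear(
    ranking: ImportanceRanking,
    signatures: pd.DataFrame,
    env_labels: Sequence[str],
    tolerance: float = 0.5,
    spec: ClassifierSpec | None = None,
) -> int:
    """Linear-scan reference for the subset search: smallest m meeting the
    accuracy criterion.  Intended for validation on small instances."""
    y = np.asarray(env_labels)
    binary = np.where(y == ranking.category, ranking.category, "rest")
    spec = spec or ClassifierSpec(backend="random_forest_gini", seed=ranking.seed)
    n_features = len(ranking.ranking)
    full_acc = _prefix_accuracy(signatures, binary, ranking, n_features, spec)
    for m in range(1, n_features + 1):
        if _prefix_accuracy(signatures, binary, ranking, m, spec) >= full_acc - tolerance:
            return m
    return n_features


def deviation_profile(
    signatures: pd.DataFrame,
    env_labels: Sequence[str],
    relevant: dict | None = None,
) -> DeviationProfile:
    """Category mean frequency minus dataset mean frequency, in percentage points.

    The size-weighted sum of category deviations is identically zero for
    every k-mer.
    """
    y = np.asarray(env_labels)
    if len(signatures) == 0 or len(y) == 0:
        raise ValueError("deviation profile needs at least one labelled sample")
    cats = list(pd.unique(pd.Series(y)))
    overall = signatures.mean(axis=0)
    rows, sizes = [], {}
    for c in cats:
        members = signatures[y == c]
        if len(members) == 0:
            raise ValueError(f"empty category {c!r}")
        sizes[c] = len(members)
        rows.append((members.mean(axis=0) - overall) * 100.0)
    dev = pd.DataFrame(rows, index=cats)
    return DeviationProfile(categories=cats, category_sizes=sizes,
                            deviations=dev, relevant=relevant or {})


def importance_fcgr(ranking: ImportanceRanking) -> FCGRGrid:
    """MDI importances rendered on the CGR pixel grid.

    Each canonical k-mer's importance is written at both its pixel and its
    reverse complement's pixel.
    """
    return fcgr_map(dict(zip(ranking.kmer_order, ranking.importances)),
                    ranking.k)
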