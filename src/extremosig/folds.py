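"""Label schemes and cross-validation fold plans.

Supports the three labelling scenarios used throughout the analysis —
taxonomy (domain), environment category, and random pseudo-labels — and the
two cross-validation regimes: standard stratified 10-fold, and the
*restricted* (non-overlapping genera) variant in which all samples of a
genus fall in exactly one fold while fold label distributions stay close to
the global distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SampleMeta",
    "FoldPlan",
    "LabelScheme",
    "label_from_ogt",
    "label_from_ogph",
    "merge_high_temperature",
    "assign_pseudo_labels",
    "build_standard_folds",
    "build_genus_restricted_folds",
    "read_metadata",
    "write_metadata",
]

logger = logging.getLogger(__name__)

TEMP_CATEGORIES = ("psychrophile", "mesophile", "thermophile", "hyperthermophile")
PH_CATEGORIES = ("acidophile", "alkaliphile")


@dataclass
class SampleMeta:
    """Taxonomy and environment annotation for one assembly."""

    assembly_id: str
    species: str
    genus: str
    domain: str  # "Bacteria" | "Archaea"
    temp_category: str = "none"
    ph_category: str = "none"
    ogt: float | None = None
    ogph: float | None = None


def label_from_ogt(ogt: float) -> str:
    """Temperature category from optimal growth temperature (degrees C).

    Boundaries are half-open on the left: <20 psychrophile, [20, 45)
    mesophile, [45, 80] thermophile, >80 hyperthermophile.
    """
    if not np.isfinite(ogt):
        raise ValueError("OGT must be finite")
    if ogt < 20:
        return "psychrophile"
    if ogt < 45:
        return "mesophile"
    if ogt <= 80:
        return "thermophile"
    return "hyperthermophile"


def label_from_ogph(ogph: float) -> str:
    """pH category from optimal growth pH: <5 acidophile, >9 alkaliphile."""
    if not np.isfinite(ogph):
        raise ValueError("OGpH must be finite")
    if ogph < 5:
        return "acidophile"
    if ogph > 9:
        return "alkaliphile"
    return "none"


def merge_high_temperature(label: str) -> str:
    """Merge thermophile and hyperthermophile into 'high-temperature'."""
    if label in ("thermophile", "hyperthermophile"):
        return "high-temperature"
    return label


@dataclass
class LabelScheme:
    """One of the three labelling scenarios.

    ``kind='random'`` draws i.i.d. pseudo-labels, either from a discrete
    uniform distribution over ``n_classes`` values (the main control
    scenario) or from the empirical environment-category proportions.
    """

    kind: str  # "taxonomy" | "environment" | "random"
    distribution: str = "uniform"  # for random: "uniform" | "empirical"
    n_classes: int = 4
    seed: int = 0


def assign_pseudo_labels(
    n: int,
    scheme: LabelScheme,
    proportions: Sequence[float] | None = None,
) -> np.ndarray:
    """Draw n i.i.d. pseudo-labels under a random LabelScheme."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(scheme.seed)
    if scheme.distribution == "uniform":
        if scheme.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        return rng.integers(0, scheme.n_classes, size=n)
    if scheme.distribution == "empirical":
        if proportions is None:
            raise ValueError("empirical pseudo-labels need class proportions")
        p = np.asarray(proportions, dtype=float)
        p = p / p.sum()
        return rng.choice(len(p), size=n, p=p)
    raise ValueError(f"unknown distribution {scheme.distribution!r}")


@dataclass
class FoldPlan:
    """A partition of sample indices into folds."""

    n_folds: int
    folds: list[np.ndarray]
    mode: str  # "standard" | "genus_restricted"
    seed: int
    label_distributions: pd.DataFrame | None = field(default=None, repr=False)

    def validate(self, n_samples: int) -> None:
        all_idx = np.concatenate(self.folds)
        if len(all_idx) != n_samples or len(np.unique(all_idx)) != n_samples:
            raise ValueError("folds do not partition the sample set")

    def to_json(self, path: str | Path, assembly_ids: Sequence[str]) -> None:
        mapping = {}
        for f, idx in enumerate(self.folds):
            for i in idx:
                mapping[assembly_ids[int(i)]] = f
        Path(path).write_text(json.dumps(
            {"mode": self.mode, "n_folds": self.n_folds, "seed": self.seed,
             "fold_of": mapping}, indent=1))


def _fold_label_table(folds: list[np.ndarray], labels: np.ndarray) -> pd.DataFrame:
    classes = pd.unique(pd.Series(labels))
    rows = []
    for idx in folds:
        s = pd.Series(labels[idx]).value_counts()
        rows.append([int(s.get(c, 0)) for c in classes])
    return pd.DataFrame(rows, columns=list(classes))


def build_standard_folds(labels: Sequence, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Standard stratified k-fold plan (shuffled, seeded)."""
    y = np.asarray(labels)
    if n_folds > len(y):
        raise ValueError("more folds than samples")
    counts = pd.Series(y).value_counts()
    if (counts < n_folds).any():
        logger.warning("some classes have fewer samples than folds; "
                       "stratification is best-effort")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros((len(y), 1)), y)]
    plan = FoldPlan(n_folds=n_folds, folds=folds, mode="standard", seed=seed,
                    label_distributions=_fold_label_table(folds, y))
    plan.validate(len(y))
    return plan


def build_genus_restricted_folds(
    genera: Sequence[str],
    labels: Sequence,
    n_folds: int = 10,
    seed: int = 0,
    size_weight: float = 4.0,
    label_weight: float = 1.0,
) -> FoldPlan:
    """Stratified folds with non-overlapping genera.

    All samples of a genus land in exactly one fold, while each fold's label
    distribution is kept close to the global distribution.  Genera are
    processed in decreasing size order and each is assigned to the fold
    minimizing a squared divergence of the fold's label proportions from the
    global proportions plus a penalty for overshooting the target fold size;
    remaining ties break toward the smallest fold, then by a seeded shuffle.
    """
    genera = np.asarray(genera)
    y = np.asarray(labels)
    if len(genera) != len(y):
        raise ValueError("genera and labels must align")
    uniq_genera = pd.unique(pd.Series(genera))
    if len(uniq_genera) < n_folds:
        logger.warning("only %d genera for %d folds; reducing n_folds",
                       len(uniq_genera), n_folds)
        n_folds = len(uniq_genera)
    classes = pd.unique(pd.Series(y))
    class_idx = {c: i for i, c in enumerate(classes)}
    global_prop = np.array([(y == c).sum() for c in classes], dtype=float)
    global_prop /= global_prop.sum()
    target_size = len(y) / n_folds

    genus_members = {g: np.flatnonzero(genera == g) for g in uniq_genera}
    genus_counts = {
        g: np.bincount([class_idx[c] for c in y[m]], minlength=len(classes))
        for g, m in genus_members.items()
    }
    rng = np.random.default_rng(seed)
    order = sorted(rng.permutation(uniq_genera),
                   key=lambda g: -len(genus_members[g]))

    fold_size = np.zeros(n_folds)
    fold_counts = np.zeros((n_folds, len(classes)))
    fold_of_genus: dict[str, int] = {}
    fold_perm = rng.permutation(n_folds)  # seeded final tie-break
    for g in order:
        gc = genus_counts[g]
        gn = gc.sum()
        best, best_key = 0, None
        # every fold must end non-empty: seed empty folds first
        empty = [f for f in range(n_folds) if fold_size[f] == 0]
        candidates = empty if empty else range(n_folds)
        for f in candidates:
            new_size = fold_size[f] + gn
            new_counts = fold_counts[f] + gc
            divergence = float(np.sum((new_counts / new_size - global_prop) ** 2))
            overshoot = max(0.0, new_size - target_size) / target_size
            cost = label_weight * divergence + size_weight * overshoot ** 2
            key = (round(cost, 12), fold_size[f], fold_perm[f])
            if best_key is None or key < best_key:
                best, best_key = f, key
        fold_of_genus[g] = best
        fold_size[best] += gn
        fold_counts[best] += gc

    # local refinement: move single genera between folds while the global
    # objective (size-weighted label divergence + size imbalance) improves
    def objective() -> float:
        props = fold_counts / np.maximum(fold_size, 1e-9)[:, None]
        div = ((props - global_prop) ** 2).sum(axis=1)
        size_pen = ((fold_size - target_size) / target_size) ** 2
        return float(label_weight * (div * fold_size).sum() / len(y)
                     + size_weight * size_pen.mean())

    for _ in range(20):
        improved = False
        for g in order:
            src = fold_of_genus[g]
            if fold_size[src] - genus_counts[g].sum() <= 0:
                continue  # never empty a fold
            gc, gn = genus_counts[g], genus_counts[g].sum()
            base = objective()
            best_f, best_val = src, base
            for f in range(n_folds):
                if f == src:
                    continue
                fold_size[src] -= gn; fold_counts[src] -= gc
                fold_size[f] += gn; fold_counts[f] += gc
                val = objective()
                fold_size[f] -= gn; fold_counts[f] -= gc
                fold_size[src] += gn; fold_counts[src] += gc
                if val < best_val - 1e-12:
                    best_f, best_val = f, val
            if best_f != src:
                fold_of_genus[g] = best_f
                fold_size[src] -= gn; fold_counts[src] -= gc
                fold_size[best_f] += gn; fold_counts[best_f] += gc
                improved = True
        if not improved:
            break

    folds = [np.sort(np.concatenate(
        [genus_members[g] for g, f in fold_of_genus.items() if f == i] or
        [np.array([], dtype=int)])) for i in range(n_folds)]
    plan = FoldPlan(n_folds=n_folds, folds=folds, mode="genus_restricted",
                    seed=seed, label_distributions=_fold_label_table(folds, y))
    plan.validate(len(y))
    return plan


# ---------------------------------------------------------------------------
# metadata I/O

_META_COLS = ["assembly_id", "species", "genus", "domain",
              "temp_category", "ph_category", "ogt", "ogph"]


def write_metadata(meta: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [[m.assembly_id, m.species, m.genus, m.domain, m.temp_category,
             m.ph_category, m.ogt, m.ogph] for m in meta]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(SampleMeta(
            assembly_id=str(r["assembly_id"]), species=str(r["species"]),
            genus=str(r["genus"]), domain=str(r["domain"]),
            temp_category=str(r.get("temp_category", "none")),
            ph_category=str(r.get("ph_category", "none")),
            ogt=None if pd.isna(r.get("ogt")) else float(r["ogt"]),
            ogph=None if pd.isna(r.get("ogph")) else float(r["ogph"])))
    return out
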