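"""Challenge experiments confirming cross-domain convergent candidates.

A candidate is an organism whose signature co-clusters with opposite-domain
organisms of the same environment category.  Confirmation uses two
supervised tests over a *challenge training set* that contains all samples
of the opposite domain plus same-domain samples of a *different* (merged)
environment category — so nothing in training shares both the candidate's
domain and its environment:

(i)  env_test — a classifier trained on merged environment labels should
     still predict the candidate's correct category, despite never seeing
     that category in the candidate's own domain;
(ii) domain_test — a classifier trained on domain labels should be "fooled"
     into the opposite domain.

Thermophiles and hyperthermophiles are merged into one "high-temperature"
category throughout, for both training and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, fit_predict
from .folds import SampleMeta, merge_high_temperature

__all__ = [
    "ChallengeResult",
    "build_challenge_training_set",
    "run_env_test",
    "run_domain_test",
    "confirm_candidates",
]


@dataclass
class ChallengeResult:
    candidate_id: str
    experiment: str          # "env_test" | "domain_test"
    backend: str
    training_size: int
    training_composition: dict
    predicted: str
    expected: str            # correct env (env_test) / true domain (domain_test)

    @property
    def correct(self) -> bool:
        return self.predicted == self.expected


def _merged_env(meta: SampleMeta, axis: str = "temperature") -> str:
    label = meta.temp_category if axis == "temperature" else meta.ph_category
    return merge_high_temperature(label)


def build_challenge_training_set(
    candidate: SampleMeta,
    dataset: Sequence[SampleMeta],
    axis: str = "temperature",
) -> np.ndarray:
    """Indices of the challenge training set for one candidate.

    All opposite-domain samples, plus same-domain samples whose merged
    environment label differs from the candidate's; the candidate itself is
    excluded.  No training sample shares both the candidate's domain and its
    merged environment category.
    """
    cand_env = _merged_env(candidate, axis)
    if candidate.domain not in ("Bacteria", "Archaea") or cand_env == "none":
        raise ValueError("candidate needs a domain and an environment label")
    idx = []
    for i, s in enumerate(dataset):
        if s.assembly_id == candidate.assembly_id:
            continue
        if s.domain != candidate.domain or _merged_env(s, axis) != cand_env:
            idx.append(i)
    idx = np.array(idx, dtype=int)
    if len(idx) == 0:
        raise ValueError("empty challenge training set")
    return idx


def _composition(meta: Sequence[SampleMeta], idx: np.ndarray, axis: str) -> dict:
    pairs = [(meta[i].domain, _merged_env(meta[i], axis)) for i in idx]
    return dict(pd.Series(pairs).value_counts())


def run_env_test(
    candidate: SampleMeta,
    signatures: pd.DataFrame,
    dataset: Sequence[SampleMeta],
    spec: ClassifierSpec,
    axis: str = "temperature",
) -> ChallengeResult:
    """Experiment (i): predict the candidate's merged environment category."""
    idx = build_challenge_training_set(candidate, dataset, axis)
    ids = [dataset[i].assembly_id for i in idx]
    train_y = np.array([_merged_env(dataset[i], axis) for i in idx])
    if len(np.unique(train_y)) < 2:
        raise ValueError("challenge training set has a single environment class")
    pred = fit_predict(spec, signatures.loc[ids].to_numpy(),
                       train_y, signatures.loc[[candidate.assembly_id]].to_numpy())
    return ChallengeResult(
        candidate_id=candidate.assembly_id, experiment="env_test",
        backend=spec.backend, training_size=len(idx),
        training_composition=_composition(dataset, idx, axis),
        predicted=str(pred[0]), expected=_merged_env(candidate, axis))


def run_domain_test(
    candidate: SampleMeta,
    signatures: pd.DataFrame,
    dataset: Sequence[SampleMeta],
    spec: ClassifierSpec,
    axis: str = "temperature",
) -> ChallengeResult:
    """Experiment (ii): predict the candidate's domain on the same challenge set.

    A "fooled" outcome (prediction != true domain) supports an environmental
    component strong enough to override the taxonomic one.
    """
    idx = build_challenge_training_set(candidate, dataset, axis)
    ids = [dataset[i].assembly_id for i in idx]
    train_y = np.array([dataset[i].domain for i in idx])
    pred = fit_predict(spec, signatures.loc[ids].to_numpy(),
                       train_y, signatures.loc[[candidate.assembly_id]].to_numpy())
    return ChallengeResult(
        candidate_id=candidate.assembly_id, experiment="domain_test",
        backend=spec.backend, training_size=len(idx),
        training_composition=_composition(dataset, idx, axis),
        predicted=str(pred[0]), expected=candidate.domain)


def confirm_candidates(
    pairs: Sequence[tuple[int, int, int]],
    signatures: pd.DataFrame,
    dataset: Sequence[SampleMeta],
    specs: Sequence[ClassifierSpec],
    axis: str = "temperature",
) -> list[dict]:
    """Confirm consensus-pair members via the two challenge experiments.

    A candidate is confirmed iff a strict majority of backends predicts its
    correct (merged) environment in experiment (i) AND a strict majority
    predicts the wrong domain in experiment (ii).  Ties count as not
    confirmed.
    """
    if not specs:
        raise ValueError("need at least one classifier spec")
    member_ids = sorted({i for p in pairs for i in p[:2]})
    out = []
    for i in member_ids:
        cand = dataset[i]
        env_results, dom_results = [], []
        for spec in specs:
            env_results.append(run_env_test(cand, signatures, dataset, spec, axis))
            dom_results.append(run_domain_test(cand, signatures, dataset, spec, axis))
        env_votes = sum(r.correct for r in env_results)
        fooled_votes = sum(not r.correct for r in dom_results)
        confirmed = env_votes > len(specs) / 2 and fooled_votes > len(specs) / 2
        out.append({
            "assembly_id": cand.assembly_id,
            "index": i,
            "confirmed": bool(confirmed),
            "env_votes": int(env_votes),
            "fooled_votes": int(fooled_votes),
            "n_backends": len(specs),
            "env_results": env_results,
            "domain_results": dom_results,
        })
    return out
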