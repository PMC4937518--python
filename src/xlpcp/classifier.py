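"""Gold-standard construction and the logistic-regression ensemble.

True positives are candidate peak pairs whose two protein groups are
co-members of at least one catalogued complex.  True negatives are sampled
from candidate pairs whose groups are both catalogued but never co-annotated;
because any single draw may contain unannotated real interactions, the
negative sampling is repeated 100 times and one logistic-regression
classifier is trained per negative set (always against the same positives).
Each candidate pair's final interaction score is the median of the 100
predicted probabilities; pairs scoring strictly above the cut-off (default
0.75) become the weighted edges of the interaction network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler

from .features import PeakPairFeatures
from .known_complexes import KnownComplex

logger = logging.getLogger(__name__)


class GoldStandardError(ValueError):
    """The catalogue and candidate pairs yield no usable training set."""


@dataclass
class GoldStandard:
    positives: list[PeakPairFeatures]
    negative_pool: list[PeakPairFeatures]
    negative_sets: list[list[int]]  # indices into negative_pool
    n_negative_sets: int
    seed: int


@dataclass
class TrainedEnsemble:
    classifiers: list[Pipeline]
    cv_auc: list[float]
    seed: int


@dataclass
class ScoredPair:
    pair: PeakPairFeatures
    score: float


def _membership_index(catalogue: list[KnownComplex]) -> dict[str, set[str]]:
    """accession -> set of complex ids."""
    idx: dict[str, set[str]] = {}
    for cx in catalogue:
        for acc in cx.member_accessions:
            idx.setdefault(acc, set()).add(cx.complex_id)
    return idx


def _group_memberships(
    accessions: list[str], idx: dict[str, set[str]]
) -> set[str]:
    out: set[str] = set()
    for acc in accessions:
        out |= idx.get(acc, set())
    return out


def build_gold_standard(
    catalogue: list[KnownComplex],
    pairs: list[PeakPairFeatures],
    accessions_by_group: dict[str, list[str]],
    seed: int = 0,
    n_negative_sets: int = 100,
) -> GoldStandard:
    """Label candidate pairs against the complex catalogue and sample
    ``n_negative_sets`` negative sets of size ``len(positives)``.

    Falls back to sampling with replacement (with a warning) if the pool of
    cross-complex pairs is smaller than the positive set.
    """
    idx = _membership_index(catalogue)
    positives: list[PeakPairFeatures] = []
    pool: list[PeakPairFeatures] = []
    for pair in pairs:
        mem_a = _group_memberships(
            accessions_by_group.get(pair.group_a, [pair.group_a]), idx
        )
        mem_b = _group_memberships(
            accessions_by_group.get(pair.group_b, [pair.group_b]), idx
        )
        if not mem_a or not mem_b:
            continue
        if mem_a & mem_b:
            pair.label = "positive"
            positives.append(pair)
        else:
            pair.label = "negative"
            pool.append(pair)
    if not positives:
        raise GoldStandardError("no candidate pair is co-annotated in the catalogue")

    rng = np.random.default_rng(seed)
    replace_flag = len(pool) < len(positives)
    if replace_flag:
        logger.warning(
            "negative pool (%d) smaller than positives (%d): "
            "sampling with replacement", len(pool), len(positives),
        )
    negative_sets = [
        list(rng.choice(len(pool), size=len(positives), replace=replace_flag))
        for _ in range(n_negative_sets)
    ]
    return GoldStandard(
        positives=positives,
        negative_pool=pool,
        negative_sets=negative_sets,
        n_negative_sets=n_negative_sets,
        seed=seed,
    )


def _make_classifier(seed: int) -> Pipeline:
    # lightly L2-regularized logistic regression on standardized features;
    # the regularization guards against separable training sets
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000, random_state=seed),
    )


def train_ensemble(
    gold: GoldStandard, cv_folds: int = 10, compute_cv: bool = True
) -> TrainedEnsemble:
    """Fit one classifier per negative set; record mean 10-fold CV AUC each.

    All randomness (CV shuffling, solver seeding) derives deterministically
    from the gold standard's seed.
    """
    if len(gold.positives) < 2 * cv_folds:
        raise GoldStandardError(
            f"need >= {2 * cv_folds} positives for {cv_folds}-fold CV, "
            f"got {len(gold.positives)}"
        )
    x_pos = np.array([p.feature_vector() for p in gold.positives])
    x_pool = (
        np.array([p.feature_vector() for p in gold.negative_pool])
        if gold.negative_pool
        else np.empty((0, x_pos.shape[1]))
    )
    classifiers, aucs = [], []
    for i, neg_idx in enumerate(gold.negative_sets):
        sub_seed = (gold.seed * 100003 + i) % (2**31 - 1)
        x = np.vstack([x_pos, x_pool[neg_idx]])
        y = np.concatenate([np.ones(len(x_pos)), np.zeros(len(neg_idx))])
        clf = _make_classifier(sub_seed)
        if compute_cv:
            cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=sub_seed)
            auc = float(
                cross_val_score(clf, x, y, cv=cv, scoring="roc_auc").mean()
            )
        else:
            auc = float("nan")
        clf.fit(x, y)
        classifiers.append(clf)
        aucs.append(auc)
    return TrainedEnsemble(classifiers=classifiers, cv_auc=aucs, seed=gold.seed)


def score_pairs(
    ensemble: TrainedEnsemble, pairs: list[PeakPairFeatures]
) -> list[ScoredPair]:
    """Median predicted interaction probability over the ensemble."""
    if not pairs:
        return []
    x = np.array([p.feature_vector() for p in pairs])
    probs = np.vstack([clf.predict_proba(x)[:, 1] for clf in ensemble.classifiers])
    med = np.median(probs, axis=0)
    return [ScoredPair(pair=p, score=float(s)) for p, s in zip(pairs, med)]


def threshold_pairs(
    scored: list[ScoredPair], cutoff: float = 0.75
) -> list[ScoredPair]:
    """Keep pairs scoring strictly above the cut-off (the network's edges)."""
    return [s for s in scored if s.score > cutoff]
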