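"""Labelled drug-disease pairs, test split, and class-imbalance strategies.

Positives are approved drug-disease indications; negatives follow the
adverse-reaction rule: a pair ``(r, p)`` is labelled 0 when disease ``p``
appears among drug ``r``'s recorded side effects (in the shared identifier
space) and the pair is not a known indication. The two sets are disjoint by
construction and that disjointness is enforced, never assumed.

Feature rows are the concatenation ``[E_r || E_p]`` of the drug and disease
embedding vectors; resampling operates on those rows. Five strategies are
supported:

* ``IMB``    — train on the imbalanced data as-is;
* ``RUS``    — randomly undersample the majority class to parity;
* ``ROS``    — randomly duplicate the minority class to parity;
* ``OSMOTE`` — SMOTE-oversample the minority to parity;
* ``SORU``   — SMOTE-oversample the minority until minority/majority reaches
  ``smote_ratio`` (default 0.9), then randomly undersample the majority to
  the new minority count.

The SMOTE interpolation here places each synthetic row uniformly on the
segment between a minority row and one of its ``k`` nearest minority
neighbours (neighbour search via scikit-learn).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .embedding import EmbeddingTable

__all__ = [
    "AssociationRecord",
    "LabelledPair",
    "PairSet",
    "FeatureBlock",
    "STRATEGIES",
    "build_positive_set",
    "build_negative_set",
    "make_pairset",
    "split_test",
    "pairs_to_features",
    "rebalance",
]

STRATEGIES = ("IMB", "RUS", "ROS", "OSMOTE", "SORU")


@dataclass(frozen=True)
class AssociationRecord:
    drug: str
    disease: str
    status: str


@dataclass(frozen=True, order=True)
class LabelledPair:
    drug: str
    disease: str
    label: int
    role: str = "train"  # train | validation | test


@dataclass
class PairSet:
    pairs: list[LabelledPair]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def positives(self) -> list[LabelledPair]:
        return [p for p in self.pairs if p.label == 1]

    @property
    def negatives(self) -> list[LabelledPair]:
        return [p for p in self.pairs if p.label == 0]

    def with_role(self, role: str) -> list[LabelledPair]:
        return [p for p in self.pairs if p.role == role]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(p.drug, p.disease, p.label, p.role) for p in self.pairs],
            columns=["drug_id", "disease_id", "label", "role"])


@dataclass
class FeatureBlock:
    """Aligned feature matrix / label vector, optionally tracking pair ids."""

    X: np.ndarray
    y: np.ndarray
    pairs: list[LabelledPair] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y are misaligned")

    def __len__(self) -> int:
        return len(self.y)


def build_positive_set(associations: Iterable[AssociationRecord],
                       status_filter: str = "approved") -> set[tuple[str, str]]:
    """Deduplicated pairs whose association status equals ``status_filter``."""
    return {(a.drug, a.disease) for a in associations if a.status == status_filter}


def build_negative_set(side_effects: Mapping[str, set],
                       diseases: set,
                       positives: set) -> set[tuple[str, str]]:
    """Adverse-reaction negatives: side-effect terms that are diseases, minus positives."""
    return {(drug, term)
            for drug, terms in side_effects.items()
            for term in set(terms) & set(diseases)} - set(positives)


def make_pairset(positives: set, negatives: set) -> PairSet:
    overlap = set(positives) & set(negatives)
    if overlap:
        raise ValueError(f"positive/negative sets overlap on {len(overlap)} pairs")
    pairs = [LabelledPair(d, p, 1) for d, p in sorted(positives)]
    pairs += [LabelledPair(d, p, 0) for d, p in sorted(negatives)]
    return PairSet(pairs, provenance={
        "n_positive": len(positives), "n_negative": len(negatives),
        "n_total": len(positives) + len(negatives)})


def split_test(pairset: PairSet, fraction: float, seed: int = 0
               ) -> tuple[PairSet, PairSet]:
    """Hold out ``floor(fraction * |positives|)`` positives plus as many negatives.

    Sampling is uniform and seeded; the held-out pairs get role ``test`` and
    the remainder role ``train``. Raises when the negative pool cannot match
    the positive test count.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    pos = sorted(pairset.positives)
    neg = sorted(pairset.negatives)
    n_test = int(np.floor(fraction * len(pos)))
    if len(neg) < n_test:
        raise ValueError(
            f"insufficient negatives: need {n_test}, have {len(neg)}")
    rng = np.random.default_rng(seed)
    pos_idx = set(rng.choice(len(pos), size=n_test, replace=False).tolist())
    neg_idx = set(rng.choice(len(neg), size=n_test, replace=False).tolist())

    def tag(p: LabelledPair, role: str) -> LabelledPair:
        return LabelledPair(p.drug, p.disease, p.label, role)

    test = [tag(p, "test") for i, p in enumerate(pos) if i in pos_idx]
    test += [tag(p, "test") for i, p in enumerate(neg) if i in neg_idx]
    train = [tag(p, "train") for i, p in enumerate(pos) if i not in pos_idx]
    train += [tag(p, "train") for i, p in enumerate(neg) if i not in neg_idx]
    prov = dict(pairset.provenance)
    prov.update(n_test_positive=n_test, n_test_negative=n_test)
    return PairSet(train, prov), PairSet(test, dict(prov))


def pairs_to_features(pairs: PairSet | Sequence[LabelledPair],
                      table: EmbeddingTable) -> FeatureBlock:
    """Row ``i`` is ``[E_drug || E_disease]`` for pair ``i`` (stable order)."""
    seq = pairs.pairs if isinstance(pairs, PairSet) else list(pairs)
    k = table.vector_size
    if not seq:
        return FeatureBlock(np.empty((0, 2 * k)), np.empty(0, dtype=int), [])
    rows, labels = [], []
    for p in seq:
        try:
            dr = table.lookup(f"drug:{p.drug}")
            di = table.lookup(f"disease:{p.disease}")
        except KeyError as exc:
            raise type(exc)(
                f"pair ({p.drug!r}, {p.disease!r}) has an unembedded token"
            ) from exc
        rows.append(np.concatenate([dr, di]))
        labels.append(p.label)
    return FeatureBlock(np.vstack(rows), np.asarray(labels), list(seq))


def _smote_sample(x_min: np.ndarray, n_new: int, k_neighbors: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Interpolate ``n_new`` synthetic rows along minority-neighbour segments."""
    if len(x_min) <= k_neighbors:
        raise ValueError(
            f"SMOTE needs minority count > k_neighbors "
            f"({len(x_min)} <= {k_neighbors}); use a smaller k_neighbors")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x_min)
    neigh = nn.kneighbors(x_min, return_distance=False)[:, 1:]  # drop self
    base = rng.integers(0, len(x_min), size=n_new)
    partner = neigh[base, rng.integers(0, k_neighbors, size=n_new)]
    gap = rng.random((n_new, 1))
    return x_min[base] + gap * (x_min[partner] - x_min[base])


def rebalance(block: FeatureBlock, strategy: str, smote_ratio: float = 0.9,
              k_neighbors: int = 5, seed: int = 0) -> FeatureBlock:
    """Apply one of the five imbalance strategies to a (training) block.

    Synthetic/resampled blocks drop pair identities (``pairs=None``) except
    under ``IMB``, which returns the block untouched.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy == "IMB":
        return block
    classes, counts = np.unique(block.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("rebalancing needs both classes present")
    if counts[0] == counts[1]:
        # already balanced: positives play the minority role by convention
        minority, majority = classes[-1], classes[0]
    else:
        minority = classes[np.argmin(counts)]
        majority = classes[np.argmax(counts)]
    x_min = block.X[block.y == minority]
    x_maj = block.X[block.y == majority]
    rng = np.random.default_rng(seed)

    if strategy == "RUS":
        keep = rng.choice(len(x_maj), size=len(x_min), replace=False)
        x_maj = x_maj[np.sort(keep)]
    elif strategy == "ROS":
        extra = rng.choice(len(x_min), size=len(x_maj) - len(x_min), replace=True)
        x_min = np.vstack([x_min, x_min[extra]])
    elif strategy == "OSMOTE":
        new = _smote_sample(x_min, len(x_maj) - len(x_min), k_neighbors, rng)
        x_min = np.vstack([x_min, new])
    elif strategy == "SORU":
        if not 0 < smote_ratio <= 1:
            raise ValueError("smote_ratio must be in (0, 1]")
        target = int(round(smote_ratio * len(x_maj)))
        if target > len(x_min):
            new = _smote_sample(x_min, target - len(x_min), k_neighbors, rng)
            x_min = np.vstack([x_min, new])
        keep = rng.choice(len(x_maj), size=min(len(x_min), len(x_maj)),
                          replace=False)
        x_maj = x_maj[np.sort(keep)]

    X = np.vstack([x_min, x_maj])
    y = np.concatenate([np.full(len(x_min), minority),
                        np.full(len(x_maj), majority)])
    order = rng.permutation(len(y))
    return FeatureBlock(X[order], y[order], None)
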