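"""Labelled drug-target pair vectors, negative sampling, scaling and splits.

A pair vector is the concatenation of the drug's descriptor block and the
target's descriptor block. Negative (non-interacting) pairs are drawn
uniformly from the non-interaction space — the drug x target cross product
minus the known positives — by default in the same number as the positives,
so the assembled experimental dataset is class-balanced.

Four evaluation scenarios are supported:

* I   — plain random split ("general" prediction);
* II  — test contains only new-drug / known-target pairs;
* III — test contains only known-drug / new-target pairs;
* IV  — test contains only new-drug / new-target pairs (mixed test pairs are
        deleted; the training set is left unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import DescriptorMatrix, InteractionCatalog
from .exceptions import CatalogError, DtiforgeError, SplitError


@dataclass
class PairSample:
    """One labelled drug-target pair."""

    drug_id: str
    target_id: str
    vector: np.ndarray
    label: int  # +1 interaction, -1 non-interaction

    def __post_init__(self):
        if self.label not in (+1, -1):
            raise DtiforgeError(f"label must be +1 or -1, got {self.label}")


@dataclass
class FeatureScaler:
    """Per-feature linear map of the training range [min, max] onto [-1, 1].

    Constant features map to 0. Transforming data outside the fitted range
    yields values outside [-1, 1]; clipping is deliberately off.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        if X.size == 0:
            raise DtiforgeError("cannot fit scaler on empty data")
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        out = np.zeros_like(X, dtype=float)
        nz = span != 0
        out[:, nz] = 2.0 * (X[:, nz] - self.mins[nz]) / span[nz] - 1.0
        return out

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        out = np.tile(self.mins, (X.shape[0], 1))
        nz = span != 0
        out[:, nz] = (X[:, nz] + 1.0) / 2.0 * span[nz] + self.mins[nz]
        return out


@dataclass
class PairDataset:
    """A collection of labelled pair samples with a train/test role."""

    drug_ids: list[str]
    target_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    role: str = "train"
    scaling: FeatureScaler | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n = len(self.drug_ids)
        if not (len(self.target_ids) == self.X.shape[0] == self.y.shape[0] == n):
            raise DtiforgeError("inconsistent pair dataset dimensions")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.drug_ids, self.target_ids))

    @property
    def samples(self) -> list[PairSample]:
        return [
            PairSample(d, t, self.X[i], int(self.y[i]))
            for i, (d, t) in enumerate(self.pairs)
        ]

    def entity_sets(self) -> tuple[set[str], set[str]]:
        return set(self.drug_ids), set(self.target_ids)

    def subset(self, idx: np.ndarray, role: str | None = None) -> "PairDataset":
        return PairDataset(
            drug_ids=[self.drug_ids[i] for i in idx],
            target_ids=[self.target_ids[i] for i in idx],
            X=self.X[idx],
            y=self.y[idx],
            role=role or self.role,
            scaling=self.scaling,
            feature_names=self.feature_names,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": self.drug_ids,
                "target_id": self.target_ids,
                "label": self.y,
                "role": self.role,
            }
        )


@dataclass
class SplitSpec:
    """Scenario (I-IV), held-out fraction and seed of a train/test split."""

    scenario: str = "I"
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.scenario = str(self.scenario).upper()
        if self.scenario not in ("I", "II", "III", "IV"):
            raise DtiforgeError(f"unknown scenario {self.scenario!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise DtiforgeError("test_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# pair assembly
# ---------------------------------------------------------------------------

def pair_vector(catalog: InteractionCatalog, drug_id: str, target_id: str) -> np.ndarray:
    return np.concatenate([catalog.drugs.row(drug_id), catalog.targets.row(target_id)])


def assemble_pairs(
    catalog: InteractionCatalog,
    pairs: list[tuple[str, str]],
    label: int,
) -> list[PairSample]:
    """Concatenate drug and target descriptor blocks for each pair."""
    return [
        PairSample(d, t, pair_vector(catalog, d, t), label) for d, t in pairs
    ]


def sample_negatives(
    catalog: InteractionCatalog,
    n: int | None = None,
    seed: int = 0,
) -> list[PairSample]:
    """Draw non-interacting pairs uniformly without replacement.

    Conceptually: enumerate the drug x target cross product, exclude known
    positives, and sample n pairs (default: as many as there are positives).
    For small request sizes a rejection sampler over a positives hash avoids
    materializing the cross product; for dense requests the complement is
    enumerated explicitly. Both paths draw from the same uniform distribution
    and are deterministic given the seed.
    """
    if n is None:
        n = len(catalog.positives)
    space = catalog.noninteraction_size
    if n > space:
        raise CatalogError(
            f"requested {n} negatives but the non-interaction space holds only {space}"
        )
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    drugs = catalog.drugs.row_ids
    targets = catalog.targets.row_ids
    chosen: list[tuple[str, str]] = []
    if n > space // 2:
        complement = [
            (d, t) for d in drugs for t in targets if (d, t) not in catalog.positives
        ]
        idx = rng.choice(len(complement), size=n, replace=False)
        chosen = [complement[i] for i in idx]
    else:
        seen: set[tuple[str, str]] = set()
        while len(chosen) < n:
            d = drugs[int(rng.integers(len(drugs)))]
            t = targets[int(rng.integers(len(targets)))]
            pair = (d, t)
            if pair in catalog.positives or pair in seen:
                continue
            seen.add(pair)
            chosen.append(pair)
    return assemble_pairs(catalog, chosen, -1)


def build_pair_dataset(
    catalog: InteractionCatalog,
    seed: int = 0,
    n_negatives: int | None = None,
    role: str = "train",
) -> PairDataset:
    """Positives plus sampled negatives as one class-balanced dataset."""
    pos = assemble_pairs(catalog, sorted(catalog.positives), +1)
    neg = sample_negatives(catalog, n=n_negatives, seed=seed)
    samples = pos + neg
    names = catalog.drugs.names + catalog.targets.names
    return PairDataset(
        drug_ids=[s.drug_id for s in samples],
        target_ids=[s.target_id for s in samples],
        X=np.vstack([s.vector for s in samples]),
        y=np.array([s.label for s in samples]),
        role=role,
        feature_names=names,
    )


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def scale_features(
    train: PairDataset,
    others: list[PairDataset] | None = None,
    mode: str = "train",
) -> tuple[PairDataset, list[PairDataset], FeatureScaler]:
    """Scale pair vectors to [-1, 1].

    ``mode='train'`` (default) fits the per-feature ranges on the training set
    only and applies them to the other datasets, which may then exceed
    [-1, 1]. ``mode='joint'`` fits on the union of all datasets — the literal
    protocol of scaling all experimental data together — at the cost of test
    information leaking into the ranges.
    """
    others = others or []
    if len(train) == 0:
        raise DtiforgeError("empty training dataset")
    if mode == "train":
        scaler = FeatureScaler.fit(train.X)
    elif mode == "joint":
        scaler = FeatureScaler.fit(np.vstack([train.X] + [o.X for o in others]) if others else train.X)
    else:
        raise DtiforgeError(f"unknown scaling mode {mode!r}")
    strain = replace(train, X=scaler.transform(train.X), scaling=scaler)
    sothers = [replace(o, X=scaler.transform(o.X), scaling=scaler) for o in others]
    return strain, sothers, scaler


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def make_split(dataset: PairDataset, spec: SplitSpec) -> tuple[PairDataset, PairDataset]:
    """Build the train/test split for one evaluation scenario.

    Scenarios II and III move samples from the initial random test set into
    the training set until the remaining test set satisfies the scenario
    predicate against the *final* training entity sets (the movement is
    iterated to a fixed point, since moved samples can introduce new entities
    into the training set). Scenario IV deletes mixed samples from the initial
    test set and leaves the training set unchanged.
    """
    n = len(dataset)
    if n == 0:
        raise SplitError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_test = int(round(n * spec.test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    test_idx = list(perm[:n_test])
    train_idx = list(perm[n_test:])

    if spec.scenario == "I":
        return (
            dataset.subset(np.array(train_idx), role="train"),
            dataset.subset(np.array(test_idx), role="test"),
        )

    drugs = dataset.drug_ids
    targets = dataset.target_ids

    if spec.scenario in ("II", "III"):
        # predicate for moving a test sample INTO train
        if spec.scenario == "II":
            def must_move(i, train_d, train_t):
                return drugs[i] in train_d or targets[i] not in train_t
        else:
            def must_move(i, train_d, train_t):
                return drugs[i] not in train_d or targets[i] in train_t
        moved = True
        while moved:
            train_d = {drugs[i] for i in train_idx}
            train_t = {targets[i] for i in train_idx}
            stay, move = [], []
            for i in test_idx:
                (move if must_move(i, train_d, train_t) else stay).append(i)
            moved = bool(move)
            train_idx.extend(move)
            test_idx = stay
        if not test_idx:
            raise SplitError(
                f"scenario {spec.scenario} produced an empty test set; "
                "use a larger test_fraction or a larger catalog"
            )
        return (
            dataset.subset(np.array(train_idx), role="train"),
            dataset.subset(np.array(test_idx), role="test"),
        )

    # scenario IV: delete mixed samples from the initial test set
    train_d = {drugs[i] for i in train_idx}
    train_t = {targets[i] for i in train_idx}
    kept = [i for i in test_idx if drugs[i] not in train_d and targets[i] not in train_t]
    if not kept:
        raise SplitError(
            "scenario IV produced an empty test set; use a larger test_fraction"
        )
    return (
        dataset.subset(np.array(train_idx), role="train"),
        dataset.subset(np.array(kept), role="test"),
    )


def split_report(train: PairDataset, test: PairDataset) -> dict:
    """Counts per role and label, the layout of the paper-style split table."""
    def counts(ds):
        return {
            "positives": int((ds.y == 1).sum()),
            "negatives": int((ds.y == -1).sum()),
            "total": len(ds),
        }

    return {"train": counts(train), "test": counts(test)}
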