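"""Core data containers: descriptor matrices and interaction catalogs.

A :class:`DescriptorMatrix` is a pandas DataFrame of named, ordered numeric
descriptors (rows = entities) plus a per-cell computability mask. The TSV
serialization (row id column ``id`` + one column per descriptor) is the
repository's canonical exchange format for both chemical and protein
descriptor sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CatalogError, DtiforgeError


@dataclass
class FeatureVector:
    """Named, ordered descriptors for one entity."""

    entity_id: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise DtiforgeError(
                f"names ({len(self.names)}) and values ({self.values.shape[0]}) differ in length"
            )
        if len(set(self.names)) != len(self.names):
            raise DtiforgeError("descriptor names must be unique")

    def __len__(self) -> int:
        return self.values.shape[0]


class DescriptorMatrix:
    """Stack of feature vectors sharing one descriptor space.

    Parameters
    ----------
    frame : DataFrame
        Rows indexed by entity id, columns are descriptor names, float values.
    mask : DataFrame, optional
        Boolean computability flags, same shape; True = computable. Cells with
        ``mask == False`` hold NaN placeholders and must be removed by curation
        before modelling.
    """

    def __init__(self, frame: pd.DataFrame, mask: pd.DataFrame | None = None):
        if frame.columns.duplicated().any():
            raise DtiforgeError("duplicate descriptor names")
        if frame.index.duplicated().any():
            raise DtiforgeError("duplicate row ids")
        self.frame = frame.astype(float)
        if mask is None:
            mask = ~self.frame.isna()
        if mask.shape != frame.shape:
            raise DtiforgeError("mask shape differs from matrix shape")
        self.mask = mask.astype(bool)

    # -- basic protocol ----------------------------------------------------
    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def row(self, entity_id: str) -> np.ndarray:
        try:
            return self.frame.loc[entity_id].to_numpy(dtype=float)
        except KeyError:
            raise CatalogError(f"unknown entity id {entity_id!r}") from None

    def is_complete(self) -> bool:
        """True when every cell is computable and finite."""
        return bool(self.mask.values.all() and np.isfinite(self.values).all())

    # -- construction ------------------------------------------------------
    @classmethod
    def from_vectors(cls, vectors: list[FeatureVector]) -> "DescriptorMatrix":
        if not vectors:
            raise DtiforgeError("no feature vectors supplied")
        names = vectors[0].names
        for v in vectors[1:]:
            if v.names != names:
                raise DtiforgeError(
                    f"descriptor space of {v.entity_id!r} differs from {vectors[0].entity_id!r}"
                )
        frame = pd.DataFrame(
            [v.values for v in vectors],
            index=[v.entity_id for v in vectors],
            columns=names,
        )
        return cls(frame)

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "DescriptorMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="id")
        return cls(frame)


@dataclass
class InteractionCatalog:
    """Drugs, targets, and the known (positive) interaction pairs.

    ``positives`` is a set of (drug_id, target_id) tuples; every id must
    resolve in the corresponding descriptor matrix.
    """

    drugs: DescriptorMatrix
    targets: DescriptorMatrix
    positives: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        self.positives = set(self.positives)
        drug_ids = set(self.drugs.row_ids)
        target_ids = set(self.targets.row_ids)
        for d, t in self.positives:
            if d not in drug_ids:
                raise CatalogError(f"positive pair references unknown drug {d!r}")
            if t not in target_ids:
                raise CatalogError(f"positive pair references unknown target {t!r}")

    @property
    def n_drugs(self) -> int:
        return self.drugs.shape[0]

    @property
    def n_targets(self) -> int:
        return self.targets.shape[0]

    @property
    def noninteraction_size(self) -> int:
        """Size of the non-interaction space (cross product minus positives)."""
        return self.n_drugs * self.n_targets - len(self.positives)

    def write_positives_tsv(self, path) -> None:
        rows = sorted(self.positives)
        pd.DataFrame(rows, columns=["drug_id", "target_id"]).to_csv(
            path, sep="\t", index=False
        )


def read_positives_tsv(path) -> set[tuple[str, str]]:
    """Read a known-interaction catalog TSV with columns drug_id, target_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug_id", "target_id"}.issubset(df.columns):
        raise CatalogError("catalog TSV needs columns drug_id and target_id")
    pairs = list(zip(df["drug_id"], df["target_id"]))
    if len(pairs) != len(set(pairs)):
        raise CatalogError("duplicate pairs in catalog TSV")
    return set(pairs)
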