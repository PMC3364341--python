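"""2D molecular descriptor battery and descriptor-matrix curation.

The battery is the full RDKit 2D descriptor list (constitutional counts,
topological indices, 2D autocorrelation-style BCUT/VSA surfaces,
physicochemical estimates). The framework is descriptor-set agnostic: any
externally computed matrix in the canonical TSV format can stand in for the
built-in battery.

Curation mirrors the standard preparation of a raw descriptor table for
modelling: descriptors that cannot be computed for every molecule are dropped,
as are constant and near-constant descriptors.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .containers import DescriptorMatrix, FeatureVector
from .exceptions import DtiforgeError, StructureError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")


@dataclass
class MoleculeRecord:
    """A molecule id plus its parsed RDKit structure."""

    id: str
    mol: Chem.Mol

    @classmethod
    def from_smiles(cls, id: str, smiles: str, keep_largest_fragment: bool = True) -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise StructureError(f"unparsable SMILES for {id!r}: {smiles!r}", record_id=id)
        if keep_largest_fragment:
            frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
            if len(frags) > 1:
                logger.warning("%s is a salt/mixture; keeping largest covalent fragment", id)
                mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        return cls(id=id, mol=mol)


def default_battery() -> list[tuple[str, callable]]:
    """The RDKit 2D descriptor battery in its fixed published order."""
    return list(Descriptors.descList)


def featurize_molecule(
    mol: MoleculeRecord,
    battery: list[tuple[str, callable]] | None = None,
) -> tuple[FeatureVector, np.ndarray]:
    """Compute the battery for one molecule.

    Returns the feature vector together with a boolean computability mask;
    incomputable descriptors hold NaN and are flagged False rather than being
    silently zeroed.
    """
    battery = battery or default_battery()
    names, vals, mask = [], [], []
    for name, fn in battery:
        names.append(name)
        try:
            v = float(fn(mol.mol))
        except Exception:
            v = math.nan
        ok = math.isfinite(v)
        vals.append(v if ok else math.nan)
        mask.append(ok)
    return FeatureVector(mol.id, names, np.array(vals)), np.array(mask, dtype=bool)


def featurize_molecules(
    mols: list[MoleculeRecord],
    battery: list[tuple[str, callable]] | None = None,
) -> DescriptorMatrix:
    battery = battery or default_battery()
    vectors, masks = [], []
    for m in mols:
        v, msk = featurize_molecule(m, battery)
        vectors.append(v)
        masks.append(msk)
    dm = DescriptorMatrix.from_vectors(vectors)
    dm.mask = pd.DataFrame(np.vstack(masks), index=dm.frame.index, columns=dm.frame.columns)
    return dm


def curate_descriptor_matrix(
    m: DescriptorMatrix,
    near_const_fraction: float = 0.95,
) -> tuple[DescriptorMatrix, list[tuple[str, str]]]:
    """Drop incomputable-anywhere, constant, and near-constant descriptors.

    Rules, applied in order per descriptor column:

    1. ``incomputable`` — not computable (or non-finite) for at least one row;
    2. ``constant`` — a single value across all rows;
    3. ``near_constant`` — modal-value fraction >= ``near_const_fraction``.

    Column order of the retained descriptors is preserved. Returns the curated
    matrix and the dropped descriptors, each with its reason.
    """
    if m.frame.empty:
        raise DtiforgeError("empty descriptor matrix")
    dropped: list[tuple[str, str]] = []
    keep: list[str] = []
    n = m.frame.shape[0]
    for col in m.frame.columns:
        vals = m.frame[col].to_numpy()
        if not m.mask[col].all() or not np.isfinite(vals).all():
            dropped.append((str(col), "incomputable"))
            continue
        uniques = np.unique(vals)
        if uniques.size == 1:
            dropped.append((str(col), "constant"))
            continue
        modal = Counter(vals.tolist()).most_common(1)[0][1]
        if modal / n >= near_const_fraction:
            dropped.append((str(col), "near_constant"))
            continue
        keep.append(col)
    if not keep:
        raise DtiforgeError("empty descriptor space: all descriptors dropped")
    curated = DescriptorMatrix(m.frame[keep].copy(), m.mask[keep].copy())
    return curated, dropped


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_smiles_tsv(path, keep_largest_fragment: bool = True) -> list[MoleculeRecord]:
    """Read a TSV with columns ``id`` and ``smiles``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "smiles"}.issubset(df.columns):
        raise DtiforgeError("SMILES TSV needs columns 'id' and 'smiles'")
    return [
        MoleculeRecord.from_smiles(r.id, r.smiles, keep_largest_fragment)
        for r in df.itertuples(index=False)
    ]


def read_sdf(path, keep_largest_fragment: bool = True) -> list[MoleculeRecord]:
    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise StructureError(f"unparsable SDF record at index {i}", record_id=str(i))
        mid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        records.append(MoleculeRecord.from_smiles(mid, Chem.MolToSmiles(mol), keep_largest_fragment))
    return records


def write_dropped_report(dropped: list[tuple[str, str]], path) -> None:
    pd.DataFrame(dropped, columns=["descriptor", "reason"]).to_csv(path, sep="\t", index=False)
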