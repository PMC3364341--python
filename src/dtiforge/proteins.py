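"""Sequence-derived protein descriptors.

Seven descriptor families computed from a primary amino-acid sequence:

* amino-acid composition (AAC, 20) and dipeptide composition (DPC, 400);
* normalized Moreau-Broto / Moran / Geary autocorrelation over physicochemical
  scales (default: 8 scales x 30 lags, Moreau-Broto);
* composition / transition / distribution (CTD) over 7 three-group residue
  partitions (147);
* sequence-order coupling numbers and quasi-sequence-order descriptors over
  two residue-distance matrices (60 + 100);
* amphiphilic pseudo-amino-acid composition (APAAC, 20 + 2*lambda);
* sequence-averaged standardized amino-acid properties (33).

The default profile concatenates the families into the fixed 1080-dimensional
vector used throughout the pair-modelling pipeline. Every lag-based family
standardizes its property scale to zero mean and unit variance over the 20
residues before use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio import SeqIO

from . import aadata
from .aadata import ALPHABET, DIPEPTIDES
from .containers import DescriptorMatrix, FeatureVector
from .exceptions import ConfigError, SequenceError

logger = logging.getLogger(__name__)

_INDEX = {r: i for i, r in enumerate(ALPHABET)}


@dataclass
class ProteinRecord:
    """A protein id plus its sanitized primary sequence."""

    id: str
    sequence: str

    @classmethod
    def from_raw(cls, id: str, sequence: str, sanitize: bool = False) -> "ProteinRecord":
        """Validate (or sanitize) a raw sequence.

        With ``sanitize`` nonstandard residues (B, J, O, U, X, Z, ``*``) and any
        other unexpected characters are stripped with a logged warning;
        otherwise the first offending residue raises :class:`SequenceError`
        naming the residue and its 1-based position.
        """
        seq = sequence.strip().upper()
        cleaned = []
        for pos, res in enumerate(seq, start=1):
            if res in _INDEX:
                cleaned.append(res)
            elif sanitize:
                logger.warning("stripping nonstandard residue %r at %s:%d", res, id, pos)
            else:
                raise SequenceError(
                    f"nonstandard residue {res!r} at position {pos} of {id!r}"
                )
        seq = "".join(cleaned)
        if len(seq) < 2:
            raise SequenceError(f"sequence {id!r} shorter than 2 residues after sanitization")
        return cls(id=id, sequence=seq)


@dataclass
class PropertyTable:
    """A named per-residue property scale."""

    name: str
    values: dict[str, float]
    standardized: bool = False

    def __post_init__(self):
        if set(self.values) != set(ALPHABET):
            raise ConfigError(f"property {self.name!r} must cover exactly the 20 residues")

    def standardized_table(self) -> "PropertyTable":
        if self.standardized:
            return self
        return PropertyTable(self.name, aadata.standardize_scale(self.values), True)

    def encode(self, sequence: str) -> np.ndarray:
        return np.array([self.values[r] for r in sequence], dtype=float)


def _check_record(seq: ProteinRecord) -> str:
    s = seq.sequence
    for pos, res in enumerate(s, start=1):
        if res not in _INDEX:
            raise SequenceError(f"nonstandard residue {res!r} at position {pos} of {seq.id!r}")
    if len(s) < 2:
        raise SequenceError(f"sequence {seq.id!r} shorter than 2 residues")
    return s


# ---------------------------------------------------------------------------
# family 1: amino-acid + dipeptide composition (420)
# ---------------------------------------------------------------------------

def composition_features(seq: ProteinRecord) -> FeatureVector:
    """AAC (20 residue frequencies) followed by DPC (400 dipeptide frequencies).

    Both blocks are frequencies over the sequence (AAC over L residues, DPC
    over the L-1 adjacent pairs) and each sums to 1.
    """
    s = _check_record(seq)
    L = len(s)
    aac = np.zeros(20)
    for r in s:
        aac[_INDEX[r]] += 1
    aac /= L
    dpc = np.zeros(400)
    for i in range(L - 1):
        dpc[_INDEX[s[i]] * 20 + _INDEX[s[i + 1]]] += 1
    dpc /= L - 1
    names = [f"AAC_{r}" for r in ALPHABET] + [f"DPC_{d}" for d in DIPEPTIDES]
    return FeatureVector(seq.id, names, np.concatenate([aac, dpc]))


# ---------------------------------------------------------------------------
# family 2: autocorrelation (|scales| * maxlag)
# ---------------------------------------------------------------------------

_AC_KINDS = ("moreau_broto", "moran", "geary")


def autocorrelation_features(
    seq: ProteinRecord,
    properties: list[PropertyTable],
    maxlag: int = 30,
    kind: str = "moreau_broto",
) -> FeatureVector:
    """Lagged autocorrelation of standardized property profiles.

    * normalized Moreau-Broto: ``AC(d) = sum_i p_i p_{i+d} / (L-d)``
    * Moran: centered products over sequence variance
    * Geary: half mean squared lag difference over (L-1)-normalized variance

    Zero-variance profiles (e.g. homopolymers) yield 0 by convention for the
    centered forms.
    """
    if kind not in _AC_KINDS:
        raise ConfigError(f"unknown autocorrelation kind {kind!r}")
    s = _check_record(seq)
    L = len(s)
    if L <= maxlag:
        raise SequenceError(
            f"sequence {seq.id!r} has length {L}; autocorrelation with maxlag "
            f"{maxlag} needs length >= {maxlag + 1}"
        )
    names, vals = [], []
    prefix = {"moreau_broto": "MB", "moran": "MORAN", "geary": "GEARY"}[kind]
    for prop in properties:
        p = prop.standardized_table().encode(s)
        pbar = p.mean()
        centered = p - pbar
        # zero-variance profiles (e.g. homopolymers) -> 0 by convention; the
        # epsilon absorbs float residue of "constant" profiles on O(1) scales
        var_l = float(centered @ centered) / L
        var_l1 = float(centered @ centered) / (L - 1)
        if var_l < 1e-12:
            var_l = var_l1 = 0.0
        for d in range(1, maxlag + 1):
            if kind == "moreau_broto":
                v = float(p[:-d] @ p[d:]) / (L - d)
            elif kind == "moran":
                num = float(centered[:-d] @ centered[d:]) / (L - d)
                v = num / var_l if var_l > 0 else 0.0
            else:  # geary
                num = float(((p[:-d] - p[d:]) ** 2).sum()) / (2 * (L - d))
                v = num / var_l1 if var_l1 > 0 else 0.0
            names.append(f"{prefix}_{prop.name}_d{d}")
            vals.append(v)
    return FeatureVector(seq.id, names, np.array(vals))


def default_autocorrelation_properties() -> list[PropertyTable]:
    """The 8 standard physicochemical scales of the default profile."""
    return [PropertyTable(n, dict(v)) for n, v in aadata.AUTOCORRELATION_SCALES.items()]


# ---------------------------------------------------------------------------
# family 3: composition / transition / distribution (147)
# ---------------------------------------------------------------------------

def _group_index(groups: tuple[str, str, str]) -> dict[str, int]:
    gi = {}
    for g, members in enumerate(groups):
        for r in members:
            gi[r] = g
    return gi


def ctd_features(
    seq: ProteinRecord,
    groupings: dict[str, tuple[str, str, str]] | None = None,
) -> FeatureVector:
    """Composition, transition and distribution over grouped residue classes.

    For each attribute the alphabet is split into three groups. Composition is
    the per-group residue fraction; transition is the fraction of adjacent
    pairs crossing each unordered group pair; distribution reports the 1-based
    positions of the first and the 25/50/75/100 % occurrence of each group as
    a percentage of the sequence length (0 for an absent group).
    """
    groupings = groupings or aadata.CTD_GROUPS
    s = _check_record(seq)
    L = len(s)
    comp_names, comp_vals = [], []
    tran_names, tran_vals = [], []
    dist_names, dist_vals = [], []
    for attr, groups in groupings.items():
        gi = _group_index(groups)
        labels = np.array([gi[r] for r in s])
        # composition
        for g in range(3):
            comp_names.append(f"CTD_C_{attr}_g{g + 1}")
            comp_vals.append(float((labels == g).sum()) / L)
        # transition
        pairs = list(zip(labels[:-1], labels[1:]))
        for a, b in ((0, 1), (0, 2), (1, 2)):
            n = sum(1 for x, y in pairs if (x, y) == (a, b) or (x, y) == (b, a))
            tran_names.append(f"CTD_T_{attr}_g{a + 1}g{b + 1}")
            tran_vals.append(n / (L - 1))
        # distribution
        for g in range(3):
            positions = np.flatnonzero(labels == g) + 1  # 1-based
            n = positions.size
            for frac, tag in ((0.0, "first"), (0.25, "p25"), (0.5, "p50"),
                              (0.75, "p75"), (1.0, "p100")):
                if n == 0:
                    v = 0.0
                else:
                    k = 1 if frac == 0.0 else max(1, int(np.ceil(frac * n)))
                    v = positions[k - 1] / L * 100.0
                dist_names.append(f"CTD_D_{attr}_g{g + 1}_{tag}")
                dist_vals.append(v)
    names = comp_names + tran_names + dist_names
    vals = comp_vals + tran_vals + dist_vals
    return FeatureVector(seq.id, names, np.array(vals))


# ---------------------------------------------------------------------------
# family 4: sequence-order coupling + quasi-sequence-order (2m + 2(20+m))
# ---------------------------------------------------------------------------

def default_distance_matrices() -> dict[str, np.ndarray]:
    return {
        "grantham": aadata.grantham_distance_matrix(),
        "physicochemical": aadata.physicochemical_distance_matrix(),
    }


def order_features(
    seq: ProteinRecord,
    maxlag: int = 30,
    weight: float = 0.1,
    matrices: dict[str, np.ndarray] | None = None,
) -> FeatureVector:
    """Sequence-order coupling numbers and quasi-sequence-order descriptors.

    For each residue-distance matrix, the coupling number at lag d is
    ``tau_d = sum_i dist(r_i, r_{i+d})^2``. The quasi-sequence-order block is
    ``X_r = f_r / (1 + w * sum tau)`` for the 20 residues (f_r = residue
    frequency) followed by ``X_{20+d} = w * tau_d / (1 + w * sum tau)``.
    """
    matrices = matrices or default_distance_matrices()
    s = _check_record(seq)
    L = len(s)
    if L <= maxlag:
        raise SequenceError(
            f"sequence {seq.id!r} has length {L}; order descriptors with maxlag "
            f"{maxlag} need length >= {maxlag + 1}"
        )
    idx = np.array([_INDEX[r] for r in s])
    freq = np.bincount(idx, minlength=20) / L
    names, vals = [], []
    qso_names, qso_vals = [], []
    for mname, dm in matrices.items():
        tau = np.empty(maxlag)
        for d in range(1, maxlag + 1):
            tau[d - 1] = float((dm[idx[:-d], idx[d:]] ** 2).sum())
        names += [f"SOC_{mname}_d{d}" for d in range(1, maxlag + 1)]
        vals += list(tau)
        denom = 1.0 + weight * tau.sum()
        qso_names += [f"QSO_{mname}_{r}" for r in ALPHABET]
        qso_vals += list(freq / denom)
        qso_names += [f"QSO_{mname}_d{d}" for d in range(1, maxlag + 1)]
        qso_vals += list(weight * tau / denom)
    return FeatureVector(seq.id, names + qso_names, np.array(vals + qso_vals))


# ---------------------------------------------------------------------------
# family 5: amphiphilic pseudo-amino-acid composition (20 + 2*lam)
# ---------------------------------------------------------------------------

def apaac_features(
    seq: ProteinRecord,
    lam: int = 30,
    weight: float = 0.05,
    hydrophobicity: dict[str, float] | None = None,
    hydrophilicity: dict[str, float] | None = None,
) -> FeatureVector:
    """Amphiphilic pseudo-amino-acid composition.

    Sequence-correlation factors alternate hydrophobicity and hydrophilicity:
    ``tau_{2j-1} = mean_i h1_i h1_{i+j}``, ``tau_{2j} = mean_i h2_i h2_{i+j}``
    with both scales standardized. The 20 composition terms and the 2*lam
    correlation terms share the denominator ``1 + w * sum tau``; at w = 0 the
    first 20 values reduce to the plain amino-acid composition.
    """
    s = _check_record(seq)
    L = len(s)
    if L <= lam:
        raise SequenceError(
            f"sequence {seq.id!r} has length {L}; APAAC with lambda {lam} "
            f"needs length >= {lam + 1}"
        )
    h1 = PropertyTable("h1", hydrophobicity or aadata.PSEAAC_HYDROPHOBICITY)
    h2 = PropertyTable("h2", hydrophilicity or aadata.PSEAAC_HYDROPHILICITY)
    p1 = h1.standardized_table().encode(s)
    p2 = h2.standardized_table().encode(s)
    idx = np.array([_INDEX[r] for r in s])
    freq = np.bincount(idx, minlength=20) / L
    tau = np.empty(2 * lam)
    for j in range(1, lam + 1):
        tau[2 * j - 2] = float(p1[:-j] @ p1[j:]) / (L - j)
        tau[2 * j - 1] = float(p2[:-j] @ p2[j:]) / (L - j)
    denom = 1.0 + weight * tau.sum()
    names = [f"APAAC_{r}" for r in ALPHABET]
    for j in range(1, lam + 1):
        names += [f"APAAC_hb_d{j}", f"APAAC_hl_d{j}"]
    vals = np.concatenate([freq / denom, weight * tau / denom])
    return FeatureVector(seq.id, names, vals)


# ---------------------------------------------------------------------------
# family 6: sequence-averaged amino-acid properties (33)
# ---------------------------------------------------------------------------

def aaprop_features(
    seq: ProteinRecord,
    property_set: list[PropertyTable] | None = None,
) -> FeatureVector:
    """One value per property: the sequence mean of the standardized scale."""
    if property_set is None:
        property_set = default_aaprop_properties()
    if not property_set:
        raise ConfigError("empty property set")
    s = _check_record(seq)
    names, vals = [], []
    for prop in property_set:
        p = prop.standardized_table().encode(s)
        names.append(f"AAPROP_{prop.name}")
        vals.append(float(p.mean()))
    return FeatureVector(seq.id, names, np.array(vals))


def default_aaprop_properties() -> list[PropertyTable]:
    """The default 33 averaged scales (see aadata.aaprop_scales)."""
    return [PropertyTable(n, dict(v)) for n, v in aadata.aaprop_scales().items()]


# ---------------------------------------------------------------------------
# profile: family concatenation
# ---------------------------------------------------------------------------

@dataclass
class DescriptorProfile:
    """Configuration of the concatenated protein descriptor vector.

    The default profile totals exactly 1080 dimensions:
    AAC 20 + DPC 400 + Moreau-Broto 8x30 + CTD 147 + SOC 60 + QSO 100
    + APAAC 80 + 33 averaged properties. A family is disabled by setting its
    flag/parameter to False/None. ``declared_total`` is checked against the
    computed length so a profile cannot silently drift.
    """

    version: str = "1.0"
    composition: bool = True
    autocorrelation_kind: str | None = "moreau_broto"
    autocorrelation_maxlag: int = 30
    autocorrelation_scales: list[str] = field(
        default_factory=lambda: list(aadata.AUTOCORRELATION_SCALES)
    )
    ctd: bool = True
    order_maxlag: int | None = 30
    order_weight: float = 0.1
    apaac_lam: int | None = 30
    apaac_weight: float = 0.05
    aaprop: bool = True
    declared_total: int | None = 1080

    def __post_init__(self):
        if self.autocorrelation_kind is not None and self.autocorrelation_kind not in _AC_KINDS:
            raise ConfigError(f"unknown autocorrelation kind {self.autocorrelation_kind!r}")
        for name in self.autocorrelation_scales:
            if name not in aadata.AUTOCORRELATION_SCALES:
                raise ConfigError(f"unknown autocorrelation scale {name!r}")
        if self.declared_total is not None and self.declared_total != self.expected_length():
            raise ConfigError(
                f"profile declares {self.declared_total} dimensions but computes "
                f"{self.expected_length()}"
            )

    def expected_length(self) -> int:
        n = 0
        if self.composition:
            n += 420
        if self.autocorrelation_kind is not None:
            n += len(self.autocorrelation_scales) * self.autocorrelation_maxlag
        if self.ctd:
            n += 147
        if self.order_maxlag is not None:
            n += 2 * self.order_maxlag + 2 * (20 + self.order_maxlag)
        if self.apaac_lam is not None:
            n += 20 + 2 * self.apaac_lam
        if self.aaprop:
            n += 33
        return n

    def min_sequence_length(self) -> int:
        """Strictest family precondition (maxlag + 1 for lag-based families)."""
        m = 2
        if self.autocorrelation_kind is not None:
            m = max(m, self.autocorrelation_maxlag + 1)
        if self.order_maxlag is not None:
            m = max(m, self.order_maxlag + 1)
        if self.apaac_lam is not None:
            m = max(m, self.apaac_lam + 1)
        return m

    # -- YAML round trip -----------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DescriptorProfile":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError("profile YAML must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown profile keys: {sorted(unknown)}")
        return cls(**data)


def featurize_protein(seq: ProteinRecord, profile: DescriptorProfile | None = None) -> FeatureVector:
    """Concatenate the profile's family blocks in fixed order.

    Family errors propagate with the failing family named.
    """
    profile = profile or DescriptorProfile()
    blocks: list[FeatureVector] = []

    def run(family: str, fn, *args, **kw):
        try:
            blocks.append(fn(*args, **kw))
        except SequenceError as e:
            raise SequenceError(f"[{family}] {e}") from e

    if profile.composition:
        run("composition", composition_features, seq)
    if profile.autocorrelation_kind is not None:
        props = [
            PropertyTable(n, dict(aadata.AUTOCORRELATION_SCALES[n]))
            for n in profile.autocorrelation_scales
        ]
        run("autocorrelation", autocorrelation_features, seq, props,
            profile.autocorrelation_maxlag, profile.autocorrelation_kind)
    if profile.ctd:
        run("ctd", ctd_features, seq)
    if profile.order_maxlag is not None:
        run("order", order_features, seq, profile.order_maxlag, profile.order_weight)
    if profile.apaac_lam is not None:
        run("apaac", apaac_features, seq, profile.apaac_lam, profile.apaac_weight)
    if profile.aaprop:
        run("aaprop", aaprop_features, seq)

    names = [n for b in blocks for n in b.names]
    values = np.concatenate([b.values for b in blocks])
    return FeatureVector(seq.id, names, values)


# ---------------------------------------------------------------------------
# FASTA -> DescriptorMatrix
# ---------------------------------------------------------------------------

def read_fasta(path, sanitize: bool = False) -> list[ProteinRecord]:
    """Read a multi-record FASTA into validated protein records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord.from_raw(rec.id, str(rec.seq), sanitize=sanitize))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def featurize_proteins(
    records: list[ProteinRecord],
    profile: DescriptorProfile | None = None,
) -> DescriptorMatrix:
    profile = profile or DescriptorProfile()
    return DescriptorMatrix.from_vectors([featurize_protein(r, profile) for r in records])
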