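"""Amino-acid property tables and residue groupings used by the protein descriptors.

All scales are standard published physicochemical tables (see docs/methods.md for
provenance). Every lag/correlation descriptor standardizes its scale to zero mean
and unit variance over the 20 residues before use, so the absolute units of a
scale never enter the feature values.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard residues, in fixed alphabetical (one-letter) order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: All 400 dipeptides in alphabetical order.
DIPEPTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)

#: Residue letters stripped (with a warning) when sanitizing, rejected otherwise.
NONSTANDARD = set("BJOUXZ*")


def _table(values: str) -> dict[str, float]:
    """Parse 'A:0.62 C:0.29 ...' into a residue->value map; must cover ALPHABET."""
    out = {}
    for item in values.split():
        res, val = item.split(":")
        out[res] = float(val)
    assert set(out) == set(ALPHABET)
    return out


# --- scales used by the autocorrelation family (8 scales x 30 lags = 240) ---

#: Hydropathy (Kyte-Doolittle).
HYDROPHOBICITY_KYTE_DOOLITTLE = _table(
    "A:1.8 R:-4.5 N:-3.5 D:-3.5 C:2.5 Q:-3.5 E:-3.5 G:-0.4 H:-3.2 I:4.5 "
    "L:3.8 K:-3.9 M:1.9 F:2.8 P:-1.6 S:-0.8 T:-0.7 W:-0.9 Y:-1.3 V:4.2"
)

#: Hydrophobicity (Eisenberg consensus scale, the pseudo-AAC convention).
HYDROPHOBICITY_EISENBERG = _table(
    "A:0.62 R:-2.53 N:-0.78 D:-0.90 C:0.29 Q:-0.85 E:-0.74 G:0.48 H:-0.40 "
    "I:1.38 L:1.06 K:-1.50 M:0.64 F:1.19 P:0.12 S:-0.18 T:-0.05 W:0.81 "
    "Y:0.26 V:1.08"
)

#: Hydrophilicity (Hopp-Woods).
HYDROPHILICITY_HOPP_WOODS = _table(
    "A:-0.5 R:3.0 N:0.2 D:3.0 C:-1.0 Q:0.2 E:3.0 G:0.0 H:-0.5 I:-1.8 "
    "L:-1.8 K:3.0 M:-1.3 F:-2.5 P:0.0 S:0.3 T:-0.4 W:-3.4 Y:-2.3 V:-1.5"
)

#: Average backbone flexibility index (Bhaskaran-Ponnuswamy).
FLEXIBILITY = _table(
    "A:0.357 R:0.529 N:0.463 D:0.511 C:0.346 Q:0.493 E:0.497 G:0.544 "
    "H:0.323 I:0.462 L:0.365 K:0.466 M:0.295 F:0.314 P:0.509 S:0.507 "
    "T:0.444 W:0.305 Y:0.420 V:0.386"
)

#: Side-chain polarizability (Charton-Charton).
POLARIZABILITY = _table(
    "A:0.046 R:0.291 N:0.134 D:0.105 C:0.128 Q:0.180 E:0.151 G:0.000 "
    "H:0.230 I:0.186 L:0.186 K:0.219 M:0.221 F:0.290 P:0.131 S:0.062 "
    "T:0.108 W:0.409 Y:0.298 V:0.140"
)

#: Free energy of solution in water (Charton-Charton).
FREE_ENERGY = _table(
    "A:-0.368 R:-1.03 N:0.0 D:2.06 C:4.53 Q:0.731 E:1.77 G:-0.525 H:0.0 "
    "I:0.791 L:1.07 K:0.0 M:0.656 F:1.06 P:-2.24 S:-0.524 T:0.0 W:1.60 "
    "Y:4.91 V:0.401"
)

#: Residue accessible surface area in a tripeptide (Chothia).
RESIDUE_ASA = _table(
    "A:115 R:225 N:160 D:150 C:135 Q:180 E:190 G:75 H:195 I:175 L:170 "
    "K:200 M:185 F:210 P:145 S:115 T:140 W:255 Y:230 V:155"
)

#: Residue volume (Bigelow).
RESIDUE_VOLUME = _table(
    "A:88.6 R:173.4 N:114.1 D:111.1 C:108.5 Q:143.8 E:138.4 G:60.1 "
    "H:153.2 I:166.7 L:166.7 K:168.6 M:162.9 F:189.9 P:112.7 S:89.0 "
    "T:116.1 W:227.8 Y:193.6 V:140.0"
)

#: Relative mutability (Dayhoff).
MUTABILITY = _table(
    "A:100 R:65 N:134 D:106 C:20 Q:93 E:102 G:49 H:66 I:96 L:40 K:56 "
    "M:94 F:41 P:56 S:120 T:97 W:18 Y:41 V:74"
)

AUTOCORRELATION_SCALES = {
    "hydrophobicity": HYDROPHOBICITY_KYTE_DOOLITTLE,
    "hydrophilicity": HYDROPHILICITY_HOPP_WOODS,
    "flexibility": FLEXIBILITY,
    "polarizability": POLARIZABILITY,
    "free_energy": FREE_ENERGY,
    "residue_asa": RESIDUE_ASA,
    "residue_volume": RESIDUE_VOLUME,
    "mutability": MUTABILITY,
}

# --- scales used by the amphiphilic pseudo-amino-acid composition ---

PSEAAC_HYDROPHOBICITY = HYDROPHOBICITY_EISENBERG
PSEAAC_HYDROPHILICITY = HYDROPHILICITY_HOPP_WOODS

# --- monomer constants ---

#: Residue (monomer, water subtracted) molecular weight in Da.
MOLECULAR_WEIGHT = _table(
    "A:71.08 R:156.19 N:114.10 D:115.09 C:103.14 Q:128.13 E:129.12 "
    "G:57.05 H:137.14 I:113.16 L:113.16 K:128.17 M:131.19 F:147.18 "
    "P:97.12 S:87.08 T:101.10 W:186.21 Y:163.18 V:99.13"
)

#: Free amino-acid isoelectric point.
ISOELECTRIC_POINT = _table(
    "A:6.00 R:10.76 N:5.41 D:2.77 C:5.07 Q:5.65 E:3.22 G:5.97 H:7.59 "
    "I:6.02 L:5.98 K:9.74 M:5.74 F:5.48 P:6.30 S:5.68 T:5.60 W:5.89 "
    "Y:5.66 V:5.96"
)

# --- Dubchak-style three-group partitions for the C/T/D descriptors ---
# Each attribute splits the alphabet into three disjoint, exhaustive groups.

CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASCTPD", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}

# --- Grantham (1974) side-chain components: composition, polarity, volume ---

GRANTHAM_COMPOSITION = _table(
    "A:0.0 R:0.65 N:1.33 D:1.38 C:2.75 Q:0.89 E:0.92 G:0.74 H:0.58 I:0.0 "
    "L:0.0 K:0.33 M:0.0 F:0.0 P:0.39 S:1.42 T:0.71 W:0.13 Y:0.20 V:0.0"
)
GRANTHAM_POLARITY = _table(
    "A:8.1 R:10.5 N:11.6 D:13.0 C:5.5 Q:10.5 E:12.3 G:9.0 H:10.4 I:5.2 "
    "L:4.9 K:11.3 M:5.7 F:5.2 P:8.0 S:9.2 T:8.6 W:5.4 Y:6.2 V:5.9"
)
GRANTHAM_VOLUME = _table(
    "A:31 R:124 N:56 D:54 C:55 Q:85 E:83 G:3 H:96 I:111 L:111 K:119 "
    "M:105 F:132 P:32.5 S:32 T:61 W:170 Y:136 V:84"
)


def standardize_scale(scale: dict[str, float]) -> dict[str, float]:
    """Zero-mean, unit-variance version of a scale over the 20 residues.

    Uses the population standard deviation (denominator 20), the convention of
    the pseudo-amino-acid composition literature.
    """
    vals = np.array([scale[r] for r in ALPHABET], dtype=float)
    mu, sd = vals.mean(), vals.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant property scale")
    return {r: (scale[r] - mu) / sd for r in ALPHABET}


def scale_vector(scale: dict[str, float]) -> np.ndarray:
    """Scale values as an array ordered like ALPHABET."""
    return np.array([scale[r] for r in ALPHABET], dtype=float)


def _distance_matrix_from_components(components: list[dict[str, float]],
                                     weights: list[float]) -> np.ndarray:
    """Weighted Euclidean residue-residue distance, max-normalized to [0, 1]."""
    cols = [scale_vector(c) for c in components]
    n = len(ALPHABET)
    d = np.zeros((n, n))
    for k, (col, w) in enumerate(zip(cols, weights)):
        diff = col[:, None] - col[None, :]
        d += w * diff**2
    d = np.sqrt(d)
    return d / d.max()


def grantham_distance_matrix() -> np.ndarray:
    """Grantham chemical distance (composition/polarity/volume), max-normalized.

    Built from Grantham's published component tables with his weighting
    constants; the overall scale factor is irrelevant after normalization.
    """
    return _distance_matrix_from_components(
        [GRANTHAM_COMPOSITION, GRANTHAM_POLARITY, GRANTHAM_VOLUME],
        [1.833, 0.1018, 0.000399],
    )


def physicochemical_distance_matrix() -> np.ndarray:
    """Euclidean residue distance over standardized hydrophobicity,
    hydrophilicity and side-chain volume, max-normalized to [0, 1].

    A documented reconstruction of a second sequence-order distance matrix.
    """
    comps = [
        standardize_scale(PSEAAC_HYDROPHOBICITY),
        standardize_scale(PSEAAC_HYDROPHILICITY),
        standardize_scale(RESIDUE_VOLUME),
    ]
    return _distance_matrix_from_components(comps, [1.0, 1.0, 1.0])


def ctd_indicator_scales() -> dict[str, dict[str, float]]:
    """21 binary group-membership scales (7 attributes x 3 groups)."""
    out = {}
    for attr, groups in CTD_GROUPS.items():
        for gi, members in enumerate(groups, start=1):
            out[f"{attr}_g{gi}"] = {r: float(r in members) for r in ALPHABET}
    return out


def aaprop_scales() -> dict[str, dict[str, float]]:
    """The default 33 scales averaged by the total-property descriptor family.

    8 autocorrelation scales + pseudo-AAC hydrophobicity/hydrophilicity +
    molecular weight + isoelectric point + 21 CTD group indicators.
    """
    out = dict(AUTOCORRELATION_SCALES)
    out["pseaac_hydrophobicity"] = PSEAAC_HYDROPHOBICITY
    out["pseaac_hydrophilicity"] = PSEAAC_HYDROPHILICITY
    out["molecular_weight"] = MOLECULAR_WEIGHT
    out["isoelectric_point"] = ISOELECTRIC_POINT
    out.update(ctd_indicator_scales())
    assert len(out) == 33
    return out
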