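"""Physicochemical data tables used by the descriptor engine.

All scales are dictionaries keyed by one-letter amino-acid code over the 20
canonical residues.  Distance matrices are built at import time from their
defining scales and exposed as ``numpy`` arrays indexed by :data:`AA_INDEX`.

Provenance notes
----------------
* ``GRANTHAM`` is computed from Grantham's chemical-distance formula
  ``D_ij = rho * sqrt(a*(c_i-c_j)^2 + b*(p_i-p_j)^2 + g*(v_i-v_j)^2)`` over
  his composition / polarity / volume scales, with the conventional
  coefficients (a=1.833, b=0.1018, g=0.000399) and rho chosen so the mean
  off-diagonal distance is 100.  Spot values reproduce the published table
  (Leu-Ile = 5, Cys-Trp = 215).
* ``SCHNEIDER_WREDE`` is a SYNTHETIC stand-in for the Schneider-Wrede
  physicochemical distance matrix (the published table is not bundled).  It
  is the root-mean-square difference of standardized hydrophobicity,
  hydrophilicity and side-chain-mass scales, rescaled to [0, 1].  It has the
  same structure (20x20, symmetric, nonnegative, zero diagonal) and the same
  role in the quasi-sequence-order descriptors.
"""

from __future__ import annotations

import hashlib

import numpy as np

#: Canonical amino-acid alphabet, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# ---------------------------------------------------------------------------
# Scales for autocorrelation descriptors (8 standard documented scales)
# ---------------------------------------------------------------------------

#: Kyte & Doolittle hydropathy.
HYDROPATHY_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Hopp & Woods hydrophilicity.
HYDROPHILICITY_HW = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
    "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
    "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
    "Y": -2.3, "V": -1.5,
}

#: Side-chain mass (Da), the values conventionally used with Chou's PseAAC.
SIDE_CHAIN_MASS = {
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0, "Q": 72.0,
    "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0, "L": 57.0, "K": 73.0,
    "M": 75.0, "F": 91.0, "P": 42.0, "S": 31.0, "T": 45.0, "W": 130.0,
    "Y": 107.0, "V": 43.0,
}

#: Grantham (1974) polarity.
POLARITY_GRANTHAM = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}

#: Grantham (1974) side-chain volume.
VOLUME_GRANTHAM = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
}

#: Isoelectric point of the free amino acid.
ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
}

#: Chothia-style accessible surface area of residue X in Gly-X-Gly (A^2).
ACCESSIBLE_SURFACE = {
    "A": 115.0, "R": 225.0, "N": 160.0, "D": 150.0, "C": 135.0, "Q": 180.0,
    "E": 190.0, "G": 75.0, "H": 195.0, "I": 175.0, "L": 170.0, "K": 200.0,
    "M": 185.0, "F": 210.0, "P": 145.0, "S": 115.0, "T": 140.0, "W": 255.0,
    "Y": 230.0, "V": 155.0,
}

#: Zimmerman bulkiness.
BULKINESS_ZIMMERMAN = {
    "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46, "Q": 14.45,
    "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40, "L": 21.40, "K": 15.71,
    "M": 16.25, "F": 19.80, "P": 17.43, "S": 9.47, "T": 15.77, "W": 21.67,
    "Y": 18.03, "V": 21.57,
}

#: Name -> scale map for the autocorrelation families, in fixed order.
AUTOCORR_SCALES = {
    "hydropathy": HYDROPATHY_KD,
    "hydrophilicity": HYDROPHILICITY_HW,
    "sidechainmass": SIDE_CHAIN_MASS,
    "polarity": POLARITY_GRANTHAM,
    "volume": VOLUME_GRANTHAM,
    "isoelectric": ISOELECTRIC_POINT,
    "surfacearea": ACCESSIBLE_SURFACE,
    "bulkiness": BULKINESS_ZIMMERMAN,
}

# ---------------------------------------------------------------------------
# CTD groupings: 7 physicochemical properties x 3 residue groups
# (Dubchak's classic partition; prop5.G2 = neutral-charge group, etc.)
# ---------------------------------------------------------------------------

CTD_PROPERTIES = (
    ("hydrophobicity", ("RKEDQN", "GASTPHY", "CLVIMFW")),
    ("normwaalsvolume", ("GASCTPD", "NVEQIL", "MHKFRYW")),
    ("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    ("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    ("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    ("secondarystruct", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    ("solventaccess", ("ALFCGIVW", "RKQEND", "MSPTHY")),
)

# ---------------------------------------------------------------------------
# Conjoint-triad classes (Shen's 7-class reduced alphabet)
# ---------------------------------------------------------------------------

CTRIAD_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

# ---------------------------------------------------------------------------
# PseAAC property scales (hydrophobicity / hydrophilicity / side-chain mass)
# ---------------------------------------------------------------------------

#: Eisenberg consensus hydrophobicity, the scale conventionally used with
#: Chou's PseAAC.
PSEAAC_HYDROPHOBICITY = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}
PSEAAC_HYDROPHILICITY = HYDROPHILICITY_HW
PSEAAC_MASS = SIDE_CHAIN_MASS

#: Grantham composition scale (atomic weight ratio of hetero elements).
COMPOSITION_GRANTHAM = {
    "A": 0.0, "R": 0.65, "N": 1.33, "D": 1.38, "C": 2.75, "Q": 0.89,
    "E": 0.92, "G": 0.74, "H": 0.58, "I": 0.0, "L": 0.0, "K": 0.33,
    "M": 0.0, "F": 0.0, "P": 0.39, "S": 1.42, "T": 0.71, "W": 0.13,
    "Y": 0.20, "V": 0.0,
}


def scale_vector(scale: dict[str, float]) -> np.ndarray:
    """Return a scale as a length-20 array in :data:`AMINO_ACIDS` order."""
    return np.array([scale[aa] for aa in AMINO_ACIDS], dtype=float)


def standardize(scale: dict[str, float]) -> np.ndarray:
    """Standardize a scale to mean 0, sd 1 (population sd over 20 residues)."""
    v = scale_vector(scale)
    return (v - v.mean()) / v.std()


def _grantham_matrix() -> np.ndarray:
    c = scale_vector(COMPOSITION_GRANTHAM)
    p = scale_vector(POLARITY_GRANTHAM)
    v = scale_vector(VOLUME_GRANTHAM)
    d2 = (
        1.833 * (c[:, None] - c[None, :]) ** 2
        + 0.1018 * (p[:, None] - p[None, :]) ** 2
        + 0.000399 * (v[:, None] - v[None, :]) ** 2
    )
    d = np.sqrt(d2)
    off = d[~np.eye(20, dtype=bool)]
    return d * (100.0 / off.mean())


def _schneider_wrede_matrix() -> np.ndarray:
    # Synthetic stand-in (see module docstring): RMS difference of three
    # standardized scales, rescaled so the largest distance is 1.
    props = np.stack(
        [
            standardize(PSEAAC_HYDROPHOBICITY),
            standardize(PSEAAC_HYDROPHILICITY),
            standardize(PSEAAC_MASS),
        ]
    )
    diff2 = (props[:, :, None] - props[:, None, :]) ** 2
    d = np.sqrt(diff2.mean(axis=0))
    return d / d.max()


#: 20x20 Grantham chemical-distance matrix (mean off-diagonal = 100).
GRANTHAM = _grantham_matrix()

#: 20x20 synthetic Schneider-Wrede-style physicochemical distance matrix.
SCHNEIDER_WREDE = _schneider_wrede_matrix()


def table_checksums() -> dict[str, str]:
    """Short SHA-256 checksums of the bundled data tables."""
    out = {}
    for name, arr in (("grantham", GRANTHAM), ("schneider_wrede", SCHNEIDER_WREDE)):
        out[name] = hashlib.sha256(np.round(arr, 10).tobytes()).hexdigest()[:12]
    for name, scale in AUTOCORR_SCALES.items():
        payload = ",".join(f"{aa}:{scale[aa]:.6g}" for aa in AMINO_ACIDS)
        out[f"scale_{name}"] = hashlib.sha256(payload.encode()).hexdigest()[:12]
    return out
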