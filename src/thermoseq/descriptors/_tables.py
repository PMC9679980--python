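"""Vendored amino-acid property constants for the descriptor families.

All tables are keyed by the fixed alphabet ACDEFGHIKLMNPQRSTVWY. Sources
are standard published scales, named below by their customary identifiers:
AAindex entries for the eight autocorrelation scales, the classic
composition/transition/distribution (CTD) three-class groupings, the
conjoint-triad seven-class partition (Shen et al.), the
hydrophobicity/hydrophilicity/side-chain-mass scales of pseudo-amino-acid
composition (Chou), and Grantham's composition/polarity/volume components
from which the Grantham distance matrix is computed at import via

    d(a, b) = rho * sqrt(alpha (c_a-c_b)^2 + beta (p_a-p_b)^2 + gamma (v_a-v_b)^2)

with alpha=1.833, beta=0.1018, gamma=0.000399 and rho fixed so the mean of
the 190 pairwise distances is 100. The second sequence-order distance
matrix is a physicochemical distance built from the normalized
hydrophobicity, hydrophilicity and side-chain-mass scales (the same
ingredients as the classic sequence-order distance), scaled to unit mean.
"""

from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_IDX = {a: i for i, a in enumerate(AA)}


def _vec(d: dict[str, float]) -> np.ndarray:
    return np.array([d[a] for a in AA], dtype=float)


# ---------------------------------------------------------------- GAAC groups
#: Five-class physicochemical partition: aliphatic, aromatic, positively
#: charged, negatively charged, uncharged polar.
GAAC_GROUPS: dict[str, str] = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}
GAAC_ORDER = list(GAAC_GROUPS)

# ------------------------------------------------------------- conjoint triad
#: Seven-class partition by dipole and side-chain volume (conjoint triad).
CTRIAD_GROUPS: list[str] = ["AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"]

# ------------------------------------------------------------------ DDE codons
#: Number of codons per amino acid in the standard genetic code.
CODON_COUNT: dict[str, int] = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}

# ------------------------------------------------- autocorrelation scales (8)
#: AAindex scales used by the Moran / Geary / normalized Moreau-Broto
#: autocorrelation families.
AUTOCORR_SCALES: dict[str, dict[str, float]] = {
    # CIDH920105: normalized average hydrophobicity
    "CIDH920105": {
        "A": 0.02, "C": 0.77, "D": -1.04, "E": -1.14, "F": 1.35, "G": -0.80,
        "H": 0.26, "I": 1.81, "K": -0.41, "L": 1.14, "M": 1.00, "N": -0.77,
        "P": -0.09, "Q": -1.10, "R": -0.42, "S": -0.97, "T": -0.77,
        "V": 1.13, "W": 1.71, "Y": 1.11,
    },
    # BHAR880101: average flexibility index
    "BHAR880101": {
        "A": 0.357, "C": 0.346, "D": 0.511, "E": 0.497, "F": 0.314,
        "G": 0.544, "H": 0.323, "I": 0.462, "K": 0.466, "L": 0.365,
        "M": 0.295, "N": 0.463, "P": 0.509, "Q": 0.493, "R": 0.529,
        "S": 0.507, "T": 0.444, "V": 0.386, "W": 0.305, "Y": 0.420,
    },
    # CHAM820101: polarizability parameter
    "CHAM820101": {
        "A": 0.046, "C": 0.128, "D": 0.105, "E": 0.151, "F": 0.290,
        "G": 0.000, "H": 0.230, "I": 0.186, "K": 0.219, "L": 0.186,
        "M": 0.221, "N": 0.134, "P": 0.131, "Q": 0.180, "R": 0.291,
        "S": 0.062, "T": 0.108, "V": 0.140, "W": 0.409, "Y": 0.298,
    },
    # CHAM820102: free energy of solution in water
    "CHAM820102": {
        "A": -0.368, "C": 4.530, "D": 2.060, "E": 1.770, "F": 1.060,
        "G": -0.525, "H": 0.000, "I": 0.791, "K": 0.000, "L": 1.070,
        "M": 0.656, "N": 0.000, "P": -2.240, "Q": 0.731, "R": -1.030,
        "S": -0.524, "T": 0.000, "V": 0.401, "W": 1.600, "Y": 4.910,
    },
    # CHOC760101: residue accessible surface area in tripeptide
    "CHOC760101": {
        "A": 115.0, "C": 135.0, "D": 150.0, "E": 190.0, "F": 210.0,
        "G": 75.0, "H": 195.0, "I": 175.0, "K": 200.0, "L": 170.0,
        "M": 185.0, "N": 160.0, "P": 145.0, "Q": 180.0, "R": 225.0,
        "S": 115.0, "T": 140.0, "V": 155.0, "W": 255.0, "Y": 230.0,
    },
    # BIGC670101: residue volume
    "BIGC670101": {
        "A": 52.6, "C": 68.3, "D": 68.4, "E": 84.7, "F": 113.9, "G": 36.3,
        "H": 91.9, "I": 102.0, "K": 105.1, "L": 102.0, "M": 97.7,
        "N": 75.7, "P": 73.6, "Q": 89.7, "R": 109.1, "S": 54.9, "T": 71.2,
        "V": 85.1, "W": 135.4, "Y": 116.2,
    },
    # CHAM810101: steric parameter
    "CHAM810101": {
        "A": 0.52, "C": 0.62, "D": 0.76, "E": 0.68, "F": 0.70, "G": 0.00,
        "H": 0.70, "I": 1.02, "K": 0.68, "L": 0.98, "M": 0.78, "N": 0.76,
        "P": 0.36, "Q": 0.68, "R": 0.68, "S": 0.53, "T": 0.50, "V": 0.76,
        "W": 0.70, "Y": 0.70,
    },
    # DAYM780201: relative mutability
    "DAYM780201": {
        "A": 100.0, "C": 20.0, "D": 106.0, "E": 102.0, "F": 41.0, "G": 49.0,
        "H": 66.0, "I": 96.0, "K": 56.0, "L": 40.0, "M": 94.0, "N": 134.0,
        "P": 56.0, "Q": 93.0, "R": 65.0, "S": 120.0, "T": 97.0, "V": 74.0,
        "W": 18.0, "Y": 41.0,
    },
}

# -------------------------------------------------------- CTD groupings (13)
#: Each property partitions the alphabet into three classes.
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}
CTD_ORDER = list(CTD_GROUPS)

# ------------------------------------------- pseudo-amino-acid (PAAC) scales
#: Hydrophobicity (Tanford/Chou), hydrophilicity (Hopp-Woods) and side-chain
#: mass, as used by pseudo- and amphiphilic-pseudo-amino-acid composition.
PAAC_HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
PAAC_HYDROPHILICITY: dict[str, float] = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
PAAC_SIDECHAIN_MASS: dict[str, float] = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}

# ------------------------------------------------ Grantham distance components
_GRANTHAM_C = {
    "A": 0.00, "C": 2.75, "D": 1.38, "E": 0.92, "F": 0.00, "G": 0.74,
    "H": 0.58, "I": 0.00, "K": 0.33, "L": 0.00, "M": 0.00, "N": 1.33,
    "P": 0.39, "Q": 0.89, "R": 0.65, "S": 1.42, "T": 0.71, "V": 0.00,
    "W": 0.13, "Y": 0.20,
}
_GRANTHAM_P = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0,
    "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6,
    "P": 8.0, "Q": 10.5, "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9,
    "W": 5.4, "Y": 6.2,
}
_GRANTHAM_V = {
    "A": 31.0, "C": 55.0, "D": 54.0, "E": 83.0, "F": 132.0, "G": 3.0,
    "H": 96.0, "I": 111.0, "K": 119.0, "L": 111.0, "M": 105.0, "N": 56.0,
    "P": 32.5, "Q": 85.0, "R": 124.0, "S": 32.0, "T": 61.0, "V": 84.0,
    "W": 170.0, "Y": 136.0,
}


def _grantham_matrix() -> np.ndarray:
    c, p, v = _vec(_GRANTHAM_C), _vec(_GRANTHAM_P), _vec(_GRANTHAM_V)
    raw = np.sqrt(
        1.833 * np.subtract.outer(c, c) ** 2
        + 0.1018 * np.subtract.outer(p, p) ** 2
        + 0.000399 * np.subtract.outer(v, v) ** 2
    )
    off = raw[np.triu_indices(20, k=1)]
    return raw * (100.0 / off.mean())


def _physchem_matrix() -> np.ndarray:
    """Distance from normalized hydrophobicity/hydrophilicity/mass scales."""
    comps = []
    for table in (PAAC_HYDROPHOBICITY, PAAC_HYDROPHILICITY, PAAC_SIDECHAIN_MASS):
        x = _vec(table)
        comps.append((x - x.mean()) / x.std())
    stack = np.stack(comps)  # 3 x 20
    diff = stack[:, :, None] - stack[:, None, :]
    raw = np.sqrt((diff**2).sum(axis=0))
    off = raw[np.triu_indices(20, k=1)]
    return raw / off.mean()


#: 20x20 distance matrices used by the sequence-order families (SOCNumber,
#: QSOrder): the physicochemical distance above and the Grantham distance.
DISTANCE_MATRICES: dict[str, np.ndarray] = {
    "physicochemical": _physchem_matrix(),
    "grantham": _grantham_matrix(),
}
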