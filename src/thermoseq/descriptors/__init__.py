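"""Classical sequence-descriptor families (5,494 features in 20 blocks).

The default parameterization fixes every block at its canonical width:

    AAC 20, DPC 400, CKSAAP 2400, DDE 400, GAAC 5, CKSAAGP 150, GDPC 25,
    GTPC 125, Moran 240, Geary 240, NMBroto 240, CTDC 39, CTDT 39,
    CTDD 195, CTriad 343, KSCTriad 343, PAAC 50, APAAC 80, SOCNumber 60,
    QSOrder 100   (total 5,494)

Gap/lag parameters are the ones these widths imply: k-spaced pair families
use gaps 0..5, autocorrelations use 8 property scales with 30 lags, the
pseudo-composition families use lambda = 30, and the sequence-order
families use 30 lags over two 20x20 distance matrices. Lag-based families
therefore require sequences longer than 30 residues; the standard corpus
filter (length >= 100) guarantees this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..records import ProteinRecord
from . import _tables as T

__all__ = [
    "DescriptorVector",
    "ScalingStats",
    "FAMILY_DIMS",
    "FAMILIES",
    "compute_family",
    "compute_all",
    "fit_scaler",
    "apply_scaler",
]

NLAG = 30
MAX_GAP = 5
PAAC_LAMBDA = 30
PAAC_WEIGHT = 0.05
QSO_WEIGHT = 0.1

FAMILY_DIMS: dict[str, int] = {
    "AAC": 20, "DPC": 400, "CKSAAP": 2400, "DDE": 400, "GAAC": 5,
    "CKSAAGP": 150, "GDPC": 25, "GTPC": 125, "Moran": 240, "Geary": 240,
    "NMBroto": 240, "CTDC": 39, "CTDT": 39, "CTDD": 195, "CTriad": 343,
    "KSCTriad": 343, "PAAC": 50, "APAAC": 80, "SOCNumber": 60,
    "QSOrder": 100,
}
FAMILIES = list(FAMILY_DIMS)

#: Minimum sequence length per family under the default parameters.
_MIN_LEN: dict[str, int] = {
    "AAC": 1, "DPC": 2, "CKSAAP": MAX_GAP + 2, "DDE": 2, "GAAC": 1,
    "CKSAAGP": MAX_GAP + 2, "GDPC": 2, "GTPC": 3,
    "Moran": NLAG + 1, "Geary": NLAG + 1, "NMBroto": NLAG + 1,
    "CTDC": 1, "CTDT": 2, "CTDD": 1, "CTriad": 3, "KSCTriad": 3,
    "PAAC": PAAC_LAMBDA + 1, "APAAC": PAAC_LAMBDA + 1,
    "SOCNumber": NLAG + 1, "QSOrder": NLAG + 1,
}


@dataclass
class DescriptorVector:
    """Named per-family blocks and their concatenation."""

    blocks: dict[str, np.ndarray]

    @property
    def total(self) -> np.ndarray:
        return np.concatenate([self.blocks[f] for f in FAMILIES])

    def names(self) -> list[str]:
        """Family-prefixed feature names aligned with :attr:`total`."""
        return [
            f"{fam}_{i}" for fam in FAMILIES for i in range(FAMILY_DIMS[fam])
        ]


@dataclass
class ScalingStats:
    mean: np.ndarray
    sd: np.ndarray


# --------------------------------------------------------------- primitives

def _indices(sequence: str) -> np.ndarray:
    try:
        return np.array([T.AA_IDX[a] for a in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from exc


def _group_map(groups: list[str] | tuple[str, ...]) -> np.ndarray:
    g = np.empty(20, dtype=np.int64)
    for gi, members in enumerate(groups):
        for a in members:
            g[T.AA_IDX[a]] = gi
    return g


_GAAC_MAP = _group_map([T.GAAC_GROUPS[k] for k in T.GAAC_ORDER])
_CTRIAD_MAP = _group_map(T.CTRIAD_GROUPS)
_CODONS = np.array([T.CODON_COUNT[a] for a in T.AA], dtype=float)


def _norm_scale(table: dict[str, float]) -> np.ndarray:
    x = T._vec(table)
    return (x - x.mean()) / x.std()


_AUTOCORR = [_norm_scale(t) for t in T.AUTOCORR_SCALES.values()]
_PAAC_SCALES = [
    _norm_scale(T.PAAC_HYDROPHOBICITY),
    _norm_scale(T.PAAC_HYDROPHILICITY),
    _norm_scale(T.PAAC_SIDECHAIN_MASS),
]


# ----------------------------------------------------------------- families

def _aac(idx: np.ndarray) -> np.ndarray:
    return np.bincount(idx, minlength=20) / len(idx)


def _kspaced_pairs(idx: np.ndarray, n_states: int, state: np.ndarray,
                   gaps: range) -> np.ndarray:
    blocks = []
    s = state[idx]
    for g in gaps:
        a, b = s[: len(s) - g - 1], s[g + 1 :]
        counts = np.bincount(a * n_states + b, minlength=n_states * n_states)
        blocks.append(counts / max(1, len(a)))
    return np.concatenate(blocks)


def _dpc(idx: np.ndarray) -> np.ndarray:
    counts = np.bincount(idx[:-1] * 20 + idx[1:], minlength=400)
    return counts / (len(idx) - 1)


def _dde(idx: np.ndarray) -> np.ndarray:
    L = len(idx)
    dc = np.bincount(idx[:-1] * 20 + idx[1:], minlength=400) / (L - 1)
    tm = np.outer(_CODONS / 61.0, _CODONS / 61.0).ravel()
    tv = tm * (1.0 - tm) / (L - 1)
    return (dc - tm) / np.sqrt(tv)


def _grouped_kmers(idx: np.ndarray, k: int) -> np.ndarray:
    g = _GAAC_MAP[idx]
    L = len(idx)
    code = np.zeros(L - k + 1, dtype=np.int64)
    for j in range(k):
        code = code * 5 + g[j : L - k + 1 + j]
    return np.bincount(code, minlength=5**k) / (L - k + 1)


def _autocorrelation(idx: np.ndarray, kind: str) -> np.ndarray:
    L = len(idx)
    out = np.zeros(len(_AUTOCORR) * NLAG)
    pos = 0
    for scale in _AUTOCORR:
        p = scale[idx]
        if np.ptp(p) == 0:  # homopolymer-like: property variance is 0
            if kind in ("moran", "geary"):
                pos += NLAG
                continue
        pbar = p.mean()
        centered = p - pbar
        var_n = float((centered**2).mean())          # Moran denominator
        var_n1 = float((centered**2).sum() / (L - 1))  # Geary denominator
        for d in range(1, NLAG + 1):
            a, b = p[: L - d], p[d:]
            if kind == "moran":
                num = float(((a - pbar) * (b - pbar)).mean())
                out[pos] = num / var_n if var_n > 0 else 0.0
            elif kind == "geary":
                num = float(((a - b) ** 2).sum() / (2.0 * (L - d)))
                out[pos] = num / var_n1 if var_n1 > 0 else 0.0
            else:  # normalized Moreau-Broto
                out[pos] = float((a * b).sum() / (L - d))
            pos += 1
    return out


def _ctd_classes(idx: np.ndarray, prop: str) -> np.ndarray:
    return _group_map(T.CTD_GROUPS[prop])[idx]


def _ctdc(idx: np.ndarray) -> np.ndarray:
    out = np.empty(39)
    for i, prop in enumerate(T.CTD_ORDER):
        cls = _ctd_classes(idx, prop)
        out[3 * i : 3 * i + 3] = np.bincount(cls, minlength=3) / len(idx)
    return out


def _ctdt(idx: np.ndarray) -> np.ndarray:
    out = np.empty(39)
    for i, prop in enumerate(T.CTD_ORDER):
        cls = _ctd_classes(idx, prop)
        a, b = cls[:-1], cls[1:]
        pairs = [(0, 1), (0, 2), (1, 2)]
        for j, (x, y) in enumerate(pairs):
            n = np.sum(((a == x) & (b == y)) | ((a == y) & (b == x)))
            out[3 * i + j] = n / (len(idx) - 1)
    return out


def _ctdd(idx: np.ndarray) -> np.ndarray:
    L = len(idx)
    out = np.zeros(195)
    pos = 0
    for prop in T.CTD_ORDER:
        cls = _ctd_classes(idx, prop)
        for c in range(3):
            where = np.flatnonzero(cls == c) + 1  # 1-based positions
            if len(where):
                for frac in (1, 25, 50, 75, 100):
                    nth = max(1, math.ceil(len(where) * frac / 100))
                    out[pos] = where[nth - 1] / L * 100.0
                    pos += 1
            else:
                pos += 5
    return out


def _ctriad(idx: np.ndarray, gap: int = 0) -> np.ndarray:
    g = _CTRIAD_MAP[idx]
    step = gap + 1
    L = len(idx)
    n = L - 2 * step
    if n < 1:
        raise ValueError(f"sequence too short for triads with gap {gap}")
    code = g[:n] * 49 + g[step : step + n] * 7 + g[2 * step : 2 * step + n]
    counts = np.bincount(code, minlength=343).astype(float)
    span = counts.max()
    return (counts - counts.min()) / span if span > 0 else counts


def _paac(idx: np.ndarray) -> np.ndarray:
    L = len(idx)
    theta = np.empty(PAAC_LAMBDA)
    for d in range(1, PAAC_LAMBDA + 1):
        acc = 0.0
        for scale in _PAAC_SCALES:
            p = scale[idx]
            acc += float(((p[: L - d] - p[d:]) ** 2).mean())
        theta[d - 1] = acc / len(_PAAC_SCALES)
    f = _aac(idx)
    den = 1.0 + PAAC_WEIGHT * theta.sum()
    return np.concatenate([f / den, PAAC_WEIGHT * theta / den])


def _apaac(idx: np.ndarray) -> np.ndarray:
    L = len(idx)
    hyd, hyl = _PAAC_SCALES[0][idx], _PAAC_SCALES[1][idx]
    tau = np.empty(2 * PAAC_LAMBDA)
    for d in range(1, PAAC_LAMBDA + 1):
        tau[2 * (d - 1)] = float((hyd[: L - d] * hyd[d:]).sum() / (L - d))
        tau[2 * (d - 1) + 1] = float((hyl[: L - d] * hyl[d:]).sum() / (L - d))
    f = _aac(idx)
    den = 1.0 + PAAC_WEIGHT * tau.sum()
    return np.concatenate([f / den, PAAC_WEIGHT * tau / den])


def _soc_taus(idx: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    L = len(idx)
    return np.array(
        [
            float((matrix[idx[: L - d], idx[d:]] ** 2).sum())
            for d in range(1, NLAG + 1)
        ]
    )


def _socnumber(idx: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [_soc_taus(idx, m) for m in T.DISTANCE_MATRICES.values()]
    )


def _qsorder(idx: np.ndarray) -> np.ndarray:
    f = _aac(idx)
    parts = []
    for m in T.DISTANCE_MATRICES.values():
        tau = _soc_taus(idx, m)
        den = 1.0 + QSO_WEIGHT * tau.sum()
        parts.append(f / den)
        parts.append(QSO_WEIGHT * tau / den)
    return np.concatenate(parts)


_DISPATCH = {
    "AAC": lambda i: _aac(i),
    "DPC": lambda i: _dpc(i),
    "CKSAAP": lambda i: _kspaced_pairs(i, 20, np.arange(20), range(MAX_GAP + 1)),
    "DDE": lambda i: _dde(i),
    "GAAC": lambda i: np.bincount(_GAAC_MAP[i], minlength=5) / len(i),
    "CKSAAGP": lambda i: _kspaced_pairs(i, 5, _GAAC_MAP, range(MAX_GAP + 1)),
    "GDPC": lambda i: _grouped_kmers(i, 2),
    "GTPC": lambda i: _grouped_kmers(i, 3),
    "Moran": lambda i: _autocorrelation(i, "moran"),
    "Geary": lambda i: _autocorrelation(i, "geary"),
    "NMBroto": lambda i: _autocorrelation(i, "nmbroto"),
    "CTDC": lambda i: _ctdc(i),
    "CTDT": lambda i: _ctdt(i),
    "CTDD": lambda i: _ctdd(i),
    "CTriad": lambda i: _ctriad(i, gap=0),
    "KSCTriad": lambda i: _ctriad(i, gap=0),
    "PAAC": lambda i: _paac(i),
    "APAAC": lambda i: _apaac(i),
    "SOCNumber": lambda i: _socnumber(i),
    "QSOrder": lambda i: _qsorder(i),
}


def compute_family(record: ProteinRecord, family: str) -> np.ndarray:
    """Compute one descriptor family at its canonical dimensionality."""
    if family not in _DISPATCH:
        raise ValueError(f"unknown descriptor family {family!r}")
    min_len = _MIN_LEN[family]
    if len(record.sequence) < min_len:
        raise ValueError(
            f"family {family}: sequence {record.id!r} has length "
            f"{len(record.sequence)}, minimum is {min_len}"
        )
    idx = _indices(record.sequence)
    vec = np.asarray(_DISPATCH[family](idx), dtype=float)
    assert vec.shape == (FAMILY_DIMS[family],)
    return vec


def compute_all(record: ProteinRecord) -> DescriptorVector:
    """All 20 families under the default parameterization (5,494 values)."""
    blocks = {fam: compute_family(record, fam) for fam in FAMILIES}
    return DescriptorVector(blocks=blocks)


def compute_matrix(records: list[ProteinRecord]) -> np.ndarray:
    """Stack :func:`compute_all` vectors into an ``n x 5494`` matrix."""
    return np.stack([compute_all(r).total for r in records])


# ------------------------------------------------------------------- scaling

def fit_scaler(matrix: np.ndarray) -> ScalingStats:
    """Per-feature mean/sd for standard scaling.

    The reference protocol fits on all samples pooled (train and test
    together); fitting on the training matrix only is the leakage-free
    alternative — the caller chooses what to pass in.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    return ScalingStats(mean=matrix.mean(axis=0), sd=matrix.std(axis=0))


def apply_scaler(matrix: np.ndarray, stats: ScalingStats) -> np.ndarray:
    """Standardize columns; constant columns map to 0."""
    matrix = np.asarray(matrix, dtype=float)
    sd = np.where(stats.sd > 0, stats.sd, 1.0)
    out = (matrix - stats.mean) / sd
    out[:, stats.sd == 0] = 0.0
    return out
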