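"""Synthetic labeled protein sets with a planted, recoverable thermal signal.

Sequences are drawn i.i.d. from configurable background residue
frequencies; short motifs are written over the background at recorded
positions and the label is a linear function of motif counts and residue
composition plus Gaussian noise:

    label = base + sum_m beta_m * count_m + sum_a c_a * freq_a + N(0, noise_sd)

The defaults emulate a mesophile-centred catalytic-temperature set at desk
scale: base 30 °C, one 5-residue motif worth +2.5 °C per occurrence
(0–4 occurrences per sequence), noise sd 2 °C, lengths 100–120 (so that
flank-extended occlusion inputs still fit a 128-residue model). Labels stay
strictly positive by construction, which keeps the relative occlusion score
(division by the unperturbed prediction) well-defined downstream.

Alongside sequences the generator emits fake annotations with a planted
truth: per-residue DSSP-style secondary structure in which motif positions
are forced to a designated code, and domain intervals, one covering each
motif occurrence (kept no longer than half the sequence so coverage
analysis treats them as eligible) plus one random decoy per sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import LabeledSet
from .records import ALPHABET, ProteinRecord

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "emulate_imbalance"]

#: Background secondary-structure states and weights (helix/strand-rich).
_SS_CODES = ["H", "E", "T", "S", "-", "B", "G"]
_SS_WEIGHTS = [0.33, 0.20, 0.12, 0.10, 0.20, 0.03, 0.02]
_SS_MEAN_RUN = 5.0

MOTIF_SS_CODE = "G"  # designated code planted at motif positions


@dataclass
class SyntheticSpec:
    n: int = 500
    length_range: tuple[int, int] = (100, 120)
    background_freqs: np.ndarray | None = None  # 20 probs in ALPHABET order
    motifs: tuple[tuple[str, float], ...] = (("FWYHC", 2.5),)
    max_motif_count: int = 4
    composition_effects: dict[str, float] = field(default_factory=dict)
    base: float = 30.0
    noise_sd: float = 2.0
    label_distribution: dict[int, int] | None = None  # 5° bin index -> count
    bin_width: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid length range {self.length_range}")
        for motif, _ in self.motifs:
            if len(motif) > lo:
                raise ValueError(
                    f"motif {motif!r} longer than minimum sequence length {lo}"
                )
            if not set(motif) <= set(ALPHABET):
                raise ValueError(f"motif {motif!r} has non-standard residues")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_freqs is not None:
            p = np.asarray(self.background_freqs, dtype=float)
            if p.shape != (20,) or abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
                raise ValueError("background_freqs must be 20 probabilities summing to 1")


@dataclass
class GroundTruth:
    """Per-record planted truth: motif positions (1-based starts), the
    per-record intercept actually used, and the noiseless label."""

    motif_positions: dict[str, list[tuple[str, int]]]
    intercepts: dict[str, float]
    noiseless_labels: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "motif_positions": self.motif_positions,
                    "intercepts": self.intercepts,
                    "noiseless_labels": self.noiseless_labels,
                },
                indent=2,
            )
        )


def _sample_ss(length: int, rng: np.random.Generator) -> str:
    """Run-length sampled secondary-structure string."""
    out: list[str] = []
    while len(out) < length:
        code = rng.choice(_SS_CODES, p=_SS_WEIGHTS)
        run = int(rng.geometric(1.0 / _SS_MEAN_RUN))
        out.extend(code * run)
    return "".join(out[:length])


def planted_label(spec: SyntheticSpec, sequence: str) -> float:
    """The noiseless label implied by a sequence under the planted function."""
    value = spec.base
    for motif, beta in spec.motifs:
        value += beta * _count_overlapping(sequence, motif)
        # motifs are inserted non-overlapping; overlap counting is only a
        # safeguard for adversarial inputs
    L = len(sequence)
    for aa, coef in spec.composition_effects.items():
        value += coef * sequence.count(aa) / L
    return value


def _count_overlapping(seq: str, motif: str) -> int:
    count = start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def _make_record(
    spec: SyntheticSpec,
    rid: str,
    rng: np.random.Generator,
    p: np.ndarray,
) -> tuple[ProteinRecord, list[tuple[str, int]], float]:
    lo, hi = spec.length_range
    L = int(rng.integers(lo, hi + 1))
    seq = list(rng.choice(list(ALPHABET), size=L, p=p))
    # Plant motifs at non-overlapping random positions (overwrite, no shift).
    placements: list[tuple[str, int]] = []  # (motif, 0-based start)
    taken: list[tuple[int, int]] = []
    for motif, _beta in spec.motifs:
        count = int(rng.integers(0, spec.max_motif_count + 1))
        m = len(motif)
        for _ in range(count):
            for _attempt in range(200):
                start = int(rng.integers(0, L - m + 1))
                if all(start + m <= s or start >= e for s, e in taken):
                    taken.append((start, start + m))
                    seq[start : start + m] = motif
                    placements.append((motif, start))
                    break
    sequence = "".join(seq)

    # Fake annotations: ss with motif positions forced to the designated
    # code; one eligible domain per motif occurrence plus a decoy.
    ss = list(_sample_ss(L, rng))
    domains: list[tuple[str, int, int]] = []
    half = L // 2
    for k, (motif, start) in enumerate(placements):
        m = len(motif)
        for j in range(start, start + m):
            ss[j] = MOTIF_SS_CODE
        max_len = max(m, min(half, m + 20))
        dlen = int(rng.integers(m, max_len + 1))
        dstart = int(rng.integers(max(0, start + m - dlen), min(start, L - dlen) + 1))
        domains.append((f"{rid}_motifdom{k + 1}", dstart + 1, dstart + dlen))
    if L >= 10:
        decoy_len = int(rng.integers(5, max(6, half + 1)))
        decoy_start = int(rng.integers(0, L - decoy_len + 1))
        domains.append((f"{rid}_decoy", decoy_start + 1, decoy_start + decoy_len))

    noiseless = planted_label(spec, sequence)
    record = ProteinRecord(
        id=rid, sequence=sequence, label=None, ss="".join(ss), domains=domains
    )
    return record, [(m, s + 1) for m, s in placements], noiseless


def generate(spec: SyntheticSpec) -> tuple[LabeledSet, GroundTruth]:
    """Generate a labeled set plus its ground-truth sidecar.

    Without ``label_distribution``, labels are the planted function of the
    sequence plus noise. With it, each record's intercept is shifted so the
    noiseless label lands uniformly inside a requested 5° bin (the planted
    motif/composition signal is preserved on top of the per-record
    intercept, which the sidecar records).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = (
        np.full(20, 0.05)
        if spec.background_freqs is None
        else np.asarray(spec.background_freqs, dtype=float)
    )
    p = p / p.sum()

    targets: list[int | None]
    if spec.label_distribution is None:
        targets = [None] * spec.n
    else:
        targets = []
        for b, count in sorted(spec.label_distribution.items()):
            targets.extend([b] * count)
        if len(targets) != spec.n:
            raise ValueError(
                f"label_distribution counts sum to {len(targets)}, expected n={spec.n}"
            )

    records: list[ProteinRecord] = []
    motif_positions: dict[str, list[tuple[str, int]]] = {}
    intercepts: dict[str, float] = {}
    noiseless_labels: dict[str, float] = {}
    for i, target_bin in enumerate(targets):
        rid = f"SYN{i + 1:05d}"
        rec, placements, noiseless = _make_record(spec, rid, rng, p)
        intercept = spec.base
        if target_bin is not None:
            u = rng.uniform(target_bin * spec.bin_width, (target_bin + 1) * spec.bin_width)
            intercept = spec.base + (u - noiseless)
            noiseless = u
        label = noiseless + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
        records.append(
            ProteinRecord(
                id=rid, sequence=rec.sequence, label=float(label),
                ss=rec.ss, domains=rec.domains,
            )
        )
        motif_positions[rid] = placements
        intercepts[rid] = float(intercept)
        noiseless_labels[rid] = float(noiseless)

    truth = GroundTruth(motif_positions, intercepts, noiseless_labels)
    return LabeledSet(records, name="synthetic"), truth


def emulate_imbalance(
    spec: SyntheticSpec,
    weights: tuple[float, float] = (0.9, 0.1),
    means: tuple[float, float] = (30.0, 70.0),
    sds: tuple[float, float] = (1.0, 1.0),
) -> LabeledSet:
    """Generate a set whose labels follow a two-component normal mixture.

    Emulates the mesophile-heavy bimodal shape of real growth-temperature
    corpora; the planted sequence signal is kept and each record's intercept
    absorbs the difference (a rebalanced subsample should flatten the
    histogram downstream).
    """
    spec.validate()
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(spec.seed)
    p = (
        np.full(20, 0.05)
        if spec.background_freqs is None
        else np.asarray(spec.background_freqs, dtype=float)
    )
    p = p / p.sum()
    records = []
    for i in range(spec.n):
        rid = f"MIX{i + 1:05d}"
        rec, _placements, _noiseless = _make_record(spec, rid, rng, p)
        comp = int(rng.random() >= weights[0])
        label = float(rng.normal(means[comp], sds[comp]))
        records.append(
            ProteinRecord(id=rid, sequence=rec.sequence, label=label,
                          ss=rec.ss, domains=rec.domains)
        )
    return LabeledSet(records, name="synthetic-imbalanced")
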