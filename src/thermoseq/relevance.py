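"""Occlusion-based model interpretation.

A *relevance profile* measures, per residue, how much the model's predicted
temperature changes when a short window of the input is hidden. For each
window position (stride 1) the window's one-hot columns are zeroed — the
same content as padding — and the relative prediction change

    score_window = (prediction_occluded - prediction_wt) / prediction_wt

is recorded. To give every residue a full complement of covering windows,
the sequence is first flanked on each side by ``width - 1`` copies of its
terminal residue; a residue's raw score is then the mean over the ``width``
windows covering it (a moving average over window scores). Scores are
standardized per protein and positions with |z| > 2 are called significant.

Downstream statistics: one-sided hypergeometric enrichment/depletion of
amino acids or secondary-structure codes at significant positions against
the pooled background, and domain-coverage analysis with an outside-domain
sliding-window control.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .records import ProteinRecord
from .seqio import encode_batch

__all__ = [
    "RelevanceProfile",
    "EnrichmentResult",
    "DomainCoverage",
    "occlusion_profile",
    "stability_check",
    "enrich",
    "domain_coverage",
    "select_domains",
    "write_profiles",
    "Z_THRESHOLD",
]

Z_THRESHOLD = 2.0


@dataclass
class RelevanceProfile:
    id: str
    scores: np.ndarray      # raw per-residue relative prediction changes
    z: np.ndarray           # per-protein standardized scores
    significant: np.ndarray  # |z| > 2
    width: int

    def __post_init__(self) -> None:
        if not (len(self.scores) == len(self.z) == len(self.significant)):
            raise ValueError("profile arrays must have equal length")


@dataclass
class EnrichmentResult:
    category: str
    k: int        # category count at significant positions
    n_sig: int    # significant positions (annotated)
    K: int        # background category count
    N: int        # background total (annotated positions)
    p_over: float
    p_under: float
    verdict: str  # enriched | depleted | neither


@dataclass
class DomainCoverage:
    domain: tuple[str, int, int]
    coverage: float
    control: float | None  # None when no full outside window exists
    eligible: bool


def _predictor(model):
    """Accept anything with a ``predict(records)`` method or a callable."""
    if hasattr(model, "predict"):
        return model.predict
    if callable(model):
        return model
    raise TypeError(f"cannot use {type(model).__name__} as a predictor")


def occlusion_profile(model, record: ProteinRecord, width: int = 5) -> RelevanceProfile:
    """Compute the per-residue occlusion relevance profile of one record.

    The model must accept sequences of the flanked length
    ``len(record) + 2 * (width - 1)``.
    """
    L = len(record.sequence)
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    if width >= L:
        raise ValueError(f"width {width} must be smaller than sequence length {L}")
    flank = width - 1
    flanked_seq = record.sequence[0] * flank + record.sequence + record.sequence[-1] * flank
    Lf = len(flanked_seq)
    flanked = ProteinRecord(id=record.id, sequence=flanked_seq)

    predict = _predictor(model)
    pred_wt = float(np.asarray(predict([flanked]))[0])
    if pred_wt == 0.0:
        raise ZeroDivisionError(
            f"record {record.id!r}: unperturbed prediction is 0; "
            "relative occlusion scores are undefined"
        )

    # One occluded variant per window start. For the package's network
    # models the occlusion zeroes the window's one-hot rows directly (the
    # same content as padding); for generic predictors — surrogate models
    # in tests, externally supplied callables — each call receives an
    # _OccludedRecord carrying the half-open masked range in `.occluded`.
    n_windows = Lf - width + 1  # = L + width - 1
    window_scores = np.empty(n_windows, dtype=float)
    if hasattr(model, "config") and hasattr(model, "_forward"):
        x = encode_batch([flanked] * n_windows, model.config.input_length)
        for s in range(n_windows):
            x[s, s : s + width, :] = 0.0
        preds = model._forward(x, training=False)[:, 0]
        window_scores = (preds - pred_wt) / pred_wt
    else:
        for s in range(n_windows):
            preds = predict([_OccludedRecord(flanked, s, width)])
            window_scores[s] = (float(np.asarray(preds)[0]) - pred_wt) / pred_wt

    # Residue i (0-based, original coordinates) sits at flanked index
    # flank + i and is covered by windows starting at s in [i, i + width - 1].
    scores = np.empty(L, dtype=float)
    for i in range(L):
        scores[i] = window_scores[i : i + width].mean()

    return profile_from_scores(record.id, scores, width)


def profile_from_scores(rid: str, scores: np.ndarray, width: int) -> RelevanceProfile:
    """Standardize raw per-residue scores into a profile.

    z-scores are per-protein (mean/sd of this profile); a flat profile
    (sd = 0) has all-zero z and no significant positions. Significance is
    the strict threshold |z| > 2.
    """
    scores = np.asarray(scores, dtype=float)
    sd = scores.std()
    if sd > 0:
        z = (scores - scores.mean()) / sd
    else:
        z = np.zeros_like(scores)
    significant = np.abs(z) > Z_THRESHOLD
    return RelevanceProfile(
        id=rid, scores=scores, z=z, significant=significant, width=width
    )


class _OccludedRecord(ProteinRecord):
    """A record carrying an occlusion mask, for mask-aware surrogate models."""

    def __init__(self, base: ProteinRecord, start: int, width: int):
        super().__init__(id=base.id, sequence=base.sequence)
        self.occluded = (start, start + width)  # half-open residue range


def stability_check(
    model, record: ProteinRecord, widths: tuple[int, ...] = (2, 5, 10, 20)
) -> np.ndarray:
    """Jaccard overlap of significant-position sets across occlusion widths.

    Two empty significant sets have Jaccard overlap 1.0 by convention.
    """
    sets = []
    for w in widths:
        prof = occlusion_profile(model, record, width=w)
        sets.append(set(np.flatnonzero(prof.significant).tolist()))
    k = len(widths)
    out = np.ones((k, k), dtype=float)
    for i, j in combinations(range(k), 2):
        union = sets[i] | sets[j]
        out[i, j] = out[j, i] = (
            1.0 if not union else len(sets[i] & sets[j]) / len(union)
        )
    return out


def enrich(
    profiles: list[RelevanceProfile],
    annotations: dict[str, str],
    alphabet: str,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Pooled hypergeometric enrichment of categories at significant positions.

    ``annotations`` maps record id to a per-residue category string (for
    amino-acid enrichment, the sequence itself; for secondary structure, a
    DSSP string). Characters outside ``alphabet`` mark unannotated positions
    and are excluded from background and significant counts alike. Both
    one-sided tails are computed; the verdict at level ``alpha`` follows the
    smaller tail. By default raw per-category p-values are thresholded;
    ``correction="benjamini-hochberg"`` applies a per-tail FDR adjustment
    across categories before the verdict (reported p-values stay raw).
    """
    bg: dict[str, int] = {c: 0 for c in alphabet}
    sig: dict[str, int] = {c: 0 for c in alphabet}
    N = n_sig = 0
    for prof in profiles:
        ann = annotations[prof.id]
        if len(ann) != len(prof.scores):
            raise ValueError(
                f"record {prof.id!r}: annotation length {len(ann)} != "
                f"profile length {len(prof.scores)}"
            )
        for pos, c in enumerate(ann):
            if c not in bg:
                continue  # unannotated: excluded everywhere
            N += 1
            bg[c] += 1
            if prof.significant[pos]:
                n_sig += 1
                sig[c] += 1

    raw = []
    for c in alphabet:
        K, k = bg[c], sig[c]
        p_over = float(hypergeom.sf(k - 1, N, K, n_sig)) if N else 1.0
        p_under = float(hypergeom.cdf(k, N, K, n_sig)) if N else 1.0
        raw.append((c, K, k, p_over, p_under))

    if correction is None:
        adj_over = [p for _, _, _, p, _ in raw]
        adj_under = [p for _, _, _, _, p in raw]
    elif correction == "benjamini-hochberg":
        adj_over = _bh_adjust([p for _, _, _, p, _ in raw])
        adj_under = _bh_adjust([p for _, _, _, _, p in raw])
    else:
        raise ValueError(f"unknown correction {correction!r}")

    results = []
    for (c, K, k, p_over, p_under), a_over, a_under in zip(raw, adj_over, adj_under):
        if min(a_over, a_under) < alpha and a_over != a_under:
            verdict = "enriched" if a_over < a_under else "depleted"
        else:
            verdict = "neither"
        results.append(
            EnrichmentResult(
                category=c, k=k, n_sig=n_sig, K=K, N=N,
                p_over=p_over, p_under=p_under, verdict=verdict,
            )
        )
    return results


def _bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, p[i] * m / (rank_from_top + 1))
        adj[i] = running
    return adj.tolist()


def domain_coverage(
    profile: RelevanceProfile, domains: list[tuple[str, int, int]]
) -> list[DomainCoverage]:
    """Significant-position coverage of domains with an outside control.

    For an eligible domain (length at most half the protein) spanning
    ``d`` residues, coverage is the fraction of its positions flagged
    significant. The control slides windows of length ``d`` (stride 1)
    across the contiguous outside segments: the number of significant
    positions outside, divided by the number of such windows, gives an
    expected per-window count, and dividing by ``d`` yields the control
    coverage fraction. If no full outside window fits, the control is
    reported as missing.
    """
    L = len(profile.scores)
    sig = profile.significant
    out = []
    for name, start, end in domains:
        if not (1 <= start <= end <= L):
            raise ValueError(
                f"domain {name!r}: interval [{start}, {end}] outside [1, {L}]"
            )
        d = end - start + 1
        eligible = d <= L / 2
        inside = sig[start - 1 : end].sum()
        coverage = float(inside) / d
        if not eligible:
            out.append(DomainCoverage((name, start, end), coverage, None, False))
            continue
        segments = [(0, start - 1), (end, L)]  # half-open outside segments
        n_windows = sum(max(0, (e - s) - d + 1) for s, e in segments)
        sig_out = int(sig[: start - 1].sum() + sig[end:].sum())
        control = (sig_out / n_windows) / d if n_windows > 0 else None
        out.append(DomainCoverage((name, start, end), coverage, control, True))
    return out


def select_domains(
    coverages: list[DomainCoverage], cutoff: float = 0.30
) -> list[str]:
    """Eligible domains with coverage >= cutoff, best-covered first."""
    hits = [c for c in coverages if c.eligible and c.coverage >= cutoff]
    hits.sort(key=lambda c: (-c.coverage, c.domain[0]))
    return [c.domain[0] for c in hits]


def write_profiles(
    profiles: list[RelevanceProfile],
    sequences: dict[str, str],
    path: str | Path,
) -> None:
    """TSV export: id, position (1-based), residue, score, z, significant."""
    with open(path, "w") as fh:
        fh.write("id\tposition\tresidue\tscore\tz\tsignificant\n")
        for prof in profiles:
            seq = sequences[prof.id]
            for i in range(len(prof.scores)):
                fh.write(
                    f"{prof.id}\t{i + 1}\t{seq[i]}\t{prof.scores[i]:.6g}\t"
                    f"{prof.z[i]:.6g}\t{int(prof.significant[i])}\n"
                )
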