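"""Sequence/label I/O, validity filtering, and one-hot encoding.

Reading and writing go through Biopython's FASTA machinery; label,
secondary-structure and domain tables are plain TSV. Filtering applies the
corpus-construction rules used throughout the package: sequences shorter
than ``min_len`` or longer than ``max_len`` residues, or containing any
non-standard amino acid, are rejected (boundary lengths are kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import AA_INDEX, ALPHABET, ProteinRecord

__all__ = [
    "ALPHABET",
    "FilterReport",
    "EncodedSequence",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "read_ss",
    "read_domains",
    "attach_annotations",
    "filter_records",
    "one_hot",
    "decode_one_hot",
    "encode_batch",
]

_STANDARD = frozenset(ALPHABET)


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


@dataclass
class FilterReport:
    """Outcome of :func:`filter_records`: kept records and rejections."""

    kept: list[ProteinRecord]
    rejected: list[tuple[str, str]]  # (id, reason)

    def __post_init__(self) -> None:
        reasons = {r for _, r in self.rejected}
        bad = reasons - {"too_short", "too_long", "nonstandard_aa"}
        if bad:
            raise ValueError(f"unknown rejection reasons: {sorted(bad)}")


@dataclass
class EncodedSequence:
    """A post-padded one-hot matrix (``L_max`` x 20) plus the true length."""

    matrix: np.ndarray
    true_length: int


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the record id and
    sequences are uppercased. Sequence data appearing before any header is a
    parse error naming the offending line.
    """
    path = Path(path)
    # Biopython silently ignores leading junk; detect it explicitly.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_labels(path: str | Path) -> list[tuple[str, float]]:
    """Read a two-column TSV of ``id <TAB> label`` (°C). No header."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric label {parts[1]!r}"
                ) from exc
            out.append((parts[0], value))
    return out


def write_labels(pairs: list[tuple[str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, value in pairs:
            fh.write(f"{rid}\t{value}\n")


def read_ss(path: str | Path) -> dict[str, str]:
    """Read a TSV of ``id <TAB> ss_string`` (DSSP codes)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>ss'")
            out[parts[0]] = parts[1]
    return out


def read_domains(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a TSV of ``id <TAB> domain_name <TAB> start <TAB> end``.

    Intervals are 1-based inclusive.
    """
    out: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 'id<TAB>name<TAB>start<TAB>end'"
                )
            out.setdefault(parts[0], []).append(
                (parts[1], int(parts[2]), int(parts[3]))
            )
    return out


def attach_annotations(
    records: list[ProteinRecord],
    labels: dict[str, float] | None = None,
    ss: dict[str, str] | None = None,
    domains: dict[str, list[tuple[str, int, int]]] | None = None,
) -> list[ProteinRecord]:
    """Return new records with label/ss/domain annotations attached by id."""
    out = []
    for r in records:
        out.append(
            ProteinRecord(
                id=r.id,
                sequence=r.sequence,
                label=labels.get(r.id, r.label) if labels else r.label,
                ss=ss.get(r.id, r.ss) if ss else r.ss,
                domains=domains.get(r.id, r.domains) if domains else r.domains,
            )
        )
    return out


def filter_records(
    records: list[ProteinRecord], min_len: int = 100, max_len: int = 2000
) -> FilterReport:
    """Classify records by the corpus validity rules.

    Keeps exactly the records with ``min_len <= length <= max_len`` whose
    residues all belong to the 20-letter standard alphabet (selenocysteine
    'U' and ambiguity codes count as non-standard). Every input is classified;
    nothing errors.
    """
    kept: list[ProteinRecord] = []
    rejected: list[tuple[str, str]] = []
    for r in records:
        n = len(r.sequence)
        if n < min_len:
            rejected.append((r.id, "too_short"))
        elif n > max_len:
            rejected.append((r.id, "too_long"))
        elif not _STANDARD.issuperset(r.sequence):
            rejected.append((r.id, "nonstandard_aa"))
        else:
            kept.append(r)
    return FilterReport(kept=kept, rejected=rejected)


def one_hot(record: ProteinRecord, L_max: int) -> EncodedSequence:
    """One-hot encode a record into an ``L_max`` x 20 matrix.

    Rows follow the sequence under the fixed alphabetical column ordering
    :data:`~thermoseq.records.ALPHABET`; rows beyond the sequence length are
    all-zero (post-padding).
    """
    L = len(record.sequence)
    if L > L_max:
        raise ValueError(
            f"record {record.id!r}: length {L} exceeds model input length {L_max}"
        )
    mat = np.zeros((L_max, 20), dtype=np.float32)
    try:
        idx = [AA_INDEX[aa] for aa in record.sequence]
    except KeyError as exc:
        raise ValueError(
            f"record {record.id!r}: non-standard residue {exc.args[0]!r}"
        ) from exc
    mat[np.arange(L), idx] = 1.0
    return EncodedSequence(matrix=mat, true_length=L)


def decode_one_hot(encoded: EncodedSequence) -> str:
    """Invert :func:`one_hot` on the first ``true_length`` rows."""
    rows = encoded.matrix[: encoded.true_length]
    return "".join(ALPHABET[i] for i in rows.argmax(axis=1))


def encode_batch(records: list[ProteinRecord], L_max: int) -> np.ndarray:
    """Stack one-hot encodings into an ``n x L_max x 20`` float32 array."""
    out = np.zeros((len(records), L_max, 20), dtype=np.float32)
    for i, r in enumerate(records):
        out[i] = one_hot(r, L_max).matrix
    return out
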