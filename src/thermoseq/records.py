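"""Core record types shared by every module.

A :class:`ProteinRecord` couples a sequence with an optional scalar thermal
label (OGT, T_opt or T_m in degrees Celsius) and optional per-residue
secondary-structure / domain annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 standard amino acids in alphabetical one-letter order. This ordering
#: is the fixed column order of every one-hot encoding produced by the package.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: DSSP 8-state secondary-structure codes ('-' denotes coil).
DSSP_CODES = "BEGHIST-"


@dataclass
class ProteinRecord:
    """One protein sequence with optional label and annotations.

    Parameters
    ----------
    id:
        Identifier (UniProt-style token).
    sequence:
        Amino-acid sequence; stored uppercased. Validity against the
        20-letter alphabet is *not* enforced here — that is the job of
        :func:`thermoseq.seqio.filter_records` — but basic structural
        invariants are.
    label:
        Optional temperature in °C.
    ss:
        Optional per-residue secondary-structure string (same length as the
        sequence). Characters outside :data:`DSSP_CODES` are treated as
        "unannotated" by downstream enrichment.
    domains:
        Optional list of ``(name, start, end)`` intervals, 1-based inclusive.
    """

    id: str
    sequence: str
    label: float | None = None
    ss: str | None = None
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.ss is not None and len(self.ss) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: secondary-structure length "
                f"{len(self.ss)} != sequence length {len(self.sequence)}"
            )
        for name, start, end in self.domains:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"record {self.id!r}: domain {name!r} interval "
                    f"[{start}, {end}] outside [1, {len(self.sequence)}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)
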