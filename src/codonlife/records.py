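"""Coding records and CDS translation with strict validation."""

from __future__ import annotations

from dataclasses import dataclass, field

from .codon_tables import standard_table


class SequenceError(ValueError):
    """Base class for malformed coding sequences."""


class LengthError(SequenceError):
    """CDS length not divisible by 3."""


class AmbiguousBaseError(SequenceError):
    """Non-ACGT base in a CDS."""

    def __init__(self, base: str, position: int):
        self.base, self.position = base, position
        super().__init__(f"ambiguous base {base!r} at position {position}")


class InternalStopError(SequenceError):
    """Stop codon before the final codon."""

    def __init__(self, codon_index: int):
        self.codon_index = codon_index
        super().__init__(f"internal stop codon at codon {codon_index}")


def normalize_dna(seq: str) -> str:
    """Uppercase and map RNA U -> T."""
    return seq.upper().replace("U", "T")


def translate_cds(cds: str) -> str:
    """Translate a CDS under the standard code, dropping a terminal stop.

    Raises :class:`LengthError`, :class:`AmbiguousBaseError` or
    :class:`InternalStopError` on malformed input.  A missing terminal stop is
    tolerated (the final codon is simply translated).
    """
    table = standard_table()
    seq = normalize_dna(cds)
    if len(seq) % 3 != 0:
        raise LengthError(f"CDS length {len(seq)} not divisible by 3")
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise AmbiguousBaseError(base, i)
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    protein = []
    for idx, codon in enumerate(codons):
        if codon in table.stop_codons:
            if idx != len(codons) - 1:
                raise InternalStopError(idx)
            break
        protein.append(table.forward[codon])
    return "".join(protein)


@dataclass(frozen=True)
class CodingRecord:
    """One coding sequence and its translation; the unit of feature extraction."""

    id: str
    cds: str
    protein: str = field(default="")

    @classmethod
    def from_cds(cls, id: str, cds: str) -> "CodingRecord":
        seq = normalize_dna(cds)
        return cls(id=id, cds=seq, protein=translate_cds(seq))

    @property
    def codons(self) -> list[str]:
        """Sense codons of the CDS (terminal stop excluded)."""
        table = standard_table()
        cods = [self.cds[i:i + 3] for i in range(0, len(self.cds), 3)]
        if cods and cods[-1] in table.stop_codons:
            cods = cods[:-1]
        return cods
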