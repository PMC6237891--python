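"""Standard genetic code bookkeeping: sense codons, synonymous subgroups, wobble classes.

The unit of the wobble analysis is the *synonymous subgroup*: the set of codons
encoding one amino acid that share their first two nucleotides.  For 15 amino
acids the subgroup is simply the full synonymous family (a pair, triplet or
quadruplet); the three six-fold amino acids (Leu, Arg, Ser) split into a pair
and a quadruplet, giving 21 subgroups in total.  Met (ATG) and Trp (TGG) are
encoded by a single codon each and therefore belong to no subgroup — they offer
no synonymous contrast — although each still has a wobble class (both G-ending).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_dna_by_id

GC_ENDING = "GC_ending"
AU_ENDING = "AU_ending"

#: Amino acids whose codons are forced (no wobble choice).
SINGLE_CODON_AA = frozenset({"M", "W"})


@dataclass(frozen=True)
class CodonTable:
    """The standard genetic code plus the groupings the wobble analysis needs.

    Attributes
    ----------
    forward : dict
        Codon -> one-letter amino acid, sense codons only.
    sense_codons : tuple
        The 61 non-stop codons, alphabetical.
    stop_codons : frozenset
        The 3 stop codons.
    synonymous_subgroups : dict
        Subgroup label (e.g. ``"Leu/CT"``) -> tuple of member codons.  21 entries.
    wobble_class : dict
        Codon -> ``"GC_ending"`` or ``"AU_ending"`` for all 61 sense codons.
    """

    forward: dict[str, str]
    sense_codons: tuple[str, ...]
    stop_codons: frozenset[str]
    synonymous_subgroups: dict[str, tuple[str, ...]] = field(repr=False)
    wobble_class: dict[str, str] = field(repr=False)

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """All sense codons encoding ``aa``, alphabetical."""
        return tuple(c for c in self.sense_codons if self.forward[c] == aa)

    def subgroup_of(self, codon: str) -> str | None:
        """Subgroup label of ``codon``, or None for ATG/TGG."""
        for name, members in self.synonymous_subgroups.items():
            if codon in members:
                return name
        return None

    @property
    def amino_acids(self) -> tuple[str, ...]:
        """The 20 amino acids, alphabetical one-letter codes."""
        return tuple(sorted(set(self.forward.values())))


# Three-letter names only used to build readable subgroup labels.
_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


@lru_cache(maxsize=1)
def standard_table() -> CodonTable:
    """Build the standard-code :class:`CodonTable` (cached singleton)."""
    ncbi = unambiguous_dna_by_id[1]
    forward = dict(sorted(ncbi.forward_table.items()))
    sense = tuple(sorted(forward))
    stops = frozenset(ncbi.stop_codons)

    # Group synonymous codons by (amino acid, first two nucleotides).
    groups: dict[tuple[str, str], list[str]] = {}
    for codon, aa in forward.items():
        groups.setdefault((aa, codon[:2]), []).append(codon)
    subgroups = {
        f"{_AA3[aa]}/{prefix}": tuple(sorted(members))
        for (aa, prefix), members in sorted(groups.items())
        if aa not in SINGLE_CODON_AA
    }

    wobble = {c: (GC_ENDING if c[2] in "GC" else AU_ENDING) for c in sense}
    return CodonTable(
        forward=forward,
        sense_codons=sense,
        stop_codons=stops,
        synonymous_subgroups=subgroups,
        wobble_class=wobble,
    )
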