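"""Translation-preserving synonymous gene design at target GC3 levels.

Given a protein (or a CDS to translate), the designer rewrites every codon so
that a requested percentage of the *tunable* codons — all codons except Met
(ATG) and Trp (TGG), whose wobble base is forced — end in G or C.  The number
of G-/C-ending codons is round(target/100 * n_tunable) (half away from zero);
their positions are drawn by seeded uniform sampling (or evenly spaced), and
within the chosen wobble class the codon is picked by usage-table weight,
defaulting to the alphabetically first codon for determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .codon_tables import AU_ENDING, GC_ENDING, standard_table
from .features import gc3_fraction
from .records import CodingRecord, translate_cds


@dataclass(frozen=True)
class DesignRequest:
    """One synonymous-variant design request."""

    protein: str  # one-letter amino-acid string (no stop)
    target_gc3: float  # percent of tunable codons that should end in G/C
    seed: int = 0
    even_spacing: bool = False  # evenly spaced G/C positions instead of random
    usage_table: dict[str, float] | None = None  # codon -> weight
    stop_codon: str = "TAA"

    def validate(self) -> None:
        if not self.protein:
            raise ValueError("empty protein")
        table = standard_table()
        bad = set(self.protein) - set(table.amino_acids)
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")
        if not 0 <= self.target_gc3 <= 100:
            raise ValueError("target_gc3 must be in [0, 100]")
        if self.stop_codon not in table.stop_codons:
            raise ValueError(f"{self.stop_codon!r} is not a stop codon")

    @classmethod
    def from_cds(cls, cds: str, target_gc3: float, **kwargs) -> "DesignRequest":
        return cls(protein=translate_cds(cds), target_gc3=target_gc3, **kwargs)


@dataclass(frozen=True)
class DesignedVariant:
    """Designer output plus its achieved wobble composition."""

    cds: str
    target_gc3: float
    achieved_gc3_tunable: float
    achieved_gc3_all: float
    overall_gc: float
    gc_positions: tuple[int, ...]  # tunable codon indices given a G/C ending
    seed: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _pick_codon(aa: str, wobble: str, usage: dict[str, float] | None) -> str:
    """Codon for ``aa`` in wobble class ``wobble``; usage weight, ties/default
    alphabetical."""
    table = standard_table()
    candidates = [c for c in table.codons_for(aa) if table.wobble_class[c] == wobble]
    if not candidates:
        raise ValueError(f"{aa} has no {wobble} codon")  # only reachable for M/W
    if usage:
        top = max(usage.get(c, 0.0) for c in candidates)
        candidates = [c for c in candidates if usage.get(c, 0.0) == top]
    return sorted(candidates)[0]


def design_variant(request: DesignRequest) -> DesignedVariant:
    """Design a synonymous CDS hitting the requested tunable-GC3 percentage."""
    request.validate()
    protein = request.protein
    tunable_idx = [i for i, aa in enumerate(protein) if aa not in "MW"]
    n_tunable = len(tunable_idx)
    n_gc = _round_half_away(request.target_gc3 / 100.0 * n_tunable)
    if request.even_spacing and n_gc > 0:
        picks = np.unique(np.linspace(0, n_tunable - 1, n_gc).round().astype(int))
        # guard against collisions from rounding on short proteins
        while picks.size < n_gc:
            pool = np.setdiff1d(np.arange(n_tunable), picks)
            picks = np.sort(np.append(picks, pool[0]))
        gc_slots = {tunable_idx[i] for i in picks}
    elif n_gc > 0:
        rng = np.random.default_rng(request.seed)
        gc_slots = {tunable_idx[i]
                    for i in rng.choice(n_tunable, size=n_gc, replace=False)}
    else:
        gc_slots = set()

    codons = []
    for i, aa in enumerate(protein):
        if aa == "M":
            codons.append("ATG")
        elif aa == "W":
            codons.append("TGG")
        else:
            wobble = GC_ENDING if i in gc_slots else AU_ENDING
            codons.append(_pick_codon(aa, wobble, request.usage_table))
    cds = "".join(codons) + request.stop_codon

    record = CodingRecord.from_cds("variant", cds)
    return DesignedVariant(
        cds=cds,
        target_gc3=request.target_gc3,
        achieved_gc3_tunable=gc3_fraction(record, "tunable_only"),
        achieved_gc3_all=gc3_fraction(record, "all_codons"),
        overall_gc=100.0 * sum(cds[:-3].count(b) for b in "GC") / max(len(cds) - 3, 1),
        gc_positions=tuple(sorted(gc_slots)),
        seed=request.seed,
    )


@dataclass(frozen=True)
class AuditReport:
    """Independent re-check of a designed variant."""

    translation_ok: bool
    gc3_tunable: float
    gc3_all: float
    overall_gc: float
    delta_vs_target: float


def audit_variant(variant: DesignedVariant, original_protein: str) -> AuditReport:
    """Verify translation identity and recompute GC3 by an independent scan.

    Translation mismatch is a designer bug and raises.
    """
    table = standard_table()
    translated = translate_cds(variant.cds)
    if translated != original_protein:
        raise ValueError("designed CDS does not translate back to the input protein")
    body = variant.cds[:-3]
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    gc3_all_n = sum(1 for c in codons if c[2] in "GC")
    tunable = [c for c in codons if table.forward[c] not in "MW"]
    gc3_tun_n = sum(1 for c in tunable if c[2] in "GC")
    gc3_all = 100.0 * gc3_all_n / len(codons) if codons else math.nan
    gc3_tun = 100.0 * gc3_tun_n / len(tunable) if tunable else math.nan
    overall_gc = 100.0 * sum(body.count(b) for b in "GC") / len(body)
    return AuditReport(
        translation_ok=True,
        gc3_tunable=gc3_tun,
        gc3_all=gc3_all,
        overall_gc=overall_gc,
        delta_vs_target=gc3_tun - variant.target_gc3 if not math.isnan(gc3_tun) else math.nan,
    )


def design_family(protein: str, targets: tuple[float, ...] = (0, 25, 50, 75, 100),
                  seed: int = 0, **kwargs) -> list[DesignedVariant]:
    """The five-member (by default) variant family of one protein."""
    return [design_variant(DesignRequest(protein=protein, target_gc3=t, seed=seed,
                                         **kwargs))
            for t in targets]
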