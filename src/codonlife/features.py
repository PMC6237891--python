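"""Sequence-derived features: composition percentages, GC3, physicochemical
indices, structure-stratified composition, and tiered feature-matrix assembly.

Feature tiers
-------------
composition
    20 amino-acid percentages + 61 sense-codon percentages = 81 columns.
sequence
    composition plus structure-stratified composition (81 per structural
    class: helix / sheet / coil), physicochemical scalars (molecular weight,
    isoelectric point, GRAVY, aliphatic index, length) and a 20-column one-hot
    encoding of the N-terminal residue (the residue at position 2, i.e. the
    one following the initiator Met).
all
    sequence plus binary annotation columns passing a minimum-prevalence
    filter (default: a term must mark at least 10 proteins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .codon_tables import standard_table
from .records import CodingRecord

logger = logging.getLogger(__name__)

TIERS = ("composition", "sequence", "all")
#: Default minimum number of proteins an annotation term must mark.
MIN_ANNOTATION_PREVALENCE = 10

STRUCTURE_CLASSES = {"H": "helix", "E": "sheet", "C": "coil"}

# Kyte-Doolittle relative side-chain volumes for the aliphatic index (Ikai):
# AI = X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)), X in mole percent.
_ALIPHATIC_VAL = 2.9
_ALIPHATIC_ILE_LEU = 3.9


def aa_feature_names() -> list[str]:
    return [f"aa_{a}" for a in standard_table().amino_acids]


def codon_feature_names() -> list[str]:
    return [f"codon_{c}" for c in standard_table().sense_codons]


def composition_feature_names() -> list[str]:
    """The 81 composition feature names in canonical order."""
    return aa_feature_names() + codon_feature_names()


@dataclass(frozen=True)
class CompositionVector:
    """Amino-acid and codon percentages (0-100 scale), stop codon excluded."""

    aa_percent: dict[str, float]
    codon_percent: dict[str, float]

    def as_features(self) -> dict[str, float]:
        out = {f"aa_{a}": v for a, v in self.aa_percent.items()}
        out.update({f"codon_{c}": v for c, v in self.codon_percent.items()})
        return out


def composition_vector(record: CodingRecord) -> CompositionVector:
    """Per-record amino-acid and codon percentages over coding positions.

    The terminal stop codon is excluded; the initiator Met is included.  Both
    blocks sum to 100 exactly (up to float rounding).
    """
    table = standard_table()
    codons = record.codons
    if not codons:
        raise ValueError(f"record {record.id!r} has an empty protein")
    n = len(codons)
    codon_counts = {c: 0 for c in table.sense_codons}
    aa_counts = {a: 0 for a in table.amino_acids}
    for codon in codons:
        codon_counts[codon] += 1
        aa_counts[table.forward[codon]] += 1
    return CompositionVector(
        aa_percent={a: 100.0 * k / n for a, k in aa_counts.items()},
        codon_percent={c: 100.0 * k / n for c, k in codon_counts.items()},
    )


def gc3_fraction(record: CodingRecord, scope: str = "all_codons") -> float:
    """Percent of codons whose wobble (third) nucleotide is G or C.

    ``scope="all_codons"`` counts every sense codon; ``scope="tunable_only"``
    excludes Met (ATG) and Trp (TGG), whose wobble base cannot be changed
    synonymously, from both numerator and denominator.  Returns NaN when the
    denominator is empty (e.g. a Met/Trp-only protein under ``tunable_only``).
    """
    if scope not in ("all_codons", "tunable_only"):
        raise ValueError(f"unknown scope {scope!r}")
    table = standard_table()
    codons = record.codons
    if scope == "tunable_only":
        codons = [c for c in codons if table.forward[c] not in "MW"]
    if not codons:
        return math.nan
    gc = sum(1 for c in codons if c[2] in "GC")
    return 100.0 * gc / len(codons)


@dataclass(frozen=True)
class PhysChemRecord:
    """Whole-protein physicochemical scalars."""

    molecular_weight: float  # Da, average isotopic masses
    isoelectric_point: float  # pH units
    gravy: float  # mean Kyte-Doolittle hydropathy
    aliphatic_index: float
    length: int  # residues, initiator Met included
    nterm_residue: str  # residue at position 2 (after the initiator Met)


def aliphatic_index(protein: str) -> float:
    """Ikai's aliphatic index from mole percentages of Ala, Val, Ile, Leu."""
    n = len(protein)
    if n == 0:
        raise ValueError("empty protein")
    x = {a: 100.0 * protein.count(a) / n for a in "AVIL"}
    return x["A"] + _ALIPHATIC_VAL * x["V"] + _ALIPHATIC_ILE_LEU * (x["I"] + x["L"])


def physchem(record: CodingRecord) -> PhysChemRecord:
    """Physicochemical profile of the translated protein.

    Molecular weight, pI (bisection on net charge) and GRAVY are computed by
    Biopython's ProtParam port; the aliphatic index follows Ikai's mole-percent
    formula.  The N-terminal residue is the residue at position 2 of the
    protein, initiator Met retained and not counted as N-terminal.
    """
    protein = record.protein
    if not protein:
        raise ValueError(f"record {record.id!r} has an empty protein")
    bad = set(protein) - set(standard_table().amino_acids)
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in {record.id!r}")
    analysis = ProteinAnalysis(protein)
    return PhysChemRecord(
        molecular_weight=analysis.molecular_weight(),
        isoelectric_point=analysis.isoelectric_point(),
        gravy=analysis.gravy(),
        aliphatic_index=aliphatic_index(protein),
        length=len(protein),
        nterm_residue=protein[1] if len(protein) > 1 else protein[0],
    )


@dataclass(frozen=True)
class StratifiedComposition:
    """Composition percentages within each secondary-structure class.

    ``blocks[cls]`` maps each of the 81 composition feature names to the
    percent of class-``cls`` residues carrying that amino acid / codon; classes
    with no residues yield all-zero blocks and are listed in
    ``empty_classes``.
    """

    blocks: dict[str, dict[str, float]]
    empty_classes: frozenset[str]


def stratified_composition(record: CodingRecord, structure: str) -> StratifiedComposition:
    """Split composition by secondary-structure class (H/E/C per residue)."""
    table = standard_table()
    codons = record.codons
    if len(structure) != len(codons):
        raise ValueError(
            f"structure length {len(structure)} != protein length {len(codons)} "
            f"for {record.id!r}"
        )
    bad = set(structure) - set(STRUCTURE_CLASSES)
    if bad:
        raise ValueError(f"unknown structure codes {sorted(bad)}")
    names = composition_feature_names()
    blocks: dict[str, dict[str, float]] = {}
    empty: set[str] = set()
    for code, cls in STRUCTURE_CLASSES.items():
        members = [c for c, s in zip(codons, structure) if s == code]
        block = dict.fromkeys(names, 0.0)
        if not members:
            empty.add(cls)
        else:
            n = len(members)
            for codon in members:
                block[f"codon_{codon}"] += 100.0 / n
                block[f"aa_{table.forward[codon]}"] += 100.0 / n
        blocks[cls] = block
    return StratifiedComposition(blocks=blocks, empty_classes=frozenset(empty))


@dataclass
class FeatureMatrix:
    """Proteins x named features with a tier tag per column."""

    values: pd.DataFrame  # rows: protein ids; columns: feature names
    tiers: dict[str, str]  # feature name -> tier tag
    dropped: list[str]  # response-leak / filter removals, for the log

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    def columns_in_tier(self, tier: str) -> list[str]:
        return [c for c, t in self.tiers.items() if t == tier]


def filter_annotations(annotations: pd.DataFrame,
                       min_prevalence: int = MIN_ANNOTATION_PREVALENCE) -> pd.DataFrame:
    """Keep annotation terms marking at least ``min_prevalence`` proteins."""
    keep = annotations.columns[annotations.sum(axis=0) >= min_prevalence]
    return annotations[keep]


# Features trivially derived from (or equal to) a given response kind; they are
# dropped from the matrix when predicting that response.
_RESPONSE_LEAKS = {
    "length": ("length",),
}


def assemble_feature_matrix(
    records: list[CodingRecord],
    tier: str = "composition",
    structures: dict[str, str] | None = None,
    annotations: pd.DataFrame | None = None,
    response_kind: str | None = None,
    min_prevalence: int = MIN_ANNOTATION_PREVALENCE,
) -> FeatureMatrix:
    """Assemble the tiered feature matrix for a cohort.

    Parameters
    ----------
    records : list of CodingRecord
    tier : {"composition", "sequence", "all"}
    structures : per-id H/E/C strings, required for tiers beyond composition.
    annotations : proteins x terms binary DataFrame, used by tier="all".
    response_kind : name of the response being predicted; features identical to
        or trivially derived from it (e.g. ``length`` when predicting length)
        are dropped and logged.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    if tier in ("sequence", "all") and structures is None:
        raise ValueError(f"tier={tier!r} requires secondary-structure strings")

    rows: dict[str, dict[str, float]] = {}
    tiers: dict[str, str] = {}
    for rec in records:
        row = composition_vector(rec).as_features()
        if tier in ("sequence", "all"):
            if rec.id not in structures:
                raise ValueError(f"no structure string for {rec.id!r}")
            strat = stratified_composition(rec, structures[rec.id])
            for cls, block in strat.blocks.items():
                row.update({f"{cls}_{name}": v for name, v in block.items()})
            pc = physchem(rec)
            row.update(
                molecular_weight=pc.molecular_weight,
                isoelectric_point=pc.isoelectric_point,
                gravy=pc.gravy,
                aliphatic_index=pc.aliphatic_index,
                length=float(pc.length),
            )
            for aa in standard_table().amino_acids:
                row[f"nterm_{aa}"] = 1.0 if pc.nterm_residue == aa else 0.0
        rows[rec.id] = row

    values = pd.DataFrame.from_dict(rows, orient="index")
    comp_names = set(composition_feature_names())
    for col in values.columns:
        tiers[col] = "composition" if col in comp_names else "sequence"

    if tier == "all" and annotations is not None:
        kept = filter_annotations(annotations, min_prevalence)
        kept = kept.reindex(values.index, fill_value=0).astype(float)
        overlap = set(kept.columns) & set(values.columns)
        if overlap:
            raise ValueError(f"annotation terms clash with feature names: {sorted(overlap)}")
        values = pd.concat([values, kept], axis=1)
        tiers.update(dict.fromkeys(kept.columns, "annotation"))

    dropped: list[str] = []
    if response_kind is not None:
        for leak in _RESPONSE_LEAKS.get(response_kind, ()):
            if leak in values.columns:
                values = values.drop(columns=[leak])
                tiers.pop(leak, None)
                dropped.append(leak)
                logger.info("dropped response-leak feature %r (response=%s)",
                            leak, response_kind)

    if values.isna().any().any():
        raise ValueError("feature matrix contains missing values after assembly")
    return FeatureMatrix(values=values, tiers=tiers, dropped=dropped)
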