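"""Readers and writers for the pipeline's plain-text formats.

Canonical dialects: FASTA for sequences, TSV (tab-separated, header row) for
tables, JSON for nested reports.  Floats are written at fixed precision and
round-trip losslessly at that precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .decay import DecayCurve, DecayFit
from .features import FeatureMatrix
from .records import CodingRecord, normalize_dna

FLOAT_FORMAT = "%.10g"

_DNA_ALPHABET = set("ACGTU")


def read_fasta(path, kind: str = "auto"):
    """Read a FASTA file into coding records or (id, protein) pairs.

    Sequences are uppercased (U -> T for DNA); ids are taken up to the first
    whitespace.  ``kind`` is ``"dna"``, ``"protein"`` or ``"auto"``
    (auto-detected from the alphabet).  Returns a list of
    :class:`CodingRecord` for DNA, or a list of ``(id, protein)`` tuples.
    """
    entries = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    ids = [i for i, _ in entries]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate FASTA ids: {sorted(dupes)}")
    if kind == "auto":
        kind = "dna" if all(set(seq) <= _DNA_ALPHABET for _, seq in entries) else "protein"
    if kind == "dna":
        return [CodingRecord.from_cds(i, normalize_dna(s)) for i, s in entries]
    if kind == "protein":
        return entries
    raise ValueError(f"unknown kind {kind!r}")


def write_fasta(entries, path, descriptions: dict[str, str] | None = None) -> None:
    """Write CodingRecords or (id, sequence) pairs as FASTA."""
    records = []
    for e in entries:
        if isinstance(e, CodingRecord):
            rid, seq = e.id, e.cds
        else:
            rid, seq = e
        desc = (descriptions or {}).get(rid, "")
        records.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(records, str(path), "fasta")


# --- feature matrices -------------------------------------------------------


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """TSV with ``name[tier]`` column headers and an ``id`` index column."""
    df = matrix.values.copy()
    df.columns = [f"{c}[{matrix.tiers[c]}]" for c in df.columns]
    df.to_csv(path, sep="\t", index_label="id", float_format=FLOAT_FORMAT)


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    tiers, names = {}, []
    for col in df.columns:
        name, _, tag = col.rstrip("]").rpartition("[")
        tiers[name] = tag
        names.append(name)
    df.columns = names
    return FeatureMatrix(values=df, tiers=tiers, dropped=[])


# --- responses, structures, annotations -------------------------------------


def write_responses(responses: dict[str, pd.Series], path) -> None:
    """Long TSV: id, dataset, value."""
    frames = [pd.DataFrame({"id": s.index, "dataset": name, "value": s.to_numpy()})
              for name, s in responses.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format=FLOAT_FORMAT)


def read_responses(path) -> dict[str, pd.Series]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return {name: sub.set_index("id")["value"].astype(float)
            for name, sub in df.groupby("dataset", sort=False)}


def write_structures(structures: dict[str, str], path) -> None:
    pd.DataFrame({"id": list(structures), "structure": list(structures.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_structures(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["id"], df["structure"]))


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index_label="id")


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


# --- decay curves -----------------------------------------------------------


def write_decay_curves(curves: list[DecayCurve], path) -> None:
    """TSV: construct, time_h, intensity, sem, n."""
    rows = []
    for c in curves:
        sem = c.sem if c.sem is not None else np.full(c.times_h.size, np.nan)
        for t, y, s in zip(c.times_h, c.intensities, sem):
            rows.append((c.construct, t, y, s, c.n_replicates))
    pd.DataFrame(rows, columns=["construct", "time_h", "intensity", "sem", "n"]
                 ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_decay_curves(path) -> list[DecayCurve]:
    df = pd.read_csv(path, sep="\t")
    curves = []
    for construct, sub in df.groupby("construct", sort=False):
        sem = sub["sem"].to_numpy() if sub["sem"].notna().all() else None
        curves.append(DecayCurve(construct=str(construct),
                                 times_h=sub["time_h"].to_numpy(),
                                 intensities=sub["intensity"].to_numpy(),
                                 sem=sem,
                                 n_replicates=int(sub["n"].iloc[0])))
    return curves


# --- reports ----------------------------------------------------------------


def write_json(obj, path) -> None:
    """Serialize a report (dataclass or dict) as indented JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if isinstance(obj, DecayFit):
            obj = dataclasses.asdict(obj)
        elif hasattr(obj, "to_dict"):
            obj = obj.to_dict()
        else:
            obj = dataclasses.asdict(obj)
    elif hasattr(obj, "to_dict"):
        obj = obj.to_dict()

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
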