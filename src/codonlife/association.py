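"""Correlation screens between sequence features and homeostasis parameters.

Per-feature Pearson correlations are computed dataset by dataset and then
aggregated as an unweighted mean with an s.e.m. over datasets; the wobble
summary averages codon correlations within each of the 21 synonymous subgroups
separately for G-/C-ending and A-/U-ending members and tests the class
difference with a two-sample Student's t-test across the per-dataset class
means.  The module also covers the N-end-rule check (position-2 residue versus
response), degron-motif presence associations, and the pairwise r-squared
matrix between response datasets.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_tables import AU_ENDING, GC_ENDING, standard_table
from .features import FeatureMatrix
from .records import CodingRecord


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CorrelationProfile:
    """Per-feature Pearson r across datasets plus the mean/s.e.m. aggregation."""

    per_dataset: pd.DataFrame  # rows: features, columns: dataset names
    mean_r: pd.Series
    sem_r: pd.Series  # sd over datasets / sqrt(n_datasets); 0 for n=1
    n_datasets: int


def correlation_profile(features: FeatureMatrix,
                        responses: dict[str, pd.Series],
                        log_transform: bool = False,
                        min_shared: int = 3) -> CorrelationProfile:
    """Correlate every feature with every response dataset.

    ids are aligned by intersection per dataset; datasets sharing fewer than
    ``min_shared`` proteins with the feature matrix are skipped with a
    warning.  ``log_transform`` applies a natural log to the response first
    (positive values required).
    """
    if not responses:
        raise ValueError("need at least one response dataset")
    columns = {}
    for name, resp in responses.items():
        shared = features.values.index.intersection(resp.index)
        if len(shared) < min_shared:
            warnings.warn(f"dataset {name!r} shares only {len(shared)} proteins; skipped")
            continue
        y = resp.loc[shared].astype(float)
        if log_transform:
            if (y <= 0).any():
                raise ValueError(f"log transform needs positive responses in {name!r}")
            y = np.log(y)
        sub = features.values.loc[shared]
        yv = y.to_numpy()
        yc = yv - yv.mean()
        sy = yv.std()
        xm = sub.to_numpy()
        xc = xm - xm.mean(axis=0)
        sx = xm.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * yc[:, None]).mean(axis=0) / (sx * sy)
        r[(sx == 0) | (sy == 0)] = np.nan
        columns[name] = pd.Series(r, index=sub.columns)
    if not columns:
        raise ValueError("no dataset shares enough proteins with the feature matrix")
    per_dataset = pd.DataFrame(columns)
    n = per_dataset.shape[1]
    mean_r = per_dataset.mean(axis=1)
    sem_r = per_dataset.std(axis=1, ddof=1).fillna(0.0) / math.sqrt(n) if n > 1 \
        else pd.Series(0.0, index=per_dataset.index)
    return CorrelationProfile(per_dataset=per_dataset, mean_r=mean_r,
                              sem_r=sem_r, n_datasets=n)


@dataclass
class WobbleSummary:
    """Per-subgroup G/C- vs A/U-ending mean correlations and their contrast."""

    table: pd.DataFrame  # 21 rows: mean_r_gc, mean_r_au, difference, t_stat, p_value
    n_gc_greater: int  # subgroups with mean_r_gc > mean_r_au


def wobble_group_summary(profile: CorrelationProfile) -> WobbleSummary:
    """Aggregate a codon correlation profile over the 21 synonymous subgroups.

    For each subgroup the per-dataset r values are averaged over the G-/C-
    ending members and over the A-/U-ending members; the two per-dataset class
    mean vectors are compared with a two-sample Student's t-test (equal
    variance, matching s.e.m.-over-datasets error bars).
    """
    table = standard_table()
    missing = [c for c in table.sense_codons
               if f"codon_{c}" not in profile.per_dataset.index]
    if missing:
        raise ValueError(f"profile lacks codon features: {missing[:5]}...")
    rows = {}
    for name, members in table.synonymous_subgroups.items():
        gc = [c for c in members if table.wobble_class[c] == GC_ENDING]
        au = [c for c in members if table.wobble_class[c] == AU_ENDING]
        if not gc or not au:  # cannot happen in the standard code
            raise ValueError(f"subgroup {name} lacks a wobble class")
        gc_means = profile.per_dataset.loc[[f"codon_{c}" for c in gc]].mean(axis=0)
        au_means = profile.per_dataset.loc[[f"codon_{c}" for c in au]].mean(axis=0)
        if profile.n_datasets > 1:
            t_stat, p = stats.ttest_ind(gc_means, au_means, equal_var=True)
        else:
            t_stat, p = math.nan, math.nan
        rows[name] = {
            "mean_r_gc": float(gc_means.mean()),
            "mean_r_au": float(au_means.mean()),
            "difference": float(gc_means.mean() - au_means.mean()),
            "t_stat": float(t_stat),
            "p_value": float(p),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return WobbleSummary(table=df, n_gc_greater=int((df["difference"] > 0).sum()))


def nend_rule_association(records: list[CodingRecord], response: pd.Series,
                          rule_map: dict[str, float]) -> float:
    """r-squared between an N-end-rule stability table and a response.

    The N-terminal residue is the residue at position 2 of the protein.  The
    rule map must cover every observed position-2 residue.
    """
    ids, values = [], []
    missing = set()
    for rec in records:
        if rec.id not in response.index:
            continue
        nterm = rec.protein[1] if len(rec.protein) > 1 else rec.protein[0]
        if nterm not in rule_map:
            missing.add(nterm)
            continue
        ids.append(rec.id)
        values.append(rule_map[nterm])
    if missing:
        raise ValueError(f"rule_map lacks residues: {sorted(missing)}")
    r = pearson_r(values, response.loc[ids].to_numpy())
    return r * r if not math.isnan(r) else math.nan


def motif_association(records: list[CodingRecord], response: pd.Series,
                      motifs: list[str]) -> pd.DataFrame:
    """Point-biserial association of motif presence with a response.

    Motifs are plain residue strings or simple regular expressions matched
    anywhere in the protein.  Returns per-motif carrier counts, point-biserial
    r, raw p and Benjamini-Hochberg adjusted p; motifs present in all or no
    proteins get NaN (constant regressor) and are excluded from adjustment.
    """
    if any(not m for m in motifs):
        raise ValueError("empty motif")
    recs = [r for r in records if r.id in response.index]
    y = response.loc[[r.id for r in recs]].to_numpy(dtype=float)
    rows = []
    for motif in motifs:
        pattern = re.compile(motif)
        present = np.array([1.0 if pattern.search(r.protein) else 0.0 for r in recs])
        n_carriers = int(present.sum())
        if n_carriers in (0, len(recs)):
            rows.append((motif, n_carriers, math.nan, math.nan))
            continue
        res = stats.pearsonr(present, y)
        rows.append((motif, n_carriers, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["motif", "n_carriers", "r", "p_value"]
                      ).set_index("motif")
    defined = df["p_value"].notna()
    adjusted = pd.Series(math.nan, index=df.index)
    if defined.any():
        adjusted.loc[defined] = stats.false_discovery_control(
            df.loc[defined, "p_value"].to_numpy(), method="bh")
    df["p_adjusted"] = adjusted
    return df


def cross_parameter_matrix(responses: dict[str, pd.Series],
                           min_shared: int = 3) -> pd.DataFrame:
    """Symmetric matrix of squared Pearson r between response datasets.

    Diagonal is 1; pairs sharing fewer than ``min_shared`` ids get NaN.
    """
    names = list(responses)
    if len(names) < 2:
        raise ValueError("need at least 2 datasets")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = responses[a].index.intersection(responses[b].index)
            if len(shared) < min_shared:
                r2 = math.nan
            else:
                r = pearson_r(responses[a].loc[shared], responses[b].loc[shared])
                r2 = r * r if not math.isnan(r) else math.nan
            out.loc[a, b] = out.loc[b, a] = r2
    return out
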