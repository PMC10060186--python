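"""Cross-compartment TCR-beta clonotype analytics.

Parses tumor (bulk TCR-seq) and blood (single-cell TCR-seq) clonotype
tables, selects frequent tumor-infiltrating clonotypes (TIL-TCRs), matches
them into blood, tracks combined frequencies over time, computes
Morisita-Horn repertoire similarity, tests per-clonotype expansion between
timepoints with Fisher's exact test under Benjamini-Hochberg control, and
summarizes CX3CR1 expression of expanded clones.

Clonotype identity for matching across platforms defaults to amino-acid
CDR3-beta plus the V gene collapsed to gene level (alleles stripped),
because bulk and single-cell pipelines annotate alleles differently;
nucleotide-level identity can be configured for within-platform work.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diagnostics import jeffreys_interval

__all__ = [
    "ClonotypeKey",
    "ClonotypeTable",
    "read_clonotypes",
    "read_cell_table",
    "cell_tables_by_timepoint",
    "frequent_til",
    "match_to_blood",
    "combined_frequency",
    "morisita_horn",
    "expansion_test",
    "cx3cr1_annotation",
    "tracking_table",
]

_ALLELE = re.compile(r"\*\d+$")


def _strip_allele(gene: str) -> str:
    return _ALLELE.sub("", str(gene).strip())


@dataclass(frozen=True, order=True)
class ClonotypeKey:
    """Identity of a TCR-beta clonotype: CDR3 plus V/J gene assignment."""

    cdr3: str
    v_gene: str = ""
    j_gene: str = ""

    def __post_init__(self):
        if not self.cdr3:
            raise ValueError("cdr3 must be non-empty")

    @classmethod
    def from_fields(cls, cdr3: str, v_call: str = "", j_call: str = "",
                    collapse_alleles: bool = True) -> "ClonotypeKey":
        if collapse_alleles:
            v_call, j_call = _strip_allele(v_call), _strip_allele(j_call)
        return cls(str(cdr3).strip(), v_call, j_call)


@dataclass
class ClonotypeTable:
    """One repertoire: clonotype -> count, for a compartment and timepoint.

    ``timepoint_week`` is a week number, or ``"pre"`` for the pretreatment
    tumor sample.  Counts are template counts (bulk) or cell counts
    (single cell); zero-count entries are not stored.
    """

    compartment: str                       # "tumor" | "blood"
    timepoint_week: float | str
    entries: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.compartment not in ("tumor", "blood"):
            raise ValueError("compartment must be 'tumor' or 'blood'")
        bad = [k for k, c in self.entries.items() if c < 1]
        if bad:
            raise ValueError(f"counts must be >= 1; offending keys: {bad[:3]}")

    @property
    def total(self) -> int:
        return int(sum(self.entries.values()))

    @property
    def n_clonotypes(self) -> int:
        return len(self.entries)

    def frequencies(self) -> dict:
        tot = self.total
        return {k: c / tot for k, c in self.entries.items()}


_DIALECTS = {
    "immunoseq": {
        "cdr3": "aminoAcid", "v": "vGeneName", "j": "jGeneName",
        "count": "count (templates)", "productive": "sequenceStatus",
    },
    "airr": {
        "cdr3": "cdr3_aa", "v": "v_call", "j": "j_call",
        "count": "duplicate_count", "productive": "productive",
    },
}


def _is_productive(value, dialect: str) -> bool:
    if dialect == "immunoseq":
        return str(value).strip().lower() in ("in", "in-frame", "productive")
    return str(value).strip().upper() in ("T", "TRUE", "1")


def read_clonotypes(path, dialect: str, compartment: str = "tumor",
                    timepoint_week="pre") -> ClonotypeTable:
    """Read a bulk clonotype TSV (``immunoseq`` or ``airr`` dialect).

    Only productive rearrangements are retained; duplicate clonotype rows
    are aggregated by summing counts.  For cell-level tables use
    :func:`read_cell_table`.
    """
    if dialect == "sc_cells":
        raise ValueError("use read_cell_table for the cell-level dialect")
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    keep = df[cols["productive"]].map(lambda v: _is_productive(v, dialect))
    df = df[keep]
    entries: dict = {}
    for _, row in df.iterrows():
        key = ClonotypeKey.from_fields(row[cols["cdr3"]], row[cols["v"]],
                                       row[cols["j"]])
        entries[key] = entries.get(key, 0) + int(row[cols["count"]])
    if not entries:
        import warnings

        warnings.warn(f"{path}: no productive clonotypes", stacklevel=2)
    return ClonotypeTable(compartment, timepoint_week, entries)


_CELL_COLS = ("cell_id", "timepoint_week", "clonotype_id", "cdr3_aa", "v_call",
              "j_call", "cx3cr1_positive")


def read_cell_table(path) -> pd.DataFrame:
    """Read the per-cell blood clonotype TSV.

    Expected columns: cell_id, timepoint_week, clonotype_id, cdr3_aa,
    v_call, j_call, cx3cr1_positive.  Returns the validated DataFrame with
    an added ``key`` column of :class:`ClonotypeKey`.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _CELL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df.copy()
    df["key"] = [
        ClonotypeKey.from_fields(r.cdr3_aa, r.v_call, r.j_call)
        for r in df.itertuples()
    ]
    df["cx3cr1_positive"] = df["cx3cr1_positive"].astype(bool)
    return df


def cell_tables_by_timepoint(cells: pd.DataFrame) -> dict:
    """Aggregate a cell-level table into per-timepoint blood repertoires."""
    out = {}
    for week, grp in cells.groupby("timepoint_week"):
        counts = grp.groupby("key").size().to_dict()
        out[float(week)] = ClonotypeTable("blood", float(week), counts)
    return out


def frequent_til(tumor: ClonotypeTable, min_count: int = 5) -> dict:
    """Clonotypes seen at least ``min_count`` times in the tumor.

    Returns ``{"keys": set, "n_frequent": int, "n_total": int, "pct": float}``
    where pct is the share of unique tumor clonotypes classified frequent.
    """
    if tumor.compartment != "tumor":
        raise ValueError("frequent_til expects a tumor repertoire")
    keys = {k for k, c in tumor.entries.items() if c >= min_count}
    n_total = tumor.n_clonotypes
    pct = 100.0 * len(keys) / n_total if n_total else float("nan")
    return {"keys": keys, "n_frequent": len(keys), "n_total": n_total, "pct": pct}


def match_to_blood(frequent_keys: set, blood_tables: Mapping) -> dict:
    """Intersect frequent TIL-TCRs with blood repertoires per timepoint.

    ``blood_tables`` maps timepoint -> ClonotypeTable.  Returns per-week
    matched keys, the pooled matched set, and the percentage of frequent
    TIL-TCRs found anywhere in blood.
    """
    per_week = {}
    pooled: set = set()
    for week, table in blood_tables.items():
        hit = frequent_keys & set(table.entries)
        per_week[week] = hit
        pooled |= hit
    pct = 100.0 * len(pooled) / len(frequent_keys) if frequent_keys else float("nan")
    return {"per_week": per_week, "pooled": pooled,
            "n_matched": len(pooled), "pct_of_frequent": pct}


def combined_frequency(keys: Iterable[ClonotypeKey], blood: ClonotypeTable) -> float:
    """Total frequency of the given clonotypes in one blood repertoire."""
    total = blood.total
    if total == 0:
        raise ValueError("blood repertoire is empty")
    keys = set(keys)
    return sum(c for k, c in blood.entries.items() if k in keys) / total


def morisita_horn(x: ClonotypeTable, y: ClonotypeTable) -> float:
    """Morisita-Horn similarity between two repertoires, in [0, 1].

    MH = 2 sum(x_i y_i) / [(sum x_i^2 / X^2 + sum y_i^2 / Y^2) X Y] over
    the union of clonotypes, X and Y the repertoire totals.  1 when
    relative abundances are proportional, 0 when supports are disjoint;
    invariant to rescaling either repertoire's counts.
    """
    if x.total == 0 or y.total == 0:
        raise ValueError("Morisita-Horn undefined for an empty repertoire")
    keys = set(x.entries) | set(y.entries)
    xv = np.array([x.entries.get(k, 0) for k in keys], dtype=float)
    yv = np.array([y.entries.get(k, 0) for k in keys], dtype=float)
    X, Y = xv.sum(), yv.sum()
    denom = (np.sum(xv**2) / X**2 + np.sum(yv**2) / Y**2) * X * Y
    return float(2.0 * np.sum(xv * yv) / denom)


def expansion_test(blood_t1: ClonotypeTable, blood_t2: ClonotypeTable,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-clonotype differential abundance between two blood timepoints.

    For every clonotype in the union, a two-sided Fisher exact test on the
    2x2 table (count vs rest at t1, count vs rest at t2); p-values are
    Benjamini-Hochberg adjusted across all clonotypes tested in the
    comparison.  ``expanded`` requires adjusted p < alpha AND a frequency
    increase from t1 to t2 (the test itself is direction-blind).
    """
    n1, n2 = blood_t1.total, blood_t2.total
    if n1 == 0 or n2 == 0:
        raise ValueError("both repertoires must be non-empty")
    keys = sorted(set(blood_t1.entries) | set(blood_t2.entries))
    c1 = np.array([blood_t1.entries.get(k, 0) for k in keys])
    c2 = np.array([blood_t2.entries.get(k, 0) for k in keys])
    pvals = np.array([
        stats.fisher_exact([[a, n1 - a], [b, n2 - b]]).pvalue
        for a, b in zip(c1, c2)
    ])
    padj = multipletests(pvals, method="fdr_bh")[1]
    f1, f2 = c1 / n1, c2 / n2
    df = pd.DataFrame({
        "key": keys, "count_t1": c1, "count_t2": c2,
        "freq_t1": f1, "freq_t2": f2,
        "p": pvals, "p_adj": padj,
        "expanded": (padj < alpha) & (f2 > f1),
    })
    return df


def cx3cr1_annotation(keys: Iterable[ClonotypeKey], cells: pd.DataFrame,
                      timepoints=None) -> pd.DataFrame:
    """Fraction of each clonotype's cells that are CX3CR1-positive.

    Jeffreys 95% intervals accompany each fraction.  Clonotypes absent from
    the cell table get NaN and ``found=False`` rather than silently 0.
    """
    if timepoints is not None:
        cells = cells[cells["timepoint_week"].isin(list(timepoints))]
    rows = []
    grouped = cells.groupby("key")
    sizes = grouped.size()
    pos = grouped["cx3cr1_positive"].sum()
    for k in keys:
        if k in sizes.index:
            n, x = int(sizes[k]), int(pos[k])
            lo, hi = jeffreys_interval(x, n)
            rows.append({"key": k, "n_cells": n, "n_positive": x,
                         "frac_cx3cr1_pos": x / n, "ci_lo": lo, "ci_hi": hi,
                         "found": True})
        else:
            rows.append({"key": k, "n_cells": 0, "n_positive": 0,
                         "frac_cx3cr1_pos": float("nan"),
                         "ci_lo": float("nan"), "ci_hi": float("nan"),
                         "found": False})
    return pd.DataFrame(rows)


def tracking_table(tumor: ClonotypeTable, blood_tables: Mapping,
                   cells: pd.DataFrame, min_count: int = 5,
                   baseline_week: float = 0.0, contrast_week: float = 6.0,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Combine tumor counts, blood tracking, expansion and CX3CR1 status.

    One row per clonotype observed in tumor or blood: tumor count, frequent
    flag, per-timepoint blood counts and frequencies, expansion p and BH-
    adjusted p for contrast_week vs baseline_week, and the CX3CR1+ cell
    fraction among that clonotype's cells.
    """
    freq = frequent_til(tumor, min_count=min_count)["keys"]
    weeks = sorted(blood_tables)
    all_keys = set(tumor.entries)
    for t in blood_tables.values():
        all_keys |= set(t.entries)
    all_keys = sorted(all_keys)
    exp = expansion_test(blood_tables[baseline_week],
                         blood_tables[contrast_week], alpha=alpha)
    exp = exp.set_index("key")
    ann = cx3cr1_annotation(all_keys, cells).set_index("key")
    rows = []
    for k in all_keys:
        row = {"cdr3": k.cdr3, "v_gene": k.v_gene, "j_gene": k.j_gene,
               "tumor_count": tumor.entries.get(k, 0),
               "frequent_til": k in freq}
        for w in weeks:
            tbl = blood_tables[w]
            row[f"count_wk{w:g}"] = tbl.entries.get(k, 0)
            row[f"freq_wk{w:g}"] = tbl.entries.get(k, 0) / tbl.total
        if k in exp.index:
            row["expansion_p"] = float(exp.loc[k, "p"])
            row["expansion_p_adj"] = float(exp.loc[k, "p_adj"])
            row["expanded"] = bool(exp.loc[k, "expanded"])
        else:
            row["expansion_p"] = math.nan
            row["expansion_p_adj"] = math.nan
            row["expanded"] = False
        row["frac_cx3cr1_pos"] = float(ann.loc[k, "frac_cx3cr1_pos"])
        rows.append(row)
    return pd.DataFrame(rows)
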