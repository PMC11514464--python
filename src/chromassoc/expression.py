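"""Threshold rules turning quantification tables into gene classes.

The rules (with their boundary conventions spelled out, since each threshold
sits on a different side of its boundary):

* low-count filter: keep genes with expected counts **strictly greater** than
  5 in *every* library;
* "expressed": FPKM **>= 0.5** (inclusive) in *every* replicate;
* DEG: max CPM **>= 10** (inclusive) in at least one library of the
  comparison, AND |log2FC| **strictly greater** than 1.5, AND p **strictly
  below** 0.05; direction follows the sign of the fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import IntervalSet, overlaps_regions

__all__ = [
    "filter_low_counts",
    "flag_expressed",
    "select_degs",
    "summarize_gene_classes",
    "GeneClassSummary",
]


def _columns(table: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in table.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"no columns with prefix {prefix!r}")
    return cols


def filter_low_counts(
    table: pd.DataFrame, min_count: float = 5, count_prefix: str = "count_"
) -> pd.DataFrame:
    """Keep genes whose expected count exceeds ``min_count`` in all libraries."""
    cols = _columns(table, count_prefix)
    keep = (table[cols] > min_count).all(axis=1)
    return table[keep].reset_index(drop=True)


def flag_expressed(
    table: pd.DataFrame, fpkm_min: float = 0.5, fpkm_prefix: str = "fpkm_"
) -> pd.Series:
    """Boolean per gene: FPKM >= ``fpkm_min`` in every replicate."""
    cols = _columns(table, fpkm_prefix)
    return (table[cols] >= fpkm_min).all(axis=1)


def select_degs(
    results: pd.DataFrame,
    min_cpm: float = 10,
    abs_lfc: float = 1.5,
    p_max: float = 0.05,
    cpm_prefix: str = "cpm_",
) -> pd.DataFrame:
    """Apply the DEG rule; returns the table with ``deg`` and ``direction``.

    direction is "up"/"down" for DEGs by log2FC sign, "" otherwise.
    """
    for col in ("gene", "log2fc", "p_value"):
        if col not in results.columns:
            raise ValueError(f"DE table lacks required column {col!r}")
    if results[["log2fc", "p_value"]].isna().any().any():
        bad = results[results[["log2fc", "p_value"]].isna().any(axis=1)]["gene"].iloc[0]
        raise ValueError(f"missing log2fc/p_value for gene {bad!r}")
    cpm_cols = _columns(results, cpm_prefix)
    out = results.copy()
    expressed_enough = (out[cpm_cols] >= min_cpm).any(axis=1)
    out["deg"] = (
        expressed_enough
        & (out["log2fc"].abs() > abs_lfc)
        & (out["p_value"] < p_max)
    )
    out["direction"] = np.where(
        out["deg"], np.where(out["log2fc"] > 0, "up", "down"), ""
    )
    return out


@dataclass
class GeneClassSummary:
    """Long-format counts/fractions per gene class.

    Classes are (direction x stage-membership x LAD-membership), where
    stage-membership records in which condition/stage's peaks the gene lies:
    one of "both", the individual stage names, or "outside".
    """

    table: pd.DataFrame

    def fraction_in_class(self, direction: str, stage_class: str) -> float:
        sub = self.table[self.table["direction"] == direction]
        total = sub["count"].sum()
        hit = sub[sub["stage_class"] == stage_class]["count"].sum()
        return float(hit / total) if total else float("nan")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def summarize_gene_classes(
    genes: IntervalSet,
    degs: pd.DataFrame,
    peaks_by_stage: dict[str, IntervalSet],
    clads: IntervalSet | None = None,
) -> GeneClassSummary:
    """Cross-classify DEGs by peak membership per stage and LAD membership.

    ``degs`` needs columns gene/direction; membership is >= 1 bp overlap.
    Every DEG lands in exactly one stage class: "both" if inside peaks in
    all stages, a stage name if only there, "outside" if in none.
    """
    gene_index = {iv.name: i for i, iv in enumerate(genes)}
    unknown = [g for g in degs["gene"] if g not in gene_index]
    if unknown:
        raise ValueError(f"unknown gene id {unknown[0]!r}")
    stage_names = list(peaks_by_stage)
    in_stage = {
        s: overlaps_regions(genes, peaks_by_stage[s]) if len(peaks_by_stage[s]) else
        np.zeros(len(genes), dtype=bool)
        for s in stage_names
    }
    in_clad = (
        overlaps_regions(genes, clads)
        if clads is not None and len(clads)
        else np.zeros(len(genes), dtype=bool)
    )
    rows = []
    for _, rec in degs.iterrows():
        gi = gene_index[rec["gene"]]
        hits = [s for s in stage_names if in_stage[s][gi]]
        if len(hits) == len(stage_names) and stage_names:
            stage_class = "both" if len(stage_names) == 2 else "all"
        elif len(hits) == 1:
            stage_class = hits[0]
        elif not hits:
            stage_class = "outside"
        else:
            stage_class = "+".join(hits)
        rows.append(
            {
                "gene": rec["gene"],
                "direction": rec.get("direction", ""),
                "stage_class": stage_class,
                "lad_class": "inside" if in_clad[gi] else "outside",
            }
        )
    per_gene = pd.DataFrame(rows)
    grouped = (
        per_gene.groupby(["direction", "stage_class", "lad_class"])
        .size()
        .rename("count")
        .reset_index()
    )
    totals = grouped.groupby("direction")["count"].transform("sum")
    grouped["fraction"] = grouped["count"] / totals
    return GeneClassSummary(grouped)
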