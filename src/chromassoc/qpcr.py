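"""ChIP-qPCR batch normalization and fold-enrichment reporting.

Input is a long table of %input recoveries with columns
``locus, sample, replicate, antibody, percent_input`` where ``antibody`` is
either a specific antibody label or ``"IgG"`` for the control IP.

Normalization removes batch-to-batch variability: each %input value is
divided by the mean %input of that locus across all samples of the same
biological replicate, so per-(locus, replicate) means of the normalized
values equal 1 exactly.  By default IgG control rows are excluded from the
group mean (configurable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["normalize_percent_input", "fold_enrichment", "compare_samples_ttest"]

REQUIRED_COLS = ["locus", "sample", "replicate", "antibody", "percent_input"]


def _check(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"qPCR table lacks columns {missing}")
    if (table["percent_input"] < 0).any():
        raise ValueError("percent_input must be non-negative")


def normalize_percent_input(
    table: pd.DataFrame, include_igg_in_mean: bool = False
) -> pd.DataFrame:
    """Add ``normalized`` = percent_input / mean over the (locus, replicate) group."""
    _check(table)
    out = table.copy()
    basis = out if include_igg_in_mean else out[out["antibody"] != "IgG"]
    means = basis.groupby(["locus", "replicate"])["percent_input"].mean()
    keys = pd.MultiIndex.from_frame(out[["locus", "replicate"]])
    denom = means.reindex(keys).to_numpy()
    bad = ~(denom > 0)
    if bad.any():
        loc, rep = out.loc[bad, ["locus", "replicate"]].iloc[0]
        raise ValueError(f"zero mean percent_input for locus {loc!r} replicate {rep!r}")
    out["normalized"] = out["percent_input"].to_numpy() / denom
    return out


def fold_enrichment(table: pd.DataFrame, value_col: str = "percent_input") -> pd.DataFrame:
    """Mean +/- sd of specific/IgG ratios across technical replicates.

    Each (locus, sample, replicate) needs one specific and one IgG row; the
    sd uses the sample (n-1) convention and is 0 for a single replicate.
    """
    _check(table)
    spec = table[table["antibody"] != "IgG"]
    igg = table[table["antibody"] == "IgG"].set_index(["locus", "sample", "replicate"])[
        value_col
    ]
    rows = []
    for (locus, sample), grp in spec.groupby(["locus", "sample"]):
        ratios = []
        for rec in grp.itertuples(index=False):
            key = (locus, sample, rec.replicate)
            if key not in igg.index:
                raise ValueError(f"missing IgG control for {key}")
            control = float(igg.loc[key])
            if control == 0:
                raise ValueError(f"IgG percent_input is 0 for {key}")
            ratios.append(getattr(rec, value_col) / control)
        ratios = np.asarray(ratios, dtype=float)
        rows.append(
            {
                "locus": locus,
                "sample": sample,
                "n": len(ratios),
                "fold_enrichment": float(ratios.mean()),
                "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def compare_samples_ttest(
    normalized: pd.DataFrame, locus: str, sample_a: str, sample_b: str
) -> dict:
    """Two-tailed, two-sample, equal-variance t-test on normalized %input."""
    sub = normalized[normalized["locus"] == locus]
    a = sub[sub["sample"] == sample_a]["normalized"].to_numpy()
    b = sub[sub["sample"] == sample_b]["normalized"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 normalized values per sample")
    res = stats.ttest_ind(a, b, equal_var=True)
    return {
        "locus": locus,
        "sample_a": sample_a,
        "sample_b": sample_b,
        "t": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_a": len(a),
        "n_b": len(b),
    }
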