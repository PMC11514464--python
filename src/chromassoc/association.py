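"""Gene binding scores, region-randomization permutation test, and
closest-distance statistics.

Three procedures sit at the heart of the analysis:

* a windowed **gene binding score** — the mean of 10 bp-window log2(ChIP/input)
  means over a gene body, with the top decile of ranked genes called "bound";
* a **region-randomization overlap permutation test** — the observed count of
  genes overlapping a domain set, compared against the counts obtained from
  randomized domain sets of identical lengths placed uniformly over the
  genome, yielding a Z-score and an empirical p-value;
* **closest-distance distributions** of genes to the nearest domain, binned
  for presentation and compared between gene classes with two-sample KS tests
  under Hochberg family-wise correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeLayout, IntervalSet, overlaps_regions
from .tracks import SignalTrack, window_means

__all__ = [
    "BindingScoreTable",
    "PermutationResult",
    "DistanceDistribution",
    "KSResult",
    "gene_binding_scores",
    "classify_bound_top_fraction",
    "randomize_regions",
    "count_gene_overlaps",
    "permutation_overlap_test",
    "bin_distances",
    "ks_compare",
    "hochberg_adjust",
]

DEFAULT_DISTANCE_EDGES = (0, 10_000, 100_000, 1_000_000)


@dataclass
class BindingScoreTable:
    """Per-gene average windowed log2 ratio with rank and bound flag."""

    table: pd.DataFrame  # columns: gene, average_log2, rank, bound
    window_bp: int
    bound_fraction: float | None = None
    min_bound_score: float | None = None

    @property
    def n_scored(self) -> int:
        return int(self.table["average_log2"].notna().sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def gene_binding_scores(
    track: SignalTrack, genes: IntervalSet, window_bp: int = 10
) -> BindingScoreTable:
    """Average of fixed-width window means over each gene body.

    The gene is tiled into ``window_bp`` windows (final partial window kept),
    the track mean is taken per window, and the windows are averaged.  Genes
    with no covered base score NaN and are excluded from ranking.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    if track.value_kind != "log2_ratio":
        raise ValueError("binding scores require a log2_ratio track")
    scores = []
    for iv in genes:
        w = window_means(track, iv, width=window_bp)
        w = w[~np.isnan(w)]
        scores.append(float(np.mean(w)) if len(w) else float("nan"))
    df = pd.DataFrame({"gene": [iv.name for iv in genes], "average_log2": scores})
    ranks = df["average_log2"].rank(method="dense", ascending=False)
    df["rank"] = ranks.astype("Int64")
    df["bound"] = False
    return BindingScoreTable(df, window_bp)


def classify_bound_top_fraction(
    table: BindingScoreTable, fraction: float = 0.10
) -> BindingScoreTable:
    """Flag the top ``fraction`` of scored genes (by score) as bound.

    Exactly max(1, floor(fraction * n_scored)) genes are flagged; ties are
    broken by (score descending, gene id ascending) so the flag set is
    invariant to input row order.  Also records the minimum bound score.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    df = table.table.copy()
    scored = df[df["average_log2"].notna()]
    if scored.empty:
        raise ValueError("no gene has a score")
    n_bound = max(1, math.floor(fraction * len(scored)))
    chosen = scored.sort_values(
        ["average_log2", "gene"], ascending=[False, True], kind="stable"
    ).head(n_bound)
    df["bound"] = df.index.isin(chosen.index)
    return BindingScoreTable(
        df,
        table.window_bp,
        bound_fraction=fraction,
        min_bound_score=float(chosen["average_log2"].min()),
    )


def randomize_regions(
    regions: IntervalSet, layout: GenomeLayout, rng: np.random.Generator
) -> IntervalSet:
    """One randomized set: lengths preserved, placement uniform over the genome.

    For each region the chromosome is drawn with probability proportional to
    its count of valid start positions (length − L + 1), then the start is
    uniform among them.  Randomized regions may overlap one another.
    """
    chrom_lens = np.asarray(layout.lengths, dtype=np.int64)
    lengths = (regions.frame["end"] - regions.frame["start"]).to_numpy()
    n = len(lengths)
    valid = np.maximum(chrom_lens[:, None] - lengths[None, :] + 1, 0)  # (C, n)
    totals = valid.sum(axis=0)
    if (totals == 0).any():
        L = int(lengths[totals == 0][0])
        raise ValueError(f"region of length {L} exceeds every chromosome")
    # chromosome index by inverse-CDF over valid start counts, then a uniform
    # start among that chromosome's valid positions
    cum = np.cumsum(valid, axis=0)
    u = rng.random(n) * totals
    ci = (u[None, :] >= cum).sum(axis=0)
    starts = np.floor(rng.random(n) * valid[ci, np.arange(n)]).astype(np.int64)
    names = np.asarray(layout.names, dtype=object)
    frame = pd.DataFrame(
        {
            "chrom": names[ci],
            "start": starts,
            "end": starts + lengths,
            "name": ".",
            "strand": ".",
        }
    )
    return IntervalSet(layout, frame)


def count_gene_overlaps(genes: IntervalSet, regions: IntervalSet) -> int:
    """Number of genes with >= 1 bp overlap with the merged regions."""
    if len(regions) == 0:
        return 0
    return int(overlaps_regions(genes, regions, min_bp=1).sum())


@dataclass
class PermutationResult:
    """Observed overlap count against a region-randomization null."""

    observed: int
    permuted: np.ndarray
    n_perm: int
    z_score: float  # NaN when the permuted sd is 0
    p_value: float  # (#at-least-as-extreme + 1) / (n_perm + 1)
    alternative: str  # "greater" | "less", by sign of (observed - mean)
    significance_line: float  # one-sided alpha=0.05 quantile of the null
    alpha: float = 0.05
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "n_perm": self.n_perm,
            "mean_perm": float(np.mean(self.permuted)),
            "sd_perm": float(np.std(self.permuted, ddof=1)) if self.n_perm > 1 else 0.0,
            "z_score": self.z_score,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "significance_line": self.significance_line,
            "alpha": self.alpha,
            "seed": self.seed,
        }


def permutation_overlap_test(
    genes: IntervalSet,
    regions: IntervalSet,
    layout: GenomeLayout,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PermutationResult:
    """Region-randomization overlap permutation test.

    The observed statistic is the count of genes overlapping the real region
    set; the null is the same count over ``n_perm`` randomized region sets of
    identical lengths.  The test is one-sided in the direction of the
    observed deviation from the null mean; the empirical p uses the +1
    pseudocount convention, so p >= 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = count_gene_overlaps(genes, regions)
    permuted = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        permuted[i] = count_gene_overlaps(
            genes, randomize_regions(regions, layout, rng)
        )
    mean = float(np.mean(permuted))
    sd = float(np.std(permuted, ddof=1)) if n_perm > 1 else 0.0
    if sd > 0:
        z = (observed - mean) / sd
    else:
        import warnings

        warnings.warn("permuted distribution is degenerate; z-score undefined")
        z = float("nan")
    alternative = "greater" if observed >= mean else "less"
    if alternative == "greater":
        extreme = int((permuted >= observed).sum())
        line = float(np.quantile(permuted, 1 - alpha))
    else:
        extreme = int((permuted <= observed).sum())
        line = float(np.quantile(permuted, alpha))
    p = (extreme + 1) / (n_perm + 1)
    return PermutationResult(
        observed, permuted, n_perm, z, p, alternative, line, alpha, seed
    )


@dataclass
class DistanceDistribution:
    """Binned closest distances: first class is exactly 0 (overlapping)."""

    label: str
    bin_edges: tuple[int, ...]
    counts: np.ndarray
    n_no_neighbor: int

    def bin_labels(self) -> list[str]:
        labels = ["overlap (0)"]
        edges = list(self.bin_edges)
        for lo, hi in zip(edges[:-1], edges[1:]):
            labels.append(f"({lo}, {hi}]")
        labels.append(f"> {edges[-1]}")
        return labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": self.label, "bin": self.bin_labels(), "count": self.counts}
        )


def bin_distances(
    distances: np.ndarray,
    bin_edges: tuple[int, ...] = DEFAULT_DISTANCE_EDGES,
    label: str = "",
) -> DistanceDistribution:
    """Bin closest distances for presentation.

    The first class holds exact zeros (overlapping queries); subsequent
    classes are half-open (lo, hi]; a final class catches everything above
    the last edge.  NaN distances ("no neighbor") are excluded and counted
    separately.
    """
    edges = tuple(bin_edges)
    if edges[0] != 0:
        raise ValueError("first bin edge must be 0 (the overlap class)")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    d = np.asarray(distances, dtype=float)
    nan_mask = np.isnan(d)
    d = d[~nan_mask]
    counts = np.zeros(len(edges) + 1, dtype=np.int64)
    counts[0] = int((d == 0).sum())
    pos = d[d > 0]
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]), start=1):
        counts[i] = int(((pos > lo) & (pos <= hi)).sum())
    counts[-1] = int((pos > edges[-1]).sum())
    return DistanceDistribution(label, edges, counts, int(nan_mask.sum()))


@dataclass
class KSResult:
    """Two-sample Kolmogorov–Smirnov comparison of raw distance samples."""

    d_statistic: float
    p_value: float
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        return {
            "a": self.label_a,
            "b": self.label_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "D": self.d_statistic,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
        }


def ks_compare(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    label_a: str = "a",
    label_b: str = "b",
    exact_max_n: int = 20,
) -> KSResult:
    """Two-sided two-sample KS test on raw (unbinned) samples.

    Uses the exact null distribution of D when both samples have at most
    ``exact_max_n`` observations, the asymptotic formula otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if max(len(a), len(b)) <= exact_max_n else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return KSResult(float(res.statistic), float(res.pvalue), label_a, label_b, len(a), len(b))


def hochberg_adjust(p_values) -> np.ndarray:
    """Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="simes-hochberg")[1]
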