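"""Valued genomic tracks and meta-region profile math.

A :class:`SignalTrack` holds per-chromosome sorted, non-overlapping steps each
carrying one value — the in-memory form of a bedGraph log2(ChIP/input) or
coverage track.  Bases not covered by any step are *missing* and are excluded
from means under the default policy (``zero_fill`` treats them as 0 instead).

Profiles come in two flavours, mirroring the two standard meta-region plots:

* :func:`scaled_region_profile` — each region's body is rescaled to a common
  percentage axis (body bins), with flanks of exactly one region-length on
  either side, the layout used for plots over peaks and over gene bodies
  (TSS→TTS).
* :func:`anchored_profile` — fixed-width windows centred on single-bp anchors
  such as transcription start sites.

Minus-strand regions are flipped so that profile columns always read 5′→3′.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Interval, IntervalSet

__all__ = [
    "SignalTrack",
    "ProfileMatrix",
    "AggregateProfile",
    "read_bedgraph",
    "mean_over_interval",
    "window_means",
    "scaled_region_profile",
    "anchored_profile",
    "aggregate_profile",
]


@dataclass
class SignalTrack:
    """Non-overlapping valued steps per chromosome."""

    layout: GenomeLayout
    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # chrom -> (starts, ends, values), sorted by start
    value_kind: str = "log2_ratio"

    def __post_init__(self) -> None:
        if self.value_kind not in ("log2_ratio", "coverage"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        clean = {}
        for chrom, (s, e, v) in self.steps.items():
            if chrom not in self.layout:
                raise ValueError(f"unknown chromosome {chrom!r}")
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if len(s) and (s[1:] < e[:-1]).any():
                raise ValueError(f"overlapping steps on {chrom}")
            if (s < 0).any() or (s >= e).any() or (e > self.layout.length_of(chrom)).any():
                raise ValueError(f"step out of bounds on {chrom}")
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite step value on {chrom}")
            clean[chrom] = (s, e, v)
        self.steps = clean

    @classmethod
    def from_frame(
        cls, layout: GenomeLayout, frame: pd.DataFrame, value_kind: str = "log2_ratio"
    ) -> "SignalTrack":
        steps = {
            str(chrom): (
                grp["start"].to_numpy(),
                grp["end"].to_numpy(),
                grp["value"].to_numpy(),
            )
            for chrom, grp in frame.groupby("chrom", sort=False)
        }
        return cls(layout, steps, value_kind)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.layout.names:
            if chrom not in self.steps:
                continue
            s, e, v = self.steps[chrom]
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e, "value": v}))
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end", "value"])
        return pd.concat(rows, ignore_index=True)

    def to_bedgraph(self, path: str | Path) -> None:
        self.to_frame().to_csv(
            path, sep="\t", header=False, index=False, float_format="%.6g"
        )

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); NaN where no step covers a base.

        ``start`` may be negative and ``end`` may exceed the chromosome:
        out-of-bounds bases come back NaN (used for clipped flanks).
        """
        n = end - start
        out = np.full(n, np.nan)
        if chrom not in self.steps:
            return out
        s, e, v = self.steps[chrom]
        j0 = np.searchsorted(e, max(start, 0), side="right")
        j1 = np.searchsorted(s, end, side="left")
        for k in range(j0, j1):
            lo = max(int(s[k]), start, 0)
            hi = min(int(e[k]), end)
            if hi > lo:
                out[lo - start : hi - start] = v[k]
        return out


def read_bedgraph(
    path: str | Path, layout: GenomeLayout, value_kind: str = "log2_ratio"
) -> SignalTrack:
    """Read a 4-column bedGraph; steps may be unsorted, must not overlap."""
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith(("#", "track", "browser")):
            continue
        parts = raw.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: bedGraph line has fewer than 4 fields")
        try:
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed coordinates/value") from exc
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return SignalTrack.from_frame(layout, frame, value_kind)


def _masked_mean(values: np.ndarray, missing_policy: str) -> float:
    if missing_policy == "zero_fill":
        values = np.nan_to_num(values, nan=0.0)
    if np.isnan(values).all():
        return float("nan")
    return float(np.nanmean(values))


def mean_over_interval(
    track: SignalTrack,
    interval: Interval,
    missing_policy: str = "exclude_missing",
) -> float:
    """Base-weighted mean of step values over the interval; NaN if uncovered."""
    if missing_policy not in ("exclude_missing", "zero_fill"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    return _masked_mean(
        track.per_base(interval.chrom, interval.start, interval.end), missing_policy
    )


def _bin_means(
    per_base: np.ndarray, n_bins: int, missing_policy: str
) -> tuple[np.ndarray, np.ndarray]:
    """Split a per-base vector into ``n_bins`` bins, remainder to the leftmost
    bins; returns (bin means, missing-base counts per bin)."""
    n = len(per_base)
    base = n // n_bins
    rem = n % n_bins
    sizes = np.full(n_bins, base, dtype=np.int64)
    sizes[:rem] += 1
    bin_ids = np.repeat(np.arange(n_bins), sizes)
    vals = per_base
    if missing_policy == "zero_fill":
        vals = np.nan_to_num(vals, nan=0.0)
    missing = np.isnan(vals)
    filled = np.where(missing, 0.0, vals)
    sums = np.bincount(bin_ids, weights=filled, minlength=n_bins)
    covered = np.bincount(bin_ids[~missing], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(covered > 0, sums / np.maximum(covered, 1), np.nan)
    raw_missing = np.isnan(per_base)
    raw_miss_counts = np.bincount(bin_ids[raw_missing], minlength=n_bins)
    return means, raw_miss_counts


def window_means(
    track: SignalTrack,
    interval: Interval,
    width: int = 10,
    missing_policy: str = "exclude_missing",
) -> np.ndarray:
    """Means over fixed-width windows tiling the interval left to right.

    The final partial window (length < width) is retained.  Windows with no
    covered base are NaN under the default policy.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    vals = track.per_base(interval.chrom, interval.start, interval.end)
    n = len(vals)
    starts = np.arange(0, n, width)
    if missing_policy == "zero_fill":
        vals = np.nan_to_num(vals, nan=0.0)
    missing = np.isnan(vals)
    filled = np.where(missing, 0.0, vals)
    sums = np.add.reduceat(filled, starts)
    counts = np.add.reduceat((~missing).astype(np.int64), starts)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


@dataclass
class ProfileMatrix:
    """Per-region binned signal: flank | body | flank columns, rows 5′→3′."""

    values: np.ndarray  # (n_regions, n_cols), NaN = missing
    missing_bases: np.ndarray  # same shape, count of missing bases per bin
    n_flank_bins: int
    n_body_bins: int
    region_names: list[str]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def column_labels(self) -> list[str]:
        up = [f"up_{i}" for i in range(self.n_flank_bins)]
        body = [f"body_{i}" for i in range(self.n_body_bins)]
        down = [f"down_{i}" for i in range(self.n_flank_bins)]
        return up + body + down

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_labels())
        df.insert(0, "region", self.region_names)
        return df


@dataclass
class AggregateProfile:
    """Per-bin mean or median across profile rows."""

    values: np.ndarray
    statistic: str
    n_regions: int

    def to_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"value": self.values})
        if labels is not None:
            df.insert(0, "bin", labels)
        return df


def scaled_region_profile(
    track: SignalTrack,
    regions: IntervalSet,
    body_bins: int = 100,
    flank_bins: int = 100,
    missing_policy: str = "exclude_missing",
) -> ProfileMatrix:
    """Percent-scaled meta-region matrix.

    Each region body is split into ``body_bins`` near-equal bins (remainder
    bases to the leftmost bins); each flank spans exactly one region-length
    split into ``flank_bins`` bins.  Flanks clipped at chromosome ends count
    as missing.  Minus-strand regions are reversed so columns read 5′→3′.
    """
    if len(regions) == 0:
        raise ValueError("regions set is empty")
    if body_bins < 1 or flank_bins < 1:
        raise ValueError("bin counts must be >= 1")
    n_cols = body_bins + 2 * flank_bins
    values = np.empty((len(regions), n_cols))
    missing = np.empty((len(regions), n_cols), dtype=np.int64)
    names = []
    for i, iv in enumerate(regions):
        L = iv.length
        per_base = track.per_base(iv.chrom, iv.start - L, iv.end + L)
        if iv.strand == "-":
            per_base = per_base[::-1]
        up, m_up = _bin_means(per_base[:L], flank_bins, missing_policy)
        body, m_body = _bin_means(per_base[L : 2 * L], body_bins, missing_policy)
        down, m_down = _bin_means(per_base[2 * L :], flank_bins, missing_policy)
        values[i] = np.concatenate([up, body, down])
        missing[i] = np.concatenate([m_up, m_body, m_down])
        names.append(iv.name)
    return ProfileMatrix(values, missing, flank_bins, body_bins, names)


def anchored_profile(
    track: SignalTrack,
    anchors: IntervalSet,
    flank_bp: int = 50_000,
    bin_bp: int = 100,
    missing_policy: str = "exclude_missing",
) -> ProfileMatrix:
    """Fixed-width matrix centred on strand-aware 5′ anchors (e.g. TSSs).

    Columns cover [anchor − flank_bp, anchor + flank_bp) in ``bin_bp`` bins;
    minus-strand anchors are flipped.  Out-of-bounds bases are missing.
    """
    if flank_bp % bin_bp:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    n_side = flank_bp // bin_bp
    n_cols = 2 * n_side
    values = np.empty((len(anchors), n_cols))
    missing = np.empty((len(anchors), n_cols), dtype=np.int64)
    names = []
    for i, iv in enumerate(anchors):
        pos = iv.start if iv.strand != "-" else iv.end - 1
        per_base = track.per_base(iv.chrom, pos - flank_bp, pos + flank_bp)
        if iv.strand == "-":
            per_base = per_base[::-1]
        values[i], missing[i] = _bin_means(per_base, n_cols, missing_policy)
        names.append(iv.name)
    return ProfileMatrix(values, missing, n_side, 0, names)


def aggregate_profile(
    matrix: ProfileMatrix, statistic: str = "mean"
) -> AggregateProfile:
    """Per-column mean or median over non-missing entries."""
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if matrix.values.shape[0] == 0:
        raise ValueError("empty profile matrix")
    fn = np.nanmean if statistic == "mean" else np.nanmedian
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            vals = fn(matrix.values, axis=0)
    return AggregateProfile(vals, statistic, matrix.values.shape[0])
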