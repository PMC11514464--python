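"""Genome layout and interval arithmetic.

All coordinates are 0-based half-open (BED-native).  Interval sets carry a
reference to the :class:`GenomeLayout` they live on; every pairwise operation
checks that its operands share one layout.  Overlap and distance operations
are strand-blind; strand is carried only for downstream anchor/profile use.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "Interval",
    "IntervalSet",
    "VennPartition",
    "read_bed",
    "read_chrom_sizes",
    "merge_intervals",
    "intersect_length",
    "venn_partition",
    "overlap_lengths",
    "overlaps_regions",
    "closest_distance",
]


class Interval(NamedTuple):
    """One genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with their lengths in bp."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes), tuple(int(v) for v in sizes.values()))

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column chrom-sizes file (name <TAB> length)."""
        sizes: dict[str, int] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name length'")
            sizes[parts[0]] = int(parts[1])
        return cls.from_dict(sizes)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{n}\t{l}\n" for n, l in zip(self.names, self.lengths))
        )

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class IntervalSet:
    """A set of intervals over one :class:`GenomeLayout`.

    ``merged`` is True when intervals are known to be sorted, pairwise
    non-overlapping and non-adjacent per chromosome.
    """

    layout: GenomeLayout
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    merged: bool = False

    def __post_init__(self) -> None:
        if self.frame.empty:
            self.frame = pd.DataFrame(
                {"chrom": pd.Series(dtype=str),
                 "start": pd.Series(dtype=np.int64),
                 "end": pd.Series(dtype=np.int64),
                 "name": pd.Series(dtype=object),
                 "strand": pd.Series(dtype=object)}
            )
            return
        df = self.frame.copy()
        if "name" not in df:
            df["name"] = "."
        if "strand" not in df:
            df["strand"] = "."
        df = df[["chrom", "start", "end", "name", "strand"]]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.frame = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        for chrom in self.frame["chrom"].unique():
            if chrom not in self.layout:
                raise ValueError(f"unknown chromosome {chrom!r}")
        starts = self.frame["start"].to_numpy()
        ends = self.frame["end"].to_numpy()
        lens = self.frame["chrom"].map(
            dict(zip(self.layout.names, self.layout.lengths))
        ).to_numpy()
        bad = (starts < 0) | (starts >= ends) | (ends > lens)
        if bad.any():
            row = self.frame[bad].iloc[0]
            raise ValueError(
                f"interval out of bounds: {row.chrom}:{row.start}-{row.end}"
            )

    @classmethod
    def from_intervals(
        cls, layout: GenomeLayout, intervals: Iterable[Interval], merged: bool = False
    ) -> "IntervalSet":
        rows = list(intervals)
        frame = pd.DataFrame(rows, columns=Interval._fields)
        if not rows:
            return cls(layout)
        return cls(layout, frame, merged=merged)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield Interval(row.chrom, int(row.start), int(row.end), row.name, row.strand)

    def per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Sorted (starts, ends) arrays per chromosome."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            order = np.argsort(grp["start"].to_numpy(), kind="stable")
            out[str(chrom)] = (
                grp["start"].to_numpy()[order],
                grp["end"].to_numpy()[order],
            )
        return out

    def total_length(self) -> int:
        """Total covered bases (after merging)."""
        return int(
            (merge_intervals(self) if not self.merged else self)
            .frame.eval("end - start")
            .sum()
        )

    def to_bed(self, path: str | Path) -> None:
        df = self.frame.copy()
        df["score"] = 0
        df[_BED_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    return GenomeLayout.from_file(path)


def read_bed(path: str | Path, layout: GenomeLayout) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Raises a ValueError naming the line on malformed input and the
    chromosome on coordinates outside the layout.
    """
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
        name = parts[3] if len(parts) > 3 else "."
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
        rows.append((parts[0], start, end, name, strand))
    if not rows:
        return IntervalSet(layout)
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return IntervalSet(layout, frame)


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Union of covered bases; adjacent intervals coalesce (bedtools-merge style)."""
    if s.merged or len(s) == 0:
        return IntervalSet(s.layout, s.frame.copy(), merged=True)
    out_rows = []
    for chrom in s.layout.names:
        grp = s.frame[s.frame["chrom"] == chrom]
        if grp.empty:
            continue
        starts = np.sort(grp["start"].to_numpy())
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        ends = grp["end"].to_numpy()[order]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for st, en in zip(starts[1:], ends[1:]):
            if st <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, int(en))
            else:
                out_rows.append((chrom, cur_s, cur_e, ".", "."))
                cur_s, cur_e = int(st), int(en)
        out_rows.append((chrom, cur_s, cur_e, ".", "."))
    frame = pd.DataFrame(out_rows, columns=["chrom", "start", "end", "name", "strand"])
    return IntervalSet(s.layout, frame, merged=True)


def _check_layouts(*sets: IntervalSet) -> None:
    first = sets[0].layout
    for s in sets[1:]:
        if s.layout != first:
            raise ValueError("interval sets live on different genome layouts")


def intersect_length(a: IntervalSet, b: IntervalSet) -> int:
    """Total bases covered by both sets (bedtools-intersect style, symmetric)."""
    _check_layouts(a, b)
    am, bm = merge_intervals(a).per_chrom(), merge_intervals(b).per_chrom()
    total = 0
    for chrom, (sa, ea) in am.items():
        if chrom not in bm:
            continue
        sb, eb = bm[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
    return total


@dataclass
class VennPartition:
    """Base-pair totals for every non-empty membership class of 2–3 sets."""

    labels: tuple[str, ...]
    classes: dict[frozenset, int]

    def bp(self, *members: str) -> int:
        """Bases belonging to exactly the given sets (and no others)."""
        return self.classes[frozenset(members)]

    @property
    def union_length(self) -> int:
        return int(sum(self.classes.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.classes, key=lambda k: (len(k), sorted(k))):
            rows.append(
                {
                    "members": "&".join(sorted(key, key=self.labels.index)),
                    "bp": self.classes[key],
                    "Mb": self.classes[key] / 1e6,
                }
            )
        return pd.DataFrame(rows)


def venn_partition(
    sets: Sequence[IntervalSet], labels: Sequence[str] | None = None
) -> VennPartition:
    """Disjoint base-pair partition of 2 or 3 interval sets.

    The 2^k − 1 classes are exclusive: a base in all k sets counts only in
    the full-intersection class.  Classes sum to the merged union length.
    """
    k = len(sets)
    if k not in (2, 3):
        raise ValueError("venn_partition takes 2 or 3 sets")
    _check_layouts(*sets)
    if labels is None:
        labels = tuple("ABC"[:k])
    labels = tuple(labels)
    merged = [merge_intervals(s).per_chrom() for s in sets]
    classes: dict[frozenset, int] = {
        frozenset(c): 0
        for r in range(1, k + 1)
        for c in itertools.combinations(labels, r)
    }
    for chrom in sets[0].layout.names:
        pts: list[np.ndarray] = []
        for m in merged:
            if chrom in m:
                pts.extend(m[chrom])
        if not pts:
            continue
        bounds = np.unique(np.concatenate(pts))
        seg_starts = bounds[:-1]
        seg_lens = np.diff(bounds)
        member = np.zeros((k, len(seg_starts)), dtype=bool)
        for idx, m in enumerate(merged):
            if chrom not in m:
                continue
            s, e = m[chrom]
            pos = np.searchsorted(s, seg_starts, side="right") - 1
            ok = pos >= 0
            member[idx, ok] = e[pos[ok]] > seg_starts[ok]
        any_member = member.any(axis=0)
        for col in np.nonzero(any_member)[0]:
            key = frozenset(labels[i] for i in range(k) if member[i, col])
            classes[key] += int(seg_lens[col])
    return VennPartition(labels, classes)


def overlap_lengths(queries: IntervalSet, regions: IntervalSet) -> np.ndarray:
    """Per-query overlap in bp with the merged regions (aligned with query rows)."""
    _check_layouts(queries, regions)
    rm = merge_intervals(regions).per_chrom()
    out = np.zeros(len(queries), dtype=np.int64)
    chroms = queries.frame["chrom"].to_numpy()
    qs = queries.frame["start"].to_numpy()
    qe = queries.frame["end"].to_numpy()
    for chrom, (s, e) in rm.items():
        idx = np.nonzero(chroms == chrom)[0]
        if len(idx) == 0:
            continue
        gs, ge = qs[idx], qe[idx]
        j0 = np.searchsorted(e, gs, side="right")
        j1 = np.searchsorted(s, ge, side="left")
        hit = j1 > j0
        if not hit.any():
            continue
        cum = np.concatenate(([0], np.cumsum(e - s)))
        hi, hj0, hj1 = idx[hit], j0[hit], j1[hit]
        full = cum[hj1] - cum[hj0]
        left_clip = np.maximum(0, gs[hit] - s[hj0])
        right_clip = np.maximum(0, e[hj1 - 1] - ge[hit])
        out[hi] = full - left_clip - right_clip
    return out


def overlaps_regions(
    queries: IntervalSet, regions: IntervalSet, min_bp: int = 1
) -> np.ndarray:
    """Boolean per query: overlap with merged regions >= ``min_bp`` bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_lengths(queries, regions) >= min_bp


def closest_distance(query: IntervalSet, reference: IntervalSet) -> np.ndarray:
    """Unsigned edge-to-edge distance to the nearest reference interval.

    0 when the query overlaps any reference interval; both chromosomal
    directions are considered.  Queries on chromosomes with no reference
    interval get NaN ("no neighbor") and should be excluded downstream.
    """
    _check_layouts(query, reference)
    if len(reference) == 0:
        raise ValueError("reference set is empty")
    rm = merge_intervals(reference).per_chrom()
    out = np.full(len(query), np.nan)
    for i, iv in enumerate(query):
        if iv.chrom not in rm:
            continue
        s, e = rm[iv.chrom]
        j0 = np.searchsorted(e, iv.start, side="right")
        j1 = np.searchsorted(s, iv.end, side="left")
        if j1 > j0:  # overlap
            out[i] = 0.0
            continue
        cands = []
        if j1 < len(s):  # next interval downstream
            cands.append(int(s[j1] - iv.end))
        if j0 > 0:  # previous interval upstream
            cands.append(int(iv.start - e[j0 - 1]))
        out[i] = float(min(cands))
    return out
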