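"""Independent brute-force oracles used across the test suite.

Everything here works on per-base boolean masks or per-base value vectors and
never calls the interval/profile code under test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from chromassoc.genome import GenomeLayout, IntervalSet


def coverage_mask(s: IntervalSet) -> dict[str, np.ndarray]:
    """Per-chromosome boolean coverage mask."""
    masks = {
        name: np.zeros(length, dtype=bool)
        for name, length in zip(s.layout.names, s.layout.lengths)
    }
    for iv in s:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def mask_total(masks: dict[str, np.ndarray]) -> int:
    return int(sum(m.sum() for m in masks.values()))


def random_interval_set(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n: int,
    max_len: int,
    with_strand: bool = False,
) -> IntervalSet:
    rows = []
    for i in range(n):
        ci = int(rng.integers(0, len(layout.names)))
        clen = layout.lengths[ci]
        L = int(rng.integers(1, min(max_len, clen) + 1))
        start = int(rng.integers(0, clen - L + 1))
        strand = ("+", "-")[int(rng.integers(0, 2))] if with_strand else "."
        rows.append((layout.names[ci], start, start + L, f"iv{i}", strand))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return IntervalSet(layout, frame)


def random_step_track_arrays(
    rng: np.random.Generator, length: int, n_steps: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted non-overlapping (starts, ends, values) with gaps, on [0, length)."""
    cuts = np.sort(rng.choice(length, size=min(2 * n_steps, length - 1), replace=False))
    starts, ends, values = [], [], []
    for lo, hi in zip(cuts[::2], cuts[1::2]):
        if hi > lo and rng.random() < 0.8:  # leave ~20% gaps
            starts.append(int(lo))
            ends.append(int(hi))
            values.append(float(rng.normal()))
    return (
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(values),
    )


def per_base_values(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray, length: int
) -> np.ndarray:
    out = np.full(length, np.nan)
    for s, e, v in zip(starts, ends, values):
        out[s:e] = v
    return out


def nanmean_or_nan(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(np.mean(x)) if len(x) else float("nan")


def bin_means_oracle(vec: np.ndarray, n_bins: int) -> np.ndarray:
    """Remainder-to-leftmost binning of a per-base vector, nanmean per bin."""
    n = len(vec)
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    out, pos = [], 0
    for sz in sizes:
        out.append(nanmean_or_nan(vec[pos : pos + sz]))
        pos += sz
    return np.array(out)


def closest_distance_oracle(query: IntervalSet, reference: IntervalSet) -> np.ndarray:
    """Exhaustive all-pairs minimum edge-to-edge gap, 0 on overlap."""
    refs = list(reference)
    out = np.full(len(query), np.nan)
    for i, q in enumerate(query):
        best = None
        for r in refs:
            if r.chrom != q.chrom:
                continue
            if q.start < r.end and r.start < q.end:
                gap = 0
            elif q.end <= r.start:
                gap = r.start - q.end
            else:
                gap = q.start - r.end
            best = gap if best is None else min(best, gap)
        if best is not None:
            out[i] = float(best)
    return out


def ks_d_oracle(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.sort(a), np.sort(b)
    allv = np.concatenate([a, b])
    cdfa = np.searchsorted(a, allv, side="right") / len(a)
    cdfb = np.searchsorted(b, allv, side="right") / len(b)
    return float(np.max(np.abs(cdfa - cdfb)))


def ks_permutation_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive label-permutation p for the two-sample two-sided KS test."""
    pooled = np.concatenate([a, b])
    n = len(a)
    obs = ks_d_oracle(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        if ks_d_oracle(pooled[mask], pooled[~mask]) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def hochberg_oracle(p: np.ndarray) -> np.ndarray:
    """Direct step-up formula: adj(i) = min_{j>=i} (m - j + 1) p_(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    running = np.inf
    for j in range(m - 1, -1, -1):
        running = min(running, (m - j) * sorted_p[j])  # m - j = m - (j+1) + 1
        adj[j] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
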