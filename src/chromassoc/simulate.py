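"""Seeded synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the shapes of a broad-domain ChIP study on a toy
genome: megabase-scale enrichment domains covering a set fraction of the
genome, genes with a planted fraction of downregulated genes inside domains,
log2(ChIP/input) step tracks with a plateau inside domains plus Gaussian
noise, differential-expression and expression tables that satisfy the
threshold rules by construction, and a ChIP-qPCR %input table with
batch-to-batch scale factors.

Every generator is a pure function of (config, seed): rerunning with the
same seed reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeLayout, IntervalSet, merge_intervals
from .tracks import SignalTrack

__all__ = [
    "SimulationConfig",
    "simulate_layout",
    "simulate_broad_domains",
    "simulate_genes_and_degs",
    "simulate_signal_track",
    "simulate_narrow_peaks",
    "make_fixture",
]


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 3 x 10 Mb genome, 1-3 Mb domains covering 15%,
    215 differentially expressed genes split 80 up / 135 down, 60% of the
    downregulated ones planted inside domains."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 10_000_000
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    domain_coverage: float = 0.15
    domain_length_range: tuple[int, int] = (1_000_000, 3_000_000)
    clad_coverage: float = 0.20
    n_narrow_peaks: int = 200
    narrow_peak_length_range: tuple[int, int] = (500, 2_000)
    plateau: float = 1.0
    background: float = -0.5
    noise_sd: float = 0.3
    step_bp: int = 100
    n_up: int = 80
    n_down: int = 135
    frac_down_in_domains: float = 0.60
    ko_domain_gene_bias: float = 0.60
    qpcr_loci: int = 2
    qpcr_samples: tuple[str, ...] = ("WT", "KO", "rescue")
    qpcr_replicates: int = 3
    qpcr_effect: float = 3.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], list):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def simulate_layout(config: SimulationConfig) -> GenomeLayout:
    """Deterministic toy layout; independent of the seed by design."""
    names = tuple(f"chr{i + 1}" for i in range(config.n_chroms))
    return GenomeLayout(names, (config.chrom_length,) * config.n_chroms)


class _Occupancy:
    """Per-chromosome sorted occupied intervals for rejection placement."""

    def __init__(self, layout: GenomeLayout):
        self.layout = layout
        self.by_chrom: dict[str, list[tuple[int, int]]] = {n: [] for n in layout.names}

    def collides(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.by_chrom[chrom])

    def add(self, chrom: str, start: int, end: int) -> None:
        self.by_chrom[chrom].append((start, end))


def _place_uniform(
    layout: GenomeLayout, length: int, rng: np.random.Generator
) -> tuple[str, int]:
    lens = np.asarray(layout.lengths, dtype=np.int64)
    valid = np.maximum(lens - length + 1, 0)
    if valid.sum() == 0:
        raise ValueError(f"length {length} exceeds every chromosome")
    ci = rng.choice(len(lens), p=valid / valid.sum())
    return layout.names[ci], int(rng.integers(0, valid[ci]))


def _place_avoiding(
    layout: GenomeLayout,
    length: int,
    occ: _Occupancy,
    rng: np.random.Generator,
    avoid: IntervalSet | None = None,
    max_tries: int = 2000,
) -> tuple[str, int]:
    avoid_pc = avoid.per_chrom() if avoid is not None and len(avoid) else {}
    for _ in range(max_tries):
        chrom, start = _place_uniform(layout, length, rng)
        end = start + length
        if occ.collides(chrom, start, end):
            continue
        if chrom in avoid_pc:
            s, e = avoid_pc[chrom]
            j0 = np.searchsorted(e, start, side="right")
            j1 = np.searchsorted(s, end, side="left")
            if j1 > j0:
                continue
        return chrom, start
    raise ValueError("placement infeasible: too little free genome space")


def simulate_broad_domains(
    config: SimulationConfig,
    rng: np.random.Generator,
    layout: GenomeLayout | None = None,
) -> IntervalSet:
    """Merged non-overlapping broad domains hitting the coverage target.

    Lengths are drawn uniformly from the configured range; the final domain
    is shortened so realized coverage lands on the target (well within the
    +/- 2 percentage-point band).
    """
    layout = layout or simulate_layout(config)
    if not 0 < config.domain_coverage <= 0.5:
        raise ValueError("domain coverage target must lie in (0, 0.5]")
    target_bp = int(round(config.domain_coverage * layout.total_length))
    lo, hi = config.domain_length_range
    max_len = max(layout.lengths)
    occ = _Occupancy(layout)
    rows = []
    covered = 0
    while covered < target_bp:
        L = int(rng.integers(lo, hi + 1))
        L = min(L, max_len)
        remaining = target_bp - covered
        if L > remaining:
            L = max(remaining, 1)
        chrom, start = _place_avoiding(layout, L, occ, rng)
        occ.add(chrom, start, start + L)
        rows.append((chrom, start, start + L, f"domain{len(rows) + 1}", "."))
        covered += L
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return merge_intervals(IntervalSet(layout, frame))


def _place_inside_regions(
    regions: IntervalSet, length: int, occ: _Occupancy, rng: np.random.Generator,
    max_tries: int = 2000,
) -> tuple[str, int]:
    ivs = [iv for iv in regions if iv.length >= length]
    if not ivs:
        raise ValueError("no region long enough to contain the gene")
    weights = np.array([iv.length - length + 1 for iv in ivs], dtype=float)
    for _ in range(max_tries):
        iv = ivs[rng.choice(len(ivs), p=weights / weights.sum())]
        start = int(rng.integers(iv.start, iv.end - length + 1))
        if not occ.collides(iv.chrom, start, start + length):
            return iv.chrom, start
    raise ValueError("placement infeasible inside domains")


def simulate_genes_and_degs(
    config: SimulationConfig,
    domains: IntervalSet,
    rng: np.random.Generator,
    layout: GenomeLayout | None = None,
) -> tuple[IntervalSet, pd.DataFrame, pd.DataFrame]:
    """Non-overlapping genes plus DE and expression tables.

    A configured fraction of the downregulated genes is planted fully inside
    domains and the rest strictly outside; upregulated and unchanged genes
    are placed uniformly.  The DE table satisfies the DEG thresholds by
    construction, so re-applying the selection rule recovers the planted set.
    Returns (genes, de_table, expression_table).
    """
    layout = layout or simulate_layout(config)
    lo, hi = config.gene_length_range
    occ = _Occupancy(layout)
    n_down_in = int(round(config.frac_down_in_domains * config.n_down))
    roles = (
        [("down", True)] * n_down_in
        + [("down", False)] * (config.n_down - n_down_in)
        + [("up", None)] * config.n_up
        + [("none", None)] * (config.n_genes - config.n_down - config.n_up)
    )
    if config.n_down + config.n_up > config.n_genes:
        raise ValueError("more DEGs than genes")
    rows = []
    rec = []
    for i, (direction, in_domain) in enumerate(roles):
        L = int(rng.integers(lo, hi + 1))
        if in_domain is True:
            chrom, start = _place_inside_regions(domains, L, occ, rng)
        elif in_domain is False:
            chrom, start = _place_avoiding(layout, L, occ, rng, avoid=domains)
        else:
            chrom, start = _place_avoiding(layout, L, occ, rng)
        occ.add(chrom, start, start + L)
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene{i + 1:04d}"
        rows.append((chrom, start, start + L, name, strand))
        rec.append((name, direction))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    genes = IntervalSet(layout, frame)

    de_rows = []
    expr_rows = []
    for name, direction in rec:
        if direction in ("up", "down"):
            lfc = float(rng.uniform(2.0, 4.0))
            if direction == "down":
                lfc = -lfc
            p = float(10 ** rng.uniform(-8.0, -1.5))
            cpm = rng.uniform(20.0, 300.0, size=3)
        else:
            lfc = float(rng.uniform(-1.2, 1.2))
            p = float(rng.uniform(0.1, 1.0))
            cpm = rng.uniform(11.0, 100.0, size=3)
        de_rows.append(
            {"gene": name, "log2fc": lfc, "p_value": p,
             "cpm_1": cpm[0], "cpm_2": cpm[1], "cpm_3": cpm[2]}
        )
        expressed = True if direction in ("up", "down") else bool(rng.random() < 0.7)
        if expressed:
            counts = rng.uniform(20.0, 5000.0, size=3)
            fpkm = rng.uniform(1.0, 100.0, size=3)
        else:
            counts = rng.uniform(0.0, 10.0, size=3)
            fpkm = rng.uniform(0.0, 0.4, size=3)
        expr_rows.append(
            {"gene": name,
             "count_1": counts[0], "count_2": counts[1], "count_3": counts[2],
             "cpm_1": cpm[0], "cpm_2": cpm[1], "cpm_3": cpm[2],
             "fpkm_1": fpkm[0], "fpkm_2": fpkm[1], "fpkm_3": fpkm[2]}
        )
    return genes, pd.DataFrame(de_rows), pd.DataFrame(expr_rows)


def simulate_signal_track(
    config: SimulationConfig,
    domains: IntervalSet,
    rng: np.random.Generator,
    layout: GenomeLayout | None = None,
) -> SignalTrack:
    """Step track: plateau + noise inside domains, background + noise outside.

    Steps of ``step_bp`` tile each chromosome (final partial step kept); a
    step belongs to a domain when its midpoint lies inside one.
    """
    layout = layout or simulate_layout(config)
    dm = merge_intervals(domains).per_chrom()
    steps = {}
    for chrom in layout.names:
        clen = layout.length_of(chrom)
        starts = np.arange(0, clen, config.step_bp, dtype=np.int64)
        ends = np.minimum(starts + config.step_bp, clen)
        mids = (starts + ends) // 2
        inside = np.zeros(len(starts), dtype=bool)
        if chrom in dm:
            s, e = dm[chrom]
            pos = np.searchsorted(s, mids, side="right") - 1
            ok = pos >= 0
            inside[ok] = e[pos[ok]] > mids[ok]
        level = np.where(inside, config.plateau, config.background)
        noise = (
            rng.normal(0.0, config.noise_sd, size=len(starts))
            if config.noise_sd > 0
            else np.zeros(len(starts))
        )
        steps[chrom] = (starts, ends, level + noise)
    return SignalTrack(layout, steps, value_kind="log2_ratio")


def simulate_narrow_peaks(
    config: SimulationConfig,
    rng: np.random.Generator,
    layout: GenomeLayout | None = None,
) -> IntervalSet:
    """MACS2-style narrow peaks placed uniformly (may overlap)."""
    layout = layout or simulate_layout(config)
    lo, hi = config.narrow_peak_length_range
    rows = []
    for i in range(config.n_narrow_peaks):
        L = int(rng.integers(lo, hi + 1))
        chrom, start = _place_uniform(layout, L, rng)
        rows.append((chrom, start, start + L, f"peak{i + 1}", "."))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return IntervalSet(layout, frame)


def _simulate_ko_domains(
    config: SimulationConfig,
    genes: IntervalSet,
    de_table: pd.DataFrame,
    rng: np.random.Generator,
    layout: GenomeLayout,
) -> IntervalSet:
    """Condition-2 domain set biased toward downregulated genes.

    Emulates relocalization: a configured fraction of domains is centred on a
    randomly chosen downregulated gene, the rest placed uniformly; lengths
    and total coverage match the condition-1 recipe.
    """
    target_bp = int(round(config.domain_coverage * layout.total_length))
    lo, hi = config.domain_length_range
    down = de_table[de_table["log2fc"] < -1.5]["gene"].tolist()
    centers = {iv.name: (iv.chrom, (iv.start + iv.end) // 2) for iv in genes}
    occ = _Occupancy(layout)
    rows = []
    covered = 0
    while covered < target_bp:
        L = min(int(rng.integers(lo, hi + 1)), max(layout.lengths))
        remaining = target_bp - covered
        if L > remaining:
            L = max(remaining, 1)
        placed = False
        if down and rng.random() < config.ko_domain_gene_bias:
            for _ in range(50):
                gname = down[int(rng.integers(0, len(down)))]
                chrom, mid = centers[gname]
                start = int(
                    np.clip(mid - L // 2, 0, layout.length_of(chrom) - L)
                )
                if not occ.collides(chrom, start, start + L):
                    placed = True
                    break
        if not placed:
            chrom, start = _place_avoiding(layout, L, occ, rng)
        occ.add(chrom, start, start + L)
        rows.append((chrom, start, start + L, f"domain{len(rows) + 1}", "."))
        covered += L
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return merge_intervals(IntervalSet(layout, frame))


def _simulate_qpcr(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """%input table with per-replicate batch factors and a KO-specific effect."""
    rows = []
    for li in range(config.qpcr_loci):
        locus = f"locus{li + 1}"
        base = float(rng.uniform(0.5, 2.0))
        for rep in range(1, config.qpcr_replicates + 1):
            batch = float(rng.lognormal(0.0, 0.4))
            for sample in config.qpcr_samples:
                effect = config.qpcr_effect if sample == "KO" else 1.0
                specific = base * batch * effect * float(rng.lognormal(0.0, 0.1))
                igg = base * batch * 0.1 * float(rng.lognormal(0.0, 0.1))
                rows.append((locus, sample, rep, "specific", specific))
                rows.append((locus, sample, rep, "IgG", igg))
    return pd.DataFrame(
        rows, columns=["locus", "sample", "replicate", "antibody", "percent_input"]
    )


def make_fixture(
    config: SimulationConfig, outdir: str | Path, seed: int | None = None
) -> dict:
    """Write a complete synthetic dataset to ``outdir``; returns the manifest.

    Emits the genome layout, genes, broad domains for two conditions (the
    second re-drawn biased toward downregulated genes to emulate
    relocalization), cLADs, narrow peaks, a log2-ratio track per condition,
    DE/expression tables, a qPCR table, and a JSON manifest recording the
    seed and config.
    """
    if seed is None:
        seed = config.seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    layout = simulate_layout(config)
    domains_wt = simulate_broad_domains(config, rng, layout)
    genes, de_table, expr_table = simulate_genes_and_degs(config, domains_wt, rng, layout)
    domains_ko = _simulate_ko_domains(config, genes, de_table, rng, layout)
    clad_cfg = dataclasses.replace(config, domain_coverage=config.clad_coverage)
    clads = simulate_broad_domains(clad_cfg, rng, layout)
    peaks = simulate_narrow_peaks(config, rng, layout)
    track_wt = simulate_signal_track(config, domains_wt, rng, layout)
    track_ko = simulate_signal_track(config, domains_ko, rng, layout)
    qpcr_table = _simulate_qpcr(config, rng)

    layout.to_file(outdir / "chrom.sizes")
    genes.to_bed(outdir / "genes.bed")
    domains_wt.to_bed(outdir / "domains_wt.bed")
    domains_ko.to_bed(outdir / "domains_ko.bed")
    clads.to_bed(outdir / "clads.bed")
    peaks.to_bed(outdir / "narrow_peaks.bed")
    track_wt.to_bedgraph(outdir / "track_wt.bedgraph")
    track_ko.to_bedgraph(outdir / "track_ko.bedgraph")
    de_table.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    expr_table.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    qpcr_table.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)

    files = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "config": config.to_dict(),
        "files": files,
        "sha256": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
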