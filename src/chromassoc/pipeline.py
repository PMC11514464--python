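"""End-to-end orchestration over a directory of standard-format inputs.

The pipeline composes the module operations in the analysis's natural order:
base-pair Venn partitions of domain sets, gene-class summaries, permutation
overlap tests, closest-distance distributions with KS tests under Hochberg
correction, gene binding scores, meta-region profiles, expression threshold
summaries, and qPCR normalization/fold enrichment.  All outputs are plain
TSV/JSON; (inputs, config, seed) fully determine every emitted number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, expression, qpcr
from .genome import (GenomeLayout, IntervalSet, closest_distance, read_bed,
                     venn_partition)
from .tracks import aggregate_profile, read_bedgraph, scaled_region_profile

ALL_STAGES = (
    "venn",
    "gene_classes",
    "permutation",
    "distances",
    "binding",
    "profiles",
    "expression",
    "qpcr",
)


@dataclass
class PipelineConfig:
    chrom_sizes: str
    output_dir: str
    genes: str | None = None
    clads: str | None = None
    domains: dict[str, str] = field(default_factory=dict)
    tracks: dict[str, str] = field(default_factory=dict)
    de_table: str | None = None
    expression_table: str | None = None
    qpcr_table: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_perm: int = 1000
    bound_fraction: float = 0.10
    window_bp: int = 10
    body_bins: int = 100
    flank_bins: int = 100
    distance_edges: tuple[int, ...] = association.DEFAULT_DISTANCE_EDGES

    def to_dict(self) -> dict:
        import dataclasses

        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["distance_edges"] = list(self.distance_edges)
        return d


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a YAML pipeline config, collecting all violations."""
    errors: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except Exception as exc:  # unreadable/invalid YAML
        return None, [f"cannot parse config: {exc}"]
    inputs = raw.get("inputs", {})
    params = raw.get("params", {})
    cfg = PipelineConfig(
        chrom_sizes=inputs.get("chrom_sizes", ""),
        output_dir=raw.get("output_dir", ""),
        genes=inputs.get("genes"),
        clads=inputs.get("clads"),
        domains=dict(inputs.get("domains", {})),
        tracks=dict(inputs.get("tracks", {})),
        de_table=inputs.get("de_table"),
        expression_table=inputs.get("expression"),
        qpcr_table=inputs.get("qpcr"),
        stages=tuple(raw.get("stages", ALL_STAGES)),
        seed=int(params.get("seed", 0)),
        n_perm=int(params.get("n_perm", 1000)),
        bound_fraction=float(params.get("bound_fraction", 0.10)),
        window_bp=int(params.get("window_bp", 10)),
        body_bins=int(params.get("body_bins", 100)),
        flank_bins=int(params.get("flank_bins", 100)),
        distance_edges=tuple(
            params.get("distance_edges", association.DEFAULT_DISTANCE_EDGES)
        ),
    )
    if not cfg.chrom_sizes:
        errors.append("inputs.chrom_sizes is required")
    if not cfg.output_dir:
        errors.append("output_dir is required")
    for label, p in [("chrom_sizes", cfg.chrom_sizes), ("genes", cfg.genes),
                     ("clads", cfg.clads), ("de_table", cfg.de_table),
                     ("expression", cfg.expression_table), ("qpcr", cfg.qpcr_table)]:
        if p and not Path(p).exists():
            errors.append(f"input file for {label!r} does not exist: {p}")
    for group in (cfg.domains, cfg.tracks):
        for label, p in group.items():
            if not Path(p).exists():
                errors.append(f"input file for {label!r} does not exist: {p}")
    for s in cfg.stages:
        if s not in ALL_STAGES:
            errors.append(f"unknown stage {s!r}")
    if cfg.n_perm < 1:
        errors.append("params.n_perm must be >= 1")
    if not 0 < cfg.bound_fraction < 1:
        errors.append("params.bound_fraction must lie in (0, 1)")
    if cfg.window_bp < 1:
        errors.append("params.window_bp must be >= 1")
    if cfg.body_bins < 1 or cfg.flank_bins < 1:
        errors.append("bin counts must be >= 1")
    edges = cfg.distance_edges
    if not edges or edges[0] != 0 or any(b <= a for a, b in zip(edges, edges[1:])):
        errors.append("params.distance_edges must start at 0 and increase strictly")
    return (None, errors) if errors else (cfg, errors)


@dataclass
class AnalysisReport:
    """Machine-readable results bundle plus a run manifest."""

    sections: dict
    manifest: dict

    @property
    def report_hash(self) -> str:
        return self.manifest["report_hash"]


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run all enabled stages; writes TSV/JSON outputs under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = GenomeLayout.from_file(config.chrom_sizes)
    sections: dict = {}
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    def load_genes() -> IntervalSet:
        if not config.genes:
            raise RuntimeError("gene BED required but not configured")
        return read_bed(config.genes, layout)

    domain_sets = {k: read_bed(v, layout) for k, v in config.domains.items()}
    clads = read_bed(config.clads, layout) if config.clads else None

    def stage_venn() -> None:
        labels = list(domain_sets)
        frames = []
        if len(labels) >= 2:
            pair = labels[:2]
            sets = [domain_sets[l] for l in pair]
            if clads is not None and len(clads):
                part = venn_partition(sets + [clads], pair + ["cLADs"])
            else:
                part = venn_partition(sets, pair)
            df = part.to_frame()
            df.insert(0, "comparison", "+".join(part.labels))
            frames.append(df)
        for label in labels:
            if clads is not None and len(clads):
                part = venn_partition([domain_sets[label], clads], [label, "cLADs"])
                df = part.to_frame()
                df.insert(0, "comparison", f"{label}+cLADs")
                frames.append(df)
        if not frames:
            raise RuntimeError("venn stage needs at least two region sets")
        table = pd.concat(frames, ignore_index=True)
        emit("venn_partitions.tsv", table)
        sections["venn"] = table

    def stage_gene_classes() -> None:
        genes = load_genes()
        de = pd.read_csv(config.de_table, sep="\t")
        degs = expression.select_degs(de)
        degs = degs[degs["deg"]][["gene", "direction"]]
        summary = expression.summarize_gene_classes(genes, degs, domain_sets, clads)
        emit("gene_class_summary.tsv", summary.table)
        sections["gene_classes"] = summary

    def stage_permutation() -> None:
        genes = load_genes()
        de = pd.read_csv(config.de_table, sep="\t")
        degs = expression.select_degs(de)
        rng = np.random.default_rng(config.seed)
        rows = []
        for label, regions in domain_sets.items():
            for direction in ("up", "down"):
                ids = set(degs[(degs["deg"]) & (degs["direction"] == direction)]["gene"])
                subset = IntervalSet(
                    layout, genes.frame[genes.frame["name"].isin(ids)]
                )
                if len(subset) == 0:
                    continue
                res = association.permutation_overlap_test(
                    subset, regions, layout, n_perm=config.n_perm, rng=rng,
                    seed=config.seed,
                )
                row = {"domains": label, "gene_class": direction, **res.to_dict()}
                rows.append(row)
        table = pd.DataFrame(rows)
        emit("permutation_tests.tsv", table)
        sections["permutation"] = table

    def stage_distances() -> None:
        genes = load_genes()
        de = pd.read_csv(config.de_table, sep="\t")
        degs = expression.select_degs(de)
        classes = {
            "up": set(degs[degs["direction"] == "up"]["gene"]),
            "down": set(degs[degs["direction"] == "down"]["gene"]),
        }
        classes["non_deg"] = (
            set(genes.frame["name"]) - classes["up"] - classes["down"]
        )
        dist_frames, ks_results = [], []
        samples: dict[tuple[str, str], np.ndarray] = {}
        for label, regions in domain_sets.items():
            if len(regions) == 0:
                continue
            d_all = closest_distance(genes, regions)
            for cname, ids in classes.items():
                mask = genes.frame["name"].isin(ids).to_numpy()
                d = d_all[mask]
                samples[(label, cname)] = d[~np.isnan(d)]
                dd = association.bin_distances(
                    d, config.distance_edges, label=f"{label}:{cname}"
                )
                dist_frames.append(dd.to_frame())
            for a, b in (("up", "down"), ("up", "non_deg"), ("down", "non_deg")):
                sa, sb = samples[(label, a)], samples[(label, b)]
                if len(sa) and len(sb):
                    ks_results.append(
                        association.ks_compare(sa, sb, f"{label}:{a}", f"{label}:{b}")
                    )
        if ks_results:
            adj = association.hochberg_adjust([k.p_value for k in ks_results])
            for k, pa in zip(ks_results, adj):
                k.p_adjusted = float(pa)
        emit("distance_distributions.tsv", pd.concat(dist_frames, ignore_index=True))
        ks_table = pd.DataFrame([k.to_dict() for k in ks_results])
        emit("ks_tests.tsv", ks_table)
        sections["distances"] = {"bins": dist_frames, "ks": ks_table}

    def stage_binding() -> None:
        genes = load_genes()
        frames = []
        for label, path in config.tracks.items():
            track = read_bedgraph(path, layout)
            table = association.gene_binding_scores(
                track, genes, window_bp=config.window_bp
            )
            table = association.classify_bound_top_fraction(
                table, fraction=config.bound_fraction
            )
            df = table.table.copy()
            df.insert(0, "track", label)
            df["min_bound_score"] = table.min_bound_score
            frames.append(df)
        if not frames:
            raise RuntimeError("binding stage needs at least one track")
        emit("binding_scores.tsv", pd.concat(frames, ignore_index=True))
        sections["binding"] = frames

    def stage_profiles() -> None:
        genes = load_genes()
        rows = []
        for label, path in config.tracks.items():
            track = read_bedgraph(path, layout)
            matrix = scaled_region_profile(
                track, genes, body_bins=config.body_bins, flank_bins=config.flank_bins
            )
            for statistic in ("mean", "median"):
                agg = aggregate_profile(matrix, statistic)
                df = agg.to_frame(matrix.column_labels())
                df.insert(0, "track", label)
                df.insert(1, "statistic", statistic)
                rows.append(df)
        if not rows:
            raise RuntimeError("profiles stage needs at least one track")
        emit("aggregate_profiles.tsv", pd.concat(rows, ignore_index=True))
        sections["profiles"] = rows

    def stage_expression() -> None:
        table = pd.read_csv(config.expression_table, sep="\t")
        kept = expression.filter_low_counts(table)
        kept = kept.assign(expressed=expression.flag_expressed(kept))
        emit("expression_flags.tsv", kept[["gene", "expressed"]])
        sections["expression"] = kept

    def stage_qpcr() -> None:
        table = pd.read_csv(config.qpcr_table, sep="\t")
        norm = qpcr.normalize_percent_input(table)
        emit("qpcr_normalized.tsv", norm)
        fold = qpcr.fold_enrichment(table)
        emit("qpcr_fold_enrichment.tsv", fold)
        tests = []
        spec = norm[norm["antibody"] != "IgG"]
        sample_names = list(dict.fromkeys(spec["sample"]))
        if len(sample_names) >= 2:
            a, b = sample_names[0], sample_names[1]
            for locus in dict.fromkeys(spec["locus"]):
                tests.append(qpcr.compare_samples_ttest(spec, locus, a, b))
        emit("qpcr_ttests.tsv", pd.DataFrame(tests))
        sections["qpcr"] = {"normalized": norm, "fold": fold}

    runners = {
        "venn": stage_venn,
        "gene_classes": stage_gene_classes,
        "permutation": stage_permutation,
        "distances": stage_distances,
        "binding": stage_binding,
        "profiles": stage_profiles,
        "expression": stage_expression,
        "qpcr": stage_qpcr,
    }
    for stage in config.stages:
        try:
            runners[stage]()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    digest = hashlib.sha256()
    for path in sorted(written):
        digest.update(path.name.encode())
        digest.update(path.read_bytes())
    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": list(config.stages),
        "outputs": [p.name for p in sorted(written)],
        "report_hash": digest.hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return AnalysisReport(sections, manifest)
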