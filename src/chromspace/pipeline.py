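"""End-to-end orchestration: tracks → spacing → matrices → clustering →
distance statistics → fold-change profiles.

Each stage reads its inputs from files and writes its outputs to files
under the run directory, so stages are independently testable and a run
can resume from any completed stage. A ``summary.json`` records every
parameter, input checksum, and output path; reruns with the same seeds
produce identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage, diststats, matrices, profiles, spacing, synthetic
from .genome import SyntheticGenome, read_chrom_sizes, write_chrom_sizes

__all__ = ["RunConfig", "run_pipeline", "demo_synthetic", "STAGES"]

log = logging.getLogger("chromspace")

STAGES = ("tracks", "spacing", "matrix", "cluster", "distcurve", "profiles")

DEFAULT_PARAMS = {
    "bin_size": 10,
    "flank": 2500,            # heatmap window half-width, bp
    "sum_upstream": 100,      # promoter-proximal window, bp upstream of TSS
    "sum_downstream": 500,    # ... and downstream
    "distance_threshold": 2000,
    "k": 3,
    "spike_constant": 10_000,
    "outlier_sds": 64.0,
    "torsion_window": 200,
    "seed": 0,
    "cluster_condition": None,   # default: the control condition
    "moving_statistic": "median",
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from a YAML file."""

    samples: list[dict]           # {id, condition, fragments, spike_count}
    control_condition: str
    promoters: str
    genome: str                   # chromosome-size TSV
    expression: str | None = None
    torsion: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params or {})
        self.params = merged
        conditions = {s["condition"] for s in self.samples}
        if self.control_condition not in conditions:
            raise ValueError(
                f"control condition {self.control_condition!r} has no samples "
                f"(conditions present: {sorted(conditions)})"
            )
        for key in ("bin_size", "flank", "sum_upstream", "sum_downstream",
                    "distance_threshold", "k", "spike_constant", "outlier_sds",
                    "torsion_window"):
            if self.params[key] <= 0:
                raise ValueError(f"parameter {key!r} must be positive")
        for s in self.samples:
            for k in ("id", "condition", "fragments", "spike_count"):
                if k not in s:
                    raise ValueError(f"sample entry missing field {k!r}: {s}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        # paths in the config are relative to the config file
        base = Path(path).parent
        cfg.promoters = str((base / cfg.promoters))
        cfg.genome = str((base / cfg.genome))
        if cfg.expression:
            cfg.expression = str(base / cfg.expression)
        if cfg.torsion:
            cfg.torsion = str(base / cfg.torsion)
        for s in cfg.samples:
            s["fragments"] = str(base / s["fragments"])
        return cfg

    def to_dict(self) -> dict:
        return {"samples": self.samples, "control_condition": self.control_condition,
                "promoters": self.promoters, "genome": self.genome,
                "expression": self.expression, "torsion": self.torsion,
                "params": self.params}

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s["condition"] not in seen:
                seen.append(s["condition"])
        return seen


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _condition_tracks(cfg: RunConfig, genome: SyntheticGenome) -> dict[str, coverage.CoverageTrack]:
    """Spike-calibrate each sample and average replicates per condition."""
    per_condition: dict[str, list[coverage.CoverageTrack]] = {}
    for s in cfg.samples:
        frags = synthetic.read_fragments_bed(s["fragments"], sample_id=s["id"],
                                             spike_count=int(s["spike_count"]))
        factor = coverage.spike_scale_factor(frags.spike_count,
                                             cfg.params["spike_constant"], sample_id=s["id"])
        track = coverage.calibrate_spike(coverage.fragment_pileup(frags, genome), factor)
        per_condition.setdefault(s["condition"], []).append(track)
    out = {}
    for cond, tracks in per_condition.items():
        vals = {c: np.mean([t.values[c] for t in tracks], axis=0)
                for c in genome.chrom_names}
        scale = float(np.mean([t.scale_used for t in tracks]))
        out[cond] = coverage.CoverageTrack(genome, vals, calibration="spike", scale_used=scale)
    return out


def run_pipeline(cfg: RunConfig, outdir, resume: bool = False) -> Path:
    """Run all stages and write a machine-readable summary.

    With ``resume=True`` a stage whose outputs already exist is skipped.
    Any stage failure aborts with the stage name in the exception message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_chrom_sizes(cfg.genome)
    proms = spacing.read_promoters_bed(cfg.promoters)
    p = cfg.params
    summary: dict = {
        "config": cfg.to_dict(),
        "inputs": {Path(s["fragments"]).name: _sha256(s["fragments"]) for s in cfg.samples},
        "outputs": [],
    }
    summary["inputs"]["promoters"] = _sha256(cfg.promoters)

    def record(path: Path) -> Path:
        summary["outputs"].append({"path": str(path.relative_to(outdir)),
                                   "sha256": _sha256(path)})
        return path

    control = cfg.control_condition
    treated_conditions = [c for c in cfg.conditions if c != control]

    try:
        stage = "tracks"
        track_dir = outdir / "tracks"
        track_dir.mkdir(exist_ok=True)
        cond_paths = {c: track_dir / f"{c}.spike.bedGraph" for c in cfg.conditions}
        if resume and all(q.exists() for q in cond_paths.values()):
            log.info("tracks: resuming from existing bedGraphs")
            tracks = {c: coverage.read_bedgraph(q, genome) for c, q in cond_paths.items()}
        else:
            log.info("tracks: pileup + spike calibration for %d samples", len(cfg.samples))
            tracks = _condition_tracks(cfg, genome)
            for cond, track in tracks.items():
                coverage.write_bedgraph(track, cond_paths[cond])
        for q in cond_paths.values():
            record(q)

        stage = "spacing"
        log.info("spacing: nearest-upstream annotation of %d promoters", len(proms))
        ann = spacing.annotate_spacing(proms)
        spacing.write_annotations(ann, outdir / "spacing.tsv")
        record(outdir / "spacing.tsv")
        fractions = spacing.orientation_fractions(
            ann, [1000, int(p["distance_threshold"])])
        fractions.to_csv(outdir / "orientation_fractions.tsv", sep="\t", index=False)
        record(outdir / "orientation_fractions.tsv")
        orient = {a.promoter_id: a.orientation for a in ann}
        distances = {a.promoter_id: a.distance for a in ann if a.distance is not None}

        stage = "matrix"
        log.info("matrix: %d-bp bins, +/-%d bp", p["bin_size"], p["flank"])
        mat_dir = outdir / "matrices"
        mat_dir.mkdir(exist_ok=True)
        wide = {c: matrices.compute_matrix(tracks[c], proms, p["flank"], p["flank"],
                                           p["bin_size"]) for c in cfg.conditions}
        prox = {c: matrices.compute_matrix(tracks[c], proms, p["sum_upstream"],
                                           p["sum_downstream"], p["bin_size"])
                for c in cfg.conditions}
        for c in cfg.conditions:
            matrices.write_matrix(wide[c], mat_dir / f"{c}.wide.tsv.gz")
            record(mat_dir / f"{c}.wide.tsv.gz")

        stage = "cluster"
        cluster_cond = p["cluster_condition"] or control
        log.info("cluster: k=%d on condition %r", p["k"], cluster_cond)
        clusters = matrices.kmeans_promoters(wide[cluster_cond], p["k"], seed=p["seed"])
        matrices.write_cluster_regions(proms, clusters, outdir / "clusters.bed")
        record(outdir / "clusters.bed")

        stage = "distcurve"
        sums = {c: {pr.id: matrices.region_sum(tracks[c], pr, p["sum_upstream"],
                                               p["sum_downstream"]) for pr in proms}
                for c in cfg.conditions}
        keep = set(distances)
        curves = {}
        for c in cfg.conditions:
            sig = {k: v for k, v in sums[c].items() if k in keep}
            curves[c] = diststats.moving_median_curve(sig, distances,
                                                      statistic=p["moving_statistic"])
            curves[c].points.to_csv(outdir / f"distcurve.{c}.tsv", sep="\t", index=False)
            record(outdir / f"distcurve.{c}.tsv")
        dist_summary = {}
        for c in treated_conditions:
            comps = diststats.threshold_group_medians(
                {k: sums[c][k] for k in keep}, {k: sums[control][k] for k in keep},
                distances, threshold=int(p["distance_threshold"]))
            sp = diststats.switch_point(curves[c], curves[control])
            dist_summary[c] = {"switch_point_bp": sp,
                               "strata": [dataclasses.asdict(g) for g in comps]}
        with open(outdir / "distance_comparisons.json", "w") as fh:
            json.dump(dist_summary, fh, indent=1)
        record(outdir / "distance_comparisons.json")
        if cfg.torsion:
            torsion = coverage.read_bedgraph(cfg.torsion, genome)
            up = diststats.upstream_sum(torsion, proms, window=int(p["torsion_window"]))
            filtered, report = diststats.filter_outliers(up, threshold_sds=p["outlier_sds"])
            pd.DataFrame(report.removed, columns=["promoter_id", "value", "z"]).to_csv(
                outdir / "torsion_outliers.tsv", sep="\t", index=False)
            record(outdir / "torsion_outliers.tsv")
            sig = {k: v for k, v in filtered.items() if k in keep}
            tcurve = diststats.moving_median_curve(
                sig, {k: distances[k] for k in sig}, statistic="mean")
            tcurve.points.to_csv(outdir / "distcurve.torsion.tsv", sep="\t", index=False)
            record(outdir / "distcurve.torsion.tsv")

        stage = "profiles"
        prof_rows = []
        for c in treated_conditions:
            for label, ids in (("all", list(prox[c].rows)),
                               ("divergent", [k for k in prox[c].rows
                                              if orient.get(k) == "divergent"]),
                               ("tandem", [k for k in prox[c].rows
                                           if orient.get(k) == "tandem"])):
                if not ids:
                    continue
                for scale in ("linear", "log2"):
                    fp = profiles.foldchange_profile(prox[c], prox[control], subset=ids,
                                                     scale=scale, subset_label=label)
                    df = fp.to_frame()
                    df.insert(0, "condition", c)
                    prof_rows.append(df)
            if cfg.expression:
                expr = synthetic.read_expression_tsv(cfg.expression)
                quint = profiles.expression_quintiles(expr)
                pd.Series(quint.labels, name="quintile").rename_axis("promoter_id").to_csv(
                    outdir / "quintiles.tsv", sep="\t")
                for fp in profiles.stratified_profiles(prox[c], prox[control], quint, orient):
                    df = fp.to_frame()
                    df.insert(0, "condition", c)
                    prof_rows.append(df)
        if prof_rows:
            pd.concat(prof_rows).to_csv(outdir / "foldchange_profiles.tsv", sep="\t",
                                        index=False)
            record(outdir / "foldchange_profiles.tsv")
        if cfg.expression and (outdir / "quintiles.tsv").exists():
            record(outdir / "quintiles.tsv")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("run complete: %s", outdir / "summary.json")
    return outdir


def demo_synthetic(seed: int = 0, outdir="chromspace_demo", n_promoters: int = 2000,
                   frags_per_condition: int = 60_000) -> Path:
    """Generate a four-condition synthetic dataset and run the full pipeline.

    Conditions emulate a control, a doxorubicin-like treatment (no
    divergent-close effect), an actinomycin-D-like treatment (mild boost)
    and an aclarubicin-like treatment (3x boost at divergent promoters
    closer than 1 kb). Spike counts differ per condition and library sizes
    scale with them, so spike calibration is exercised for real.
    """
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chrom_len = int(n_promoters * 6500 / 2) + 100_000
    genome = synthetic.make_genome(n_chroms=2, chrom_length=chrom_len)
    write_chrom_sizes(genome, inputs / "genome.chrom.sizes")
    proms = synthetic.make_promoter_table(n_promoters, genome, seed=seed)
    spacing.write_promoters_bed(proms, inputs / "promoters.bed")

    boosts = {"control": 1.0, "doxo": 1.0, "actd": 1.5, "acla": 3.0}
    spikes = {"control": 10_000, "doxo": 8_000, "actd": 12_000, "acla": 5_000}
    samples = []
    for i, (cond, boost) in enumerate(boosts.items()):
        effects = synthetic.EffectModel(divergent_close_boost=boost, distance_cutoff=1000,
                                        seed=seed * 13 + i)
        n_total = int(frags_per_condition * spikes[cond] / 10_000)
        frags = synthetic.make_fragments(proms, effects, n_total=n_total,
                                         spike_count=spikes[cond], genome=genome,
                                         sample_id=f"{cond}_1")
        synthetic.write_fragments_bed(frags, inputs / f"{cond}_1.bed")
        synthetic.write_spike_json(frags, inputs / f"{cond}_1.spike.json")
        samples.append({"id": f"{cond}_1", "condition": cond,
                        "fragments": str(inputs / f"{cond}_1.bed"),
                        "spike_count": spikes[cond]})

    expr = synthetic.make_expression(proms, seed=seed + 5)
    synthetic.write_expression_tsv(expr, inputs / "expression.tsv")
    torsion = synthetic.make_torsion_track(proms, close_pair_enrichment=4.0,
                                           seed=seed + 9, genome=genome)
    coverage.write_bedgraph(torsion, inputs / "torsion.bedGraph")

    cfg = RunConfig(samples=samples, control_condition="control",
                    promoters=str(inputs / "promoters.bed"),
                    genome=str(inputs / "genome.chrom.sizes"),
                    expression=str(inputs / "expression.tsv"),
                    torsion=str(inputs / "torsion.bedGraph"),
                    params={"seed": seed})
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    return run_pipeline(cfg, outdir / "run")
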