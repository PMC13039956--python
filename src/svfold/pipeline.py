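"""End-to-end pipeline orchestration.

Stages (simulate -> score -> abc-score -> rdr -> cohort) communicate only
through files in the run directory; a JSON manifest records the config
hash, seeds, and every stage's inputs and outputs so runs are resumable
and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc_weighting, cohort_stats, rdr, sv_io
from .annotation import read_genes_gff3, read_repeats_bed
from .disruption import results_to_frame, score_variant
from .predictor import get_predictor
from .synthetic import SimulationConfig, simulate_study, write_study

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Structured run configuration (YAML-serializable)."""

    seed: int = 0
    outdir: str = "svfold_run"
    predictor: str = "toy"
    metric: str = "mse"
    aggregate: str = "median"
    cutoff_percentile: float = 98.8
    abc_top_fraction: float = 0.10
    rank_shift_threshold: float = 40.0
    simulation: dict = field(default_factory=dict)
    rdr: dict = field(default_factory=dict)

    _KNOWN_PREDICTORS = ("toy", "akita_adapter")

    def __post_init__(self) -> None:
        if self.predictor not in self._KNOWN_PREDICTORS:
            raise ValueError(
                f"config field 'predictor': unknown value {self.predictor!r}"
            )
        if self.metric not in ("mse", "corr", "both"):
            raise ValueError(f"config field 'metric': unknown value {self.metric!r}")
        if self.aggregate not in ("median", "mean"):
            raise ValueError(
                f"config field 'aggregate': unknown value {self.aggregate!r}"
            )
        known = {f.name for f in SimulationConfig.__dataclass_fields__.values()}
        bad = set(self.simulation) - known
        if bad:
            raise ValueError(f"config field 'simulation': unknown keys {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def content_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if not k.startswith("_")}
        payload["simulation"] = dict(sorted(self.simulation.items()))
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class Manifest:
    """Run manifest: config hash, seeds and per-stage artifact paths."""

    def __init__(self, config: PipelineConfig, outdir: Path):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {
                "config_hash": config.content_hash(),
                "seed": config.seed,
                "stages": {},
            }

    def record(self, stage: str, inputs: dict, outputs: dict, **extra) -> None:
        self.data["stages"][stage] = {
            "inputs": {k: str(v) for k, v in inputs.items()},
            "outputs": {k: str(v) for k, v in outputs.items()},
            **extra,
        }
        self.path.write_text(json.dumps(self.data, indent=2, default=str))

    def completed(self, stage: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        return all(Path(p).exists() for p in entry["outputs"].values())

    def output(self, stage: str, key: str) -> Path:
        return Path(self.data["stages"][stage]["outputs"][key])


def _simulation_config(config: PipelineConfig) -> SimulationConfig:
    return SimulationConfig(seed=config.seed, **config.simulation)


def run_simulate(config: PipelineConfig, manifest: Manifest) -> None:
    outdir = Path(config.outdir) / "simulate"
    study = simulate_study(_simulation_config(config))
    paths = write_study(study, outdir)
    manifest.record("simulate", {}, paths)


def _load_genome(fasta_path: Path):
    import pyfaidx

    return pyfaidx.Fasta(str(fasta_path), sequence_always_upper=True)


def _contig_sizes(genome) -> dict[str, int]:
    return {name: len(genome[name]) for name in genome.keys()}


def run_score(config: PipelineConfig, manifest: Manifest) -> None:
    outdir = Path(config.outdir) / "score"
    outdir.mkdir(parents=True, exist_ok=True)
    genome = _load_genome(manifest.output("simulate", "genome"))
    vcf_dir = manifest.output("simulate", "vcf_dir")
    meta = sv_io.read_sample_metadata(manifest.output("simulate", "metadata"))

    all_svs, n_errors = [], 0
    for sample in meta.sample_id:
        errors: list[str] = []
        all_svs.extend(
            sv_io.read_sv_vcf(vcf_dir / f"{sample}.vcf", sample, errors=errors)
        )
        n_errors += len(errors)
    retained, report = sv_io.filter_variants(all_svs)

    pred = get_predictor(config.predictor)
    results, failures = [], 0
    for sv in retained:
        try:
            results.append(
                score_variant(
                    sv, genome, pred,
                    aggregate=config.aggregate, compute_tracks=False,
                )
            )
        except Exception as exc:  # per-variant failures never kill the run
            failures += 1
            log.warning("scoring failed for %s: %s", sv.id, exc)
    scored = results_to_frame(results, retained)

    scored_path = outdir / "scored_variants.tsv"
    scored.to_csv(scored_path, sep="\t", index=False)
    report_path = outdir / "filter_report.tsv"
    pd.DataFrame([report.as_dict()]).to_csv(report_path, sep="\t", index=False)
    manifest.record(
        "score",
        {"vcf_dir": vcf_dir},
        {"scored": scored_path, "filter_report": report_path},
        parse_errors=n_errors,
        scoring_failures=failures,
    )


def run_abc(config: PipelineConfig, manifest: Manifest) -> None:
    outdir = Path(config.outdir) / "abc"
    outdir.mkdir(parents=True, exist_ok=True)
    scored = pd.read_csv(manifest.output("score", "scored"), sep="\t")
    genome = _load_genome(manifest.output("simulate", "genome"))
    elements = abc_weighting.read_elements_bed(
        manifest.output("simulate", "enhancers")
    )
    meta = sv_io.read_sample_metadata(manifest.output("simulate", "metadata"))
    vcf_dir = manifest.output("simulate", "vcf_dir")

    col = f"{'mse' if config.metric == 'both' else config.metric}_{config.aggregate}"
    top_n = max(2, int(np.ceil(len(scored) * config.abc_top_fraction)))
    top = scored.nlargest(top_n, col)

    svs_by_id = {}
    for sample in meta.sample_id:
        for sv in sv_io.read_sv_vcf(vcf_dir / f"{sample}.vcf", sample):
            svs_by_id[sv.id] = sv

    pred = get_predictor(config.predictor)
    rows = []
    for sv_id in top.sv_id:
        sv = svs_by_id[sv_id]
        result = score_variant(sv, genome, pred, aggregate=config.aggregate)
        abc_score, flags = abc_weighting.abc_score_variant(result, elements)
        rows.append({"sv_id": sv_id, "abc_score": abc_score,
                     "flags": ";".join(sorted(flags))})
    abc_df = pd.DataFrame(rows).set_index("sv_id")

    shifts = abc_weighting.rank_shifts(
        top.set_index("sv_id")[col],
        abc_df.abc_score,
        threshold=config.rank_shift_threshold,
    )
    shift_df = abc_weighting.rank_shift_frame(shifts).set_index("sv_id")
    merged = abc_df.join(shift_df)

    abc_path = outdir / "abc_scores.tsv"
    merged.to_csv(abc_path, sep="\t")
    manifest.record("abc", {"scored": manifest.output("score", "scored")},
                    {"abc_scores": abc_path})


def run_rdr(config: PipelineConfig, manifest: Manifest) -> None:
    outdir = Path(config.outdir) / "rdr"
    outdir.mkdir(parents=True, exist_ok=True)
    scored = pd.read_csv(manifest.output("score", "scored"), sep="\t")
    meta = sv_io.read_sample_metadata(manifest.output("simulate", "metadata"))
    genome = _load_genome(manifest.output("simulate", "genome"))

    metric = "mse" if config.metric == "both" else config.metric
    rdr_cfg = rdr.RdrConfig(
        metric=metric, aggregate=config.aggregate,
        cutoff_percentile=config.cutoff_percentile,
        umap_seed=config.seed, **config.rdr,
    )
    calls, table, clustering = rdr.find_rdrs(
        scored, _contig_sizes(genome), meta, rdr_cfg
    )

    calls_path = outdir / "rdr_calls.tsv"
    pd.DataFrame(
        [
            {
                "bin": c.bin_id,
                "n_samples": len(c.samples),
                "samples": ",".join(c.samples),
                "tumor_types": ",".join(c.tumor_types),
                "n_mutated": c.n_mutated,
                "n_disrupted": c.n_disrupted,
                "q_mutated": c.q_mutated,
                "q_disrupted": c.q_disrupted,
                "quality": c.quality,
            }
            for c in calls
        ]
    ).to_csv(calls_path, sep="\t", index=False)
    table_path = outdir / "bin_recurrence.tsv"
    table.to_csv(table_path, sep="\t")
    clusters_path = outdir / "sample_clusters.tsv"
    clustering.embedding.assign(cluster=clustering.labels).to_csv(
        clusters_path, sep="\t"
    )
    manifest.record(
        "rdr",
        {"scored": manifest.output("score", "scored")},
        {"rdr_calls": calls_path, "bin_recurrence": table_path,
         "sample_clusters": clusters_path},
    )


def run_cohort(config: PipelineConfig, manifest: Manifest) -> None:
    outdir = Path(config.outdir) / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    scored = pd.read_csv(manifest.output("score", "scored"), sep="\t")
    meta = sv_io.read_sample_metadata(manifest.output("simulate", "metadata"))
    genes = read_genes_gff3(manifest.output("simulate", "genes"))
    repeats = read_repeats_bed(manifest.output("simulate", "repeats"))
    vcf_dir = manifest.output("simulate", "vcf_dir")

    metric = "corr" if config.metric in ("corr", "both") else "mse"
    metric_col = f"{metric}_{config.aggregate}"
    outputs = {}

    summary = cohort_stats.summarize_categories(scored, meta, metric_col)
    outputs["category_summary"] = outdir / "category_summary.tsv"
    summary.to_csv(outputs["category_summary"], sep="\t")

    prog = cohort_stats.progressive_vs_initial(scored, meta, metric_col,
                                               seed=config.seed)
    outputs["progressive_vs_initial"] = outdir / "progressive_vs_initial.tsv"
    prog.to_csv(outputs["progressive_vs_initial"], sep="\t", index=False)

    cal = cohort_stats.calibrate_cutoff(
        scored.set_index("sv_id")[
            [f"mse_{config.aggregate}", f"corr_{config.aggregate}"]
        ],
        chosen=config.cutoff_percentile,
    )
    outputs["cutoff_grid"] = outdir / "cutoff_grid.tsv"
    cal.thresholds.to_csv(outputs["cutoff_grid"], sep="\t")
    outputs["highly_disruptive"] = outdir / "highly_disruptive.tsv"
    scored[scored.sv_id.isin(cal.selected)].to_csv(
        outputs["highly_disruptive"], sep="\t", index=False
    )

    high = scored[scored.sv_id.isin(cal.selected)]
    pairs = cohort_stats.disrupted_genes(high, genes, meta)
    outputs["disrupted_genes"] = outdir / "disrupted_genes.tsv"
    pairs.to_csv(outputs["disrupted_genes"], sep="\t", index=False)

    all_svs = []
    for sample in meta.sample_id:
        all_svs.extend(sv_io.read_sv_vcf(vcf_dir / f"{sample}.vcf", sample))
    ci = cohort_stats.breakpoint_ci_and_repeats(all_svs, repeats)
    outputs["breakpoint_ci"] = outdir / "breakpoint_ci.tsv"
    ci.to_csv(outputs["breakpoint_ci"], sep="\t", index=False)

    assoc, classed = cohort_stats.score_associations(scored, meta, genes,
                                                     metric_col)
    outputs["associations"] = outdir / "associations.tsv"
    assoc.to_csv(outputs["associations"], sep="\t", index=False)
    outputs["genic_context"] = outdir / "genic_context.tsv"
    classed.to_csv(outputs["genic_context"], sep="\t", index=False)

    manifest.record("cohort", {"scored": manifest.output("score", "scored")},
                    outputs, selection_seed=config.seed)


_STAGES = {
    "simulate": run_simulate,
    "score": run_score,
    "abc": run_abc,
    "rdr": run_rdr,
    "cohort": run_cohort,
}


def run_all(config: PipelineConfig, resume: bool = False) -> Manifest:
    """Execute every stage in order; with ``resume`` completed stages skip."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config, outdir)
    for name, stage in _STAGES.items():
        if resume and manifest.completed(name):
            log.info("stage %s already complete; skipping", name)
            continue
        log.info("running stage %s", name)
        stage(config, manifest)
    return manifest
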