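"""End-to-end orchestration: simulate -> QC -> map -> network -> assign ->
compare, seeded, configured, and logged, with a machine-readable report.

One :class:`RunConfig` describes any number of viromes (each an embedded
:class:`~viromenet.community.CommunityConfig` with its own seed) plus the
analysis thresholds. ``run`` executes the stages in order, writes every
intermediate artifact under the output directory, and returns the report
that is also written as ``report.json``. Identical (config, seed) gives a
byte-identical report: the log is structured (stage, event, counts) and
carries no timestamps, and all randomness flows through named substreams
of the per-virome seeds, so changing comparison settings cannot perturb
simulation draws.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from . import assignment as asg
from . import community as com
from . import compare as cmp
from . import mapping as mpg
from . import network as net
from .fileio import write_fasta, write_fastq
from .taxonomy import TaxonomyTable, default_taxonomy

__all__ = ["RunConfig", "PipelineStageError", "run", "demo_config", "load_run_config"]


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs are preserved in the output dir."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Full pipeline configuration; ``seed`` is mandatory.

    ``viromes`` maps virome name -> CommunityConfig. Thresholds default to
    the analysis constants: QC Q25/150 bp, e-value 0.001, coverage
    spotlight 1000x, no edge-weight threshold (min_pairs 1).
    """

    seed: int
    viromes: dict[str, com.CommunityConfig]
    outdir: str = "viromenet_run"
    qc_min_quality: int = 25
    qc_min_length: int = 150
    qc_window: int = 4
    contaminant_screen: bool = True
    min_pairs: int = 1
    coverage_threshold: float = 1000.0
    e_max: float = 0.001
    hit_detection_rate: float = 0.4  # 0.6 dropout of contigs to "unknown"
    hit_noise_rate: float = 0.0
    marker_keywords: tuple[str, ...] = ("integrase",)
    rank: str = "species"
    linkage: str = "complete"

    def __post_init__(self) -> None:
        if not self.viromes:
            raise ValueError("at least one virome is required")
        for name, t in [
            ("coverage_threshold", self.coverage_threshold),
            ("e_max", self.e_max),
            ("min_pairs", self.min_pairs),
            ("qc_min_quality", self.qc_min_quality),
            ("qc_min_length", self.qc_min_length),
        ]:
            if t <= 0:
                raise ValueError(f"{name} must be positive")


def demo_config(seed: int, outdir: str = "viromenet_run", **overrides) -> RunConfig:
    """The default two-virome demonstration configuration: 2 viromes of 20
    genomes with 50,000 read pairs each, hit-table dropout 0.6."""
    viromes = {
        f"virome{i + 1}": com.CommunityConfig(seed=(seed * 1000 + i) % (2**31))
        for i in range(2)
    }
    return RunConfig(seed=seed, viromes=viromes, outdir=outdir, **overrides)


def load_run_config(path: str) -> RunConfig:
    """Read a RunConfig from YAML/JSON; virome entries are CommunityConfig
    field mappings."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    viromes = {
        name: com.CommunityConfig(**fields) for name, fields in doc.pop("viromes").items()
    }
    return RunConfig(viromes=viromes, **doc)


class _RunLog:
    def __init__(self, path: str):
        self.path = path
        self.lines: list[str] = []

    def event(self, stage: str, event: str, **counts) -> None:
        parts = [f"stage={stage}", f"event={event}"]
        parts += [f"{k}={v}" for k, v in sorted(counts.items())]
        self.lines.append(" ".join(parts))

    def flush(self) -> None:
        with open(self.path, "w") as fh:
            fh.write("\n".join(self.lines) + "\n")


def _write_json(doc: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _run_virome(
    name: str,
    cconf: com.CommunityConfig,
    config: RunConfig,
    taxonomy: TaxonomyTable,
    vdir: str,
    log: _RunLog,
) -> dict:
    os.makedirs(vdir, exist_ok=True)

    stage = "simulate"
    try:
        if cconf.n_read_pairs == 0:
            raise ValueError("n_read_pairs must be positive for a pipeline run")
        specs, seqs, contigs, truth, reads1, reads2 = com.simulate_community(cconf, taxonomy)
        write_fasta(seqs, os.path.join(vdir, "genomes.fasta"))
        write_fasta(contigs, os.path.join(vdir, "contigs.fasta"))
        write_fastq(reads1, os.path.join(vdir, "reads_1.fastq"))
        write_fastq(reads2, os.path.join(vdir, "reads_2.fastq"))
        truth.contigs.to_csv(os.path.join(vdir, "truth_contigs.tsv"), sep="\t", index=False)
        truth.reads.to_csv(os.path.join(vdir, "truth_reads.tsv"), sep="\t", index=False)
        log.event(stage, "community", virome=name, n_genomes=len(specs),
                  n_contigs=len(contigs), n_pairs=len(reads1))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError(stage, exc) from exc

    stage = "qc"
    try:
        q1, q2, qc_report = mpg.qc_reads(
            reads1, reads2,
            min_quality=config.qc_min_quality,
            min_length=config.qc_min_length,
            window=config.qc_window,
        )
        n_removed = 0
        if config.contaminant_screen:
            q1, q2, n_removed = mpg.screen_contaminants(q1, q2, com.pseudo_phix())
        qc_report["n_pairs_contaminant_removed"] = n_removed
        write_fastq(q1, os.path.join(vdir, "reads_qc_1.fastq"))
        write_fastq(q2, os.path.join(vdir, "reads_qc_2.fastq"))
        _write_json(qc_report, os.path.join(vdir, "qc_report.json"))
        log.event(stage, "filtered", virome=name, kept=len(q1), contaminant=n_removed)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "map"
    try:
        result = mpg.map_reads_exact((q1, q2), contigs, mode="paired")
        coverage = mpg.compute_coverage(result, contigs)
        mpg.export_mapping(result, os.path.join(vdir, "mapping.tsv"))
        with open(os.path.join(vdir, "coverage.tsv"), "w") as fh:
            fh.write("contig_id\tcoverage\n")
            for cid in sorted(coverage):
                fh.write(f"{cid}\t{coverage[cid]:.6g}\n")
        log.event(stage, "mapped", virome=name, total=result.n_reads_total,
                  mapped=result.n_reads_mapped)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "network"
    try:
        graph = net.build_graph(result, contigs, coverage, min_pairs=config.min_pairs)
        partition = net.extract_networks(graph)
        flagged, stats = net.flag_high_coverage(partition, threshold=config.coverage_threshold)
        net.export_cytoscape(graph, partition, os.path.join(vdir, "cytoscape"))
        net.partition_to_json(partition, os.path.join(vdir, "networks.json"))
        log.event(stage, "components", virome=name, networks=len(partition.networks),
                  singletons=len(partition.singletons), flagged=len(flagged))
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "assign"
    try:
        hit_frame = com.simulate_hits(
            truth.contigs, specs, taxonomy,
            detection_rate=config.hit_detection_rate,
            noise_rate=config.hit_noise_rate,
            seed=cconf.seed,
        )
        hits_path = os.path.join(vdir, "hits.tsv")
        asg.write_hits(hit_frame, hits_path)
        hits, rejects = asg.read_hits(hits_path, taxonomy, e_max=config.e_max)
        annotations = asg.assign_contigs(hits, taxonomy, contig_ids=contigs.keys())
        net_assign = asg.assign_networks(partition, annotations, taxonomy, hits=hits)
        annotations, gain = asg.propagate(partition, annotations, net_assign)
        markers = {kw: asg.tally_marker(hits, kw) for kw in config.marker_keywords}
        summary = asg.network_summary(partition, net_assign, taxonomy)
        summary = summary.merge(stats[["network_id", "flagged"]], on="network_id")
        summary.to_csv(os.path.join(vdir, "network_summary.tsv"), sep="\t", index=False)
        with open(os.path.join(vdir, "annotations.tsv"), "w") as fh:
            fh.write("contig_id\ttaxon_id\tprovenance\n")
            for cid in sorted(annotations):
                a = annotations[cid]
                fh.write(f"{cid}\t{a.taxon_id}\t{a.provenance}\n")
        log.event(stage, "annotated", virome=name, hits=len(hits), rejects=len(rejects),
                  unknown_before=gain["unknown_before"], unknown_after=gain["unknown_after"])
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    return {
        "reads": {
            "n_pairs_total": len(reads1),
            "n_pairs_post_qc": len(q1),
            "n_mates_mapped": result.n_reads_mapped,
            "n_mates_total": result.n_reads_total,
            "self_mapped_fraction": mpg.mapped_fraction(result),
        },
        "contigs": {"n_contigs": len(contigs), "n_genomes": len(specs)},
        "networks": {
            "n_networks": len(partition.networks),
            "n_singletons": len(partition.singletons),
            "n_flagged": len(flagged),
            "flagged_ids": flagged,
            "summary": summary.to_dict(orient="records"),
        },
        "annotation": {
            "gain": gain,
            "marker_tallies": markers,
            "lca_above_family": asg.lca_diagnostics(net_assign, taxonomy),
        },
        "_internal": {
            "reads_qc": (q1, q2),
            "contigs": contigs,
            "annotations": annotations,
        },
    }


def run(config: RunConfig, taxonomy: TaxonomyTable | None = None) -> dict:
    """Execute the full pipeline; returns the report dict (also written as
    ``report.json`` in ``config.outdir``)."""
    taxonomy = taxonomy or default_taxonomy()
    os.makedirs(config.outdir, exist_ok=True)
    log = _RunLog(os.path.join(config.outdir, "run.log"))
    per_virome: dict[str, dict] = {}
    internal: dict[str, dict] = {}
    for name, cconf in config.viromes.items():
        vdir = os.path.join(config.outdir, name)
        vreport = _run_virome(name, cconf, config, taxonomy, vdir, log)
        internal[name] = vreport.pop("_internal")
        per_virome[name] = vreport

    stage = "compare"
    try:
        read_sets = {
            name: internal[name]["reads_qc"][0] + internal[name]["reads_qc"][1]
            for name in config.viromes
        }
        contig_sets = {name: internal[name]["contigs"] for name in config.viromes}
        cross = cmp.cross_mapping_matrix(read_sets, contig_sets)
        cross.to_csv(os.path.join(config.outdir, "cross_mapping.tsv"), sep="\t")

        profiles = cmp.presence_absence(
            {name: internal[name]["annotations"] for name in config.viromes},
            taxonomy,
            rank=config.rank,
        )
        cmp.profiles_to_frame(profiles).to_csv(
            os.path.join(config.outdir, "profiles.tsv"), sep="\t", index=False
        )
        dissim = cmp.bray_curtis(profiles)
        dissim.to_frame().to_csv(os.path.join(config.outdir, "bray_curtis.tsv"), sep="\t")
        newick, merges = cmp.cluster_viromes(dissim, linkage=config.linkage)
        with open(os.path.join(config.outdir, "dendrogram.nwk"), "w") as fh:
            fh.write(newick + "\n")
        log.event(stage, "compared", viromes=len(config.viromes))
    except Exception as exc:
        log.flush()
        raise PipelineStageError(stage, exc) from exc

    report = {
        "config": {
            "seed": config.seed,
            "coverage_threshold": config.coverage_threshold,
            "e_max": config.e_max,
            "min_pairs": config.min_pairs,
            "rank": config.rank,
            "linkage": config.linkage,
            "viromes": {
                name: dataclasses.asdict(cconf) for name, cconf in config.viromes.items()
            },
        },
        "viromes": per_virome,
        "cross_virome": {
            "mapped_fraction_matrix": {
                r: {c: (None if cross.isna().loc[r, c] else float(cross.loc[r, c]))
                    for c in cross.columns}
                for r in cross.index
            },
            "bray_curtis": {
                a: {b: float(dissim.to_frame().loc[a, b]) for b in dissim.ids}
                for a in dissim.ids
            },
            "dendrogram_newick": newick,
            "merges": [
                {"height": m["height"], "members": m["members"]} for m in merges
            ],
        },
    }
    _write_json(report, os.path.join(config.outdir, "report.json"))
    log.flush()
    return report
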