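"""End-to-end orchestration: simulate (optional) -> process -> profile ->
enrich -> network, with a JSON run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment as enr
from . import network as net
from . import processing as proc
from .synthetic import (
    GroundTruth,
    LibraryDesign,
    PlantedEnrichment,
    SimulationConfig,
    generate_peptide_pool,
    synthesize_reads,
)


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    ``tissue_fastqs`` maps sample labels to FASTQ paths; ``library_label`` (and
    optionally ``serum_label``) name the normalizing samples among them.  When
    ``simulate`` is set, inputs are generated first and ``tissue_fastqs`` is
    filled in automatically.
    """

    outdir: str = "phagescape_run"
    tissue_fastqs: dict[str, str] = field(default_factory=dict)
    library_label: str = "library"
    serum_label: str | None = None
    normalization_scheme: str = "library"
    q_min: int = proc.DEFAULT_Q_MIN
    max_mismatch: int = proc.DEFAULT_MAX_MISMATCH
    alpha: float = enr.DEFAULT_ALPHA
    min_fold: float = enr.DEFAULT_MIN_FOLD
    heatmap_min_frequency: float = enr.DEFAULT_MIN_FREQUENCY_PCT
    min_edge_weight: int = net.DEFAULT_MIN_EDGE_WEIGHT
    weighting: str = "unique_peptide"
    seed: int = 7
    simulate: bool = False
    simulation: SimulationConfig | None = None
    planted: list[PlantedEnrichment] = field(default_factory=list)

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_inputs(config: PipelineConfig, outdir: Path) -> dict[str, str]:
    sim = config.simulation or SimulationConfig(seed=config.seed)
    design = LibraryDesign()
    truth = generate_peptide_pool(sim, config.planted)
    fastqs = synthesize_reads(truth, design, sim, outdir / "fastq")
    # the unselected library sample is an independent draw from the same
    # residue composition, sequenced like any tissue
    lib_sim = dataclasses.replace(sim, n_tissues=1, seed=sim.seed + 1)
    lib_truth = generate_peptide_pool(lib_sim, ())
    lib_fastq = synthesize_reads(lib_truth, design, lib_sim, outdir / "fastq_library")
    mapping = {tissue: str(p) for tissue, p in fastqs.items()}
    mapping[config.library_label] = str(lib_fastq["tissue_1"])
    return mapping


def run_all(config: PipelineConfig) -> dict:
    """Execute the full workflow and return a result bundle.

    Deterministic given the seed and inputs; each stage's record counts are
    written to ``manifest.json`` along with a config hash and per-file
    checksums.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        config.tissue_fastqs = _simulate_inputs(config, outdir)
    if not config.tissue_fastqs:
        raise ValueError("no input FASTQ files configured")
    if config.normalization_scheme == "library" and config.library_label not in config.tissue_fastqs:
        raise ValueError(f"library sample {config.library_label!r} not among inputs")
    if config.normalization_scheme == "serum" and config.serum_label not in config.tissue_fastqs:
        raise ValueError("serum normalization requested but no serum sample configured")

    design = LibraryDesign()
    peptides: dict[str, list[proc.PeptideRecord]] = {}
    stage_counts: dict[str, dict] = {}
    outputs: list[Path] = []
    proc_dir = outdir / "peptides"
    proc_dir.mkdir(exist_ok=True)
    for label, fastq in sorted(config.tissue_fastqs.items()):
        recs, stats = proc.process_fastq(
            fastq, design, q_min=config.q_min, max_mismatch=config.max_mismatch
        )
        peptides[label] = recs
        tsv = proc_dir / f"{label}.peptides.tsv"
        proc.write_peptides_tsv(recs, tsv)
        stats_path = proc_dir / f"{label}.stats.json"
        stats.to_json(stats_path)
        outputs += [tsv, stats_path]
        stage_counts[label] = {
            "reads_in": stats.reads_in,
            "reads_passed": stats.passed,
            "unique_peptides": len(recs),
        }

    normalizer_labels = {config.library_label, config.serum_label}
    tissue_labels = [t for t in sorted(peptides) if t not in normalizer_labels]

    tables = {
        label: enr.count_motifs(recs, config.weighting, tissue_id=label)
        for label, recs in peptides.items()
        if recs
    }
    profiles = [enr.motif_frequencies(t) for t in tables.values()]
    profile_dir = outdir / "motifs"
    profile_dir.mkdir(exist_ok=True)
    freq_df = pd.DataFrame({p.tissue_id: p.frequencies for p in profiles}).fillna(0.0)
    freq_path = profile_dir / "motif_frequencies_pct.tsv"
    freq_df.to_csv(freq_path, sep="\t")
    outputs.append(freq_path)
    if len(profiles) >= 2:
        clustered = enr.cluster_profiles(profiles, config.heatmap_min_frequency)
        clus_path = profile_dir / "clustered_matrix.tsv"
        clustered.matrix.to_csv(clus_path, sep="\t")
        outputs.append(clus_path)

    enrich_dir = outdir / "enrichment"
    enrich_dir.mkdir(exist_ok=True)
    net_dir = outdir / "networks"
    net_dir.mkdir(exist_ok=True)
    selective_sets: dict[str, set[str]] = {}
    for tissue in tissue_labels:
        if tissue not in tables:
            continue
        if config.normalization_scheme == "library":
            norm_table = tables[config.library_label]
        elif config.normalization_scheme == "serum":
            norm_table = tables[config.serum_label]
        else:
            others = [
                tables[t]
                for t in tissue_labels
                if t != tissue and t in tables
            ]
            norm_table = enr.pool_counts(others)
        results = enr.fisher_enrichment(
            tables[tissue], norm_table, config.normalization_scheme
        )
        results = enr.adjust_and_flag(results, config.alpha, config.min_fold)
        res_path = enrich_dir / f"{tissue}.enrichment.tsv"
        results.to_csv(res_path, sep="\t", index=False)
        outputs.append(res_path)
        selective, volcano = enr.select_tissue_selective(
            results, config.alpha, config.min_fold
        )
        volcano_path = enrich_dir / f"{tissue}.volcano.tsv"
        volcano.to_csv(volcano_path, sep="\t", index=False)
        outputs.append(volcano_path)
        selective_sets[tissue] = selective
        stage_counts[tissue]["motifs_tested"] = len(results)
        stage_counts[tissue]["motifs_selective"] = len(selective)

        if selective:
            graph = net.build_network(peptides[tissue], selective)
            filtered = net.filter_edges(graph, config.min_edge_weight)
            net.classify_components(filtered)
            g_path = net.export_network(filtered, net_dir / f"{tissue}.graphml")
            edges_path = net_dir / f"{tissue}.edges.tsv"
            net.edge_table(graph).to_csv(edges_path, sep="\t", index=False)
            nodes_path = net_dir / f"{tissue}.nodes.tsv"
            net.node_table(filtered).to_csv(nodes_path, sep="\t", index=False)
            outputs += [g_path, edges_path, nodes_path]

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_counts": stage_counts,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "peptides": peptides,
        "selective": selective_sets,
        "stage_counts": stage_counts,
        "manifest": manifest,
        "manifest_path": manifest_path,
    }
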