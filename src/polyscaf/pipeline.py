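"""End-to-end pipeline: assign -> build -> qc -> (optional) evaluate.

Every run echoes its resolved configuration and the tool version into the
output directory; reruns with the same configuration are byte-identical for
all deterministic stages (which is all of them — the only randomness is the
seeded mixture initialisation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as pio
from .assign import assign_subgenomes, count_intra_cluster_edges
from .build import build_agp, build_chromosomes
from .errors import PolyscafError
from .evaluate import evaluate_assignment, evaluate_order
from .params import PipelineConfig
from .qc import find_tandem_centromere, find_telomeres, subgenome_specific_kmers

log = logging.getLogger(__name__)


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(
    contigs_path: str | Path,
    diploid_paths: list[str | Path],
    pairs_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig,
    truth_path: str | Path | None = None,
) -> dict:
    """Run the full scaffolding pipeline and write all outputs.

    Returns a summary dict (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = _stage("load")
    contigs = pio.read_sequences(contigs_path)
    references = [pio.read_sequences(p) for p in diploid_paths]
    pairs = pio.read_pairs(pairs_path, contigs)
    timings["load"] = time.perf_counter() - t0

    t0 = _stage("assign")
    assignment, extras = assign_subgenomes(contigs, references, pairs, config)
    timings["assign"] = time.perf_counter() - t0
    out_assign = assignment.copy()
    out_assign["label"] = out_assign["label"].map(
        lambda l: "unassigned" if l == 0 else str(l))
    pio.write_assignment(out_assign, out / "assignment.tsv")

    t0 = _stage("build")
    build = build_chromosomes(contigs, assignment, references[0], pairs, config)
    agp_rows, scaffolds = build_agp(build, contigs, config.gap_size)
    timings["build"] = time.perf_counter() - t0
    pio.write_agp(agp_rows, out / "scaffolds.agp")
    pio.write_fasta(scaffolds, out / "scaffolds.fasta")
    unplaced = {c: contigs[c] for c in sorted(set(build.unplaced))}
    if unplaced:
        pio.write_fasta(unplaced, out / "unplaced.fasta")
    build.to_frame().to_csv(out / "ordering.tsv", sep="\t", index=False)

    t0 = _stage("qc")
    by_sg: dict[int, dict[str, str]] = {}
    for (sg, group), _entries in build.groups.items():
        by_sg.setdefault(sg, {})[f"sg{sg}_{group}"] = scaffolds[f"sg{sg}_{group}"]
    kmer_report = None
    if len(by_sg) >= 2:
        kmer_report = subgenome_specific_kmers(
            by_sg, config.k_val, config.enrichment_ratio)
        kmer_report.informative_counts.to_csv(
            out / "informative_kmers.tsv", sep="\t")
    feature_rows = []
    for name, seq in scaffolds.items():
        arrays = find_tandem_centromere(
            seq, config.centromere_unit, config.centromere_min_copies,
            config.centromere_min_identity)
        if arrays:
            a = arrays[0]
            feature_rows.append({"chromosome": name, "feature": "centromere",
                                 "start": a.start, "end": a.end,
                                 "copies": int(a.copies)})
        tel = find_telomeres(seq, config.telomere_monomer,
                             config.telomere_end_window, config.telomere_min_copies)
        for end, call in tel.items():
            if call.present:
                feature_rows.append({
                    "chromosome": name,
                    "feature": f"telomere{'5' if end == '5p' else '3'}",
                    "start": 0 if end == "5p" else len(seq) - config.telomere_end_window,
                    "end": config.telomere_end_window if end == "5p" else len(seq),
                    "copies": call.copies})
    pio.write_features(
        pd.DataFrame(feature_rows, columns=pio.FEATURE_COLUMNS),
        out / "feature_calls.tsv")
    timings["qc"] = time.perf_counter() - t0

    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_contigs": len(contigs),
        "n_pairs": int(len(pairs)),
        "n_assigned": int((assignment["label"] != 0).sum()),
        "n_allelic_edges": len(extras["graph"]),
        "intra_cluster_allelic_edges": count_intra_cluster_edges(
            assignment, extras["graph"]),
        "stage_changes": extras["changes"],
        "n_scaffolds": len(scaffolds),
        "n_unplaced": len(set(build.unplaced)),
        "kmer_partition_matches_subgenomes": (
            bool(kmer_report.matches_subgenomes) if kmer_report else None),
    }

    if truth_path is not None:
        t0 = _stage("evaluate")
        truth = pio.read_truth(truth_path)
        ae = evaluate_assignment(assignment, truth)
        oe = evaluate_order(build, truth)
        summary["evaluation"] = {
            "base_weighted_accuracy": ae.base_weighted_accuracy,
            "count_weighted_accuracy": ae.count_weighted_accuracy,
            "unassigned_rate": ae.unassigned_rate,
            "purity": {str(k): v for k, v in ae.purity.items()},
            "per_chromosome_tau": oe.per_chromosome_tau,
            "adjacency_accuracy": oe.adjacency_accuracy,
            "orientation_accuracy": oe.orientation_accuracy,
            "anchoring_rate": oe.anchoring_rate,
        }
        timings["evaluate"] = time.perf_counter() - t0
        with open(out / "evaluation.json", "w") as fh:
            json.dump(summary["evaluation"], fh, indent=2, sort_keys=True)

    summary["timings_sec"] = {k: round(v, 3) for k, v in timings.items()}
    pio.dump_config(
        {"pipeline": config.to_dict(), "version": __version__,
         "inputs": {"contigs": str(contigs_path),
                    "diploid": [str(p) for p in diploid_paths],
                    "pairs": str(pairs_path),
                    "truth": str(truth_path) if truth_path else None}},
        out / "config.yaml")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
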