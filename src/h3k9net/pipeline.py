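"""End-to-end orchestration: filter -> sets -> validation -> network -> mimicry -> enrichment.

``run_pipeline`` consumes a bundle of in-memory inputs (the synthetic
generator's output, or the same objects loaded from files), writes every
intermediate table to the output directory, and returns a summary dict whose
every number is recomputable from those intermediates. A plain-text log
records records-in/records-out for each filtering stage.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as nio
from .config import (
    NUCLEUS_TERM,
    READERS,
    WRITERS,
    FilterConfig,
    NetworkConfig,
)
from .enrichment import overrepresentation
from .ipms import SpectralCountTable, classify_hits, qc_enrichment_ratio, reason_tallies
from .mimicry import (
    DEFAULT_PRESET,
    PRESETS,
    evidence_crosscheck,
    motif_to_pattern,
    phase_split,
    scan_proteome,
    tier_screen,
)
from .network import degree_statistics, filter_edges_by_score, induce_graph, pair_overlap_edge_share
from .sets import (
    InteractomeCollection,
    hits_to_sets,
    phase_overlap,
    phase_switchers,
    shared_by_at_least,
    venn_partition,
)
from .validation import expression_validate, filter_by_term


@dataclass
class PipelineConfig:
    """Knobs for a full pipeline run; every threshold is surfaced here."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    motif_preset: str = DEFAULT_PRESET
    nucleus_term: str = NUCLEUS_TERM
    min_complex_size: int = 4
    alpha: float = 0.05
    hub_fraction: float = 0.024  # top-hub subset size as a fraction of the partition
    percent_digits: int = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


def load_inputs(indir: str | Path) -> dict:
    """Load a pipeline input bundle from a directory of standard files."""
    indir = Path(indir)
    bundle = {
        "counts": nio.read_counts(indir / "counts.tsv"),
        "sequences": nio.read_fasta(indir / "proteome.fasta"),
        "annotation": nio.read_annotation(indir / "annotation.tsv"),
        "expression": nio.read_table(indir / "expression.tsv"),
        "edges": nio.read_table(indir / "edges.tsv"),
        "complexes": nio.read_complexes(indir / "complexes.tsv"),
    }
    sites = indir / "known_sites.tsv"
    bundle["known_sites"] = (
        nio.read_table(sites)
        if sites.exists()
        else pd.DataFrame(columns=["protein", "position", "modification"])
    )
    return bundle


def write_inputs(bundle: Mapping, outdir: str | Path) -> None:
    """Write a (synthetic) input bundle to a directory, ground truth included."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nio.write_counts(bundle["counts"], outdir / "counts.tsv")
    nio.write_fasta(bundle["sequences"], outdir / "proteome.fasta")
    nio.write_annotation(bundle["annotation"], outdir / "annotation.tsv")
    nio.write_table(bundle["expression"], outdir / "expression.tsv")
    nio.write_table(bundle["edges"], outdir / "edges.tsv")
    nio.write_complexes(bundle["complexes"], outdir / "complexes.tsv")
    nio.write_table(bundle["known_sites"], outdir / "known_sites.tsv")
    truth = bundle.get("truth")
    if truth is not None:
        nio.write_protein_sets(truth.true_interactors, outdir / "truth_interactors.tsv")
        nio.write_table(
            pd.DataFrame(
                [
                    (p, pos)
                    for p in sorted(truth.planted_motifs)
                    for pos in truth.planted_motifs[p]
                ],
                columns=["protein", "k_position"],
            ),
            outdir / "truth_motifs.tsv",
        )
        nio.write_table(
            pd.DataFrame(
                sorted(
                    [(p, "contaminant") for p in truth.contaminants]
                    + [(p, "noise") for p in truth.noise]
                ),
                columns=["protein", "category"],
            ),
            outdir / "truth_categories.tsv",
        )


def _pct(k: int, n: int, digits: int) -> float:
    return round(100.0 * k / n, digits) if n else 0.0


def run_pipeline(bundle: Mapping, outdir: str | Path, config: PipelineConfig | None = None) -> dict:
    """Execute every stage, write intermediates, and return the summary."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    summary: dict = {}

    # -- stage 1: spectral-count filtering --------------------------------
    counts: SpectralCountTable = bundle["counts"]
    try:
        hits = classify_hits(counts, config.filter)
    except Exception as exc:
        raise PipelineError(f"ipms_filter: {exc}") from exc
    nio.write_table(hits, outdir / "hits.tsv")
    tallies = reason_tallies(hits)
    log.append(
        f"ipms_filter: records_in={len(hits)} true_hits={tallies['hit']} "
        + " ".join(f"{r}={tallies[r]}" for r in ("low_enrichment", "low_fold_change", "contaminant"))
    )
    summary["records_classified"] = len(hits)
    summary["true_hits"] = int(tallies["hit"])
    for bait in counts.baits:
        for phase in counts.phases:
            before, after = qc_enrichment_ratio(counts, hits, bait, phase, config.filter.pseudocount)
            summary[f"qc_ratio_{bait}_{phase}"] = {"before": round(before, 3), "after": round(after, 3)}

    # -- stage 2: interactome set algebra ---------------------------------
    collection = hits_to_sets(hits)
    nio.write_protein_sets(collection.sets, outdir / "interactomes.tsv")
    collection.membership_matrix().rename_axis("protein").to_csv(
        outdir / "membership_matrix.tsv", sep="\t"
    )
    bait_sets = {b: collection.bait_union(b) for b in collection.baits}
    venn = venn_partition(bait_sets)
    nio.write_table(venn.to_frame(), outdir / "venn_cellular.tsv")
    summary["interactome_sizes"] = {b: len(s) for b, s in bait_sets.items()}
    summary["total_unique_proteins"] = len(collection.union())
    shared2 = shared_by_at_least(collection, 2)
    summary["shared_by_2"] = len(shared2)
    summary["shared_by_2_pct"] = _pct(len(shared2), len(collection.union()), 2)
    overlaps = []
    phases = collection.phases
    if len(phases) == 2:
        for bait in collection.baits:
            ov = phase_overlap(collection, bait, phases)  # type: ignore[arg-type]
            pct = ov.percentages(config.percent_digits)
            overlaps.append(
                (bait, len(ov.both), len(ov.only_g1s), len(ov.only_g2m), ov.total, *pct)
            )
        nio.write_table(
            pd.DataFrame(
                overlaps,
                columns=[
                    "bait", "both", "only_g1s", "only_g2m", "total",
                    "pct_both", "pct_only_g1s", "pct_only_g2m",
                ],
            ),
            outdir / "phase_overlap.tsv",
        )
        summary["phase_overlap"] = {
            row[0]: {"both": row[1], "only_g1s": row[2], "only_g2m": row[3], "total": row[4]}
            for row in overlaps
        }
        switchers = phase_switchers(collection, phases)  # type: ignore[arg-type]
        summary["phase_switchers"] = len(switchers)
    log.append(f"interactome_sets: baits={len(bait_sets)} union={len(collection.union())}")

    # -- stage 3: nuclear + expression validation -------------------------
    annotation = bundle["annotation"]
    expression = bundle["expression"]
    cellular = collection.union()
    nuclear_retained, nuclear_removed = filter_by_term(cellular, annotation, config.nucleus_term)
    summary["nuclear"] = len(nuclear_retained)
    summary["non_nuclear"] = len(nuclear_removed)
    summary["nuclear_pct"] = _pct(len(nuclear_retained), len(cellular), 0)
    nuclear_collection = collection.restrict(nuclear_retained)
    validated_sets = {}
    removed_by_expression = set()
    for (bait, phase), members in nuclear_collection.sets.items():
        validated, removed = expression_validate(members, expression, phase)
        validated_sets[(bait, phase)] = validated
        removed_by_expression.update(removed)
    validated_collection = InteractomeCollection(validated_sets)
    nio.write_protein_sets(validated_collection.sets, outdir / "validated_interactomes.tsv")
    summary["expression_removed"] = len(removed_by_expression)
    summary["validated_nuclear_union"] = len(validated_collection.union())
    if len(phases) == 2:
        summary["validated_shared_by_2"] = len(shared_by_at_least(validated_collection, 2))
        both_phases = validated_collection.phase_union(phases[0]) & validated_collection.phase_union(phases[1])
        summary["validated_in_both_phases"] = len(both_phases)
    log.append(
        f"nuclear_validation: in={len(cellular)} nuclear={len(nuclear_retained)} "
        f"expression_removed={len(removed_by_expression)} "
        f"validated={len(validated_collection.union())}"
    )

    # -- stage 4: physical network statistics ------------------------------
    edges = filter_edges_by_score(
        bundle["edges"], config.network.min_confidence, config.network.unscored
    )
    graph = induce_graph(edges, cellular)
    nio.write_table(nio.graph_to_edge_frame(graph), outdir / "induced_edges.tsv")
    nio.write_graphml(graph, outdir / "induced_network.graphml")
    stats = degree_statistics(graph, nuclear_retained)
    nio.write_table(stats, outdir / "degree_statistics.tsv")
    summary["network_edges"] = graph.number_of_edges()
    summary["mean_degree"] = {
        row.partition: round(float(row.mean_degree), 2)
        for row in stats.itertuples(index=False)
        if row.nodes
    }
    part_a = sorted(set(nuclear_retained) & set(graph.nodes))
    part_b = sorted(set(graph.nodes) - set(nuclear_retained))
    if part_a and part_b:
        from .network import hub_coverage

        k = max(1, round(config.hub_fraction * len(part_a)))
        top, frac = hub_coverage(graph, part_a, part_b, k)
        summary["hub_coverage"] = {"k": k, "fraction": round(frac, 3)}
    if len(phases) == 2:
        pair_rows = []
        for phase in phases:
            phase_graph = induce_graph(edges, validated_collection.phase_union(phase))
            for w in WRITERS:
                for r in READERS:
                    if (w, phase) in validated_collection.sets and (r, phase) in validated_collection.sets:
                        touched, total = pair_overlap_edge_share(
                            phase_graph, validated_collection, (w, r), phase
                        )
                        pair_rows.append((phase, w, r, touched, total))
        nio.write_table(
            pd.DataFrame(pair_rows, columns=["phase", "writer", "reader", "edges_touched", "total_edges"]),
            outdir / "pair_edge_share.tsv",
        )
    log.append(f"network_analysis: edges_kept={len(edges)} induced_edges={graph.number_of_edges()}")

    # -- stage 5: histone-mimicry SLiM screen ------------------------------
    motif = PRESETS[config.motif_preset]
    (outdir / "motif_pattern.txt").write_text(motif_to_pattern(motif) + "\n")
    motif_hits, motif_proteins = scan_proteome(bundle["sequences"], motif)
    nio.write_table(motif_hits, outdir / "motif_hits.tsv")
    writer_slice = InteractomeCollection(
        {k: v for k, v in validated_collection.sets.items() if k[0] in WRITERS}
    )
    reader_slice = InteractomeCollection(
        {k: v for k, v in collection.sets.items() if k[0] in READERS}
    )
    mimicry = tier_screen(motif_hits, writer_slice, reader_slice)
    mimicry = evidence_crosscheck(mimicry, bundle["known_sites"])
    nio.write_table(mimicry, outdir / "mimicry.tsv")
    tier1 = set(mimicry.loc[mimicry["tier1"], "protein"])
    tier2 = set(mimicry.loc[mimicry["tier2"], "protein"])
    summary["motif_proteins"] = len(motif_proteins)
    summary["tier1_candidates"] = len(tier1)
    summary["tier2_candidates"] = len(tier2)
    summary["evidence_flagged"] = int(mimicry.loc[mimicry["tier2"], "evidence"].sum())
    if len(phases) == 2:
        summary["mimicry_phase_split"] = phase_split(mimicry, phases)  # type: ignore[arg-type]
    log.append(
        f"slim_mimicry: motif_proteins={len(motif_proteins)} tier1={len(tier1)} tier2={len(tier2)}"
    )

    # -- stage 6: complex over-representation ------------------------------
    catalog = bundle["complexes"]
    universe = set().union(*catalog.values()) | tier2 if catalog else set(tier2)
    if tier2 and catalog:
        result = overrepresentation(
            tier2, catalog, universe, min_size=config.min_complex_size, alpha=config.alpha
        )
    else:
        result = overrepresentation(set(), catalog, universe or {"_"},
                                    min_size=config.min_complex_size, alpha=config.alpha)
    nio.write_table(result, outdir / "enrichment.tsv")
    summary["complexes_tested"] = len(result)
    summary["complexes_significant"] = int(result["significant"].sum()) if len(result) else 0
    log.append(
        f"enrichment: tested={summary['complexes_tested']} "
        f"significant={summary['complexes_significant']}"
    )

    (outdir / "pipeline.log").write_text("\n".join(log) + "\n")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
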