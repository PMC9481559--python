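"""End-to-end pipeline: generate -> off-target -> hybrid -> crosstalk ->
select -> construct, with deterministic file outputs per stage."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import networkx as nx

from . import construct as construct_mod
from . import crosstalk as crosstalk_mod
from .config import PipelineConfig
from .io import SequenceRecord, read_fasta, transcribe, write_fasta, write_report
from .offtarget import (
    filter_by_offtarget_score,
    find_offtarget_hits,
    score_guide,
    write_hits_bed,
    write_hits_tsv,
)
from .pool import (
    CandidateSequence,
    assemble_repeat_spacer,
    evaluate_constraints,
    generate_pool,
)
from .select import maximum_independent_set, write_selection_tsv
from .thermo import filter_by_hybrid_energy

logger = logging.getLogger("guideforge")


@dataclass
class PipelineResult:
    candidates: list
    hits_by_candidate: dict
    metrics: list
    graph: nx.Graph | None
    selected_ids: tuple
    constructs: list


def candidates_from_records(records, constraints, validate: bool = False):
    """Wrap an externally supplied spacer pool as candidates."""
    out = []
    for rec in records:
        report = evaluate_constraints(rec.seq, constraints) if validate else {}
        cand = CandidateSequence(
            id=rec.id,
            spacer=rec.seq,
            repeat_spacer_rna=assemble_repeat_spacer(rec.seq, constraints.spacer_length),
            tm=report["tm"]["value"] if validate else None,
            constraint_report=report,
            stage_pass=(
                {"generation": all(v["pass"] for v in report.values())} if validate else {}
            ),
        )
        out.append(cand)
    return out


def run_pipeline(
    config: PipelineConfig, outdir: str | os.PathLike, seed: int | None = None
) -> PipelineResult:
    """Run every stage, writing all reports under ``outdir``.

    ``seed`` overrides the config's rng_seed.  Outputs are byte-identical
    across runs for a fixed config and seed.
    """
    os.makedirs(outdir, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    out = lambda name: os.path.join(outdir, name)

    # (i) candidate pool
    if config.pool_fasta is not None:
        logger.info("loading external pool from %s", config.pool_fasta)
        candidates = candidates_from_records(
            read_fasta(config.pool_fasta), config.generation, validate=True
        )
    else:
        logger.info("generating pool of %d candidates", config.generation.pool_size)
        candidates = generate_pool(config.generation, seed)
    write_fasta(
        [SequenceRecord(c.id, c.spacer) for c in candidates], out("pool.fasta")
    )
    write_fasta(
        [SequenceRecord(c.id, c.repeat_spacer_rna, "RNA") for c in candidates],
        out("repeat_spacers.fasta"),
    )

    # (ii) off-target screen
    genome_records = [rec for path in config.genomes for rec in read_fasta(path)]
    hits_by_candidate = {}
    for cand in candidates:
        hits = []
        for rec in genome_records:
            hits.extend(find_offtarget_hits(cand.spacer, rec, config.scoring))
        hits_by_candidate[cand.id] = hits
        cand.offtarget_score = score_guide(hits, config.scoring)
    write_hits_tsv(hits_by_candidate, out("offtarget_hits.tsv"))
    write_hits_bed(hits_by_candidate, out("offtarget_hits.bed"))
    retained, eliminated = filter_by_offtarget_score(candidates, config.scoring)
    logger.info("off-target screen: %d retained, %d eliminated", len(retained), len(eliminated))

    # (iii) hybrid free-energy screen
    if config.hybrid_energy_range is None:
        logger.warning("no hybrid energy_range configured; skipping the hybrid screen")
        survivors = retained
    else:
        survivors, rejected = filter_by_hybrid_energy(
            retained, config.hybrid_energy_range, config.generation.conditions
        )
        logger.info("hybrid screen: %d retained, %d rejected", len(survivors), len(rejected))

    # (iv) crosstalk graph + maximum independent set
    metrics = []
    graph = nx.Graph()
    graph.add_nodes_from(c.id for c in survivors)
    if len(survivors) >= 2:
        metrics = crosstalk_mod.pairwise_crosstalk(
            survivors, config.alignment, config.generation.conditions
        )
        graph = crosstalk_mod.build_interaction_graph(metrics, config.thresholds)
        crosstalk_mod.write_metrics_tsv(metrics, out("crosstalk_metrics.tsv"))
    crosstalk_mod.write_edges_tsv(graph, out("interaction_edges.tsv"))
    selection = maximum_independent_set(graph)
    selected_ids = selection.member_ids
    by_id = {c.id: c for c in candidates}
    for cid in selected_ids:
        by_id[cid].selected = True
    write_selection_tsv(selection, graph, out("selected.tsv"))
    write_fasta(
        [SequenceRecord(cid, by_id[cid].spacer) for cid in selected_ids],
        out("selected.fasta"),
    )
    logger.info("selected %d orthogonal guides: %s", len(selected_ids), ", ".join(selected_ids))

    # (v) promoter constructs for the selected guides
    constructs = []
    construct_dir = out("constructs")
    os.makedirs(construct_dir, exist_ok=True)
    for idx, cid in enumerate(selected_ids):
        built = construct_mod.build_repressible_promoter(
            by_id[cid].spacer,
            config.layout,
            rng_seed=(seed * 31 + idx) % 2**31,
            disallowed_motifs=config.generation.disallowed_motifs,
            construct_id=f"P_{cid}",
        )
        constructs.append(built)
        construct_mod.write_genbank(built, os.path.join(construct_dir, f"P_{cid}.gb"))
        construct_mod.write_features_bed(built, os.path.join(construct_dir, f"P_{cid}.bed"))
    if constructs:
        write_fasta(
            [SequenceRecord(b.construct_id, b.full_seq) for b in constructs],
            out("constructs.fasta"),
        )

    write_report(candidates, out("report.tsv"))
    return PipelineResult(
        candidates=candidates,
        hits_by_candidate=hits_by_candidate,
        metrics=metrics,
        graph=graph,
        selected_ids=selected_ids,
        constructs=constructs,
    )
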