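"""All-against-all pairwise interaction metrics and the interaction graph.

Three symmetric metrics are computed per candidate pair: the Smith-Waterman
local-alignment score and the longest shared substring (both on the DNA
spacers — the shared 21-nt direct repeat would otherwise dominate), and the
intermolecular RNA:RNA duplex MFE of the full repeat-spacer RNAs.  Nodes are
candidates; an undirected edge marks a potential cross-interaction whenever
sw_score > max_sw_score OR shared_substring_len > max_shared_substring OR
duplex_mfe < min_mfe (strict inequalities, disjunctive); each edge records
every criterion that triggered it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
from Bio import Align

from .thermo import DEFAULT_CONDITIONS, dg_rna_rna_duplex


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0  # linear gap penalty

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0 or self.gap >= 0:
            raise ValueError("require match > 0, mismatch <= 0, gap < 0")


DEFAULT_ALIGNMENT = AlignmentParams()


@dataclass(frozen=True)
class OrthogonalityThresholds:
    """Edge thresholds; set a bound to +/-inf to disable that criterion."""

    max_sw_score: float = 30.0
    max_shared_substring: int = 10
    min_mfe: float = -15.0  # kcal/mol; edge when the duplex is MORE stable


@dataclass(frozen=True)
class CrosstalkMetrics:
    id_a: str
    id_b: str
    sw_score: float
    shared_substring_len: int
    duplex_mfe: float


def smith_waterman_score(
    a: str, b: str, params: AlignmentParams = DEFAULT_ALIGNMENT
) -> float:
    """Best local-alignment score (score floor 0, linear gaps)."""
    if not a or not b:
        return 0.0
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=params.match,
        mismatch_score=params.mismatch,
        open_gap_score=params.gap,
        extend_gap_score=params.gap,
    )
    return float(aligner.score(a, b))


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest contiguous substring present in both (exact,
    same strand)."""
    if not a or not b:
        return 0
    if len(a) > len(b):
        a, b = b, a
    # binary search on the answer; substring sets are cheap at guide scale
    lo, hi = 0, len(a)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        subs = {a[i : i + mid] for i in range(len(a) - mid + 1)}
        if any(b[i : i + mid] in subs for i in range(len(b) - mid + 1)):
            lo = mid
        else:
            hi = mid - 1
    return lo


def pairwise_crosstalk(
    candidates,
    params: AlignmentParams = DEFAULT_ALIGNMENT,
    conditions=DEFAULT_CONDITIONS,
) -> list[CrosstalkMetrics]:
    """One CrosstalkMetrics per unordered candidate pair (n(n-1)/2 entries).

    SW and substring metrics are computed on DNA spacers; the duplex MFE on
    the full repeat-spacer RNAs.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates for pairwise metrics")
    out = []
    for a, b in combinations(candidates, 2):
        out.append(
            CrosstalkMetrics(
                id_a=a.id,
                id_b=b.id,
                sw_score=smith_waterman_score(a.spacer, b.spacer, params),
                shared_substring_len=longest_common_substring(a.spacer, b.spacer),
                duplex_mfe=dg_rna_rna_duplex(
                    a.repeat_spacer_rna, b.repeat_spacer_rna, conditions
                ).dg,
            )
        )
    return out


def build_interaction_graph(
    metrics, thresholds: OrthogonalityThresholds, node_ids=None
) -> nx.Graph:
    """Thresholded undirected interaction graph.

    Every pair of nodes must appear in ``metrics`` (error otherwise); each
    edge carries a ``criteria`` tuple naming what triggered it.
    """
    graph = nx.Graph()
    ids = set()
    for m in metrics:
        ids.update((m.id_a, m.id_b))
    if node_ids is not None:
        ids = set(node_ids)
    graph.add_nodes_from(sorted(ids))
    seen_pairs = set()
    for m in metrics:
        seen_pairs.add(frozenset((m.id_a, m.id_b)))
        criteria = []
        if m.sw_score > thresholds.max_sw_score:
            criteria.append("sw_score")
        if m.shared_substring_len > thresholds.max_shared_substring:
            criteria.append("shared_substring")
        if m.duplex_mfe < thresholds.min_mfe:
            criteria.append("duplex_mfe")
        if criteria:
            graph.add_edge(m.id_a, m.id_b, criteria=tuple(criteria))
    expected = {frozenset(p) for p in combinations(sorted(ids), 2)}
    missing = expected - seen_pairs
    if missing:
        pair = sorted(next(iter(missing)))
        raise ValueError(f"metrics missing for pair {pair} ({len(missing)} pairs absent)")
    return graph


def write_metrics_tsv(metrics, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tsw_score\tshared_substring_len\tduplex_mfe\n")
        for m in metrics:
            fh.write(
                f"{m.id_a}\t{m.id_b}\t{m.sw_score:.6g}\t"
                f"{m.shared_substring_len}\t{m.duplex_mfe:.6g}\n"
            )


def read_metrics_tsv(path: str | os.PathLike) -> list[CrosstalkMetrics]:
    metrics = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            id_a, id_b, sw, lcs, mfe = line.rstrip("\n").split("\t")
            metrics.append(CrosstalkMetrics(id_a, id_b, float(sw), int(lcs), float(mfe)))
    return metrics


def write_edges_tsv(graph: nx.Graph, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tcriteria\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{','.join(data['criteria'])}\n")
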