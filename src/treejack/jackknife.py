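"""First-order gene-tree jackknife over loci.

The concatenated MR of all gene trees is scored once (baseline network),
then re-scored with each locus left out in turn.  A locus whose removal
*increases* the number of network edges (strictly) is "stabilizing": its
presence suppresses taxonomic instability, making it a candidate for a
targeted increase in taxon sampling.  The locus with the greatest edge
increase is the best candidate.

``evaluate_graft`` measures the effect of the complementary intervention:
adding pseudo-data for a taxon to a locus it is missing from, by grafting
it onto that locus tree as sister to its nearest sampled relative in a
reference topology, then rebuilding the full network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Tuple

from .concatab import ConcatNetwork, build_network
from .matrix_rep import concatenate, encode_tree, MRMatrix
from .sufficiency import CoveragePattern
from .trees import PhyloTree, TreeError, graft as graft_leaf, nearest_sampled_relative

__all__ = [
    "LocusRecord",
    "JackknifeReport",
    "GraftResult",
    "jackknife",
    "evaluate_graft",
    "candidate_report",
    "write_report_tsv",
    "report_json",
]


@dataclass(frozen=True)
class LocusRecord:
    locus: str
    edges_without: int
    taxa_in_network: int
    taxa_in_locus: int
    delta: int
    stabilizing: bool
    dropped_taxa: Tuple[str, ...] = ()


@dataclass(frozen=True)
class JackknifeReport:
    baseline_edges: int
    baseline_taxa: int
    records: Tuple[LocusRecord, ...]

    @property
    def ranking(self) -> Tuple[LocusRecord, ...]:
        """Records by delta descending (locus name breaks ties)."""
        return tuple(sorted(self.records, key=lambda r: (-r.delta, r.locus)))

    @property
    def stabilizing_loci(self) -> Tuple[str, ...]:
        return tuple(r.locus for r in self.ranking if r.stabilizing)

    @property
    def best_candidate(self) -> Optional[str]:
        top = self.ranking[0] if self.records else None
        return top.locus if top is not None and top.stabilizing else None


def _pruned_network(matrix: MRMatrix):
    """Network on the matrix with all-missing rows removed; reports drops."""
    dropped = matrix.uncovered_taxa
    if dropped:
        keep = tuple(t for t in matrix.taxa if t not in dropped)
        matrix = MRMatrix(taxa=keep, columns=matrix.columns)
    return build_network(matrix), dropped


def jackknife(
    gene_trees: Mapping[str, PhyloTree],
    universe=None,
) -> JackknifeReport:
    """Leave-one-locus-out concatabomination analysis.

    Performs exactly ``k + 1`` network builds (baseline plus one per locus).
    Taxa left with all-missing rows in a replicate are dropped there and
    recorded; the baseline uses the same rule.
    """
    loci = sorted(gene_trees)
    if len(loci) < 2:
        raise ValueError("jackknife needs at least 2 loci")
    if universe is None:
        universe = frozenset().union(*(gene_trees[l].leaves for l in loci))
    else:
        universe = frozenset(universe)
    encoded = {l: encode_tree(gene_trees[l], universe, l) for l in loci}
    baseline_net, _ = _pruned_network(concatenate([encoded[l] for l in loci]))
    baseline_edges = baseline_net.edge_count
    records = []
    for left_out in loci:
        rest = [encoded[l] for l in loci if l != left_out]
        net, dropped = _pruned_network(concatenate(rest))
        delta = net.edge_count - baseline_edges
        records.append(
            LocusRecord(
                locus=left_out,
                edges_without=net.edge_count,
                taxa_in_network=len(net.nodes),
                taxa_in_locus=len(gene_trees[left_out].leaves),
                delta=delta,
                stabilizing=delta > 0,
                dropped_taxa=dropped,
            )
        )
    return JackknifeReport(
        baseline_edges=baseline_edges,
        baseline_taxa=len(baseline_net.nodes),
        records=tuple(records),
    )


@dataclass(frozen=True)
class GraftResult:
    locus: str
    taxon: str
    sister: str
    edges_before: int
    edges_after: int

    @property
    def delta(self) -> int:
        return self.edges_after - self.edges_before


def evaluate_graft(
    gene_trees: Mapping[str, PhyloTree],
    locus: str,
    taxon: str,
    reference: PhyloTree,
    universe=None,
) -> GraftResult:
    """Effect of adding pseudo-data for ``taxon`` to ``locus``.

    The taxon is grafted onto the locus tree as sister to its nearest
    sampled relative in the reference topology, and the full-concatenation
    network is rebuilt; fewer edges after means the addition mitigates
    instability.
    """
    if locus not in gene_trees:
        raise KeyError(f"unknown locus: {locus}")
    target_tree = gene_trees[locus]
    if taxon in target_tree.leaves:
        raise TreeError(f"taxon {taxon} already present in locus {locus}")
    sampled = target_tree.leaves & reference.leaves
    if taxon not in reference.leaves or not sampled:
        raise TreeError(
            "reference must contain the taxon and at least one leaf of the locus"
        )
    sister = nearest_sampled_relative(reference, taxon, sampled)
    grafted = graft_leaf(target_tree, taxon, sister)
    loci = sorted(gene_trees)
    if universe is None:
        universe = frozenset({taxon}).union(*(gene_trees[l].leaves for l in loci))
    else:
        universe = frozenset(universe) | {taxon}
    before_mats = [encode_tree(gene_trees[l], universe, l) for l in loci]
    after_mats = [
        encode_tree(grafted if l == locus else gene_trees[l], universe, l)
        for l in loci
    ]
    net_before, _ = _pruned_network(concatenate(before_mats))
    net_after, _ = _pruned_network(concatenate(after_mats))
    return GraftResult(
        locus=locus,
        taxon=taxon,
        sister=sister,
        edges_before=net_before.edge_count,
        edges_after=net_after.edge_count,
    )


def candidate_report(report: JackknifeReport, coverage: CoveragePattern) -> list:
    """Stabilizing loci ranked by delta, annotated with coverage.

    The ranking stays by delta; per-locus taxon counts and the taxa missing
    from each locus are shown so users can apply a realism filter by hand
    (no automatic filtering is done).
    """
    rows = []
    for rec in report.ranking:
        if not rec.stabilizing:
            continue
        sampled = coverage.sampled.get(rec.locus, frozenset())
        missing = sorted(coverage.universe - sampled)
        rows.append(
            {
                "locus": rec.locus,
                "delta": rec.delta,
                "edges_without": rec.edges_without,
                "taxa_in_locus": len(sampled),
                "n_missing": len(missing),
                "missing_taxa": missing,
            }
        )
    return rows


def write_report_tsv(report: JackknifeReport, path) -> None:
    """Per-locus table: locus, taxa in network, edges, taxa in locus, delta."""
    lines = ["locus\ttaxa_in_network\tedges_without\ttaxa_in_locus\tdelta\tstabilizing\tdropped_taxa"]
    for r in report.ranking:
        lines.append(
            f"{r.locus}\t{r.taxa_in_network}\t{r.edges_without}\t{r.taxa_in_locus}"
            f"\t{r.delta}\t{str(r.stabilizing).lower()}\t{','.join(r.dropped_taxa)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def report_json(report: JackknifeReport, path=None) -> str:
    payload = {
        "baseline_edges": report.baseline_edges,
        "baseline_taxa": report.baseline_taxa,
        "loci": [
            {
                "locus": r.locus,
                "edges_without": r.edges_without,
                "taxa_in_network": r.taxa_in_network,
                "taxa_in_locus": r.taxa_in_locus,
                "delta": r.delta,
                "stabilizing": r.stabilizing,
                "dropped_taxa": list(r.dropped_taxa),
            }
            for r in report.ranking
        ],
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
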