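"""One-command diagnosis of a directory of gene trees.

``run_diagnosis`` executes the full flow -- encode each locus tree to its
matrix representation, concatenate, build the concatabomination network,
run the first-order gene-tree jackknife, compute the gene-sampling
sufficiency statistics, and (when a parent tree is supplied) the terrace
-- and collects everything into a :class:`DiagnosisBundle`.
``export_reports`` writes the file artifacts plus a checksum manifest.
Every number in the bundle is recomputable from the inputs and options
alone; timestamps are deliberately excluded.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from . import __version__
from .concatab import build_network, summary_json, write_edge_tsv, write_graphml, write_sif
from .jackknife import (
    JackknifeReport,
    candidate_report,
    jackknife,
    report_json,
    write_report_tsv,
)
from .matrix_rep import concatenate, encode_tree, write_nexus, write_tsv
from .sufficiency import CoveragePattern, DEFAULT_P, SufficiencyResult, evaluate
from .terrace import DEFAULT_ENUM_CAP, TerraceResult, terrace
from .trees import NewickError, PhyloTree, read_newick, read_newick_dir, write_newick

__all__ = ["DiagnosisBundle", "run_diagnosis", "export_reports"]

log = logging.getLogger(__name__)


@dataclass
class DiagnosisBundle:
    gene_trees: Dict[str, PhyloTree]
    universe: frozenset
    network_summary: dict
    network: object
    matrix: object
    jackknife_report: JackknifeReport
    sufficiency: SufficiencyResult
    coverage: CoveragePattern
    terrace_result: Optional[TerraceResult] = None
    metadata: dict = field(default_factory=dict)
    artifacts: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "metadata": self.metadata,
            "network": self.network_summary,
            "jackknife": json.loads(report_json(self.jackknife_report)),
            "sufficiency": self.sufficiency.as_dict(),
        }
        if self.terrace_result is not None:
            tr = self.terrace_result
            payload["terrace"] = {
                "size": str(tr.size),
                "decisive": tr.decisive,
                "enumerated": tr.enumerated,
                "sc": tr.sc.to_newick() if tr.sc is not None else None,
            }
        payload["artifacts"] = dict(sorted(self.artifacts.items()))
        return json.dumps(payload, indent=2, sort_keys=True)


def _config_hash(options: dict) -> str:
    canon = json.dumps(options, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_diagnosis(
    tree_dir,
    *,
    parent: Optional[PhyloTree] = None,
    p_value: float = DEFAULT_P,
    enum_cap: int = DEFAULT_ENUM_CAP,
    seed: int = 0,
    skip_bad: bool = False,
) -> DiagnosisBundle:
    """Full diagnosis of a directory of per-locus Newick files."""
    tree_dir = Path(tree_dir)
    try:
        gene_trees = read_newick_dir(tree_dir)
    except NewickError:
        if not skip_bad:
            raise
        gene_trees = {}
        for path in sorted(tree_dir.glob("*.nwk")):
            try:
                gene_trees.update(read_newick_dir(path.parent, path.name))
            except NewickError as exc:  # pragma: no cover - salvage path
                log.warning("skipping %s: %s", path, exc)
    if len(gene_trees) < 2:
        raise ValueError(f"need at least 2 parsable locus trees in {tree_dir}")
    universe = frozenset().union(*(t.leaves for t in gene_trees.values()))
    encoded = [encode_tree(gene_trees[l], universe, l) for l in sorted(gene_trees)]
    matrix = concatenate(encoded)
    network = build_network(matrix)
    report = jackknife(gene_trees, universe)
    coverage = CoveragePattern.from_trees(gene_trees, universe)
    suff = evaluate(coverage, p=p_value)
    terrace_result = None
    if parent is not None:
        terrace_result = terrace(parent, coverage, enum_cap=enum_cap)
    options = {
        "p_value": p_value,
        "enum_cap": enum_cap,
        "seed": seed,
        "loci": sorted(gene_trees),
        "parent": parent.to_newick() if parent is not None else None,
    }
    metadata = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(options),
        "n_loci": len(gene_trees),
        "n_taxa": len(universe),
    }
    return DiagnosisBundle(
        gene_trees=gene_trees,
        universe=universe,
        network_summary=network.summary(),
        network=network,
        matrix=matrix,
        jackknife_report=report,
        sufficiency=suff,
        coverage=coverage,
        terrace_result=terrace_result,
        metadata=metadata,
    )


ALL_FORMATS = ("json", "tsv", "sif", "graphml", "nexus")


def export_reports(
    bundle: DiagnosisBundle,
    out_dir,
    formats=ALL_FORMATS,
    force: bool = False,
) -> Dict[str, str]:
    """Write report artifacts and a manifest with sha256 checksums."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"{out} is not empty; pass force=True (--force) to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    if "sif" in formats:
        write_sif(bundle.network, out / "network.sif")
        written["network.sif"] = out / "network.sif"
    if "graphml" in formats:
        write_graphml(bundle.network, out / "network.graphml")
        written["network.graphml"] = out / "network.graphml"
    if "tsv" in formats:
        write_edge_tsv(bundle.network, out / "network_edges.tsv")
        written["network_edges.tsv"] = out / "network_edges.tsv"
        write_report_tsv(bundle.jackknife_report, out / "jackknife.tsv")
        written["jackknife.tsv"] = out / "jackknife.tsv"
        write_tsv(bundle.matrix, out / "matrix.tsv")
        written["matrix.tsv"] = out / "matrix.tsv"
        bundle.coverage.to_tsv(out / "coverage.tsv")
        written["coverage.tsv"] = out / "coverage.tsv"
    if "nexus" in formats:
        write_nexus(bundle.matrix, out / "matrix.nex", paup_block=True)
        written["matrix.nex"] = out / "matrix.nex"
    if "json" in formats:
        (out / "network_summary.json").write_text(
            summary_json(bundle.network) + "\n"
        )
        written["network_summary.json"] = out / "network_summary.json"
        (out / "diagnosis.json").write_text(bundle.to_json() + "\n")
        written["diagnosis.json"] = out / "diagnosis.json"
        cands = candidate_report(bundle.jackknife_report, bundle.coverage)
        (out / "candidates.json").write_text(
            json.dumps(cands, indent=2, sort_keys=True) + "\n"
        )
        written["candidates.json"] = out / "candidates.json"
    if bundle.terrace_result is not None and bundle.terrace_result.sc is not None:
        write_newick(bundle.terrace_result.sc, out / "terrace_sc.nwk")
        written["terrace_sc.nwk"] = out / "terrace_sc.nwk"
    manifest = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(written.items())
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    bundle.artifacts = {name: str(path) for name, path in written.items()}
    bundle.artifacts["manifest.json"] = str(out / "manifest.json")
    return bundle.artifacts
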