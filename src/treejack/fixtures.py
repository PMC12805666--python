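"""Seeded synthetic multilocus tree sets.

The generator emulates the statistical structure the diagnostics target:
a known binary species tree, per-locus partial taxon sampling, optional
topological conflict injected by local NNI perturbations, and *rogue*
taxa present in exactly one host locus -- optionally attached inside a
polytomy, the pattern under which a single taxon can destroy supertree
resolution while every gene tree looks unremarkable.

All randomness flows through one explicitly threaded ``random.Random``
instance, so every output is fully reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import random

from .sufficiency import CoveragePattern
from .trees import PhyloTree, TreeError, restrict, write_newick

__all__ = [
    "RogueSpec",
    "FixtureConfig",
    "SimulatedData",
    "random_binary_tree",
    "random_nni",
    "simulate",
    "gordon_like",
    "write_simulation",
]


@dataclass(frozen=True)
class RogueSpec:
    """A taxon confined to a single host locus."""

    taxon: str
    host_locus: str
    placement: str = "polytomy"  # or "resolved"

    def __post_init__(self):
        if self.placement not in ("polytomy", "resolved"):
            raise ValueError(f"unknown placement: {self.placement}")


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic multilocus data set.

    ``coverage`` is either a sampling probability applied per taxon per
    locus, or an explicit per-locus taxon count list.  Taxa left uncovered
    by chance are assigned to one random locus so that every taxon appears
    in at least one locus; loci are topped up to three sampled taxa when
    needed (the minimum for an informative rooted tree).
    """

    n_taxa: int
    k_loci: int
    coverage: Union[float, Sequence[int]] = 0.6
    rogues: Tuple[RogueSpec, ...] = ()
    conflict_nni: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if self.k_loci < 1:
            raise ValueError("need at least 1 locus")
        if self.conflict_nni < 0:
            raise ValueError("conflict_nni must be >= 0")
        object.__setattr__(self, "rogues", tuple(self.rogues))

    @property
    def locus_labels(self) -> Tuple[str, ...]:
        return tuple(f"L{i + 1}" for i in range(self.k_loci))

    @property
    def taxon_labels(self) -> Tuple[str, ...]:
        return tuple(f"t{i + 1:02d}" for i in range(self.n_taxa))


@dataclass(frozen=True)
class SimulatedData:
    true_tree: PhyloTree
    gene_trees: Dict[str, PhyloTree]
    coverage: CoveragePattern
    config: FixtureConfig


def random_binary_tree(labels: Sequence[str], rng: random.Random) -> PhyloTree:
    """Uniform random rooted binary tree by sequential random attachment.

    Every labelled rooted binary shape arises from exactly one insertion
    sequence, and each step offers the same number of attachment edges, so
    the distribution is uniform.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    order = labels[:]
    rng.shuffle(order)
    tree = (order[0], order[1]) if len(order) > 1 else order[0]
    for leaf in order[2:]:
        edges = _count_insertions(tree)
        tree = _insert_at(tree, leaf, rng.randrange(edges))[0]
    acc: list = []
    leaves = _collect(tree, acc)
    return PhyloTree(leaves, acc, validate=False)


def _count_insertions(t) -> int:
    if isinstance(t, str):
        return 1
    return 1 + _count_insertions(t[0]) + _count_insertions(t[1])


def _insert_at(t, leaf, idx):
    """Insert on the idx-th edge (preorder, root edge first)."""
    if idx == 0:
        return (t, leaf), -1
    idx -= 1
    if isinstance(t, str):
        return t, idx
    left, rem = _insert_at(t[0], leaf, idx)
    if rem == -1:
        return (left, t[1]), -1
    right, rem = _insert_at(t[1], leaf, rem)
    if rem == -1:
        return (t[0], right), -1
    return t, rem


def _collect(t, acc) -> frozenset:
    if isinstance(t, str):
        return frozenset((t,))
    cl = _collect(t[0], acc) | _collect(t[1], acc)
    acc.append(cl)
    return cl


def random_nni(tree: PhyloTree, rng: random.Random, times: int = 1) -> PhyloTree:
    """Apply ``times`` random nearest-neighbour interchanges.

    Each move picks a cluster, one of its child subtrees, and one sibling
    subtree under its parent, and swaps them; only the chosen cluster's
    leaf content changes, so the result is always a valid tree.
    """
    clusters = set(tree.clusters)
    leaves = tree.leaves
    for _ in range(times):
        if not clusters:
            break
        children = PhyloTree(leaves, clusters, validate=False).children_map()
        target = rng.choice(sorted(clusters, key=min))
        parent = leaves
        for c in clusters:
            if target < c and len(c) < len(parent):
                parent = c
        siblings = [k for k in children[parent] if k != target]
        if not siblings:
            continue
        sib = rng.choice(sorted(siblings, key=min))
        child = rng.choice(sorted(children[target], key=min))
        new_target = (target - child) | sib
        clusters.discard(target)
        if 2 <= len(new_target) < len(leaves):
            clusters.add(new_target)
    return PhyloTree(leaves, clusters, validate=False)


def _sample_coverage(config: FixtureConfig, rng: random.Random) -> Dict[str, set]:
    taxa = list(config.taxon_labels)
    loci = list(config.locus_labels)
    sampled: Dict[str, set] = {}
    if isinstance(config.coverage, (int, float)) and not isinstance(
        config.coverage, bool
    ):
        p = float(config.coverage)
        if not 0 < p <= 1:
            raise ValueError("coverage probability must be in (0, 1]")
        for l in loci:
            sampled[l] = {t for t in taxa if rng.random() < p}
    else:
        counts = list(config.coverage)
        if len(counts) != config.k_loci:
            raise ValueError("per-locus counts must match k_loci")
        for l, c in zip(loci, counts):
            if not 1 <= c <= config.n_taxa:
                raise ValueError(f"invalid taxon count for {l}: {c}")
            sampled[l] = set(rng.sample(taxa, c))
    # top up loci below three taxa (minimum for an informative rooted tree)
    for l in loci:
        short = 3 - len(sampled[l])
        if short > 0:
            pool = sorted(set(taxa) - sampled[l])
            sampled[l] |= set(rng.sample(pool, min(short, len(pool))))
    # every taxon must appear in at least one locus
    for t in taxa:
        if not any(t in sampled[l] for l in loci):
            sampled[rng.choice(loci)].add(t)
    return sampled


def simulate(config: FixtureConfig) -> SimulatedData:
    """Generate a true tree, per-locus gene trees, and the coverage pattern."""
    rng = random.Random(config.seed)
    for r in config.rogues:
        if r.host_locus not in config.locus_labels:
            raise ValueError(f"unknown host locus: {r.host_locus}")
        if r.taxon in config.taxon_labels:
            raise ValueError(f"rogue label collides with a base taxon: {r.taxon}")
    all_leaves = list(config.taxon_labels) + [r.taxon for r in config.rogues]
    if len(set(all_leaves)) != len(all_leaves):
        raise ValueError("duplicate rogue taxon labels")
    true_tree = random_binary_tree(all_leaves, rng)
    sampled = _sample_coverage(config, rng)
    for r in config.rogues:
        if len(sampled[r.host_locus]) < 2:
            raise ValueError(f"rogue host {r.host_locus} has fewer than 2 other taxa")
        sampled[r.host_locus].add(r.taxon)
    gene_trees: Dict[str, PhyloTree] = {}
    for l in config.locus_labels:
        t = restrict(true_tree, sampled[l])
        if config.conflict_nni:
            t = random_nni(t, rng, config.conflict_nni)
        for r in config.rogues:
            if r.host_locus == l and r.placement == "polytomy":
                t = _collapse_parent(t, r.taxon)
        gene_trees[l] = t
    coverage = CoveragePattern(
        loci=config.locus_labels,
        sampled={l: frozenset(sampled[l]) for l in config.locus_labels},
        universe=frozenset(all_leaves),
    )
    return SimulatedData(
        true_tree=true_tree,
        gene_trees=gene_trees,
        coverage=coverage,
        config=config,
    )


def _collapse_parent(tree: PhyloTree, taxon: str) -> PhyloTree:
    """Collapse the edge above ``taxon``'s parent, producing a polytomy."""
    parent = None
    for c in tree.clusters:
        if taxon in c and (parent is None or len(c) < len(parent)):
            parent = c
    if parent is None:
        return tree  # already attached at the root polytomy
    return PhyloTree(tree.leaves, tree.clusters - {parent}, validate=False)


def gordon_like(
    n_shared: int, n_a: int, n_b: int, seed: int = 0
) -> Tuple[PhyloTree, PhyloTree]:
    """Two compatible locus trees sharing exactly ``n_shared`` leaves.

    Both are restrictions of one random parent on ``n_a + n_b - n_shared``
    taxa, the classic two-gene pattern whose partial overlap permits
    multiple plenary supertrees.
    """
    if n_shared < 3:
        raise ValueError("need at least 3 shared taxa")
    if n_a < n_shared or n_b < n_shared:
        raise ValueError("per-locus sizes must be at least the shared count")
    rng = random.Random(seed)
    total = n_a + n_b - n_shared
    taxa = [f"t{i + 1:02d}" for i in range(total)]
    parent = random_binary_tree(taxa, rng)
    shared = set(rng.sample(taxa, n_shared))
    others = [t for t in taxa if t not in shared]
    rng.shuffle(others)
    only_a = set(others[: n_a - n_shared])
    only_b = set(others[n_a - n_shared :])
    return (
        restrict(parent, shared | only_a),
        restrict(parent, shared | only_b),
    )


def write_simulation(data: SimulatedData, out_dir) -> dict:
    """Write locus Newick files, the coverage TSV and a provenance JSON."""
    out = Path(out_dir)
    loci_dir = out / "loci"
    loci_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for locus, tree in sorted(data.gene_trees.items()):
        p = loci_dir / f"{locus}.nwk"
        write_newick(tree, p)
        paths[locus] = str(p)
    cov = out / "coverage.tsv"
    data.coverage.to_tsv(cov)
    truth = out / "true_tree.nwk"
    write_newick(data.true_tree, truth)
    cfg = data.config
    provenance = {
        "n_taxa": cfg.n_taxa,
        "k_loci": cfg.k_loci,
        "coverage": cfg.coverage
        if isinstance(cfg.coverage, (int, float))
        else list(cfg.coverage),
        "rogues": [
            {"taxon": r.taxon, "host_locus": r.host_locus, "placement": r.placement}
            for r in cfg.rogues
        ],
        "conflict_nni": cfg.conflict_nni,
        "seed": cfg.seed,
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return {
        "loci_dir": str(loci_dir),
        "trees": paths,
        "coverage": str(cov),
        "true_tree": str(truth),
        "provenance": str(prov_path),
    }
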