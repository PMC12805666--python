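"""Gene-sampling-sufficiency statistics for a taxon coverage pattern.

Given n taxa and k loci with per-locus sampled taxon counts n_l, the
statistics are:

* taxon coverage density        d = (sum_l n_l / n) / k
* minimum locus number          k_min ~= log(n^3 / 6p) / -log(1 - d^4)
* gene sampling sufficiency     zeta = ln(k / k_min)

k_min approximates the number of randomly taxon-sampled loci needed for
the coverage pattern to be decisive for a binary tree with confidence
1 - p; it is reported rounded half-up, but zeta always uses the unrounded
value.  zeta >= 0 means enough loci have been sampled for probable
decisiveness; zeta < 0 means more are needed.  If any locus covers every
taxon the pattern is decisive a priori and k_min is 1 by convention.

Note on the sign of zeta: the convention here is ln(k / k_min), i.e. the
log-ratio of sampled to required loci, which is the form consistent with
the stated interpretation (zeta >= 0 iff k >= k_min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Tuple

__all__ = [
    "CoveragePattern",
    "KMin",
    "SufficiencyResult",
    "coverage_density",
    "k_min",
    "zeta",
    "evaluate",
    "compare",
]

DEFAULT_P = 0.05


@dataclass(frozen=True)
class CoveragePattern:
    """Which taxa are sampled for which locus."""

    loci: Tuple[str, ...]
    sampled: Mapping[str, frozenset]
    universe: frozenset

    def __post_init__(self):
        for l in self.loci:
            s = self.sampled[l]
            if not s:
                raise ValueError(f"locus {l} samples no taxa")
            if not s <= self.universe:
                extra = s - self.universe
                raise ValueError(
                    f"locus {l} samples taxa outside the universe: {sorted(extra)}"
                )

    @property
    def n(self) -> int:
        return len(self.universe)

    @property
    def k(self) -> int:
        return len(self.loci)

    @property
    def counts(self) -> Tuple[int, ...]:
        return tuple(len(self.sampled[l]) for l in self.loci)

    def has_full_locus(self) -> bool:
        return any(self.sampled[l] == self.universe for l in self.loci)

    def drop(self, locus: str) -> "CoveragePattern":
        if locus not in self.loci:
            raise KeyError(locus)
        loci = tuple(l for l in self.loci if l != locus)
        sampled = {l: self.sampled[l] for l in loci}
        return CoveragePattern(loci=loci, sampled=sampled, universe=self.universe)

    @classmethod
    def from_counts(cls, counts: Iterable[int], n: int, prefix: str = "L"):
        """Synthetic pattern with given per-locus taxon counts over n taxa.

        Density and the statistics depend only on the counts, so the first
        ``n_l`` taxa are assigned to each locus.
        """
        taxa = tuple(f"x{i + 1:03d}" for i in range(n))
        counts = list(counts)
        loci = tuple(f"{prefix}{i + 1:02d}" for i in range(len(counts)))
        sampled = {
            l: frozenset(taxa[:c]) for l, c in zip(loci, counts)
        }
        return cls(loci=loci, sampled=sampled, universe=frozenset(taxa))

    @classmethod
    def from_trees(cls, gene_trees: Mapping[str, object], universe=None):
        loci = tuple(sorted(gene_trees))
        sampled = {l: frozenset(gene_trees[l].leaves) for l in loci}
        if universe is None:
            universe = frozenset().union(*sampled.values())
        return cls(loci=loci, sampled=sampled, universe=frozenset(universe))

    @classmethod
    def from_tsv(cls, path):
        """Read a taxa x loci 0/1 table (tab-separated, header = loci)."""
        lines = Path(path).read_text().strip().splitlines()
        loci = tuple(lines[0].split("\t")[1:])
        sampled = {l: set() for l in loci}
        taxa = []
        for line in lines[1:]:
            cells = line.split("\t")
            taxa.append(cells[0])
            for l, v in zip(loci, cells[1:]):
                if v.strip() == "1":
                    sampled[l].add(cells[0])
        return cls(
            loci=loci,
            sampled={l: frozenset(s) for l, s in sampled.items()},
            universe=frozenset(taxa),
        )

    def to_tsv(self, path) -> None:
        taxa = sorted(self.universe)
        lines = ["\t".join(["taxon"] + list(self.loci))]
        for t in taxa:
            lines.append(
                "\t".join([t] + ["1" if t in self.sampled[l] else "0" for l in self.loci])
            )
        Path(path).write_text("\n".join(lines) + "\n")


def coverage_density(pattern: CoveragePattern) -> float:
    """Average proportion of taxa sampled per locus, full precision."""
    if pattern.k < 1 or pattern.n < 1:
        raise ValueError("empty coverage pattern")
    return sum(c / pattern.n for c in pattern.counts) / pattern.k


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class KMin:
    raw: float
    rounded: int
    decisive_a_priori: bool = False


def k_min(n: int, d: float, p: float = DEFAULT_P) -> KMin:
    """Approximate minimum locus number for decisiveness at confidence p.

    The ratio of logs is base-invariant; natural logs are used.  d = 1
    (or a full-coverage locus, handled by the caller) short-circuits to 1
    with the decisive-a-priori flag, since one locus sampled for all taxa
    is sufficient for decisiveness.
    """
    if d <= 0:
        raise ValueError("coverage density must be positive")
    if not 0 < p < 1:
        raise ValueError("confidence level p must be in (0, 1)")
    if n < 4:
        raise ValueError("k_min needs at least 4 taxa")
    if d >= 1:
        return KMin(raw=1.0, rounded=1, decisive_a_priori=True)
    raw = math.log(n**3 / (6 * p)) / -math.log(1 - d**4)
    return KMin(raw=raw, rounded=_round_half_up(raw))


def zeta(k: int, k_min_raw: float) -> float:
    """Gene sampling sufficiency: ln(k / k_min), unrounded k_min."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if k_min_raw <= 0:
        raise ValueError("k_min must be positive")
    return math.log(k / k_min_raw)


@dataclass(frozen=True)
class SufficiencyResult:
    n: int
    k: int
    d: float
    p: float
    k_min_raw: float
    k_min: int
    zeta: float
    decisive_a_priori: bool = False

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "k": self.k,
            "d": self.d,
            "d_2dp": round(self.d, 2),
            "p": self.p,
            "k_min_raw": self.k_min_raw,
            "k_min": self.k_min,
            "zeta": self.zeta,
            "zeta_2dp": round(self.zeta, 2),
            "decisive_a_priori": self.decisive_a_priori,
        }


def evaluate(pattern: CoveragePattern, p: float = DEFAULT_P) -> SufficiencyResult:
    """d, k_min and zeta for a coverage pattern."""
    d = coverage_density(pattern)
    if pattern.has_full_locus() or d >= 1:
        km = KMin(raw=1.0, rounded=1, decisive_a_priori=True)
    else:
        km = k_min(pattern.n, d, p)
    return SufficiencyResult(
        n=pattern.n,
        k=pattern.k,
        d=d,
        p=p,
        k_min_raw=km.raw,
        k_min=km.rounded,
        zeta=zeta(pattern.k, km.raw),
        decisive_a_priori=km.decisive_a_priori,
    )


def compare(before: SufficiencyResult, after: SufficiencyResult) -> dict:
    """Element-wise differences (after - before), as in pre/post tables."""
    if before.n != after.n:
        raise ValueError(f"taxon counts differ: {before.n} vs {after.n}")
    return {
        "delta_d": after.d - before.d,
        "delta_zeta": after.zeta - before.zeta,
    }
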