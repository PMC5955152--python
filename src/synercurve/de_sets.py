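"""Differential-expression filtering and gene-set algebra.

A gene is called differentially expressed when three filters all pass:

* ``FDR < fdr_max`` (strict, default 0.05),
* ``max(FPKM_control, FPKM_treated) >= fpkm_min`` (inclusive, default 1 —
  at least one condition must express the gene),
* ``|linear fold change| >= fc_min`` (default 2, i.e. |log2FC| >= 1);
  infinite fold changes (one FPKM exactly zero) always satisfy this.

The sign of log2FC routes each passing gene to the up- or down-regulated
set.  Downstream set algebra defines *unique-to-combination* genes —
combination-condition calls absent from both single-agent call sets — and
n-way Venn region counts, optionally direction-aware.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_tables import DERecord

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "GeneSet",
    "VennCounts",
    "PersistenceSummary",
    "filter_de",
    "overlap",
    "venn_counts",
    "unique_to_combination",
    "persistence_report",
]


@dataclass(frozen=True)
class FilterSpec:
    """Significance / expression / effect-size thresholds for DE calls."""

    fdr_max: float = 0.05
    fpkm_min: float = 1.0
    fc_min: float = 2.0  # linear fold-change magnitude

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr_max <= 1.0):
            raise ValueError("fdr_max must be in [0,1]")
        if self.fpkm_min < 0:
            raise ValueError("fpkm_min must be nonnegative")
        if self.fc_min < 1:
            raise ValueError("fc_min is a linear magnitude and must be >= 1")


@dataclass(frozen=True)
class GeneSet:
    """Directional DE call set for one condition; up and down are disjoint."""

    condition: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        clash = self.up & self.down
        if clash:
            raise ValueError(f"genes in both up and down sets: {sorted(clash)[:5]}")

    @property
    def members(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def sign_of(self, gene: str) -> int:
        if gene in self.up:
            return 1
        if gene in self.down:
            return -1
        return 0


@dataclass(frozen=True)
class VennCounts:
    """Exact region cardinalities of an n-set Venn decomposition.

    ``region_counts`` maps each nonempty frozenset of labels to the number
    of genes belonging to exactly those sets.  In direction-agnostic mode
    the counts partition the union of all sets.
    """

    labels: tuple[str, ...]
    region_counts: Mapping[frozenset[str], int]
    direction_aware: bool = False

    def count(self, *labels: str) -> int:
        return self.region_counts.get(frozenset(labels), 0)

    @property
    def shared_all(self) -> int:
        return self.count(*self.labels)

    def total(self) -> int:
        return sum(self.region_counts.values())


@dataclass(frozen=True)
class PersistenceSummary:
    """Direction-aware carry-over of DE calls between two time points."""

    shared_up: int
    shared_down: int
    earlier_total: int
    retained_fraction: float | None  # None when the earlier set is empty


def filter_de(table: Sequence[DERecord], spec: FilterSpec = FilterSpec()) -> GeneSet:
    """Apply the FDR / FPKM / fold-change filters to one DE table.

    Genes with zero FPKM in both conditions are excluded up front (their
    fold change is undefined and they cannot satisfy the expression
    filter).  Genes passing FDR and FPKM with log2FC exactly 0 have no
    direction; they are excluded and counted in a log line.
    """
    if not table:
        raise ValueError("DE table is empty")
    log2_min = math.log2(spec.fc_min)
    up: set[str] = set()
    down: set[str] = set()
    n_directionless = 0
    condition = table[0].condition
    for rec in table:
        if rec.fpkm_control == 0 and rec.fpkm_treated == 0:
            continue
        if not (rec.fdr < spec.fdr_max):
            continue
        if max(rec.fpkm_control, rec.fpkm_treated) < spec.fpkm_min:
            continue
        if math.isinf(rec.log2_fc):
            pass  # infinite fold change always satisfies the FC filter
        elif abs(rec.log2_fc) < log2_min:
            continue
        if rec.log2_fc > 0:
            up.add(rec.gene_id)
        elif rec.log2_fc < 0:
            down.add(rec.gene_id)
        else:
            n_directionless += 1
    if n_directionless:
        logger.info(
            "%d gene(s) passed FDR/FPKM with log2FC == 0; excluded (no direction)",
            n_directionless,
        )
    return GeneSet(condition=condition, up=frozenset(up), down=frozenset(down))


def _signed_regions(sets: Sequence[GeneSet], sign: int) -> dict[frozenset[str], int]:
    pools = [gs.up if sign > 0 else gs.down for gs in sets]
    labels = [gs.condition for gs in sets]
    union: set[str] = set().union(*pools)
    counts: dict[frozenset[str], int] = {}
    for gene in union:
        region = frozenset(l for l, p in zip(labels, pools) if gene in p)
        counts[region] = counts.get(region, 0) + 1
    return counts


def venn_counts(sets: Sequence[GeneSet], direction_aware: bool = False) -> VennCounts:
    """Region counts of the Venn decomposition of 2 or more gene sets.

    Direction-agnostic (default): membership is ``up | down`` and regions
    partition the union, so counts sum to its size.  Direction-aware:
    up-regulated and down-regulated calls are decomposed separately and the
    region counts summed, so a gene moving in opposite directions in two
    conditions is *not* counted as shared.
    """
    labels = tuple(gs.condition for gs in sets)
    if len(set(labels)) != len(labels):
        raise ValueError("gene sets must carry distinct condition labels")
    counts: dict[frozenset[str], int] = {}
    if direction_aware:
        for sign in (1, -1):
            for region, n in _signed_regions(sets, sign).items():
                counts[region] = counts.get(region, 0) + n
    else:
        pools = [gs.members for gs in sets]
        union: set[str] = set().union(*pools)
        for gene in union:
            region = frozenset(l for l, p in zip(labels, pools) if gene in p)
            counts[region] = counts.get(region, 0) + 1
    return VennCounts(labels=labels, region_counts=counts, direction_aware=direction_aware)


def overlap(a: GeneSet, b: GeneSet, direction_aware: bool = False) -> VennCounts:
    """Two-set overlap; ``result.shared_all`` is the shared-gene count."""
    return venn_counts([a, b], direction_aware=direction_aware)


def unique_to_combination(agent_a: GeneSet, agent_b: GeneSet, combo: GeneSet) -> GeneSet:
    """Combination-condition calls absent from both single-agent call sets.

    Membership in the single agents is direction-agnostic (a gene counted
    up in agent A and down in the combination is still *not* unique);
    direction labels of the result are inherited from the combination.
    """
    seen = agent_a.members | agent_b.members
    return GeneSet(
        condition=f"{combo.condition}|unique",
        up=frozenset(combo.up - seen),
        down=frozenset(combo.down - seen),
    )


def persistence_report(earlier: GeneSet, later: GeneSet) -> PersistenceSummary:
    """Direction-aware carry-over of calls from an earlier to a later time.

    The retained fraction is the share of the earlier set present in the
    later set *with the same direction*; it is ``None`` (not an error) when
    the earlier set is empty.
    """
    shared_up = len(earlier.up & later.up)
    shared_down = len(earlier.down & later.down)
    total = len(earlier)
    frac = (shared_up + shared_down) / total if total else None
    return PersistenceSummary(
        shared_up=shared_up,
        shared_down=shared_down,
        earlier_total=total,
        retained_fraction=frac,
    )
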