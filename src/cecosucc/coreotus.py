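"""Prevalence-based per-age presence sets and the Venn persistence partition.

An OTU is "present" at an age when it is detected (count > 0) in at least a
threshold fraction (default 75%) of that age's samples, diet groups pooled.
The Venn partition classifies every OTU in the union of per-age sets by its
exact age-membership pattern; named regions capture the succession story:

* ``persistent`` — present at every age;
* ``milk_only`` — present only at the first (exclusively milk-fed) age;
* ``acquired`` — absent at the first age, present at every later age;
* ``milk_late_shared`` — present at the first and the last two ages only.

Region percentages are relative to the union of all per-age sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tableio import CountTable


@dataclass
class CorePartition:
    ages: list[int]
    presence: dict[int, frozenset]
    regions: dict[frozenset, frozenset]          # age-pattern -> OTU ids
    named: dict[str, frozenset]
    union_size: int

    def percentage(self, region: str) -> float:
        """Region size as percent of the union of per-age sets."""
        if self.union_size == 0:
            return 0.0
        return 100.0 * len(self.named[region]) / self.union_size

    def region_sizes(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.named.items()}


def presence_by_age(table: CountTable, threshold: float = 0.75
                    ) -> dict[int, frozenset]:
    """Per-age OTU presence sets at a prevalence threshold.

    OTU is in set(age) iff it has count > 0 in at least
    ``ceil(threshold * n_samples(age))`` of the age's samples.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    out: dict[int, frozenset] = {}
    for age in table.ages():
        ids = table.samples_at_age(age)
        need = math.ceil(threshold * len(ids))
        hits = (table.counts[ids] > 0).sum(axis=1)
        out[age] = frozenset(hits.index[hits >= need])
    return out


def venn_partition(presence: dict[int, frozenset]) -> CorePartition:
    """Exact Venn partition of the union of per-age presence sets."""
    ages = sorted(presence)
    if len(ages) < 2:
        raise ValueError("need presence sets for at least 2 ages")
    union = frozenset().union(*presence.values())
    regions: dict[frozenset, set] = {}
    for otu in union:
        pattern = frozenset(a for a in ages if otu in presence[a])
        regions.setdefault(pattern, set()).add(otu)
    regions = {p: frozenset(s) for p, s in regions.items()}

    def region(pattern) -> frozenset:
        return regions.get(frozenset(pattern), frozenset())

    named = {
        "persistent": region(ages),
        "milk_only": region([ages[0]]),
        "acquired": region(ages[1:]),
        # first + last two ages only; degenerate (== persistent) under 4 ages
        "milk_late_shared": region([ages[0], ages[-2], ages[-1]])
        if len(ages) >= 4 else frozenset(),
    }
    named["other"] = union - frozenset().union(*named.values())
    return CorePartition(ages=ages, presence=dict(presence), regions=regions,
                         named=named, union_size=len(union))


def partition_abundance(table: CountTable, otu_set, age: int) -> float:
    """Mean percent of each sample's reads carried by ``otu_set`` at an age."""
    otu_set = set(otu_set)
    unknown = otu_set - set(table.otu_ids)
    if unknown:
        raise ValueError(f"OTUs not in table: {sorted(unknown)[:10]}")
    ids = table.samples_at_age(age)
    if not otu_set:
        return 0.0
    sub = table.counts.loc[sorted(otu_set), ids].sum(axis=0)
    totals = table.counts[ids].sum(axis=0)
    return float((sub / totals).mean() * 100.0)
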