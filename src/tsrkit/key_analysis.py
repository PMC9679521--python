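"""Common- and specific-key mining over a two-level class hierarchy.

A *common* key of a set of structures is present in every member
(optionally weighted by its minimum occurrence frequency).  A *specific*
key of a hierarchy node is present in (a configurable fraction of) the
node's members and absent from every structure outside the node —
candidate structural motifs.  Venn region counts summarize how the
per-class distinct-key unions overlap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .keys import KeyVector

__all__ = [
    "HierarchyEntry",
    "HierarchyDataset",
    "common_keys",
    "common_key_percentage",
    "percentage_from_counts",
    "specific_keys",
    "venn_counts",
]


@dataclass
class HierarchyEntry:
    structure_id: str
    chain: str
    level1_class: str
    level2_group: str
    key_vector: KeyVector


@dataclass
class HierarchyDataset:
    """Structures annotated with a level-1 class and a level-2 group."""

    entries: list[HierarchyEntry] = field(default_factory=list)

    def __post_init__(self):
        group_owner: dict[str, str] = {}
        for e in self.entries:
            if not e.level1_class:
                raise ValueError(f"{e.structure_id}: empty level-1 class")
            owner = group_owner.setdefault(e.level2_group, e.level1_class)
            if owner != e.level1_class:
                raise ValueError(
                    f"level-2 group '{e.level2_group}' appears under both "
                    f"'{owner}' and '{e.level1_class}'"
                )

    def classes(self, level: int) -> list[str]:
        attr = "level1_class" if level == 1 else "level2_group"
        out: list[str] = []
        for e in self.entries:
            name = getattr(e, attr)
            if name not in out:
                out.append(name)
        return out

    def members(self, node: str) -> list[HierarchyEntry]:
        hits = [
            e for e in self.entries
            if node in (e.level1_class, e.level2_group)
        ]
        if not hits:
            raise ValueError(f"unknown hierarchy node '{node}'")
        return hits

    def non_members(self, node: str) -> list[HierarchyEntry]:
        return [
            e for e in self.entries
            if node not in (e.level1_class, e.level2_group)
        ]

    def to_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "structure_id": e.structure_id,
                    "chain": e.chain,
                    "level1": e.level1_class,
                    "level2": e.level2_group,
                }
                for e in self.entries
            ]
        )


def common_keys(members, weighted: bool = False):
    """Keys present in every member.

    Unweighted: a set of keys.  Weighted: a dict key → minimum
    occurrence frequency across members.
    """
    members = list(members)
    if not members:
        raise ValueError("need at least one member")
    shared = set(members[0].counts)
    for v in members[1:]:
        shared &= set(v.counts)
    if not weighted:
        return shared
    return {k: min(v.counts[k] for v in members) for k in shared}


def percentage_from_counts(n_common: int, n_total: int) -> float:
    """100 · common / total, reported to one decimal."""
    if n_total == 0:
        raise ValueError("empty key union")
    return round(100.0 * n_common / n_total, 1)


def common_key_percentage(members) -> float:
    """Percentage of distinct common keys among the union of distinct keys."""
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least two members")
    union: set[int] = set()
    for v in members:
        union |= set(v.counts)
    return percentage_from_counts(len(common_keys(members)), len(union))


def specific_keys(dataset: HierarchyDataset, node: str,
                  min_support: float = 1.0) -> set[int]:
    """Keys supported by ≥ ``min_support`` of the node's members and
    absent from every structure outside the node."""
    members = dataset.members(node)
    outside = dataset.non_members(node)
    if not outside:
        raise ValueError(f"node '{node}' has no outside structures")
    support: dict[int, int] = {}
    for e in members:
        for k in e.key_vector.counts:
            support[k] = support.get(k, 0) + 1
    needed = min_support * len(members)
    candidates = {k for k, c in support.items() if c >= needed}
    for e in outside:
        candidates -= set(e.key_vector.counts)
        if not candidates:
            break
    return candidates


def venn_counts(dataset: HierarchyDataset, level: int = 1) -> dict[frozenset, int]:
    """Distinct-key counts of every non-empty Venn region at a level.

    A key belongs to a class if any member has it (union over members).
    Regions are keyed by the frozenset of class names whose key unions
    contain — exclusively — the region's keys.
    """
    classes = dataset.classes(level)
    if not 2 <= len(classes) <= 5:
        raise ValueError(f"Venn analysis supports 2-5 classes, got {len(classes)}")
    unions = {
        c: set().union(*(set(e.key_vector.counts) for e in dataset.members(c)))
        for c in classes
    }
    regions: dict[frozenset, int] = {}
    for r in range(1, len(classes) + 1):
        for inside in itertools.combinations(classes, r):
            region = set.intersection(*(unions[c] for c in inside))
            for c in classes:
                if c not in inside:
                    region -= unions[c]
            if region:
                regions[frozenset(inside)] = len(region)
    return regions
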