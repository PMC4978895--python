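"""Complementation-group assembly from pairwise test outcomes.

Two recessive mutants define the same gene when their trans-heterozygote
shows the mutant phenotype (they *fail to complement*).  Groups are the
connected components of the fails-to-complement graph — not cliques, since
genetic practice never tests every pair: an untested pair within a
component is treated as uninformative, never as complementation.

The assembly audits its own consistency: a tested pair that complements
*inside* one component is a transitivity violation; a pair tested more than
once with conflicting outcomes is merged conservatively (fail to
complement) and reported; a component containing two different reference
testers is reported rather than silently fusing gene labels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .tables import ScreenTableError

__all__ = [
    "ComplementationTest",
    "GroupPartition",
    "assemble_groups",
    "group_sizes",
]


@dataclass(frozen=True)
class ComplementationTest:
    """One pairwise test; ``complements=True`` means wild-type trans-het
    (different genes)."""

    mutant_a: str
    mutant_b: str
    complements: bool

    def __post_init__(self) -> None:
        if self.mutant_a == self.mutant_b:
            raise ScreenTableError(f"self-test on {self.mutant_a!r}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.mutant_a, self.mutant_b))


@dataclass
class GroupPartition:
    """Disjoint isolate groups with gene labels and a consistency audit.

    ``groups[i]`` is a set of isolate/tester ids; ``labels[i]`` is the gene
    name of the reference tester the group contains, or ``"novel-<j>"``
    with novel groups numbered by decreasing size then lexicographically
    smallest member.  ``testers`` maps tester id -> gene name.
    """

    groups: list[frozenset[str]]
    labels: list[str]
    testers: dict[str, str] = field(default_factory=dict)
    anomalies: list[tuple[frozenset[str], str]] = field(default_factory=list)

    def label_of(self, isolate: str) -> str:
        for grp, label in zip(self.groups, self.labels):
            if isolate in grp:
                return label
        raise ScreenTableError(f"unknown isolate {isolate!r}")

    def members(self, label: str) -> frozenset[str]:
        for grp, lab in zip(self.groups, self.labels):
            if lab == label:
                return grp
        raise ScreenTableError(f"unknown group label {label!r}")


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}
        self.rank = {x: 0 for x in self.parent}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


def assemble_groups(
    isolates: Sequence[str],
    tests: Iterable[ComplementationTest],
    testers: Mapping[str, str] | None = None,
) -> GroupPartition:
    """Partition isolates into complementation groups.

    ``testers`` maps reference-tester ids to known gene names; testers are
    graph nodes like any isolate, and a group containing one is labelled
    with that tester's gene.  Untested isolates form singleton groups.
    """
    testers = dict(testers or {})
    nodes = list(dict.fromkeys(list(isolates) + list(testers)))
    known = set(nodes)
    tests = list(tests)
    for t in tests:
        for m in (t.mutant_a, t.mutant_b):
            if m not in known:
                raise ScreenTableError(f"test references unknown id {m!r}")

    anomalies: list[tuple[frozenset[str], str]] = []

    # conservative merge of duplicate tests: any recorded failure wins
    by_pair: dict[frozenset[str], bool] = {}
    for t in tests:
        prev = by_pair.get(t.pair)
        if prev is None:
            by_pair[t.pair] = t.complements
        elif prev != t.complements:
            by_pair[t.pair] = False
            anomalies.append((t.pair, "conflicting duplicate tests; merged as fail-to-complement"))

    uf = _UnionFind(nodes)
    for pair, complements in by_pair.items():
        if not complements:
            a, b = tuple(pair)
            uf.union(a, b)

    # transitivity audit: complementing pairs that ended up in one component
    for pair, complements in sorted(by_pair.items(), key=lambda kv: sorted(kv[0])):
        if complements:
            a, b = tuple(pair)
            if uf.find(a) == uf.find(b):
                anomalies.append(
                    (pair, "complementing pair joined through intermediates "
                           "(transitivity violation)")
                )

    comp: dict[str, set[str]] = {}
    for x in nodes:
        comp.setdefault(uf.find(x), set()).add(x)

    # deterministic order: decreasing non-tester size, then smallest member id
    def sort_key(members: set[str]):
        size = len([m for m in members if m not in testers])
        return (-size, min(members))

    ordered = sorted(comp.values(), key=sort_key)

    groups: list[frozenset[str]] = []
    labels: list[str] = []
    novel_idx = 0
    for members in ordered:
        grp_testers = sorted(m for m in members if m in testers)
        if len(grp_testers) > 1:
            anomalies.append(
                (frozenset(grp_testers),
                 "multiple reference testers in one group: "
                 + ", ".join(f"{t} ({testers[t]})" for t in grp_testers))
            )
        if grp_testers:
            label = testers[grp_testers[0]]
        else:
            novel_idx += 1
            label = f"novel-{novel_idx}"
        groups.append(frozenset(members))
        labels.append(label)
    return GroupPartition(groups=groups, labels=labels, testers=testers, anomalies=anomalies)


def group_sizes(partition: GroupPartition) -> dict[str, int]:
    """Allele count per group label (reference testers are not alleles)."""
    out: dict[str, int] = {}
    for grp, label in zip(partition.groups, partition.labels):
        out[label] = len([m for m in grp if m not in partition.testers])
    return out
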