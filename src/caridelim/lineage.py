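"""Lineage partitioning and intra-/inter-lineage distance summaries.

The primary partitioning path is *supervised*: lineage labels come from
specimen metadata (species/lineage assignments). An unsupervised fallback is
provided by :func:`upgma` + :func:`cut_tree` — a clock-consistent hierarchical
clusterer, deliberately lightweight and clearly not a substitute for full
phylogenetic inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .sitestats import DistanceMatrix


@dataclass(frozen=True)
class ClusterNode:
    """Node of an ultrametric cluster tree; ``height`` is divergence/2 units."""

    height: float
    name: str | None = None
    children: tuple["ClusterNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class ClusterTree:
    """Rooted ultrametric tree over the distance-matrix labels."""

    root: ClusterNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)

        def build(node: ClusterNode, parent_height: float) -> dendropy.Node:
            dnode = dendropy.Node()
            dnode.edge.length = parent_height - node.height
            if node.is_leaf:
                dnode.taxon = taxa.require_taxon(label=node.name)
            for child in node.children:
                dnode.add_child(build(child, node.height))
            return dnode

        tree.seed_node = build(self.root, self.root.height)
        tree.seed_node.edge.length = None
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


@dataclass(frozen=True)
class LineagePartition:
    """Assignment of every sequence id to exactly one lineage label."""

    assignment: dict[str, str]
    source: str = "predefined"  # or "tree-cut"

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("partition must assign at least one id")

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for i, g in self.assignment.items():
            out.setdefault(g, []).append(i)
        return {g: sorted(m) for g, m in sorted(out.items())}


@dataclass(frozen=True)
class SummaryCell:
    """min/mean/max over one set of pairwise distances; undefined for <1 pair."""

    min: float | None
    mean: float | None
    max: float | None
    n_comparisons: int

    @classmethod
    def from_values(cls, vals: list[float]) -> "SummaryCell":
        if not vals:
            return cls(None, None, None, 0)
        return cls(float(np.min(vals)), float(np.mean(vals)), float(np.max(vals)), len(vals))


@dataclass(frozen=True)
class PartitionSummary:
    """Per-group intra and per-pair inter distance summaries (the barcode-gap surface)."""

    intra: dict[str, SummaryCell] = field(default_factory=dict)
    inter: dict[tuple[str, str], SummaryCell] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for g, cell in sorted(self.intra.items()):
            rows.append(("intra", g, "", cell.min, cell.mean, cell.max, cell.n_comparisons))
        for (g, h), cell in sorted(self.inter.items()):
            rows.append(("inter", g, h, cell.min, cell.mean, cell.max, cell.n_comparisons))
        return pd.DataFrame(
            rows, columns=["kind", "group1", "group2", "min", "mean", "max", "n"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intra": {g: vars(c) for g, c in self.intra.items()},
            "inter": {f"{g}|{h}": vars(c) for (g, h), c in self.inter.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def partition_from_groups(groups: Mapping[str, str]) -> LineagePartition:
    """Supervised partition from metadata ``id -> lineage label`` (the primary path)."""
    return LineagePartition(assignment=dict(groups), source="predefined")


def upgma(dm: DistanceMatrix) -> ClusterTree:
    """Unweighted pair-group agglomeration with average linkage.

    Node height is half the joining distance (so leaf-to-leaf path spans the
    distance). Ties are broken by the lexicographically smallest member-id
    pair, making the output deterministic.
    """
    if len(dm.labels) < 2:
        raise ValueError("UPGMA requires at least two labels")
    if np.any(np.isnan(dm.values)) or np.any(dm.values < 0):
        raise ValueError("distance matrix contains NaN or negative entries")

    # active clusters: key -> (node, member index list, smallest member label)
    nodes: dict[int, ClusterNode] = {
        k: ClusterNode(height=0.0, name=lab) for k, lab in enumerate(dm.labels)
    }
    members: dict[int, list[int]] = {k: [k] for k in range(len(dm.labels))}
    minlabel: dict[int, str] = {k: lab for k, lab in enumerate(dm.labels)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(dm.labels)):
        for j in range(i + 1, len(dm.labels)):
            dist[(i, j)] = float(dm.values[i, j])

    next_key = len(dm.labels)
    while len(nodes) > 1:
        # minimum joining distance; ties broken by the lexicographically
        # smallest (minlabel_i, minlabel_j) pair
        best_pair = min(
            dist,
            key=lambda ij: (
                dist[ij],
                tuple(sorted((minlabel[ij[0]], minlabel[ij[1]]))),
            ),
        )
        i, j = best_pair
        d_join = dist[best_pair]
        ci, cj = sorted((nodes[i], nodes[j]), key=lambda n: min(n.leaves()))
        new_node = ClusterNode(height=d_join / 2.0, children=(ci, cj))
        ni, nj = len(members[i]), len(members[j])
        new_members = members[i] + members[j]

        new_dists = {}
        for k in nodes:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new_dists[tuple(sorted((next_key, k)))] = (ni * dik + nj * djk) / (ni + nj)

        for k in (i, j):
            del nodes[k], members[k], minlabel[k]
        dist = {
            (a, b): v for (a, b), v in dist.items() if a in nodes and b in nodes
        }
        dist.update(new_dists)
        nodes[next_key] = new_node
        members[next_key] = new_members
        minlabel[next_key] = min(new_node.leaves())
        next_key += 1

    return ClusterTree(root=next(iter(nodes.values())))


def cut_tree(tree: ClusterTree, height: float) -> LineagePartition:
    """Cut the ultrametric tree at ``height``; connected leaf sets below become groups.

    Groups are labelled ``group1..groupK`` ordered by their smallest member id.
    A cut above the root yields a single group; a cut at 0 yields singletons
    (assuming distinct leaves join above height 0).
    """
    if height < 0:
        raise ValueError("cut height must be non-negative")

    clusters: list[list[str]] = []

    def descend(node: ClusterNode) -> None:
        if node.height <= height:
            clusters.append(sorted(node.leaves()))
        else:
            for child in node.children:
                descend(child)

    descend(tree.root)
    clusters.sort(key=lambda c: c[0])
    assignment = {
        leaf: f"group{k + 1}" for k, cluster in enumerate(clusters) for leaf in cluster
    }
    return LineagePartition(assignment=assignment, source="tree-cut")


def summarize_distances(dm: DistanceMatrix, part: LineagePartition) -> PartitionSummary:
    """Exact min/mean/max of intra-group and cross-group pairwise distances.

    Intra cells for singleton groups are flagged undefined (``None``), never
    zero. Means are unweighted arithmetic means over pairs.
    """
    missing = [lab for lab in dm.labels if lab not in part.assignment]
    if missing:
        raise ValueError(f"partition does not cover labels: {missing}")
    groups = {
        g: [m for m in members if m in dm.labels] for g, members in part.groups().items()
    }
    empty = [g for g, m in groups.items() if not m]
    if empty:
        raise ValueError(f"groups with no members in the matrix: {empty}")

    idx = {lab: k for k, lab in enumerate(dm.labels)}
    intra: dict[str, SummaryCell] = {}
    for g, mem in groups.items():
        vals = [
            float(dm.values[idx[a], idx[b]])
            for ai, a in enumerate(mem)
            for b in mem[ai + 1:]
        ]
        intra[g] = SummaryCell.from_values(vals)

    inter: dict[tuple[str, str], SummaryCell] = {}
    names = sorted(groups)
    for gi, g in enumerate(names):
        for h in names[gi + 1:]:
            vals = [
                float(dm.values[idx[a], idx[b]]) for a in groups[g] for b in groups[h]
            ]
            inter[(g, h)] = SummaryCell.from_values(vals)
    return PartitionSummary(intra=intra, inter=inter)
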