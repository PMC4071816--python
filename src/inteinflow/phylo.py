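"""Tree-based analyses of intein distribution.

Presence-absence characters are mapped onto a reference phylogeny with
minimum-change (Fitch/Sankoff) parsimony; an allele compatible with a
single gain and no loss is treated as vertically inherited.  Monophyly of
a focal leaf set (here: the halobacterial sequences in an allele tree) is
decided on the unrooted tree via split compatibility, so polytomies —
including those produced by collapsing weakly supported nodes — are
treated permissively: a polytomy does not break monophyly if some
resolution of it yields the focal|rest split.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy


@dataclass
class PhyloConfig:
    """support_threshold: bootstrap value below which nodes are collapsed;
    vertical_max_events: maximum parsimony changes consistent with vertical
    inheritance (a single gain)."""

    support_threshold: float = 70.0
    vertical_max_events: int = 1

    def __post_init__(self):
        if not 0 <= self.support_threshold <= 100:
            raise ValueError("support_threshold must lie in [0, 100]")


@dataclass
class MonophylyResult:
    classification: str  # "monophyletic" | "polyphyletic"
    interrupting_labels: list[str] = field(default_factory=list)
    interrupting_group: str = "none"
    degenerate: bool = False

    @property
    def is_monophyletic(self) -> bool:
        return self.classification == "monophyletic"


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _node_support(node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except (TypeError, ValueError):
        return None


def collapse_low_support(tree: dendropy.Tree, threshold: float = 70.0) -> dendropy.Tree:
    """Contract internal edges whose child-node support is below ``threshold``.

    Nodes without a numeric support label are kept.  The leaf set is
    unchanged; the result may be multifurcating.  Operates on a clone.
    """
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = _node_support(node)
        if sup is not None and sup < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


def _splits(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Non-trivial bipartitions as the leaf set under each internal edge."""
    all_leaves = frozenset(leaf_labels(tree))
    splits = []
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
            if node.parent_node is not None:
                side = below[node]
                if 1 < len(side) < len(all_leaves) - 1:
                    splits.append(side)
    return splits


def _compatible(split_a: frozenset, focal: frozenset, universe: frozenset) -> bool:
    """Two unrooted splits are compatible iff one of the four intersections is empty."""
    b = universe - split_a
    cofocal = universe - focal
    return (not (split_a & focal) or not (split_a & cofocal)
            or not (b & focal) or not (b & cofocal))


def monophyly_class(tree: dendropy.Tree, focal: Iterable[str],
                    groups: Mapping[str, str] | None = None) -> MonophylyResult:
    """Classify a focal leaf set as monophyletic or polyphyletic (unrooted).

    Monophyletic iff the focal|rest split is compatible with every split of
    the tree — i.e., some resolution of the (possibly multifurcating) tree
    contains an edge separating exactly the focal leaves.  Otherwise the
    interrupting taxa are the non-focal leaves inside the subtree spanned
    by the focal leaves (computed after rooting at the lexicographically
    smallest non-focal leaf, which makes the report independent of the
    input rooting), and ``interrupting_group`` is their majority group
    annotation (ties report all tied groups, '+'-joined).
    """
    focal = frozenset(focal)
    universe = frozenset(leaf_labels(tree))
    if not focal:
        raise ValueError("focal set is empty")
    if not focal <= universe:
        raise ValueError(f"focal leaves not in tree: {sorted(focal - universe)}")
    if len(universe) < 3:
        raise ValueError("monophyly requires at least 3 leaves")
    if focal == universe:
        return MonophylyResult("monophyletic", degenerate=True)

    if all(_compatible(s, focal, universe) for s in _splits(tree)):
        return MonophylyResult("monophyletic")

    outgroup = min(universe - focal)
    rooted = tree.clone(depth=1)
    og_node = next(lf for lf in rooted.leaf_node_iter() if lf.taxon.label == outgroup)
    rooted.reroot_at_edge(og_node.edge, update_bipartitions=False)
    # MRCA of focal leaves in the outgroup-rooted tree; interrupting taxa
    # are the non-focal leaves under it.
    below: dict = {}
    mrca = None
    for node in rooted.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if focal <= below[node] and mrca is None:
            mrca = node
    interrupting = sorted(below[mrca] - focal)
    group_label = "none"
    if groups is not None and interrupting:
        counts = Counter(groups.get(lbl, "unannotated") for lbl in interrupting)
        top = max(counts.values())
        tied = sorted(g for g, c in counts.items() if c == top)
        group_label = "+".join(tied)
    return MonophylyResult("polyphyletic", interrupting_labels=interrupting,
                           interrupting_group=group_label)


def fitch_events(tree: dendropy.Tree, character: Mapping[str, int]) -> int:
    """Minimum number of 0/1 state changes required on the tree.

    Unit-cost Sankoff dynamic programming, invariant under rerooting.
    Polytomies are treated as soft (unresolved uncertainty, e.g. from
    collapsing weakly supported nodes): the count is the minimum over all
    binary resolutions, so contracting an edge can never increase it.
    For a binary character this minimum has a closed form at a polytomy:
    every child subtree pays its own minimum, plus one change if any
    child strictly prefers the state opposite the node's (all such
    children can be bundled under a single new edge).  Leaves absent from
    ``character`` (missing data) are pruned before counting.
    """
    retained = [lbl for lbl in leaf_labels(tree) if lbl in character]
    if len(retained) < 2:
        raise ValueError("fitch_events requires the character on >= 2 retained leaves")
    work = tree.clone(depth=1)
    if len(retained) < len(leaf_labels(work)):
        taxa = [lf.taxon for lf in work.leaf_node_iter() if lf.taxon.label in character]
        work.retain_taxa(taxa)

    def combine(children, soft: bool) -> list[float]:
        if soft:
            total_min = sum(min(cost[c]) for c in children)
            return [
                total_min + (1 if any(cost[c][1 - s] < cost[c][s]
                                      for c in children) else 0)
                for s in (0, 1)
            ]
        return [
            sum(min(cost[c][sp] + (0 if sp == s else 1) for sp in (0, 1))
                for c in children)
            for s in (0, 1)
        ]

    cost: dict = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            obs = character[node.taxon.label]
            cost[node] = [0.0 if s == obs else math.inf for s in (0, 1)]
            continue
        children = node.child_nodes()
        if len(children) == 1:  # unifurcation from pruning: pass through
            cost[node] = cost[children[0]]
            continue
        # a true polytomy has unrooted degree >= 4: >= 3 children for an
        # internal node with a parent, >= 4 children at the seed (a
        # trifurcating seed is just an unrooted binary node)
        at_seed = node.parent_node is None
        soft = len(children) >= (4 if at_seed else 3)
        cost[node] = combine(children, soft)
    return int(min(cost[work.seed_node]))


def vertical_compatibility(tree: dendropy.Tree, profile,
                           config: PhyloConfig | None = None
                           ) -> tuple[dict[str, bool], float]:
    """Per-allele test of concordance with the reference phylogeny.

    An allele is vertically compatible when its presence character maps
    onto the tree with at most ``vertical_max_events`` parsimony changes
    (a single gain and no loss, by default).  Returns the per-allele map
    and the overall fraction compatible.
    """
    config = config or PhyloConfig()
    tree_leaves = set(leaf_labels(tree))
    missing = set(profile.genomes) - tree_leaves
    if missing:
        raise ValueError(f"profile genomes not on tree: {sorted(missing)}")
    out: dict[str, bool] = {}
    for allele in profile.alleles:
        char = profile.presence_character(allele)
        if len(char) < 2 or len(set(char.values())) == 1:
            # constant (or near-empty) characters need no change
            out[allele] = True
            continue
        out[allele] = fitch_events(tree, char) <= config.vertical_max_events
    frac = sum(out.values()) / len(out) if out else float("nan")
    return out, frac


def shared_alleles(profile, members: Iterable[str], strict: bool = True) -> int:
    """Number of alleles carried (mini or large) by every member genome.

    In strict mode a MISSING cell disqualifies the allele; in lenient mode
    MISSING cells are ignored provided every non-missing member carries it
    (and at least one member does).
    """
    members = list(members)
    unknown = [m for m in members if m not in profile.genomes]
    if unknown:
        raise ValueError(f"unknown genome(s): {unknown}")
    if len(members) < 2:
        raise ValueError("shared_alleles requires >= 2 member genomes")
    from .states import State

    count = 0
    for a in profile.alleles:
        states = [profile.state(m, a) for m in members]
        if strict:
            if all(s.present for s in states):
                count += 1
        else:
            non_missing = [s for s in states if s is not State.MISSING]
            if non_missing and all(s.present for s in non_missing):
                count += 1
    return count
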