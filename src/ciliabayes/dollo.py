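"""Dollo-parsimony reconstruction and differential Dollo parsimony (DDP).

Under Dollo parsimony a binary trait (ortholog presence) is gained exactly
once on the species tree and may subsequently be lost any number of times.
For a given rooted tree and presence/absence profile the most parsimonious
reconstruction is unique:

* the gain sits on the branch above the last common ancestor of all
  species carrying the trait;
* the losses sit on the maximal subtrees below the gain that contain no
  carrier.

Two genes co-evolve when their reconstructed event sets coincide. The
differential Dollo parsimony of two profiles is the size of the symmetric
difference of their event sets, events being (branch, gain|loss) pairs
with branches identified by the set of leaves they subtend. A perfectly
matched profile pair has DDP 0; every gain or loss present in one
reconstruction but not the other adds 1. Comparing each gene's profile
against the organelle's own presence/absence profile and thresholding the
DDP yields a two-bin categorical evidence column for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

__all__ = [
    "SpeciesTree",
    "DolloReconstruction",
    "DdpResult",
    "infer_dollo_events",
    "ddp",
    "ddp_table",
    "ddp_against_reference",
    "replay_events",
]

Event = tuple[frozenset, str]  # (subtended leaf set, "gain" | "loss")


class SpeciesTree:
    """Rooted species tree with uniquely named leaves.

    Internal nodes are identified by the set of leaf names they subtend,
    which makes event sets invariant under child reordering.
    Multifurcations are allowed; a root with fewer than two children is
    rejected (the tree would be effectively unrooted or trivial).
    """

    def __init__(self, tree: dendropy.Tree):
        root = tree.seed_node
        if len(root.child_nodes()) < 2:
            raise ValueError(
                "tree root has fewer than 2 children; supply a rooted tree"
            )
        self._children: dict[frozenset, list[frozenset]] = {}
        self._parent: dict[frozenset, frozenset | None] = {}
        self.leaves: list[str] = []

        def build(node) -> frozenset:
            kids = node.child_nodes()
            if not kids:
                name = node.taxon.label if node.taxon else node.label
                if name is None:
                    raise ValueError("unnamed leaf in tree")
                clade = frozenset([name])
                self.leaves.append(name)
                self._children[clade] = []
                return clade
            child_clades = [build(k) for k in kids]
            if len(child_clades) < 2:
                # unifurcation: collapse silently
                return child_clades[0]
            clade = frozenset().union(*child_clades)
            self._children[clade] = child_clades
            for c in child_clades:
                self._parent[c] = clade
            return clade

        self.root: frozenset = build(root)
        self._parent[self.root] = None
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("leaf names are not unique")
        self.leaves.sort()

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as err:
            raise ValueError(f"could not parse Newick tree: {err}") from err
        return cls(tree)

    def children(self, clade: frozenset) -> list[frozenset]:
        return self._children[clade]

    def postorder(self):
        """Clades in postorder (children before parents)."""
        stack = [(self.root, False)]
        while stack:
            clade, done = stack.pop()
            if done:
                yield clade
            else:
                stack.append((clade, True))
                for c in self._children[clade]:
                    stack.append((c, False))

    def validate_profile(self, profile: dict) -> None:
        missing = [l for l in self.leaves if l not in profile]
        extra = [s for s in profile if frozenset([s]) not in self._children]
        if missing or extra:
            raise ValueError(
                f"profile/tree mismatch: missing leaves {missing}, "
                f"unknown species {extra}"
            )
        bad = {s: v for s, v in profile.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"non-binary presence calls: {bad}")


def _tree_arrays(tree: SpeciesTree):
    """Integer-indexed tree structure cached on the SpeciesTree instance.

    Returns (nodes, parent, depth, leaf_node_index) where ``nodes`` lists
    clades in postorder, ``parent[i]`` is the postorder index of node i's
    parent (-1 for the root), ``depth[i]`` its root distance, and
    ``leaf_node_index`` maps each leaf name to its node index.
    """
    cached = getattr(tree, "_arrays_cache", None)
    if cached is not None:
        return cached
    import numpy as np

    nodes = list(tree.postorder())
    idx = {clade: i for i, clade in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    depth = np.zeros(len(nodes), dtype=np.int64)
    for clade in nodes:
        for c in tree.children(clade):
            parent[idx[c]] = idx[clade]
    # depths: root has depth 0; process preorder (reverse postorder)
    for clade in reversed(nodes):
        i = idx[clade]
        if parent[i] >= 0:
            depth[i] = depth[parent[i]] + 1
    leaf_node_index = {l: idx[frozenset([l])] for l in tree.leaves}
    cached = (nodes, parent, depth, leaf_node_index)
    tree._arrays_cache = cached
    return cached


def ddp_against_reference(tree: SpeciesTree, profiles, reference: dict):
    """Vectorized DDP of many gene profiles against one reference profile.

    Parameters
    ----------
    tree : SpeciesTree
    profiles : pandas.DataFrame
        Genes in rows, species (tree leaves) in columns, 0/1 entries.
    reference : dict
        Leaf name -> 0/1 organelle presence.

    Returns
    -------
    numpy.ndarray of int
        One DDP value per profile row, identical to calling
        :func:`ddp` gene by gene.
    """
    import numpy as np
    import pandas as pd

    nodes, parent, depth, leaf_idx = _tree_arrays(tree)
    n_nodes = len(nodes)
    profiles = profiles[tree.leaves]
    P = profiles.to_numpy(dtype=np.int64)
    n_genes = P.shape[0]

    def node_stats(mat):
        """present_below counts per node, postorder accumulation."""
        cnt = np.zeros((mat.shape[0], n_nodes), dtype=np.int64)
        for leaf, j in leaf_idx.items():
            cnt[:, j] = mat[:, tree.leaves.index(leaf)]
        for i in range(n_nodes):  # postorder: children precede parents
            if parent[i] >= 0:
                cnt[:, parent[i]] += cnt[:, i]
        return cnt

    def events(mat):
        cnt = node_stats(mat)
        total = cnt[:, -1]  # root is last in postorder
        has_any = total > 0
        # origin: deepest node holding all carriers
        full = cnt == total[:, None]
        key = np.where(full, depth[None, :], -1)
        origin = np.argmax(key, axis=1)
        origin[~has_any] = -1
        # losses: empty child whose parent is inside the origin subtree
        par_cnt = np.where(parent[None, :] >= 0, cnt[:, parent], 0)
        par_is_origin = parent[None, :] == origin[:, None]
        par_in_subtree = (par_cnt < total[:, None]) | par_is_origin
        losses = (
            (cnt == 0)
            & (par_cnt > 0)
            & par_in_subtree
            & (parent[None, :] >= 0)
            & has_any[:, None]
        )
        return origin, losses

    ref_mat = pd.DataFrame([reference])[tree.leaves].to_numpy(dtype=np.int64)
    ref_origin, ref_losses = events(ref_mat)
    g_origin, g_losses = events(P)

    loss_diff = (g_losses != ref_losses[0][None, :]).sum(axis=1)
    gain_diff = np.where(
        g_origin == ref_origin[0],
        0,
        (g_origin >= 0).astype(np.int64) + int(ref_origin[0] >= 0),
    )
    return (loss_diff + gain_diff).astype(int)


@dataclass(frozen=True)
class DolloReconstruction:
    """Single-gain / multiple-loss reconstruction of a binary profile.

    ``origin`` is the branch (identified by the clade below it) carrying
    the gain, or ``None`` for an all-absent profile; ``losses`` are the
    branches of the maximal trait-free subtrees below the origin.
    """

    origin: frozenset | None
    losses: frozenset

    @property
    def events(self) -> frozenset:
        ev = set()
        if self.origin is not None:
            ev.add((self.origin, "gain"))
        for b in self.losses:
            ev.add((b, "loss"))
        return frozenset(ev)

    @property
    def n_events(self) -> int:
        return (self.origin is not None) + len(self.losses)


def infer_dollo_events(tree: SpeciesTree, profile: dict) -> DolloReconstruction:
    """Most parsimonious Dollo reconstruction of ``profile`` on ``tree``.

    Parameters
    ----------
    tree : SpeciesTree
    profile : dict
        Mapping of every leaf name to 0/1 presence.
    """
    tree.validate_profile(profile)
    present_below: dict[frozenset, int] = {}
    for clade in tree.postorder():
        kids = tree.children(clade)
        if not kids:
            (leaf,) = clade
            present_below[clade] = int(profile[leaf])
        else:
            present_below[clade] = sum(present_below[c] for c in kids)
    if present_below[tree.root] == 0:
        return DolloReconstruction(origin=None, losses=frozenset())
    # origin: walk down from the root while exactly one child holds all carriers
    origin = tree.root
    total = present_below[origin]
    while True:
        kids = tree.children(origin)
        carriers = [c for c in kids if present_below[c] > 0]
        if len(carriers) == 1 and present_below[carriers[0]] == total:
            origin = carriers[0]
        else:
            break
    # losses: maximal empty subtrees strictly below the origin
    losses: set[frozenset] = set()
    stack = [origin]
    while stack:
        clade = stack.pop()
        for c in tree.children(clade):
            if present_below[c] == 0:
                losses.add(c)
            elif tree.children(c):
                stack.append(c)
    return DolloReconstruction(origin=origin, losses=frozenset(losses))


def replay_events(tree: SpeciesTree, rec: DolloReconstruction) -> dict:
    """Replay a gain-then-losses reconstruction into a leaf profile.

    Used as the round-trip check: replaying ``infer_dollo_events``'s output
    must reproduce the input profile bit-exactly.
    """
    profile = {l: 0 for l in tree.leaves}
    if rec.origin is None:
        return profile
    lost = set(rec.losses)

    def paint(clade: frozenset, state: int) -> None:
        state = 0 if clade in lost else state
        kids = tree.children(clade)
        if not kids:
            (leaf,) = clade
            profile[leaf] = state
        for c in kids:
            paint(c, state)

    paint(rec.origin, 1)
    return profile


def ddp(tree: SpeciesTree, profile_a: dict, profile_b: dict) -> int:
    """Differential Dollo parsimony between two profiles on the same tree.

    The number of (branch, gain/loss) events present in exactly one of the
    two reconstructions — 0 for perfectly co-evolving profiles.
    """
    ea = infer_dollo_events(tree, profile_a).events
    eb = infer_dollo_events(tree, profile_b).events
    return len(ea ^ eb)


@dataclass(frozen=True)
class DdpResult:
    gene: str
    ddp: int
    category: str


def ddp_table(
    tree: SpeciesTree,
    profiles: dict,
    reference: dict,
    threshold: int,
    low_label: str | None = None,
    high_label: str | None = None,
) -> list[DdpResult]:
    """DDP of every gene's profile against the reference organelle profile.

    Genes with ``ddp <= threshold`` (boundary inclusive) get the low-bin
    label — the co-evolving category fed to the classifier.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    low = low_label if low_label is not None else f"DDP<={threshold}"
    high = high_label if high_label is not None else f"DDP>{threshold}"
    ref_events = infer_dollo_events(tree, reference).events
    out = []
    for gene, prof in profiles.items():
        ev = infer_dollo_events(tree, prof).events
        d = len(ev ^ ref_events)
        out.append(DdpResult(gene=gene, ddp=d, category=low if d <= threshold else high))
    return out
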