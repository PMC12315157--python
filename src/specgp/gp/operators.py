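"""Typed variation operators: tournament selection, subtree crossover,
and the 75/25 non-leaf/leaf mutation.

Only non-leaf nodes are valid crossover points (most nodes are parameter
leaves, so leaf swaps would carry almost no variation). Offspring that
would exceed the structure's depth cap are rejected and the crossover
retried a bounded number of times before the parents are returned
unchanged.
"""

from __future__ import annotations

import numpy as np

from .primitives import GPType, PrimitiveSet
from .tree import Node, ProgramTree, generate_subtree, generate_tree

__all__ = ["tournament_select", "crossover", "mutate"]

MAX_CROSSOVER_ATTEMPTS = 5
#: Probability that mutation targets a non-leaf (internal) node.
MUTATE_INTERNAL_P = 0.75


def tournament_select(population: list, k: int, rng: np.random.Generator, maximize: bool = True):
    """Best of ``k`` uniform draws with replacement; ties favour the
    smaller tree."""
    if not population:
        raise ValueError("empty population")
    picks = [population[int(rng.integers(len(population)))] for _ in range(k)]
    sign = 1.0 if maximize else -1.0
    return max(picks, key=lambda ind: (sign * ind.fitness, -ind.tree.size()))


def _internal_points(tree: ProgramTree) -> list[tuple[Node, Node | None, int, int]]:
    """All non-leaf nodes as (node, parent, child_index, depth)."""
    points: list[tuple[Node, Node | None, int, int]] = []

    def walk(node: Node, parent: Node | None, idx: int, depth: int) -> None:
        if not node.is_leaf:
            points.append((node, parent, idx, depth))
            for i, c in enumerate(node.children):
                walk(c, node, i, depth + 1)

    walk(tree.root, None, -1, 0)
    return points


def _replace(tree: ProgramTree, parent: Node | None, idx: int, new: Node) -> None:
    if parent is None:
        tree.root = new
    else:
        parent.children[idx] = new


def crossover(
    parent_a: ProgramTree,
    parent_b: ProgramTree,
    pset: PrimitiveSet,
    rng: np.random.Generator,
) -> tuple[ProgramTree, ProgramTree]:
    """Swap subtrees rooted at two type-matching non-leaf nodes.

    A swap into the root position must itself be a legal root primitive.
    After ``MAX_CROSSOVER_ATTEMPTS`` failed attempts (no compatible pair,
    depth violation) the parents are returned unchanged (as clones).
    """
    if parent_a.structure != parent_b.structure:
        raise ValueError("crossover requires parents of the same structure")
    for _ in range(MAX_CROSSOVER_ATTEMPTS):
        child_a, child_b = parent_a.clone(), parent_b.clone()
        pts_a = _internal_points(child_a)
        node_a, par_a, idx_a, depth_a = pts_a[int(rng.integers(len(pts_a)))]
        compatible = [
            pt
            for pt in _internal_points(child_b)
            if pt[0].ret_type == node_a.ret_type
            # a subtree moving into a root slot must be a legal root
            and (par_a is not None or pt[0].primitive.name in pset.root_names)
            and (pt[1] is not None or node_a.primitive.name in pset.root_names)
        ]
        if not compatible:
            continue
        node_b, par_b, idx_b, depth_b = compatible[int(rng.integers(len(compatible)))]
        _replace(child_a, par_a, idx_a, node_b)
        _replace(child_b, par_b, idx_b, node_a)
        if (
            child_a.height() <= pset.max_depth
            and child_b.height() <= pset.max_depth
        ):
            return child_a, child_b
    return parent_a.clone(), parent_b.clone()


def mutate(
    tree: ProgramTree, pset: PrimitiveSet, rng: np.random.Generator
) -> ProgramTree:
    """Mutate one node: non-leaf with probability 0.75 (subtree regrown in
    place within the depth budget), else a parameter leaf is re-sampled
    from its terminal range."""
    child = tree.clone()
    leaves = [
        (node, parent, idx)
        for node, parent, idx, _ in _all_points(child)
        if node.is_leaf and node.value is not None
    ]
    internal = _internal_points(child)
    pick_internal = rng.random() < MUTATE_INTERNAL_P or not leaves
    if pick_internal:
        node, parent, idx, depth = internal[int(rng.integers(len(internal)))]
        if parent is None:
            return generate_tree(pset, "grow", (pset.init_depth[0], pset.max_depth), rng)
        budget = pset.max_depth - depth
        new = generate_subtree(pset, node.ret_type, budget, rng, "grow")
        parent.children[idx] = new
    else:
        node, parent, idx = leaves[int(rng.integers(len(leaves)))]
        node.value = pset.terminals[node.terminal_type].sampler(rng)
    return child


def _all_points(tree: ProgramTree) -> list[tuple[Node, Node | None, int, int]]:
    points: list[tuple[Node, Node | None, int, int]] = []

    def walk(node: Node, parent: Node | None, idx: int, depth: int) -> None:
        points.append((node, parent, idx, depth))
        for i, c in enumerate(node.children):
            walk(c, node, i, depth + 1)

    walk(tree.root, None, -1, 0)
    return points
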