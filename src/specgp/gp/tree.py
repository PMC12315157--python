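"""Program trees: typed generation, validation, evaluation.

Trees are generated by *ramped half-and-half* under per-type height
budgets: at every node only primitives whose arguments can still be
completed within the remaining height are candidates, which forces each
branch to transition toward terminals before the depth cap. The *full*
method additionally requires every data-flow branch to terminate at one
sampled target depth — which is exactly why primitives consuming the raw
input (an interval selection on the input spectrum, say) are only placed
at ``target - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from ..cube import HyperspectralCube, ReflectanceSpectrum
from .primitives import DATA_TYPES, GPType, Primitive, PrimitiveSet

__all__ = [
    "Node",
    "ProgramTree",
    "generate_tree",
    "generate_subtree",
    "evaluate_tree",
    "evaluate_batch",
    "tree_from_dict",
]

#: Probability of closing a data-type branch with a terminal during grow,
#: once the minimum depth has been reached and a terminal is available.
GROW_TERMINAL_P = 0.35


@dataclass
class Node:
    """One tree node: a primitive with children, or a leaf.

    Leaves are either the tree input (``value is None``) or a parameter
    constant (``value`` holds the sampled constant).
    """

    primitive: Primitive | None = None
    children: list["Node"] = field(default_factory=list)
    terminal_type: GPType | None = None
    value: object = None

    @property
    def is_leaf(self) -> bool:
        return self.primitive is None

    @property
    def ret_type(self) -> GPType:
        return self.terminal_type if self.is_leaf else self.primitive.ret

    def height(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.height() for c in self.children)

    def size(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + sum(c.size() for c in self.children)

    def clone(self) -> "Node":
        return Node(
            self.primitive,
            [c.clone() for c in self.children],
            self.terminal_type,
            self.value,
        )

    def iter_nodes(self, depth: int = 0) -> Iterator[tuple["Node", int]]:
        """Yield (node, depth) pairs in pre-order."""
        yield self, depth
        for c in self.children:
            yield from c.iter_nodes(depth + 1)

    def to_sexpr(self) -> str:
        if self.is_leaf:
            if self.value is None:
                return "x"
            if isinstance(self.value, float):
                return f"{self.terminal_type.value}={self.value:.4g}"
            return f"{self.terminal_type.value}={self.value}"
        return f"{self.primitive.name}({', '.join(c.to_sexpr() for c in self.children)})"

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"terminal": self.terminal_type.value, "value": self.value}
        return {
            "primitive": self.primitive.name,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class ProgramTree:
    """A typed feature-extraction program with its structure tag."""

    root: Node
    structure: str  # "spectra" | "image"

    def height(self) -> int:
        return self.root.height()

    def size(self) -> int:
        return self.root.size()

    def clone(self) -> "ProgramTree":
        return ProgramTree(self.root.clone(), self.structure)

    def to_sexpr(self) -> str:
        return self.root.to_sexpr()

    def to_dict(self) -> dict:
        return {"structure": self.structure, "root": self.root.to_dict()}

    def type_check(self, pset: PrimitiveSet) -> bool:
        """Verify type correctness, depth legality and the root rule."""
        if self.root.is_leaf or self.root.primitive.name not in pset.root_names:
            return False
        if self.root.ret_type != GPType.FV:
            return False
        if self.height() > pset.max_depth:
            return False
        ok = True
        for node, _ in self.root.iter_nodes():
            if node.is_leaf:
                if node.value is None and node.terminal_type != pset.input_type:
                    ok = False
                continue
            if len(node.children) != node.primitive.arity:
                ok = False
                continue
            for child, want in zip(node.children, node.primitive.args):
                if child.ret_type != want:
                    ok = False
        return ok


def _make_leaf(pset: PrimitiveSet, t: GPType, rng: np.random.Generator) -> Node:
    if t == pset.input_type:
        return Node(terminal_type=t, value=None)
    spec = pset.terminals.get(t)
    if spec is None:
        raise ValueError(f"type {t} has no terminal in this structure")
    return Node(terminal_type=t, value=spec.sampler(rng))


def _gen_full(
    pset: PrimitiveSet, t: GPType, depth: int, target: int, rng: np.random.Generator
) -> Node:
    remaining = target - depth
    if t not in DATA_TYPES or remaining <= 0:
        if pset.has_terminal(t):
            return _make_leaf(pset, t, rng)
        raise ValueError(f"cannot terminate type {t} at depth {depth}")
    # every data argument must be completable at exactly remaining-1
    candidates = [
        p
        for p in pset.by_ret(t)
        if all(
            pset.can_reach(a, remaining - 1) for a in p.args if a in DATA_TYPES
        )
    ]
    if not candidates:
        if pset.has_terminal(t) and pset.can_reach(t, 0):
            return _make_leaf(pset, t, rng)
        raise ValueError(f"no full-method candidate for {t} at remaining {remaining}")
    prim = candidates[int(rng.integers(len(candidates)))]
    children = [_gen_full(pset, a, depth + 1, target, rng) for a in prim.args]
    return Node(prim, children)


def _gen_grow(
    pset: PrimitiveSet,
    t: GPType,
    depth: int,
    min_depth: int,
    max_depth: int,
    rng: np.random.Generator,
) -> Node:
    if t not in DATA_TYPES:
        return _make_leaf(pset, t, rng)
    remaining = max_depth - depth
    candidates = [
        p
        for p in pset.by_ret(t)
        if 1 + max((pset.min_height(a) for a in p.args), default=0) <= remaining
    ]
    term_ok = pset.has_terminal(t)
    if not candidates:
        if term_ok:
            return _make_leaf(pset, t, rng)
        raise ValueError(f"type {t} cannot fit in remaining height {remaining}")
    needed = min_depth - depth
    if needed > 0:
        # prefer primitives that can still push a branch down to min_depth
        def max_h(p: Primitive) -> int:
            return 1 + max(
                (
                    (remaining - 1 if pset.extensible(a) else pset.min_height(a))
                    for a in p.args
                ),
                default=0,
            )

        deep = [p for p in candidates if max_h(p) >= needed]
        if deep:
            candidates = deep
    use_terminal = (
        term_ok
        and depth >= min_depth
        and rng.random() < GROW_TERMINAL_P
    )
    if use_terminal:
        return _make_leaf(pset, t, rng)
    prim = candidates[int(rng.integers(len(candidates)))]
    children = [
        _gen_grow(pset, a, depth + 1, min_depth, max_depth, rng) for a in prim.args
    ]
    return Node(prim, children)


def generate_subtree(
    pset: PrimitiveSet,
    t: GPType,
    max_height: int,
    rng: np.random.Generator,
    method: str = "grow",
) -> Node:
    """Generate a subtree of type ``t`` no taller than ``max_height``."""
    if method == "grow":
        return _gen_grow(pset, t, 0, 0, max_height, rng)
    return _gen_full(pset, t, 0, max_height, rng)


def generate_tree(
    pset: PrimitiveSet,
    method: str = "half",
    depth_range: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> ProgramTree:
    """Generate one type-correct tree rooted at a concatenation/conversion.

    ``method`` is ``"full"``, ``"grow"`` or ``"half"`` (ramped
    half-and-half: a fair coin between the two). The target depth is
    sampled uniformly from ``depth_range`` (defaults to the structure's
    initial depth range).
    """
    rng = rng if rng is not None else np.random.default_rng()
    lo, hi = depth_range if depth_range is not None else pset.init_depth
    if hi > pset.max_depth:
        raise ValueError("depth_range exceeds the structure's maximum depth")
    target = int(rng.integers(lo, hi + 1))
    chosen = method if method != "half" else ("full" if rng.random() < 0.5 else "grow")
    roots = [
        p
        for p in pset.roots()
        if all(
            (
                pset.can_reach(a, target - 1)
                if chosen == "full"
                else pset.can_fit(a, target - 1)
            )
            for a in p.args
            if a in DATA_TYPES
        )
    ]
    if not roots:
        raise ValueError(f"no root primitive can produce a depth-{target} tree")
    prim = roots[int(rng.integers(len(roots)))]
    if chosen == "full":
        children = [_gen_full(pset, a, 1, target, rng) for a in prim.args]
    else:
        children = [_gen_grow(pset, a, 1, lo, target, rng) for a in prim.args]
    return ProgramTree(Node(prim, children), pset.structure)


def tree_from_dict(d: dict, pset: PrimitiveSet) -> ProgramTree:
    """Rebuild a tree from :meth:`ProgramTree.to_dict` output."""

    def build(nd: dict) -> Node:
        if "terminal" in nd:
            return Node(terminal_type=GPType(nd["terminal"]), value=nd["value"])
        prim = pset.get(nd["primitive"])
        return Node(prim, [build(c) for c in nd["children"]])

    return ProgramTree(build(d["root"]), d["structure"])


def _eval_node(node: Node, input_value):
    if node.is_leaf:
        return input_value if node.value is None else node.value
    args = [_eval_node(c, input_value) for c in node.children]
    return node.primitive.fn(*args)


def evaluate_batch(tree: ProgramTree, X: np.ndarray) -> np.ndarray:
    """Evaluate a spectra-structure tree on an ``n x B`` spectra matrix.

    Returns the ``n x k`` feature matrix. Vectorised: SPECTRA values flow
    as the full matrix and SF values as length-n vectors, so this costs a
    handful of numpy operations per tree node.
    """
    if tree.structure != "spectra":
        raise ValueError("batch evaluation applies to spectra-structure trees")
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be (n_samples, n_bands)")
    out = _eval_node(tree.root, X)
    return np.asarray(out, dtype=np.float64)


def evaluate_tree(tree: ProgramTree, sample) -> np.ndarray:
    """Evaluate a tree on one sample, returning its 1-D feature vector.

    Spectra-structure trees take a :class:`ReflectanceSpectrum` or a
    length-B vector; image-structure trees take a
    :class:`HyperspectralCube`.
    """
    if tree.structure == "spectra":
        if isinstance(sample, HyperspectralCube):
            raise ValueError("spectra-structure trees take a spectrum, not a cube")
        if isinstance(sample, ReflectanceSpectrum):
            values = sample.values
        else:
            values = np.asarray(sample, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("spectra-structure input must be a single spectrum")
        return evaluate_batch(tree, values[None, :])[0]
    if not isinstance(sample, HyperspectralCube):
        raise ValueError("image-structure input must be a HyperspectralCube")
    out = np.asarray(_eval_node(tree.root, sample), dtype=np.float64)
    return out.reshape(-1)
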