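"""Exact fractional weights over concept-tree variants.

The root of a tree carries weight 1; every child receives an equal fraction of
its parent's weight (parent weight divided by the number of siblings,
including itself).  A complete, internally consistent arrangement of concepts
therefore sums to exactly 1, which is the quantity the checklist validator
tests.  All arithmetic is exact rational (:class:`fractions.Fraction`) so that
sum-to-1 checks are equality tests, never tolerance tests; 1/3 is stored
exactly and rendered as ``0.333`` only for display.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable

from .errors import EmptyScopeError, UnknownNodeError
from .store import TreeVariant

__all__ = ["compute_weights", "scoped_weights", "arrangement_sum", "display_weight"]


def compute_weights(variant: TreeVariant) -> dict[str, Fraction]:
    """Weight of every node of *variant*: root 1, children equal shares.

    Raises :class:`StructuralError` if the variant is not a single rooted
    tree.
    """
    root = variant.root
    weights: dict[str, Fraction] = {root: Fraction(1)}
    stack = [root]
    while stack:
        node = stack.pop()
        children = variant.children(node)
        if not children:
            continue
        share = weights[node] / len(children)
        for child in children:
            weights[child] = share
            stack.append(child)
    return weights


def scoped_weights(variant: TreeVariant, scope: Iterable[str]) -> dict[str, Fraction]:
    """Weights recomputed after restricting the tree to the leaves in *scope*.

    Leaves outside the scope are pruned, nodes whose leaf set becomes empty
    disappear, and a node left with a single child keeps it (the child's
    weight then equals the parent's).  With the full leaf set as scope the
    result is identical to :func:`compute_weights`.
    """
    scope = frozenset(scope)
    if not scope:
        raise EmptyScopeError("scope must contain at least one leaf")
    root = variant.root
    leaves = variant.leaf_set(root)
    unknown = scope - leaves
    if unknown:
        raise UnknownNodeError(f"scope entries are not leaves of this variant: "
                               f"{sorted(unknown)}")
    weights: dict[str, Fraction] = {root: Fraction(1)}
    stack = [root]
    while stack:
        node = stack.pop()
        kept = [c for c in variant.children(node) if variant.leaf_set(c) & scope]
        if not kept:
            continue
        share = weights[node] / len(kept)
        for child in kept:
            weights[child] = share
            stack.append(child)
    return weights


def arrangement_sum(ids: Iterable[str], variant: TreeVariant) -> Fraction:
    """Exact sum of the weights of *ids* under *variant*.

    A valid complete arrangement sums to exactly 1; anything above 1 marks an
    over-complete (invalid) listing.
    """
    ids = list(ids)
    weights = compute_weights(variant)
    missing = sorted(set(ids) - set(weights))
    if missing:
        raise UnknownNodeError(f"not nodes of this variant: {missing}")
    return sum((weights[i] for i in ids), Fraction(0))


def display_weight(value: Fraction | float) -> str:
    """Three-decimal display form of a weight (e.g. ``Fraction(1, 3)`` ->
    ``'0.333'``); storage stays exact."""
    return f"{float(value):.3f}"
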