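"""Independent oracles used by the tests.

The brute-force parsimony oracle enumerates every ancestral labeling
explicitly and never touches the dynamic-programming code it checks.
"""

from __future__ import annotations

import itertools
from typing import Optional

import numpy as np

from intronevo.parsimony import CostScheme
from intronevo.trees import SpeciesTree, TreeNode


def brute_force_optima(states: dict[str, Optional[int]], tree: SpeciesTree,
                       costs: CostScheme = CostScheme()):
    """Exhaustive minimum over all labelings of internal nodes and unknown
    tips.  Returns (score, labelings, root_states, edge_pairs) where
    ``labelings`` is the set of optimal full assignments (as frozensets of
    (node, state) items), ``edge_pairs[branch]`` the set of
    (parent_state, child_state) pairs realised in >= 1 optimum.
    """
    fixed = {t.name: states[t.name] for t in tree.tips()
             if states[t.name] is not None}
    free = [n.name for n in tree.preorder() if not n.is_tip]
    free += [t.name for t in tree.tips() if states[t.name] is None]
    branches = [(n.parent.name, n.name) for n in tree.branches()]

    best = float("inf")
    optima: list[dict[str, int]] = []
    for combo in itertools.product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        total = sum(costs.cost(assign[p], assign[c]) for p, c in branches)
        if total < best - 1e-12:
            best = total
            optima = [assign]
        elif abs(total - best) <= 1e-12:
            optima.append(assign)

    labelings = {frozenset(a.items()) for a in optima}
    root_states = {a[tree.root.name] for a in optima}
    edge_pairs = {c: {(a[p], a[c]) for a in optima} for p, c in branches}
    return best, labelings, root_states, edge_pairs


def all_rooted_binary_topologies(labels: list[str]) -> list[SpeciesTree]:
    """Every rooted binary labeled topology ((2n-3)!! of them)."""

    def build(subset: tuple[str, ...]) -> list[TreeNode]:
        if len(subset) == 1:
            return [TreeNode(subset[0])]
        out = []
        first, rest = subset[0], subset[1:]
        for r in range(len(rest) + 1):
            for left_rest in itertools.combinations(rest, r):
                left = (first,) + left_rest
                right = tuple(x for x in rest if x not in left_rest)
                if not right:
                    continue
                for lt in build(left):
                    for rt in build(right):
                        out.append(TreeNode("", children=[
                            _clone(lt), _clone(rt)]))
        return out

    return [SpeciesTree(root) for root in build(tuple(labels))]


def _clone(node: TreeNode) -> TreeNode:
    return TreeNode(node.name, node.length,
                    children=[_clone(c) for c in node.children])


def random_rooted_binary_tree(labels: list[str],
                              rng: np.random.Generator) -> SpeciesTree:
    nodes = [TreeNode(name) for name in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(TreeNode("", children=[a, b]))
    return SpeciesTree(nodes[0])


def random_pattern(tips: list[str], rng: np.random.Generator,
                   p_unknown: float = 0.0) -> dict[str, Optional[int]]:
    out = {}
    for t in tips:
        u = rng.random()
        if u < p_unknown:
            out[t] = None
        else:
            out[t] = int(rng.integers(2))
    return out
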