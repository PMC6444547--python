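"""Small parsimony for binary splice-site characters, with all optima.

For each character (intron site) scored present/absent/unknown at the tips of
a rooted species tree, this module computes

* the minimal weighted number of gain/loss changes (Sankoff dynamic
  programming over the two states; unknown tips cost nothing in either
  state),
* *exact* per-branch event ranges over all most-parsimonious (MP) scenarios,
  derived from edge-state-pair optimality membership rather than from capped
  enumeration,
* the explicit set of MP scenarios (ancestral labelings with per-branch
  events), capped with a truncation flag,
* family- and study-level aggregates: total changes, per-branch ranges,
  root-presence range, the count of ancestral sites retained in all species,
  and sites whose every MP scenario requires independent parallel changes.

When gains or losses are equally parsimonious the reconstruction stays
agnostic and reports ranges — the min/max of each branch's event count across
all MP scenarios.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .site_homology import ABSENT, PRESENT, UNKNOWN, SiteMatrix
from .trees import SpeciesTree, TreeNode

EPS = 1e-9


class ParsimonyError(ValueError):
    pass


@dataclass(frozen=True)
class CostScheme:
    """Gain/loss change costs.  Unit costs = unweighted parsimony (default);
    a large ``gain_cost`` approximates Dollo parsimony."""

    gain_cost: float = 1.0
    loss_cost: float = 1.0

    def __post_init__(self):
        if self.gain_cost < 0 or self.loss_cost < 0:
            raise ParsimonyError("costs must be >= 0")
        if self.gain_cost == 0 and self.loss_cost == 0:
            raise ParsimonyError("gain and loss costs cannot both be zero")

    def cost(self, parent_state: int, child_state: int) -> float:
        if parent_state == child_state:
            return 0.0
        return self.gain_cost if child_state == 1 else self.loss_cost


def _as_binary(states: dict[str, object]) -> dict[str, Optional[int]]:
    out = {}
    for tip, value in states.items():
        if value in (1, PRESENT, True):
            out[tip] = 1
        elif value in (0, ABSENT, False):
            out[tip] = 0
        elif value in (None, UNKNOWN):
            out[tip] = None
        else:
            raise ParsimonyError(f"bad state {value!r} for tip {tip!r}")
    return out


def _tip_vector(state: Optional[int]) -> np.ndarray:
    if state is None:
        return np.zeros(2)
    vec = np.full(2, np.inf)
    vec[state] = 0.0
    return vec


def sankoff_up(tree: SpeciesTree, states: dict[str, Optional[int]],
               costs: CostScheme) -> dict[str, np.ndarray]:
    """Bottom-up cost vectors C_v(s) = min cost of v's subtree given v = s."""
    up: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            if node.name not in states:
                raise ParsimonyError(f"no state for tip {node.name!r}")
            up[node.name] = _tip_vector(states[node.name])
        else:
            vec = np.zeros(2)
            for s in (0, 1):
                vec[s] = sum(
                    min(costs.cost(s, t) + up[child.name][t] for t in (0, 1))
                    for child in node.children)
            up[node.name] = vec
    return up


def site_score(states: dict[str, object], tree: SpeciesTree,
               costs: CostScheme = CostScheme()) -> float:
    """Minimal weighted change count explaining the tip states."""
    binary = _as_binary(states)
    up = sankoff_up(tree, binary, costs)
    return float(min(up[tree.root.name]))


@dataclass
class SiteOptima:
    """Exact all-optima structure for one character."""

    score: float
    degenerate: bool                       # all tips unknown
    root_states: frozenset[int]            # root states in >= 1 MP labeling
    # branch name -> set of (parent_state, child_state) pairs in >= 1 MP
    edge_pairs: dict[str, frozenset[tuple[int, int]]]

    def branch_range(self, branch: str, direction: str) -> tuple[int, int]:
        """[min, max] events of ``direction`` on ``branch`` across MP
        scenarios (0 or 1 for a binary character)."""
        pair = (0, 1) if direction == "gain" else (1, 0)
        pairs = self.edge_pairs[branch]
        possible = pair in pairs
        forced = possible and len(pairs) == 1
        return (1 if forced else 0, 1 if possible else 0)

    @property
    def root_present_range(self) -> tuple[int, int]:
        return (1 if self.root_states == frozenset({1}) else 0,
                1 if 1 in self.root_states else 0)


def site_optima(states: dict[str, object], tree: SpeciesTree,
                costs: CostScheme = CostScheme()) -> SiteOptima:
    """Compute MP membership of root states and edge state pairs exactly.

    ``out[v][t]`` is the best cost of everything outside v's subtree given
    v = t; an edge pair (s, t) on branch (u, v) belongs to an MP labeling iff
    ``out[u][s] + cost(s, t) + up[v][t] + siblings' best given u = s`` equals
    the optimum.
    """
    binary = _as_binary(states)
    degenerate = all(v is None for v in binary.values())
    up = sankoff_up(tree, binary, costs)
    total = float(min(up[tree.root.name]))

    out: dict[str, np.ndarray] = {tree.root.name: np.zeros(2)}
    edge_pairs: dict[str, frozenset[tuple[int, int]]] = {}
    for node in tree.preorder():
        if node.is_tip and node.children:
            continue
        for child in node.children:
            # Sibling contribution given each state of `node`.
            sib = np.zeros(2)
            for s in (0, 1):
                sib[s] = sum(
                    min(costs.cost(s, t) + up[w.name][t] for t in (0, 1))
                    for w in node.children if w is not child)
            child_out = np.full(2, np.inf)
            pairs = set()
            for t in (0, 1):
                for s in (0, 1):
                    val = out[node.name][s] + sib[s] + costs.cost(s, t)
                    child_out[t] = min(child_out[t], val)
                    if (val + up[child.name][t]) <= total + EPS:
                        pairs.add((s, t))
            out[child.name] = child_out
            edge_pairs[child.name] = frozenset(pairs)

    root_states = frozenset(
        s for s in (0, 1) if up[tree.root.name][s] <= total + EPS)
    return SiteOptima(score=total, degenerate=degenerate,
                      root_states=root_states, edge_pairs=edge_pairs)


@dataclass
class Scenario:
    node_states: dict[str, int]
    events: list[tuple[str, str]]      # (branch, "gain"|"loss")


def enumerate_scenarios(states: dict[str, object], tree: SpeciesTree,
                        costs: CostScheme = CostScheme(),
                        cap: int = 10_000) -> tuple[list[Scenario], bool]:
    """All MP ancestral labelings with per-branch events.

    Returns (scenarios, truncated).  When the count exceeds ``cap`` the list
    is cut short and ``truncated`` is True; exact per-branch ranges should
    then come from :func:`site_optima`, which is cap-independent.
    """
    binary = _as_binary(states)
    up = sankoff_up(tree, binary, costs)
    root = tree.root
    total = float(min(up[root.name]))

    scenarios: list[Scenario] = []
    truncated = False

    def optimal_child_states(parent_state: int, child: TreeNode) -> list[int]:
        vals = {t: costs.cost(parent_state, t) + up[child.name][t]
                for t in (0, 1)}
        best = min(vals.values())
        return [t for t in (0, 1) if vals[t] <= best + EPS]

    def expand(nodes: list[TreeNode], assignment: dict[str, int]) -> bool:
        nonlocal truncated
        if not nodes:
            events = []
            for node in tree.branches():
                ps = assignment[node.parent.name]
                cs = assignment[node.name]
                if ps != cs:
                    events.append(
                        (node.name, "gain" if cs == 1 else "loss"))
            scenarios.append(Scenario(dict(assignment), events))
            if len(scenarios) >= cap:
                truncated = True
                return False
            return True
        node, rest = nodes[0], nodes[1:]
        for t in optimal_child_states(assignment[node.parent.name], node):
            assignment[node.name] = t
            if not expand(rest + node.children, assignment):
                return False
            del assignment[node.name]
        return True

    root_choices = [s for s in (0, 1)
                    if up[root.name][s] <= total + EPS]
    for s in root_choices:
        if not expand(list(root.children), {root.name: s}):
            break
    return scenarios, truncated


def _independent_branches(tree: SpeciesTree, branches: Sequence[str]) -> bool:
    nodes = [tree.node(b) for b in branches]
    for a, b in itertools.combinations(nodes, 2):
        if not (tree.is_ancestor(a, b) or tree.is_ancestor(b, a)):
            return True
    return False


@dataclass
class FamilyReconstruction:
    family_id: str
    site_scores: dict[tuple[int, int], float]
    branch_ranges: dict[str, dict[str, tuple[int, int]]]
    root_present: tuple[int, int]
    retained_all: int
    parallel_events: list[dict]
    n_variable_sites: int
    n_changes: float
    degenerate_sites: list[tuple[int, int]] = field(default_factory=list)
    truncated_sites: list[tuple[int, int]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "n_variable_sites": self.n_variable_sites,
            "n_changes": self.n_changes,
            "root_present": list(self.root_present),
            "retained_all": self.retained_all,
            "site_scores": {f"{c}/{p}": s
                            for (c, p), s in sorted(self.site_scores.items())},
            "branch_ranges": {
                b: {d: list(r) for d, r in sorted(dirs.items())}
                for b, dirs in sorted(self.branch_ranges.items())},
            "parallel_events": self.parallel_events,
            "degenerate_sites": [list(s) for s in self.degenerate_sites],
            "truncated_sites": [list(s) for s in self.truncated_sites],
        }


def summarize_family(matrix: SiteMatrix, tree: SpeciesTree,
                     costs: CostScheme = CostScheme(),
                     enumeration_cap: int = 10_000) -> FamilyReconstruction:
    """Per-branch ranges, root range, retention, and parallel events for one
    family's site matrix."""
    tips = set(tree.tip_names())
    matrix_species = set(matrix.states.index)
    if matrix_species != tips:
        raise ParsimonyError(
            f"matrix species {sorted(matrix_species)} != tree tips "
            f"{sorted(tips)}")

    branch_names = [n.name for n in tree.branches()]
    ranges = {b: {"gain": [0, 0], "loss": [0, 0]} for b in branch_names}
    site_scores: dict[tuple[int, int], float] = {}
    root_min = root_max = 0
    retained = 0
    parallel: list[dict] = []
    degenerate, truncated_sites = [], []
    n_variable = 0

    for key in matrix.sites:
        states = matrix.states_for(key)
        optima = site_optima(states, tree, costs)
        site_scores[key] = optima.score
        if optima.degenerate:
            degenerate.append(key)
            continue
        for b in branch_names:
            for d in ("gain", "loss"):
                lo, hi = optima.branch_range(b, d)
                ranges[b][d][0] += lo
                ranges[b][d][1] += hi
        lo, hi = optima.root_present_range
        root_min += lo
        root_max += hi

        known = [v for v in _as_binary(states).values() if v is not None]
        if known and all(v == 1 for v in known) \
                and optima.root_states == frozenset({1}):
            retained += 1

        if optima.score > 0:
            n_variable += 1

        if optima.score >= 2 * min(costs.gain_cost, costs.loss_cost) - EPS \
                and optima.score > 0:
            scenarios, truncated = enumerate_scenarios(
                states, tree, costs, cap=enumeration_cap)
            if truncated:
                truncated_sites.append(key)
            elif scenarios and all(
                    len(sc.events) >= 2
                    and _independent_branches(
                        tree, [b for b, _ in sc.events])
                    for sc in scenarios):
                parallel.append({
                    "site": list(key),
                    "branches": sorted({b for sc in scenarios
                                        for b, _ in sc.events}),
                    "directions": sorted({d for sc in scenarios
                                          for _, d in sc.events}),
                })

    return FamilyReconstruction(
        family_id=matrix.family_id,
        site_scores=site_scores,
        branch_ranges={b: {d: tuple(r) for d, r in dirs.items()}
                       for b, dirs in ranges.items()},
        root_present=(root_min, root_max),
        retained_all=retained,
        parallel_events=parallel,
        n_variable_sites=n_variable,
        n_changes=float(sum(site_scores.values())),
        degenerate_sites=degenerate,
        truncated_sites=truncated_sites,
    )


@dataclass
class StudyAggregate:
    n_families: int
    n_variable_sites: int
    n_changes: float
    root_present: tuple[int, int]
    retained_all: int
    branch_ranges: dict[str, dict[str, tuple[int, int]]]
    species_changes: dict[str, tuple[int, int]]   # terminal-branch totals
    parallel_events: list[dict]

    def to_json_dict(self) -> dict:
        return {
            "n_families": self.n_families,
            "n_variable_sites": self.n_variable_sites,
            "n_changes": self.n_changes,
            "root_present": list(self.root_present),
            "retained_all": self.retained_all,
            "branch_ranges": {
                b: {d: list(r) for d, r in sorted(dirs.items())}
                for b, dirs in sorted(self.branch_ranges.items())},
            "species_changes": {sp: list(r) for sp, r
                                in sorted(self.species_changes.items())},
            "parallel_events": self.parallel_events,
        }


def aggregate_families(reconstructions: Sequence[FamilyReconstruction],
                       tree: SpeciesTree) -> StudyAggregate:
    """Study totals across families (per-branch ranges summed site-wise)."""
    ids = [r.family_id for r in reconstructions]
    if len(set(ids)) != len(ids):
        raise ParsimonyError(f"duplicate family ids in {ids}")
    if not reconstructions:
        raise ParsimonyError("no families to aggregate")

    branch_names = [n.name for n in tree.branches()]
    ranges = {b: {"gain": [0, 0], "loss": [0, 0]} for b in branch_names}
    root = [0, 0]
    retained = 0
    parallel: list[dict] = []
    n_var, n_changes = 0, 0.0
    for rec in reconstructions:
        n_var += rec.n_variable_sites
        n_changes += rec.n_changes
        retained += rec.retained_all
        root[0] += rec.root_present[0]
        root[1] += rec.root_present[1]
        for b in branch_names:
            for d in ("gain", "loss"):
                ranges[b][d][0] += rec.branch_ranges[b][d][0]
                ranges[b][d][1] += rec.branch_ranges[b][d][1]
        for ev in rec.parallel_events:
            parallel.append({"family": rec.family_id, **ev})

    species_changes = {}
    for tip in tree.tips():
        b = ranges[tip.name]
        species_changes[tip.name] = (b["gain"][0] + b["loss"][0],
                                     b["gain"][1] + b["loss"][1])

    return StudyAggregate(
        n_families=len(reconstructions),
        n_variable_sites=n_var,
        n_changes=n_changes,
        root_present=(root[0], root[1]),
        retained_all=retained,
        branch_ranges={b: {d: tuple(r) for d, r in dirs.items()}
                       for b, dirs in ranges.items()},
        species_changes=species_changes,
        parallel_events=parallel,
    )


def annotated_newick(tree: SpeciesTree, aggregate: StudyAggregate) -> str:
    """Newick with per-branch "[+g, -l]" tags (ranges shown as a..b)."""

    def fmt(lo: int, hi: int, sign: str) -> str:
        return f"{sign}{lo}" if lo == hi else f"{sign}{lo}..{hi}"

    def comment(node: TreeNode) -> str:
        r = aggregate.branch_ranges.get(node.name)
        if r is None:
            return ""
        parts = []
        if r["gain"][1] > 0:
            parts.append(fmt(*r["gain"], "+"))
        if r["loss"][1] > 0:
            parts.append(fmt(*r["loss"], "-"))
        return ", ".join(parts)

    return tree.to_newick(branch_comment=comment)


# ---------------------------------------------------------------------------
# Genome size vs intron number
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str
    table: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {"rho": self.rho, "p_value": self.p_value, "n": self.n,
                "method": self.method,
                "pairs": self.table.to_dict(orient="records")}


def genome_size_correlation(intron_counts: dict[str, float],
                            genome_sizes: dict[str, float],
                            exact_max_n: int = 10) -> CorrelationResult:
    """Spearman rank correlation of genome size with intron number.

    Ties get average ranks.  For n <= ``exact_max_n`` the two-sided p-value
    is exact: the full permutation distribution of |rho| over all n!
    pairings.  Larger n falls back to scipy's asymptotic p.
    """
    shared = sorted(set(intron_counts) & set(genome_sizes))
    if len(shared) < 3:
        raise ParsimonyError(
            f"need >= 3 species with both values, have {len(shared)}")
    x = np.array([intron_counts[sp] for sp in shared], dtype=float)
    y = np.array([genome_sizes[sp] for sp in shared], dtype=float)
    table = pd.DataFrame(
        {"species": shared, "intron_count": x, "genome_size": y})

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(shared)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return CorrelationResult(float("nan"), 1.0, n, "degenerate", table)

    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_max_n:
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
        hits = 0
        total = 0
        chunk: list[Sequence[int]] = []

        def flush(chunk_perms):
            nonlocal hits
            if not chunk_perms:
                return
            P = np.array(chunk_perms)
            rhos = (cy[P] @ cx) / denom
            hits += int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))

        for perm in itertools.permutations(range(n)):
            chunk.append(perm)
            total += 1
            if len(chunk) >= 200_000:
                flush(chunk)
                chunk = []
        flush(chunk)
        p = hits / total
        method = "exact permutation"
    else:
        p = float(stats.spearmanr(x, y).pvalue)
        method = "asymptotic"
    return CorrelationResult(rho, float(p), n, method, table)
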