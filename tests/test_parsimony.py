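import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import (all_rooted_binary_topologies, brute_force_optima,
                      random_pattern, random_rooted_binary_tree)
from intronevo.parsimony import (CostScheme, ParsimonyError,
                                 aggregate_families, enumerate_scenarios,
                                 genome_size_correlation, site_optima,
                                 site_score, summarize_family)
from intronevo.site_homology import build_site_matrix
from intronevo.genemodel_io import IntronSite
from intronevo.synthetic_data import (SimulationParams, constructed_history,
                                      eight_species_tree, simulate_history)
from intronevo.trees import SpeciesTree


def scenarios_as_labelings(scenarios):
    return {frozenset(sc.node_states.items()) for sc in scenarios}


def test_all_tips_present_costs_nothing(eight_sp_tree):
    states = {sp: 1 for sp in eight_sp_tree.tip_names()}
    assert site_score(states, eight_sp_tree) == 0.0
    optima = site_optima(states, eight_sp_tree)
    assert optima.root_states == frozenset({1})


def test_single_present_tip_costs_one_change(eight_sp_tree):
    tips = eight_sp_tree.tip_names()
    states = {sp: 0 for sp in tips}
    states[tips[0]] = 1
    assert site_score(states, eight_sp_tree) == 1.0


def test_all_tips_absent_root_forced_absent(quartet_tree):
    states = {sp: 0 for sp in "ABCD"}
    optima = site_optima(states, quartet_tree)
    assert optima.score == 0.0
    assert optima.root_states == frozenset({0})


def test_all_unknown_is_degenerate_zero(quartet_tree):
    states = {sp: None for sp in "ABCD"}
    optima = site_optima(states, quartet_tree)
    assert optima.score == 0.0
    assert optima.degenerate


def test_discordant_quartet_has_ambiguous_root_and_ranges(quartet_tree):
    # present in A and C only: 2 changes; either 2 independent gains or a
    # present root with 2 losses — root state ambiguous, ranges non-trivial.
    states = {"A": 1, "B": 0, "C": 1, "D": 0}
    optima = site_optima(states, quartet_tree)
    assert optima.score == 2.0
    assert optima.root_states == frozenset({0, 1})
    assert optima.branch_range("A", "gain") == (0, 1)
    assert optima.branch_range("B", "loss") == (0, 1)
    score, labelings, roots, pairs = brute_force_optima(states, quartet_tree)
    assert score == 2.0
    scenarios, truncated = enumerate_scenarios(states, quartet_tree)
    assert not truncated
    assert scenarios_as_labelings(scenarios) == labelings


def test_clade_pattern_has_unique_change_ambiguous_direction(quartet_tree):
    # present in the (A,B) clade only: one change on the AB branch whose
    # direction (gain vs loss) depends on the ambiguous root state.
    states = {"A": 1, "B": 1, "C": 0, "D": 0}
    optima = site_optima(states, quartet_tree)
    assert optima.score == 1.0
    assert optima.root_present_range == (0, 1)
    scenarios, _ = enumerate_scenarios(states, quartet_tree)
    assert len(scenarios) == 2
    directions = {tuple(sc.events) for sc in scenarios}
    assert (("AB", "gain"),) in directions
    assert (("CD", "loss"),) in directions or any(
        ev == ("AB", "loss") for sc in scenarios for ev in sc.events) is False


def test_dp_matches_bruteforce_on_random_trees_with_unknowns():
    rng = np.random.default_rng(12)
    labels = list("ABCDEF")
    for _ in range(60):
        tree = random_rooted_binary_tree(labels, rng)
        states = random_pattern(labels, rng, p_unknown=0.25)
        if all(v is None for v in states.values()):
            continue
        score, labelings, roots, pairs = brute_force_optima(states, tree)
        optima = site_optima(states, tree)
        assert optima.score == pytest.approx(score)
        assert optima.root_states == frozenset(roots)
        for branch, expected in pairs.items():
            assert optima.edge_pairs[branch] == frozenset(expected), branch
        scenarios, truncated = enumerate_scenarios(states, tree)
        assert not truncated
        assert scenarios_as_labelings(scenarios) == labelings


def test_score_bounds_and_zero_iff_constant():
    rng = np.random.default_rng(3)
    labels = list("ABCDEFG")
    for _ in range(50):
        tree = random_rooted_binary_tree(labels, rng)
        states = random_pattern(labels, rng)
        score = site_score(states, tree)
        n1 = sum(v == 1 for v in states.values())
        n0 = sum(v == 0 for v in states.values())
        assert 0 <= score <= min(n1, n0) + (0 if min(n1, n0) else 0)
        assert (score == 0) == (n1 == 0 or n0 == 0)


def test_unknown_tip_never_increases_score():
    rng = np.random.default_rng(7)
    labels = list("ABCDEF")
    for _ in range(40):
        tree = random_rooted_binary_tree(labels, rng)
        states = random_pattern(labels, rng)
        base = site_score(states, tree)
        for tip in labels:
            relaxed = dict(states)
            relaxed[tip] = None
            assert site_score(relaxed, tree) <= base


def test_enumeration_cap_flags_truncation_but_ranges_stay_exact(quartet_tree):
    states = {"A": 1, "B": 0, "C": 1, "D": 0}
    scenarios, truncated = enumerate_scenarios(states, quartet_tree, cap=1)
    assert truncated
    assert len(scenarios) == 1
    # exact ranges come from optimal-state membership, not the enumeration
    optima = site_optima(states, quartet_tree)
    _, _, _, pairs = brute_force_optima(states, quartet_tree)
    for branch, expected in pairs.items():
        assert optima.edge_pairs[branch] == frozenset(expected)


def test_dollo_like_costs_force_single_origin(quartet_tree):
    states = {"A": 1, "B": 0, "C": 1, "D": 0}
    costs = CostScheme(gain_cost=10.0, loss_cost=1.0)
    optima = site_optima(states, quartet_tree, costs)
    assert optima.score == 2.0  # root present, two losses
    assert optima.root_states == frozenset({1})


def _matrix_from_states(tree, site_states, family_id="fam"):
    """SiteMatrix straight from per-site state dicts (identical proteins)."""
    sites_by_species = {}
    msa = {}
    max_anchor = max((col for (col, _p) in site_states), default=1)
    for sp in tree.tip_names():
        msa[sp] = "A" * max(200, max_anchor + 5)
        sites_by_species[sp] = [
            IntronSite(col, phase)
            for (col, phase), states in site_states.items()
            if states[sp] == 1]
    return build_site_matrix(sites_by_species, msa, tree,
                             family_id=family_id)


def test_zero_change_family_summary(quartet_tree):
    site_states = {(10, 0): {sp: 1 for sp in "ABCD"},
                   (20, 1): {sp: 1 for sp in "ABCD"}}
    matrix = _matrix_from_states(quartet_tree, site_states)
    rec = summarize_family(matrix, quartet_tree)
    assert rec.n_changes == 0.0
    assert rec.n_variable_sites == 0
    assert rec.root_present == (2, 2)
    assert rec.retained_all == 2
    for dirs in rec.branch_ranges.values():
        assert dirs == {"gain": (0, 0), "loss": (0, 0)}


def test_single_gain_fixture_pins_one_branch(quartet_tree):
    site_states = {(10, 0): {"A": 1, "B": 0, "C": 0, "D": 0}}
    matrix = _matrix_from_states(quartet_tree, site_states)
    rec = summarize_family(matrix, quartet_tree)
    assert rec.n_changes == 1.0
    assert rec.branch_ranges["A"]["gain"] == (1, 1)
    for b, dirs in rec.branch_ranges.items():
        if b != "A":
            assert dirs["gain"] == (0, 0) and dirs["loss"] == (0, 0)


def test_tie_fixture_reports_ranges(quartet_tree):
    site_states = {(10, 0): {"A": 1, "B": 0, "C": 1, "D": 0}}
    matrix = _matrix_from_states(quartet_tree, site_states)
    rec = summarize_family(matrix, quartet_tree)
    assert rec.root_present == (0, 1)
    assert any(dirs["gain"][0] < dirs["gain"][1]
               or dirs["loss"][0] < dirs["loss"][1]
               for dirs in rec.branch_ranges.values())


def test_parallel_loss_detected_when_forced(eight_sp_tree):
    # ancestral site lost independently in Dmel and Tcas (non-sister tips):
    # every MP scenario needs two changes on independent branches.
    states = {sp: 1 for sp in eight_sp_tree.tip_names()}
    states["Dmel"] = 0
    states["Tcas"] = 0
    matrix = _matrix_from_states(eight_sp_tree, {(30, 0): states})
    rec = summarize_family(matrix, eight_sp_tree)
    assert rec.n_changes == 2.0
    assert len(rec.parallel_events) == 1
    assert set(rec.parallel_events[0]["branches"]) >= {"Dmel", "Tcas"}
    assert rec.parallel_events[0]["directions"] == ["loss"]


def test_aggregate_totals_are_additive(quartet_tree):
    fams = {
        "f1": {(10, 0): {"A": 1, "B": 0, "C": 1, "D": 0},      # 2 changes
               (20, 0): {"A": 1, "B": 1, "C": 0, "D": 0}},      # 1 change
        "f2": {(12, 1): {"A": 0, "B": 0, "C": 0, "D": 1}},      # 1 change
        "f3": {(5, 2): {"A": 1, "B": 1, "C": 1, "D": 0},        # 1
               (6, 0): {"A": 1, "B": 0, "C": 0, "D": 0},        # 1
               (7, 0): {"A": 1, "B": 0, "C": 1, "D": 0}},       # 2
    }
    recs = [summarize_family(_matrix_from_states(quartet_tree, s, f),
                             quartet_tree)
            for f, s in fams.items()]
    assert [(r.n_variable_sites, r.n_changes) for r in recs] == [
        (2, 3.0), (1, 1.0), (3, 4.0)]
    agg = aggregate_families(recs, quartet_tree)
    assert (agg.n_variable_sites, agg.n_changes) == (6, 8.0)
    for b in agg.branch_ranges:
        for d in ("gain", "loss"):
            assert agg.branch_ranges[b][d][0] == sum(
                r.branch_ranges[b][d][0] for r in recs)
            assert agg.branch_ranges[b][d][1] == sum(
                r.branch_ranges[b][d][1] for r in recs)
    assert set(agg.species_changes) == {"A", "B", "C", "D"}


def test_duplicate_family_ids_fatal(quartet_tree):
    matrix = _matrix_from_states(
        quartet_tree, {(10, 0): {"A": 1, "B": 0, "C": 0, "D": 0}}, "same")
    rec = summarize_family(matrix, quartet_tree)
    with pytest.raises(ParsimonyError, match="duplicate"):
        aggregate_families([rec, rec], quartet_tree)


def test_parsimony_never_exceeds_true_event_count(eight_sp_tree):
    rng = np.random.default_rng(5)
    for rep in range(30):
        params = SimulationParams(seed=int(rng.integers(2 ** 30)),
                                  gain_rate=1.5, loss_rate=0.3,
                                  n_ancestral_sites=10, protein_length=300)
        hist = simulate_history(eight_sp_tree, params)
        site_states = {}
        for sid, slot in hist.sites.items():
            key = (slot.anchor, slot.phase)
            present = {sp: int(sid in hist.tip_sites[sp])
                       for sp in eight_sp_tree.tip_names()}
            if any(present.values()):
                site_states[key] = present
        if not site_states:
            continue
        matrix = _matrix_from_states(eight_sp_tree, site_states)
        rec = summarize_family(matrix, eight_sp_tree)
        assert rec.n_changes <= len(hist.events)


def test_homoplasy_free_history_recovered_exactly(eight_sp_tree):
    for seed in range(25):
        params = SimulationParams(seed=seed, gain_rate=0.4, loss_rate=0.05,
                                  n_ancestral_sites=12, protein_length=300,
                                  max_events_per_site=1)
        hist = simulate_history(eight_sp_tree, params)
        assert hist.is_homoplasy_free()
        site_states = {
            (slot.anchor, slot.phase): {
                sp: int(sid in hist.tip_sites[sp])
                for sp in eight_sp_tree.tip_names()}
            for sid, slot in hist.sites.items()}
        matrix = _matrix_from_states(eight_sp_tree, site_states)
        rec = summarize_family(matrix, eight_sp_tree)
        assert rec.n_changes == len(hist.events)
        assert rec.n_variable_sites == sum(
            1 for n in hist.n_events_per_site().values() if n > 0)


def test_low_rate_inferred_events_match_truth(eight_sp_tree):
    """At low rates (expected <= 1 event per site on the whole tree),
    >= 95% of inferred changes match the true branch and direction, i.e.
    the true event set is among the most-parsimonious scenarios of its
    site.  (The reconstruction stays agnostic under ties, so membership in
    the MP scenario set, not forcedness, is the recovery criterion; events
    erased at the tips — a gain later lost again — produce no inferred
    changes and therefore no mismatch.)
    """
    matched = total_inferred = 0
    for seed in range(100):
        params = SimulationParams(seed=7000 + seed, gain_rate=0.3,
                                  loss_rate=0.03, n_ancestral_sites=10,
                                  protein_length=300)
        hist = simulate_history(eight_sp_tree, params)
        events_per_site = {}
        for ev in hist.events:
            events_per_site.setdefault(ev.site, []).append(ev)
        for sid, evs in events_per_site.items():
            states = {sp: int(sid in hist.tip_sites[sp])
                      for sp in eight_sp_tree.tip_names()}
            if not any(states.values()):
                continue  # invisible site: nothing inferred
            optima = site_optima(states, eight_sp_tree)
            total_inferred += optima.score
            if optima.score == len(evs) and all(
                    optima.branch_range(e.branch, e.direction)[1] >= 1
                    for e in evs):
                matched += optima.score
    assert total_inferred > 100
    assert matched / total_inferred >= 0.95


# ---------------------------------------------------------------------------
# Genome size vs intron number
# ---------------------------------------------------------------------------

def test_concordant_and_reversed_ranks():
    counts = {f"s{i}": float(i) for i in range(5)}
    sizes = {f"s{i}": 100.0 + 10 * i for i in range(5)}
    res = genome_size_correlation(counts, sizes)
    assert res.rho == pytest.approx(1.0)
    reversed_sizes = {f"s{i}": 100.0 - 10 * i for i in range(5)}
    res2 = genome_size_correlation(counts, reversed_sizes)
    assert res2.rho == pytest.approx(-1.0)


def test_rho_matches_rank_formula_without_ties():
    rng = np.random.default_rng(9)
    x = {f"s{i}": float(v) for i, v in enumerate(rng.permutation(8))}
    y = {f"s{i}": float(v) for i, v in enumerate(rng.permutation(8) * 3.7)}
    res = genome_size_correlation(x, y)
    rx = stats.rankdata([x[f"s{i}"] for i in range(8)])
    ry = stats.rankdata([y[f"s{i}"] for i in range(8)])
    d2 = float(np.sum((rx - ry) ** 2))
    n = 8
    assert res.rho == pytest.approx(1 - 6 * d2 / (n * (n ** 2 - 1)))
    assert res.method == "exact permutation"
    assert 0.0 <= res.p_value <= 1.0


def test_ties_use_average_ranks():
    x = {"a": 1.0, "b": 1.0, "c": 2.0, "d": 3.0, "e": 4.0}
    y = {"a": 5.0, "b": 6.0, "c": 7.0, "d": 8.0, "e": 9.0}
    res = genome_size_correlation(x, y)
    expected = stats.spearmanr(
        [x[k] for k in sorted(x)], [y[k] for k in sorted(y)]).statistic
    assert res.rho == pytest.approx(float(expected))


def test_exact_permutation_p_matches_enumeration_small_n():
    x = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
    y = {"a": 10.0, "b": 30.0, "c": 20.0, "d": 40.0}
    res = genome_size_correlation(x, y)
    rx = np.array([1, 2, 3, 4], dtype=float)
    ry = np.array([1, 3, 2, 4], dtype=float)
    obs = np.corrcoef(rx, ry)[0, 1]
    hits = sum(
        abs(np.corrcoef(rx, np.array(p, dtype=float))[0, 1]) >= abs(obs) - 1e-12
        for p in itertools.permutations(ry))
    assert res.p_value == pytest.approx(hits / 24)


def test_fewer_than_three_shared_species_fatal():
    with pytest.raises(ParsimonyError):
        genome_size_correlation({"a": 1.0, "b": 2.0}, {"a": 3.0, "b": 4.0})
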