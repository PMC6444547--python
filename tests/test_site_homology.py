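import json
from pathlib import Path

import pytest

from intronevo.genemodel_io import (IntronSite, derive_intron_sites,
                                    parse_gene_models, read_alignment)
from intronevo.site_homology import (ABSENT, PRESENT, UNKNOWN, HomologyError,
                                     build_site_matrix, map_site_to_column,
                                     render_annotated_alignment)
from intronevo.synthetic_data import (SimulationParams, TrueHistory,
                                      emit_gene_models, eight_species_tree,
                                      simulate_history)


@pytest.mark.parametrize("row,anchor,column", [
    ("AC-DE", 3, 4),   # gap shifts residue 3 (D) to column 4
    ("ACDE", 3, 3),    # ungapped: identity
    ("-ACD", 1, 2),    # leading gap
])
def test_anchor_residue_to_alignment_column(row, anchor, column):
    assert map_site_to_column(IntronSite(anchor, 0), row) == column


def test_anchor_beyond_protein_is_fatal():
    with pytest.raises(HomologyError):
        map_site_to_column(IntronSite(5, 0), "AC-D")


def test_shared_site_scored_present_present_absent(triplet_tree):
    msa = {sp: "M" + "A" * 49 for sp in "ABC"}
    sites = {"A": [IntronSite(10, 0)], "B": [IntronSite(10, 0)], "C": []}
    matrix = build_site_matrix(sites, msa, triplet_tree)
    assert matrix.sites == [(10, 0)]
    states = matrix.states_for((10, 0))
    assert states == {"A": PRESENT, "B": PRESENT, "C": ABSENT}


def test_gap_at_site_column_is_unknown_by_default(triplet_tree):
    msa = {"A": "MAAAAAAAAAAA", "B": "MAAAAAAAAAAA", "C": "MAAAAAAAA---"}
    sites = {"A": [IntronSite(10, 0)], "B": [IntronSite(10, 0)], "C": []}
    matrix = build_site_matrix(sites, msa, triplet_tree)
    assert matrix.states_for((10, 0))["C"] == UNKNOWN
    strict = build_site_matrix(sites, msa, triplet_tree, gap_policy="absent")
    assert strict.states_for((10, 0))["C"] == ABSENT


def test_phase_is_part_of_site_identity(triplet_tree):
    msa = {sp: "M" + "A" * 19 for sp in "ABC"}
    sites = {"A": [IntronSite(10, 0)], "B": [IntronSite(10, 1)], "C": []}
    matrix = build_site_matrix(sites, msa, triplet_tree)
    assert matrix.sites == [(10, 0), (10, 1)]
    assert matrix.states_for((10, 0)) == {
        "A": PRESENT, "B": ABSENT, "C": ABSENT}
    assert matrix.states_for((10, 1)) == {
        "A": ABSENT, "B": PRESENT, "C": ABSENT}


def test_species_missing_from_msa_gets_all_unknown_row(triplet_tree):
    msa = {"A": "M" + "A" * 19, "B": "M" + "A" * 19}
    sites = {"A": [IntronSite(5, 2)], "B": []}
    matrix = build_site_matrix(sites, msa, triplet_tree)
    assert matrix.states_for((5, 2))["C"] == UNKNOWN
    assert matrix.provenance["C"][(5, 2)] == "no data"


def test_two_introns_at_one_character_in_one_species_fatal(triplet_tree):
    # distinct anchors collapsing onto one column cannot happen for one
    # species (its own row has no gap at its anchors), but identical
    # (anchor, phase) duplicates must be rejected
    msa = {sp: "M" + "A" * 19 for sp in "ABC"}
    sites = {"A": [IntronSite(10, 0), IntronSite(10, 0)], "B": [], "C": []}
    with pytest.raises(HomologyError):
        build_site_matrix(sites, msa, triplet_tree)


def test_character_order_independent_of_species_order(triplet_tree):
    msa = {sp: "M" + "A" * 29 for sp in "ABC"}
    sites1 = {"A": [IntronSite(10, 0)], "B": [IntronSite(20, 1)], "C": []}
    sites2 = {"C": [], "B": [IntronSite(20, 1)], "A": [IntronSite(10, 0)]}
    m1 = build_site_matrix(sites1, msa, triplet_tree)
    m2 = build_site_matrix(sites2, msa, triplet_tree)
    assert m1.sites == m2.sites
    assert m1.states.equals(m2.states)


def test_panel_gap_fixture_shows_unknown_state(panel_study):
    # In the gap_containing family, species D lost the site anchored at
    # residue 40 and deleted that residue: a gap at the character's column.
    from intronevo.genemodel_io import read_tree

    tree = read_tree(panel_study["tree"])
    sites_by_species, proteins = {}, {}
    for sp in tree.tip_names():
        models, _ = parse_gene_models(
            panel_study["species"][sp]["gff3"],
            panel_study["species"][sp]["genome"], species=sp)
        model = next(m for m in models
                     if m.attributes.get("family") == "gap_containing")
        proteins[sp] = model.protein
        sites_by_species[sp] = derive_intron_sites(model)
    msa = read_alignment(panel_study["families"]["gap_containing"],
                         proteins=proteins)
    matrix = build_site_matrix(sites_by_species, msa, tree,
                               family_id="gap_containing")
    truth = TrueHistory.from_json_dict(
        json.loads(Path(panel_study["truth"]["gap_containing"]).read_text()))
    anchor40 = next(s for s in truth.root_sites.values() if s.anchor == 40)
    key = (40, anchor40.phase)  # no indels upstream: column == anchor
    assert matrix.states_for(key)["D"] == UNKNOWN
    assert matrix.states_for(key)["A"] == PRESENT


def test_indel_simulation_preserves_truth_on_ungapped_columns(tmp_path):
    tree = eight_species_tree()
    params = SimulationParams(seed=17, indel_rate=0.04, protein_length=250,
                              n_ancestral_sites=12, gain_rate=0.4,
                              loss_rate=0.05)
    hist = simulate_history(tree, params)
    manifest = emit_gene_models(hist, tree, params, tmp_path)
    sites_by_species, proteins = {}, {}
    for sp in tree.tip_names():
        models, _ = parse_gene_models(
            manifest["species"][sp]["gff3"],
            manifest["species"][sp]["genome"], species=sp)
        (model,) = models
        proteins[sp] = model.protein
        sites_by_species[sp] = derive_intron_sites(model)
    msa = read_alignment(manifest["families"]["fam1"], proteins=proteins)
    matrix = build_site_matrix(sites_by_species, msa, tree)

    # Truth in alignment coordinates: every species carrying a site must map
    # it to one and the same column (homology preserved through indels), and
    # each species' known state must equal the true presence.
    from intronevo.synthetic_data import emit_family

    em = emit_family(hist, tree, params)  # deterministic re-emission
    site_keys = {}
    for sid, slot in hist.sites.items():
        cols = set()
        for sp in tree.tip_names():
            if sid in hist.tip_sites[sp]:
                loc = em.local_sites[sp][sid]
                cols.add((map_site_to_column(loc, em.msa[sp]), slot.phase))
        if cols:
            assert len(cols) == 1, f"site {sid} maps to multiple columns"
            site_keys[sid] = cols.pop()

    assert sorted(site_keys.values()) == sorted(matrix.sites)
    for sid, key in site_keys.items():
        for sp in tree.tip_names():
            state = matrix.states_for(key)[sp]
            if state == UNKNOWN:
                continue
            assert (state == PRESENT) == (sid in hist.tip_sites[sp]), \
                (sid, key, sp)


def test_annotated_alignment_rendering_marks_splice_positions(triplet_tree):
    msa = {sp: "MKVLT" for sp in "ABC"}
    sites = {"A": [IntronSite(3, 0)], "B": [IntronSite(3, 0)], "C": []}
    matrix = build_site_matrix(sites, msa, triplet_tree)
    text = render_annotated_alignment(matrix, msa)
    lines = text.strip().splitlines()
    assert lines[0].startswith("# family")
    row_a = next(line for line in lines if line.startswith("A"))
    row_c = next(line for line in lines if line.startswith("C"))
    assert "MKV|LT" in row_a
    assert "|" not in row_c
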