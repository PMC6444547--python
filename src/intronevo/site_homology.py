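"""Homologous splice-site characters on a protein multiple alignment.

A splice-site character is a (alignment column, phase) pair: two introns in
different species are homologous exactly when their anchor residues occupy the
same alignment column and they share the same phase.  Each species is scored
``present``, ``absent`` or ``unknown`` per character; a gap at the character's
column means the region is not alignable for that species and is treated as
missing data by default (``gap_policy="unknown"``), or as ``absent`` when the
caller opts in to the stricter reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genemodel_io import IntronSite
from .trees import SpeciesTree

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"


class HomologyError(ValueError):
    pass


def map_site_to_column(site: IntronSite, aligned_row: str) -> int:
    """Alignment column (1-based) occupied by the site's anchor residue."""
    seen = 0
    for col, ch in enumerate(aligned_row, start=1):
        if ch != "-":
            seen += 1
            if seen == site.anchor:
                return col
    raise HomologyError(
        f"anchor {site.anchor} beyond ungapped length {seen} of aligned row")


@dataclass
class SiteMatrix:
    """Character states (species x site) for one ortholog family."""

    family_id: str
    sites: list[tuple[int, int]]          # (column, phase), sorted
    states: pd.DataFrame                  # index=species, columns=sites
    provenance: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def states_for(self, site: tuple[int, int]) -> dict[str, str]:
        return self.states[site].to_dict()

    def to_frame(self) -> pd.DataFrame:
        df = self.states.T.reset_index()
        df.insert(0, "family", self.family_id)
        df = df.rename(columns={"level_0": "column", "level_1": "phase"})
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_site_matrix(
    sites_by_species: dict[str, list[IntronSite]],
    msa: dict[str, str],
    tree: SpeciesTree,
    family_id: str = "fam",
    gap_policy: str = "unknown",
) -> SiteMatrix:
    """Merge per-species intron sites into homologous characters.

    Characters are the distinct (column, phase) pairs observed in >= 1
    species.  Species in the tree but without an MSA row get an all-unknown
    row.  ``gap_policy`` decides the state of a species whose row has a gap at
    a character's column: ``"unknown"`` (default) or ``"absent"``.
    """
    if gap_policy not in (UNKNOWN, ABSENT):
        raise ValueError(f"gap_policy must be 'unknown' or 'absent'")
    tips = sorted(tree.tip_names())

    mapped: dict[str, dict[tuple[int, int], IntronSite]] = {}
    for sp, sites in sites_by_species.items():
        if sp not in msa:
            continue
        row = msa[sp]
        seen: dict[tuple[int, int], IntronSite] = {}
        for site in sites:
            key = (map_site_to_column(site, row), site.phase)
            if key in seen:
                raise HomologyError(
                    f"species {sp}: two introns map to column {key[0]} "
                    f"phase {key[1]}")
            seen[key] = site
        mapped[sp] = seen

    characters = sorted({key for m in mapped.values() for key in m})
    provenance: dict = {}
    data = {}
    for sp in tips:
        if sp not in msa:
            data[sp] = [UNKNOWN] * len(characters)
            provenance[sp] = {key: "no data" for key in characters}
            continue
        row = msa[sp]
        states, prov = [], {}
        for key in characters:
            col, _phase = key
            if key in mapped.get(sp, {}):
                states.append(PRESENT)
                prov[key] = f"residue {mapped[sp][key].anchor}"
            elif row[col - 1] == "-":
                states.append(UNKNOWN if gap_policy == UNKNOWN else ABSENT)
                prov[key] = "gap at column"
            else:
                states.append(ABSENT)
                prov[key] = "no intron"
        data[sp] = states
        provenance[sp] = prov

    states = pd.DataFrame.from_dict(data, orient="index",
                                    columns=pd.MultiIndex.from_tuples(
                                        characters, names=["column", "phase"])
                                    if characters else [])
    states = states.reindex(tips)
    return SiteMatrix(family_id=family_id, sites=characters, states=states,
                      provenance=provenance)


def render_annotated_alignment(matrix: SiteMatrix, msa: dict[str, str]) -> str:
    """Text rendering with '|' markers after each species' splice positions.

    Mirrors the display convention of annotated curated alignments: each row
    shows the aligned protein with a pipe inserted after every column where
    that species carries an intron (phase shown in the header per site).
    """
    header = [f"# family {matrix.family_id}: "
              f"{matrix.n_sites} site(s): "
              + ", ".join(f"col{c}/p{p}" for c, p in matrix.sites)]
    width = max((len(sp) for sp in msa), default=0)
    lines = []
    for sp in sorted(msa):
        row = msa[sp]
        present_cols = {c for (c, p) in matrix.sites
                        if sp in matrix.states.index
                        and matrix.states.loc[sp, (c, p)] == PRESENT}
        chars = []
        for col, ch in enumerate(row, start=1):
            chars.append(ch)
            if col in present_cols:
                chars.append("|")
        lines.append(f"{sp:<{width}}  " + "".join(chars))
    return "\n".join(header + lines) + "\n"
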