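"""Simulation of intron presence/absence evolution and gene-model emission.

The generator plays the role of the curated ortholog datasets the inference
stages are designed for: ortholog families evolve intron presence/absence on
a rooted species tree under per-branch Poisson gain and loss processes, and
the resulting per-species gene structures are materialised as internally
consistent GFF3 + genome FASTA + protein FASTA + protein MSA files, together
with the true event history for ground-truth checks.

Design of the process
---------------------
* An intron *site* is a (anchor residue, phase) slot in the ancestral protein;
  a gene of length L offers the slots with coding offset 1 .. 3L-1.
* Gains per branch are Poisson with mean ``gain_rate x branch_length`` and
  draw a slot unused anywhere in the history so far, so independent lineages
  never create colliding characters (the emitted data then round-trips to the
  exact tip presence matrix).
* Losses per branch are Poisson with mean ``loss_rate x branch_length x
  n_present`` and remove sites uniformly without replacement.
* Emitted nucleotide sequences use a random codon per residue and fixed-length
  introns (default 60 nt) with canonical GT..AG boundaries; downstream stages
  use coordinates only, never splice motifs.
* Optional indels insert/delete whole codons only, so true alignment columns
  stay well defined; a species never deletes a residue that anchors one of
  its own introns.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .genemodel_io import IntronSite
from .trees import SpeciesTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _AA_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_CODONS.values():
    codons.sort()


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generative process.

    Defaults emulate a large, conserved, intron-rich insect gene family of the
    kind the comparative analysis targets: a 400-residue protein carrying 20
    ancestral introns, with slow turnover (a handful of expected changes per
    family across an 8-species tree of unit branch lengths).
    """

    n_ancestral_sites: int = 20
    gain_rate: float = 0.3    # expected gains per unit branch length
    loss_rate: float = 0.02   # per present site per unit branch length
    protein_length: int = 400
    indel_rate: float = 0.0   # per-residue whole-codon indel probability
    seed: int = 0
    intron_length: int = 60
    max_events_per_site: Optional[int] = None  # 1 => homoplasy-free regime

    def __post_init__(self):
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise SimulationError("rates must be >= 0")
        if self.n_ancestral_sites < 0:
            raise SimulationError("n_ancestral_sites must be >= 0")
        if self.protein_length < 10:
            raise SimulationError("protein_length must be >= 10")


@dataclass(frozen=True)
class Event:
    branch: str          # name of the child node of the branch
    site: str            # site id
    direction: str       # "gain" | "loss"


@dataclass
class TrueHistory:
    """Ground truth: root sites, per-branch events, resulting tip matrix."""

    family_id: str
    root_sites: dict[str, IntronSite]
    sites: dict[str, IntronSite]            # every site ever existing
    events: list[Event]
    tip_sites: dict[str, frozenset[str]]    # species -> present site ids

    def verify(self, tree: SpeciesTree) -> None:
        """Replay events along the tree; raise if tip_sites disagree."""
        events_by_branch: dict[str, list[Event]] = {}
        for ev in self.events:
            events_by_branch.setdefault(ev.branch, []).append(ev)
        state: dict[str, set[str]] = {tree.root.name: set(self.root_sites)}
        for node in tree.preorder():
            if node.parent is None:
                continue
            current = set(state[node.parent.name])
            for ev in events_by_branch.get(node.name, []):
                if ev.direction == "gain":
                    if ev.site in current:
                        raise SimulationError(
                            f"gain of {ev.site} on {node.name}: already present")
                    current.add(ev.site)
                else:
                    if ev.site not in current:
                        raise SimulationError(
                            f"loss of {ev.site} on {node.name}: absent")
                    current.remove(ev.site)
            state[node.name] = current
        for tip in tree.tips():
            if frozenset(state[tip.name]) != self.tip_sites[tip.name]:
                raise SimulationError(
                    f"tip matrix inconsistent with events at {tip.name}")

    def n_events_per_site(self) -> dict[str, int]:
        counts = {s: 0 for s in self.sites}
        for ev in self.events:
            counts[ev.site] += 1
        return counts

    def is_homoplasy_free(self) -> bool:
        return all(n <= 1 for n in self.n_events_per_site().values())

    # -------------------------------------------------------------- json
    def to_json_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "root_sites": {k: [v.anchor, v.phase]
                           for k, v in sorted(self.root_sites.items())},
            "sites": {k: [v.anchor, v.phase]
                      for k, v in sorted(self.sites.items())},
            "events": [[e.branch, e.site, e.direction] for e in self.events],
            "tip_sites": {sp: sorted(ids)
                          for sp, ids in sorted(self.tip_sites.items())},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TrueHistory":
        return cls(
            family_id=d["family_id"],
            root_sites={k: IntronSite(*v) for k, v in d["root_sites"].items()},
            sites={k: IntronSite(*v) for k, v in d["sites"].items()},
            events=[Event(*e) for e in d["events"]],
            tip_sites={sp: frozenset(ids)
                       for sp, ids in d["tip_sites"].items()},
        )


def _all_slots(protein_length: int) -> list[IntronSite]:
    """Every legal (anchor, phase) slot: coding offsets 1 .. 3L-1."""
    return [IntronSite.from_coding_offset(c)
            for c in range(1, 3 * protein_length)]


def simulate_history(tree: SpeciesTree, params: SimulationParams,
                     family_id: str = "fam1") -> TrueHistory:
    """Evolve intron presence/absence along the tree; reproducible by seed."""
    tips = tree.tip_names()
    if not tips:
        raise SimulationError("tree has no tips")
    rng = np.random.default_rng([params.seed, 0x51])

    pool = _all_slots(params.protein_length)
    if params.n_ancestral_sites > len(pool):
        raise SimulationError(
            f"protein_length {params.protein_length} offers only {len(pool)} "
            f"slots; cannot host {params.n_ancestral_sites} ancestral sites")

    free = list(range(len(pool)))
    chosen = rng.choice(len(free), size=params.n_ancestral_sites,
                        replace=False) if params.n_ancestral_sites else []
    chosen = sorted(int(i) for i in np.atleast_1d(chosen))
    site_counter = 0
    sites: dict[str, IntronSite] = {}
    root_sites: dict[str, IntronSite] = {}
    for idx in chosen:
        site_counter += 1
        sid = f"s{site_counter:03d}"
        root_sites[sid] = sites[sid] = pool[idx]
    used = set(chosen)

    events: list[Event] = []
    event_count: dict[str, int] = {s: 0 for s in sites}
    state: dict[str, set[str]] = {tree.root.name: set(root_sites)}

    for node in tree.preorder():
        if node.parent is None:
            continue
        present = set(state[node.parent.name])
        L = node.length

        # Losses first, drawn from the state at the branch start.
        candidates = sorted(present)
        if params.max_events_per_site == 1:
            candidates = [s for s in candidates if event_count[s] == 0]
        n_loss = int(rng.poisson(params.loss_rate * L * len(present)))
        n_loss = min(n_loss, len(candidates))
        if n_loss:
            lost = rng.choice(len(candidates), size=n_loss, replace=False)
            for i in sorted(int(x) for x in lost):
                sid = candidates[i]
                present.remove(sid)
                events.append(Event(node.name, sid, "loss"))
                event_count[sid] += 1

        # Gains draw globally fresh slots.
        n_gain = int(rng.poisson(params.gain_rate * L))
        for _ in range(n_gain):
            free_now = [i for i in range(len(pool)) if i not in used]
            if not free_now:
                raise SimulationError(
                    "distinct (residue, phase) slots exhausted; "
                    "increase protein_length or lower gain_rate")
            idx = int(rng.choice(len(free_now)))
            slot = free_now[idx]
            used.add(slot)
            site_counter += 1
            sid = f"s{site_counter:03d}"
            sites[sid] = pool[slot]
            present.add(sid)
            events.append(Event(node.name, sid, "gain"))
            event_count[sid] = 1

        state[node.name] = present

    history = TrueHistory(
        family_id=family_id,
        root_sites=root_sites,
        sites=sites,
        events=events,
        tip_sites={t: frozenset(state[t]) for t in tips},
    )
    history.verify(tree)
    return history


# ---------------------------------------------------------------------------
# Emission of gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneEmission:
    species: str
    contig_id: str
    contig_seq: str
    strand: str
    cds_exons: list[tuple[int, int]]   # ascending genomic coordinates
    phases: list[int]                  # transcription order
    protein: str


@dataclass
class FamilyEmission:
    family_id: str
    genes: dict[str, GeneEmission]     # keyed by species
    msa: dict[str, str]                # aligned rows keyed by species
    local_sites: dict[str, dict[str, IntronSite]]  # species -> site id -> local


def emit_family(history: TrueHistory, tree: SpeciesTree,
                params: SimulationParams,
                forced_deletions: Optional[dict[str, set[int]]] = None,
                ) -> FamilyEmission:
    """Materialise one family's per-species gene structures and its MSA.

    ``forced_deletions`` maps species to ancestral residue positions deleted
    regardless of ``indel_rate`` (used to construct gap-containing fixtures);
    positions anchoring a present intron of that species are rejected.
    """
    rng = np.random.default_rng(
        [params.seed, 0xE7, zlib.crc32(history.family_id.encode())])
    L = params.protein_length
    species_order = sorted(tree.tip_names())
    ancestral = "M" + "".join(
        rng.choice(list(AMINO_ACIDS), size=L - 1))

    # Anchors each species must keep.
    protected: dict[str, set[int]] = {}
    for sp in species_order:
        protected[sp] = {history.sites[sid].anchor
                         for sid in history.tip_sites[sp]} | {1}

    deletions: dict[str, set[int]] = {sp: set() for sp in species_order}
    insertions: dict[str, dict[int, str]] = {sp: {} for sp in species_order}
    if forced_deletions:
        for sp, positions in forced_deletions.items():
            bad = positions & protected[sp]
            if bad:
                raise SimulationError(
                    f"cannot delete anchor residues {sorted(bad)} in {sp}")
            deletions[sp] |= set(positions)
    if params.indel_rate > 0:
        for sp in species_order:
            for j in range(2, L + 1):
                u = rng.random()
                if u < params.indel_rate / 2 and j not in protected[sp]:
                    deletions[sp].add(j)
                elif u < params.indel_rate:
                    insertions[sp][j] = str(rng.choice(list(AMINO_ACIDS)))

    # Global column layout: ancestral column j, then any insertion columns
    # after j, one per inserting species, in species order.
    columns: list[tuple] = []
    for j in range(1, L + 1):
        columns.append(("anc", j))
        for sp in species_order:
            if j in insertions[sp]:
                columns.append(("ins", j, sp))

    rows: dict[str, str] = {}
    residue_index_of_anchor: dict[str, dict[int, int]] = {}
    for sp in species_order:
        chars = []
        local = 0
        anchor_map: dict[int, int] = {}
        for col in columns:
            if col[0] == "anc":
                j = col[1]
                if j in deletions[sp]:
                    chars.append("-")
                else:
                    chars.append(ancestral[j - 1])
                    local += 1
                    anchor_map[j] = local
            else:
                _, j, owner = col
                if owner == sp:
                    chars.append(insertions[sp][j])
                    local += 1
                else:
                    chars.append("-")
        rows[sp] = "".join(chars)
        residue_index_of_anchor[sp] = anchor_map

    genes: dict[str, GeneEmission] = {}
    local_sites: dict[str, dict[str, IntronSite]] = {}
    for i, sp in enumerate(species_order):
        protein = rows[sp].replace("-", "")
        locs: dict[str, IntronSite] = {}
        for sid in sorted(history.tip_sites[sp]):
            anc = history.sites[sid]
            r_local = residue_index_of_anchor[sp][anc.anchor]
            locs[sid] = IntronSite(anchor=r_local, phase=anc.phase)
        offsets = sorted(s.coding_offset for s in locs.values())
        if len(set(offsets)) != len(offsets):
            raise SimulationError(
                f"two introns at one (residue, phase) slot in {sp}")
        local_sites[sp] = locs

        cds = "".join(str(rng.choice(_AA_CODONS[aa])) for aa in protein)
        cds += "TAA"  # stop codon included in the CDS features

        pieces = []
        prev = 0
        for c in offsets:
            pieces.append(cds[prev:c])
            prev = c
        pieces.append(cds[prev:])

        flank = "".join(rng.choice(list("ACGT"), size=50))
        flank2 = "".join(rng.choice(list("ACGT"), size=50))
        body_parts, exon_coords = [], []
        pos = len(flank)
        for k, piece in enumerate(pieces):
            if k > 0:
                intron = ("GT"
                          + "".join(rng.choice(list("ACGT"),
                                               size=params.intron_length - 4))
                          + "AG")
                body_parts.append(intron)
                pos += params.intron_length
            body_parts.append(piece)
            exon_coords.append((pos + 1, pos + len(piece)))  # 1-based incl.
            pos += len(piece)
        plus_contig = flank + "".join(body_parts) + flank2

        strand = "+" if i % 2 == 0 else "-"
        phases_tx = [(3 - (c % 3)) % 3 for c in [0] + offsets]
        if strand == "+":
            contig_seq = plus_contig
            exons = exon_coords
        else:
            Lc = len(plus_contig)
            contig_seq = str(Seq(plus_contig).reverse_complement())
            exons = sorted((Lc - e + 1, Lc - s + 1) for (s, e) in exon_coords)

        genes[sp] = GeneEmission(
            species=sp,
            contig_id=f"{history.family_id}_{sp}",
            contig_seq=contig_seq,
            strand=strand,
            cds_exons=exons,
            phases=phases_tx,
            protein=protein,
        )

    return FamilyEmission(family_id=history.family_id, genes=genes,
                          msa=rows, local_sites=local_sites)


def write_study(outdir, tree: SpeciesTree, emissions: Sequence[FamilyEmission],
                histories: Sequence[TrueHistory],
                genome_sizes: Optional[dict[str, float]] = None) -> dict:
    """Write a complete study directory; returns the path manifest.

    Layout::

        outdir/tree.nwk
        outdir/species/<sp>.genome.fa, <sp>.gff3, <sp>.proteins.fa
        outdir/families/<fam>.aln.fa
        outdir/truth/<fam>.history.json
        outdir/genome_sizes.tsv          (if provided)
    """
    outdir = str(outdir)
    species_dir = os.path.join(outdir, "species")
    fam_dir = os.path.join(outdir, "families")
    truth_dir = os.path.join(outdir, "truth")
    for d in (outdir, species_dir, fam_dir, truth_dir):
        os.makedirs(d, exist_ok=True)

    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(tree.to_newick() + "\n")

    species = sorted(tree.tip_names())
    manifest = {"tree": os.path.join(outdir, "tree.nwk"), "species": {},
                "families": {}, "truth": {}}
    for sp in species:
        fa = os.path.join(species_dir, f"{sp}.genome.fa")
        gff = os.path.join(species_dir, f"{sp}.gff3")
        pfa = os.path.join(species_dir, f"{sp}.proteins.fa")
        with open(fa, "w") as fa_fh, open(gff, "w") as gff_fh, \
                open(pfa, "w") as pfa_fh:
            gff_fh.write("##gff-version 3\n")
            for em in emissions:
                gene = em.genes[sp]
                fa_fh.write(f">{gene.contig_id}\n{gene.contig_seq}\n")
                gid = f"{em.family_id}__{sp}"
                tid = f"{gid}.t1"
                start = min(s for s, _ in gene.cds_exons)
                end = max(e for _, e in gene.cds_exons)
                gff_fh.write(
                    f"{gene.contig_id}\tintronevo\tgene\t{start}\t{end}\t.\t"
                    f"{gene.strand}\t.\tID={gid};family={em.family_id}\n")
                gff_fh.write(
                    f"{gene.contig_id}\tintronevo\tmRNA\t{start}\t{end}\t.\t"
                    f"{gene.strand}\t.\tID={tid};Parent={gid}\n")
                phases = gene.phases if gene.strand == "+" \
                    else gene.phases[::-1]
                for k, ((s, e), ph) in enumerate(zip(gene.cds_exons, phases)):
                    gff_fh.write(
                        f"{gene.contig_id}\tintronevo\tCDS\t{s}\t{e}\t.\t"
                        f"{gene.strand}\t{ph}\t"
                        f"ID={tid}.cds{k + 1};Parent={tid}\n")
                pfa_fh.write(f">{gid}\n{gene.protein}\n")
        manifest["species"][sp] = {"genome": fa, "gff3": gff, "proteins": pfa}

    for em, hist in zip(emissions, histories):
        aln = os.path.join(fam_dir, f"{em.family_id}.aln.fa")
        with open(aln, "w") as fh:
            for sp in species:
                fh.write(f">{sp}\n{em.msa[sp]}\n")
        tj = os.path.join(truth_dir, f"{em.family_id}.history.json")
        with open(tj, "w") as fh:
            json.dump(hist.to_json_dict(), fh, indent=1, sort_keys=True)
        manifest["families"][em.family_id] = aln
        manifest["truth"][em.family_id] = tj

    if genome_sizes is not None:
        gs = os.path.join(outdir, "genome_sizes.tsv")
        with open(gs, "w") as fh:
            fh.write("species\tgenome_mb\n")
            for sp in species:
                fh.write(f"{sp}\t{genome_sizes[sp]:.1f}\n")
        manifest["genome_sizes"] = gs

    return manifest


def emit_gene_models(history: TrueHistory, tree: SpeciesTree,
                     params: SimulationParams, outdir) -> dict:
    """Emit a single-family study directory for ``history``."""
    em = emit_family(history, tree, params)
    return write_study(outdir, tree, [em], [history])


# ---------------------------------------------------------------------------
# Constructed and sized studies
# ---------------------------------------------------------------------------

def eight_species_tree() -> SpeciesTree:
    """8-tip rooted binary tree shaped like a holometabolan/hemipteroid split."""
    return SpeciesTree.from_newick(
        "(((Ccap:1,Dmel:1)Dipt:1,(Agla:1,Tcas:1)Col:1)Holo:1,"
        "(Focc:1,(Apis:1,(Gbue:1,Ofas:1)Heterop:1)Hemi:1)Hemipt:1)Root;")


def constructed_history(family_id: str, tree: SpeciesTree,
                        root_slots: Sequence[IntronSite],
                        event_spec: Sequence[tuple[str, str, str]],
                        extra_sites: Optional[dict[str, IntronSite]] = None,
                        ) -> TrueHistory:
    """Build a TrueHistory by hand.

    ``event_spec`` entries are (branch name, site id, direction); site ids
    ``a1..aN`` refer to root slots in order, other ids must appear in
    ``extra_sites`` with their slot.
    """
    root_sites = {f"a{i + 1}": s for i, s in enumerate(root_slots)}
    sites = dict(root_sites)
    if extra_sites:
        sites.update(extra_sites)
    events = [Event(*e) for e in event_spec]

    events_by_branch: dict[str, list[Event]] = {}
    for ev in events:
        events_by_branch.setdefault(ev.branch, []).append(ev)
    state = {tree.root.name: set(root_sites)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        cur = set(state[node.parent.name])
        for ev in events_by_branch.get(node.name, []):
            if ev.direction == "gain":
                cur.add(ev.site)
            else:
                cur.discard(ev.site)
        state[node.name] = cur
    hist = TrueHistory(
        family_id=family_id, root_sites=root_sites, sites=sites,
        events=events,
        tip_sites={t: frozenset(state[t]) for t in tree.tip_names()})
    hist.verify(tree)
    return hist


def sized_study(tree: SpeciesTree, n_sites: int = 148, n_events: int = 165,
                n_families: int = 3, n_constant_sites: int = 24,
                protein_length: int = 900, seed: int = 0,
                ) -> tuple[list[TrueHistory], SimulationParams]:
    """Construct a study with exactly ``n_sites`` variable sites carrying
    exactly ``n_events`` parsimony-recoverable changes.

    Each variable site carries either one event (a single gain or a single
    loss on a uniformly chosen branch) or two events (independent parallel
    losses of an ancestral site on two branches chosen so that neither the
    absent-tip set nor the present-tip set forms a clade — which guarantees,
    by clade logic alone, that the minimal change count equals two).  Constant
    ancestral sites (no events, retained in all species) are added for
    root-retention reporting and contribute no changes.
    """
    if n_events < n_sites or n_events > 2 * n_sites:
        raise SimulationError(
            "n_events must lie in [n_sites, 2 * n_sites] for the "
            "one/two-event construction")
    rng = np.random.default_rng([seed, 0x5D])
    branches = [n for n in tree.branches()]
    clades = {tree.clade_tips(n) for n in tree.preorder()}
    all_tips = frozenset(tree.tip_names())

    # Candidate branch pairs for guaranteed-score-2 parallel losses.
    pairs = []
    for i, u in enumerate(branches):
        for v in branches[i + 1:]:
            if tree.is_ancestor(u, v) or tree.is_ancestor(v, u):
                continue
            absent = tree.clade_tips(u) | tree.clade_tips(v)
            present = all_tips - absent
            if not present or absent in clades or present in clades:
                continue
            pairs.append((u.name, v.name))
    if not pairs:
        raise SimulationError("tree offers no valid parallel-loss pair")

    n_two = n_events - n_sites
    site_kinds = ["two"] * n_two + ["one"] * (n_sites - n_two)

    per_fam = np.array_split(np.arange(n_sites + n_constant_sites), n_families)
    kinds_all = site_kinds + ["const"] * n_constant_sites

    histories = []
    params = SimulationParams(protein_length=protein_length, seed=seed,
                              n_ancestral_sites=0)
    for f, idxs in enumerate(per_fam):
        fam_kinds = [kinds_all[i] for i in idxs]
        pool = _all_slots(protein_length)
        slot_idx = rng.choice(len(pool), size=len(fam_kinds), replace=False)
        slots = [pool[int(i)] for i in sorted(int(x) for x in slot_idx)]

        root_slots, event_spec, extra = [], [], {}
        gain_counter = 0
        for kind, slot in zip(fam_kinds, slots):
            if kind == "const":
                root_slots.append(slot)
            elif kind == "two":
                root_slots.append(slot)
                u, v = pairs[int(rng.integers(len(pairs)))]
                sid = f"a{len(root_slots)}"
                event_spec.append((u, sid, "loss"))
                event_spec.append((v, sid, "loss"))
            else:  # one event: coin-flip loss of ancestral vs fresh gain
                if rng.random() < 0.5:
                    root_slots.append(slot)
                    b = branches[int(rng.integers(len(branches)))]
                    event_spec.append((b.name, f"a{len(root_slots)}", "loss"))
                else:
                    gain_counter += 1
                    sid = f"g{gain_counter:03d}"
                    extra[sid] = slot
                    b = branches[int(rng.integers(len(branches)))]
                    event_spec.append((b.name, sid, "gain"))

        # Root-slot ids are assigned by order of appending; rebuild spec with
        # correct ids (they were appended in order, so ids already match).
        histories.append(constructed_history(
            f"fam{f + 1}", tree, root_slots, event_spec, extra))

    return histories, params


def synthetic_genome_sizes(tree: SpeciesTree,
                           histories: Sequence[TrueHistory],
                           seed: int = 0) -> dict[str, float]:
    """Genome sizes (Mb) increasing with a species' total intron count.

    The generator's world realises the positive genome-size/intron-number
    association the correlation stage is meant to detect: size is an affine
    function of the species' intron count plus seeded noise.
    """
    rng = np.random.default_rng([seed, 0x65])
    counts = {sp: 0 for sp in tree.tip_names()}
    for hist in histories:
        for sp, ids in hist.tip_sites.items():
            counts[sp] += len(ids)
    return {sp: 150.0 + 8.0 * counts[sp] + float(rng.normal(0, 5))
            for sp in sorted(counts)}


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

def _panel_families(tree: SpeciesTree) -> list[TrueHistory]:
    """Hand-constructed 4-tip families exercising each inference edge case."""
    s = IntronSite
    return [
        constructed_history("zero_change", tree,
                            [s(10, 0), s(20, 1)], []),
        constructed_history("single_gain", tree, [s(10, 0)],
                            [("A", "g001", "gain")],
                            extra_sites={"g001": s(30, 2)}),
        constructed_history("single_loss", tree, [s(10, 0), s(25, 0)],
                            [("A", "a2", "loss")]),
        constructed_history("tie_inducing", tree, [],
                            [("A", "g001", "gain"), ("C", "g001", "gain")],
                            extra_sites={"g001": s(15, 1)}),
        constructed_history("parallel_loss", tree, [s(12, 0)],
                            [("A", "a1", "loss"), ("C", "a1", "loss")]),
        constructed_history("gap_containing", tree, [s(10, 0), s(40, 2)],
                            [("D", "a2", "loss")]),
    ]


def generate_fixture_suite(preset: str, outdir, seed: int = 0) -> dict:
    """Materialise a named small study used by the test suite.

    Presets:

    * ``minimal`` — 2-tip tree, 1 simulated family.
    * ``eight-species`` — the 8-tip tree with 3 simulated families.
    * ``panel`` — 4-tip tree with the 6 constructed edge-case families
      (zero-change, single-gain, single-loss, tie-inducing, parallel-loss,
      gap-containing; the last is emitted with a forced deletion so one
      species shows a gap at a site column).
    """
    if preset == "minimal":
        tree = SpeciesTree.from_newick("(A:1,B:1)R;")
        params = SimulationParams(seed=seed, n_ancestral_sites=5,
                                  protein_length=120)
        hists = [simulate_history(tree, params, "fam1")]
        ems = [emit_family(h, tree, params) for h in hists]
    elif preset == "eight-species":
        tree = eight_species_tree()
        hists, ems = [], []
        for f in range(3):
            params = SimulationParams(seed=seed + f, n_ancestral_sites=20,
                                      protein_length=400)
            h = simulate_history(tree, params, f"fam{f + 1}")
            hists.append(h)
            ems.append(emit_family(h, tree, params))
        params = SimulationParams(seed=seed)
    elif preset == "panel":
        tree = SpeciesTree.from_newick("((A:1,B:1)AB:1,(C:1,D:1)CD:1)R;")
        params = SimulationParams(seed=seed, n_ancestral_sites=0,
                                  protein_length=120)
        hists = _panel_families(tree)
        ems = []
        for h in hists:
            forced = None
            if h.family_id == "gap_containing":
                # D lost site a2 (anchor 40) and additionally deleted the
                # anchor residue: its state at that column becomes a gap.
                forced = {"D": {40}}
            ems.append(emit_family(h, tree, params,
                                   forced_deletions=forced))
    else:
        raise ValueError(f"unknown fixture preset: {preset!r}")

    sizes = synthetic_genome_sizes(tree, hists, seed=seed)
    manifest = write_study(outdir, tree, ems, hists, genome_sizes=sizes)
    manifest["preset"] = preset
    manifest["seed"] = seed
    with open(os.path.join(str(outdir), "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
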