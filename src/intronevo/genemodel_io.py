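"""Gene-model input, validation, and intron positions in protein coordinates.

The core quantity is the *coding-nucleotide offset* ``c`` of an intron: the
number of coding nucleotides 5' of the intron within the mRNA.  It determines

* the intron **phase** ``p = c mod 3`` (0 between codons, 1 after the first
  nucleotide of a codon, 2 after the second), and
* the **anchor residue** ``r`` — for ``p = 0`` the residue immediately 5' of
  the junction (``r = c / 3``); for ``p > 0`` the residue whose codon the
  intron interrupts (``r = floor(c / 3) + 1``).

The same convention is applied in simulation and inference, so downstream
results do not depend on it.

GFF3 parsing goes through :mod:`gffutils` (in-memory DB); sequences through
:mod:`pyfaidx` and :mod:`Bio.Seq`.  Coordinates are GFF3 1-based inclusive
throughout; protein coordinates are 1-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from pyfaidx import Fasta

from .trees import SpeciesTree

STOP_CODONS = {"TAA", "TAG", "TGA"}


class GeneModelError(ValueError):
    """Fatal gene-model input problem (e.g. missing contig)."""


@dataclass(frozen=True, order=True)
class IntronSite:
    """An intron's position in protein coordinates: (anchor residue, phase)."""

    anchor: int  # 1-based residue index
    phase: int   # 0, 1 or 2

    def __post_init__(self):
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0/1/2, got {self.phase}")
        if self.anchor < 1:
            raise ValueError(f"anchor must be >= 1, got {self.anchor}")

    @property
    def coding_offset(self) -> int:
        """Coding nucleotides 5' of the intron implied by (anchor, phase)."""
        if self.phase == 0:
            return 3 * self.anchor
        return 3 * (self.anchor - 1) + self.phase

    @classmethod
    def from_coding_offset(cls, c: int) -> "IntronSite":
        p = c % 3
        r = c // 3 if p == 0 else c // 3 + 1
        return cls(anchor=r, phase=p)


@dataclass
class GeneModel:
    """One species' gene: ordered coding exons plus the translated protein.

    ``cds_exons`` are (contig, start, end) 1-based inclusive intervals in
    *transcription order* (minus-strand genes have descending coordinates).
    """

    species: str
    gene_id: str
    transcript_id: str
    strand: str
    cds_exons: list[tuple[str, int, int]]
    phases: list[int]
    protein: str
    attributes: dict = field(default_factory=dict)
    valid: bool = True
    invalid_reason: str = ""

    @property
    def exon_nt_lengths(self) -> list[int]:
        return [end - start + 1 for (_, start, end) in self.cds_exons]

    @property
    def cds_length(self) -> int:
        return sum(self.exon_nt_lengths)

    @property
    def n_exons(self) -> int:
        return len(self.cds_exons)


def expected_phases(exon_nt_lengths: Iterable[int]) -> list[int]:
    """GFF3 phases implied by cumulative upstream coding length."""
    phases, cum = [], 0
    for length in exon_nt_lengths:
        phases.append((3 - cum % 3) % 3)
        cum += length
    return phases


def _translate(cds: str) -> tuple[str, int, str]:
    """Translate a CDS, trimming a trailing stop codon if present.

    Returns (protein, trimmed_nt, problem); ``problem`` is "" when clean.
    Trailing-stop trimming happens before the divisible-by-3 check because
    GFF3 dialects differ on whether the stop codon belongs to the CDS.
    """
    cds = cds.upper()
    trimmed = 0
    if len(cds) % 3 == 0 and len(cds) >= 6 and cds[-3:] in STOP_CODONS:
        cds, trimmed = cds[:-3], 3
    if len(cds) % 3 != 0:
        return "", trimmed, f"CDS length {len(cds)} not divisible by 3"
    protein = str(Seq(cds).translate())
    if "*" in protein:
        return protein, trimmed, "internal stop codon in translation"
    return protein, trimmed, ""


def parse_gene_models(
    gff3_path,
    fasta_path,
    species: str,
    isoform_policy: str = "longest_cds",
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Read gene models from GFF3 + genome FASTA, one isoform per gene.

    ``isoform_policy`` currently supports ``"longest_cds"`` (ties broken by
    lexicographically smallest transcript id).  Returns the models (invalid
    ones flagged, not dropped) and a validation report with columns
    (gene_id, status, reason).
    """
    if isoform_policy != "longest_cds":
        raise ValueError(f"unknown isoform policy: {isoform_policy!r}")
    if not os.path.exists(str(fasta_path)):
        raise GeneModelError(f"genome FASTA not found: {fasta_path}")

    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genome = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    models: list[GeneModel] = []
    report_rows: list[dict] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            report_rows.append(
                {"gene_id": gene.id, "status": "skipped", "reason": "no mRNA"}
            )
            continue

        def cds_of(mrna):
            return list(db.children(mrna, featuretype="CDS", order_by="start"))

        # Isoform choice: longest total CDS, ties to smallest transcript id.
        mrna = min(
            mrnas,
            key=lambda m: (-sum(c.end - c.start + 1 for c in cds_of(m)), m.id),
        )
        cds = cds_of(mrna)
        if not cds:
            report_rows.append(
                {"gene_id": gene.id, "status": "skipped",
                 "reason": f"isoform {mrna.id} has no CDS"}
            )
            continue

        strand = cds[0].strand
        if strand == "-":
            cds = cds[::-1]  # transcription order
        contig = cds[0].seqid
        if contig not in genome:
            raise GeneModelError(
                f"contig {contig!r} referenced by {gene.id} missing from FASTA"
            )

        exons = [(c.seqid, c.start, c.end) for c in cds]
        seq_parts = []
        for c in cds:
            part = str(genome[c.seqid][c.start - 1:c.end])
            if strand == "-":
                part = str(Seq(part).reverse_complement())
            seq_parts.append(part)
        protein, trimmed, problem = _translate("".join(seq_parts))

        given_phases = [
            int(c.frame) if c.frame not in (".", None) else -1 for c in cds
        ]
        want = expected_phases(
            [c.end - c.start + 1 for c in cds]
        )
        if not problem and given_phases != want:
            problem = (
                f"phase mismatch: annotated {given_phases}, expected {want}"
            )

        model = GeneModel(
            species=species, gene_id=gene.id, transcript_id=mrna.id,
            strand=strand, cds_exons=exons, phases=want, protein=protein,
            attributes={k: v[0] for k, v in gene.attributes.items()},
            valid=not problem, invalid_reason=problem,
        )
        if trimmed:
            model.attributes["stop_codon_trimmed"] = "3nt"
        models.append(model)
        report_rows.append(
            {"gene_id": gene.id,
             "status": "ok" if model.valid else "invalid",
             "reason": problem}
        )

    report = pd.DataFrame(report_rows, columns=["gene_id", "status", "reason"])
    return models, report


def derive_intron_sites(gene: GeneModel) -> list[IntronSite]:
    """Protein-coordinate intron positions of a gene, in coding order.

    One site per junction between consecutive coding exons; junctions falling
    outside the coding region (c = 0 or c = total CDS length, impossible for
    well-formed models) are excluded.
    """
    if not gene.valid:
        raise GeneModelError(
            f"gene {gene.gene_id} flagged invalid: {gene.invalid_reason}"
        )
    total = 3 * len(gene.protein)
    sites, cum = [], 0
    lengths = gene.exon_nt_lengths
    # A retained stop codon inflates the final exon only; junction offsets
    # are unaffected.
    for length in lengths[:-1]:
        cum += length
        if cum <= 0 or cum >= total:
            continue
        sites.append(IntronSite.from_coding_offset(cum))
    offsets = [s.coding_offset for s in sites]
    if len(set(offsets)) != len(offsets) or offsets != sorted(offsets):
        raise GeneModelError(
            f"gene {gene.gene_id}: intron sites not strictly ordered"
        )
    return sites


def read_tree(newick_path) -> SpeciesTree:
    """Read a rooted Newick species tree (basal trifurcation is rejected)."""
    return SpeciesTree.read(newick_path)


def read_alignment(fasta_path, proteins: Optional[dict[str, str]] = None
                   ) -> dict[str, str]:
    """Read a protein MSA (aligned FASTA) keyed by species.

    If ``proteins`` is given, each row with gaps removed must equal that
    species' protein; mismatches raise with the offending species named.
    """
    aln = AlignIO.read(str(fasta_path), "fasta")
    rows = {rec.id: str(rec.seq) for rec in aln}
    lengths = {len(row) for row in rows.values()}
    if len(lengths) > 1:
        raise GeneModelError(f"alignment rows differ in length: {lengths}")
    if proteins:
        for sp, row in rows.items():
            if sp in proteins and row.replace("-", "") != proteins[sp]:
                raise GeneModelError(
                    f"MSA row for species {sp!r} does not match its protein"
                )
    return rows


def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_validation_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
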