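"""Construction helpers shared by the tests."""

from __future__ import annotations

from intronevo.genemodel_io import GeneModel, expected_phases


def make_model(species: str, gene_id: str, exon_nt_lengths: list[int],
               strand: str = "+") -> GeneModel:
    """A synthetic validated GeneModel with the given coding-exon lengths.

    Coordinates are laid out on a fake contig with 100-nt introns; the
    protein is a poly-alanine of the implied length (lengths must sum to a
    multiple of 3).
    """
    total = sum(exon_nt_lengths)
    assert total % 3 == 0, "exon lengths must sum to a codon multiple"
    exons, pos = [], 1
    for nt in exon_nt_lengths:
        exons.append(("chr", pos, pos + nt - 1))
        pos += nt + 100
    return GeneModel(
        species=species, gene_id=gene_id, transcript_id=f"{gene_id}.t1",
        strand=strand, cds_exons=exons,
        phases=expected_phases(exon_nt_lengths),
        protein="A" * (total // 3),
    )


TWO_ISOFORM_GFF = """\
##gff-version 3
chr1\ttest\tgene\t1\t1000\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t1\t1000\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttest\tCDS\t101\t400\t.\t+\t0\tID=geneA.t1.cds1;Parent=geneA.t1
chr1\ttest\tmRNA\t1\t1000\t.\t+\t.\tID=geneA.t2;Parent=geneA
chr1\ttest\tCDS\t101\t370\t.\t+\t0\tID=geneA.t2.cds1;Parent=geneA.t2
"""


def write_two_isoform_inputs(tmp_path):
    """A gene with 300-nt and 270-nt CDS isoforms plus its contig."""
    gff = tmp_path / "two_isoform.gff3"
    gff.write_text(TWO_ISOFORM_GFF)
    fasta = tmp_path / "two_isoform.fa"
    # 'GCT' repeats = poly-Ala; no stop codons anywhere.
    fasta.write_text(">chr1\n" + "GCT" * 400 + "\n")
    return gff, fasta
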