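#!/usr/bin/env python
"""Project intron positions onto each family's protein alignment.

Derives every gene's intron positions in protein coordinates, maps them to
alignment columns, and merges them into homologous splice-site characters
(column, phase) scored present/absent/unknown per species.  Writes one
character table and one '|'-annotated alignment per family under
results/sites/.
"""

import glob
import os
import sys

from intronevo.genemodel_io import (derive_intron_sites, parse_gene_models,
                                    read_alignment, read_tree)
from intronevo.site_homology import build_site_matrix, \
    render_annotated_alignment

STUDY = os.path.join(os.path.dirname(__file__), "..", "results", "study")
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "sites")


def main() -> int:
    os.makedirs(OUT, exist_ok=True)
    tree = read_tree(os.path.join(STUDY, "tree.nwk"))

    models_by_species = {}
    for sp in tree.tip_names():
        parsed, _ = parse_gene_models(
            os.path.join(STUDY, "species", f"{sp}.gff3"),
            os.path.join(STUDY, "species", f"{sp}.genome.fa"), species=sp)
        models_by_species[sp] = {
            m.attributes.get("family", m.gene_id.split("__")[0]): m
            for m in parsed if m.valid}

    total = 0
    for aln in sorted(glob.glob(os.path.join(STUDY, "families",
                                             "*.aln.fa"))):
        fam = os.path.basename(aln)[:-len(".aln.fa")]
        fam_models = {sp: models[fam]
                      for sp, models in models_by_species.items()
                      if fam in models}
        proteins = {sp: m.protein for sp, m in fam_models.items()}
        msa = read_alignment(aln, proteins=proteins)
        sites = {sp: derive_intron_sites(m)
                 for sp, m in fam_models.items()}
        matrix = build_site_matrix(sites, msa, tree, family_id=fam)
        matrix.to_tsv(os.path.join(OUT, f"{fam}.sites.tsv"))
        with open(os.path.join(OUT, f"{fam}.annotated.txt"), "w") as fh:
            fh.write(render_annotated_alignment(matrix, msa))
        total += matrix.n_sites
        print(f"  {fam}: {matrix.n_sites} splice-site characters")
    print(f"{total} homologous splice-site characters in total -> {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
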