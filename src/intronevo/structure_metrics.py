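"""Comparative gene-structure statistics.

Per-species medians of protein size, coding-exon count and coding-exon size
(in amino acids), with the robust dispersion measures used for cross-species
comparison (median absolute deviation, quartiles).  Exon sizes are computed
as nt/3 with fractional values retained — internal exon boundaries need not
respect codon boundaries, and rounding would bias small exons.  Terminal
(first/last) coding exons below a threshold (default 10 aa) are excluded from
the exon-size table because such stubs are frequently mis-annotated UTR or
placeholder exons; internal exons are never dropped.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .genemodel_io import GeneModel


class MetricsError(ValueError):
    pass


def exon_table(models: Sequence[GeneModel],
               min_terminal_aa: float = 10.0) -> pd.DataFrame:
    """One row per retained coding exon.

    Columns: species, gene_id, exon_index (1-based, transcription order),
    exon_aa, terminal_flag in {first, last, internal, only}.  First/last
    exons (and single-exon genes) shorter than ``min_terminal_aa`` are
    dropped.
    """
    rows = []
    for model in models:
        lengths = model.exon_nt_lengths
        n = len(lengths)
        for i, nt in enumerate(lengths, start=1):
            if n == 1:
                flag = "only"
            elif i == 1:
                flag = "first"
            elif i == n:
                flag = "last"
            else:
                flag = "internal"
            aa = nt / 3.0
            if flag != "internal" and aa < min_terminal_aa:
                continue
            rows.append({"species": model.species, "gene_id": model.gene_id,
                         "exon_index": i, "exon_aa": aa,
                         "terminal_flag": flag})
    return pd.DataFrame(
        rows, columns=["species", "gene_id", "exon_index", "exon_aa",
                       "terminal_flag"])


def _mad(values: np.ndarray) -> float:
    med = np.median(values)
    return float(np.median(np.abs(values - med)))


def species_summary(records: pd.DataFrame,
                    models: Sequence[GeneModel],
                    low_n_threshold: int = 3) -> pd.DataFrame:
    """Per-species medians: protein aa and exon count over genes; exon aa
    median/MAD/Q1/Q3 over the (filtered) exon records.

    Quartiles use linear interpolation.  Species with fewer than
    ``low_n_threshold`` genes are kept but flagged ``low_n``.
    """
    per_gene = pd.DataFrame(
        [{"species": m.species, "gene_id": m.gene_id,
          "protein_aa": len(m.protein), "n_exons": m.n_exons}
         for m in models])
    if per_gene.empty:
        raise MetricsError("no gene models supplied")

    out = []
    for sp, genes in per_gene.groupby("species"):
        exons = records.loc[records["species"] == sp, "exon_aa"].to_numpy()
        row = {
            "species": sp,
            "n_genes": len(genes),
            "n_exons": int(len(exons)),
            "median_protein_aa": float(genes["protein_aa"].median()),
            "median_exon_count": float(genes["n_exons"].median()),
            "median_exon_aa": float(np.median(exons)) if len(exons) else
            float("nan"),
            "mad_exon_aa": _mad(exons) if len(exons) else float("nan"),
            "q1_exon_aa": float(np.percentile(exons, 25)) if len(exons)
            else float("nan"),
            "q3_exon_aa": float(np.percentile(exons, 75)) if len(exons)
            else float("nan"),
            "low_n": len(genes) < low_n_threshold,
        }
        out.append(row)
    return pd.DataFrame(out).sort_values("species").reset_index(drop=True)


def stratified_sample(reference_sizes: dict[str, float],
                      candidate_sizes: dict[str, float],
                      per_stratum: int = 10,
                      seed: int = 0) -> list[str]:
    """Equal sampling of candidate genes across the reference size range.

    The reference size distribution (the complete dataset's ortholog sizes)
    is split into three equal-count strata by size rank (small / medium /
    big); each candidate is assigned to a stratum by comparing its size to
    the stratum boundaries, and up to ``per_stratum`` candidates are sampled
    per stratum without replacement, reproducibly by seed.
    """
    if len(reference_sizes) < 3:
        raise MetricsError("need >= 3 reference genes to form strata")
    ref = np.sort(np.array(list(reference_sizes.values()), dtype=float))
    strata = np.array_split(ref, 3)
    # Upper inclusive bound of small and medium strata.
    small_max = strata[0][-1]
    medium_max = strata[1][-1]

    buckets: dict[int, list[str]] = {0: [], 1: [], 2: []}
    for gene in sorted(candidate_sizes):
        size = candidate_sizes[gene]
        if size <= small_max:
            buckets[0].append(gene)
        elif size <= medium_max:
            buckets[1].append(gene)
        else:
            buckets[2].append(gene)

    rng = np.random.default_rng([seed, 0x57])
    chosen: list[str] = []
    for k in (0, 1, 2):
        genes = buckets[k]
        if len(genes) <= per_stratum:
            chosen.extend(genes)
        else:
            picks = rng.choice(len(genes), size=per_stratum, replace=False)
            chosen.extend(genes[int(i)] for i in sorted(picks))
    return chosen
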