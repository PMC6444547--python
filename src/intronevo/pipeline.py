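"""End-to-end orchestration: parse -> metrics -> map -> infer -> report.

A :class:`RunConfig` names the inputs (tree, per-species GFF3 + genome FASTA,
one protein MSA per ortholog family, optional genome sizes) and the policy
set (isoform choice, gap handling, cost scheme, terminal-exon filter, seed).
:func:`run_pipeline` validates everything up front (no partial outputs on a
bad config), executes the stages, and writes a deterministic report bundle:
per-stage TSV/JSON files plus a top-level ``summary.json`` embedding the
config hash and all policies, and an annotated Newick mirroring the
per-branch ``[+g, -l]`` display convention.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import genemodel_io, parsimony, site_homology, structure_metrics
from .parsimony import CostScheme
from .trees import SpeciesTree


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    tree: str
    species: dict[str, dict[str, str]]      # name -> {gff3, genome}
    families: dict[str, str]                # family id -> MSA path
    outdir: str
    genome_sizes: Optional[str] = None
    isoform_policy: str = "longest_cds"
    gap_policy: str = "unknown"
    gain_cost: float = 1.0
    loss_cost: float = 1.0
    min_terminal_aa: float = 10.0
    seed: int = 0

    # ------------------------------------------------------------ loading
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        policies = raw.get("policies", {})
        return cls(
            tree=raw["tree"],
            species=raw["species"],
            families=raw["families"],
            outdir=raw["outdir"],
            genome_sizes=raw.get("genome_sizes"),
            isoform_policy=policies.get("isoform", "longest_cds"),
            gap_policy=policies.get("gap", "unknown"),
            gain_cost=float(policies.get("gain_cost", 1.0)),
            loss_cost=float(policies.get("loss_cost", 1.0)),
            min_terminal_aa=float(policies.get("min_terminal_aa", 10.0)),
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_study_dir(cls, study_dir, outdir, **policies) -> "RunConfig":
        """Build a config from a study directory laid out by the simulator
        (``tree.nwk``, ``species/*.gff3``, ``families/*.aln.fa``)."""
        study_dir = str(study_dir)
        species = {}
        for gff in sorted(glob.glob(os.path.join(study_dir, "species",
                                                 "*.gff3"))):
            sp = os.path.basename(gff)[:-len(".gff3")]
            species[sp] = {
                "gff3": gff,
                "genome": os.path.join(study_dir, "species",
                                       f"{sp}.genome.fa"),
            }
        families = {}
        for aln in sorted(glob.glob(os.path.join(study_dir, "families",
                                                 "*.aln.fa"))):
            fam = os.path.basename(aln)[:-len(".aln.fa")]
            families[fam] = aln
        gs = os.path.join(study_dir, "genome_sizes.tsv")
        return cls(
            tree=os.path.join(study_dir, "tree.nwk"),
            species=species,
            families=families,
            outdir=str(outdir),
            genome_sizes=gs if os.path.exists(gs) else None,
            **policies,
        )

    # ---------------------------------------------------------- validation
    def validate(self) -> None:
        missing = []
        if not os.path.exists(self.tree):
            missing.append(self.tree)
        for sp, paths in self.species.items():
            for key in ("gff3", "genome"):
                if not os.path.exists(paths[key]):
                    missing.append(paths[key])
        for fam, path in self.families.items():
            if not os.path.exists(path):
                missing.append(path)
        if self.genome_sizes and not os.path.exists(self.genome_sizes):
            missing.append(self.genome_sizes)
        if missing:
            raise ConfigError(f"missing input path(s): {missing}")
        if self.gap_policy not in ("unknown", "absent"):
            raise ConfigError(f"bad gap policy {self.gap_policy!r}")
        if not self.species:
            raise ConfigError("no species configured")
        if not self.families:
            raise ConfigError("no families configured")

    def policy_dict(self) -> dict:
        return {
            "isoform": self.isoform_policy,
            "gap": self.gap_policy,
            "gain_cost": self.gain_cost,
            "loss_cost": self.loss_cost,
            "min_terminal_aa": self.min_terminal_aa,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(
            {"tree": self.tree, "species": self.species,
             "families": self.families, "genome_sizes": self.genome_sizes,
             "policies": self.policy_dict()},
            sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    models_by_species: dict
    exon_records: pd.DataFrame
    structure_summary: pd.DataFrame
    matrices: dict
    reconstructions: list
    aggregate: parsimony.StudyAggregate
    correlation: Optional[parsimony.CorrelationResult]
    summary: dict = field(default_factory=dict)


def _family_of(model) -> str:
    fam = model.attributes.get("family")
    if fam:
        return fam
    return model.gene_id.split("__")[0]


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    fam_dir = os.path.join(outdir, "families")
    os.makedirs(fam_dir, exist_ok=True)

    tree = genemodel_io.read_tree(config.tree)

    # ---- parse ----------------------------------------------------------
    models_by_species: dict[str, list] = {}
    reports = []
    for sp in sorted(config.species):
        paths = config.species[sp]
        models, report = genemodel_io.parse_gene_models(
            paths["gff3"], paths["genome"], species=sp,
            isoform_policy=config.isoform_policy)
        models_by_species[sp] = models
        report.insert(0, "species", sp)
        reports.append(report)
    validation = pd.concat(reports, ignore_index=True)
    validation.to_csv(os.path.join(outdir, "validation_report.tsv"),
                      sep="\t", index=False)

    valid_models = [m for ms in models_by_species.values() for m in ms
                    if m.valid]
    if not valid_models:
        raise ConfigError("no valid gene models after parsing")

    # ---- metrics --------------------------------------------------------
    records = structure_metrics.exon_table(
        valid_models, min_terminal_aa=config.min_terminal_aa)
    summary_df = structure_metrics.species_summary(records, valid_models)
    records.to_csv(os.path.join(outdir, "exon_records.tsv"),
                   sep="\t", index=False)
    summary_df.to_csv(os.path.join(outdir, "structure_summary.tsv"),
                      sep="\t", index=False)

    # ---- map + infer ----------------------------------------------------
    costs = CostScheme(gain_cost=config.gain_cost,
                       loss_cost=config.loss_cost)
    matrices: dict[str, site_homology.SiteMatrix] = {}
    reconstructions = []
    intron_counts = {sp: 0 for sp in tree.tip_names()}
    for fam in sorted(config.families):
        fam_models = {
            m.species: m
            for ms in models_by_species.values() for m in ms
            if m.valid and _family_of(m) == fam}
        proteins = {sp: m.protein for sp, m in fam_models.items()}
        msa = genemodel_io.read_alignment(config.families[fam],
                                          proteins=proteins)
        sites_by_species = {
            sp: genemodel_io.derive_intron_sites(m)
            for sp, m in fam_models.items()}
        matrix = site_homology.build_site_matrix(
            sites_by_species, msa, tree, family_id=fam,
            gap_policy=config.gap_policy)
        matrices[fam] = matrix
        matrix.to_tsv(os.path.join(fam_dir, f"{fam}.sites.tsv"))
        with open(os.path.join(fam_dir, f"{fam}.annotated.txt"), "w") as fh:
            fh.write(site_homology.render_annotated_alignment(matrix, msa))

        rec = parsimony.summarize_family(matrix, tree, costs)
        reconstructions.append(rec)
        with open(os.path.join(fam_dir, f"{fam}.reconstruction.json"),
                  "w") as fh:
            json.dump(rec.to_json_dict(), fh, indent=1, sort_keys=True)

        for sp in tree.tip_names():
            intron_counts[sp] += int(
                (matrix.states.loc[sp] == site_homology.PRESENT).sum()
            ) if matrix.n_sites else 0

    aggregate = parsimony.aggregate_families(reconstructions, tree)

    # ---- correlation ----------------------------------------------------
    correlation = None
    if config.genome_sizes:
        sizes_df = pd.read_csv(config.genome_sizes, sep="\t")
        sizes = dict(zip(sizes_df["species"], sizes_df["genome_mb"]))
        if len(set(sizes) & set(intron_counts)) >= 3:
            correlation = parsimony.genome_size_correlation(
                {sp: float(c) for sp, c in intron_counts.items()}, sizes)

    # ---- report ---------------------------------------------------------
    with open(os.path.join(outdir, "report.nwk"), "w") as fh:
        fh.write(parsimony.annotated_newick(tree, aggregate) + "\n")

    summary = {
        "config_hash": config.config_hash(),
        "policies": config.policy_dict(),
        "n_species": len(config.species),
        "aggregate": aggregate.to_json_dict(),
        "intron_counts": {sp: int(c) for sp, c
                          in sorted(intron_counts.items())},
        "structure_summary": summary_df.to_dict(orient="records"),
        "correlation": correlation.to_json_dict() if correlation else None,
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    return PipelineResult(
        config=config,
        models_by_species=models_by_species,
        exon_records=records,
        structure_summary=summary_df,
        matrices=matrices,
        reconstructions=reconstructions,
        aggregate=aggregate,
        correlation=correlation,
        summary=summary,
    )
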