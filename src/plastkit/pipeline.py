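"""End-to-end orchestration of the synthetic comparative pipeline.

A single declarative configuration drives generation, genome comparison,
coding-variation analysis, phylogenetic input preparation, transcript
quantification and editing analysis, writing a manifest of every output
with checksums. Reruns with the same configuration are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, editing, io, phyloprep, quant, variation
from .editing import ThresholdPolicy
from .simulate import SimulationConfig, simulate_study

log = logging.getLogger("plastkit")

STAGES = ("simulate", "compare", "variation", "phyloprep", "quant", "edit")


@dataclass
class RunConfig:
    """Declarative pipeline configuration (round-trips through YAML)."""

    output_dir: str = "plastkit_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    editing_policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    indel_model: str = "indelblock"
    antisense_floor: float | str = "auto"
    antisense_min_length: int = 100
    fdr_alpha: float = 0.05
    write_sam: bool = False  # SAM export of all simulated reads (large)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        sim = SimulationConfig(**_tuplify(data.pop("simulation", {})))
        pol = ThresholdPolicy(**data.pop("editing_policy", {}))
        data = {k: (tuple(v) if k == "stages" else v) for k, v in data.items()}
        return cls(simulation=sim, editing_policy=pol, **data)


def _tuplify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the manifest (also written to ``manifest.json``): one entry per
    output file with its producing stage and SHA-256 checksum. Any stage
    failure aborts with the stage name in the exception message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    manifest: dict[str, dict] = {}

    def record(stage: str, path: Path):
        manifest[str(path.relative_to(out))] = {
            "stage": stage, "sha256": _sha256(path)
        }

    stage = "simulate"
    try:
        log.info("stage %s: generating study (seed=%d)", stage, config.seed)
        need_reads = bool({"quant", "edit"} & set(config.stages)) or (
            config.write_sam and "simulate" in config.stages)
        study = simulate_study(sim, with_reads=need_reads)
        if stage in config.stages:
            for h, p in study.plastomes.items():
                io.write_fasta({p.id: p.sequence}, out / f"genome_{h}.fasta")
                io.write_gff3(p, out / f"genome_{h}.gff3")
                record(stage, out / f"genome_{h}.fasta")
                record(stage, out / f"genome_{h}.gff3")
                io.write_fasta(
                    {study.mitos[h].id: study.mitos[h].sequence},
                    out / f"mito_{h}.fasta",
                )
                record(stage, out / f"mito_{h}.fasta")
                io.write_insert_table(study.mitos[h].inserts,
                                      out / f"mtpt_inserts_{h}.tsv")
                record(stage, out / f"mtpt_inserts_{h}.tsv")
            io.write_fasta(study.msa, out / "haplotype_alignment.fasta")
            record(stage, out / "haplotype_alignment.fasta")
            truth_rows = []
            for h, t in study.truths.items():
                for s in t.editing_sites:
                    truth_rows.append(
                        {"genome": h, "kind": "editing", "start": s.position + 1,
                         "end": s.position + 1, "detail": s.context,
                         "value": s.rate_for(h)}
                    )
                for l in t.ssrs:
                    truth_rows.append(
                        {"genome": h, "kind": "ssr", "start": l.start + 1,
                         "end": l.end, "detail": l.unit, "value": l.unit_count}
                    )
                for a in t.antisense:
                    if h in a.present_in:
                        truth_rows.append(
                            {"genome": h, "kind": "antisense", "start": a.start + 1,
                             "end": a.end, "detail": a.strand,
                             "value": a.expression}
                        )
            io.write_table(pd.DataFrame(truth_rows), out / "ground_truth.tsv")
            record(stage, out / "ground_truth.tsv")
            if config.write_sam:
                for ind, ras in study.reads.items():
                    ras.to_sam(out / f"reads_{ind}.sam")
                    record(stage, out / f"reads_{ind}.sam")
    except Exception as e:
        raise RuntimeError(f"stage {stage} failed: {e}") from e

    if "compare" in config.stages:
        stage = "compare"
        try:
            rows_b = []
            for h, p in study.plastomes.items():
                qs = compare.find_inverted_repeats(p.sequence)
                rows_b.append(
                    {"genome": h, "lsc": qs.lsc[1] - qs.lsc[0] if qs.lsc else 0,
                     "ssc": qs.ssc[1] - qs.ssc[0] if qs.ssc else 0,
                     "ir": qs.ir_length}
                )
            io.write_table(pd.DataFrame(rows_b), out / "boundaries.tsv")
            record(stage, out / "boundaries.tsv")
            subs, indels = compare.distance_matrices(study.msa, config.indel_model)
            io.write_table(subs, out / "distance_substitutions.tsv", index=True)
            io.write_table(indels, out / f"distance_indels_{config.indel_model}.tsv",
                           index=True)
            record(stage, out / "distance_substitutions.tsv")
            record(stage, out / f"distance_indels_{config.indel_model}.tsv")
            loci = {h: compare.find_ssrs(p) for h, p in study.plastomes.items()}
            io.write_table(
                pd.concat([compare.ssr_table(l) for l in loci.values()]),
                out / "ssr_loci.tsv",
            )
            record(stage, out / "ssr_loci.tsv")
            poly = compare.ssr_polymorphism(loci, study.msa)
            io.write_table(poly, out / "ssr_polymorphism.tsv")
            record(stage, out / "ssr_polymorphism.tsv")
        except Exception as e:
            raise RuntimeError(f"stage {stage} failed: {e}") from e

    base = study.plastomes["A"]
    if "variation" in config.stages:
        stage = "variation"
        try:
            gene_alns = extract_gene_alignments(study.plastomes)
            sites_by_gene = {}
            rows = []
            for gene, aln in gene_alns.items():
                res = variation.classify_segregating_sites(aln, gene)
                sites_by_gene[gene] = res.sites
            summary = variation.summarize_genes(
                sites_by_gene, sorted(gene_alns)
            )
            io.write_table(summary, out / "gene_variation.tsv")
            record(stage, out / "gene_variation.tsv")
            frames = [
                variation.kaks_matrix(aln, gene)
                for gene, aln in gene_alns.items()
            ]
            kaks = pd.concat(
                [f for f in frames if not f.empty], ignore_index=True
            )
            io.write_table(kaks, out / "kaks_pairwise.tsv")
            record(stage, out / "kaks_pairwise.tsv")
        except Exception as e:
            raise RuntimeError(f"stage {stage} failed: {e}") from e

    if "phyloprep" in config.stages:
        stage = "phyloprep"
        try:
            trimmed, _ = phyloprep.remove_ira(
                study.msa, base.boundaries["IRa"], "A")
            masked = phyloprep.mask_homopolymers(
                trimmed, base.cds_features(), "A")
            rows = masked.without_masked()
            phyloprep.write_fasta_alignment(rows, out / "phylo_alignment.fasta")
            record(stage, out / "phylo_alignment.fasta")
            indels = phyloprep.simple_indel_coding(rows)
            sm = phyloprep.concatenate_cds(study.plastomes)
            phyloprep.write_phylip(sm.rows, out / "cds_supermatrix.phy")
            phyloprep.write_raxml_partitions(
                sm.partitions, out / "cds_partitions.txt")
            phyloprep.write_nexus(rows, out / "phylo_alignment.nex", indels)
            io.write_table(masked.mask_log_table(), out / "mask_log.tsv")
            for f in ("cds_supermatrix.phy", "cds_partitions.txt",
                      "phylo_alignment.nex", "mask_log.tsv"):
                record(stage, out / f)
        except Exception as e:
            raise RuntimeError(f"stage {stage} failed: {e}") from e

    profiles: dict[str, quant.CoverageProfile] = {}
    strand_sets: dict[str, quant.StrandSeparation] = {}
    filtered: dict[str, dict[str, quant.ReadAlignmentSet]] = {}
    if {"quant", "edit"} & set(config.stages):
        stage = "quant"
        try:
            tpm_by_hap: dict[str, dict[str, pd.Series]] = {}
            anti_calls: dict[str, list] = {}
            for ind, ras in study.reads.items():
                h = study.haplotype_of(ind)
                p = study.plastomes[h]
                sep = quant.separate_strands(ras, sim.strandedness)
                strand_sets[ind] = sep
                inserts = [(a, b) for a, b, _ in study.truths[h].mtpt_intervals]
                plus, _dp = quant.filter_mtpt_reads(
                    sep.plus, inserts, p.sequence, "+")
                minus, _dm = quant.filter_mtpt_reads(
                    sep.minus, inserts, p.sequence, "-")
                filtered[ind] = {"+": plus, "-": minus}
                prof = quant.coverage_profile(plus, minus, p)
                profiles[ind] = prof
                tpm_by_hap.setdefault(h, {})[ind] = (
                    prof.features.set_index("feature")["tpm"])
                anti_calls[ind] = quant.detect_antisense(
                    prof, p, config.antisense_min_length, config.antisense_floor)
            if "quant" in config.stages:
                for h, cols in tpm_by_hap.items():
                    tpm = pd.DataFrame(cols)
                    io.write_table(tpm, out / f"tpm_{h}.tsv", index=True)
                    record(stage, out / f"tpm_{h}.tsv")
                    sexes = {i: study.sex_of(i) for i in cols}
                    cmp_res = quant.compare_groups(tpm, sexes, config.fdr_alpha)
                    io.write_table(cmp_res, out / f"expression_sex_compare_{h}.tsv",
                                   index=True)
                    record(stage, out / f"expression_sex_compare_{h}.tsv")
                presence = quant.antisense_presence(
                    anti_calls, {i: study.haplotype_of(i) for i in anti_calls})
                io.write_table(presence, out / "antisense_presence.tsv")
                record(stage, out / "antisense_presence.tsv")
        except Exception as e:
            raise RuntimeError(f"stage {stage} failed: {e}") from e

    if "edit" in config.stages:
        stage = "edit"
        try:
            for h in study.plastomes:
                p = study.plastomes[h]
                pileups = {
                    ind: {
                        s: editing.build_pileup(
                            filtered[ind][s], p.sequence,
                            config.editing_policy.min_baseq)
                        for s in "+-"
                    }
                    for ind in study.individuals_of(h)
                }
                res = editing.call_editing_sites(
                    pileups, p.sequence, config.editing_policy, p)
                sites = res.sites.copy()
                effects = [
                    editing.annotate_effect(int(r.position), r.strand, p).label
                    for r in sites.itertuples()
                ]
                sites["effect"] = effects
                sites["position"] += 1  # 1-based on disk
                io.write_table(sites, out / f"editing_sites_{h}.tsv")
                record(stage, out / f"editing_sites_{h}.tsv")
                per = res.per_individual.copy()
                sexes = {i: study.sex_of(i) for i in study.individuals_of(h)}
                cmp_res = editing.compare_editing(per, sexes, config.fdr_alpha)
                io.write_table(cmp_res, out / f"editing_sex_compare_{h}.tsv")
                record(stage, out / f"editing_sex_compare_{h}.tsv")
        except Exception as e:
            raise RuntimeError(f"stage {stage} failed: {e}") from e

    cfg_path = out / "run_config.yaml"
    config.to_yaml(cfg_path)
    record("config", cfg_path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def extract_gene_alignments(plastomes) -> dict[str, dict[str, str]]:
    """Per-gene CDS 'alignments' across genomes.

    Valid for the synthetic study, whose coding sequences are colinear and
    indel-free across haplotypes; real data would go through a per-gene
    aligner first.
    """
    genes = sorted({f.name for p in plastomes.values() for f in p.cds_features()})
    out = {}
    for gene in genes:
        aln = {}
        for gid, p in plastomes.items():
            try:
                aln[gid] = p.feature(gene).extract(p.sequence)
            except KeyError:
                continue
        if len({len(s) for s in aln.values()}) == 1:
            out[gene] = aln
    return out
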