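"""End-to-end orchestration: simulate -> reads -> cluster -> map -> call ->
analyze, with every threshold exposed in one configuration object.

The pipeline can run wholly in memory (`run_pipeline`) or stage by stage
through plain-text files (used by the command-line interface); both paths
share the same library calls, and identical configuration and seed give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as _cluster
from . import diversity as _diversity
from . import evaluate as _evaluate
from . import mapping as _mapping
from . import reads as _reads
from . import simdata as _simdata
from . import variants as _variants


@dataclass(frozen=True)
class PipelineParams:
    """All pipeline thresholds, defaulting to the study's printed values."""

    min_ref_depth: int = 10          # consensus depth floor for references
    cluster_max_mismatch: int = 3
    map_max_mismatch: int = 3
    min_pooled_depth: int = 100      # SNP prediction floor
    max_founder_depth: int = 300     # filter rule 2 cap
    presence_frac: float = 0.05      # filter rule 3 presence threshold
    max_ratio: float = 3.0           # filter rule 4 allele-depth ratio cap
    min_founder_depth: int = 20      # genotyping depth floor
    haplotype_tolerance: float = 4.0
    str_di: int = 8
    str_tri: int = 5
    str_tetra: int = 4
    nboot: int = 10_000
    seed: int = 0

    @property
    def str_thresholds(self) -> dict[int, int]:
        return {2: self.str_di, 3: self.str_tri, 4: self.str_tetra}


def save_config(sim: _simdata.SimConfig, params: PipelineParams,
                path) -> None:
    data = {
        "simulation": {k: v for k, v in dataclasses.asdict(sim).items()
                       if k not in ("enzymes",)},
        "pipeline": dataclasses.asdict(params),
    }
    data["simulation"]["allele_freq_beta"] = list(sim.allele_freq_beta)
    data["simulation"]["related_pairs"] = [list(p) for p in
                                           sim.related_pairs]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path) -> tuple[_simdata.SimConfig, PipelineParams]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    simd = data.get("simulation", {})
    simd["allele_freq_beta"] = tuple(simd.get("allele_freq_beta", (2.0, 2.0)))
    simd["related_pairs"] = tuple(
        tuple(p) for p in simd.get("related_pairs", ()))
    sim = _simdata.SimConfig(**simd)
    params = PipelineParams(**data.get("pipeline", {}))
    return sim, params


@dataclass
class PipelineResult:
    config: _simdata.SimConfig
    params: PipelineParams
    sim: _simdata.SimResult
    pairs: list[_reads.ReadPair]
    read_summary: pd.DataFrame
    loci: list[_cluster.ConsensusLocus]
    references: list[_cluster.ConsensusLocus]
    reference_summary: pd.DataFrame
    mapped: list[_mapping.MappedPair]
    mapping_summary: pd.DataFrame
    depth_table: _mapping.AlleleDepthTable
    predicted: list[_variants.PredictedSNP]
    putative: list[_variants.PutativeSNP]
    genotypes: _variants.GenotypeMatrix
    haplotype_sets: list[_variants.HaplotypeSet]
    haplotype_histogram: pd.Series
    haplotype_determined_pct: float | None
    str_groups: list[_variants.STRLocusGroup]
    str_genotypes: pd.DataFrame
    snp_eval: _evaluate.SNPEvaluation
    str_eval: _evaluate.STREvaluation
    zygosity: pd.DataFrame | None = None
    shared: _diversity.SharedGenotypes | None = None
    specific_alleles: pd.Series | None = None
    pca: _diversity.PCAResult | None = None
    mds: _diversity.MDSResult | None = None
    hclust: _diversity.HclustResult | None = None

    @property
    def loci_by_id(self) -> dict[str, _cluster.ConsensusLocus]:
        return {loc.locus_id: loc for loc in self.loci}


def _group_pairs(sim: _simdata.SimResult
                 ) -> tuple[list[_reads.ReadPair], pd.DataFrame]:
    all_pairs: list[_reads.ReadPair] = []
    discarded: dict[str, int] = {}
    for fid, records in sim.reads.items():
        pairs = _reads.pairs_from_records(records, fid)
        kept, n_disc = _reads.filter_pairs(pairs)
        discarded[fid] = n_disc
        all_pairs.extend(_reads.classify_pairs(kept))
    summary = _reads.quality_summary(all_pairs, discarded)
    return all_pairs, summary


def build_loci(pairs: list[_reads.ReadPair], max_mismatch: int = 3
               ) -> list[_cluster.ConsensusLocus]:
    """Cluster each terminal group and emit consensus loci with stable ids."""
    by_group: dict[str, list[_reads.ReadPair]] = defaultdict(list)
    for p in pairs:
        by_group[p.group].append(p)
    loci: list[_cluster.ConsensusLocus] = []
    for group in sorted(by_group):
        clusters = _cluster.cluster_pairs(by_group[group], max_mismatch)
        for i, cl in enumerate(clusters):
            loci.append(_cluster.build_consensus(
                cl, f"{group}-{i:06d}", group))
    return loci


def run_pipeline(config: _simdata.SimConfig,
                 params: PipelineParams | None = None,
                 analyze: bool = True,
                 nboot: int | None = None) -> PipelineResult:
    """Run the whole pipeline in memory on a simulated library."""
    if params is None:
        params = PipelineParams(seed=config.seed)
    sim = _simdata.simulate_library(config)
    pairs, read_summary = _group_pairs(sim)

    loci = build_loci(pairs, params.cluster_max_mismatch)
    references, ref_summary = _cluster.select_references(
        loci, params.min_ref_depth)

    index = _mapping.ReferenceIndex(references, params.map_max_mismatch)
    mapped, n_mapped, n_total = _mapping.map_all(pairs, index)
    mapping_summary = _mapping.mapping_report(n_mapped, n_total)
    table = _mapping.tally_alleles(mapped, config.founder_ids,
                                   config.read_length)

    predicted = _variants.predict_snps(table, params.min_pooled_depth)
    putative = _variants.filter_snps(
        predicted, params.max_founder_depth, params.presence_frac,
        params.max_ratio)
    genotypes = _variants.call_genotypes(putative, config.founder_ids,
                                         params.min_founder_depth)
    hapsets = _variants.phase_all_loci(putative, params.haplotype_tolerance)
    hap_hist, hap_pct = _variants.summarize_haplotypes(hapsets)

    candidates = _variants.detect_strs(references, params.str_thresholds)
    str_groups = _variants.group_str_loci(candidates,
                                          params.map_max_mismatch)
    str_genotypes = _variants.genotype_strs(
        str_groups, table.pair_counts, config.founder_ids,
        params.min_founder_depth, params.presence_frac)

    loci_by_id = {loc.locus_id: loc for loc in loci}
    snp_eval = _evaluate.evaluate_snps(putative, loci_by_id, sim.founders,
                                       config)
    str_eval = _evaluate.evaluate_strs(str_groups, loci_by_id, sim.founders,
                                       config)

    result = PipelineResult(
        config=config, params=params, sim=sim, pairs=pairs,
        read_summary=read_summary, loci=loci, references=references,
        reference_summary=ref_summary, mapped=mapped,
        mapping_summary=mapping_summary, depth_table=table,
        predicted=predicted, putative=putative, genotypes=genotypes,
        haplotype_sets=hapsets, haplotype_histogram=hap_hist,
        haplotype_determined_pct=hap_pct, str_groups=str_groups,
        str_genotypes=str_genotypes, snp_eval=snp_eval, str_eval=str_eval)

    if analyze and genotypes.n_loci >= 3 and len(config.founder_ids) >= 3:
        result.zygosity = _diversity.zygosity_summary(genotypes)
        result.shared = _diversity.pairwise_shared_genotypes(genotypes)
        presence = _diversity.snp_allele_presence(genotypes)
        result.specific_alleles = _diversity.count_specific_alleles(
            presence, config.founder_ids)
        result.pca = _diversity.pca_founders(genotypes)
        result.mds = _diversity.mds_founders(genotypes)
        result.hclust = _diversity.hclust_founders(
            genotypes, nboot if nboot is not None else params.nboot,
            seed=params.seed)
    return result


# ---------------------------------------------------------------------------
# manifest and file outputs
# ---------------------------------------------------------------------------

def write_manifest(path, stage: str, params: dict, counts: dict) -> None:
    payload = {"stage": stage, "parameters": params, "counts": counts}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write every stage's tables into `outdir`."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.read_summary.to_csv(out / "read_summary.tsv", sep="\t",
                               index=False)
    result.reference_summary.to_csv(out / "reference_summary.tsv", sep="\t",
                                    index=False)
    _cluster.write_reference_fasta(result.references,
                                   out / "references.fasta")
    result.mapping_summary.to_csv(out / "mapping_summary.tsv", sep="\t",
                                  index=False)
    _variants.write_vcf(result.putative, result.config.founder_ids,
                        out / "putative_snps.vcf",
                        result.config.read_length)
    result.genotypes.df.to_csv(out / "genotypes.tsv", sep="\t", index=False)
    hap_rows = [{"locus_id": h.locus_id, "n_offsets": len(h.offsets),
                 "n_haplotypes": len(h.haplotypes), "status": h.status}
                for h in result.haplotype_sets]
    pd.DataFrame(hap_rows).to_csv(out / "haplotypes.tsv", sep="\t",
                                  index=False)
    result.str_genotypes.to_csv(out / "str_genotypes.tsv", sep="\t",
                                index=False)
    _simdata.write_truth(result.sim.truth, out / "truth_snps.tsv",
                         out / "truth_strs.tsv")
    if result.zygosity is not None:
        result.zygosity.to_csv(out / "zygosity.tsv", sep="\t", index=False)
        result.shared.table().to_csv(out / "shared_genotypes.tsv", sep="\t")
        result.specific_alleles.to_csv(out / "specific_alleles.tsv",
                                       sep="\t")
        pd.DataFrame(result.pca.coordinates,
                     index=result.pca.founder_ids).to_csv(
            out / "pca_coordinates.tsv", sep="\t")
        pd.DataFrame(result.mds.coordinates,
                     index=result.mds.founder_ids).to_csv(
            out / "mds_coordinates.tsv", sep="\t")
        (out / "dendrogram.nwk").write_text(result.hclust.newick() + "\n")
    counts = {
        "n_pairs": len(result.pairs),
        "n_loci": len(result.loci),
        "n_references": len(result.references),
        "n_mapped": len(result.mapped),
        "n_predicted_snps": len(result.predicted),
        "n_putative_snps": len(result.putative),
        "n_genotyped_snps": result.genotypes.n_loci,
        "n_str_groups": len(result.str_groups),
        "snp_recall": round(result.snp_eval.recall, 4),
        "snp_precision": round(result.snp_eval.precision, 4),
    }
    write_manifest(out / "manifest.json", "run-all",
                   dataclasses.asdict(result.params), counts)
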