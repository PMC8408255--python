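"""End-to-end analysis: simulate -> synteny -> Ka/Ks -> bias -> dynamics ->
LTR -> SV enrichment -> coexpression.

This is the glue that runs every stage on one dataset (typically the bundled
synthetic tetraploid) and collects the headline quantities.  Each stage is a
thin call into the corresponding module, so the pipeline doubles as a worked
example of the library API.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import coexpr, dynamics, ltr, seqevol, svenrich, synteny
from .simdata import SimConfig, simulate_dataset, simulate_ltr_elements, _revcomp

__all__ = ["run_pipeline", "extract_cds"]


def extract_cds(genome: dict[str, str], gene: dict) -> str:
    """Spliced CDS of a gene dict from chromosome sequences (strand-aware)."""
    chunks = [genome[gene["chrom"]][s:e] for s, e in gene["exons"]]
    cds = "".join(chunks)
    return _revcomp(cds) if gene["strand"] == "-" else cds


def run_pipeline(config: Optional[SimConfig] = None, outdir: Optional[str] = None,
                 max_kaks_pairs: int = 400) -> dict:
    """Run the whole analysis on a simulated dataset; returns a results dict.

    ``max_kaks_pairs`` bounds the number of homoeolog pairs sent through
    codon alignment + NG86 (sampled deterministically) to keep runtime modest.
    """
    config = config or SimConfig()
    if outdir is None:
        import tempfile

        outdir = tempfile.mkdtemp(prefix="homoevol_")
    bundle, truth = simulate_dataset(config, outdir)
    results: dict = {"config": config, "truth": truth, "bundle": bundle}

    # --- synteny ---------------------------------------------------------
    gene_models = {
        gid: synteny.GeneModel(
            gene_id=gid, chrom=g["chrom"], start=g["start"], end=g["end"],
            strand=g["strand"], exon_count=len(g["exons"]), cds_length=g["cds_len"])
        for gid, g in truth.gene_info.items()
    }
    genes_sorted = sorted(gene_models.values(), key=lambda g: (g.chrom, g.start))
    ranks: dict[str, int] = {}
    counter: dict[str, int] = {}
    for g in genes_sorted:
        ranks[g.gene_id] = counter.get(g.chrom, 0)
        counter[g.chrom] = ranks[g.gene_id] + 1
    gene_chrom = {g.gene_id: g.chrom for g in genes_sorted}

    blocks = []
    for ca, cb in truth.chrom_pairs:
        anchors = synteny.anchors_from_pairs(
            [(p.gene_a, p.gene_b) for p in truth.homoeolog_pairs
             if p.chrom_a == ca], ranks)
        blocks.extend(synteny.chain_anchors(anchors, ca, cb))
    homoeologs = synteny.identify_homoeologs(blocks, truth.chrom_pairs)
    results["n_blocks"] = len(blocks)
    results["homoeologs"] = homoeologs

    # --- Ka/Ks and the Ks distribution ----------------------------------
    kaks_results = []
    genome = _read_fasta(bundle.genome_fasta) if bundle is not None else None
    pair_list = sorted(homoeologs, key=lambda p: (p.gene_a, p.gene_b))
    step = max(len(pair_list) // max_kaks_pairs, 1)
    sampled = pair_list[::step][:max_kaks_pairs]
    info = truth.gene_info
    for p in sampled:
        if genome is not None:
            ca = extract_cds(genome, info[p.gene_a])
            cb = extract_cds(genome, info[p.gene_b])
        else:
            continue
        aln = seqevol.align_cds_pair(ca, cb)
        kaks_results.append(seqevol.kaks_ng86(aln))
    if kaks_results:
        dist = seqevol.ks_distribution(kaks_results)
        peaks = seqevol.detect_ks_peaks(dist)
        results["ks_distribution"] = dist
        results["ks_peaks"] = peaks
        results["kaks"] = kaks_results

    # --- expression bias -------------------------------------------------
    design = config.sample_table()
    counts_df = pd.read_csv(bundle.counts_tsv, sep="\t", index_col=0) \
        if bundle is not None else None
    lengths = pd.Series({gid: g["cds_len"] for gid, g in info.items()})
    cm = bias_mod.CountMatrix(counts=counts_df, design=design, gene_lengths=lengths)
    tpm = bias_mod.compute_tpm(counts_df, lengths)
    expressed = bias_mod.flag_expressed(tpm)
    hc_pairs = bias_mod.high_confidence_pairs(homoeologs, expressed)
    sf = bias_mod.size_factors(counts_df)
    pooled_de = [bias_mod.test_homoeolog_de(cm, p, "pooled", sf=sf) for p in hc_pairs]
    categories = {
        (r.pair.gene_a, r.pair.gene_b): bias_mod.classify_bias_category(r)
        for r in pooled_de
    }
    grouping = bias_mod.chromosome_bias_grouping(pooled_de, truth.chrom_pairs, gene_chrom)
    results.update(tpm=tpm, expressed=expressed, hc_pairs=hc_pairs,
                   pooled_de=pooled_de, categories=categories, grouping=grouping)

    n_sig = sum(bias_mod.is_significant_twofold(r) for r in pooled_de)
    results["pct_significant_twofold"] = 100.0 * n_sig / len(pooled_de) if pooled_de else np.nan

    # --- per-scope DE and dynamics ---------------------------------------
    scopes = [(t, v) for v in config.varieties for t in config.tissues]
    per_scope_de: dict = {}
    for scope in scopes:
        samples = cm.samples_in_scope(scope)
        sf_scope = sf.reindex(samples)
        per_scope_de[scope] = {
            (r.pair.gene_a, r.pair.gene_b): r
            for r in (bias_mod.test_homoeolog_de(cm, p, scope, sf=sf_scope)
                      for p in hc_pairs)
        }
    pooled_by_pair = {(r.pair.gene_a, r.pair.gene_b): r for r in pooled_de}
    profiles = [
        dynamics.fc_profile(pid, {s: per_scope_de[s][pid] for s in scopes},
                            pooled_by_pair[pid])
        for pid in sorted(pooled_by_pair)
    ]
    sets = dynamics.rank_dynamic_stable(profiles)
    per_tissue_categories = {
        scope: {pid: bias_mod.classify_bias_category(r) for pid, r in de.items()}
        for scope, de in per_scope_de.items()
    }
    transitions = dynamics.category_transitions(per_tissue_categories, categories)
    results.update(profiles=profiles, dynamic_stable=sets, transitions=transitions)

    # --- LTR classification, dating, clustering --------------------------
    candidates, _, gagpol = simulate_ltr_elements(config)
    classed = ltr.classify_ltr(candidates, gagpol, flank_len=config.ltr_flank_len)
    for el in classed:
        if el.structural_class == "intact" and el.ltr3_seq:
            el.age_years = ltr.insertion_time(el.ltr5_seq, el.ltr3_seq, config.mu)
    clusters = ltr.cluster_ltrs(classed)
    removal = ltr.removal_ratios(clusters)
    te_bed = pd.read_csv(bundle.te_bed, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score", "strand"])
    te_dist = ltr.nearest_te_distance(genes_sorted, te_bed)
    strata = bias_mod.te_stratified_bias(grouping, pooled_de, te_dist.to_dict(),
                                         gene_chrom)
    results.update(ltr_elements=classed, ltr_clusters=clusters, removal=removal,
                   te_distances=te_dist, te_strata=strata)

    # --- SV enrichment ----------------------------------------------------
    chrom_sizes = {c: config.chrom_length
                   for pair in truth.chrom_pairs for c in pair}
    svs = [svenrich.SVRecord(r["sv_id"], r["type"], r["chrom"], r["start"], r["end"])
           for r in truth.sv_truth]
    flanks = svenrich.breakpoint_flanks(svs, chrom_sizes)
    randoms = svenrich.sample_random_regions(chrom_sizes, n_per_chrom=1000,
                                             size=4000, seed=config.seed)
    enrichment = svenrich.te_enrichment(flanks, randoms, te_bed)
    impact = svenrich.sv_expression_impact(
        svs, genes_sorted, pooled_de,
        homoeolog_block_genes={g for b in blocks for a in b.anchors
                               for g in (a.gene_a, a.gene_b)})
    results.update(sv_enrichment=enrichment, sv_impact=impact)

    # --- coexpression (per variety) --------------------------------------
    divergence = {}
    for variety in config.varieties:
        samp = [s for s in tpm.columns if design.loc[s, "variety"] == variety]
        expr = np.log2(tpm[samp] + 1.0).loc[sorted(expressed)]
        beta = coexpr.pick_soft_power(expr)
        net = coexpr.adjacency_tom(expr, beta)
        modules = coexpr.detect_modules(expr, net, min_module_size=30)
        eig = coexpr.module_eigengenes(expr, modules)
        calls, summary = coexpr.classify_homoeolog_divergence(
            [(p.gene_a, p.gene_b) for p in hc_pairs], modules, eig)
        divergence[variety] = {"beta": beta, "modules": modules,
                               "eigengenes": eig, "calls": calls,
                               "summary": summary}
    results["coexpression"] = divergence
    return results


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
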