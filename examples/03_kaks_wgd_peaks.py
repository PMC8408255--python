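"""Estimate Ka/Ks for homoeolog pairs and locate the Ks peak of the WGD.

Coding sequences are extracted from the genome via the annotation, codon-
aligned through their protein translation, and scored with the NG86 counting
method; Ks values above 5 are treated as saturated and excluded.
"""

import numpy as np

from homoevol import SimConfig, simulate_dataset
from homoevol.pipeline import extract_cds, _read_fasta
from homoevol.seqevol import align_cds_pair, detect_ks_peaks, kaks_ng86, ks_distribution

config = SimConfig(n_chrom_pairs=2, genes_per_chrom=80, chrom_length=500_000,
                   seed=11)
bundle, truth = simulate_dataset(config, outdir="scratch_example_bundle")
genome = _read_fasta(bundle.genome_fasta)

results = []
for p in truth.homoeolog_pairs[:120]:
    cds_a = extract_cds(genome, truth.gene_info[p.gene_a])
    cds_b = extract_cds(genome, truth.gene_info[p.gene_b])
    results.append(kaks_ng86(align_cds_pair(cds_a, cds_b)))

ks = [r.ks for r in results if r.ks is not None]
ratios = [r.ratio for r in results if r.ratio is not None]
print(f"pairs scored : {len(results)}")
print(f"median Ks    : {np.median(ks):.4f}")
print(f"median Ka/Ks : {np.median(ratios):.3f}")

dist = ks_distribution(results)
peaks = detect_ks_peaks(dist)
print(f"Ks peaks     : {[(round(m, 3), round(h, 2)) for m, h in peaks]}")

# The Ks mode sits near the planted divergence (0.08 substitutions per
# synonymous site — the scale of a recent WGD), and Ka/Ks below 1 reflects
# the planted purifying-selection ratio.
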