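"""Synthetic tetraploid dataset generator with a machine-readable truth table.

Emulates the data shapes of a recent-allotetraploid genome study at desk
scale: homoeologous chromosomes emitted as consecutive pairs (chr01/chr02,
...), collinear planted homoeolog pairs (plus one inverted segment per pair),
negative-binomially distributed RNA-seq counts over a five-tissue x
two-variety x three-replicate design with planted bias-category effects,
TE placement with planted proximity-suppression, LTR elements with planted
insertion ages, and SV breakpoints with controllable TE enrichment.  Every
planted quantity is recorded in a :class:`GenomeTruth` so downstream stages
can be tested as parameter-recovery problems without any external download.

All randomness flows from ``SimConfig.seed`` through per-component
``numpy.random.default_rng([seed, tag])`` streams, so the same config yields
byte-identical output bundles and each component is independently
deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqevol import SENSE_CODONS, STOP_CODONS, _CODON_TO_AA

__all__ = [
    "SimConfig",
    "GenomeTruth",
    "SimBundle",
    "simulate_dataset",
    "simulate_counts",
    "simulate_ltr_elements",
    "simulate_sv_table",
    "jc_mutate",
    "random_dna",
    "random_cds",
    "mutate_cds",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TISSUES_DEFAULT = ("root", "stem", "leaf", "calyx", "corolla")
_VARIETIES_DEFAULT = ("red", "purple")
CATEGORIES = ("no_difference", "lower", "medium", "higher")

# rng stream tags (stable across runs; never reorder)
_TAG_LAYOUT, _TAG_SEQ, _TAG_TE, _TAG_COUNTS, _TAG_LTR, _TAG_SV = range(1, 7)


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design constants for the synthetic tetraploid."""

    n_chrom_pairs: int = 4
    chrom_length: int = 1_000_000
    genes_per_chrom: int = 200
    homoeolog_fraction: float = 0.8
    tissues: tuple = _TISSUES_DEFAULT
    varieties: tuple = _VARIETIES_DEFAULT
    replicates: int = 3
    # four bias categories: no_difference / lower / medium / higher
    bias_fractions: tuple = (0.55, 0.20, 0.15, 0.10)
    bias_log2_effects: tuple = (0.0, 0.8, 2.0, 3.5)
    tissue_specific_bias_fraction: float = 0.10
    biased_pair_fraction: float = 0.5  # chromosome pairs with directional bias
    bias_direction_prob: float = 0.85  # P(dominant side hosts the higher copy)
    nb_dispersion: float = 0.05
    base_mean_log: float = math.log(150.0)
    base_mean_sigma: float = 1.0
    n_modules: int = 4
    cross_module_fraction: float = 0.25
    module_tissue_boost: float = 6.0
    te_density: dict = field(default_factory=lambda: {
        "Gypsy": 3.0, "Copia": 1.5, "LINE1": 0.8})  # per 100 kb
    line1_pericentromere_factor: float = 5.0
    te_suppression_factor: float = 0.5
    te_suppression_fraction: float = 0.3
    te_suppress_side: Optional[str] = None  # None | "recessive"
    ks_mean: float = 0.08
    ka_ks_ratio: float = 0.3
    ltr_class_counts: tuple = (20, 40, 15)  # intact, solo, truncated
    ltr_age_mean: float = 2.0e6
    ltr_flank_len: int = 2000
    gagpol_protein_len: int = 200
    mu: float = 1.3e-8
    sv_counts_per_type: dict = field(default_factory=lambda: {
        "duplication": 30, "inversion": 4, "translocation": 9,
        "inverted_duplication": 31, "inverted_translocation": 8})
    sv_breakpoint_te_enrichment: float = 3.0
    sv_overlap_extra_log2fc: float = 0.0
    plant_inversion: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.bias_fractions) - 1.0) > 1e-9:
            raise SimConfigError("bias_fractions must sum to 1")
        for name in ("n_chrom_pairs", "genes_per_chrom", "replicates"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be >= 1")
        if self.mu <= 0:
            raise SimConfigError("mu must be positive")
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be positive")
        lo, med, hi = self.bias_log2_effects[1:]
        if not (0 < lo < 1.0):
            raise SimConfigError("'lower' planted effect must be < 2-fold (|log2FC| < 1)")
        if not (1.0 < med < 3.0):
            raise SimConfigError("'medium' planted effect must be in (2,8)-fold")
        if hi < 3.0:
            raise SimConfigError("'higher' planted effect must be >= 8-fold (|log2FC| >= 3)")
        # geometric feasibility: every gene must fit between its neighbours
        max_span = 1500 + 7 * 300  # max CDS + max introns, see _make_gene
        spacing = self.chrom_length // (self.genes_per_chrom + 1)
        if spacing <= max_span:
            raise SimConfigError(
                f"chromosome too short: {self.genes_per_chrom} genes need spacing "
                f"> {max_span} bp but chrom_length {self.chrom_length} gives {spacing} bp"
            )

    @property
    def n_samples(self) -> int:
        return len(self.tissues) * len(self.varieties) * self.replicates

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for v in self.varieties:
            for t in self.tissues:
                for r in range(1, self.replicates + 1):
                    rows.append((f"{v}_{t}_rep{r}", t, v, r))
        return pd.DataFrame(rows, columns=["sample", "tissue", "variety",
                                           "replicate"]).set_index("sample")


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random in-frame coding sequence of sense codons (no stop)."""
    idx = rng.integers(0, len(SENSE_CODONS), n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


_SYNONYMS = {c: [d for d in SENSE_CODONS
                 if d != c and _CODON_TO_AA[d] == _CODON_TO_AA[c]]
             for c in SENSE_CODONS}
_NONSYN_NEIGHBOURS = {}
for _c in SENSE_CODONS:
    alts = []
    for _pos in range(3):
        for _b in "ACGT":
            if _b == _c[_pos]:
                continue
            _alt = _c[:_pos] + _b + _c[_pos + 1:]
            if _alt not in STOP_CODONS and _CODON_TO_AA[_alt] != _CODON_TO_AA[_c]:
                alts.append(_alt)
    _NONSYN_NEIGHBOURS[_c] = alts


def mutate_cds(rng: np.random.Generator, cds: str, p_syn: float,
               p_nonsyn: float) -> str:
    """Codon-wise substitution: synonymous swaps and single-step nonsynonymous."""
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        u = rng.random()
        if u < p_syn and _SYNONYMS.get(codon):
            codon = _SYNONYMS[codon][rng.integers(len(_SYNONYMS[codon]))]
        elif u < p_syn + p_nonsyn and _NONSYN_NEIGHBOURS.get(codon):
            codon = _NONSYN_NEIGHBOURS[codon][rng.integers(len(_NONSYN_NEIGHBOURS[codon]))]
        out.append(codon)
    return "".join(out)


def jc_mutate(rng: np.random.Generator, seq: str, d: float) -> str:
    """Apply Jukes–Cantor substitutions at expected ``d`` substitutions/site.

    The observable per-site difference probability is p = 3/4 (1 - e^(-4d/3)),
    so the JC-corrected distance of the output vs input recovers ``d`` in
    expectation.  Substitutions only (no indels), keeping dating oracles exact.
    """
    if d < 0:
        raise SimConfigError("divergence must be nonnegative")
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.where(rng.random(len(arr)) < p)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_COMP)[::-1].decode()


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class TruthPair:
    gene_a: str
    gene_b: str
    category: str
    log2fc: float  # signed, B relative to A; applies in `tissues` scopes
    tissues: Optional[tuple] = None  # None = all tissues
    chrom_a: str = ""
    chrom_b: str = ""


@dataclass
class GenomeTruth:
    """Everything planted by the generator, resolvable against the emitted files."""

    chrom_pairs: list
    homoeolog_pairs: list  # TruthPair
    gene_info: dict  # gene_id -> dict(chrom, start, end, strand, cds_len, exons)
    gene_base_mean: dict  # gene_id -> float
    gene_module: dict  # gene_id -> module label
    te_suppressed_genes: set
    biased_chrom_pairs: list  # [(chrom_a, chrom_b, dominant_chrom or None)]
    ltr_truth: list  # dicts: element_id, structural_class, age_years
    sv_truth: list  # dicts: sv_id, type, chrom, start, end, te_adjacent
    gagpol_protein: str = ""
    sv_boosted_genes: set = field(default_factory=set)
    config: Optional[SimConfig] = None
    version: str = "1"

    def pair_tuples(self) -> list[tuple[str, str]]:
        return [(p.gene_a, p.gene_b) for p in self.homoeolog_pairs]

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, set):
                return sorted(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if dataclasses.is_dataclass(o):
                return asdict(o)
            raise TypeError(type(o))
        payload = asdict(self)
        payload["config"] = asdict(self.config) if self.config else None
        return json.dumps(payload, default=_default, indent=1, sort_keys=True)


@dataclass
class SimBundle:
    """Paths of the emitted files."""

    outdir: Path
    genome_fasta: Path
    gff3: Path
    te_bed: Path
    ltr_table: Path
    ltr_fasta: Path
    gagpol_fasta: Path
    sv_tsv: Path
    counts_tsv: Path
    design_tsv: Path
    chrom_pairs_tsv: Path
    truth_json: Path


# ---------------------------------------------------------------------------
# gene layout
# ---------------------------------------------------------------------------

def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str, anchor: int,
               cds: str) -> dict:
    n_codons = len(cds) // 3
    exon_count = int(rng.integers(1, 9))
    exon_count = min(exon_count, n_codons)  # at least 1 bp per exon
    cuts = np.sort(rng.choice(np.arange(1, len(cds)), exon_count - 1,
                              replace=False)) if exon_count > 1 else np.array([], int)
    exon_lens = np.diff(np.concatenate([[0], cuts, [len(cds)]])).astype(int)
    intron_lens = rng.integers(50, 301, exon_count - 1) if exon_count > 1 else []
    strand = "+" if rng.random() < 0.7 else "-"
    exons = []
    pos = anchor
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < exon_count - 1:
            pos += int(intron_lens[i])
    return {
        "gene_id": gene_id, "chrom": chrom, "start": anchor, "end": pos,
        "strand": strand, "exons": exons, "cds": cds, "cds_len": len(cds),
    }


def _layout_genomes(config: SimConfig):
    rng = np.random.default_rng([config.seed, _TAG_LAYOUT])
    rng_seq = np.random.default_rng([config.seed, _TAG_SEQ])
    chrom_pairs = []
    genes: dict[str, dict] = {}
    pairs: list[TruthPair] = []
    biased: list[tuple] = []
    p_syn = config.ks_mean * 0.76
    p_non = config.ka_ks_ratio * config.ks_mean * 2.24
    n_biased = int(round(config.biased_pair_fraction * config.n_chrom_pairs))
    for pi in range(config.n_chrom_pairs):
        ca, cb = f"chr{2 * pi + 1:02d}", f"chr{2 * pi + 2:02d}"
        chrom_pairs.append((ca, cb))
        pair_is_biased = pi < n_biased
        biased.append((ca, cb, ca if pair_is_biased else None))
        spacing = config.chrom_length // (config.genes_per_chrom + 1)
        jitter = max(spacing // 8, 1)
        retained = rng.random(config.genes_per_chrom) < config.homoeolog_fraction
        retained_orders = [i for i in range(config.genes_per_chrom) if retained[i]]
        # one planted inverted segment of up to 15 consecutive retained pairs
        inv_set: set[int] = set()
        if config.plant_inversion and len(retained_orders) >= 40:
            k0 = len(retained_orders) // 2 - 7
            inv_run = retained_orders[k0:k0 + 15]
            inv_set = set(inv_run)
        for gi in range(config.genes_per_chrom):
            anchor = (gi + 1) * spacing + int(rng.integers(-jitter, jitter + 1))
            cds = random_cds(rng_seq, int(rng.integers(100, 501)))
            ga = _make_gene(rng, f"{ca}g{gi + 1:04d}", ca, anchor, cds)
            genes[ga["gene_id"]] = ga
            if not retained[gi]:
                continue
            cds_b = mutate_cds(rng_seq, cds, p_syn, p_non)
            cat_idx = int(rng.choice(4, p=np.asarray(config.bias_fractions)))
            cat = CATEGORIES[cat_idx]
            mag = config.bias_log2_effects[cat_idx]
            if cat == "no_difference":
                log2fc = 0.0
            else:
                if pair_is_biased:
                    # dominant side is chrom A: higher copy on A with prob p
                    sign = -1.0 if rng.random() < config.bias_direction_prob else 1.0
                else:
                    sign = -1.0 if rng.random() < 0.5 else 1.0
                log2fc = sign * mag
            tiss = None
            if cat != "no_difference" and rng.random() < config.tissue_specific_bias_fraction:
                tiss = (config.tissues[int(rng.integers(len(config.tissues)))],)
            # B-side position mirrors the A order, with the planted inversion
            if gi in inv_set:
                run = sorted(inv_set)
                order_key = run[len(run) - 1 - run.index(gi)]
            else:
                order_key = gi
            anchor_b = (order_key + 1) * spacing + int(rng.integers(-jitter, jitter + 1))
            gb = _make_gene(rng, f"{cb}g{gi + 1:04d}", cb, anchor_b, cds_b)
            genes[gb["gene_id"]] = gb
            pairs.append(TruthPair(ga["gene_id"], gb["gene_id"], cat, log2fc,
                                   tiss, ca, cb))
    return chrom_pairs, genes, pairs, biased


def _assign_modules(config: SimConfig, genes: dict, pairs: list[TruthPair]):
    rng = np.random.default_rng([config.seed, _TAG_LAYOUT, 2])
    module = {}
    partner = {p.gene_a: p.gene_b for p in pairs}
    in_pair_b = {p.gene_b for p in pairs}
    labels = [f"K{m + 1}" for m in range(config.n_modules)]
    for gid in sorted(genes):
        if gid in in_pair_b:
            continue
        module[gid] = labels[int(rng.integers(config.n_modules))]
        mate = partner.get(gid)
        if mate is not None:
            if rng.random() < config.cross_module_fraction:
                others = [l for l in labels if l != module[gid]]
                module[mate] = others[int(rng.integers(len(others)))]
            else:
                module[mate] = module[gid]
    return module


# ---------------------------------------------------------------------------
# TEs
# ---------------------------------------------------------------------------

def _simulate_tes(config: SimConfig, genes: dict, biased: list,
                  pairs: list[TruthPair]) -> tuple[pd.DataFrame, set]:
    rng = np.random.default_rng([config.seed, _TAG_TE])
    chroms = sorted({g["chrom"] for g in genes.values()})
    rows = []
    L = config.chrom_length
    peri_lo, peri_hi = int(0.4 * L), int(0.6 * L)
    for chrom in chroms:
        for cls in sorted(config.te_density):
            rate = config.te_density[cls] * L / 1e5
            n = rng.poisson(rate)
            starts = rng.integers(0, L, n)
            if cls == "LINE1" and config.line1_pericentromere_factor > 1:
                extra_rate = rate * (peri_hi - peri_lo) / L * (
                    config.line1_pericentromere_factor - 1.0)
                n_extra = rng.poisson(extra_rate)
                starts = np.concatenate([
                    starts, rng.integers(peri_lo, peri_hi, n_extra)])
            for s in np.sort(starts):
                te_len = int(np.clip(rng.lognormal(8.0, 0.6), 500, 10000))
                e = min(int(s) + te_len, L)
                rows.append((chrom, int(s), e, cls))
    # planted TE-proximal (suppressed) genes
    dominant = {pair[2] for pair in biased if pair[2] is not None}
    recessive_of = {}
    for ca, cb, dom in biased:
        if dom is not None:
            recessive_of[ca], recessive_of[cb] = (dom != ca), (dom != cb)
    candidates = sorted(genes)
    if config.te_suppress_side == "recessive":
        candidates = [g for g in candidates if recessive_of.get(genes[g]["chrom"], False)]
    k = int(round(config.te_suppression_fraction * len(candidates)))
    suppressed = set(
        np.array(candidates)[rng.choice(len(candidates), k, replace=False)]
    ) if k else set()
    for gid in sorted(suppressed):
        g = genes[gid]
        te_len = int(rng.integers(500, 3000))
        gap = int(rng.integers(100, 1500))
        end = max(g["start"] - gap, 1)
        start = max(end - te_len, 0)
        cls = ("Gypsy", "Copia")[int(rng.integers(2))]
        rows.append((g["chrom"], start, end, cls))
    te_bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    te_bed = te_bed.sort_values(["chrom", "start", "end", "name"]).reset_index(drop=True)
    return te_bed, suppressed


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _sign_for(gene_id: str) -> float:
    """Deterministic ±1 derived from the gene id (process-independent)."""
    return 1.0 if sum(gene_id.encode()) % 2 else -1.0


def _gene_means(config: SimConfig, truth: "GenomeTruth") -> pd.DataFrame:
    """Per-gene expected counts for every sample (before size factors)."""
    design = config.sample_table()
    tissues_arr = design["tissue"].to_numpy()
    tissues = list(config.tissues)
    module_pref = {f"K{m + 1}": tissues[m % len(tissues)]
                   for m in range(config.n_modules)}
    gene_ids = sorted(truth.gene_info)
    base = truth.gene_base_mean
    fc = {p.gene_b: (p.log2fc, p.tissues) for p in truth.homoeolog_pairs}
    means = np.zeros((len(gene_ids), len(design)))
    for i, gid in enumerate(gene_ids):
        row = np.full(len(design), base[gid])
        pref = module_pref.get(truth.gene_module.get(gid))
        if pref is not None:
            row = np.where(tissues_arr == pref, row * config.module_tissue_boost, row)
        if gid in fc:
            l2, tiss = fc[gid]
            mask = np.ones(len(design), bool) if tiss is None else np.isin(tissues_arr, tiss)
            row = np.where(mask, row * 2.0 ** l2, row)
        if gid in truth.sv_boosted_genes:
            row = row * 2.0 ** (_sign_for(gid) * config.sv_overlap_extra_log2fc)
        if gid in truth.te_suppressed_genes:
            row = row * config.te_suppression_factor
        means[i] = row
    return pd.DataFrame(means, index=gene_ids, columns=design.index)


def simulate_counts(truth: "GenomeTruth", config: SimConfig,
                    seed_offset: int = 0) -> pd.DataFrame:
    """Draw the NB count matrix (genes x samples) from the planted means.

    counts ~ NB(mean * size_factor, dispersion) with Var = mu + alpha mu^2;
    per-sample size factors are lognormal(0, 0.1).  Homoeolog B means equal A
    times 2^(planted log2FC) in the tissues the effect applies; TE-suppressed
    genes are multiplied by the suppression factor.
    """
    if config.nb_dispersion <= 0:
        raise SimConfigError("nb_dispersion must be positive")
    rng = np.random.default_rng([config.seed, _TAG_COUNTS, seed_offset])
    means = _gene_means(config, truth)
    if not (means.to_numpy() > 0).any():
        raise SimConfigError("all planted means are zero; nothing to simulate")
    sf = np.exp(rng.normal(0.0, 0.1, means.shape[1]))
    mu = means.to_numpy() * sf
    alpha = config.nb_dispersion
    n_param = 1.0 / alpha
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)
    return pd.DataFrame(counts, index=means.index, columns=means.columns)


# ---------------------------------------------------------------------------
# LTR elements
# ---------------------------------------------------------------------------

def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    by_aa: dict[str, list[str]] = {}
    for c in SENSE_CODONS:
        by_aa.setdefault(_CODON_TO_AA[c], []).append(c)
    return "".join(by_aa[a][rng.integers(len(by_aa[a]))] for a in protein)


def simulate_ltr_elements(config: SimConfig):
    """Plant LTR-RT candidates with known classes and insertion ages.

    Intact elements get a 3'-LTR that is the 5'-LTR mutated at expected
    2 * mu * age substitutions per site; their downstream flank carries the
    complete Gag-Pol domain.  Truncated elements carry a partial (50–90%)
    Gag-Pol on one flank; solo elements have random flanks.  Returns
    (candidates, truth_records, gagpol_protein).
    """
    from .ltr import LTRCandidate

    rng = np.random.default_rng([config.seed, _TAG_LTR])
    aas = "ACDEFGHIKLMNPQRSTVWY"
    gagpol = "".join(aas[i] for i in rng.integers(0, 20, config.gagpol_protein_len))
    gagpol_dna = _reverse_translate(rng, gagpol)
    flank = config.ltr_flank_len
    n_i, n_s, n_t = config.ltr_class_counts
    candidates = []
    records = []
    eid = 0
    for cls, n in (("intact", n_i), ("solo", n_s), ("truncated", n_t)):
        for _ in range(n):
            eid += 1
            element_id = f"LTR{eid:04d}"
            ltr_len = int(rng.integers(300, 601))
            ltr5 = random_dna(rng, ltr_len)
            age = float(rng.exponential(config.ltr_age_mean))
            chrom = f"chr{int(rng.integers(1, 2 * config.n_chrom_pairs + 1)):02d}"
            start = int(rng.integers(0, config.chrom_length - ltr_len))
            ltr3 = None
            if cls == "intact":
                ltr3 = jc_mutate(rng, ltr5, 2.0 * config.mu * age)
                pad = random_dna(rng, int(rng.integers(50, 200)))
                core = pad + gagpol_dna + pad
                down = (core + ltr3 + random_dna(rng, max(flank - len(core) - ltr_len, 0)))[:flank]
                up = random_dna(rng, flank)
            elif cls == "truncated":
                frac = rng.uniform(0.5, 0.9)
                part = gagpol_dna[: 3 * int(frac * config.gagpol_protein_len)]
                side_up = rng.random() < 0.5
                filler = random_dna(rng, max(flank - len(part), 0))
                if side_up:
                    up, down = (filler + part)[-flank:], random_dna(rng, flank)
                else:
                    up, down = random_dna(rng, flank), (part + filler)[:flank]
            else:
                up, down = random_dna(rng, flank), random_dna(rng, flank)
            candidates.append(LTRCandidate(
                element_id=element_id, chrom=chrom, start=start,
                end=start + ltr_len, ltr5_seq=ltr5, ltr3_seq=ltr3,
                flank_up=up, flank_down=down))
            records.append({"element_id": element_id, "structural_class": cls,
                            "age_years": age if cls == "intact" else None})
    return candidates, records, gagpol


# ---------------------------------------------------------------------------
# SVs
# ---------------------------------------------------------------------------

def _near_te(te_starts: np.ndarray, te_ends: np.ndarray, pos: int,
             window: int = 2000) -> bool:
    if len(te_starts) == 0:
        return False
    i = np.searchsorted(te_starts, pos + window, side="left")
    j = np.searchsorted(te_ends, pos - window, side="right")
    return i > j


def simulate_sv_table(truth: "GenomeTruth", config: SimConfig,
                      te_bed: pd.DataFrame) -> pd.DataFrame:
    """Plant SVs of the five types with controllable breakpoint TE enrichment.

    With enrichment 1.0 breakpoints are uniform; with enrichment k the odds
    that a breakpoint lands within 2 kb of a TE are multiplied by k (via
    importance resampling of candidate placements).
    """
    from .svenrich import SV_TYPES

    for t in config.sv_counts_per_type:
        if t not in SV_TYPES:
            raise SimConfigError(f"unknown SV type label {t!r}")
    rng = np.random.default_rng([config.seed, _TAG_SV])
    k = config.sv_breakpoint_te_enrichment
    chroms = sorted({g["chrom"] for g in truth.gene_info.values()})
    te_by_chrom = {
        c: (np.sort(sub["start"].to_numpy()), np.sort(sub["end"].to_numpy()))
        for c, sub in te_bed.groupby("chrom")
    }
    rows = []
    svi = 0
    max_tries = 2000
    for sv_type in sorted(config.sv_counts_per_type):
        for _ in range(int(config.sv_counts_per_type[sv_type])):
            svi += 1
            # rejection sampling: accept a uniform candidate with probability
            # k^near / k^2, tilting the breakpoint-near-TE odds by k
            best = None
            for _try in range(max_tries):
                chrom = chroms[int(rng.integers(len(chroms)))]
                length = int(rng.integers(5000, 30001))
                start = int(rng.integers(0, config.chrom_length - length))
                end = start + length
                ts, te_ = te_by_chrom.get(chrom, (np.array([]), np.array([])))
                near = int(_near_te(ts, te_, start)) + int(_near_te(ts, te_, end))
                if best is None or near > best[3]:
                    best = (chrom, start, end, near)
                accept = 1.0 if k <= 1.0 else k ** near / k ** 2
                if rng.random() < accept:
                    best = (chrom, start, end, near)
                    break
            chrom, start, end, near = best
            rows.append({"sv_id": f"SV{svi:05d}", "type": sv_type, "chrom": chrom,
                         "start": start, "end": end, "te_adjacent": near > 0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _write_fasta(path: Path, records: Sequence[tuple[str, str]], width: int = 80):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _build_chromosomes(config: SimConfig, genes: dict) -> list[tuple[str, str]]:
    rng = np.random.default_rng([config.seed, _TAG_SEQ, 2])
    chroms = sorted({g["chrom"] for g in genes.values()})
    out = []
    for chrom in chroms:
        arr = _BASES[rng.integers(0, 4, config.chrom_length)].copy()
        for gid in sorted(genes):
            g = genes[gid]
            if g["chrom"] != chrom:
                continue
            cds = g["cds"] if g["strand"] == "+" else _revcomp(g["cds"])
            exons = g["exons"] if g["strand"] == "+" else g["exons"]
            pos = 0
            for (s, e) in exons:
                chunk = cds[pos:pos + (e - s)]
                arr[s:e] = np.frombuffer(chunk.encode(), dtype=np.uint8)
                pos += e - s
        out.append((chrom, arr.tobytes().decode()))
    return out


def _write_gff3(path: Path, genes: dict) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genes, key=lambda g: (genes[g]["chrom"], genes[g]["start"])):
            g = genes[gid]
            c, s, e, st = g["chrom"], g["start"] + 1, g["end"], g["strand"]
            fh.write(f"{c}\tsim\tgene\t{s}\t{e}\t.\t{st}\t.\tID={gid}\n")
            tid = f"{gid}.t1"
            fh.write(f"{c}\tsim\tmRNA\t{s}\t{e}\t.\t{st}\t.\tID={tid};Parent={gid}\n")
            for i, (xs, xe) in enumerate(g["exons"], start=1):
                fh.write(f"{c}\tsim\texon\t{xs + 1}\t{xe}\t.\t{st}\t.\t"
                         f"ID={tid}.e{i};Parent={tid}\n")
                fh.write(f"{c}\tsim\tCDS\t{xs + 1}\t{xe}\t.\t{st}\t0\t"
                         f"ID={tid}.c{i};Parent={tid}\n")


def simulate_dataset(config: SimConfig, outdir: Optional[str] = None
                     ) -> tuple[Optional[SimBundle], GenomeTruth]:
    """Generate the full synthetic bundle; write files when ``outdir`` given.

    Emits genome FASTA, gene GFF3 (1–8 exons per gene), TE BED (class in the
    name field), LTR candidate table + sequence FASTA, Gag-Pol reference
    protein FASTA, SV TSV, counts TSV, design TSV, declared chromosome-pair
    TSV, and a versioned truth JSON with the config embedded.  Deterministic
    (byte-identical) for a fixed config.
    """
    chrom_pairs, genes, pairs, biased = _layout_genomes(config)
    module = _assign_modules(config, genes, pairs)
    te_bed, suppressed = _simulate_tes(config, genes, biased, pairs)
    rng_base = np.random.default_rng([config.seed, _TAG_COUNTS, 99])
    base_mean = {gid: float(np.exp(rng_base.normal(config.base_mean_log,
                                                   config.base_mean_sigma)))
                 for gid in sorted(genes)}
    # homoeolog B's baseline equals A's; the planted log2FC is the only
    # systematic within-pair difference
    for p in pairs:
        base_mean[p.gene_b] = base_mean[p.gene_a]
    gene_info = {gid: {k: v for k, v in g.items() if k != "cds"}
                 for gid, g in genes.items()}
    truth = GenomeTruth(
        chrom_pairs=chrom_pairs, homoeolog_pairs=pairs, gene_info=gene_info,
        gene_base_mean=base_mean, gene_module=module,
        te_suppressed_genes=suppressed, biased_chrom_pairs=biased,
        ltr_truth=[], sv_truth=[], config=config,
    )
    sv_table = simulate_sv_table(truth, config, te_bed)
    truth.sv_truth = sv_table.to_dict("records")
    # optional extra expression divergence for genes under duplication-type
    # SVs (expression-level only; planted categories are left untouched)
    if config.sv_overlap_extra_log2fc:
        dup = sv_table[sv_table["type"].isin(["duplication", "inverted_duplication"])]
        for p in pairs:
            gb = truth.gene_info[p.gene_b]
            sub = dup[dup["chrom"] == gb["chrom"]]
            if ((sub["start"] < gb["end"]) & (sub["end"] > gb["start"])).any():
                truth.sv_boosted_genes.add(p.gene_b)
    counts = simulate_counts(truth, config)
    candidates, ltr_records, gagpol = simulate_ltr_elements(config)
    truth.ltr_truth = ltr_records
    truth.gagpol_protein = gagpol

    if outdir is None:
        return None, truth

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = SimBundle(
        outdir=out,
        genome_fasta=out / "genome.fa",
        gff3=out / "genes.gff3",
        te_bed=out / "te.bed",
        ltr_table=out / "ltr_table.tsv",
        ltr_fasta=out / "ltr_seqs.fa",
        gagpol_fasta=out / "gagpol.faa",
        sv_tsv=out / "sv.tsv",
        counts_tsv=out / "counts.tsv",
        design_tsv=out / "design.tsv",
        chrom_pairs_tsv=out / "chrom_pairs.tsv",
        truth_json=out / "truth.json",
    )
    _write_fasta(bundle.genome_fasta, _build_chromosomes(config, genes))
    _write_gff3(bundle.gff3, genes)
    te_out = te_bed.copy()
    te_out["score"] = 0
    te_out["strand"] = "+"
    te_out.to_csv(bundle.te_bed, sep="\t", header=False, index=False)
    lt_rows = []
    fasta_records = []
    for cand, rec in zip(candidates, ltr_records):
        lt_rows.append((cand.element_id, cand.chrom, cand.start, cand.end))
        fasta_records.append((f"{cand.element_id}_5ltr", cand.ltr5_seq))
        if cand.ltr3_seq:
            fasta_records.append((f"{cand.element_id}_3ltr", cand.ltr3_seq))
        fasta_records.append((f"{cand.element_id}_up", cand.flank_up))
        fasta_records.append((f"{cand.element_id}_down", cand.flank_down))
    pd.DataFrame(lt_rows, columns=["element_id", "chrom", "start", "end"]).to_csv(
        bundle.ltr_table, sep="\t", index=False)
    _write_fasta(bundle.ltr_fasta, fasta_records)
    _write_fasta(bundle.gagpol_fasta, [("GagPol_ref", gagpol)])
    sv_table.to_csv(bundle.sv_tsv, sep="\t", index=False)
    counts.to_csv(bundle.counts_tsv, sep="\t")
    config.sample_table().to_csv(bundle.design_tsv, sep="\t")
    pd.DataFrame(chrom_pairs, columns=["chrom_a", "chrom_b"]).to_csv(
        bundle.chrom_pairs_tsv, sep="\t", index=False)
    bundle.truth_json.write_text(truth.to_json())
    return bundle, truth
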