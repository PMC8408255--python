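"""LTR retrotransposon structural classification, insertion dating, clustering,
removal-rate statistics, and gene-to-TE distances.

An intact LTR-RT carries two long terminal repeats flanking a complete
Gag-Pol internal domain; a solo-LTR is the recombinational ghost of a removed
element (no Gag-Pol on either flank); a truncated element retains a partial
internal domain.  Insertion ages come from the divergence between the 5' and
3' LTR of the same element — identical at insertion, then diverging neutrally
— as T = K / (2 mu) with K the Jukes–Cantor-corrected distance and mu the
per-site yearly substitution rate (default 1.3e-8).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .synteny import GeneModel

__all__ = [
    "LTRCandidate",
    "LTRElement",
    "LTRCluster",
    "RemovalStats",
    "classify_ltr",
    "insertion_time",
    "age_from_divergence",
    "cluster_ltrs",
    "removal_ratios",
    "nearest_te_distance",
]

MU_DEFAULT = 1.3e-8  # substitutions per site per year


class LTRError(ValueError):
    pass


@dataclass
class LTRCandidate:
    """A candidate element: an LTR sequence plus its genomic flanks."""

    element_id: str
    chrom: str
    start: int
    end: int
    ltr5_seq: str
    ltr3_seq: Optional[str] = None
    flank_up: str = ""
    flank_down: str = ""


@dataclass
class LTRElement:
    element_id: str
    chrom: str
    start: int
    end: int
    ltr5_seq: str
    ltr3_seq: Optional[str]
    structural_class: str  # intact | solo | truncated
    age_years: Optional[float] = None
    cluster_id: Optional[int] = None


@dataclass
class LTRCluster:
    cluster_id: int
    members: list[str]
    n_intact: int
    n_solo: int
    n_truncated: int

    @property
    def s_to_i(self) -> Optional[float]:
        return self.n_solo / self.n_intact if self.n_intact else None

    @property
    def t_to_i(self) -> Optional[float]:
        return self.n_truncated / self.n_intact if self.n_intact else None


@dataclass
class RemovalStats:
    s_to_i: Optional[float]
    t_to_i: Optional[float]
    st_to_i: Optional[float]
    prop_clusters_si_gt3: Optional[float]
    n_ratio_clusters: int


# ---------------------------------------------------------------------------
# alignment helpers
# ---------------------------------------------------------------------------

def _nuc_global_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "global"
    aln.match_score = 1.0
    aln.mismatch_score = -1.0
    aln.open_gap_score = -5.0
    aln.extend_gap_score = -1.0
    return aln


def _prot_local_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    return aln


_NUC = _nuc_global_aligner()
_PROT = _prot_local_aligner()


def _core_alignment_stats(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """Identity and mutual coverage of the terminal-gap-trimmed global alignment.

    Returns (identity over core columns, coverage of a, coverage of b).
    """
    aln = _NUC.align(seq_a.upper(), seq_b.upper())[0]
    ra, rb = str(aln[0]), str(aln[1])
    # trim terminal gap columns
    lo = 0
    hi = len(ra)
    while lo < hi and (ra[lo] == "-" or rb[lo] == "-"):
        lo += 1
    while hi > lo and (ra[hi - 1] == "-" or rb[hi - 1] == "-"):
        hi -= 1
    if hi <= lo:
        return 0.0, 0.0, 0.0
    core_a, core_b = ra[lo:hi], rb[lo:hi]
    cols = hi - lo
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    span_a = sum(1 for x in core_a if x != "-")
    span_b = sum(1 for x in core_b if x != "-")
    return matches / cols, span_a / len(seq_a), span_b / len(seq_b)


def _six_frames(dna: str):
    dna = dna.upper()
    rc = str(Seq(dna).reverse_complement())
    for src in (dna, rc):
        for off in range(3):
            frame = src[off:]
            frame = frame[: len(frame) - len(frame) % 3]
            if frame:
                yield str(Seq(frame).translate()).replace("*", "X")


def _gagpol_hit(dna: str, ref_protein: str) -> tuple[float, float]:
    """Best (reference coverage, identity) of a translated search of ``dna``.

    All six reading frames are locally aligned against the reference Gag-Pol
    protein; the best-scoring frame wins.
    """
    best_cov = 0.0
    best_ident = 0.0
    best_score = -1.0
    if not dna or not ref_protein:
        return 0.0, 0.0
    for prot in _six_frames(dna):
        if len(prot) == 0:
            continue
        alns = _PROT.align(prot, ref_protein)
        if len(alns) == 0:
            continue
        aln = alns[0]
        if aln.score <= 0 or aln.score <= best_score:
            continue
        ra, rb = str(aln[0]), str(aln[1])
        cols = sum(1 for x, y in zip(ra, rb) if x != "-" and y != "-")
        if cols == 0:
            continue
        matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
        ref_res = sum(1 for y in rb if y != "-")
        best_score = aln.score
        best_cov = ref_res / len(ref_protein)
        best_ident = matches / cols
    return best_cov, best_ident


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_ltr(candidates: Sequence[LTRCandidate],
                 gagpol_reference: str,
                 intact_coverage: float = 0.95,
                 truncated_coverage: float = 0.50,
                 min_identity: float = 0.30,
                 flank_len: int = 15000) -> list[LTRElement]:
    """Classify candidates as intact / truncated / solo by flanking Gag-Pol homology.

    A translated search of each flank (up to ``flank_len`` bp) against the
    reference Gag-Pol protein decides the class: a complete domain
    (>= ``intact_coverage`` of the reference at >= ``min_identity``) on either
    side makes the element intact; >= ``truncated_coverage`` on one side makes
    it truncated; no homology on either side makes it a solo-LTR.  Flanks
    shorter than ``flank_len`` are used as-is (a warning notes how many were
    short).  Every candidate receives exactly one class.
    """
    if not gagpol_reference:
        raise LTRError("empty Gag-Pol reference protein")
    out: list[LTRElement] = []
    n_short = 0
    for cand in candidates:
        up = cand.flank_up[-flank_len:]
        down = cand.flank_down[:flank_len]
        if len(cand.flank_up) < flank_len or len(cand.flank_down) < flank_len:
            n_short += 1
        cov_u, id_u = _gagpol_hit(up, gagpol_reference)
        cov_d, id_d = _gagpol_hit(down, gagpol_reference)
        hits = [(c, i) for c, i in ((cov_u, id_u), (cov_d, id_d)) if i >= min_identity]
        best_cov = max((c for c, _ in hits), default=0.0)
        if best_cov >= intact_coverage:
            cls = "intact"
        elif best_cov >= truncated_coverage:
            cls = "truncated"
        else:
            cls = "solo"
        out.append(
            LTRElement(element_id=cand.element_id, chrom=cand.chrom,
                       start=cand.start, end=cand.end, ltr5_seq=cand.ltr5_seq,
                       ltr3_seq=cand.ltr3_seq if cls == "intact" else None,
                       structural_class=cls)
        )
    if n_short:
        warnings.warn(f"{n_short} candidate(s) had flanks shorter than {flank_len} bp; "
                      "classified on the available sequence", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# insertion dating
# ---------------------------------------------------------------------------

def age_from_divergence(k: float, mu: float = MU_DEFAULT) -> float:
    """Insertion age T = K / (2 mu) from a corrected LTR-LTR distance."""
    if mu <= 0:
        raise LTRError("mu must be positive")
    return k / (2.0 * mu)


def insertion_time(ltr5_seq: str, ltr3_seq: str,
                   mu: float = MU_DEFAULT) -> Optional[float]:
    """Estimate the insertion age of an element from its two LTRs.

    The LTRs are globally aligned; the p-distance over aligned non-gap columns
    is Jukes–Cantor corrected (K = -3/4 ln(1 - 4p/3)) and converted to years
    as T = K / (2 mu).  Returns None when p >= 3/4 (saturated).
    """
    if not ltr5_seq or not ltr3_seq:
        raise LTRError("both LTR sequences must be nonempty")
    aln = _NUC.align(ltr5_seq.upper(), ltr3_seq.upper())[0]
    ra, rb = str(aln[0]), str(aln[1])
    cols = 0
    diffs = 0
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            continue
        cols += 1
        if x != y:
            diffs += 1
    if cols == 0:
        raise LTRError("LTR alignment has no aligned columns")
    p = diffs / cols
    if p >= 0.75:
        return None
    k = -0.75 * math.log1p(-4.0 * p / 3.0)
    return age_from_divergence(k, mu)


# ---------------------------------------------------------------------------
# clustering and removal stats
# ---------------------------------------------------------------------------

def _pair_qualifies(seq_a: str, seq_b: str, min_coverage: float,
                    min_identity: float) -> bool:
    ident, cov_a, cov_b = _core_alignment_stats(seq_a, seq_b)
    return ident >= min_identity and cov_a >= min_coverage and cov_b >= min_coverage


def cluster_ltrs(elements: Sequence[LTRElement],
                 min_coverage: float = 0.70,
                 min_identity: float = 0.60) -> list[LTRCluster]:
    """Single-linkage clusters over 5'-LTR sequences.

    Two elements share a cluster when their LTRs cover at least
    ``min_coverage`` of each other with at least ``min_identity`` identity;
    clusters are the transitive closure of qualifying pairs, so solo and
    truncated elements join the cluster of their most similar intact element
    whenever they meet the same thresholds.  The partition is independent of
    input order.
    """
    order = sorted(range(len(elements)), key=lambda i: elements[i].element_id)
    parent = list(range(len(elements)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for pa in range(len(order)):
        for pb in range(pa + 1, len(order)):
            i, j = order[pa], order[pb]
            if find(i) == find(j):
                continue
            if _pair_qualifies(elements[i].ltr5_seq, elements[j].ltr5_seq,
                               min_coverage, min_identity):
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(len(elements)):
        comps.setdefault(find(i), []).append(i)
    clusters: list[LTRCluster] = []
    for cid, members in enumerate(
        sorted(comps.values(), key=lambda m: elements[m[0]].element_id), start=1
    ):
        ids = sorted(elements[i].element_id for i in members)
        classes = [elements[i].structural_class for i in members]
        for i in members:
            elements[i].cluster_id = cid
        clusters.append(
            LTRCluster(cluster_id=cid, members=ids,
                       n_intact=classes.count("intact"),
                       n_solo=classes.count("solo"),
                       n_truncated=classes.count("truncated"))
        )
    return clusters


def removal_ratios(clusters: Sequence[LTRCluster]) -> RemovalStats:
    """Genome-wide S:I, T:I and (S+T):I ratios plus the S:I > 3 cluster share.

    Per-cluster ratios are defined only for clusters with at least one intact
    member; those clusters form the denominator of the S:I > 3 proportion
    (strictly greater — a cluster at exactly 3 is not counted).
    """
    tot_i = sum(c.n_intact for c in clusters)
    tot_s = sum(c.n_solo for c in clusters)
    tot_t = sum(c.n_truncated for c in clusters)
    ratio_clusters = [c for c in clusters if c.n_intact > 0]
    if tot_i == 0:
        warnings.warn("no cluster contains an intact element; removal ratios undefined",
                      stacklevel=2)
        return RemovalStats(None, None, None, None, 0)
    n_gt3 = sum(1 for c in ratio_clusters if c.s_to_i > 3.0)
    return RemovalStats(
        s_to_i=tot_s / tot_i,
        t_to_i=tot_t / tot_i,
        st_to_i=(tot_s + tot_t) / tot_i,
        prop_clusters_si_gt3=n_gt3 / len(ratio_clusters),
        n_ratio_clusters=len(ratio_clusters),
    )


# ---------------------------------------------------------------------------
# gene-to-TE distances
# ---------------------------------------------------------------------------

def nearest_te_distance(genes: Sequence[GeneModel], te_bed: pd.DataFrame,
                        known_chroms: Optional[set[str]] = None) -> pd.Series:
    """Distance (bp) from each gene to its nearest TE on the same chromosome.

    ``te_bed`` is a BED-style frame with columns chrom/start/end (0-based
    half-open).  Overlap gives distance 0; otherwise the gap between interval
    ends.  Genes on TE-free chromosomes get NaN.  A TE on a chromosome absent
    from ``known_chroms`` (default: the genes' chromosomes) is an error.
    """
    import pyranges as pr

    gene_chroms = {g.chrom for g in genes}
    if known_chroms is None:
        known_chroms = gene_chroms
    unknown = set(te_bed["chrom"]) - set(known_chroms)
    if unknown:
        raise LTRError(f"unknown chromosome(s) in TE BED: {sorted(unknown)[:5]}")
    if len(te_bed) == 0:
        raise LTRError("empty TE annotation")
    gdf = pd.DataFrame({
        "Chromosome": [g.chrom for g in genes],
        "Start": [g.start for g in genes],
        "End": [g.end for g in genes],
        "gene_id": [g.gene_id for g in genes],
    })
    tdf = pd.DataFrame({
        "Chromosome": te_bed["chrom"].to_numpy(),
        "Start": te_bed["start"].to_numpy(),
        "End": te_bed["end"].to_numpy(),
    })
    nearest = pr.PyRanges(gdf).nearest(pr.PyRanges(tdf), overlap=True).df
    out = pd.Series(np.nan, index=[g.gene_id for g in genes], dtype=float)
    if len(nearest):
        # pyranges reports bedtools-style distance: 0 for overlap, gap+1 otherwise
        dist = np.maximum(nearest["Distance"].to_numpy() - 1, 0)
        overlap = (nearest["Start_b"] < nearest["End"]) & (nearest["End_b"] > nearest["Start"])
        dist = np.where(overlap, 0, dist)
        out.loc[nearest["gene_id"].to_numpy()] = dist
    return out
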