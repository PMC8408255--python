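"""Codon-aware alignment, NG86 Ka/Ks estimation and Ks-distribution peak detection.

The Ka/Ks estimator is the Nei–Gojobori (1986) counting method: per-codon
synonymous/nonsynonymous site fractions, difference counts averaged over all
minimal substitution pathways (pathways through stop codons excluded), and a
Jukes–Cantor multiple-hit correction.  Recent homoeologs from a whole-genome
duplication sit at low divergence (Ks on the order of 0.1), where NG86 is an
adequate and fully enumerable estimator; the estimator interface is a plain
function, so model variants can be swapped in.

Ks values above ``ks_max`` (default 5.0) are treated as saturated and are
excluded from distribution building, because synonymous sites are saturated at
that distance and the Jukes–Cantor correction is no longer informative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "KsDistribution",
    "align_cds_pair",
    "kaks_ng86",
    "ks_distribution",
    "detect_ks_peaks",
    "SENSE_CODONS",
    "STOP_CODONS",
]

_BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_CODON_TO_AA = dict(standard_dna_table.forward_table)
SENSE_CODONS = tuple(sorted(_CODON_TO_AA))


class SeqEvolError(ValueError):
    """Raised for invalid coding sequences or degenerate distributions."""


# ---------------------------------------------------------------------------
# NG86 lookup tables
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of a sense codon.

    At each position, the fraction of the possible single-nucleotide changes
    that are synonymous is computed over changes to *sense* codons only
    (mutations to stop codons are not counted as mutational opportunities,
    following NG86).  The three positions sum to exactly 3 sites.
    """
    aa = _CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if _CODON_TO_AA[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


_SITES: dict[str, tuple[float, float]] = {c: _codon_sites(c) for c in SENSE_CODONS}


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts between two codons.

    All minimal substitution pathways (orderings of the differing positions)
    are enumerated; pathways passing through a stop codon are excluded.  In
    the degenerate case where every pathway is blocked, all pathways are used
    and steps into or out of a stop codon count as nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                ok = False
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                nd += 1.0
            elif _CODON_TO_AA[cur] == _CODON_TO_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (paths if ok else blocked).append((sd, nd))
    use = paths if paths else blocked
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _diffs(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    hit = _DIFFS.get(key)
    if hit is None:
        hit = _pathway_differences(c1, c2)
        _DIFFS[key] = hit
        _DIFFS[(c2, c1)] = hit
    return hit


# ---------------------------------------------------------------------------
# Codon-aware pairwise alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """A pair of gapped CDSs whose gaps fall on whole-codon boundaries."""

    aligned_cds_a: str
    aligned_cds_b: str

    def __post_init__(self) -> None:
        if len(self.aligned_cds_a) != len(self.aligned_cds_b):
            raise SeqEvolError("aligned sequences differ in length")
        if len(self.aligned_cds_a) % 3:
            raise SeqEvolError("aligned length not divisible by 3")

    @property
    def codon_columns(self) -> int:
        return len(self.aligned_cds_a) // 3

    def codon_pairs(self):
        a, b = self.aligned_cds_a, self.aligned_cds_b
        for i in range(0, len(a), 3):
            yield a[i:i + 3], b[i:i + 3]


def _translate_checked(cds: str, label: str) -> str:
    if len(cds) % 3:
        raise SeqEvolError(f"{label}: length {len(cds)} not divisible by 3")
    cds = cds.upper()
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
        cds = cds[:-3]
    if "*" in prot:
        raise SeqEvolError(
            f"{label}: internal stop codon at codon index {prot.index('*')}"
        )
    return prot


_PROT_ALIGNER: Optional[PairwiseAligner] = None


def _protein_aligner() -> PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        aln = PairwiseAligner()
        aln.mode = "global"
        aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aln.open_gap_score = -10.0
        aln.extend_gap_score = -1.0
        _PROT_ALIGNER = aln
    return _PROT_ALIGNER


def align_cds_pair(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided global codon alignment of two coding sequences.

    The CDSs are translated (a trailing stop codon is trimmed), the proteins
    globally aligned with BLOSUM62 and affine gaps (open 10, extend 1), and
    the alignment back-translated so that every gap spans whole codons.
    """
    prot_a = _translate_checked(cds_a, "cds_a")
    prot_b = _translate_checked(cds_b, "cds_b")
    cds_a = cds_a.upper()[: 3 * len(prot_a)]
    cds_b = cds_b.upper()[: 3 * len(prot_b)]
    alignment = _protein_aligner().align(prot_a, prot_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for ra, rb in zip(row_a, row_b):
        if ra == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia:3 * ia + 3])
            ia += 1
        if rb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib:3 * ib + 3])
            ib += 1
    return CodonAlignment("".join(out_a), "".join(out_b))


# ---------------------------------------------------------------------------
# NG86 estimation
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    """NG86 estimates for one aligned pair.

    ``ka``/``ks`` are ``None`` when the corresponding p-distance is saturated
    (p >= 3/4, Jukes–Cantor undefined); ``ratio`` is ``None`` when either rate
    is undefined or Ks is zero.
    """

    ka: Optional[float]
    ks: Optional[float]
    ratio: Optional[float]
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    codon_columns: int = 0


def _jukes_cantor(p: float) -> Optional[float]:
    if p < 0:
        raise SeqEvolError("negative proportion of differences")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_ng86(aln: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks from a codon alignment.

    Columns with a gap, an ambiguous base, or a stop codon in either sequence
    are skipped.  Site counts are averaged over the two sequences; difference
    counts average over all minimal stop-free substitution pathways.
    """
    s_sites = n_sites = sd = nd = 0.0
    used = 0
    for ca, cb in aln.codon_pairs():
        if "-" in ca or "-" in cb:
            continue
        if any(b not in _BASES for b in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = _SITES[ca]
        sb, nb = _SITES[cb]
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        dsd, dnd = _diffs(ca, cb)
        sd += dsd
        nd += dnd
        used += 1
    if used == 0:
        raise SeqEvolError("no comparable codon columns (all gapped or invalid)")
    ks = _jukes_cantor(sd / s_sites) if s_sites > 0 else None
    ka = _jukes_cantor(nd / n_sites) if n_sites > 0 else None
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, n_sites=n_sites,
                      s_sites=s_sites, nd=nd, sd=sd, codon_columns=used)


# ---------------------------------------------------------------------------
# Ks distributions and WGD peaks
# ---------------------------------------------------------------------------

@dataclass
class KsDistribution:
    """Filtered Ks values with their Gaussian KDE and detected modes."""

    values: np.ndarray
    kde_x: np.ndarray
    kde_density: np.ndarray
    peaks: list[tuple[float, float]] = field(default_factory=list)
    n_dropped: int = 0


def ks_distribution(results: Sequence[KaKsResult], ks_max: float = 5.0,
                    grid_points: int = 512) -> KsDistribution:
    """Build a Ks KDE (Silverman bandwidth) from finite Ks in (0, ks_max].

    Saturated (undefined), zero, and > ``ks_max`` values are dropped; the
    number dropped is recorded on the result.
    """
    raw = [r.ks for r in results]
    values = np.array([v for v in raw if v is not None and 0.0 < v <= ks_max])
    n_dropped = len(raw) - len(values)
    if len(values) < 2:
        raise SeqEvolError(
            f"need >= 2 usable Ks values in (0, {ks_max}], got {len(values)}"
        )
    if np.ptp(values) == 0.0:
        # Point mass: KDE is singular; report a narrow Gaussian by hand.
        center = float(values[0])
        bw = max(0.01 * center, 1e-4)
        x = np.linspace(center - 6 * bw, center + 6 * bw, grid_points)
        dens = np.exp(-0.5 * ((x - center) / bw) ** 2) / (bw * math.sqrt(2 * math.pi))
        return KsDistribution(values, x, dens, n_dropped=n_dropped)
    kde = gaussian_kde(values, bw_method="silverman")
    bw = kde.factor * values.std(ddof=1)
    x = np.linspace(values.min() - 5 * bw, values.max() + 5 * bw, grid_points)
    dens = kde(x)
    return KsDistribution(values, x, dens, n_dropped=n_dropped)


def detect_ks_peaks(dist: KsDistribution,
                    min_prominence: float = 0.05) -> list[tuple[float, float]]:
    """Local maxima of the KDE with prominence >= min_prominence * max density.

    Returns (mode, height) tuples in increasing mode order and stores them on
    the distribution.
    """
    dens = dist.kde_density
    if dens.size == 0:
        return []
    idx, _ = find_peaks(dens, prominence=min_prominence * float(dens.max()))
    peaks = [(float(dist.kde_x[i]), float(dens[i])) for i in idx]
    peaks.sort(key=lambda t: t[0])
    dist.peaks = peaks
    return peaks
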