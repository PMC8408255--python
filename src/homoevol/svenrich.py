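"""TE enrichment at structural-variant breakpoints and SV expression impact.

The null model follows the random-region design: 2 kb windows on each side of
every SV breakpoint are compared with fixed-size regions (default 4 kb)
sampled uniformly from each chromosome (default 1000 per chromosome).  Two
complementary statistics are reported per TE class: a 2x2 presence/absence
chi-square (primary) and a Mann–Whitney rank test on per-region TE counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bias import DEResult, is_significant_twofold
from .dynamics import mann_whitney
from .synteny import GeneModel

__all__ = [
    "SVRecord",
    "RegionSet",
    "EnrichmentResult",
    "SV_TYPES",
    "breakpoint_flanks",
    "sample_random_regions",
    "te_enrichment",
    "sv_expression_impact",
]

SV_TYPES = (
    "duplication",
    "inversion",
    "translocation",
    "inverted_duplication",
    "inverted_translocation",
)


class SVError(ValueError):
    pass


@dataclass(frozen=True)
class SVRecord:
    sv_id: str
    sv_type: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise SVError(f"unknown SV type {self.sv_type!r}")
        if self.start >= self.end:
            raise SVError(f"{self.sv_id}: start must be < end")


@dataclass
class RegionSet:
    regions: pd.DataFrame  # chrom, start, end
    provenance: str  # "breakpoint_flank" | "random"

    def __len__(self) -> int:
        return len(self.regions)


def breakpoint_flanks(svs: Sequence[SVRecord],
                      chrom_sizes: Mapping[str, int],
                      flank: int = 2000) -> RegionSet:
    """Windows of ±``flank`` bp around both breakpoints of every SV.

    Windows are truncated at chromosome edges and deduplicated.  An SV whose
    coordinates fall outside its chromosome is an error.
    """
    seen: set[tuple[str, int, int]] = set()
    for sv in svs:
        size = chrom_sizes.get(sv.chrom)
        if size is None:
            raise SVError(f"{sv.sv_id}: chromosome {sv.chrom} has no declared size")
        if sv.start < 0 or sv.end > size:
            raise SVError(f"{sv.sv_id}: coordinates outside chromosome bounds")
        for bp in (sv.start, sv.end):
            lo = max(bp - flank, 0)
            hi = min(bp + flank, size)
            if hi > lo:
                seen.add((sv.chrom, lo, hi))
    df = pd.DataFrame(sorted(seen), columns=["chrom", "start", "end"])
    return RegionSet(regions=df, provenance="breakpoint_flank")


def sample_random_regions(chrom_sizes: Mapping[str, int],
                          n_per_chrom: int = 1000, size: int = 4000,
                          seed: int = 0) -> RegionSet:
    """Uniformly placed fixed-size regions, ``n_per_chrom`` per chromosome.

    Overlaps among sampled regions are permitted; chromosomes shorter than
    ``size`` are skipped with a warning.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_skipped = 0
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        if length < size:
            n_skipped += 1
            continue
        starts = rng.integers(0, length - size + 1, n_per_chrom)
        rows.extend((chrom, int(s), int(s) + size) for s in starts)
    if n_skipped:
        warnings.warn(f"{n_skipped} chromosome(s) shorter than {size} bp skipped",
                      stacklevel=2)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return RegionSet(regions=df, provenance="random")


def _overlap_counts(regions: pd.DataFrame, tes: pd.DataFrame) -> np.ndarray:
    """Number of TEs overlapping each region (sorted-interval counting)."""
    out = np.zeros(len(regions), dtype=int)
    for chrom, idx in regions.groupby("chrom").groups.items():
        sub = tes[tes["chrom"] == chrom]
        if sub.empty:
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        r = regions.loc[idx]
        # overlapping intervals = (# starts < region_end) - (# ends <= region_start)
        n = (np.searchsorted(starts, r["end"].to_numpy(), side="left")
             - np.searchsorted(ends, r["start"].to_numpy(), side="right"))
        out[regions.index.get_indexer(idx)] = n
    return out


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per TE class + overall
    enriched: bool


def te_enrichment(flanks: RegionSet, random_regions: RegionSet,
                  te_bed: pd.DataFrame) -> EnrichmentResult:
    """Compare TE content of breakpoint flanks against the random-region null.

    Per TE class (BED ``name`` column) and overall: (a) a Pearson chi-square
    on the 2x2 table of regions containing >= 1 TE vs not, flanks vs random;
    (b) a Mann–Whitney test on per-region TE counts.  The overall verdict is
    "enriched" when the all-class chi-square has p < 0.05 with a higher
    flank presence fraction.
    """
    if len(flanks) == 0 or len(random_regions) == 0:
        raise SVError("both region sets must be nonempty")
    if len(te_bed) == 0:
        raise SVError("empty TE annotation")
    classes = ["all"] + sorted(te_bed["name"].unique())
    rows = []
    enriched = False
    for cls in classes:
        tes = te_bed if cls == "all" else te_bed[te_bed["name"] == cls]
        cf = _overlap_counts(flanks.regions, tes)
        cr = _overlap_counts(random_regions.regions, tes)
        with_f, with_r = int((cf > 0).sum()), int((cr > 0).sum())
        table = np.array([[with_f, len(cf) - with_f], [with_r, len(cr) - with_r]])
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            chi2, p_chi2 = 0.0, 1.0
        else:
            chi2, p_chi2, _, _ = stats.chi2_contingency(table, correction=False)
        u, p_mw = mann_whitney(cf, cr)
        frac_f = with_f / len(cf)
        frac_r = with_r / len(cr)
        rows.append((cls, len(cf), with_f, frac_f, len(cr), with_r, frac_r,
                     float(chi2), float(p_chi2), u, p_mw))
        if cls == "all" and p_chi2 < 0.05 and frac_f > frac_r:
            enriched = True
    table = pd.DataFrame(
        rows,
        columns=["te_class", "n_flank", "flank_with_te", "flank_frac",
                 "n_random", "random_with_te", "random_frac", "chi2", "p_chi2",
                 "mw_u", "p_mw"],
    )
    return EnrichmentResult(table=table, enriched=enriched)


def sv_expression_impact(svs: Sequence[SVRecord], genes: Sequence[GeneModel],
                         de_results: Sequence[DEResult],
                         homoeolog_block_genes: Optional[set[str]] = None
                         ) -> pd.DataFrame:
    """Per-SV-type counts of overlapped genes and their DE fraction.

    A gene overlapping SVs of several types is counted once per type.  The DE
    fraction is the share of SV-overlapping homoeolog genes with significant
    >= 2-fold pooled differential expression; it is NaN for types overlapping
    no homoeolog gene.  When ``homoeolog_block_genes`` is given, the count of
    SV genes inside homoeologous-chromosome synteny blocks is also reported.
    """
    de_genes: set[str] = set()
    tested_genes: set[str] = set()
    for res in de_results:
        tested_genes.update((res.pair.gene_a, res.pair.gene_b))
        if is_significant_twofold(res):
            de_genes.update((res.pair.gene_a, res.pair.gene_b))
    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for sv_type in SV_TYPES:
        hit: set[str] = set()
        for sv in svs:
            if sv.sv_type != sv_type:
                continue
            for g in by_chrom.get(sv.chrom, ()):
                if g.start < sv.end and g.end > sv.start:
                    hit.add(g.gene_id)
        homoeo = hit & tested_genes
        n_de = len(homoeo & de_genes)
        frac = n_de / len(homoeo) if homoeo else np.nan
        n_block = len(hit & homoeolog_block_genes) if homoeolog_block_genes else np.nan
        rows.append((sv_type, len(hit), len(homoeo), n_de, frac, n_block))
    return pd.DataFrame(
        rows, columns=["sv_type", "n_genes", "n_homoeolog_genes",
                       "n_de_genes", "de_fraction", "n_in_synteny_blocks"],
    )
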