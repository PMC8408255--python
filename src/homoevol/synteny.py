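"""Gene-annotation parsing, collinear anchor chaining, and homoeolog calling.

Homoeologs are defined positionally: anchor gene pairs are chained into
collinear synteny blocks of at least ``min_block_size`` genes (both rank
coordinates strictly monotone, gaps bounded), and only the pairs lying on
blocks between *declared* homoeologous chromosome pairs are retained as
homoeologs.  The declared pair list always comes from the caller — homoeology
between chromosomes is an assembly-level fact, never inferred from anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils

__all__ = [
    "GeneModel",
    "AnchorPair",
    "SyntenyBlock",
    "HomoeologPair",
    "parse_annotation",
    "chain_anchors",
    "identify_homoeologs",
    "anchors_from_pairs",
]


class AnnotationError(ValueError):
    """Raised when a GFF3 file violates basic structural invariants."""


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene with 0-based half-open coordinates and per-gene structure counts."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_count: int
    cds_length: int

    @property
    def intron_count(self) -> int:
        return max(self.exon_count - 1, 0)


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    similarity: Optional[float] = None


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str  # "same" | "inverted"
    score: float = 0.0
    block_id: str = ""

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class HomoeologPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    block_id: str = ""


# ---------------------------------------------------------------------------
# GFF3 parsing
# ---------------------------------------------------------------------------

def _prescan_gff3(path: str) -> None:
    """Line-level validation so errors can name the offending line."""
    seen_ids: set[str] = set()
    pending_parents: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: non-integer coordinates") from exc
            if start > end:
                raise AnnotationError(f"line {lineno}: start {start} > end {end}")
            if cols[6] not in {"+", "-", ".", "?"}:
                raise AnnotationError(f"line {lineno}: unknown strand {cols[6]!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" in attrs:
                seen_ids.add(attrs["ID"])
            for parent in attrs.get("Parent", "").split(","):
                if parent:
                    pending_parents.append((lineno, parent))
    for lineno, parent in pending_parents:
        if parent not in seen_ids:
            raise AnnotationError(f"line {lineno}: orphan feature, Parent {parent!r} not found")


def parse_annotation(gff3_path: str) -> tuple[list[GeneModel], dict[str, int]]:
    """Parse a GFF3 into gene models plus per-chromosome gene-order ranks.

    Coordinates are converted to 0-based half-open.  Exon and CDS counts come
    from the transcript with the longest total CDS (longest total exon span
    when no CDS is annotated).  Returns ``(genes, ranks)`` with genes sorted
    by (chrom, start) and ``ranks[gene_id]`` the gene's order index along its
    chromosome.
    """
    _prescan_gff3(gff3_path)
    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        best_exons = 0
        best_cds = 0
        best_key = -1
        for t in db.children(g, level=1):
            exons = list(db.children(t, featuretype="exon"))
            cds = list(db.children(t, featuretype="CDS"))
            for feat in exons + cds:
                if feat.start < g.start or feat.end > g.end:
                    raise AnnotationError(
                        f"{feat.featuretype} {feat.id} outside gene span of {g.id}"
                    )
            cds_len = sum(c.end - c.start + 1 for c in cds)
            exon_len = sum(e.end - e.start + 1 for e in exons)
            key = cds_len if cds else exon_len
            if key > best_key:
                best_key = key
                best_exons = len(exons) if exons else 1
                best_cds = cds_len
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exon_count=best_exons or 1,
                cds_length=best_cds,
            )
        )
    genes.sort(key=lambda x: (x.chrom, x.start, x.gene_id))
    ranks: dict[str, int] = {}
    counter: dict[str, int] = {}
    for gene in genes:
        ranks[gene.gene_id] = counter.get(gene.chrom, 0)
        counter[gene.chrom] = ranks[gene.gene_id] + 1
    return genes, ranks


# ---------------------------------------------------------------------------
# Collinear chaining
# ---------------------------------------------------------------------------

def _best_chain(anchors: list[AnchorPair], max_rank_gap: int,
                gap_penalty: float) -> tuple[float, list[AnchorPair], str]:
    """Best-scoring collinear chain over one anchor set (both orientations).

    Dynamic programme over rank-sorted anchors; an anchor extends a chain when
    both rank gaps are within ``max_rank_gap`` and both rank coordinates are
    strictly monotone.  Score = anchor count - gap_penalty * total rank gap.
    Ties prefer the chain whose first anchor has the smallest rank_a, then the
    "same" orientation.
    """
    best_score = -1.0
    best_chain: list[AnchorPair] = []
    best_orient = "same"
    for orient in ("same", "inverted"):
        sign = 1 if orient == "same" else -1
        idx = sorted(range(len(anchors)),
                     key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b))
        score = [1.0] * len(anchors)
        prev: list[int] = [-1] * len(anchors)
        for pi, i in enumerate(idx):
            ai = anchors[i]
            for j in idx[:pi]:
                aj = anchors[j]
                da = ai.rank_a - aj.rank_a
                db = sign * (ai.rank_b - aj.rank_b)
                if da <= 0 or db <= 0:
                    continue
                if da - 1 > max_rank_gap or db - 1 > max_rank_gap:
                    continue
                cand = score[j] + 1.0 - gap_penalty * ((da - 1) + (db - 1))
                if cand > score[i] + 1e-12:
                    score[i] = cand
                    prev[i] = j
        if not anchors:
            continue
        end = max(range(len(anchors)), key=lambda i: score[i])
        chain: list[AnchorPair] = []
        k = end
        while k != -1:
            chain.append(anchors[k])
            k = prev[k]
        chain.reverse()
        better = score[end] > best_score + 1e-12
        tie = abs(score[end] - best_score) <= 1e-12
        if better or (tie and best_chain and chain[0].rank_a < best_chain[0].rank_a):
            best_score = score[end]
            best_chain = chain
            best_orient = orient
    return best_score, best_chain, best_orient


def chain_anchors(anchors: Sequence[AnchorPair], chrom_a: str = "", chrom_b: str = "",
                  min_block_size: int = 5, max_rank_gap: int = 25,
                  gap_penalty: float = 0.1) -> list[SyntenyBlock]:
    """Chain anchors between one chromosome pair into collinear synteny blocks.

    Blocks are extracted greedily: the best-scoring chain is removed first,
    the programme re-run on the remaining anchors, until no chain of at least
    ``min_block_size`` anchors remains.  Each anchor belongs to at most one
    block.  The default ``max_rank_gap`` of 25 mirrors the conventional
    MCScanX MAX_GAPS setting.
    """
    remaining = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b, a.gene_a, a.gene_b))
    blocks: list[SyntenyBlock] = []
    n = 0
    while len(remaining) >= min_block_size:
        score, chain, orient = _best_chain(remaining, max_rank_gap, gap_penalty)
        if len(chain) < min_block_size:
            break
        n += 1
        blocks.append(
            SyntenyBlock(
                chrom_a=chrom_a, chrom_b=chrom_b, anchors=chain,
                orientation=orient, score=score,
                block_id=f"{chrom_a}-{chrom_b}-b{n}",
            )
        )
        chain_set = set(chain)
        remaining = [a for a in remaining if a not in chain_set]
    return blocks


def anchors_from_pairs(pairs: Iterable[tuple[str, str]],
                       ranks: dict[str, int]) -> list[AnchorPair]:
    """Build AnchorPairs from (gene_a, gene_b) tuples and precomputed ranks."""
    out = []
    for ga, gb in pairs:
        if ga not in ranks or gb not in ranks:
            raise SyntenyError(f"gene without rank: {ga if ga not in ranks else gb}")
        out.append(AnchorPair(ga, gb, ranks[ga], ranks[gb]))
    return out


def identify_homoeologs(blocks: Sequence[SyntenyBlock],
                        chrom_pairs: Sequence[tuple[str, str]]) -> list[HomoeologPair]:
    """Retain anchor pairs on blocks between declared homoeologous chromosomes.

    Blocks between undeclared chromosome pairs are excluded.  Duplicate
    (gene_a, gene_b) pairs across blocks collapse to one homoeolog; a gene
    appearing with several distinct partners contributes each partner once.
    """
    if not chrom_pairs:
        raise SyntenyError("empty homoeologous chromosome pair list")
    declared = {frozenset(p) for p in chrom_pairs}
    orient = {}
    for a, b in chrom_pairs:
        orient[frozenset((a, b))] = (a, b)
    seen: dict[tuple[str, str], HomoeologPair] = {}
    for blk in blocks:
        key = frozenset((blk.chrom_a, blk.chrom_b))
        if key not in declared:
            continue
        ca, cb = orient[key]
        flip = (blk.chrom_a, blk.chrom_b) != (ca, cb)
        for anc in blk.anchors:
            ga, gb = (anc.gene_b, anc.gene_a) if flip else (anc.gene_a, anc.gene_b)
            pair_key = (ga, gb)
            if pair_key not in seen:
                seen[pair_key] = HomoeologPair(ga, gb, ca, cb, blk.block_id)
    return sorted(seen.values(), key=lambda p: (p.gene_a, p.gene_b))
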