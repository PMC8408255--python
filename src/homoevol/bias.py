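"""Homoeolog expression-bias testing and chromosome-level bias grouping.

The differential-expression contrast is *within pair*: counts of homoeolog A
vs homoeolog B over the same samples, so library composition largely cancels.
The test is a self-contained negative-binomial Wald test — median-of-ratios
size factors, method-of-moments dispersion with a floor, log2 fold change with
a 0.5 pseudocount — in the spirit of the standard NB DE machinery, but small
enough to reason about and to calibrate against the bundled generator.  An
external DE table (e.g. from DESeq2) can be imported instead via
:func:`de_results_from_table`.

Bias categories follow the four-way partition used for homoeolog pairs:
``no_difference`` (p > 0.05), and for p <= 0.05 ``lower`` (FC <= 2),
``medium`` (2 < FC < 8), ``higher`` (FC >= 8), with FC the linear max/min
fold change (>= 1).  No multiple-testing correction is applied by default,
mirroring raw-p thresholds; a Benjamini–Hochberg option exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .synteny import HomoeologPair

__all__ = [
    "CountMatrix",
    "DEResult",
    "ChromGroupResult",
    "compute_tpm",
    "flag_expressed",
    "high_confidence_pairs",
    "size_factors",
    "test_homoeolog_de",
    "classify_bias_category",
    "chi_square_gof",
    "chromosome_bias_grouping",
    "te_stratified_bias",
    "BIAS_CATEGORIES",
]

BIAS_CATEGORIES = ("no_difference", "lower", "medium", "higher")

Scope = Union[str, tuple[str, str]]  # "pooled", tissue, or (tissue, variety)


class BiasError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Integer RNA-seq counts (genes x samples) with design and gene lengths."""

    counts: pd.DataFrame
    design: pd.DataFrame  # index = sample, columns tissue/variety/replicate
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise BiasError("negative counts")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise BiasError(f"samples missing from design: {sorted(missing)[:5]}")
        if (self.gene_lengths.reindex(self.counts.index) <= 0).any():
            raise BiasError("gene lengths must be positive for every gene")

    def samples_in_scope(self, scope: Scope) -> list[str]:
        if scope == "pooled":
            return list(self.counts.columns)
        if isinstance(scope, tuple):
            tissue, variety = scope
            mask = (self.design["tissue"] == tissue) & (self.design["variety"] == variety)
        else:
            mask = self.design["tissue"] == scope
        return [s for s in self.counts.columns if s in self.design.index[mask]]


@dataclass
class DEResult:
    pair: HomoeologPair
    log2fc: float  # signed, log2(mean_b / mean_a)
    p_value: float
    higher_copy: str
    scope: Scope = "pooled"

    @property
    def fc(self) -> float:
        """Linear fold change max/min, always >= 1."""
        return 2.0 ** abs(self.log2fc)


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: rate = count/length, scaled to 1e6 per sample."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise BiasError("gene length missing for some genes")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])[:5]
        raise BiasError(f"zero total expression rate in sample(s) {bad}")
    return rate.div(totals, axis=1) * 1e6


def flag_expressed(tpm: pd.DataFrame, threshold: float = 0.5) -> set[str]:
    """Genes whose TPM exceeds ``threshold`` in at least one sample."""
    return set(tpm.index[(tpm > threshold).any(axis=1)])


def high_confidence_pairs(pairs: Iterable[HomoeologPair],
                          expressed: set[str]) -> list[HomoeologPair]:
    """Pairs whose members are both expressed (the high-confidence set)."""
    return [p for p in pairs if p.gene_a in expressed and p.gene_b in expressed]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = per-gene geometric mean)."""
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)
    usable = np.isfinite(log_ref) & log_counts.notna().all(axis=1)
    if not usable.any():
        raise BiasError("no gene with all-positive counts for size factor estimation")
    ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def _moment_dispersion(x: np.ndarray, floor: float = 1e-8) -> float:
    m = x.mean()
    if m <= 0:
        return floor
    v = x.var(ddof=1)
    return max((v - m) / m ** 2, floor)


def test_homoeolog_de(counts: CountMatrix, pair: HomoeologPair,
                      scope: Scope = "pooled",
                      sf: Optional[pd.Series] = None,
                      dispersion_floor: float = 1e-8) -> DEResult:
    """NB Wald test of homoeolog A vs homoeolog B over the samples in scope.

    Normalized means use a pseudocount of 0.5; the Wald z is
    log2FC / SE(log2FC) with the delta-method standard error under
    Var(X) = mu + alpha mu^2, and a two-sided normal p-value.
    """
    samples = counts.samples_in_scope(scope)
    if len(samples) < 2:
        raise BiasError(f"scope {scope!r} has {len(samples)} samples; need >= 2")
    if sf is None:
        sf = size_factors(counts.counts[samples])
    sf = sf.reindex(samples)
    xa = (counts.counts.loc[pair.gene_a, samples] / sf).to_numpy(float)
    xb = (counts.counts.loc[pair.gene_b, samples] / sf).to_numpy(float)
    alpha = max(
        (_moment_dispersion(xa, 0.0) + _moment_dispersion(xb, 0.0)) / 2.0,
        dispersion_floor,
    )
    sfv = sf.to_numpy(float)
    n = len(samples)
    ma, mb = xa.mean(), xb.mean()
    log2fc = math.log2((mb + 0.5) / (ma + 0.5))

    def _var_log2_mean(mu: float) -> float:
        # Var(mean of c_s/sf_s) for NB counts, then delta method onto log2.
        var_mean = float(np.sum(mu / sfv + alpha * mu ** 2)) / n ** 2
        return var_mean / (((mu + 0.5) ** 2) * math.log(2.0) ** 2)

    se = math.sqrt(_var_log2_mean(ma) + _var_log2_mean(mb))
    if se == 0.0:
        p = 1.0
    else:
        p = 2.0 * stats.norm.sf(abs(log2fc) / se)
    higher = pair.gene_b if log2fc > 0 else pair.gene_a
    return DEResult(pair=pair, log2fc=log2fc, p_value=min(p, 1.0),
                    higher_copy=higher, scope=scope)


def classify_bias_category(result: DEResult) -> str:
    """Four-way bias category from fold change and p-value.

    p > 0.05 -> no_difference; otherwise FC <= 2 -> lower, 2 < FC < 8 ->
    medium, FC >= 8 -> higher (boundary p = 0.05 counts as significant).
    """
    if result.p_value > 0.05:
        return "no_difference"
    fc = result.fc
    if fc <= 2.0:
        return "lower"
    if fc < 8.0:
        return "medium"
    return "higher"


def chi_square_gof(observed: Sequence[float],
                   expected: Sequence[float]) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit; expected given as counts or weights."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if (exp <= 0).any():
        raise BiasError("expected counts must be positive")
    exp = exp * obs.sum() / exp.sum()
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), len(obs) - 1, float(p)


def is_significant_twofold(res: DEResult, p_threshold: float = 0.05) -> bool:
    """The ">= 2-fold significantly differential" rule used for grouping."""
    return res.p_value <= p_threshold and res.fc >= 2.0


@dataclass
class ChromGroupResult:
    """Per-chromosome-pair bias grouping (SA/SB significant, SC/SD not)."""

    table: pd.DataFrame  # chrom_a, chrom_b, n_a, n_b, chi2, p, group_a, group_b
    groups: dict[str, str] = field(default_factory=dict)
    unclassifiable: list[tuple[str, str]] = field(default_factory=list)


def chromosome_bias_grouping(de_results: Sequence[DEResult],
                             chrom_pairs: Sequence[tuple[str, str]],
                             gene_chrom: dict[str, str]) -> ChromGroupResult:
    """Group chromosomes as SA/SB (significant bias) or SC/SD (no bias).

    For each declared pair, the significant >= 2-fold pairs are counted by the
    side hosting the higher-expressed copy; a chi-square test against a 50/50
    split at p < 0.05 assigns SA (majority) / SB (minority), otherwise SC/SD.
    A pair with zero significant genes is flagged unclassifiable.  Equal
    counts put SC on the lexicographically smaller chromosome.
    """
    rows = []
    groups: dict[str, str] = {}
    unclassifiable: list[tuple[str, str]] = []
    counts: dict[frozenset, dict[str, int]] = {
        frozenset(p): {p[0]: 0, p[1]: 0} for p in chrom_pairs
    }
    for res in de_results:
        if not is_significant_twofold(res):
            continue
        chrom = gene_chrom.get(res.higher_copy)
        key = frozenset((res.pair.chrom_a, res.pair.chrom_b))
        if key in counts and chrom in counts[key]:
            counts[key][chrom] += 1
    for ca, cb in chrom_pairs:
        na, nb = counts[frozenset((ca, cb))][ca], counts[frozenset((ca, cb))][cb]
        if na + nb == 0:
            unclassifiable.append((ca, cb))
            rows.append((ca, cb, 0, 0, np.nan, np.nan, "NA", "NA"))
            continue
        chi2, _, p = chi_square_gof([na, nb], [1, 1])
        if na > nb or (na == nb and ca < cb):
            major, minor, nmaj, nmin = ca, cb, na, nb
        else:
            major, minor, nmaj, nmin = cb, ca, nb, na
        if p < 0.05:
            gmaj, gmin = "SA", "SB"
        else:
            gmaj, gmin = "SC", "SD"
        groups[major], groups[minor] = gmaj, gmin
        rows.append((ca, cb, na, nb, chi2, p, groups[ca], groups[cb]))
    table = pd.DataFrame(
        rows, columns=["chrom_a", "chrom_b", "n_a", "n_b", "chi2", "p",
                       "group_a", "group_b"],
    )
    return ChromGroupResult(table=table, groups=groups, unclassifiable=unclassifiable)


def te_stratified_bias(grouping: ChromGroupResult,
                       de_results: Sequence[DEResult],
                       te_distances: dict[str, float],
                       gene_chrom: dict[str, str],
                       window: int = 2000) -> pd.DataFrame:
    """Stratify biased pairs by TE-within-``window`` status of each member.

    Each significant >= 2-fold pair on an SA/SB (or SC/SD) chromosome pair is
    assigned to one of four strata (e.g. ``SAyes_SBno``) by whether the SA-
    and SB-side genes have a TE strictly within ``window`` bp.  Within each
    stratum the higher copies are counted per side with a chi-square test
    against 50/50.  Pairs with a missing TE distance are excluded; the count
    of exclusions is reported in the ``n_missing`` attribute of the frame.
    """
    rows: dict[tuple[str, str], list[int]] = {}
    n_missing = 0
    for res in de_results:
        if not is_significant_twofold(res):
            continue
        ga, gb = res.pair.gene_a, res.pair.gene_b
        grp_a = grouping.groups.get(gene_chrom.get(ga, ""), None)
        grp_b = grouping.groups.get(gene_chrom.get(gb, ""), None)
        if grp_a is None or grp_b is None:
            continue
        # orient so that the first member is the SA (or SC) side
        if grp_a in ("SA", "SC"):
            dom_gene, rec_gene, dom_lab, rec_lab = ga, gb, grp_a, grp_b
        else:
            dom_gene, rec_gene, dom_lab, rec_lab = gb, ga, grp_b, grp_a
        d_dom = te_distances.get(dom_gene)
        d_rec = te_distances.get(rec_gene)
        if d_dom is None or d_rec is None or not np.isfinite([d_dom, d_rec]).all():
            n_missing += 1
            continue
        dom_yes = "yes" if d_dom < window else "no"
        rec_yes = "yes" if d_rec < window else "no"
        stratum = (f"{dom_lab}{dom_yes}_{rec_lab}{rec_yes}",
                   "significant" if dom_lab == "SA" else "nonsignificant")
        cell = rows.setdefault(stratum, [0, 0])
        if res.higher_copy == dom_gene:
            cell[0] += 1
        else:
            cell[1] += 1
    out = []
    for (stratum, kind), (n_dom, n_rec) in sorted(rows.items()):
        if n_dom + n_rec > 0:
            chi2, _, p = chi_square_gof([n_dom, n_rec], [1, 1])
        else:
            chi2, p = np.nan, np.nan
        out.append((stratum, kind, n_dom, n_rec, chi2, p))
    frame = pd.DataFrame(
        out, columns=["stratum", "pair_kind", "n_dominant_side",
                      "n_recessive_side", "chi2", "p"],
    )
    frame.attrs["n_missing"] = n_missing
    return frame


def de_results_from_table(table: pd.DataFrame,
                          pairs: Sequence[HomoeologPair],
                          scope: Scope = "pooled") -> list[DEResult]:
    """Adapt an external DE table (gene_a, gene_b, log2fc, p) to DEResults."""
    lookup = {(p.gene_a, p.gene_b): p for p in pairs}
    out = []
    for row in table.itertuples(index=False):
        pair = lookup.get((row.gene_a, row.gene_b))
        if pair is None:
            continue
        higher = pair.gene_b if row.log2fc > 0 else pair.gene_a
        out.append(DEResult(pair=pair, log2fc=float(row.log2fc),
                            p_value=float(row.p), higher_copy=higher, scope=scope))
    return out


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p thresholds are the default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out
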