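"""Spatiotemporal homoeolog dynamics: fold-change profiles, dynamic/stable
ranking, category transitions, expression width, and group comparisons.

A pair's fold-change profile holds its signed log2 fold change in every
tissue-by-variety scope plus the pooled analysis, with non-significant scopes
(p >= 0.05) zeroed — "no difference means FC = 0".  The change score is the
largest absolute difference between any single-scope fold change and the
pooled fold change; the top decile by change score are the *dynamic*
homoeologs, the bottom decile the *stable* ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bias import BIAS_CATEGORIES, DEResult

__all__ = [
    "FCProfile",
    "DynamicStableSets",
    "fc_profile",
    "rank_dynamic_stable",
    "category_transitions",
    "expression_width",
    "motif_overlap",
    "mann_whitney",
]


class DynamicsError(ValueError):
    pass


@dataclass
class FCProfile:
    pair_id: tuple[str, str]
    scopes: tuple
    log2fc: np.ndarray  # per scope, zeroed where p >= 0.05
    pooled_log2fc: float
    change_score: float


def _zeroed(res: DEResult) -> float:
    return 0.0 if res.p_value >= 0.05 else res.log2fc


def fc_profile(pair_id: tuple[str, str],
               per_scope_de: Mapping[object, DEResult],
               pooled_de: DEResult) -> FCProfile:
    """Signed per-scope log2FC vector (zeroed at p >= 0.05) and change score."""
    if pooled_de is None:
        raise DynamicsError(f"missing pooled DE result for pair {pair_id}")
    scopes = tuple(sorted(per_scope_de, key=str))
    vec = np.array([_zeroed(per_scope_de[s]) for s in scopes], dtype=float)
    pooled = _zeroed(pooled_de)
    if not np.isfinite(vec).all() or not np.isfinite(pooled):
        raise DynamicsError(f"non-finite fold change for pair {pair_id}")
    score = float(np.max(np.abs(vec - pooled))) if len(vec) else 0.0
    return FCProfile(pair_id=pair_id, scopes=scopes, log2fc=vec,
                     pooled_log2fc=pooled, change_score=score)


@dataclass
class DynamicStableSets:
    dynamic: list[tuple[str, str]]
    stable: list[tuple[str, str]]


def rank_dynamic_stable(profiles: Sequence[FCProfile],
                        quantile: float = 0.10) -> DynamicStableSets:
    """Top/bottom ``quantile`` of profiles by change score (ties by pair id).

    Dynamic pairs have the largest difference between single-tissue and pooled
    fold changes; stable pairs the smallest.  Both sets have exactly
    ``floor(quantile * n)`` members and are disjoint.
    """
    n = len(profiles)
    if n < 10:
        raise DynamicsError(f"need >= 10 profiles to take deciles, got {n}")
    k = int(np.floor(quantile * n))
    by_score = sorted(profiles, key=lambda p: (-p.change_score, p.pair_id))
    dynamic = [p.pair_id for p in by_score[:k]]
    by_score_asc = sorted(profiles, key=lambda p: (p.change_score, p.pair_id))
    taken = set(dynamic)
    stable = [p.pair_id for p in by_score_asc if p.pair_id not in taken][:k]
    return DynamicStableSets(dynamic=dynamic, stable=stable)


def category_transitions(per_tissue_categories: Mapping[object, Mapping[tuple, str]],
                         pooled_categories: Mapping[tuple, str]) -> dict:
    """Tabulate pooled-category -> tissue-category moves.

    Returns a dict with a 4x4 transition count DataFrame summed over scopes,
    per-scope matrices, and counts of adjacent (lower<->medium,
    medium<->higher) vs across (lower<->higher) shifts with percentages.
    """
    cats = list(BIAS_CATEGORIES)
    total = pd.DataFrame(0, index=cats, columns=cats)
    per_scope = {}
    adjacent = across = changed = 0
    adj_sets = {frozenset(("lower", "medium")), frozenset(("medium", "higher"))}
    n_pairs = len(pooled_categories)
    for scope, tiss_cats in per_tissue_categories.items():
        if set(tiss_cats) != set(pooled_categories):
            raise DynamicsError(f"scope {scope!r} covers a different pair set")
        mat = pd.DataFrame(0, index=cats, columns=cats)
        for pair, pooled_cat in pooled_categories.items():
            tcat = tiss_cats[pair]
            mat.loc[pooled_cat, tcat] += 1
        per_scope[scope] = mat
        total += mat
    # per-pair shift classification: a pair "changes" if any tissue category
    # differs from pooled; adjacent/across refer to the bias categories only.
    for pair, pooled_cat in pooled_categories.items():
        moves = {m[pair] for m in per_tissue_categories.values()}
        if moves - {pooled_cat}:
            changed += 1
        for tcat in moves:
            key = frozenset((pooled_cat, tcat))
            if key in adj_sets:
                adjacent += 1
                break
        for tcat in moves:
            if frozenset((pooled_cat, tcat)) == frozenset(("lower", "higher")):
                across += 1
                break
    return {
        "total": total,
        "per_scope": per_scope,
        "n_pairs": n_pairs,
        "changed": changed,
        "changed_pct": 100.0 * changed / n_pairs if n_pairs else 0.0,
        "adjacent_shifts": adjacent,
        "across_shifts": across,
    }


def expression_width(tpm: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Per-gene number of samples with TPM above ``threshold``."""
    return (tpm > threshold).sum(axis=1)


def motif_overlap(hits_a: set[str], hits_b: set[str]) -> tuple[int, int, int]:
    """(shared, specific to a, specific to b) motif counts for a promoter pair."""
    shared = hits_a & hits_b
    return len(shared), len(hits_a - shared), len(hits_b - shared)


def mann_whitney(values_a: Sequence[float],
                 values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when the combined sample size is <= 20 and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DynamicsError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (a.size + b.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)
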