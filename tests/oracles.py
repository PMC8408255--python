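"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by exhaustive enumeration or direct
formula evaluation, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

STOPS = set(standard_dna_table.stop_codons)
AA = dict(standard_dna_table.forward_table)
SENSE = sorted(AA)
BASES = "ACGT"


# --- NG86 ------------------------------------------------------------------

def ng86_codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) sites of one sense codon by enumeration."""
    syn_total = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:] for b in BASES if b != codon[pos]]
        alts = [a for a in alts if a not in STOPS]
        if alts:
            syn_total += sum(AA[a] == AA[codon] for a in alts) / len(alts)
    return syn_total, 3.0 - syn_total


def ng86_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over minimal stop-free pathways."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    clean, dirty = [], []
    for perm in itertools.permutations(positions):
        codons = [c1]
        for pos in perm:
            prev = codons[-1]
            codons.append(prev[:pos] + c2[pos] + prev[pos + 1:])
        through_stop = any(c in STOPS for c in codons[1:-1]) or codons[-1] in STOPS
        sd = nd = 0.0
        for x, y in zip(codons, codons[1:]):
            if x in STOPS or y in STOPS:
                nd += 1
            elif AA[x] == AA[y]:
                sd += 1
            else:
                nd += 1
        (dirty if through_stop else clean).append((sd, nd))
    chosen = clean or dirty
    return (sum(p[0] for p in chosen) / len(chosen),
            sum(p[1] for p in chosen) / len(chosen))


def ng86_kaks(cds_a: str, cds_b: str):
    """Full NG86 Ka/Ks on two gap-free, equal-length, stop-free CDSs."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if ca in STOPS or cb in STOPS:
            continue
        sa, na = ng86_codon_sites(ca)
        sb, nb = ng86_codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = ng86_pair_differences(ca, cb)
        Sd += ds
        Nd += dn

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(Nd / N) if N else None, jc(Sd / S) if S else None, S, N, Sd, Nd


# --- collinear chaining ----------------------------------------------------

def best_chain_oracle(anchors, max_gap: int, gap_penalty: float):
    """Best chain by longest-path DP on an explicit DAG (networkx).

    ``anchors`` is a list of (rank_a, rank_b) tuples.  Both orientations are
    searched; returns (score, chain as list of tuples, orientation).
    """
    import networkx as nx

    best = (-math.inf, [], "same")
    for orient, sign in (("same", 1), ("inverted", -1)):
        g = nx.DiGraph()
        g.add_node("S")
        g.add_node("T")
        for i, (ra, rb) in enumerate(anchors):
            g.add_edge("S", i, weight=1.0)
            g.add_edge(i, "T", weight=0.0)
        for i, (ra, rb) in enumerate(anchors):
            for j, (rc, rd) in enumerate(anchors):
                da, db = rc - ra, sign * (rd - rb)
                if da > 0 and db > 0 and da - 1 <= max_gap and db - 1 <= max_gap:
                    g.add_edge(i, j, weight=1.0 - gap_penalty * ((da - 1) + (db - 1)))
        path = nx.dag_longest_path(g, weight="weight")
        score = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        chain = [anchors[i] for i in path if i not in ("S", "T")]
        if score > best[0] + 1e-12:
            best = (score, chain, orient)
        elif abs(score - best[0]) <= 1e-12 and chain and best[1] \
                and chain[0][0] < best[1][0][0]:
            best = (score, chain, orient)
    return best


# --- set / interval brute force -------------------------------------------

def brute_nearest_distance(gene, tes):
    """Min gap between a (start, end) gene and a list of TE intervals."""
    best = None
    for (s, e) in tes:
        if s < gene[1] and e > gene[0]:
            d = 0
        elif e <= gene[0]:
            d = gene[0] - e
        else:
            d = s - gene[1]
        best = d if best is None else min(best, d)
    return best


def brute_overlap_count(region, tes):
    return sum(1 for (s, e) in tes if s < region[1] and e > region[0])


# --- TOM -------------------------------------------------------------------

def tom_oracle(adjacency: np.ndarray) -> np.ndarray:
    """Direct double-loop evaluation of the unsigned TOM formula."""
    n = adjacency.shape[0]
    k = adjacency.sum(axis=1)
    tom = np.zeros_like(adjacency)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l = sum(adjacency[i, u] * adjacency[u, j] for u in range(n))
            tom[i, j] = (l + adjacency[i, j]) / (min(k[i], k[j]) + 1 - adjacency[i, j])
    return tom


# --- LTR cluster closure ---------------------------------------------------

def closure_partition(n: int, qualifies) -> list[set]:
    """Transitive closure over an explicit full qualification matrix."""
    adj = [[i != j and qualifies(i, j) for j in range(n)] for i in range(n)]
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        comp = {i}
        frontier = [i]
        seen[i] = True
        while frontier:
            u = frontier.pop()
            for v in range(n):
                if not seen[v] and adj[u][v]:
                    seen[v] = True
                    comp.add(v)
                    frontier.append(v)
        comps.append(comp)
    return comps
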