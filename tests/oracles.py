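"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives its quantity from first principles through a
different mechanism than the package (explicit enumeration, Biopython
translation, graph search), so agreement is informative.
"""

import math
from itertools import combinations, permutations

import networkx as nx
from Bio.Seq import Seq

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_ng86(seq1: str, seq2: str):
    """(Ka, Ks) by literal per-codon pathway enumeration and Biopython
    translation; returns (ka, ks, n_sites, s_sites, nd, sd)."""
    codons1 = [seq1[i : i + 3] for i in range(0, len(seq1), 3)]
    codons2 = [seq2[i : i + 3] for i in range(0, len(seq2), 3)]

    def syn_count(codon):
        n = 0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt not in _STOPS and _translate(alt) == _translate(codon):
                    n += 1
        return n / 3.0

    s_sites = sum((syn_count(a) + syn_count(b)) / 2.0 for a, b in zip(codons1, codons2))
    n_sites = 3.0 * len(codons1) - s_sites

    sd = nd = 0.0
    for a, b in zip(codons1, codons2):
        if a == b:
            continue
        diffs = [i for i in range(3) if a[i] != b[i]]
        paths = []
        for order in permutations(diffs):
            cur, s, n, ok = a, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if nxt in _STOPS:
                    ok = False
                    break
                if _translate(nxt) == _translate(cur):
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                paths.append((s, n))
        if not paths:
            for order in permutations(diffs):
                cur, s, n = a, 0, 0
                for pos in order:
                    nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                    if nxt not in _STOPS and _translate(nxt) == _translate(cur):
                        s += 1
                    else:
                        n += 1
                    cur = nxt
                paths.append((s, n))
        sd += sum(p[0] for p in paths) / len(paths)
        nd += sum(p[1] for p in paths) / len(paths)

    def jc(p):
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ks = jc(sd / s_sites) if s_sites else 0.0
    ka = jc(nd / n_sites) if n_sites else 0.0
    return ka, ks, n_sites, s_sites, nd, sd


def oracle_classify(catalog, pairs, blocks, proximal_max_gap=10):
    """Duplication-mode rules re-stated as a label-priority scan."""
    anchored = set()
    for blk in blocks:
        for a, b in blk.anchors:
            anchored.update((a, b))
    priority = ["WGD", "TD", "PD", "TRD", "DSD"]
    pair_modes = {}
    for p in pairs:
        a, b = p[0], p[1]
        labels = set()
        if a in anchored and b in anchored:
            labels.add("WGD")
        same = catalog.chrom_of(a) == catalog.chrom_of(b)
        gap = abs(catalog.rank_of(a) - catalog.rank_of(b)) if same else None
        if same and gap == 1:
            labels.add("TD")
        if same and gap is not None and 1 < gap < proximal_max_gap:
            labels.add("PD")
        if (a in anchored) != (b in anchored):
            labels.add("TRD")
        labels.add("DSD")
        pair_modes[(a, b)] = next(m for m in priority if m in labels)
    gene_modes = {}
    for (a, b), m in pair_modes.items():
        for g in (a, b):
            if g not in gene_modes or priority.index(m) < priority.index(gene_modes[g]):
                gene_modes[g] = m
    return pair_modes, gene_modes


def oracle_chain_blocks(anchors_ranks, min_anchors=5, max_rank_gap=25):
    """Greedy longest-chain peeling via longest path in an explicit DAG.

    ``anchors_ranks`` is a list of (rank_a, rank_b); returns the list of
    block sizes found (the quantity compared against the implementation).
    """
    avail = sorted(set(anchors_ranks))
    sizes = []
    while len(avail) >= min_anchors:
        best = []
        for sign in (+1, -1):
            g = nx.DiGraph()
            g.add_nodes_from(range(len(avail)))
            for i, (ra1, rb1) in enumerate(avail):
                for j, (ra2, rb2) in enumerate(avail):
                    if (
                        0 < ra2 - ra1 <= max_rank_gap
                        and 0 < sign * (rb2 - rb1) <= max_rank_gap
                    ):
                        g.add_edge(i, j)
            path = nx.dag_longest_path(g)
            if len(path) > len(best):
                best = path
        if len(best) < min_anchors:
            break
        sizes.append(len(best))
        used = set(best)
        avail = [a for i, a in enumerate(avail) if i not in used]
    return sizes


def oracle_bh(pvalues):
    """Classic step-up adjustment written longhand."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def oracle_hypergeom_upper(N, K, n, k):
    """P(X >= k) by literal enumeration of all C(N, n) draws."""
    population = list(range(N))
    marked = set(range(K))
    total = hits = 0
    for draw in combinations(population, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def oracle_pwm_hits(seq, pwm, threshold, pseudocount=0.01):
    """Window-by-window rescoring on both strands, longhand."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    w = pwm.width
    counts = pwm.counts + pseudocount
    probs = counts / counts.sum(axis=0)
    lo = {
        b: [math.log2(probs[i, j] / 0.25) for j in range(w)]
        for i, b in enumerate("ACGT")
    }
    max_score = sum(max(lo[b][j] for b in "ACGT") for j in range(w))
    cut = threshold * max_score
    rc = "".join(comp[b] for b in reversed(seq))
    hits = []
    for strand, s in (("+", seq), ("-", rc)):
        for pos in range(len(s) - w + 1):
            score = sum(lo[s[pos + j]][j] for j in range(w))
            if score >= cut:
                off = pos if strand == "+" else len(seq) - w - pos
                hits.append((off, strand))
    return sorted(hits)
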