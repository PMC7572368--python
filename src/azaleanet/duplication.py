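"""Classification of duplicated genes into WGD/TD/PD/TRD/DSD.

The five modes follow the standard gene-duplication taxonomy: whole-genome
duplicates sit inside collinear (synteny) blocks; tandem duplicates are
adjacent homologs on one chromosome; proximal duplicates are separated by
fewer than ``proximal_max_gap`` genes; transposed duplicates pair an
ancestral (block-anchored) locus with a novel one; everything else is
dispersed. Modes are assigned with priority WGD > TD > PD > TRD > DSD, and a
gene in several pairs takes the highest-priority mode among them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

from .catalog import GeneCatalog

MODES = ("WGD", "TD", "PD", "TRD", "DSD")
_PRIORITY = {m: i for i, m in enumerate(MODES)}


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Synteny block chaining
# ---------------------------------------------------------------------------

@dataclass
class SyntenyBlock:
    block_id: int
    anchors: list  # ordered (gene_a, gene_b) pairs
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"

    def genes(self) -> set:
        out = set()
        for a, b in self.anchors:
            out.add(a)
            out.add(b)
        return out


def _orient_pair(pair, catalog: GeneCatalog):
    """Canonical anchor orientation: side a is the smaller chromosome id, or
    the smaller rank for intra-chromosomal pairs."""
    a, b = pair[0], pair[1]
    ca, cb = catalog.chrom_of(a), catalog.chrom_of(b)
    if (cb, catalog.rank_of(b)) < (ca, catalog.rank_of(a)):
        a, b, ca, cb = b, a, cb, ca
    return a, b, ca, cb


def _longest_chain(anchors, ranks_a, ranks_b, max_rank_gap, sign):
    """Longest strictly-monotone chain (rank_a increasing, rank_b increasing
    for sign=+1 / decreasing for sign=-1) with per-step gaps <= max_rank_gap
    on both sides. Deterministic: ties prefer the smaller anchor index."""
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    order = sorted(range(n), key=lambda i: (ranks_a[i], ranks_b[i]))
    for ii, i in enumerate(order):
        for j in order[:ii]:
            if ranks_a[j] >= ranks_a[i]:
                continue
            if ranks_a[i] - ranks_a[j] > max_rank_gap:
                continue
            step_b = sign * (ranks_b[i] - ranks_b[j])
            if step_b <= 0 or step_b > max_rank_gap:
                continue
            if best_len[j] + 1 > best_len[i] or (
                best_len[j] + 1 == best_len[i] and prev[i] != -1 and j < prev[i]
            ):
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(
        range(n), key=lambda i: (best_len[i], -ranks_a[i], -ranks_b[i])
    )
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_synteny(
    pairs,
    catalog: GeneCatalog,
    min_anchors: int = 5,
    max_rank_gap: int = 25,
) -> list[SyntenyBlock]:
    """Chain homolog pairs into collinear blocks by longest-chain DP.

    Anchor candidates are grouped by (chromosome a, chromosome b); within a
    group, blocks are peeled greedily: the longest admissible chain (either
    orientation) is emitted and its anchors removed, until no chain reaches
    ``min_anchors``. Each homolog pair is used in at most one block.
    """
    for p in pairs:
        catalog.require(p[:2])
    groups: dict[tuple, list] = defaultdict(list)
    for p in pairs:
        a, b, ca, cb = _orient_pair(p, catalog)
        groups[(ca, cb)].append((a, b))
    blocks: list[SyntenyBlock] = []
    bid = 0
    for key in sorted(groups):
        ca, cb = key
        avail = sorted(
            set(groups[key]),
            key=lambda ab: (catalog.rank_of(ab[0]), catalog.rank_of(ab[1])),
        )
        while len(avail) >= min_anchors:
            ranks_a = [catalog.rank_of(a) for a, _ in avail]
            ranks_b = [catalog.rank_of(b) for _, b in avail]
            cand = []
            for sign in (+1, -1):
                chain = _longest_chain(avail, ranks_a, ranks_b, max_rank_gap, sign)
                cand.append((len(chain), sign, chain))
            # longest wins; ties prefer same orientation then smaller start
            cand.sort(key=lambda c: (-c[0], -c[1], [avail[i] for i in c[2]]))
            length, sign, chain = cand[0]
            if length < min_anchors:
                break
            anchors = [avail[i] for i in chain]
            blocks.append(
                SyntenyBlock(
                    block_id=bid,
                    anchors=anchors,
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation="same" if sign == 1 else "inverted",
                )
            )
            bid += 1
            used = set(chain)
            avail = [ab for i, ab in enumerate(avail) if i not in used]
    return blocks


# ---------------------------------------------------------------------------
# Mode classification
# ---------------------------------------------------------------------------

@dataclass
class DuplicationAssignment:
    pair_modes: dict  # (gene_a, gene_b) -> mode
    gene_modes: dict  # gene -> mode (highest priority among its pairs)
    witness: dict = field(default_factory=dict)  # gene -> partner of witness pair

    def genes_in_modes(self, modes) -> set:
        wanted = set(modes)
        return {g for g, m in self.gene_modes.items() if m in wanted}

    def mode_counts(self) -> dict:
        counts = {m: 0 for m in MODES}
        for m in self.gene_modes.values():
            counts[m] += 1
        return counts


def classify_duplicates(
    catalog: GeneCatalog,
    pairs,
    blocks,
    proximal_max_gap: int = 10,
) -> DuplicationAssignment:
    """Assign each homolog pair, then each duplicated gene, a mode.

    Pair rules (checked in priority order):
      WGD  both members anchored in some synteny block;
      TD   same chromosome, adjacent ranks;
      PD   same chromosome, 1 < rank gap < ``proximal_max_gap``;
      TRD  exactly one member anchored (ancestral locus);
      DSD  everything else.
    """
    anchored: set = set()
    for blk in blocks:
        anchored |= blk.genes()
    pair_modes = {}
    for p in pairs:
        a, b = p[0], p[1]
        catalog.require((a, b))
        n_anch = (a in anchored) + (b in anchored)
        if n_anch == 2:
            mode = "WGD"
        elif catalog.chrom_of(a) == catalog.chrom_of(b):
            gap = abs(catalog.rank_of(a) - catalog.rank_of(b))
            if gap == 1:
                mode = "TD"
            elif gap < proximal_max_gap:
                mode = "PD"
            elif n_anch == 1:
                mode = "TRD"
            else:
                mode = "DSD"
        elif n_anch == 1:
            mode = "TRD"
        else:
            mode = "DSD"
        pair_modes[(a, b)] = mode

    gene_modes: dict = {}
    witness: dict = {}
    for (a, b), mode in sorted(
        pair_modes.items(), key=lambda kv: (_PRIORITY[kv[1]], kv[0])
    ):
        for g, partner in ((a, b), (b, a)):
            if g not in gene_modes or _PRIORITY[mode] < _PRIORITY[gene_modes[g]]:
                gene_modes[g] = mode
                witness[g] = partner
    return DuplicationAssignment(pair_modes, gene_modes, witness)


# ---------------------------------------------------------------------------
# Proportion statistics
# ---------------------------------------------------------------------------

def mode_proportions(assignment: DuplicationAssignment, total_genes: int) -> dict:
    """Per-mode duplicated-gene counts and percentages of ``total_genes``
    (one decimal, half-up)."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    counts = assignment.mode_counts()
    n_dup = sum(counts.values())
    if total_genes < n_dup:
        raise ValueError(
            f"total_genes ({total_genes}) smaller than duplicated genes ({n_dup})"
        )
    return {
        m: {
            "count": counts[m],
            "percent": round_half_up(100.0 * counts[m] / total_genes, 1),
        }
        for m in MODES
    }


def set_td_pd_fraction(assignment: DuplicationAssignment, gene_set) -> tuple:
    """(count in TD∪PD, set size, percentage to two decimals)."""
    genes = set(gene_set)
    if not genes:
        raise ValueError("gene set is empty")
    tdpd = assignment.genes_in_modes(("TD", "PD"))
    k = len(genes & tdpd)
    return k, len(genes), round_half_up(100.0 * k / len(genes), 2)


def egf_mode_overlap(egf_genes, assignment: DuplicationAssignment) -> dict:
    """Venn-style intersections of an expanded-gene-family set with each mode,
    plus the share of the set that arose by small-scale TD/PD duplication."""
    egf = set(egf_genes)
    out = {m: len(egf & assignment.genes_in_modes((m,))) for m in MODES}
    out["EGF"] = len(egf)
    out["TD_PD_share_percent"] = (
        round_half_up(
            100.0 * len(egf & assignment.genes_in_modes(("TD", "PD"))) / len(egf), 2
        )
        if egf
        else 0.0
    )
    return out
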