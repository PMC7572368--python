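"""Hierarchical regulator inference with promoter binding-site evidence.

From a leveled co-expression network: extract pathway sub-networks, list
potential direct TF regulators of enzyme genes (time-ordered: a regulator's
level may not exceed its target's), enumerate first- to third-order
regulator chains, scan 2-kb promoters with family position weight matrices,
and keep only chains whose direct link is supported by a binding site of
the right family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Count-based binding motif of a TF family (rows A, C, G, T)."""

    motif_id: str
    family: str
    counts: np.ndarray  # shape (4, w)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError("PWM must be 4 x w with w >= 4")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("PWM has an all-zero column")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def log_odds(self, pseudocount: float = 0.01) -> np.ndarray:
        c = self.counts + pseudocount
        probs = c / c.sum(axis=0, keepdims=True)
        return np.log2(probs / self.background[:, None])

    def max_score(self, pseudocount: float = 0.01) -> float:
        return float(self.log_odds(pseudocount).max(axis=0).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


def write_jaspar(pwms, path) -> None:
    """JASPAR-like 4-row count format: >id family, then A/C/G/T rows."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.family}\n")
            for base, row in zip("ACGT", p.counts):
                cells = " ".join(f"{int(v)}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")


def read_jaspar(path) -> list[PWM]:
    pwms = []
    with open(path) as fh:
        header, rows = None, []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    pwms.append(_pwm_from_rows(header, rows))
                header, rows = line[1:], []
            else:
                rows.append(line)
        if header is not None:
            pwms.append(_pwm_from_rows(header, rows))
    return pwms


def _pwm_from_rows(header: str, rows: list[str]) -> PWM:
    parts = header.split()
    motif_id = parts[0]
    family = parts[1] if len(parts) > 1 else motif_id
    counts = {}
    for row in rows:
        base = row[0]
        nums = row[row.index("[") + 1 : row.index("]")].split()
        counts[base] = [float(x) for x in nums]
    return PWM(motif_id, family, np.array([counts[b] for b in "ACGT"]))


# ---------------------------------------------------------------------------
# Promoter scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    gene_id: str
    motif_id: str
    family: str
    offset: int  # 0-based from promoter start, forward coordinates
    strand: str  # "+" | "-"
    score: float


def _strand_scores(seq: str, lo: np.ndarray) -> np.ndarray:
    idx = np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.intp, count=len(seq))
    w = lo.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return lo[windows, np.arange(w)].sum(axis=1)


def pwm_scan(
    promoter: str,
    pwm: PWM,
    threshold: float = 0.85,
    gene_id: str = "",
    pseudocount: float = 0.01,
) -> list[MotifHit]:
    """All sites scoring >= ``threshold`` × the maximal achievable log-odds
    score, on both strands; offsets are forward-strand coordinates of the
    window start. A promoter shorter than the motif yields no hits."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    promoter = promoter.upper()
    if set(promoter) - set("ACGT"):
        raise ValueError("promoter contains characters outside ACGT")
    w = pwm.width
    if len(promoter) < w:
        return []
    lo = pwm.log_odds(pseudocount)
    cut = threshold * pwm.max_score(pseudocount)
    hits = []
    fwd = _strand_scores(promoter, lo)
    for pos in np.nonzero(fwd >= cut)[0]:
        hits.append(MotifHit(gene_id, pwm.motif_id, pwm.family, int(pos), "+", float(fwd[pos])))
    rev = _strand_scores(revcomp(promoter), lo)
    L = len(promoter)
    for pos in np.nonzero(rev >= cut)[0]:
        hits.append(
            MotifHit(gene_id, pwm.motif_id, pwm.family, int(L - w - pos), "-", float(rev[pos]))
        )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(promoters: dict, pwms, threshold: float = 0.85) -> list[MotifHit]:
    """Scan every promoter with every PWM."""
    hits = []
    for gene in sorted(promoters):
        for pwm in pwms:
            hits.extend(pwm_scan(promoters[gene], pwm, threshold, gene_id=gene))
    return hits


# ---------------------------------------------------------------------------
# Direct regulators and hierarchical chains
# ---------------------------------------------------------------------------

@dataclass
class DirectRegulators:
    target: str
    activators: list  # (tf, r), r descending — time-order-admissible positives
    repressors: list  # (tf, r), negative-edge TFs reported separately


def direct_regulators(gcn, levels, target: str) -> DirectRegulators:
    """TFs positively linked to ``target`` with level(TF) <= level(target).

    Negative-edge TFs are excluded from the activator list and reported as
    potential repressors (same level rule).
    """
    lvl = levels.level_by_node.get(target)
    if lvl is None:
        raise ValueError(f"target {target!r} has no assigned level")
    acts, reps = [], []
    for a, b, r, s in gcn.edges_of(target).itertuples(index=False):
        tf = b if a == target else a
        if tf not in gcn.tf_nodes:
            continue
        tf_lvl = levels.level_by_node.get(tf)
        if tf_lvl is None or tf_lvl > lvl:
            continue
        (acts if s == "+" else reps).append((tf, float(r)))
    acts.sort(key=lambda x: (-x[1], x[0]))
    reps.sort(key=lambda x: (x[1], x[0]))
    return DirectRegulators(target, acts, reps)


@dataclass
class RegulatorChain:
    tfs: tuple  # most upstream first; tfs[-1] is the direct regulator
    target: str
    corr_product: float
    supported: bool | None = None
    demoted: bool = False
    unknown_family: bool = False

    @property
    def order(self) -> int:
        return len(self.tfs)

    @property
    def direct(self) -> str:
        return self.tfs[-1]


def regulator_chains(gcn, levels, target: str, max_order: int = 3) -> list:
    """Simple positive-edge paths TF_k → … → TF_1 → target with levels
    non-decreasing toward the target and length <= ``max_order``.

    Ordering is deterministic: by level of the most-upstream TF, then by
    correlation product (descending), then lexicographically.
    """
    regs = direct_regulators(gcn, levels, target)
    pos = gcn.positive_edge_lookup()
    lvl = levels.level_by_node
    chains: list[RegulatorChain] = []

    def extend(path: list, product: float) -> None:
        # path is direct-regulator-first; emit reversed (upstream first)
        chains.append(RegulatorChain(tuple(reversed(path)), target, product))
        if len(path) >= max_order:
            return
        head = path[-1]
        ups = []
        for key, r in pos.items():
            if head not in key:
                continue
            (other,) = key - {head}
            if (
                other in gcn.tf_nodes
                and other not in path
                and lvl.get(other) is not None
                and lvl[other] <= lvl[head]
            ):
                ups.append((other, r))
        for other, r in sorted(ups):
            extend(path + [other], product * abs(r))

    for tf, r in regs.activators:
        extend([tf], abs(r))
    chains.sort(key=lambda c: (lvl[c.tfs[0]], -c.corr_product, c.tfs))
    return chains


def filter_chains_by_binding(chains, hits, family_of: dict) -> list:
    """Flag chains whose direct link has promoter binding support.

    A chain is supported iff its target's promoter holds >= 1 hit whose PWM
    family matches the direct regulator's family. When a target has at least
    one supported chain, its unsupported chains are demoted (flagged, not
    dropped). TFs without a family label are flagged unknown-family and never
    supported.
    """
    by_gene: dict = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, set()).add(h.family)
    for c in chains:
        fam = family_of.get(c.direct)
        if fam is None:
            c.unknown_family = True
            c.supported = False
        else:
            c.supported = fam in by_gene.get(c.target, set())
    supported_targets = {c.target for c in chains if c.supported}
    for c in chains:
        c.demoted = (not c.supported) and c.target in supported_targets
    return chains


# ---------------------------------------------------------------------------
# Pathway sub-networks
# ---------------------------------------------------------------------------

@dataclass
class PathwaySubnetwork:
    stage_group: str
    enzyme_genes: list
    tfs: list
    edges: pd.DataFrame
    family_tally: dict


def pathway_subnetwork(
    gcn, levels, pathway_genes, stage_group: str, family_of: dict | None = None
) -> PathwaySubnetwork:
    """Induced sub-network of pathway enzyme genes whose level maps to
    ``stage_group``, with every TF sharing an edge with them and a tally of
    those TFs' families."""
    in_group = sorted(
        g
        for g in set(pathway_genes)
        if levels.level_by_node.get(g) is not None
        and levels.level_to_group.get(levels.level_by_node[g]) == stage_group
    )
    enzyme_set = set(in_group)
    mask = gcn.edges["gene_a"].isin(enzyme_set) | gcn.edges["gene_b"].isin(enzyme_set)
    edges = gcn.edges[mask].reset_index(drop=True)
    tfs = sorted(
        {
            tf
            for a, b, r, s in edges.itertuples(index=False)
            for tf in (a, b)
            if tf in gcn.tf_nodes
        }
    )
    tally: dict = {}
    if family_of:
        for tf in tfs:
            fam = family_of.get(tf)
            if fam:
                tally[fam] = tally.get(fam, 0) + 1
    return PathwaySubnetwork(stage_group, in_group, tfs, edges, tally)
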