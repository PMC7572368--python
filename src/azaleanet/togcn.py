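"""Time-ordered gene co-expression network (TO-GCN) construction.

From a stage × replicate TPM matrix: filter weakly expressed genes, gate on
differential expression between stages, build a signed Pearson network
between TFs and genes at the 0.81 / -0.57 cutoffs, pick a seed TF expressed
only at the first time point, assign time-order levels L1..L8 by
breadth-first expansion over positive TF-TF edges, and map levels back to
developmental stages (initial / transitional / terminal).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_adjust

logger = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(r"^T(\d+)_R(\d+)$")


@dataclass
class TimeCourseMatrix:
    """Genes × samples TPM matrix with a stage/replicate design.

    Sample names encode the design as ``T{stage}_R{replicate}``.
    """

    values: pd.DataFrame
    tf_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        self.stage_of = {}
        for col in self.values.columns:
            m = _SAMPLE_RE.match(col)
            if not m:
                raise ValueError(f"sample name {col!r} not of the form T<i>_R<j>")
            self.stage_of[col] = int(m.group(1))

    @property
    def stages(self) -> list[int]:
        return sorted(set(self.stage_of.values()))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def replicate_columns(self, stage: int) -> list[str]:
        return [c for c in self.values.columns if self.stage_of[c] == stage]

    def stage_means(self) -> pd.DataFrame:
        cols = {t: self.replicate_columns(t) for t in self.stages}
        return pd.DataFrame(
            {t: self.values[cc].mean(axis=1) for t, cc in cols.items()}
        )

    def subset(self, gene_ids) -> "TimeCourseMatrix":
        keep = [g for g in self.values.index if g in set(gene_ids)]
        return TimeCourseMatrix(self.values.loc[keep], self.tf_flags & set(keep))

    def to_tsv(self, path) -> None:
        self.values.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, tf_flags=()) -> "TimeCourseMatrix":
        v = pd.read_csv(path, sep="\t", index_col=0)
        return cls(v, set(tf_flags))


def filter_expressed(
    matrix: TimeCourseMatrix, min_avg_tpm: float = 0.5
) -> TimeCourseMatrix:
    """Drop genes whose all-sample mean TPM is below ``min_avg_tpm``
    (boundary kept)."""
    means = matrix.values.mean(axis=1)
    keep = means[means >= min_avg_tpm].index
    removed = len(matrix.values) - len(keep)
    logger.info("expression filter removed %d genes (mean TPM < %g)", removed, min_avg_tpm)
    if len(keep) == 0:
        logger.warning("expression filter removed every gene")
    return TimeCourseMatrix(matrix.values.loc[keep], matrix.tf_flags & set(keep))


def differential_genes(
    matrix: TimeCourseMatrix, fdr: float = 0.05, min_abs_log2fc: float = 1.0
) -> set:
    """Genes differentially expressed between any two stages.

    Welch t-tests on log2(TPM+1) per stage pair, Benjamini–Hochberg
    corrected jointly across genes × stage-pairs; a gene passes if any pair
    reaches adjusted p <= ``fdr`` with |mean log2 fold change| >=
    ``min_abs_log2fc``.
    """
    stages = matrix.stages
    for t in stages:
        if len(matrix.replicate_columns(t)) < 2:
            raise ValueError(f"stage T{t} has fewer than 2 replicates")
    logv = np.log2(matrix.values.values + 1.0)
    cols = {t: [matrix.values.columns.get_loc(c) for c in matrix.replicate_columns(t)]
            for t in stages}
    pvals, fcs = [], []
    for t1, t2 in combinations(stages, 2):
        a, b = logv[:, cols[t1]], logv[:, cols[t2]]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        diff = a.mean(axis=1) - b.mean(axis=1)
        # zero-variance groups: identical means are null, distinct are certain
        degenerate = ~np.isfinite(p)
        p[degenerate & (np.abs(diff) > 0)] = 0.0
        p[degenerate & (np.abs(diff) == 0)] = 1.0
        pvals.append(p)
        fcs.append(diff)
    P = np.column_stack(pvals)
    FC = np.column_stack(fcs)
    adj = np.asarray(bh_adjust(P.ravel())).reshape(P.shape)
    hit = ((adj <= fdr) & (np.abs(FC) >= min_abs_log2fc)).any(axis=1)
    return set(np.asarray(matrix.gene_ids)[hit])


# ---------------------------------------------------------------------------
# Signed correlation network
# ---------------------------------------------------------------------------

@dataclass
class SignedGCN:
    edges: pd.DataFrame  # gene_a, gene_b, r, sign
    tf_nodes: set
    gene_nodes: set
    pos_cutoff: float
    neg_cutoff: float

    def positive_tf_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.tf_nodes)
        sub = self.edges[(self.edges["sign"] == "+")]
        for a, b, r in sub[["gene_a", "gene_b", "r"]].itertuples(index=False):
            if a in self.tf_nodes and b in self.tf_nodes:
                g.add_edge(a, b, r=r)
        return g

    def edges_of(self, node: str, sign: str | None = None) -> pd.DataFrame:
        sub = self.edges[(self.edges["gene_a"] == node) | (self.edges["gene_b"] == node)]
        if sign is not None:
            sub = sub[sub["sign"] == sign]
        return sub

    def positive_edge_lookup(self) -> dict:
        return {
            frozenset((a, b)): r
            for a, b, r, s in self.edges.itertuples(index=False)
            if s == "+"
        }


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[~np.isfinite(z)] = np.nan
    return z


def pearson_network(
    matrix: TimeCourseMatrix,
    tf_set,
    gene_set,
    pos_cutoff: float = 0.81,
    neg_cutoff: float = -0.57,
    stage_means: bool = False,
) -> SignedGCN:
    """Signed TF–gene / TF–TF Pearson network.

    Correlations run across all stage × replicate samples by default
    (``stage_means=True`` collapses replicates first). Edges are stored when
    r >= ``pos_cutoff`` or r <= ``neg_cutoff``; gene–gene edges are not
    formed; constant profiles yield no edges.
    """
    if not neg_cutoff < 0 < pos_cutoff:
        raise ValueError("cutoffs must satisfy neg < 0 < pos")
    tfs = sorted(set(tf_set) & set(matrix.gene_ids))
    genes = sorted((set(gene_set) - set(tfs)) & set(matrix.gene_ids))
    nodes = tfs + genes
    data = matrix.stage_means() if stage_means else matrix.values
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    X = _standardize_rows(data.loc[nodes].values.astype(float))
    n = X.shape[1]
    tf_idx = np.arange(len(tfs))
    R = (X[tf_idx] @ X.T) / n  # TF rows vs all nodes
    rows = []
    for i, tf in enumerate(tfs):
        for j in range(i + 1, len(nodes)):  # j > i: each TF-TF once, plus TF-gene
            r = R[i, j]
            if not np.isfinite(r):
                continue
            if r >= pos_cutoff:
                rows.append((tf, nodes[j], float(r), "+"))
            elif r <= neg_cutoff:
                rows.append((tf, nodes[j], float(r), "-"))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign"])
    return SignedGCN(
        edges=edges,
        tf_nodes=set(tfs),
        gene_nodes=set(genes),
        pos_cutoff=pos_cutoff,
        neg_cutoff=neg_cutoff,
    )


def suggest_cutoffs(
    matrix: TimeCourseMatrix,
    tf_set,
    gene_set,
    n_permutations: int = 1000,
    target_edge_fdr: float = 0.01,
    seed: int = 0,
    pos_grid=None,
    neg_grid=None,
) -> tuple[float, float]:
    """Permutation-calibrated correlation cutoffs.

    For each candidate cutoff the edge FDR is estimated as the mean edge
    count over sample-permuted matrices divided by the real edge count; the
    smallest-magnitude cutoffs with FDR <= ``target_edge_fdr`` are returned.
    Falls back to (0.81, -0.57) with a warning when no candidate qualifies.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    if pos_grid is None:
        pos_grid = np.round(np.arange(0.50, 0.96, 0.01), 2)
    if neg_grid is None:
        neg_grid = np.round(np.arange(-0.30, -0.96, -0.01), 2)
    rng = np.random.default_rng(seed)
    tfs = sorted(set(tf_set) & set(matrix.gene_ids))
    genes = sorted((set(gene_set) - set(tfs)) & set(matrix.gene_ids))
    nodes = tfs + genes
    raw = matrix.values.loc[nodes].values.astype(float)
    n = raw.shape[1]

    def edge_counts(x):
        z = _standardize_rows(x)
        R = (z[: len(tfs)] @ z.T) / n
        iu = np.triu_indices(len(tfs), k=1)
        vals = np.concatenate([R[iu], R[:, len(tfs):].ravel()])
        vals = vals[np.isfinite(vals)]
        pos = np.array([(vals >= c).sum() for c in pos_grid], dtype=float)
        neg = np.array([(vals <= c).sum() for c in neg_grid], dtype=float)
        return pos, neg

    real_pos, real_neg = edge_counts(raw)
    perm_pos = np.zeros_like(real_pos)
    perm_neg = np.zeros_like(real_neg)
    for _ in range(n_permutations):
        perm = raw.copy()
        for row in perm:  # break correlation, keep per-gene distribution
            rng.shuffle(row)
        p, q = edge_counts(perm)
        perm_pos += p
        perm_neg += q
    perm_pos /= n_permutations
    perm_neg /= n_permutations

    pos_cut = neg_cut = None
    # FDR = mean permuted edge count / max(real count, 1): at cutoffs where no
    # real edge survives the bound is trivially controlled, so a pure-noise
    # matrix is answered with stringent cutoffs rather than a fallback
    for c, real, null in zip(pos_grid, real_pos, perm_pos):
        if null / max(real, 1.0) <= target_edge_fdr:
            pos_cut = float(c)
            break
    for c, real, null in zip(neg_grid, real_neg, perm_neg):
        if null / max(real, 1.0) <= target_edge_fdr:
            neg_cut = float(c)
            break
    if pos_cut is None or neg_cut is None:
        logger.warning(
            "permutation calibration found no admissible cutoffs; "
            "falling back to (0.81, -0.57)"
        )
        return 0.81, -0.57
    return pos_cut, neg_cut


# ---------------------------------------------------------------------------
# Seed selection and level assignment
# ---------------------------------------------------------------------------

def select_seed(matrix: TimeCourseMatrix, tf_set, min_avg_tpm: float = 0.5) -> str:
    """TF most specific to the first stage: maximal z(T1) - max z(T2..Tn)
    on stage-mean z-scored profiles, requiring mean T1 TPM >= ``min_avg_tpm``.
    Ties break toward larger T1 TPM, then lexicographically smaller id."""
    tfs = sorted(set(tf_set) & set(matrix.gene_ids))
    if not tfs:
        raise ValueError("no TFs present in matrix")
    sm = matrix.stage_means().loc[tfs]
    first = sm.columns[0]
    candidates = []
    for tf, row in sm.iterrows():
        if row[first] < min_avg_tpm:
            continue
        sd = row.std(ddof=0)
        if sd == 0:
            continue
        z = (row - row.mean()) / sd
        score = z.iloc[0] - z.iloc[1:].max()
        candidates.append((-score, -row[first], tf))
    if not candidates:
        raise ValueError("no TF passes the first-stage expression floor")
    candidates.sort()
    return candidates[0][2]


@dataclass
class LevelAssignment:
    level_by_node: dict  # node -> level (TFs and attached genes)
    tf_nodes: set
    seed: str
    max_level: int
    level_to_stage: dict = field(default_factory=dict)  # level -> peak stage
    level_to_group: dict = field(default_factory=dict)  # level -> stage-group label

    def tf_levels(self) -> dict:
        return {n: l for n, l in self.level_by_node.items() if n in self.tf_nodes}

    def members(self, level: int) -> list:
        return sorted(n for n, l in self.level_by_node.items() if l == level)

    def level_counts(self) -> dict:
        out: dict = {}
        for n, l in self.level_by_node.items():
            d = out.setdefault(l, {"members": 0, "tfs": 0})
            d["members"] += 1
            if n in self.tf_nodes:
                d["tfs"] += 1
        return dict(sorted(out.items()))


def assign_levels(
    gcn: SignedGCN, seed: str, max_levels: int = 8, min_nodes: int = 20
) -> LevelAssignment:
    """Breadth-first time-order levels from the seed TF.

    A TF's level is 1 + its shortest positive-path distance to the seed over
    TF–TF edges; a non-TF gene attaches at 1 + the minimum level of its
    positively linked TFs. Construction stops past ``max_levels``, or at the
    first level (beyond the seed's) holding <= ``min_nodes`` members, which
    is discarded together with everything deeper.
    """
    if seed not in gcn.tf_nodes:
        raise ValueError(f"seed {seed!r} is not a TF node of the network")
    g = gcn.positive_tf_graph()
    dist = nx.single_source_shortest_path_length(g, seed, cutoff=max_levels - 1)
    tf_level = {tf: d + 1 for tf, d in dist.items()}

    gene_level = {}
    pos = gcn.edges[gcn.edges["sign"] == "+"]
    for a, b, r, s in pos.itertuples(index=False):
        tf, gene = (a, b) if b in gcn.gene_nodes else (b, a)
        if gene in gcn.gene_nodes and tf in tf_level:
            lvl = tf_level[tf] + 1
            if lvl <= max_levels and (gene not in gene_level or lvl < gene_level[gene]):
                gene_level[gene] = lvl

    level_by_node = dict(tf_level)
    level_by_node.update(gene_level)
    counts: dict = {}
    for l in level_by_node.values():
        counts[l] = counts.get(l, 0) + 1
    cut = max_levels
    for l in range(2, max_levels + 1):
        if counts.get(l, 0) <= min_nodes:
            cut = l - 1
            break
    level_by_node = {n: l for n, l in level_by_node.items() if l <= cut}
    return LevelAssignment(
        level_by_node=level_by_node,
        tf_nodes=set(gcn.tf_nodes),
        seed=seed,
        max_level=cut,
    )


def default_stage_groups(n_stages: int) -> dict:
    """Stage -> group label: first stage initial, last two terminal, middle
    transitional (degenerate designs collapse gracefully)."""
    groups = {}
    for t in range(1, n_stages + 1):
        if t == 1:
            groups[t] = "initial"
        elif t > n_stages - 2:
            groups[t] = "terminal"
        else:
            groups[t] = "transitional"
    if n_stages == 2:
        groups[2] = "terminal"
    return groups


def map_levels_to_stages(
    levels: LevelAssignment, matrix: TimeCourseMatrix, stage_groups: dict | None = None
) -> dict:
    """Tag each level with the stage where its mean z-scored profile peaks,
    group stages into initial/transitional/terminal, and tally members.

    Mutates ``levels`` (level_to_stage / level_to_group) and returns a report
    dict with per-level and per-group member and TF counts.
    """
    if stage_groups is None:
        stage_groups = default_stage_groups(len(matrix.stages))
    sm = matrix.stage_means()
    report_levels = {}
    group_counts: dict = {}
    for lvl in sorted(set(levels.level_by_node.values())):
        members = [m for m in levels.members(lvl) if m in sm.index]
        if not members:
            continue
        prof = sm.loc[members].values.astype(float)
        mu = prof.mean(axis=1, keepdims=True)
        sd = prof.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        mean_z = ((prof - mu) / sd).mean(axis=0)
        peak_stage = int(sm.columns[int(np.argmax(mean_z))])
        group = stage_groups[peak_stage]
        levels.level_to_stage[lvl] = peak_stage
        levels.level_to_group[lvl] = group
        n_tf = sum(1 for m in members if m in levels.tf_nodes)
        report_levels[lvl] = {
            "peak_stage": peak_stage,
            "group": group,
            "members": len(members),
            "tfs": n_tf,
        }
        gc = group_counts.setdefault(group, {"members": 0, "tfs": 0})
        gc["members"] += len(members)
        gc["tfs"] += n_tf
    return {"levels": report_levels, "groups": group_counts}
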