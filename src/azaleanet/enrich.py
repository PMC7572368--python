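"""Hypergeometric functional enrichment and proportion reporting.

Over-representation of an annotation term in a study gene set is scored by
the upper-tail hypergeometric probability P(X >= k) for k study genes
annotated with the term, out of n study genes, K term genes and N background
genes, with Benjamini–Hochberg control across all tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving,
    clipped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    term: str
    k: int  # study genes with the term
    n: int  # study size
    K: int  # background genes with the term
    N: int  # background size
    p: float
    p_adj: float


def _as_gene_terms(annotation) -> dict:
    """Accept a mapping gene -> iterable of terms, or a two-column DataFrame
    (gene_id, term_id)."""
    if isinstance(annotation, pd.DataFrame):
        out: dict = {}
        for g, t in annotation.iloc[:, :2].itertuples(index=False):
            out.setdefault(g, set()).add(t)
        return out
    return {g: set(ts) for g, ts in annotation.items()}


def hypergeom_enrichment(
    study, annotation, background, alpha: float = 0.001
) -> pd.DataFrame:
    """Term-by-term over-representation test of ``study`` against
    ``background``.

    Returns the full table (term, k, n, K, N, p, p_adj, enriched) sorted by
    adjusted p; ``enriched`` flags adjusted p < ``alpha``. Terms absent from
    the background are skipped.
    """
    study = set(study)
    background = set(background)
    offenders = sorted(study - background)
    if offenders:
        raise ValueError(f"study genes outside background: {offenders[:10]}")
    gene_terms = _as_gene_terms(annotation)
    term_pop: dict = {}
    term_study: dict = {}
    for g in background:
        for t in gene_terms.get(g, ()):
            term_pop[t] = term_pop.get(t, 0) + 1
            if g in study:
                term_study[t] = term_study.get(t, 0) + 1
    N, n = len(background), len(study)
    terms = sorted(t for t, K in term_pop.items() if K > 0)
    rows = []
    for t in terms:
        K = term_pop[t]
        k = term_study.get(t, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((t, k, n, K, N, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "p", "p_adj", "enriched"]
        )
    table = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    table["p_adj"] = bh_adjust(table["p"].values)
    table["enriched"] = table["p_adj"] < alpha
    return table.sort_values(["p_adj", "p", "term"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Proportion / composition reports
# ---------------------------------------------------------------------------

@dataclass
class ProportionReport:
    label: str
    numerator: int
    denominator: int
    percent: float
    decimals: int


def proportion(
    numerator: int, denominator: int, decimals: int = 2, label: str = ""
) -> ProportionReport:
    """Percentage with half-up rounding at the requested precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    q = Decimal(1).scaleb(-decimals)
    pct = float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )
    return ProportionReport(label, numerator, denominator, pct, decimals)


def network_composition_report(levels) -> dict:
    """Per-stage-group member and TF counts from a level assignment, plus
    grand totals (total members = TFs + structural genes exactly)."""
    groups: dict = {}
    total = {"members": 0, "tfs": 0, "structural_genes": 0}
    for node, lvl in levels.level_by_node.items():
        group = levels.level_to_group.get(lvl, "unassigned")
        g = groups.setdefault(group, {"members": 0, "tfs": 0})
        g["members"] += 1
        total["members"] += 1
        if node in levels.tf_nodes:
            g["tfs"] += 1
            total["tfs"] += 1
        else:
            total["structural_genes"] += 1
    return {"groups": groups, "total": total}
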