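"""Hypergeometric functional enrichment of a network gene set.

For each annotation term with K carriers among N background genes, the
upper-tail probability of observing >= k carriers in an n-gene study set is
tested and Benjamini-Hochberg adjusted; terms with adjusted p < 0.001 are
reported as over-represented.
"""

import azaleanet as az

ds = az.generate_all(az.SyntheticConfig(seed=5))
study = sorted(ds.truth.network_members)
table = az.hypergeom_enrichment(
    study, ds.annotations, ds.catalog.gene_ids, alpha=0.001
)

print(f"study set: {len(study)} genes; background: {len(ds.catalog)}; "
      f"terms tested: {len(table)}")
print(f"planted over-represented terms: {ds.truth.enriched_terms}\n")
print(table.head(6).to_string(index=False,
                              formatters={"p": "{:.2e}".format,
                                          "p_adj": "{:.2e}".format}))
enriched = list(table.loc[table["enriched"], "term"])
print(f"\nterms passing adjusted p < 0.001: {enriched} "
      "(k of n study genes vs K of N background genes)")

pct = az.proportion(len(enriched), len(table), 2)
print(f"that is {pct.numerator}/{pct.denominator} = {pct.percent}% of tested terms")
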