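"""Classify duplicated genes into WGD/TD/PD/TRD/DSD and summarize.

Builds a synthetic genome with planted duplication modes, chains collinear
blocks, runs the rule-based classifier and prints per-mode proportions next
to the planted truth.
"""

import azaleanet as az

cfg = az.SyntheticConfig(seed=1)
catalog, pairs, anchors, truth = az.generate_genome(cfg)
pair_list = [(a, b) for a, b, _ in pairs]

blocks = az.chain_synteny(pair_list, catalog)
assign = az.classify_duplicates(catalog, pair_list, blocks)

correct = sum(
    assign.pair_modes[(a, b)] == truth.pair_mode(a, b) for a, b in pair_list
)
print(f"{len(pair_list)} homolog pairs, {len(blocks)} collinear blocks")
print(f"planted modes recovered: {correct}/{len(pair_list)}")

props = az.mode_proportions(assign, total_genes=len(catalog))
print("\nmode  genes  % of catalog   (percentage of all genes in each mode)")
for mode, row in props.items():
    print(f"{mode:4s}  {row['count']:5d}  {row['percent']:5.1f}")

# overlap of an "expanded gene family" set with each duplication mode
egf = sorted(assign.genes_in_modes(("TD", "PD")))[:40] + sorted(
    assign.genes_in_modes(("WGD",))
)[:20]
venn = az.egf_mode_overlap(egf, assign)
print(f"\nEGF set of {venn['EGF']} genes vs duplication modes: "
      f"{ {m: venn[m] for m in ('WGD', 'TD', 'PD', 'TRD', 'DSD')} }")
print(f"share of the family expansion due to tandem/proximal events: "
      f"{venn['TD_PD_share_percent']}%")
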