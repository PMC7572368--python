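# azaleanet

Downstream comparative-genomics and network-inference toolkit for flower
pigmentation studies, modeled on the analysis chain used for the azalea
(*Rhododendron simsii*) genome: how gene duplication shaped the pigment
biosynthesis pathways, when the ancestral whole-genome duplication happened,
and which transcription factors regulate the pathway enzymes across flower
development — plus a synthetic-data generator that plants every ground truth
so the whole chain is testable without any genome download.

It is a library for people who work on gene family evolution and regulatory
network inference in plants: you import it from Python, and `examples/`
holds one short narrative script per capability.

## What it computes

**Duplication modes.** Homolog pairs are classified with priority
WGD > TD > PD > TRD > DSD: whole-genome duplicates have both members
anchored in collinear (synteny) blocks, found here by longest-chain dynamic
programming over gene-rank coordinates; tandem duplicates are adjacent on a
chromosome; proximal duplicates lie < 10 genes apart; transposed duplicates
keep exactly one member at an ancestral (block-anchored) locus; the rest
are dispersed. Reports include per-mode percentages, pathway TD∪PD
fractions, and expanded-gene-family (EGF) overlaps.

**Ka/Ks and WGD dating.** For a codon-aligned pair, the Nei–Gojobori (1986)
counting method gives synonymous and nonsynonymous substitution rates per
site with Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p); ω = Ka/Ks > 1
flags positive selection. The paralog Ks distribution is smoothed with a
Gaussian kernel; a peak Ks* converts to an event age through the synonymous
rate per year r = Ks/(2T), calibrated on an ortholog peak with known
divergence time, so T_WGD = Ks*/(2r).

**Time-ordered gene co-expression network (TO-GCN).** From a 5-stage × 5-
replicate TPM matrix: genes with mean TPM < 0.5 are dropped, genes without
significant between-stage differences (Welch tests on log2(TPM+1), joint
BH, |log2FC| ≥ 1) are gated out, and a signed Pearson network is built
between TFs and genes at cutoffs r ≥ 0.81 / r ≤ −0.57. A seed TF expressed
only at the first stage starts a breadth-first expansion over positive
TF–TF edges that assigns time-order levels L1..L8; levels map back to the
initial/transitional/terminal stages of corolla pigmentation.

**Hierarchical regulators with binding support.** For an enzyme gene (an
F3H-like hub, say), candidate direct regulators are TFs positively linked
to it from the same or an earlier level; first- to third-order chains
(e.g. WRKY → GRAS → MYB → F3H) are enumerated over positive TF–TF edges
with non-decreasing levels, and a chain is *supported* only if the target's
2-kb promoter carries a log-odds PWM hit of the direct regulator's family.

**Enrichment.** Term over-representation by upper-tail hypergeometric
probability P(X ≥ k | N, K, n) with Benjamini–Hochberg control, enriched at
adjusted p < 0.001.

## Worked example

```bash
python examples/02_kaks_wgd_dating.py
```

prints, for 150 generated pairs planted at Ks = 0.65:

```
mean NG86 Ks over 150 pairs: 0.651 (planted 0.65)
Ks density peak: 0.651 (bandwidth 0.004)
implied substitution rate r = 4.167e-09 /site/year
estimated WGD age from the detected peak: 78.1 Mya (a peak at exactly 0.65 would date to 78 Mya)
```

The first line says the counting-method estimator recovers the planted
synonymous divergence; the peak of the kernel density is the signature a
whole-genome duplication leaves in a paralog Ks distribution; the last two
lines convert that peak into an event age with a rate calibrated from a
0.65 ortholog peak at a 78-Mya divergence. `examples/03_togcn_levels.py`
reconstructs the eight network levels and reports that 100% of planted TF
levels are recovered within ±1; `examples/04_regulator_chains.py` shows the
two planted regulator chains recovered and binding-supported.

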