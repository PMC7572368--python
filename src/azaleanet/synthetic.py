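"""Synthetic study-condition generator with planted ground truth.

Every input the analysis chain consumes is generated here with a recorded
truth, so each downstream stage can be tested as a recovery experiment:

* a multi-chromosome gene catalog with homolog pairs planted in each
  duplication mode (collinear WGD blocks, adjacent tandem pairs, proximal
  pairs, transposed pairs with one block-anchored member, dispersed pairs);
* codon-aligned CDS pairs whose synonymous/nonsynonymous divergence is
  placed to match target Ks and Ka/Ks under the NG86 counting method;
* a stage × replicate TPM time course carrying a TF cascade whose levels
  progress through the flowering stages, with regulator→enzyme chains
  mirroring the hierarchical regulation of F3H-like pathway genes;
* uniform-random promoters with the direct regulator's family consensus
  embedded at a recorded offset and strand;
* flat gene→term annotations with terms truly over-represented in the
  planted network gene set.

The expression profile of time-order level ℓ is a point on a curve in the
plane spanned by orthonormalized cosine/sine waves over the stage axis:
adjacent levels then correlate at exactly cos(π/(L−1)) (0.901 for L = 8),
two-apart levels at cos(2π/(L−1)) (0.623), so the breadth-first level
reconstruction at the 0.81 cutoff is well-posed by construction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, CATALOG_COLUMNS
from .config import SyntheticConfig
from .kaks import SENSE_CODONS, STOP_CODONS, SYN_SITES, _aa, BASES
from .regnet import PWM, revcomp


class ConfigurationError(ValueError):
    """Requested synthetic design is infeasible."""


class SaturationError(ValueError):
    """Requested divergence is beyond the estimator's saturation limit."""


BULK_TF_FAMILIES = ("bHLH", "WD40", "ERF", "NAC", "bZIP", "TCP")
#: families reserved for planted regulator chains (kept out of the bulk pool
#: so binding-site support identifies the planted direct regulator uniquely)
CHAIN_TF_FAMILIES = ("WRKY", "GRAS", "MYB", "C3H", "C2H2")
PATHWAY_TAGS = ("anthocyanin", "carotenoid", "none", "flowering_time")

#: per-duplication-mode (Ks, Ka/Ks) targets for generated CDS pairs; tandem
#: and proximal pairs are younger and under weaker purifying selection, the
#: contrast reported for small-scale duplicates
MODE_KAKS_TARGETS = {
    "WGD": (0.65, 0.20),
    "TD": (0.30, 0.70),
    "PD": (0.30, 0.60),
    "TRD": (0.50, 0.30),
    "DSD": (0.55, 0.30),
}

_BACKGROUND_TPM = 8.0
_LOW_TPM = 0.1


@dataclass
class PlantedChain:
    tfs: tuple  # most upstream first; tfs[-1] is the direct regulator
    target: str


@dataclass
class PlantedTruth:
    """Ground truth recorded while generating; the recovery oracle."""

    mode_by_pair: dict = field(default_factory=dict)  # (a, b) -> mode
    level_by_tf: dict = field(default_factory=dict)  # tf -> 1..n_levels
    chains: list = field(default_factory=list)  # list[PlantedChain]
    target_parent: dict = field(default_factory=dict)  # gene -> (tf, +1|-1)
    background_genes: list = field(default_factory=list)
    low_expression_genes: list = field(default_factory=list)
    expected_ka_ks: dict = field(default_factory=dict)  # pair id -> counts
    enriched_terms: list = field(default_factory=list)
    motif_sites: list = field(default_factory=list)  # (gene, motif, offset, strand)

    def pair_mode(self, a: str, b: str):
        return self.mode_by_pair.get((a, b)) or self.mode_by_pair.get((b, a))

    @property
    def network_members(self) -> set:
        return set(self.level_by_tf) | set(self.target_parent) | {
            c.target for c in self.chains
        }

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["mode_by_pair"] = {f"{a}|{b}": m for (a, b), m in self.mode_by_pair.items()}
        d["target_parent"] = {g: list(v) for g, v in self.target_parent.items()}
        d["chains"] = [{"tfs": list(c.tfs), "target": c.target} for c in self.chains]
        return d


def _gene_id(chrom_i: int, rank: int) -> str:
    return f"Rs{chrom_i:02d}G{rank:04d}"


def _free_runs(free: set, length: int) -> list[int]:
    """Start ranks of runs of `length` consecutive free ranks."""
    starts = []
    for r in sorted(free):
        if all(r + k in free for k in range(length)):
            starts.append(r)
    return starts


# ---------------------------------------------------------------------------
# Genome, homolog pairs, collinear anchors
# ---------------------------------------------------------------------------

def generate_genome(config: SyntheticConfig):
    """Gene catalog + homolog pairs + collinearity anchors + planted truth.

    Returns ``(catalog, pairs, anchors, truth)`` where ``pairs`` is a list of
    (gene_a, gene_b, score) and ``anchors`` a list of (block_id, gene_a,
    gene_b). Duplication modes are planted so the rule-based classifier can
    recover them exactly; TF cascade roles (levels, chains, targets) are
    stamped on the catalog for the time-course generator.
    """
    rng = np.random.default_rng([config.seed, 0])
    n_chrom, gpc = config.n_chromosomes, config.genes_per_chromosome
    chroms = [f"chr{i:02d}" for i in range(1, n_chrom + 1)]

    rows = []
    for ci, chrom in enumerate(chroms, start=1):
        for rank in range(gpc):
            start = rank * 3000
            rows.append(
                {
                    "gene_id": _gene_id(ci, rank),
                    "chrom": chrom,
                    "start": start,
                    "end": start + 1500,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "rank": rank,
                    "is_tf": False,
                    "tf_family": "",
                    "pathway_tag": "none",
                }
            )
    table = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    id_of = {}
    for ci, chrom in enumerate(chroms, start=1):
        for rank in range(gpc):
            id_of[(chrom, rank)] = _gene_id(ci, rank)

    free = {c: set(range(gpc)) for c in chroms}
    truth = PlantedTruth()
    pairs: list[tuple] = []
    anchors: list[tuple] = []
    inter_anchor_count: dict = defaultdict(int)  # chrom-pair -> planted anchors
    blocked_chrompairs: set = set()

    fr = config.dup_mode_fractions
    n_pairs_mode = {
        m: int(round(fr.get(m, 0.0) * config.n_genes / 2.0)) for m in MODE_KAKS_TARGETS
    }

    def take_pair(ca, ra, cb, rb, mode):
        a, b = id_of[(ca, ra)], id_of[(cb, rb)]
        pairs.append((a, b, 1.0))
        truth.mode_by_pair[(a, b)] = mode
        free[ca].discard(ra)
        free[cb].discard(rb)
        return a, b

    # --- WGD: collinear blocks across distinct chromosome pairs ------------
    n_wgd = n_pairs_mode["WGD"]
    if 0 < n_wgd < 5:
        raise ConfigurationError(
            f"WGD fraction yields {n_wgd} pairs but a collinear block needs >= 5 anchors"
        )
    sizes = []
    rem = n_wgd
    while rem > 0:
        if rem >= config.anchors_per_block + 5 or rem <= config.anchors_per_block:
            take = min(config.anchors_per_block, rem)
        else:  # avoid a trailing fragment below the anchor floor
            take = rem
        if take < 5:
            sizes[-1] += take
        else:
            sizes.append(take)
        rem -= take
    block_id = 0
    for size in sizes:
        placed = False
        for _ in range(500):
            ca, cb = rng.choice(chroms, size=2, replace=False)
            key = tuple(sorted((ca, cb)))
            if key in blocked_chrompairs:
                continue
            runs_a = _free_runs(free[ca], size)
            runs_b = _free_runs(free[cb], size)
            if not runs_a or not runs_b:
                continue
            sa = int(rng.choice(runs_a))
            sb = int(rng.choice(runs_b))
            for k in range(size):
                a, b = take_pair(ca, sa + k, cb, sb + k, "WGD")
                anchors.append((block_id, a, b))
            blocked_chrompairs.add(key)
            block_id += 1
            placed = True
            break
        if not placed:
            raise ConfigurationError(
                "cannot place WGD blocks: more WGD pairs than block capacity"
            )

    # --- TD / PD: intra-chromosomal, capped so they can never chain --------
    intra_cap = 4  # < min_anchors, so planted TD/PD anchors never form a block
    intra_count: dict = defaultdict(int)

    def place_intra(mode, gap_choices):
        for _ in range(2000):
            chrom = str(rng.choice(chroms))
            if intra_count[chrom] >= intra_cap:
                continue
            gap = int(rng.choice(gap_choices))
            starts = [
                r for r in free[chrom] if (r + gap) in free[chrom]
            ]
            if not starts:
                continue
            r = int(rng.choice(sorted(starts)))
            take_pair(chrom, r, chrom, r + gap, mode)
            intra_count[chrom] += 1
            return
        raise ConfigurationError(f"cannot place a {mode} pair: catalog too crowded")

    for _ in range(n_pairs_mode["TD"]):
        place_intra("TD", [1])
    for _ in range(n_pairs_mode["PD"]):
        place_intra("PD", list(range(2, 10)))

    # --- TRD: one block-anchored member, one novel locus --------------------
    anchored_genes = sorted({g for _, a, b in anchors for g in (a, b)})
    if n_pairs_mode["TRD"] > 0 and not anchored_genes:
        raise ConfigurationError(
            "TRD pairs need block-anchored ancestral loci; plant WGD blocks too"
        )
    rank_of_id = {g: (table.loc[i, "chrom"], table.loc[i, "rank"])
                  for i, g in enumerate(table["gene_id"])}

    def place_inter(mode, fixed_gene=None):
        for _ in range(2000):
            if fixed_gene is not None:
                ga = fixed_gene
                ca = rank_of_id[ga][0]
            else:
                ca = str(rng.choice(chroms))
                if not free[ca]:
                    continue
            cb = str(rng.choice([c for c in chroms if c != ca]))
            key = tuple(sorted((ca, cb)))
            if key in blocked_chrompairs or inter_anchor_count[key] >= 4:
                continue
            if not free[cb]:
                continue
            rb = int(rng.choice(sorted(free[cb])))
            if fixed_gene is None:
                ra = int(rng.choice(sorted(free[ca])))
                a, b = take_pair(ca, ra, cb, rb, mode)
            else:
                b = id_of[(cb, rb)]
                pairs.append((ga, b, 1.0))
                truth.mode_by_pair[(ga, b)] = mode
                free[cb].discard(rb)
            inter_anchor_count[key] += 1
            return
        raise ConfigurationError(f"cannot place a {mode} pair")

    for i in range(n_pairs_mode["TRD"]):
        g = str(rng.choice(anchored_genes))
        place_inter("TRD", fixed_gene=g)
    for _ in range(n_pairs_mode["DSD"]):
        place_inter("DSD")

    # --- cascade roles on unpaired genes ------------------------------------
    free_ids = [id_of[(c, r)] for c in chroms for r in sorted(free[c])]
    free_ids = [free_ids[i] for i in rng.permutation(len(free_ids))]
    L = config.n_levels
    n_chain_tfs = 5 if L >= 4 else 0
    need = (
        L * config.tfs_per_level
        + n_chain_tfs
        + 1  # shared chain target
        + L * config.targets_per_level
        + config.n_repressed_targets
        + config.n_background_tfs
    )
    if len(free_ids) < need:
        raise ConfigurationError(
            f"catalog too small for cascade roles: need {need} unpaired genes, "
            f"have {len(free_ids)}"
        )
    cursor = 0

    def draw(n):
        nonlocal cursor
        out = free_ids[cursor : cursor + n]
        cursor += n
        return out

    tf_rows = {}
    fam_i = 0
    for lvl in range(1, L + 1):
        for tf in draw(config.tfs_per_level):
            truth.level_by_tf[tf] = lvl
            tf_rows[tf] = BULK_TF_FAMILIES[fam_i % len(BULK_TF_FAMILIES)]
            fam_i += 1

    if n_chain_tfs:
        w_tf, gras_tf, myb_tf, c3h_tf, c2h2_tf = draw(5)
        (chain_target,) = draw(1)
        lv = {w_tf: L - 3, gras_tf: L - 2, myb_tf: L - 1, c3h_tf: L - 2, c2h2_tf: L - 1}
        fams = dict(zip((w_tf, gras_tf, myb_tf, c3h_tf, c2h2_tf), CHAIN_TF_FAMILIES))
        for tf, lvl in lv.items():
            truth.level_by_tf[tf] = lvl
            tf_rows[tf] = fams[tf]
        truth.chains = [
            PlantedChain((w_tf, gras_tf, myb_tf), chain_target),
            PlantedChain((w_tf, c3h_tf, c2h2_tf), chain_target),
        ]
        # the direct regulators' profiles drive the shared enzyme target
        truth.target_parent[chain_target] = (myb_tf, +1)
        pathway_of = {chain_target: "anthocyanin"}
    else:
        pathway_of = {}

    level_tf_list = defaultdict(list)
    for tf, lvl in truth.level_by_tf.items():
        if tf_rows.get(tf) in BULK_TF_FAMILIES:
            level_tf_list[lvl].append(tf)

    tag_i = 0
    for lvl in range(1, L + 1):
        for j, gene in enumerate(draw(config.targets_per_level)):
            parent = level_tf_list[lvl][j % len(level_tf_list[lvl])]
            truth.target_parent[gene] = (parent, +1)
            pathway_of[gene] = PATHWAY_TAGS[tag_i % len(PATHWAY_TAGS)]
            tag_i += 1
    for j, gene in enumerate(draw(config.n_repressed_targets)):
        parent = level_tf_list[1][j % len(level_tf_list[1])]
        truth.target_parent[gene] = (parent, -1)

    for tf in draw(config.n_background_tfs):
        tf_rows[tf] = BULK_TF_FAMILIES[fam_i % len(BULK_TF_FAMILIES)]
        fam_i += 1

    rest = free_ids[cursor:]
    n_low = int(round(config.low_expression_fraction * len(rest)))
    truth.low_expression_genes = sorted(rest[:n_low])
    truth.background_genes = sorted(rest[n_low:])

    table = table.set_index("gene_id", drop=False)
    for tf, fam in tf_rows.items():
        table.loc[tf, ["is_tf", "tf_family"]] = [True, fam]
    for gene, tag in pathway_of.items():
        table.loc[gene, "pathway_tag"] = tag
    catalog = GeneCatalog(table.reset_index(drop=True))
    return catalog, pairs, anchors, truth


# ---------------------------------------------------------------------------
# Expression time course
# ---------------------------------------------------------------------------

def level_profiles(n_stages: int, n_levels: int, pos_cutoff: float = 0.81) -> np.ndarray:
    """Stage-mean profile shape (z-form) per time-order level.

    Rows are unit vectors z_ℓ = cos(θℓ)·u + sin(θℓ)·w with θ uniform on
    [0, π] and u, w the orthonormalized cosine/sine stage waves, giving
    Pearson(z_i, z_j) = cos(θi − θj) exactly and peak stages progressing
    monotonically from the first to the last stage.
    """
    if n_stages < 3:
        raise ConfigurationError("need >= 3 stages to represent time-order levels")
    if n_levels < 2:
        raise ConfigurationError("need >= 2 levels")
    phi = np.pi / (n_levels - 1)
    if np.cos(phi) < pos_cutoff:
        raise ConfigurationError(
            f"{n_levels} levels are not representable over {n_stages} stages at "
            f"cutoff {pos_cutoff}: adjacent-level correlation cos(π/(L−1)) = "
            f"{np.cos(phi):.3f} falls below it"
        )
    s = np.arange(n_stages, dtype=float)
    u = np.cos(np.pi * s / (n_stages - 1))
    w = np.sin(np.pi * s / (n_stages - 1))
    u = u - u.mean()
    w = w - w.mean()
    u /= np.linalg.norm(u)
    w /= np.linalg.norm(w)
    theta = np.linspace(0.0, np.pi, n_levels)
    return np.outer(np.cos(theta), u) + np.outer(np.sin(theta), w)


def generate_timecourse(config: SyntheticConfig, catalog: GeneCatalog, truth: PlantedTruth):
    """Realize the planted cascade as a TPM matrix (stages × replicates).

    Level-ℓ TFs follow the level-ℓ profile; activator targets copy their
    parent TF's profile and repressed targets mirror it (2·baseline − x);
    background genes sit at a flat baseline; the low-expression set sits
    below the 0.5-TPM filter. Gaussian noise of sd ``noise_sd`` is applied
    on the log2(TPM+1) scale.
    """
    from .togcn import TimeCourseMatrix

    rng = np.random.default_rng([config.seed, 1])
    Z = level_profiles(config.n_stages, config.n_levels, config.pos_cutoff)
    base, amp = config.baseline_tpm, config.amplitude_tpm
    stage_profile = {
        lvl: base + amp * Z[lvl - 1] for lvl in range(1, config.n_levels + 1)
    }
    if min(p.min() for p in stage_profile.values()) <= 0:
        raise ConfigurationError("amplitude exceeds baseline: negative TPM profile")

    low = set(truth.low_expression_genes)
    vec = {}
    for tf, lvl in truth.level_by_tf.items():
        vec[tf] = stage_profile[lvl]
    for gene, (parent, sign) in truth.target_parent.items():
        parent_vec = vec[parent]
        vec[gene] = parent_vec if sign > 0 else 2.0 * base - parent_vec

    n_rep = config.n_replicates
    data = np.empty((len(catalog), config.n_stages * n_rep))
    for i, gene in enumerate(catalog.gene_ids):
        if gene in vec:
            stage_vec = vec[gene]
        elif gene in low:
            stage_vec = np.full(config.n_stages, _LOW_TPM)
        else:
            stage_vec = np.full(config.n_stages, _BACKGROUND_TPM)
        row = np.repeat(stage_vec, n_rep)
        if config.noise_sd > 0:
            lg = np.log2(row + 1.0) + rng.normal(0.0, config.noise_sd, row.size)
            row = np.clip(2.0 ** lg - 1.0, 0.0, None)
        data[i] = row
    values = pd.DataFrame(data, index=catalog.gene_ids, columns=config.samples)
    matrix = TimeCourseMatrix(values, set(catalog.tf_ids))
    return matrix, truth


# ---------------------------------------------------------------------------
# Divergent CDS pairs
# ---------------------------------------------------------------------------

_SYN_ALTS: dict = {}
_NONSYN_ALTS: dict = {}
for _c in SENSE_CODONS:
    syn, non = [], []
    for _i in range(3):
        for _b in BASES:
            if _b == _c[_i]:
                continue
            _alt = _c[:_i] + _b + _c[_i + 1 :]
            if _alt in STOP_CODONS:
                continue
            (syn if _aa(_alt) == _aa(_c) else non).append(_alt)
    _SYN_ALTS[_c] = syn
    _NONSYN_ALTS[_c] = non


def _expected_p(d: float) -> float:
    """Jukes–Cantor forward map: expected difference proportion at distance d."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


@dataclass
class CDSPair:
    pair_id: str
    seq_a: str
    seq_b: str
    n_syn: int
    n_nonsyn: int


def generate_divergent_cds(
    n_pairs: int,
    target_ks: float,
    target_omega: float,
    seed: int = 0,
    length_nt: int = 900,
):
    """Codon-aligned pairs whose NG86 estimates match the targets in
    expectation.

    Substitutions are placed one per codon at synonymous or nonsynonymous
    positions (never creating stops) in the numbers implied by the targets
    through the inverse Jukes–Cantor map. Returns ``(pairs, truth_records)``
    with per-pair realized counts.
    """
    if target_ks < 0 or target_omega < 0:
        raise ValueError("targets must be non-negative")
    if length_nt % 3 != 0:
        raise ValueError(f"sequence length {length_nt} is not a multiple of 3")
    target_ka = target_omega * target_ks
    ps, pn = _expected_p(target_ks), _expected_p(target_ka)
    if ps >= 0.745 or pn >= 0.745:
        raise SaturationError(
            "target divergence is at the counting-method saturation limit "
            "(expected difference proportion >= 3/4)"
        )
    rng = np.random.default_rng(seed)
    n_codons = length_nt // 3
    out, records = [], {}
    for ip in range(n_pairs):
        codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
        s_sites = sum(SYN_SITES[c] for c in codons)
        n_sites = 3.0 * n_codons - s_sites
        n_syn = int(round(ps * s_sites))
        n_non = int(round(pn * n_sites))
        if n_syn + n_non > n_codons:
            raise ValueError(
                "requested divergence needs more than one substitution per codon; "
                "increase sequence length"
            )
        order = rng.permutation(n_codons)
        mutated = list(codons)
        placed_syn = placed_non = 0
        for idx in order:
            c = codons[idx]
            if placed_syn < n_syn and _SYN_ALTS[c]:
                mutated[idx] = _SYN_ALTS[c][rng.integers(0, len(_SYN_ALTS[c]))]
                placed_syn += 1
            elif placed_non < n_non and _NONSYN_ALTS[c]:
                mutated[idx] = _NONSYN_ALTS[c][rng.integers(0, len(_NONSYN_ALTS[c]))]
                placed_non += 1
            if placed_syn == n_syn and placed_non == n_non:
                break
        pair_id = f"pair{ip:05d}"
        pair = CDSPair(pair_id, "".join(codons), "".join(mutated), placed_syn, placed_non)
        out.append(pair)
        records[pair_id] = {
            "n_syn": placed_syn,
            "n_nonsyn": placed_non,
            "target_ks": target_ks,
            "target_omega": target_omega,
        }
    return out, records


def cds_pairs_to_fasta(pairs, path) -> None:
    """Two records per pair; the pair id is carried in both headers."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.pair_id}_a {p.pair_id}\n{p.seq_a}\n")
            fh.write(f">{p.pair_id}_b {p.pair_id}\n{p.seq_b}\n")


def sample_ks_mixture(peaks, n: int, seed: int = 0) -> np.ndarray:
    """Draw Ks values from a mixture of (location, weight, spread) Gaussian
    components truncated at 0 (negative draws are resampled)."""
    rng = np.random.default_rng(seed)
    locs = np.array([p[0] for p in peaks])
    weights = np.array([p[1] for p in peaks], dtype=float)
    weights /= weights.sum()
    sds = np.array([p[2] for p in peaks])
    comp = rng.choice(len(peaks), size=n, p=weights)
    vals = rng.normal(locs[comp], sds[comp])
    while (vals < 0).any():
        bad = vals < 0
        vals[bad] = rng.normal(locs[comp[bad]], sds[comp[bad]])
    return vals


# ---------------------------------------------------------------------------
# PWMs, promoters, annotations
# ---------------------------------------------------------------------------

def generate_pwms(families, width: int = 10, seed: int = 0) -> dict:
    """One high-information-content PWM per family: a random non-palindromic
    consensus with 85/5/5/5 column counts. Consensi are pairwise distinct."""
    rng = np.random.default_rng(seed)
    pwms: dict = {}
    used = set()
    for k, fam in enumerate(sorted(set(families))):
        for _ in range(200):
            cons = "".join("ACGT"[i] for i in rng.integers(0, 4, width))
            if cons != revcomp(cons) and cons not in used and revcomp(cons) not in used:
                used.add(cons)
                break
        else:
            raise ConfigurationError("cannot draw distinct non-palindromic consensi")
        counts = np.full((4, width), 5.0)
        for j, b in enumerate(cons):
            counts["ACGT".index(b), j] = 85.0
        pwms[fam] = PWM(f"M{k:03d}_{fam}", fam, counts)
    return pwms


def generate_promoters(
    catalog: GeneCatalog,
    pwms: dict,
    truth: PlantedTruth,
    upstream_length: int = 2000,
    seed: int = 0,
):
    """Uniform-random promoters for pathway genes, with the consensus of each
    planted chain's direct-regulator family embedded in the target's promoter
    at a recorded offset and strand."""
    widths = [p.width for p in pwms.values()]
    if widths and upstream_length < max(widths):
        raise ValueError("upstream_length shorter than the widest motif")
    rng = np.random.default_rng(seed)
    genes = sorted(
        set(catalog.table.loc[catalog.table["pathway_tag"] != "none", "gene_id"])
        | {c.target for c in truth.chains}
    )
    promoters = {
        g: "".join("ACGT"[i] for i in rng.integers(0, 4, upstream_length))
        for g in genes
    }
    family = catalog.family_of()
    occupied: dict = defaultdict(list)
    truth.motif_sites = []
    for chain in truth.chains:
        fam = family.get(chain.tfs[-1])
        pwm = pwms[fam]
        w = pwm.width
        for _ in range(200):
            off = int(rng.integers(0, upstream_length - w + 1))
            if all(off + w <= s or off >= s + w2 for s, w2 in occupied[chain.target]):
                break
        strand = "+" if rng.random() < 0.5 else "-"
        site = pwm.consensus() if strand == "+" else revcomp(pwm.consensus())
        seq = promoters[chain.target]
        promoters[chain.target] = seq[:off] + site + seq[off + w :]
        occupied[chain.target].append((off, w))
        truth.motif_sites.append((chain.target, pwm.motif_id, off, strand))
    return promoters, truth


def generate_annotations(
    catalog: GeneCatalog,
    n_terms: int,
    enriched_terms,
    study_genes,
    seed: int = 0,
    background_rate: float = 0.05,
    enriched_rate: float = 0.6,
):
    """Flat gene→term annotations with the given terms over-represented in
    ``study_genes``; all other gene–term memberships are Bernoulli at the
    background rate."""
    enriched_terms = list(enriched_terms)
    if n_terms < len(enriched_terms):
        raise ValueError("n_terms smaller than the number of enriched terms")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    term_index = {t: i for i, t in enumerate(terms)}
    for t in enriched_terms:
        if t not in term_index:
            raise ValueError(f"enriched term {t} not among generated terms")
    genes = catalog.gene_ids
    member = rng.random((len(genes), n_terms)) < background_rate
    study = set(study_genes)
    for t in enriched_terms:
        j = term_index[t]
        for i, g in enumerate(genes):
            if g in study:
                member[i, j] = rng.random() < enriched_rate
    rows = [
        (genes[i], terms[j])
        for i in range(len(genes))
        for j in np.nonzero(member[i])[0]
    ]
    return pd.DataFrame(rows, columns=["gene_id", "term_id"]), terms


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    catalog: GeneCatalog
    pairs: list
    anchors: list
    truth: PlantedTruth
    matrix: "object"
    pwms: dict
    promoters: dict
    cds_by_pair: dict  # (gene_a, gene_b) -> CDSPair
    annotations: pd.DataFrame
    terms: list


def generate_all(config: SyntheticConfig, n_annotation_terms: int = 50) -> SyntheticDataset:
    """Run every generator stage under sub-seeds derived from ``config.seed``."""
    catalog, pairs, anchors, truth = generate_genome(config)
    matrix, truth = generate_timecourse(config, catalog, truth)

    families = sorted(set(catalog.table["tf_family"]) - {""})
    pwms = generate_pwms(families or ["MYB"], config.motif_length, seed=config.seed + 2)
    promoters, truth = generate_promoters(
        catalog, pwms, truth, upstream_length=2000, seed=config.seed + 3
    )

    cds_by_pair: dict = {}
    by_mode: dict = defaultdict(list)
    for a, b, _ in pairs:
        by_mode[truth.pair_mode(a, b)].append((a, b))
    for mi, (mode, mode_pairs) in enumerate(sorted(by_mode.items())):
        ks, omega = MODE_KAKS_TARGETS[mode]
        gen, records = generate_divergent_cds(
            len(mode_pairs), ks, omega, seed=config.seed + 100 + mi, length_nt=900
        )
        for (a, b), cp in zip(mode_pairs, gen):
            cds_by_pair[(a, b)] = cp
            truth.expected_ka_ks[f"{a}|{b}"] = records[cp.pair_id]

    enriched = [f"GO:{i + 1:07d}" for i in range(3)]
    annotations, terms = generate_annotations(
        catalog,
        n_annotation_terms,
        enriched,
        sorted(truth.network_members),
        seed=config.seed + 4,
    )
    truth.enriched_terms = enriched
    return SyntheticDataset(
        config=config,
        catalog=catalog,
        pairs=pairs,
        anchors=anchors,
        truth=truth,
        matrix=matrix,
        pwms=pwms,
        promoters=promoters,
        cds_by_pair=cds_by_pair,
        annotations=annotations,
        terms=terms,
    )
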