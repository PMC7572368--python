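"""Ka/Ks estimation, Ks distributions and WGD dating.

Substitution rates per synonymous/nonsynonymous site are estimated with the
Nei–Gojobori (1986) counting method: sites are apportioned by the fraction of
single-nucleotide changes that are synonymous under the standard genetic
code, multi-hit codons average over all minimal substitution pathways
(pathways through stop codons are excluded and weights renormalized), and
raw proportions are corrected for multiple hits with the Jukes–Cantor
formula d = -(3/4)·ln(1 - (4/3)p).

A whole-genome duplication leaves a peak in the distribution of Ks between
paralog pairs; with a synonymous rate per year r calibrated from an ortholog
Ks peak and a known divergence time (r = Ks/(2T)), the paralog peak converts
to an event age T = Ks/(2r).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable
from scipy.signal import find_peaks
from scipy.stats import norm

_TABLE = CodonTable.unambiguous_dna_by_id[1]
BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]
_AA = dict(_TABLE.forward_table)


def _aa(codon: str) -> str | None:
    return _AA.get(codon)


def _syn_sites(codon: str) -> float:
    """Synonymous site count of a codon (0..3).

    Each of the nine possible single-nucleotide changes contributes 1/3 of a
    site; changes to stop codons count as nonsynonymous so that S + N always
    equals 3 per codon.
    """
    s = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt not in STOP_CODONS and _aa(alt) == _aa(codon):
                s += 1.0 / 3.0
    return s


SYN_SITES = {c: _syn_sites(c) for c in SENSE_CODONS}

_PAIR_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between codons.

    Enumerates every ordering of the differing positions; orderings whose
    intermediate codons are stops are dropped and the remaining paths share
    equal weight. If every path passes through a stop (possible for
    triple-difference codons), all paths are used unweighted.
    """
    key = (c1, c2)
    cached = _PAIR_CACHE.get(key)
    if cached is not None:
        return cached
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if _aa(nxt) == _aa(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every ordering stop-blocked: fall back to raw counting
        for order in permutations(diff):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt not in STOP_CODONS and _aa(nxt) == _aa(cur):
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    _PAIR_CACHE[key] = (sd, nd)
    _PAIR_CACHE[(c2, c1)] = (sd, nd)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4)·ln(1 - (4/3)p); requires p < 3/4."""
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    ka: float  # nonsynonymous substitutions per nonsynonymous site (nan if saturated)
    ks: float  # synonymous substitutions per synonymous site (nan if saturated)
    omega: float | None  # Ka/Ks; None when Ks = 0 or either distance saturated
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    ka_saturated: bool = False
    ks_saturated: bool = False

    @property
    def saturated(self) -> bool:
        return self.ka_saturated or self.ks_saturated


def _split_codons(seq: str, label: str) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"{label}: length {len(seq)} is not a multiple of 3")
    if set(seq) - set(BASES):
        raise ValueError(f"{label}: alphabet outside ACGT")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for j, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"{label}: stop codon {c} at codon {j}")
    return codons


def ng86_kaks(seq1: str, seq2: str) -> KaKsResult:
    """NG86 Ka, Ks and omega for one codon-aligned pair (gap-free, no stops).

    Symmetric in argument order; site counts are averaged over the two
    sequences. Proportions >= 3/4 flag the corresponding distance as
    saturated (undefined).
    """
    a = _split_codons(seq1, "seq1")
    b = _split_codons(seq2, "seq2")
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    n_codons = len(a)
    if n_codons == 0:
        raise ValueError("empty alignment")

    s_sites = sum((SYN_SITES[c1] + SYN_SITES[c2]) * 0.5 for c1, c2 in zip(a, b))
    n_sites = 3.0 * n_codons - s_sites
    sd = nd = 0.0
    for c1, c2 in zip(a, b):
        if c1 != c2:
            s_i, n_i = _pathway_counts(c1, c2)
            sd += s_i
            nd += n_i

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks_sat = ps >= 0.75
    ka_sat = pn >= 0.75
    ks = float("nan") if ks_sat else jukes_cantor(ps)
    ka = float("nan") if ka_sat else jukes_cantor(pn)
    omega = None
    if not (ks_sat or ka_sat) and ks > 0:
        omega = ka / ks
    return KaKsResult(
        ka=ka, ks=ks, omega=omega, n_sites=n_sites, s_sites=s_sites,
        nd=nd, sd=sd, ka_saturated=ka_sat, ks_saturated=ks_sat,
    )


# ---------------------------------------------------------------------------
# Ks distributions and peaks
# ---------------------------------------------------------------------------

@dataclass
class KsPeakModel:
    grid: np.ndarray
    density: np.ndarray
    peaks: list[float]  # sorted by height, descending
    peak_heights: list[float]
    bandwidth: float


def silverman_bandwidth(values: np.ndarray) -> float:
    n = len(values)
    sd = float(np.std(values, ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def ks_density(
    ks_values,
    bandwidth: float | str = "auto",
    grid_points: int = 512,
    peak_min_height: float = 0.05,
) -> KsPeakModel:
    """Gaussian-kernel density of Ks values with peak detection.

    Peaks are local maxima with height >= ``peak_min_height`` of the global
    maximum, reported sorted by height. Saturated/undefined values must be
    excluded by the caller.
    """
    v = np.asarray([x for x in ks_values if np.isfinite(x)], dtype=float)
    if len(v) < 30:
        raise ValueError(f"need >= 30 finite Ks values, got {len(v)}")
    if bandwidth == "auto":
        bw = silverman_bandwidth(v)
        if bw <= 0:
            raise ValueError("degenerate values; supply an explicit bandwidth")
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
    # grid padded past the largest value so the kernel mass is captured
    grid = np.linspace(0.0, float(v.max()) + 3.0 * bw, grid_points)
    density = norm.pdf(grid[:, None], loc=v[None, :], scale=bw).mean(axis=1)
    idx, _ = find_peaks(density, height=peak_min_height * density.max())
    order = np.argsort(density[idx])[::-1]
    idx = idx[order]
    return KsPeakModel(
        grid=grid,
        density=density,
        peaks=[float(grid[i]) for i in idx],
        peak_heights=[float(density[i]) for i in idx],
        bandwidth=bw,
    )


# ---------------------------------------------------------------------------
# Rate calibration and event dating
# ---------------------------------------------------------------------------

def substitution_rate(ortholog_ks_peak: float, divergence_time_years: float) -> float:
    """Synonymous substitutions per site per year, r = Ks/(2·T)."""
    if ortholog_ks_peak <= 0 or divergence_time_years <= 0:
        raise ValueError("Ks peak and divergence time must be positive")
    return ortholog_ks_peak / (2.0 * divergence_time_years)


def wgd_time(paralog_ks_peak: float, r: float) -> float:
    """Age in years of a duplication event with Ks peak, T = Ks/(2·r)."""
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    if paralog_ks_peak < 0:
        raise ValueError("Ks peak must be non-negative")
    return paralog_ks_peak / (2.0 * r)


# ---------------------------------------------------------------------------
# Per-duplication-mode omega summaries
# ---------------------------------------------------------------------------

def class_kaks_summary(assignment, results: dict) -> "pd.DataFrame":
    """Summaries of omega per duplication mode (boxplot statistics).

    ``results`` maps pair (gene_a, gene_b) -> KaKsResult; pairs with undefined
    omega are skipped. Quartiles use linear interpolation; whiskers extend to
    the most extreme values within 1.5×IQR of the hinges. ``frac_omega_gt1``
    is the positive-selection fraction within each mode.
    """
    import pandas as pd

    by_mode: dict[str, list[float]] = {}
    for pair, res in results.items():
        if res.omega is None:
            continue
        mode = assignment.pair_modes.get(tuple(pair)) or assignment.pair_modes.get(
            (pair[1], pair[0])
        )
        if mode is None:
            continue
        by_mode.setdefault(mode, []).append(res.omega)
    rows = []
    for mode in ("WGD", "TD", "PD", "TRD", "DSD"):
        vals = np.asarray(by_mode.get(mode, []), dtype=float)
        if len(vals) == 0:
            continue  # empty mode omitted, not an error
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_bound) & (vals <= hi_bound)]
        rows.append(
            {
                "mode": mode,
                "n": len(vals),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": inside.min(),
                "whisker_high": inside.max(),
                "frac_omega_gt1": float(np.mean(vals > 1.0)),
            }
        )
    return pd.DataFrame(rows)
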