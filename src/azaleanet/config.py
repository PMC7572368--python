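"""Configuration for the synthetic study-condition generator.

The defaults emulate the design of the azalea corolla study: 13 chromosomes,
a five-stage flower time course with five replicates per stage, eight
time-order levels, Pearson cutoffs 0.81 / -0.57 and a paralog Ks peak near
0.65.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_MODE_FRACTIONS = {
    "WGD": 0.10,
    "TD": 0.05,
    "PD": 0.04,
    "TRD": 0.05,
    "DSD": 0.08,
}

#: (peak location, mixture weight, spread) of the synthetic paralog-Ks mixture
DEFAULT_KS_PEAKS = [(0.65, 1.0, 0.10)]


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 13
    genes_per_chromosome: int = 60
    n_stages: int = 5
    n_replicates: int = 5
    n_levels: int = 8
    pos_cutoff: float = 0.81
    neg_cutoff: float = -0.57
    noise_sd: float = 0.10
    dup_mode_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_MODE_FRACTIONS)
    )
    ks_peaks: list = field(default_factory=lambda: list(DEFAULT_KS_PEAKS))
    motif_length: int = 12

    # cascade geometry: members planted per time-order level
    tfs_per_level: int = 12
    targets_per_level: int = 10
    n_repressed_targets: int = 2
    n_background_tfs: int = 10
    low_expression_fraction: float = 0.10

    # expression scale (TPM): profile = baseline + amplitude * z
    baseline_tpm: float = 35.0
    amplitude_tpm: float = 30.0

    # synteny-block geometry for planted WGD pairs
    anchors_per_block: int = 6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "genes_per_chromosome": self.genes_per_chromosome,
            "n_stages": self.n_stages,
            "n_replicates": self.n_replicates,
            "n_levels": self.n_levels,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        fr = self.dup_mode_fractions
        bad = {m: f for m, f in fr.items() if not 0.0 <= f <= 1.0}
        if bad:
            raise ValueError(f"duplication-mode fractions outside [0,1]: {bad}")
        if sum(fr.values()) > 1.0 + 1e-12:
            raise ValueError("duplication-mode fractions sum to more than 1")
        unknown = set(fr) - {"WGD", "TD", "PD", "TRD", "DSD"}
        if unknown:
            raise ValueError(f"unknown duplication modes: {sorted(unknown)}")
        if not self.neg_cutoff < 0.0 < self.pos_cutoff:
            raise ValueError(
                "cutoffs must satisfy neg_cutoff < 0 < pos_cutoff, got "
                f"({self.pos_cutoff}, {self.neg_cutoff})"
            )
        if self.motif_length < 4:
            raise ValueError("motif_length must be >= 4")

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome

    @property
    def samples(self) -> list[str]:
        """Sample names, stage-major: T1_R1 ... T{n}_R{m}."""
        return [
            f"T{t}_R{r}"
            for t in range(1, self.n_stages + 1)
            for r in range(1, self.n_replicates + 1)
        ]
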