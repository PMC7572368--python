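"""Gene catalog: ordered genes on chromosomes with regulatory/pathway labels.

The catalog is the positional backbone for duplication-mode classification:
tandem and proximal duplicates are defined by *gene distance*, i.e. the
difference of order indices (ranks) within a chromosome, not by base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CATALOG_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "rank",
    "is_tf",
    "tf_family",
    "pathway_tag",
]


@dataclass
class GeneCatalog:
    """Ordered gene models with transcription-factor and pathway labels.

    Parameters
    ----------
    table:
        One row per gene with columns ``gene_id, chrom, start, end, strand,
        rank, is_tf, tf_family, pathway_tag``. Coordinates are 0-based
        half-open; ``rank`` is the 0-based order index within its chromosome.
    """

    table: pd.DataFrame
    _rank: dict = field(init=False, repr=False, default=None)
    _chrom: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        missing = [c for c in CATALOG_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        self.validate()
        self._rank = dict(zip(self.table["gene_id"], self.table["rank"]))
        self._chrom = dict(zip(self.table["gene_id"], self.table["chrom"]))

    def validate(self) -> None:
        t = self.table
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id: {dup}")
        if (t["start"] >= t["end"]).any():
            raise ValueError("gene with start >= end")
        for chrom, sub in t.groupby("chrom"):
            ranks = sorted(sub["rank"])
            if ranks != list(range(len(sub))):
                raise ValueError(
                    f"ranks on {chrom} are not a permutation of 0..{len(sub) - 1}"
                )

    # -- lookups -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def rank_of(self, gene_id: str) -> int:
        return self._rank[gene_id]

    def chrom_of(self, gene_id: str) -> str:
        return self._chrom[gene_id]

    def require(self, gene_ids) -> None:
        """Raise naming the first unknown gene id, if any."""
        for g in gene_ids:
            if g not in self._rank:
                raise KeyError(f"unknown gene id: {g}")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_tf"], "gene_id"])

    def family_of(self) -> dict[str, str]:
        """Map TF gene id -> family label."""
        sub = self.table.loc[self.table["is_tf"]]
        return dict(zip(sub["gene_id"], sub["tf_family"]))

    def pathway_genes(self, tag: str) -> list[str]:
        return list(self.table.loc[self.table["pathway_tag"] == tag, "gene_id"])

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneCatalog":
        t = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        t["is_tf"] = t["is_tf"].astype(bool)
        return cls(t)
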