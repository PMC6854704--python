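"""Genotype containers and SNP-to-SDP compression for recombinant-inbred panels.

A recombinant-inbred (RI) panel carries only two parental alleles and no
heterozygotes, so a marker is fully described by its *strain distribution
pattern* (SDP): the 0/1 vector of alleles across the panel.  With a few dozen
strains, thousands of SNPs share the same pattern; mapping is therefore run on
the distinct patterns, each anchored at the median position of its member SNPs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SnpMatrix",
    "SdpPanel",
    "collapse_to_sdps",
    "genome_order",
    "chromosome_rank",
]


def chromosome_rank(chrom: object) -> tuple[int, int]:
    """Sort key for chromosome labels: autosomes numerically, then X.

    Accepts "1".."19", "X" (case-insensitive) with or without a "chr" prefix.
    """
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() == "X":
        return (1, 0)
    try:
        return (0, int(c))
    except ValueError as exc:
        raise ValueError(f"unrecognized chromosome label: {chrom!r}") from exc


def _normalize_chrom(chrom: object) -> str:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.upper() == "X" else c


@dataclass
class SnpMatrix:
    """Biallelic SNP genotypes for an inbred panel, 0/1 coded, no missing data.

    ``alleles`` is SNP x strain.  Positions are 1-based bp and must be strictly
    increasing within each chromosome (in the row order given).
    """

    strains: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray([_normalize_chrom(c) for c in self.chrom], dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alleles = np.asarray(self.alleles)
        if self.alleles.shape != (len(self.snp_ids), len(self.strains)):
            raise ValueError("allele matrix shape does not match snp/strain ids")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("alleles must be 0/1 with no missing values")
        self.alleles = self.alleles.astype(np.uint8)
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpMatrix":
        """Build from a wide table: id, chromosome, position columns then strains."""
        cols = {c.lower(): c for c in df.columns}
        id_c = cols.get("id", df.columns[0])
        chr_c = cols.get("chromosome", cols.get("chr", df.columns[1]))
        pos_c = cols.get("position_bp", cols.get("pos", df.columns[2]))
        strain_cols = [c for c in df.columns if c not in (id_c, chr_c, pos_c)]
        return cls(
            strains=[str(s) for s in strain_cols],
            snp_ids=[str(s) for s in df[id_c]],
            chrom=df[chr_c].to_numpy(),
            pos=df[pos_c].to_numpy(),
            alleles=df[strain_cols].to_numpy(),
        )


@dataclass
class SdpPanel:
    """Distinct strain distribution patterns with their genomic anchors.

    Each SDP records the SNPs it compresses; its representative position is the
    median member-SNP position.  ``patterns`` is SDP x strain, 0/1.
    """

    strains: list[str]
    sdp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    patterns: np.ndarray
    member_ids: list[list[str]] = field(default_factory=list)
    member_pos: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = np.asarray([_normalize_chrom(c) for c in self.chrom], dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.patterns = np.asarray(self.patterns, dtype=np.uint8)
        if self.patterns.shape != (len(self.sdp_ids), len(self.strains)):
            raise ValueError("pattern matrix shape does not match sdp/strain ids")
        if not self.member_ids:
            self.member_ids = [[i] for i in self.sdp_ids]
        if not self.member_pos:
            self.member_pos = [np.array([p]) for p in self.pos]
        self.member_pos = [np.asarray(p, dtype=np.int64) for p in self.member_pos]

    @property
    def n_sdps(self) -> int:
        return len(self.sdp_ids)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def span(self, i: int) -> tuple[int, int]:
        """Widest member-SNP extent of SDP ``i`` (used to expand point intervals)."""
        mp = self.member_pos[i]
        return int(mp.min()), int(mp.max())

    def genome_order(self) -> np.ndarray:
        """Stable ordering by (chromosome 1..19 then X, representative position)."""
        keys = [(chromosome_rank(c), int(p)) for c, p in zip(self.chrom, self.pos)]
        return np.array(sorted(range(self.n_sdps), key=lambda i: keys[i]), dtype=int)

    def reorder(self, idx: np.ndarray) -> "SdpPanel":
        return SdpPanel(
            strains=self.strains,
            sdp_ids=[self.sdp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            patterns=self.patterns[idx],
            member_ids=[self.member_ids[i] for i in idx],
            member_pos=[self.member_pos[i] for i in idx],
        )

    def index_of(self, sdp_id: str) -> int:
        try:
            return self.sdp_ids.index(sdp_id)
        except ValueError as exc:
            raise KeyError(f"unknown SDP id: {sdp_id}") from exc

    # ---- I/O: genotype CSV (rows=SDP, cols=strains) + map TSV ----

    def to_genotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.patterns, index=self.sdp_ids, columns=self.strains)

    def to_map_frame(self) -> pd.DataFrame:
        spans = [self.span(i) for i in range(self.n_sdps)]
        return pd.DataFrame(
            {
                "id": self.sdp_ids,
                "chromosome": self.chrom,
                "position_bp": self.pos,
                "span_start_bp": [s[0] for s in spans],
                "span_end_bp": [s[1] for s in spans],
                "n_member_snps": [len(m) for m in self.member_ids],
            }
        )

    def write(self, genotype_csv: str, map_tsv: str) -> None:
        self.to_genotype_frame().to_csv(genotype_csv, index_label="id")
        self.to_map_frame().to_csv(map_tsv, sep="\t", index=False)

    @classmethod
    def read(cls, genotype_csv: str, map_tsv: str) -> "SdpPanel":
        geno = pd.read_csv(genotype_csv, index_col=0)
        gmap = pd.read_csv(map_tsv, sep="\t", dtype={"chromosome": str})
        gmap = gmap.set_index("id").loc[geno.index]
        lo = gmap.get("span_start_bp", gmap["position_bp"])
        hi = gmap.get("span_end_bp", gmap["position_bp"])
        return cls(
            strains=[str(c) for c in geno.columns],
            sdp_ids=[str(i) for i in geno.index],
            chrom=gmap["chromosome"].to_numpy(),
            pos=gmap["position_bp"].to_numpy(),
            patterns=geno.to_numpy(),
            member_ids=[[str(i)] for i in geno.index],
            member_pos=[np.array([a, b]) for a, b in zip(lo, hi)],
        )


def _median_bp(positions: np.ndarray) -> int:
    """Median member position; even counts use the mean of the two middle
    positions rounded to the nearest integer bp."""
    m = float(np.median(positions))
    return int(np.floor(m + 0.5))


def collapse_to_sdps(snps: SnpMatrix) -> SdpPanel:
    """Compress SNPs sharing a (chromosome, strain-pattern) into one SDP.

    Monomorphic SNPs are uninformative for mapping and are dropped with a
    warning.  SDPs are ordered by genome position of their first member SNP;
    the representative position is the median member position.  Identical
    patterns on *different* chromosomes stay separate SDPs, so every SDP has a
    single genomic location.
    """
    colsum = snps.alleles.sum(axis=1)
    mono = (colsum == 0) | (colsum == len(snps.strains))
    if mono.any():
        log.warning("excluding %d monomorphic SNPs from SDP compression", int(mono.sum()))

    groups: dict[tuple, list[int]] = {}
    for i in np.nonzero(~mono)[0]:
        key = (snps.chrom[i], snps.alleles[i].tobytes())
        groups.setdefault(key, []).append(int(i))

    # genome order of first member SNP
    ordered = sorted(
        groups.values(),
        key=lambda idx: (chromosome_rank(snps.chrom[idx[0]]), int(snps.pos[idx[0]])),
    )
    sdp_ids, chroms, poss, member_ids, member_pos, patterns = [], [], [], [], [], []
    for k, idx in enumerate(ordered):
        mp = snps.pos[idx]
        sdp_ids.append(f"sdp{k:05d}")
        chroms.append(snps.chrom[idx[0]])
        poss.append(_median_bp(mp))
        member_ids.append([snps.snp_ids[i] for i in idx])
        member_pos.append(np.sort(mp))
        patterns.append(snps.alleles[idx[0]])
    return SdpPanel(
        strains=list(snps.strains),
        sdp_ids=sdp_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        patterns=np.array(patterns, dtype=np.uint8),
        member_ids=member_ids,
        member_pos=member_pos,
    )


def genome_order(panel: SdpPanel) -> np.ndarray:
    """Stable genome ordering of a panel's SDPs (chr 1..19 then X, position)."""
    return panel.genome_order()
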