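"""Bin-based eQTL hotspot detection with a Poisson count threshold.

The genome-ordered SDP list is cut into non-overlapping bins of ``width``
SDPs.  Under a uniform scatter of eQTL, the count in a bin is Poisson with
mean lambda = (number of eligible eQTL) / (number of bins); a bin is a
hotspot when its count reaches the smallest k whose upper-tail probability
falls below a Bonferroni-corrected alpha over the bins.  Eligibility uses the
raw single-test p of each trait's peak (Bonferroni over traits x SDPs), and
adjacent significant bins on one chromosome are merged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import SdpPanel, chromosome_rank

log = logging.getLogger(__name__)

__all__ = ["Bin", "BinGrid", "Hotspot", "make_bins", "poisson_threshold", "detect_hotspots"]


@dataclass
class Bin:
    index: int
    sdp_indices: list[int]
    chromosomes: list[str]
    start_bp: int
    end_bp: int


@dataclass
class BinGrid:
    bins: list[Bin]
    width: int

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_of(self) -> dict[int, int]:
        """Map original SDP index -> bin index."""
        return {s: b.index for b in self.bins for s in b.sdp_indices}


@dataclass
class Hotspot:
    chromosome: str
    start_bp: int
    end_bp: int
    n_eqtl: int
    traits: list[str]
    bin_indices: list[int]

    @property
    def start_mb(self) -> float:
        return round(self.start_bp / 1e6, 1)

    @property
    def end_mb(self) -> float:
        return round(self.end_bp / 1e6, 1)


def make_bins(panel: SdpPanel, width: int = 4, cross_chromosomes: bool = False) -> BinGrid:
    """Cut the genome-ordered SDPs into runs of ``width``.

    By default runs restart at each chromosome boundary so a bin never
    straddles chromosomes; ``cross_chromosomes=True`` uses plain division of
    the genome-ordered list instead.  The genomic span of a bin is the
    [min, max] of its members' representative positions.
    """
    if width < 1:
        raise ValueError("bin width must be at least 1")
    order = panel.genome_order()
    if cross_chromosomes:
        runs = [order[i : i + width] for i in range(0, len(order), width)]
    else:
        runs = []
        by_chr: dict[str, list[int]] = {}
        for i in order:
            by_chr.setdefault(str(panel.chrom[i]), []).append(i)
        for c in sorted(by_chr, key=chromosome_rank):
            idx = by_chr[c]
            runs.extend(idx[i : i + width] for i in range(0, len(idx), width))
    bins = []
    for k, run in enumerate(runs):
        run = list(run)
        pos = panel.pos[run]
        bins.append(
            Bin(
                index=k,
                sdp_indices=run,
                chromosomes=sorted({str(panel.chrom[i]) for i in run}, key=chromosome_rank),
                start_bp=int(pos.min()),
                end_bp=int(pos.max()),
            )
        )
    return BinGrid(bins=bins, width=width)


def poisson_threshold(n_eqtl: int, n_bins: int, alpha: float = 0.05) -> int:
    """Smallest count k with P(X >= k; lambda) < alpha/n_bins, lambda = n_eqtl/n_bins."""
    if n_bins < 1:
        raise ValueError("need at least one bin")
    if n_eqtl < 0:
        raise ValueError("negative eQTL count")
    cut = alpha / n_bins
    if cut >= 1.0 or n_eqtl == 0:
        return 1
    lam = n_eqtl / n_bins
    k = 1
    while stats.poisson.sf(k - 1, lam) >= cut:
        k += 1
    return k


def detect_hotspots(
    hits: pd.DataFrame,
    grid: BinGrid,
    panel: SdpPanel,
    n_traits: int,
    alpha: float = 0.05,
    peak_alpha: float = 0.05,
) -> tuple[list[Hotspot], dict]:
    """Find bins whose eligible-eQTL count clears the Poisson threshold.

    ``hits`` carries one peak per trait with columns ``sdp`` (id) and
    ``raw_p`` (single-test marker-regression p).  Eligibility is the
    Bonferroni rule raw_p < peak_alpha / (n_traits * n_SDPs).  Adjacent
    significant bins (consecutive bin indices on one chromosome) are merged,
    counting distinct traits.  Returns the hotspots plus a detail dict with
    the eligibility threshold, lambda and minimum count.
    """
    per_test = peak_alpha / (n_traits * panel.n_sdps)
    eligible = hits[hits["raw_p"] < per_test]
    sdp_to_bin = grid.bin_of()
    id_to_idx = {sid: i for i, sid in enumerate(panel.sdp_ids)}
    counts: dict[int, list[str]] = {}
    for trait, row in eligible.iterrows():
        b = sdp_to_bin[id_to_idx[row["sdp"]]]
        counts.setdefault(b, []).append(str(trait))
    k_min = poisson_threshold(len(eligible), grid.n_bins, alpha=alpha)
    sig = sorted(b for b, traits in counts.items() if len(traits) >= k_min)

    hotspots: list[Hotspot] = []
    run: list[int] = []
    for b in sig:
        same_chrom = (
            run
            and b == run[-1] + 1
            and grid.bins[b].chromosomes == grid.bins[run[-1]].chromosomes
        )
        if same_chrom:
            run.append(b)
        else:
            if run:
                hotspots.append(_merge(run, grid, counts))
            run = [b]
    if run:
        hotspots.append(_merge(run, grid, counts))
    detail = {
        "per_test_threshold": per_test,
        "n_eligible": int(len(eligible)),
        "poisson_mean": len(eligible) / grid.n_bins,
        "min_count": k_min,
        "n_bins": grid.n_bins,
    }
    return hotspots, detail


def _merge(run: list[int], grid: BinGrid, counts: dict[int, list[str]]) -> Hotspot:
    traits = sorted({t for b in run for t in counts.get(b, [])})
    bins = [grid.bins[b] for b in run]
    chroms = sorted({c for b in bins for c in b.chromosomes}, key=chromosome_rank)
    if len(chroms) > 1:
        log.warning("merged hotspot spans chromosomes %s", chroms)
    return Hotspot(
        chromosome=",".join(chroms),
        start_bp=min(b.start_bp for b in bins),
        end_bp=max(b.end_bp for b in bins),
        n_eqtl=len(traits),
        traits=traits,
        bin_indices=list(run),
    )


def hotspots_table(hotspots: list[Hotspot]) -> pd.DataFrame:
    """Report table: name, chromosome, start/end in Mb, number of eQTL."""
    return pd.DataFrame(
        [
            {
                "name": f"Hotspot-chr{h.chromosome}",
                "chromosome": h.chromosome,
                "start_mb": h.start_mb,
                "end_mb": h.end_mb,
                "n_eqtl": h.n_eqtl,
            }
            for h in hotspots
        ],
        columns=["name", "chromosome", "start_mb", "end_mb", "n_eqtl"],
    )
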