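"""Characterization of significant eQTL: heritability, group contrasts,
and phenotype associations.

Heritability of a trait on an inbred panel is estimated by the intraclass
correlation (ICC) from a one-way random-effects ANOVA on the replicate layer.
eQTL strength (LOD) is contrasted between groups of hits (cis vs trans,
annotated vs novel, intronic vs non-intronic, highly vs lowly conserved) with
Wilcoxon rank-sum tests, and related to heritability by Spearman correlation.
Phenotype associations use Spearman correlation on strain means with a BH-FDR
filter, plus a simple-regression behavioral QTL test at the eQTL's own SDP.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import fdr_adjust

log = logging.getLogger(__name__)

__all__ = [
    "icc",
    "rank_sum",
    "spearman",
    "compare_groups",
    "phenotype_assoc",
    "bqtl",
]


def icc(values, strains) -> float:
    """One-way random-effects intraclass correlation (method of moments).

    With a strains, group sizes n_i, N total and the unbalanced-design
    coefficient k0 = (N - sum n_i^2 / N) / (a - 1),

        ICC = (MSB - MSW) / (MSB + (k0 - 1) * MSW),

    truncated to [0, 1].  Degenerate data with no variance at all gives 0.
    """
    values = np.asarray(values, dtype=float)
    strains = np.asarray(strains)
    groups = pd.unique(strains)
    if len(groups) < 2:
        raise ValueError("need at least 2 strains")
    sizes = np.array([(strains == g).sum() for g in groups], dtype=float)
    if not (sizes >= 2).any():
        raise ValueError("need at least one strain with 2+ replicates")
    if np.ptp(values) == 0:
        return 0.0
    N, a = float(len(values)), float(len(groups))
    grand = values.mean()
    means = np.array([values[strains == g].mean() for g in groups])
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(sum(((values[strains == g] - m) ** 2).sum() for g, m in zip(groups, means)))
    msb = ssb / (a - 1)
    msw = ssw / (N - a) if N > a else 0.0
    k0 = (N - (sizes**2).sum() / N) / (a - 1)
    denom = msb + (k0 - 1.0) * msw
    if denom <= 0:
        return 0.0
    return float(np.clip((msb - msw) / denom, 0.0, 1.0))


def rank_sum(group_a, group_b) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) of the FIRST group, two-sided.

    Returns (W, p) where W = #{(a,b): a > b} + half-ties.  The p-value is
    exact (full enumeration of the rank distribution) when there are no ties
    and the product of group sizes is modest, otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "asymptotic" if (ties or len(a) * len(b) > 1_000_000) else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def compare_groups(hits: pd.DataFrame, conservation_cut: float = 0.5) -> pd.DataFrame:
    """Rank-sum contrasts of eQTL LOD between annotation groups.

    ``hits`` needs columns lod, cis_trans (cis/trans or C/T), annotation
    (A/N), mirna_type (I/N) and conservation (float, NaN allowed).  First
    groups are cis, annotated, intronic and high-conservation.  Missing
    conservation scores are excluded listwise from that contrast only.  A
    contrast with an empty group is skipped with a note.  The Spearman
    correlation between LOD and ICC is appended when an ``icc`` column exists.
    """
    lod = hits["lod"].to_numpy(dtype=float)

    def norm(col, first_tokens):
        vals = hits[col].astype(str).str.upper().str.slice(0, 1)
        return vals.isin(first_tokens).to_numpy()

    masks = {
        "cis_vs_trans": (norm("cis_trans", {"C"}), np.ones(len(hits), bool)),
        "annotated_vs_novel": (norm("annotation", {"A"}), np.ones(len(hits), bool)),
        "intronic_vs_nonintronic": (norm("mirna_type", {"I"}), np.ones(len(hits), bool)),
    }
    if "conservation" in hits:
        cons = hits["conservation"].to_numpy(dtype=float)
        scored = np.isfinite(cons)
        masks["high_vs_low_conservation"] = (scored & (cons > conservation_cut), scored)
    rows = []
    for name, (first, keep) in masks.items():
        ga, gb = lod[keep & first], lod[keep & ~first]
        if len(ga) == 0 or len(gb) == 0:
            log.warning("comparison %s skipped: a group is empty", name)
            rows.append({"comparison": name, "n_first": len(ga), "n_second": len(gb),
                         "W": np.nan, "p": np.nan, "note": "skipped: empty group"})
            continue
        w, p = rank_sum(ga, gb)
        rows.append({"comparison": name, "n_first": len(ga), "n_second": len(gb),
                     "W": w, "p": p, "note": ""})
    if "icc" in hits:
        iccs = hits["icc"].to_numpy(dtype=float)
        if len(hits) >= 3 and np.ptp(lod) > 0 and np.ptp(iccs) > 0:
            rho, p = spearman(lod, iccs)
            rows.append({"comparison": "spearman_lod_icc", "n_first": len(hits),
                         "n_second": len(hits), "W": rho, "p": p,
                         "note": "rho in W column"})
        else:
            log.warning("LOD~ICC correlation skipped: too few or constant values")
            rows.append({"comparison": "spearman_lod_icc", "n_first": len(hits),
                         "n_second": len(hits), "W": np.nan, "p": np.nan,
                         "note": "skipped: too few or constant values"})
    return pd.DataFrame(rows).set_index("comparison")


def phenotype_assoc(
    mirna_means: pd.DataFrame, phenotypes: pd.DataFrame, fdr: float = 0.2
) -> pd.DataFrame:
    """Spearman association of each miRNA with each phenotype on strain means.

    BH q-values are computed per phenotype across miRNAs; rows with q below
    ``fdr`` are flagged.  Requires at least 10 shared strains.
    """
    if isinstance(phenotypes, pd.Series):
        phenotypes = phenotypes.to_frame()
    shared = [s for s in mirna_means.columns if s in phenotypes.index]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared strains; need at least 10")
    rows = []
    for ph in phenotypes.columns:
        pv = phenotypes.loc[shared, ph].to_numpy(dtype=float)
        stats_rows = []
        for feat in mirna_means.index:
            rho, p = spearman(mirna_means.loc[feat, shared].to_numpy(dtype=float), pv)
            stats_rows.append((feat, rho, p))
        # a perfectly monotone association yields p = 0 exactly; keep BH happy
        q = fdr_adjust(np.clip([r[2] for r in stats_rows], 1e-300, 1.0))
        for (feat, rho, p), qq in zip(stats_rows, q):
            rows.append({"mirna": feat, "phenotype": ph, "rho": rho, "p": p,
                         "q": qq, "significant": qq < fdr})
    return pd.DataFrame(rows)


def bqtl(phenotype, genotype) -> tuple[float, float]:
    """Behavioral QTL: OLS slope of a phenotype on a 0/1 SDP genotype.

    Returns (slope, two-sided p) from simple linear regression.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(genotype, dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("monomorphic genotype")
    res = stats.linregress(g, y)
    return float(res.slope), float(res.pvalue)
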