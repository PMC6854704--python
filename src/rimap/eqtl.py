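"""Single-marker eQTL mapping on strain distribution patterns.

The model is marker regression with no covariates: for each trait y (strain
means) and each SDP g in {0,1},

    LOD = (n/2) * log10(RSS0 / RSS1)

where RSS0 is the residual sum of squares about the grand mean and RSS1 about
the two genotype-group means.  Each trait keeps its single genome-wide peak;
significance combines a genome-wide permutation p-value for the max-LOD
statistic (with the exact-test correction p = (b+1)/(B+1), so p is never zero)
and a Benjamini-Hochberg FDR across traits.  A 95% Bayes credible interval is
formed on the peak chromosome from the normalized 10^LOD profile, and peaks
are labelled cis/trans by a 5-Mb window around the trait's own locus.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionSet
from .genotypes import SdpPanel, chromosome_rank

log = logging.getLogger(__name__)

__all__ = [
    "LodProfile",
    "PermutationResult",
    "EqtlScan",
    "EqtlScanResults",
    "lod_scores",
    "peak_hit",
    "permutation_pvalue",
    "fdr_adjust",
    "credible_interval",
    "classify_cis_trans",
    "resolve_multilocation",
    "lod_to_pvalue",
]

DEFAULT_LOD_CAP = 50.0
CIS_WINDOW_BP = 5_000_000
MIN_GROUP = 2


@dataclass
class LodProfile:
    """Per-SDP LOD scores for one trait; skipped SDPs carry NaN."""

    trait: str
    lod: np.ndarray
    n_strains: int
    cap: float = DEFAULT_LOD_CAP

    def max(self) -> float:
        return float(np.nanmax(self.lod))


@dataclass
class PermutationResult:
    p: float
    b: int
    n_perm: int
    max_lod: float


def _design(panel: SdpPanel) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Genotype matrix as float plus group sizes and a validity mask."""
    G = panel.patterns.astype(np.float64)
    n1 = G.sum(axis=1)
    n0 = panel.n_strains - n1
    valid = (n1 >= MIN_GROUP) & (n0 >= MIN_GROUP)
    return G, n1, n0, valid


def _lod_matrix(
    Y: np.ndarray, G: np.ndarray, n1: np.ndarray, n0: np.ndarray, cap: float
) -> np.ndarray:
    """LOD for every (SDP, trait-vector) pair; Y is (B x n), result (S x B)."""
    n = Y.shape[1]
    tot = Y.sum(axis=1)
    rss0 = (Y**2).sum(axis=1) - tot**2 / n
    s1 = G @ Y.T  # S x B
    s0 = tot[None, :] - s1
    rss1 = (Y**2).sum(axis=1)[None, :] - s1**2 / n1[:, None] - s0**2 / n0[:, None]
    rss1 = np.maximum(rss1, 0.0)
    with np.errstate(divide="ignore"):
        lod = (n / 2.0) * np.log10(rss0[None, :] / np.maximum(rss1, 1e-300))
    return np.minimum(lod, cap)


def lod_scores(y, panel: SdpPanel, cap: float = DEFAULT_LOD_CAP, trait: str = "") -> LodProfile:
    """Marker-regression LOD at every SDP for one strain-mean trait.

    SDPs with a genotype group below 2 strains are skipped (NaN) with a
    warning; a perfectly separating SDP (RSS1 = 0) is capped at ``cap``.
    """
    y = _as_vector(y, panel)
    if np.ptp(y) == 0:
        raise ValueError(f"constant trait{': ' + trait if trait else ''}")
    G, n1, n0, valid = _design(panel)
    if not valid.all():
        log.warning(
            "trait %s: skipping %d SDPs with a genotype group below %d strains",
            trait or "<anon>", int((~valid).sum()), MIN_GROUP,
        )
    lod = _lod_matrix(y[None, :], G, np.maximum(n1, 1), np.maximum(n0, 1), cap)[:, 0]
    if (lod >= cap).any():
        log.warning("trait %s: %d LOD scores capped at %g", trait or "<anon>",
                    int((lod >= cap).sum()), cap)
    lod[~valid] = np.nan
    return LodProfile(trait=trait, lod=lod, n_strains=panel.n_strains, cap=cap)


def _as_vector(y, panel: SdpPanel) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [s for s in panel.strains if s not in y.index]
        if missing:
            raise ValueError(f"trait is missing strains: {missing}")
        y = y.reindex(panel.strains)
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (panel.n_strains,):
        raise ValueError("trait must have one value per strain")
    return y


def peak_hit(profile: LodProfile, panel: SdpPanel) -> tuple[int, float]:
    """Genome-wide argmax SDP index (original indexing); ties break by genome order."""
    order = panel.genome_order()
    lods = profile.lod[order]
    best = np.nanmax(lods)
    first = int(np.nonzero(lods == best)[0][0])
    return int(order[first]), float(best)


def permutation_pvalue(
    y,
    panel: SdpPanel,
    B: int = 1000,
    seed: int = 0,
    trait: str = "",
    cap: float = DEFAULT_LOD_CAP,
) -> PermutationResult:
    """Genome-wide permutation p for the max-LOD statistic of one trait.

    Strain labels are permuted; one shared permutation schedule covers all
    SDPs, so the null respects the genome-wide maximum.  The reported p is the
    exact-test estimate (b+1)/(B+1), which can never be zero.  The permutation
    stream is derived from the global seed and a stable hash of the trait id,
    so traits can be mapped in any order (or in parallel) reproducibly.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    y = _as_vector(y, panel)
    profile = lod_scores(y, panel, cap=cap, trait=trait)
    obs = profile.max()
    G, n1, n0, valid = _design(panel)
    Gv, n1v, n0v = G[valid], n1[valid], n0[valid]
    rng = _trait_rng(seed, trait)
    Yperm = rng.permuted(np.tile(y, (B, 1)), axis=1)
    null_max = _lod_matrix(Yperm, Gv, n1v, n0v, cap).max(axis=0)
    b = int((null_max >= obs).sum())
    return PermutationResult(p=(b + 1) / (B + 1), b=b, n_perm=B, max_lod=obs)


def _trait_rng(seed: int, trait: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(trait.encode())])
    )


def fdr_adjust(pvalues, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``m_total`` lets the correction count tests beyond those supplied (used
    when re-deriving q-values for a reported subset of a larger family of
    traits, assuming the omitted p-values fall above the step-up boundary).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if m_total is None:
        return multipletests(p, method="fdr_bh")[1]
    if m_total < len(p):
        raise ValueError("m_total smaller than number of p-values supplied")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_total / np.arange(1, len(p) + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def credible_interval(
    profile: LodProfile, panel: SdpPanel, coverage: float = 0.95
) -> tuple[int, int]:
    """Bayes credible interval on the peak chromosome.

    Posterior mass at each SDP is proportional to 10^LOD, normalized over the
    peak's chromosome.  SDPs are accumulated in decreasing-mass order (ties by
    genome order) until the target coverage is reached; the interval is the
    [min, max] representative position of the accumulated set.  A zero-width
    (single-SDP) interval is expanded to that SDP's widest member-SNP span.
    """
    peak_idx, _ = peak_hit(profile, panel)
    chrom = panel.chrom[peak_idx]
    order = panel.genome_order()
    on_chr = [i for i in order if panel.chrom[i] == chrom and np.isfinite(profile.lod[i])]
    mass = np.power(10.0, [profile.lod[i] - profile.lod[peak_idx] for i in on_chr])
    mass = mass / mass.sum()
    take = sorted(range(len(on_chr)), key=lambda k: -mass[k])  # stable: ties keep genome order
    cum, chosen = 0.0, []
    for k in take:
        chosen.append(on_chr[k])
        cum += mass[k]
        if cum >= coverage:
            break
    pos = panel.pos[chosen]
    lo, hi = int(pos.min()), int(pos.max())
    if len(chosen) == 1:
        lo, hi = panel.span(chosen[0])
    return lo, hi


def classify_cis_trans(
    peak_chrom,
    peak_pos: float,
    feature_chrom,
    feature_pos: float | None,
    window_bp: int = CIS_WINDOW_BP,
) -> str:
    """Local/distal label: cis iff same chromosome and within ``window_bp``."""
    if feature_chrom is None or feature_pos is None or (
        isinstance(feature_pos, float) and np.isnan(feature_pos)
    ):
        return "unknown"
    if chromosome_rank(peak_chrom) != chromosome_rank(feature_chrom):
        return "trans"
    return "cis" if abs(float(peak_pos) - float(feature_pos)) <= window_bp else "trans"


def lod_to_pvalue(lod: float, n: int) -> float:
    """Raw single-test p of a marker-regression LOD via the monotone F map.

    F = (n-2) * (10^(2*LOD/n) - 1) with (1, n-2) degrees of freedom.
    """
    f = (n - 2) * (np.power(10.0, 2.0 * np.asarray(lod) / n) - 1.0)
    return stats.f.sf(f, 1, n - 2)


def resolve_multilocation(
    candidates: list[tuple[object, int]],
    profile: LodProfile,
    panel: SdpPanel,
    window_bp: int = CIS_WINDOW_BP,
) -> tuple[object, int]:
    """Pick one genomic location for a multi-copy miRNA.

    Rule 1: the candidate whose 5-Mb local window holds the strongest SDP
    found in any candidate's window.  Rule 2: if that SDP sits in several
    candidates' (shared) windows, the candidate nearest it.  Rule 3: if no SDP
    falls in any window, the candidate nearest the strongest SDP on a
    candidate chromosome.
    """
    if not candidates:
        raise ValueError("no candidate locations supplied")
    if len(candidates) == 1:
        return candidates[0]
    order = panel.genome_order()

    def strongest(indices: list[int]) -> int:
        best = max(np.nan_to_num(profile.lod[i], nan=-np.inf) for i in indices)
        for i in order:
            if i in indices and profile.lod[i] == best:
                return i
        raise AssertionError

    windows: list[list[int]] = []
    for chrom, pos in candidates:
        win = [
            i
            for i in range(panel.n_sdps)
            if chromosome_rank(panel.chrom[i]) == chromosome_rank(chrom)
            and abs(int(panel.pos[i]) - int(pos)) <= window_bp
            and np.isfinite(profile.lod[i])
        ]
        windows.append(win)
    union = sorted({i for w in windows for i in w})
    if union:
        best = strongest(union)
        holders = [k for k, w in enumerate(windows) if best in w]
        if len(holders) == 1:
            return candidates[holders[0]]
        dist = [abs(int(candidates[k][1]) - int(panel.pos[best])) for k in holders]
        return candidates[holders[int(np.argmin(dist))]]
    # rule 3: nearest candidate to the strongest SDP on any candidate chromosome
    cand_chroms = {chromosome_rank(c) for c, _ in candidates}
    on_chrom = [
        i
        for i in range(panel.n_sdps)
        if chromosome_rank(panel.chrom[i]) in cand_chroms and np.isfinite(profile.lod[i])
    ]
    if not on_chrom:
        raise ValueError("no SDPs on any candidate chromosome")
    best = strongest(on_chrom)
    dist = [
        abs(int(pos) - int(panel.pos[best]))
        if chromosome_rank(chrom) == chromosome_rank(panel.chrom[best])
        else np.inf
        for chrom, pos in candidates
    ]
    return candidates[int(np.argmin(dist))]


class EqtlScan:
    """Genome-wide eQTL scan of an expression set against an SDP panel.

    Parameters
    ----------
    expression : ExpressionSet
        Strain-mean traits; strains must cover the panel's strains.
    panel : SdpPanel
        Genotypes as strain distribution patterns.
    cis_window_bp : int
        Local/distal window around the trait's own locus.
    lod_cap : float
        Ceiling for degenerate (zero-residual) fits.

    ``fit`` runs the scan and returns :class:`EqtlScanResults`.
    """

    def __init__(
        self,
        expression: ExpressionSet,
        panel: SdpPanel,
        cis_window_bp: int = CIS_WINDOW_BP,
        lod_cap: float = DEFAULT_LOD_CAP,
    ) -> None:
        missing = [s for s in panel.strains if s not in expression.means.columns]
        if missing:
            raise ValueError(f"expression data is missing panel strains: {missing}")
        self.expression = expression.align(panel.strains)
        self.panel = panel
        self.cis_window_bp = cis_window_bp
        self.lod_cap = lod_cap

    def fit(
        self,
        n_perm: int = 1000,
        seed: int = 0,
        fdr: float = 0.05,
        coverage: float = 0.95,
        keep_profiles: bool = False,
    ) -> "EqtlScanResults":
        rows, profiles = [], {}
        n = self.panel.n_strains
        for trait in self.expression.features:
            y = self.expression.means.loc[trait]
            profile = lod_scores(y, self.panel, cap=self.lod_cap, trait=trait)
            idx, lod = peak_hit(profile, self.panel)
            perm = permutation_pvalue(
                y, self.panel, B=n_perm, seed=seed, trait=trait, cap=self.lod_cap
            )
            lo, hi = credible_interval(profile, self.panel, coverage=coverage)
            label = "unknown"
            if self.expression.locations is not None and trait in self.expression.locations.index:
                locrow = self.expression.locations.loc[trait]
                label = classify_cis_trans(
                    self.panel.chrom[idx],
                    float(self.panel.pos[idx]),
                    locrow.get("chromosome"),
                    locrow.get("start_bp"),
                    window_bp=self.cis_window_bp,
                )
            rows.append(
                {
                    "trait": trait,
                    "sdp": self.panel.sdp_ids[idx],
                    "chromosome": self.panel.chrom[idx],
                    "position_bp": int(self.panel.pos[idx]),
                    "lod": lod,
                    "raw_p": float(lod_to_pvalue(lod, n)),
                    "perm_p": perm.p,
                    "perm_b": perm.b,
                    "n_perm": perm.n_perm,
                    "ci_lo_bp": lo,
                    "ci_hi_bp": hi,
                    "cis_trans": label,
                }
            )
            if keep_profiles:
                profiles[trait] = profile
        hits = pd.DataFrame(rows).set_index("trait")
        hits["q"] = fdr_adjust(hits["perm_p"].to_numpy())
        hits["significant"] = hits["q"] <= fdr
        return EqtlScanResults(self, hits, profiles, n_perm=n_perm, seed=seed, fdr=fdr)


class EqtlScanResults:
    """Peak-per-trait results of an :class:`EqtlScan`.

    ``hits`` is a DataFrame indexed by trait with the peak SDP, LOD,
    permutation p, BH q, credible interval and cis/trans label.
    """

    def __init__(self, model, hits, profiles, n_perm, seed, fdr) -> None:
        self.model = model
        self.hits = hits
        self.profiles = profiles
        self.n_perm = n_perm
        self.seed = seed
        self.fdr = fdr

    @property
    def significant(self) -> pd.DataFrame:
        return self.hits[self.hits["significant"]]

    def summary(self) -> str:
        h = self.hits
        sig = h["significant"].sum()
        lines = [
            "eQTL scan results",
            "=================",
            f"traits mapped:        {len(h)}",
            f"strains:              {self.model.panel.n_strains}",
            f"SDPs:                 {self.model.panel.n_sdps}",
            f"permutations:         {self.n_perm} (seed {self.seed})",
            f"significant (q<={self.fdr:g}): {sig}",
        ]
        if sig:
            lab = self.significant["cis_trans"].value_counts().to_dict()
            lines.append(f"cis/trans among significant: {lab}")
        return "\n".join(lines)

    def to_table(self) -> pd.DataFrame:
        """Report table in the conventional layout (positions in Mb, 1 decimal)."""
        h = self.hits
        return pd.DataFrame(
            {
                "trait": h.index,
                "eqtl_chr": h["chromosome"].to_numpy(),
                "eqtl_pos_mb": (h["position_bp"] / 1e6).round(1).to_numpy(),
                "ci_lo_mb": (h["ci_lo_bp"] / 1e6).round(1).to_numpy(),
                "ci_hi_mb": (h["ci_hi_bp"] / 1e6).round(1).to_numpy(),
                "lod": h["lod"].round(2).to_numpy(),
                "genomewide_p": h["perm_p"].round(4).to_numpy(),
                "fdr": h["q"].round(4).to_numpy(),
                "cis_trans": h["cis_trans"].to_numpy(),
            }
        ).set_index("trait")

    def write(self, path: str) -> None:
        self.to_table().to_csv(path, sep="\t")

    def plot_lod(self, trait: str, ax=None):
        """LOD profile of one trait along the genome (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if trait not in self.profiles:
            raise KeyError(f"profile for {trait!r} not kept; refit with keep_profiles=True")
        panel = self.model.panel
        order = panel.genome_order()
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.plot(self.profiles[trait].lod[order], lw=0.8)
        ax.set_xlabel("SDP (genome order)")
        ax.set_ylabel("LOD")
        ax.set_title(trait)
        return ax
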