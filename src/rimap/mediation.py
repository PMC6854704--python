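"""Baron-Kenny mediation screening for SDP-miRNA-gene triplets.

Candidate triplets arise wherever a miRNA eQTL and a gene eQTL share an SDP;
both the miRNA and the gene are evaluated as mediator (causal and reverse
mediation).  For genotype g, mediator m and outcome y the linear structural
equations are

    m = alpha1 + a*g
    y = alpha2 + c*g            (total effect)
    y = alpha3 + c'*g + b*m     (direct effect c', mediator effect b)

with indirect effect a*b (identically c - c' in OLS).  A non-parametric
bootstrap over strains gives a percentile confidence interval for a*b; a
triplet is flagged when the interval excludes zero.  This stage is a filter
for network modelling, so no multiple-testing correction is applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "find_triplets",
    "fit_mediation",
    "bootstrap_ci",
    "MediationModel",
    "MediationResults",
    "MediationCoefficients",
]


def find_triplets(mi_hits: pd.DataFrame, g_hits: pd.DataFrame) -> pd.DataFrame:
    """All (sdp, miRNA, gene, mediator_role) candidates from shared SDPs.

    ``mi_hits`` and ``g_hits`` carry one peak per trait with columns ``sdp``
    (the hit index is the trait id).  miRNAs and genes at a common SDP are
    paired cartesianly, each pair enqueued twice: once with the miRNA as
    mediator (outcome = gene) and once with the gene as mediator.
    """
    mi = mi_hits.reset_index().rename(columns={mi_hits.index.name or "index": "mirna"})
    g = g_hits.reset_index().rename(columns={g_hits.index.name or "index": "gene"})
    joined = mi[["mirna", "sdp"]].merge(g[["gene", "sdp"]], on="sdp")
    rows = []
    for _, r in joined.iterrows():
        for role in ("mirna", "gene"):
            rows.append(
                {
                    "sdp": r["sdp"],
                    "mirna": r["mirna"],
                    "gene": r["gene"],
                    "mediator_role": role,
                    "mediator": r["mirna"] if role == "mirna" else r["gene"],
                    "outcome": r["gene"] if role == "mirna" else r["mirna"],
                }
            )
    return pd.DataFrame(
        rows, columns=["sdp", "mirna", "gene", "mediator_role", "mediator", "outcome"]
    )


@dataclass
class MediationCoefficients:
    a: float
    b: float
    c: float
    c_prime: float

    @property
    def indirect(self) -> float:
        return self.a * self.b


def _check_triplet(g: np.ndarray, m: np.ndarray, y: np.ndarray) -> None:
    if not (len(g) == len(m) == len(y)):
        raise ValueError("g, m, y must have equal length")
    for name, v in (("genotype", g), ("mediator", m), ("outcome", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"constant {name}")


def fit_mediation(g, m, y) -> MediationCoefficients:
    """OLS path coefficients for one triplet (closed form).

    Raises on constant variables or when the mediator is an exact linear
    function of the genotype (singular y ~ g + m design).
    """
    g = np.asarray(g, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_triplet(g, m, y)
    a, b, c, c_prime = _paths(g[None, :], m[None, :], y[None, :], strict=True)
    return MediationCoefficients(float(a[0]), float(b[0]), float(c[0]), float(c_prime[0]))


def _paths(G: np.ndarray, M: np.ndarray, Y: np.ndarray, strict: bool = False):
    """Vectorized path coefficients over rows of (G, M, Y)."""
    def cov(u, v):
        return (u * v).mean(axis=1) - u.mean(axis=1) * v.mean(axis=1)

    vg, vm = cov(G, G), cov(M, M)
    cgm, cgy, cmy = cov(G, M), cov(G, Y), cov(M, Y)
    a = cgm / vg
    c = cgy / vg
    det = vg * vm - cgm**2
    scale = np.maximum(vg * vm, 1e-300)
    singular = det <= 1e-12 * scale
    if strict and singular.any():
        raise ValueError("mediator is collinear with genotype; mediation model is singular")
    det = np.where(singular, np.nan, det)
    b = (vg * cmy - cgm * cgy) / det
    c_prime = (vm * cgy - cgm * cmy) / det
    return a, b, c, c_prime


def bootstrap_ci(
    g,
    m,
    y,
    n_boot: int = 1000,
    level: float = 0.995,
    seed: int = 0,
    return_draws: bool = False,
):
    """Percentile bootstrap interval for the indirect effect a*b.

    Strains are resampled with replacement; resamples with a constant
    genotype or mediator are redrawn (their number is logged).  Deterministic
    under ``seed``.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap iterations")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    g = np.asarray(g, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_triplet(g, m, y)
    n = len(g)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    redrawn = 0
    for _ in range(1000):
        G, M = g[idx], m[idx]
        bad = (np.ptp(G, axis=1) == 0) | (np.ptp(M, axis=1) == 0)
        if not bad.any():
            break
        redrawn += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    else:
        raise ValueError("could not draw non-degenerate bootstrap resamples")
    if redrawn:
        log.info("redrew %d degenerate bootstrap resamples", redrawn)
    a, b, _, _ = _paths(g[idx], m[idx], y[idx])
    draws = a * b
    draws = draws[np.isfinite(draws)]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    if return_draws:
        return float(lo), float(hi), draws
    return float(lo), float(hi)


class MediationModel:
    """Single-mediator linear SEM for one (genotype, mediator, outcome) triplet.

    ``fit`` estimates the path coefficients by OLS and bootstraps the
    indirect effect; the returned :class:`MediationResults` carries the
    coefficients, the CI and the significance flag (CI excludes zero).
    """

    def __init__(self, g, m, y, sdp: str = "", mediator: str = "", outcome: str = "") -> None:
        self.g = np.asarray(g, dtype=float)
        self.m = np.asarray(m, dtype=float)
        self.y = np.asarray(y, dtype=float)
        _check_triplet(self.g, self.m, self.y)
        self.sdp, self.mediator, self.outcome = sdp, mediator, outcome

    def fit(self, n_boot: int = 1000, level: float = 0.995, seed: int = 0) -> "MediationResults":
        coefs = fit_mediation(self.g, self.m, self.y)
        lo, hi = bootstrap_ci(self.g, self.m, self.y, n_boot=n_boot, level=level, seed=seed)
        return MediationResults(self, coefs, lo, hi, level=level, n_boot=n_boot)


class MediationResults:
    def __init__(self, model, coefs: MediationCoefficients, ci_lo, ci_hi, level, n_boot):
        self.model = model
        self.coefs = coefs
        self.ci = (ci_lo, ci_hi)
        self.level = level
        self.n_boot = n_boot

    @property
    def indirect(self) -> float:
        return self.coefs.indirect

    @property
    def significant(self) -> bool:
        lo, hi = self.ci
        return not (lo <= 0.0 <= hi)

    def summary(self) -> str:
        c = self.coefs
        lo, hi = self.ci
        return "\n".join(
            [
                "Mediation (Baron-Kenny LSEM)",
                "============================",
                f"triplet: {self.model.sdp or 'g'} -> "
                f"{self.model.mediator or 'm'} -> {self.model.outcome or 'y'}",
                f"a (g->m):        {c.a: .4f}",
                f"b (m->y | g):    {c.b: .4f}",
                f"c (total):       {c.c: .4f}",
                f"c' (direct):     {c.c_prime: .4f}",
                f"indirect (a*b):  {c.indirect: .4f}",
                f"{self.level:.1%} bootstrap CI ({self.n_boot} draws): "
                f"({lo:.4f}, {hi:.4f})",
                f"significant:     {self.significant}",
            ]
        )

    def row(self) -> dict:
        c = self.coefs
        return {
            "sdp": self.model.sdp,
            "mediator": self.model.mediator,
            "outcome": self.model.outcome,
            "a": c.a,
            "b": c.b,
            "c": c.c,
            "c_prime": c.c_prime,
            "indirect": c.indirect,
            "ci_lo": self.ci[0],
            "ci_hi": self.ci[1],
            "level": self.level,
            "significant": self.significant,
        }


def screen_triplets(
    triplets: pd.DataFrame,
    panel,
    mirna,
    mrna,
    n_boot: int = 1000,
    level: float = 0.995,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every candidate triplet and collect one row per fit."""
    rows = []
    for k, t in triplets.iterrows():
        g = panel.patterns[panel.index_of(t["sdp"])].astype(float)
        med_block = mirna if t["mediator"] in set(mirna.features) else mrna
        out_block = mirna if t["outcome"] in set(mirna.features) else mrna
        model = MediationModel(
            g,
            med_block.means.loc[t["mediator"]].to_numpy(dtype=float),
            out_block.means.loc[t["outcome"]].to_numpy(dtype=float),
            sdp=t["sdp"],
            mediator=t["mediator"],
            outcome=t["outcome"],
        )
        res = model.fit(n_boot=n_boot, level=level, seed=seed + int(k))
        row = res.row()
        row["mirna"] = t["mirna"]
        row["gene"] = t["gene"]
        row["mediator_role"] = t["mediator_role"]
        rows.append(row)
    return pd.DataFrame(rows)
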