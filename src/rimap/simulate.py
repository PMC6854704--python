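"""Synthetic recombinant-inbred panels with known ground truth.

The generator emulates an LXS-like mouse panel: 59 inbred strains, 2-3
replicates per strain, biallelic SNPs at roughly 50:50 allele frequency, and
local linkage modelled as pattern persistence (the next SNP copies the
previous SNP's strain pattern with probability ``ld_persistence``), which
makes SNP-to-SDP compression non-trivial.  Expression is post-normalization
Gaussian at the replicate level,

    x[f, s, r] = beta * g(s) + u_s + eps_{s,r},

with the strain effect u_s ~ N(0, icc) and replicate noise
eps ~ N(0, 1 - icc), so the non-genetic intraclass correlation equals
``icc_target`` and planted genetic effects add to the strain-level variance.
Planted structures (cis/trans eQTL, a hotspot SDP controlling many miRNAs,
and mediation chains SDP -> mediator -> outcome) are recorded in truth
tables so every downstream stage can be validated against ground truth.

All randomness flows from one seed; each stage draws from its own
deterministic substream so stages can be re-run independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import ExpressionSet
from .genotypes import SdpPanel, SnpMatrix, collapse_to_sdps

__all__ = [
    "SimConfig",
    "PlantedEqtl",
    "HotspotSpec",
    "MediationChain",
    "SimulatedPanel",
    "simulate_genotypes",
    "simulate_expression",
    "plant_structures",
    "simulate_mediation_data",
    "simulate_panel",
    "beta_for_variance_fraction",
]


@dataclass(frozen=True)
class PlantedEqtl:
    """A genetic effect of ``beta`` expression-SD units of one SDP on one feature."""

    feature: str
    sdp: str
    beta: float
    kind: str = "cis"  # cis | trans: controls where the feature's locus is placed


@dataclass(frozen=True)
class HotspotSpec:
    """One SDP driving many miRNAs (a planted trans band)."""

    sdp: str
    features: tuple[str, ...]
    beta: float = 2.0


@dataclass(frozen=True)
class MediationChain:
    """A causal chain g -> mediator -> outcome with path coefficients a, b
    and direct effect c_direct; strain-level noise has SD ``noise_sd``."""

    sdp: str
    mediator: str
    outcome: str
    a: float
    b: float
    c_direct: float = 0.0
    noise_sd: float = 0.5


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults follow the emulated panel: 59 strains with 3 replicates,
    ~34,600 informative SNPs over 20 chromosomes collapsing to roughly 1,400
    SDPs (``ld_persistence=0.96`` gives ~71 pattern runs per chromosome of
    1,732 SNPs), 881 miRNAs, and moderately heritable expression
    (``icc_target=0.5``, the middle of the observed ICC range).
    """

    n_strains: int = 59
    n_reps: int = 3
    n_chromosomes: int = 20
    snps_per_chromosome: int = 1732
    chromosome_size_bp: int = 150_000_000
    ld_persistence: float = 0.96
    n_mirna: int = 881
    n_mrna: int = 3000
    planted_eqtl: tuple[PlantedEqtl, ...] = ()
    hotspot_spec: HotspotSpec | None = None
    mediation_spec: tuple[MediationChain, ...] = ()
    icc_target: float = 0.5
    phenotype_feature: str | None = None
    phenotype_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strains", "n_reps", "n_chromosomes", "snps_per_chromosome",
                     "n_mirna", "n_mrna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.ld_persistence <= 1.0:
            raise ValueError("ld_persistence must lie in [0, 1]")
        if not 0.0 <= self.icc_target < 1.0:
            raise ValueError("icc_target must lie in [0, 1)")

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i:04d}" for i in range(self.n_mirna)]

    def mrna_ids(self) -> list[str]:
        return [f"gene-{i:04d}" for i in range(self.n_mrna)]

    def _stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


@dataclass
class SimulatedPanel:
    """A generated panel plus the truth tables of everything planted."""

    genotypes: SdpPanel
    mirna: ExpressionSet
    mrna: ExpressionSet
    phenotype: pd.Series | None
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        feats = set(self.mirna.features) | set(self.mrna.features)
        sdps = set(self.genotypes.sdp_ids)
        for name in ("eqtl", "mediation"):
            if name in self.truth and len(self.truth[name]):
                t = self.truth[name]
                for col in [c for c in t.columns if c in ("feature", "mediator", "outcome")]:
                    bad = set(t[col]) - feats
                    if bad:
                        raise ValueError(f"truth table {name} references unknown features {bad}")
                bad = set(t["sdp"]) - sdps
                if bad:
                    raise ValueError(f"truth table {name} references unknown SDPs {bad}")


def simulate_genotypes(config: SimConfig) -> SdpPanel:
    """Simulate biallelic SNPs and collapse them to SDPs.

    Each chromosome starts from a fresh Bernoulli(1/2) strain pattern; every
    subsequent SNP copies the previous pattern with probability
    ``ld_persistence`` and otherwise draws a new one.  Monomorphic patterns
    are redrawn (the emulated genotype set contains informative SNPs only).
    """
    if config.n_strains < 4:
        raise ValueError("need at least 4 strains for mapping")
    rng = config._stage_rng(0)
    snp_ids, chroms, poss, alleles = [], [], [], []
    spacing = config.chromosome_size_bp // (config.snps_per_chromosome + 1)
    for c in range(1, config.n_chromosomes + 1):
        chrom = "X" if c == 20 else str(c)
        pattern = _polymorphic(rng, config.n_strains)
        pos = 0
        for j in range(config.snps_per_chromosome):
            pos += int(rng.integers(1, 2 * spacing))
            if j > 0 and rng.random() >= config.ld_persistence:
                pattern = _polymorphic(rng, config.n_strains)
            snp_ids.append(f"snp_{chrom}_{j:05d}")
            chroms.append(chrom)
            poss.append(pos)
            alleles.append(pattern.copy())
    snps = SnpMatrix(
        strains=[f"LXS{i:03d}" for i in range(1, config.n_strains + 1)],
        snp_ids=snp_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        alleles=np.array(alleles, dtype=np.uint8),
    )
    return collapse_to_sdps(snps)


def _polymorphic(rng: np.random.Generator, n: int) -> np.ndarray:
    while True:
        p = rng.integers(0, 2, size=n).astype(np.uint8)
        if 0 < p.sum() < n:
            return p


def beta_for_variance_fraction(
    fraction: float, icc: float, n_reps: int, freq: float = 0.5
) -> float:
    """Effect size giving a target genetic share of strain-mean variance.

    The strain-mean non-genetic variance is icc + (1-icc)/n_reps; a 0/1
    genotype at frequency ``freq`` contributes beta^2 * freq*(1-freq).
    """
    if not 0 <= fraction < 1:
        raise ValueError("variance fraction must lie in [0, 1)")
    resid = icc + (1.0 - icc) / n_reps
    return float(np.sqrt(fraction / (1.0 - fraction) * resid / (freq * (1.0 - freq))))


def _genetic_component(
    features: list[str], panel: SdpPanel, effects: dict[str, list[tuple[str, float]]]
) -> np.ndarray:
    out = np.zeros((len(features), panel.n_strains))
    for i, f in enumerate(features):
        for sdp, beta in effects.get(f, []):
            out[i] += beta * panel.patterns[panel.index_of(sdp)]
    return out


def simulate_expression(
    panel: SdpPanel, config: SimConfig
) -> tuple[ExpressionSet, ExpressionSet]:
    """Replicate-level expression for miRNAs and mRNAs (strain means attached).

    Planted eQTL and hotspot effects from the config are applied here; feature
    loci are placed near the driving SDP for cis effects, elsewhere for trans.
    """
    effects: dict[str, list[tuple[str, float]]] = {}
    for e in config.planted_eqtl:
        effects.setdefault(e.feature, []).append((e.sdp, e.beta))
    if config.hotspot_spec is not None:
        for f in config.hotspot_spec.features:
            effects.setdefault(f, []).append((config.hotspot_spec.sdp, config.hotspot_spec.beta))
    known = set(config.mirna_ids()) | set(config.mrna_ids())
    bad = set(effects) - known
    if bad:
        raise ValueError(f"planted effects reference unknown features: {bad}")
    for f, lst in effects.items():
        for sdp, _ in lst:
            panel.index_of(sdp)  # raises KeyError if absent

    mirna = _simulate_block(panel, config, config.mirna_ids(), effects, stage=1)
    mrna = _simulate_block(panel, config, config.mrna_ids(), effects, stage=2)
    return mirna, mrna


def _simulate_block(
    panel: SdpPanel,
    config: SimConfig,
    features: list[str],
    effects: dict[str, list[tuple[str, float]]],
    stage: int,
) -> ExpressionSet:
    rng = config._stage_rng(stage)
    nf, ns, nr = len(features), panel.n_strains, config.n_reps
    icc = config.icc_target
    gen = _genetic_component(features, panel, effects)
    u = rng.normal(0.0, np.sqrt(icc), size=(nf, ns)) if icc > 0 else np.zeros((nf, ns))
    eps = rng.normal(0.0, np.sqrt(1.0 - icc), size=(nf, ns, nr))
    reps = gen[:, :, None] + u[:, :, None] + eps
    cols = pd.MultiIndex.from_product([panel.strains, range(1, nr + 1)])
    rep_df = pd.DataFrame(reps.reshape(nf, ns * nr), index=features, columns=cols)
    locations = _place_features(panel, config, features, effects, rng)
    return ExpressionSet.from_replicates(rep_df, locations=locations)


def _place_features(
    panel: SdpPanel,
    config: SimConfig,
    features: list[str],
    effects: dict[str, list[tuple[str, float]]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign each feature a locus; cis-planted features sit near their SDP."""
    cis_sdp = {
        e.feature: e.sdp for e in config.planted_eqtl if e.kind == "cis"
    }
    trans_feats = {e.feature for e in config.planted_eqtl if e.kind == "trans"}
    if config.hotspot_spec is not None:
        trans_feats |= set(config.hotspot_spec.features)
    chroms = sorted(set(panel.chrom), key=lambda c: (str(c) != "X", str(c)))
    rows = []
    for f in features:
        if f in cis_sdp:
            i = panel.index_of(cis_sdp[f])
            chrom = panel.chrom[i]
            start = max(1, int(panel.pos[i]) + int(rng.integers(-1_000_000, 1_000_000)))
        else:
            chrom = chroms[rng.integers(0, len(chroms))]
            start = int(rng.integers(1, config.chromosome_size_bp))
            if f in trans_feats:
                sdp = (
                    config.hotspot_spec.sdp
                    if config.hotspot_spec and f in config.hotspot_spec.features
                    else next(e.sdp for e in config.planted_eqtl if e.feature == f)
                )
                i = panel.index_of(sdp)
                others = [c for c in chroms if c != panel.chrom[i]]
                chrom = others[rng.integers(0, len(others))]
        rows.append({"feature": f, "chromosome": chrom, "start_bp": start,
                     "end_bp": start + 21})
    return pd.DataFrame(rows).set_index("feature")


def simulate_mediation_data(
    n: int,
    a: float,
    b: float,
    c_direct: float = 0.0,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
    g: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One triplet (g, mediator, outcome) from the chain model.

    m = a*g + e_m,  y = c_direct*g + b*m + e_y, with e ~ N(0, noise_sd^2).
    The genotype is Bernoulli(1/2) unless supplied.
    """
    rng = rng or np.random.default_rng()
    if g is None:
        while True:
            g = rng.integers(0, 2, size=n).astype(float)
            if 0 < g.sum() < n:
                break
    m = a * g + rng.normal(0.0, noise_sd, size=n)
    y = c_direct * g + b * m + rng.normal(0.0, noise_sd, size=n)
    return g, m, y


def plant_structures(panel: SdpPanel, config: SimConfig) -> SimulatedPanel:
    """Generate expression with all planted structures and record truth tables.

    Mediation chains overwrite their mediator/outcome features at the strain
    level (replicate noise is re-added around the strain values), so the
    chains coexist with the planted eQTL/hotspot effects on other features.
    """
    if config.hotspot_spec is not None and len(config.hotspot_spec.features) < 7:
        raise ValueError("a planted hotspot must control at least 7 miRNAs")
    known = set(config.mirna_ids()) | set(config.mrna_ids())
    for ch in config.mediation_spec:
        for f in (ch.mediator, ch.outcome):
            if f not in known:
                raise ValueError(f"mediation chain references unknown feature: {f}")
        panel.index_of(ch.sdp)

    mirna, mrna = simulate_expression(panel, config)
    rng = config._stage_rng(3)
    rep_sd = np.sqrt(1.0 - config.icc_target)
    for ch in config.mediation_spec:
        g = panel.patterns[panel.index_of(ch.sdp)].astype(float)
        _, m, y = simulate_mediation_data(
            panel.n_strains, ch.a, ch.b, ch.c_direct, ch.noise_sd, rng=rng, g=g
        )
        for feat, strain_vals in ((ch.mediator, m), (ch.outcome, y)):
            block = mirna if feat in set(mirna.features) else mrna
            reps = np.repeat(strain_vals, config.n_reps) + rng.normal(
                0.0, rep_sd, size=panel.n_strains * config.n_reps
            )
            block.replicates.loc[feat] = reps
            block.means.loc[feat] = (
                np.asarray(reps).reshape(panel.n_strains, config.n_reps).mean(axis=1)
            )

    phenotype = None
    if config.phenotype_feature is not None:
        src = mirna if config.phenotype_feature in set(mirna.features) else mrna
        base = src.means.loc[config.phenotype_feature]
        phenotype = pd.Series(
            config.phenotype_effect * base.to_numpy()
            + rng.normal(0.0, 1.0, size=panel.n_strains),
            index=panel.strains,
            name="phenotype",
        )

    truth = {
        "eqtl": pd.DataFrame(
            [
                {"feature": e.feature, "sdp": e.sdp, "beta": e.beta, "kind": e.kind}
                for e in config.planted_eqtl
            ],
            columns=["feature", "sdp", "beta", "kind"],
        ),
        "hotspot": pd.DataFrame(
            [
                {"feature": f, "sdp": config.hotspot_spec.sdp,
                 "beta": config.hotspot_spec.beta}
                for f in (config.hotspot_spec.features if config.hotspot_spec else ())
            ],
            columns=["feature", "sdp", "beta"],
        ),
        "mediation": pd.DataFrame(
            [
                {
                    "sdp": ch.sdp, "mediator": ch.mediator, "outcome": ch.outcome,
                    "a": ch.a, "b": ch.b, "c_direct": ch.c_direct,
                    "indirect": ch.a * ch.b,
                }
                for ch in config.mediation_spec
            ],
            columns=["sdp", "mediator", "outcome", "a", "b", "c_direct", "indirect"],
        ),
    }
    return SimulatedPanel(
        genotypes=panel, mirna=mirna, mrna=mrna, phenotype=phenotype, truth=truth
    )


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Genotypes plus expression and truth tables in one call."""
    return plant_structures(simulate_genotypes(config), config)
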