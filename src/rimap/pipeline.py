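"""End-to-end driver: map -> characterize -> hotspots -> mediation -> networks."""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bayesnet import GaussianNetwork
from .characterize import compare_groups, icc, phenotype_assoc
from .eqtl import EqtlScan
from .expression import ExpressionSet
from .genotypes import SdpPanel
from .hotspot import detect_hotspots, hotspots_table, make_bins
from .mediation import find_triplets, screen_triplets

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds and counts for a full pipeline run."""

    genotype_csv: str
    map_tsv: str
    mirna_tsv: str
    mrna_tsv: str | None = None
    mirna_locations_tsv: str | None = None
    mrna_locations_tsv: str | None = None
    phenotype_tsv: str | None = None
    out_dir: str = "rimap_out"
    fdr: float = 0.05
    cis_window_bp: int = 5_000_000
    hotspot_alpha: float = 0.05
    bin_width: int = 4
    bins_cross_chromosomes: bool = False
    phenotype_fdr: float = 0.2
    mediation_level: float = 0.995
    network_threshold: float = 0.5
    n_perm: int = 1000
    n_boot_mediation: int = 1000
    n_boot_network: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr", "hotspot_alpha", "phenotype_fdr", "mediation_level",
                     "network_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("n_perm", "n_boot_mediation", "n_boot_network", "bin_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write its outputs under ``config.out_dir``.

    Returns a result bundle (DataFrames and objects keyed by stage).  The run
    is idempotent: the same config and seed reproduce every output byte for
    byte.  Strain consistency is checked before any stage runs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    panel = SdpPanel.read(config.genotype_csv, config.map_tsv)
    mirna = ExpressionSet.read(config.mirna_tsv, config.mirna_locations_tsv)
    mrna = None
    if config.mrna_tsv:
        mrna = ExpressionSet.read(config.mrna_tsv, config.mrna_locations_tsv)
    for name, ex in (("mirna", mirna), ("mrna", mrna)):
        if ex is None:
            continue
        missing = [s for s in panel.strains if s not in ex.means.columns]
        if missing:
            raise ValueError(f"{name} expression is missing strains {missing}")

    bundle: dict = {"config": asdict(config)}

    log.info("stage: miRNA eQTL scan (%d traits)", len(mirna.features))
    mi_res = EqtlScan(mirna, panel, cis_window_bp=config.cis_window_bp).fit(
        n_perm=config.n_perm, seed=config.seed, fdr=config.fdr
    )
    mi_res.write(out / "mi_eqtl.tsv")
    bundle["mi_eqtl"] = mi_res

    g_res = None
    if mrna is not None:
        log.info("stage: gene eQTL scan (%d traits)", len(mrna.features))
        g_res = EqtlScan(mrna, panel, cis_window_bp=config.cis_window_bp).fit(
            n_perm=config.n_perm, seed=config.seed, fdr=config.fdr
        )
        g_res.write(out / "g_eqtl.tsv")
        bundle["g_eqtl"] = g_res

    log.info("stage: characterization")
    char_in = mi_res.significant.copy()
    if mirna.replicates is not None:
        char_in["icc"] = [
            icc(*mirna.replicate_groups(t)) for t in char_in.index
        ]
    if not char_in.empty and "icc" in char_in:
        comp = compare_groups(char_in.assign(
            annotation=["N" if t.startswith("novel:") else "A" for t in char_in.index],
            mirna_type="N", conservation=float("nan"),
        ))
        comp.to_csv(out / "comparisons.tsv", sep="\t")
        bundle["comparisons"] = comp

    log.info("stage: hotspots")
    grid = make_bins(panel, width=config.bin_width,
                     cross_chromosomes=config.bins_cross_chromosomes)
    hs, hs_detail = detect_hotspots(
        mi_res.hits, grid, panel, n_traits=len(mirna.features),
        alpha=config.hotspot_alpha,
    )
    hotspots_table(hs).to_csv(out / "hotspots.tsv", sep="\t", index=False)
    bundle["hotspots"], bundle["hotspot_detail"] = hs, hs_detail

    if g_res is not None:
        log.info("stage: mediation")
        triplets = find_triplets(mi_res.significant, g_res.significant)
        screened = screen_triplets(
            triplets, panel, mirna, mrna,
            n_boot=config.n_boot_mediation, level=config.mediation_level,
            seed=config.seed,
        )
        screened.to_csv(out / "mediation.tsv", sep="\t", index=False)
        bundle["mediation"] = screened

        log.info("stage: networks")
        networks = {}
        sig = screened[screened["significant"]] if len(screened) else screened
        for sdp in sorted(set(sig["sdp"])) if len(sig) else []:
            rows = sig[sig["sdp"] == sdp]
            feats = sorted(set(rows["mediator"]) | set(rows["outcome"]))
            data = pd.DataFrame({sdp: panel.patterns[panel.index_of(sdp)].astype(float)},
                                index=panel.strains)
            types = {sdp: "sdp"}
            for f in feats:
                block = mirna if f in set(mirna.features) else mrna
                data[f] = block.means.loc[f].to_numpy(dtype=float)
                types[f] = "mirna" if block is mirna else "gene"
            net = GaussianNetwork(data, sdp_nodes=[sdp], node_types=types).fit_averaged(
                n_boot=config.n_boot_network, threshold=config.network_threshold,
                seed=config.seed,
            )
            networks[sdp] = net
            (out / f"network_{sdp}.json").write_text(net.to_json())
        bundle["networks"] = networks

    if config.phenotype_tsv:
        log.info("stage: phenotypes")
        pheno = pd.read_csv(config.phenotype_tsv, sep="\t", index_col=0)
        assoc = phenotype_assoc(mirna.means.loc[mi_res.significant.index], pheno,
                                fdr=config.phenotype_fdr)
        assoc.to_csv(out / "phenotype_assoc.tsv", sep="\t", index=False)
        bundle["phenotype_assoc"] = assoc
    else:
        log.info("phenotype file not given; phenotype stage skipped")

    manifest = {
        "rimap_version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
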