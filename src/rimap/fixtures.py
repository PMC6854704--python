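"""Packaged worked-example tables: the 38 significant brain miRNA eQTL.

``table1`` carries the eQTL themselves (peak chromosome/position, 95%
credible interval, LOD, genome-wide permutation p, FDR q, cis/trans label);
``table2`` the characteristics of the involved miRNAs (genomic location,
intronic flag, annotated/novel flag, PhastCons conservation with NA allowed,
ICC heritability, validated target count).  They drive the worked examples
and the re-derivation checks in the test-suite.
"""
from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["read_fixture_tables", "merged_fixture"]


def _read(name: str) -> tuple[str, pd.DataFrame]:
    ref = resources.files("rimap.data").joinpath(name)
    raw = ref.read_bytes()
    return hashlib.sha256(raw).hexdigest(), pd.read_csv(
        ref.open("r"), sep="\t", dtype={"eqtl_chr": str, "chr": str}
    )


def read_fixture_tables(verify: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load (table1, table2); validates shape, id correspondence and checksums."""
    d1, t1 = _read("table1.tsv")
    d2, t2 = _read("table2.tsv")
    if verify:
        expected = {
            "table1.tsv": "47d770914d3a905f883c9c321bfb4b033b80774a128eb81db64eb26b694c5323",
            "table2.tsv": "82209a842d4d360cf431902b22068a3d7c5ad00522d3054bf566a633e9dae18e",
        }
        for name, digest in (("table1.tsv", d1), ("table2.tsv", d2)):
            if digest != expected[name]:
                raise ValueError(f"fixture checksum mismatch for {name}")
    if len(t1) != 38 or len(t2) != 38:
        raise ValueError("fixture tables must have 38 rows each")
    if set(t1["mirna"]) != set(t2["mirna"]):
        raise ValueError("fixture miRNA ids do not correspond 1:1")
    return t1, t2


def merged_fixture() -> pd.DataFrame:
    """table1 joined with table2 on the miRNA id (38 rows)."""
    t1, t2 = read_fixture_tables()
    return t1.merge(t2, on="mirna")
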