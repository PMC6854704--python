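"""Expression containers: normalized strain means with an optional replicate layer.

Expression here is post-normalization and approximately Gaussian (the upstream
pipeline applies a variance-stabilizing transformation before collapsing mice
to strain averages).  Mapping runs on strain means; heritability (ICC) needs
the replicate layer.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionSet"]


@dataclass
class ExpressionSet:
    """Feature x strain expression matrix.

    ``means``       features x strains (strain averages), the mapping input.
    ``replicates``  optional features x samples with MultiIndex columns
                    (strain, rep); means are the per-strain average of this.
    ``locations``   optional per-feature genomic location (chromosome,
                    start_bp, end_bp) used for cis/trans classification.
    """

    means: pd.DataFrame
    replicates: pd.DataFrame | None = None
    locations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.means.index.has_duplicates:
            raise ValueError("duplicate feature ids in expression matrix")
        self.means.columns = [str(c) for c in self.means.columns]
        if self.locations is not None:
            missing = self.means.index.difference(self.locations.index)
            # features without a location are allowed; they classify as "unknown"
            self.locations = self.locations.reindex(self.means.index)
            _ = missing

    @property
    def features(self) -> list[str]:
        return list(self.means.index)

    @property
    def strains(self) -> list[str]:
        return list(self.means.columns)

    @classmethod
    def from_replicates(
        cls, replicates: pd.DataFrame, locations: pd.DataFrame | None = None
    ) -> "ExpressionSet":
        """Build from replicate-level data with (strain, rep) MultiIndex columns."""
        if not isinstance(replicates.columns, pd.MultiIndex):
            raise ValueError("replicate columns must be a (strain, rep) MultiIndex")
        means = replicates.T.groupby(level=0).mean().T
        means.columns = [str(c) for c in means.columns]
        return cls(means=means, replicates=replicates, locations=locations)

    def align(self, strains: list[str]) -> "ExpressionSet":
        """Restrict/reorder to the given strains; error on any that are absent."""
        missing = [s for s in strains if s not in self.means.columns]
        if missing:
            raise ValueError(f"strains absent from expression data: {missing}")
        reps = None
        if self.replicates is not None:
            keep = [c for c in self.replicates.columns if str(c[0]) in set(strains)]
            reps = self.replicates[keep]
        return ExpressionSet(self.means[strains], reps, self.locations)

    def replicate_groups(self, feature: str) -> tuple[np.ndarray, list]:
        """Replicate values and their strain labels for one feature."""
        if self.replicates is None:
            raise ValueError("no replicate layer available")
        row = self.replicates.loc[feature]
        return row.to_numpy(dtype=float), [str(s) for s, _ in row.index]

    # ---- TSV I/O (columns "strain" for means, "strain_<rep>" for replicates) ----

    def write_means(self, path: str) -> None:
        self.means.to_csv(path, sep="\t", index_label="feature")

    def write_replicates(self, path: str) -> None:
        if self.replicates is None:
            raise ValueError("no replicate layer to write")
        flat = self.replicates.copy()
        flat.columns = [f"{s}_{r}" for s, r in flat.columns]
        flat.to_csv(path, sep="\t", index_label="feature")

    def write_locations(self, path: str) -> None:
        if self.locations is None:
            raise ValueError("no feature locations to write")
        self.locations.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def read(
        cls, path: str, locations_path: str | None = None, replicates: bool | None = None
    ) -> "ExpressionSet":
        """Read a TSV of strain means, or of replicates (columns ``strain_rep``).

        With ``replicates=None`` the layout is inferred: if every column name
        ends in an underscore-separated integer the file is treated as
        replicate-level.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        loc = None
        if locations_path is not None:
            loc = pd.read_csv(locations_path, sep="\t", index_col=0, dtype={"chromosome": str})
        if replicates is None:
            replicates = all("_" in str(c) and str(c).rsplit("_", 1)[1].isdigit() for c in df.columns)
        if replicates:
            tuples = [tuple(str(c).rsplit("_", 1)) for c in df.columns]
            df.columns = pd.MultiIndex.from_tuples([(s, int(r)) for s, r in tuples])
            return cls.from_replicates(df, locations=loc)
        return cls(means=df, locations=loc)
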