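"""Core in-memory containers: genotype panels and genomic relationship matrices.

A :class:`GenotypePanel` holds an individuals x SNPs additive dosage matrix
(values in {0,1,2}, NaN for missing) together with a SNP map carrying the
chromosome, physical position, alleles and the per-SNP imputation accuracy
score DR2. Panels are tagged ``chip``, ``wgs`` or ``merged`` according to
their provenance in the study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SNP_MAP_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "dr2"]


class PanelError(ValueError):
    """Raised on structurally invalid genotype panels or empty selections."""


@dataclass
class GenotypePanel:
    ids: np.ndarray            # (n,) individual identifiers (str)
    dosages: np.ndarray        # (n, m) float, values 0/1/2 or NaN
    snp_map: pd.DataFrame      # columns SNP_MAP_COLUMNS, one row per SNP
    tag: str = "wgs"           # chip | wgs | merged

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise PanelError("dosage matrix must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        if len(self.ids) != n:
            raise PanelError(f"{len(self.ids)} ids but {n} dosage rows")
        if len(self.snp_map) != m:
            raise PanelError(f"{len(self.snp_map)} SNP-map rows but {m} dosage columns")
        missing = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing:
            raise PanelError(f"snp_map lacks columns {missing}")
        if self.snp_map["id"].duplicated().any():
            dupes = self.snp_map.loc[self.snp_map["id"].duplicated(), "id"].tolist()
            raise PanelError(f"duplicate SNP ids: {dupes[:5]}")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise PanelError("positions must be strictly increasing within chromosome")
        self.snp_map = self.snp_map.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["id"].to_numpy()

    def snp_indexer(self, snp_ids) -> np.ndarray:
        """Column indices of the given SNP ids (raises on unknown ids)."""
        lookup = pd.Index(self.snp_map["id"])
        idx = lookup.get_indexer(list(snp_ids))
        if np.any(idx < 0):
            unknown = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise PanelError(f"unknown SNP ids: {unknown[:5]}")
        return idx

    def subset_snps(self, snp_ids, tag: str | None = None) -> "GenotypePanel":
        idx = self.snp_indexer(snp_ids)
        return GenotypePanel(
            ids=self.ids,
            dosages=self.dosages[:, idx].copy(),
            snp_map=self.snp_map.iloc[idx].reset_index(drop=True),
            tag=tag or self.tag,
        )

    def subset_individuals(self, row_idx) -> "GenotypePanel":
        row_idx = np.asarray(row_idx)
        return GenotypePanel(
            ids=self.ids[row_idx],
            dosages=self.dosages[row_idx].copy(),
            snp_map=self.snp_map.copy(),
            tag=self.tag,
        )

    # -- allele statistics ----------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted (a1) allele, ignoring missing."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.where(np.isnan(p), 0.0, p)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def copy(self) -> "GenotypePanel":
        return replace(
            self,
            ids=self.ids.copy(),
            dosages=self.dosages.copy(),
            snp_map=self.snp_map.copy(),
        )


@dataclass
class GRM:
    """Additive genomic relationship matrix (VanRaden method 1).

    ``matrix`` is n x n symmetric, built from centered dosages Z as
    Z Z' / (2 sum p(1-p)); ``snp_ids`` records which SNPs entered and
    ``scale_constant`` is 2 sum p(1-p).
    """

    matrix: np.ndarray
    snp_ids: np.ndarray
    scale_constant: float
    ids: np.ndarray = field(default=None)  # individual ids, aligned with rows

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise PanelError("GRM must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise PanelError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def regularized(self, ridge: float = 1e-6) -> np.ndarray:
        """Matrix with a small ridge on the diagonal (stabilises inversion)."""
        return self.matrix + ridge * np.eye(self.n)

    def submatrix(self, rows, cols=None) -> np.ndarray:
        rows = np.asarray(rows)
        cols = rows if cols is None else np.asarray(cols)
        return self.matrix[np.ix_(rows, cols)]
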