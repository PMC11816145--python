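"""Quality control, GRM construction, panel merging and LD pruning.

These are the marker-level preprocessing steps of the study: SNPs are
filtered on minor-allele frequency and imputation accuracy (DR2), genomic
relationship matrices are built over arbitrary SNP subsets by VanRaden's
first method, chip and sequence panels are merged without duplicating
markers, and PLINK-style windowed LD pruning yields the independent-SNP
count that sets the genome-wide significance threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import GRM, GenotypePanel, PanelError

logger = logging.getLogger(__name__)


def qc_filter(panel: GenotypePanel, maf_min: float = 0.05, dr2_min: float = 0.9) -> GenotypePanel:
    """Retain SNPs with MAF >= ``maf_min`` and DR2 >= ``dr2_min``.

    Thresholds are inclusive: markers exactly at the boundary are kept
    (the filters drop what is *below* 0.9 / *less than* 0.05). Chip panels
    without imputation scores should carry DR2 = 1.
    """
    maf = panel.maf()
    dr2 = panel.snp_map["dr2"].to_numpy(dtype=float)
    dr2 = np.where(np.isnan(dr2), 1.0, dr2)  # unscored markers treated as observed
    keep_maf = maf >= maf_min
    keep_dr2 = dr2 >= dr2_min
    keep = keep_maf & keep_dr2
    logger.info(
        "qc_filter: %d/%d retained (%d failed MAF<%g, %d failed DR2<%g)",
        keep.sum(), panel.n_snps, (~keep_maf).sum(), maf_min, (~keep_dr2).sum(), dr2_min,
    )
    if not keep.any():
        raise PanelError("QC removed every SNP")
    return GenotypePanel(
        ids=panel.ids,
        dosages=panel.dosages[:, keep].copy(),
        snp_map=panel.snp_map.loc[keep].reset_index(drop=True),
        tag=panel.tag,
    )


def centered_dosages(panel: GenotypePanel, snp_idx=None, freqs: np.ndarray | None = None):
    """Mean-imputed, 2p-centered dosage matrix Z and the frequencies used.

    Missing dosages are imputed at 2p before centering, so they contribute
    zero to relationships; ``freqs`` may be supplied to center a validation
    panel with training-derived frequencies.
    """
    dos = panel.dosages if snp_idx is None else panel.dosages[:, snp_idx]
    if freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(dos, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.0, p)
    else:
        p = np.asarray(freqs, dtype=float)
    Z = np.where(np.isnan(dos), 2.0 * p, dos) - 2.0 * p
    return Z, p


def compute_grm(panel: GenotypePanel, snp_subset=None) -> GRM:
    """VanRaden method-1 GRM: G = Z Z' / 2*sum(p(1-p)) on centered dosages.

    Allele frequencies come from the panel itself; monomorphic SNPs are
    excluded automatically.
    """
    if snp_subset is None:
        idx = np.arange(panel.n_snps)
    else:
        idx = panel.snp_indexer(snp_subset)
        if len(idx) == 0:
            raise PanelError("empty SNP subset for GRM")
    Z, p = centered_dosages(panel, idx)
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise PanelError("no polymorphic SNPs left for GRM")
    Z = Z[:, poly]
    p = p[poly]
    scale = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / scale
    return GRM(
        matrix=G,
        snp_ids=panel.snp_map["id"].to_numpy()[idx][poly],
        scale_constant=scale,
        ids=panel.ids,
    )


def merge_panels(chip: GenotypePanel, selected_wgs: GenotypePanel) -> GenotypePanel:
    """Union of chip SNPs and selected sequence SNPs, tagged ``merged``.

    Chip markers that intersect the selected sequence SNPs are dropped in
    favour of the sequence version, so no marker is counted twice.
    """
    if chip.n_individuals != selected_wgs.n_individuals or np.any(chip.ids != selected_wgs.ids):
        raise PanelError("panels must cover identical individuals in the same order")
    sel_ids = set(selected_wgs.snp_map["id"])
    keep_chip = ~chip.snp_map["id"].isin(sel_ids).to_numpy()
    dosages = np.concatenate([chip.dosages[:, keep_chip], selected_wgs.dosages], axis=1)
    snp_map = pd.concat(
        [chip.snp_map.loc[keep_chip], selected_wgs.snp_map], ignore_index=True
    )
    order = np.lexsort((snp_map["pos"].to_numpy(), snp_map["chrom"].to_numpy()))
    return GenotypePanel(
        ids=chip.ids,
        dosages=dosages[:, order],
        snp_map=snp_map.iloc[order].reset_index(drop=True),
        tag="merged",
    )


def _prune_window(R2, maf, pos, active_idx, keep, r2_threshold):
    # Greedy pairwise rule inside one window, on a precomputed r^2 block:
    # drop the lower-MAF SNP of any pair above threshold; equal MAF drops
    # the later position. Pairs visited in (i, j) position order.
    k = len(active_idx)
    for a in range(k):
        i = active_idx[a]
        if not keep[i]:
            continue
        for b in range(a + 1, k):
            j = active_idx[b]
            if not keep[j]:
                continue
            if R2[a, b] > r2_threshold:
                if maf[i] < maf[j]:
                    keep[i] = False
                    break
                elif maf[j] < maf[i]:
                    keep[j] = False
                else:
                    drop = i if pos[i] > pos[j] else j
                    keep[drop] = False
                    if drop == i:
                        break


def ld_prune(
    panel: GenotypePanel,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_threshold: float = 0.5,
) -> list:
    """PLINK-style ``--indep-pairwise`` greedy LD pruning; returns kept SNP ids.

    Windows of ``window_snps`` SNPs slide in ``step_snps`` increments along
    each chromosome; within a window any pair with genotype r^2 above the
    threshold loses its lower-MAF member (ties: the later position). The
    size of the returned list is the independent-SNP count N used by the
    1/N genome-wide threshold.
    """
    if panel.n_snps < 2:
        return list(panel.snp_map["id"])
    Z, _ = centered_dosages(panel)
    sd = Z.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Zs = np.where(sd > 0, Z / sd, 0.0)
    maf = panel.maf()
    pos = panel.snp_map["pos"].to_numpy()
    chrom = panel.snp_map["chrom"].to_numpy()
    keep = np.ones(panel.n_snps, dtype=bool)
    n = panel.n_individuals
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        start = 0
        while True:
            window = cols[start : start + window_snps]
            if len(window) >= 2:
                B = Zs[:, window]
                R2 = np.square((B.T @ B) / n)
                _prune_window(R2, maf, pos, window, keep, r2_threshold)
            if start + window_snps >= len(cols):
                break
            start += step_snps
    return list(panel.snp_map.loc[keep, "id"])
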