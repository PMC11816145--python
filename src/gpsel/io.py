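"""Genotype and phenotype file I/O.

Panels round-trip through PLINK 1 binary filesets (.bed/.bim/.fam,
variant-major) and VCF 4.2. Dosages written to PLINK are hard calls; VCF
output carries both GT and a DS (dosage) FORMAT field plus a DR2 INFO tag,
and VCF input honours DS when present, falling back to GT otherwise.
Phenotype/covariate tables are tab-delimited with the columns
``id, trait1, trait2, sex, batch, cw, cw_type``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PanelError

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 2-bit codes (variant-major): 00 hom A1, 10 het, 11 hom A2, 01 missing.
# We count the A1 allele, so dosage 2 -> 00, 1 -> 10, 0 -> 11, NaN -> 01.
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: np.nan}


def write_plink(panel: GenotypePanel, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bim = panel.snp_map
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, row in bim.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{int(row['pos'])}\t{row['a1']}\t{row['a2']}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in panel.ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")
    n = panel.n_individuals
    nbytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros(nbytes, dtype=np.uint8)
        for j in range(panel.n_snps):
            buf[:] = 0
            col = panel.dosages[:, j]
            for i in range(n):
                d = col[i]
                code = 0b01 if np.isnan(d) else _DOSAGE_TO_CODE[int(round(d))]
                buf[i >> 2] |= code << ((i & 3) * 2)
            fh.write(buf.tobytes())


def read_plink(prefix) -> GenotypePanel:
    prefix = Path(prefix)
    try:
        fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
        bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                          names=["chrom", "id", "cm", "pos", "a1", "a2"],
                          dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    except Exception as exc:  # pragma: no cover - depends on corruption mode
        raise PanelError(f"malformed PLINK text file near {prefix}: {exc}") from exc
    ids = fam[1].astype(str).to_numpy()
    n, m = len(ids), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PanelError(f"{prefix}.bed: bad magic bytes (not variant-major PLINK bed)")
    nbytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != nbytes * m:
        raise PanelError(f"{prefix}.bed: expected {nbytes * m} data bytes, found {len(body)}")
    dosages = np.empty((n, m))
    codes = np.empty(n, dtype=np.uint8)
    for j in range(m):
        block = body[j * nbytes : (j + 1) * nbytes]
        for shift in range(4):
            part = (block >> (2 * shift)) & 0b11
            codes[shift::4] = part[: len(codes[shift::4])]
        dosages[:, j] = [_CODE_TO_DOSAGE[int(c)] for c in codes]
    snp_map = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    snp_map["dr2"] = 1.0
    return GenotypePanel(ids=ids, dosages=dosages, snp_map=snp_map, tag="wgs")


def write_vcf(panel: GenotypePanel, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DR2,Number=1,Type=Float,Description="Dosage R-squared imputation accuracy">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        for c in pd.unique(panel.snp_map["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(i) for i in panel.ids) + "\n")
        gt_map = {2: "1/1", 1: "0/1", 0: "0/0"}
        for j, row in panel.snp_map.iterrows():
            col = panel.dosages[:, j]
            cells = []
            for d in col:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_map[int(round(d))]}:{d:g}")
            dr2 = row["dr2"]
            info = f"DR2={dr2:g}" if np.isfinite(dr2) else "."
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['a2']}\t{row['a1']}\t.\t.\t"
                f"{info}\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path) -> GenotypePanel:
    """Read a VCF into a panel; alt-allele dosage from DS, else from GT."""
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise PanelError(f"cannot open VCF {path}: {exc}") from exc
    ids = np.asarray(vcf.samples, dtype=object)
    rows, dosage_cols = [], []
    for var in vcf:
        try:
            ds = var.format("DS")
        except Exception:
            ds = None
        if ds is not None:
            col = ds[:, 0].astype(float)
            # cyvcf2 encodes missing format floats as a large sentinel
            col = np.where(np.isfinite(col) & (col < 100), col, np.nan)
        else:
            gts = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            col = np.select(
                [gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan
            )
        dr2 = var.INFO.get("DR2")
        rows.append(
            {
                "id": var.ID or f"{var.CHROM}_{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "a1": var.ALT[0] if var.ALT else ".",
                "a2": var.REF,
                "dr2": float(dr2) if dr2 is not None else np.nan,
            }
        )
        dosage_cols.append(col)
    if not rows:
        raise PanelError(f"VCF {path} contains no variant records")
    return GenotypePanel(
        ids=ids,
        dosages=np.column_stack(dosage_cols),
        snp_map=pd.DataFrame(rows),
        tag="wgs",
    )


def read_panel(path, format: str) -> GenotypePanel:
    if format == "plink":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown panel format {format!r}")


def write_panel(panel: GenotypePanel, path, format: str) -> None:
    if format == "plink":
        write_plink(panel, path)
    elif format == "vcf":
        write_vcf(panel, path)
    else:
        raise ValueError(f"unknown panel format {format!r}")


PHENO_COLUMNS = ["id", "trait1", "trait2", "sex", "batch", "cw", "cw_type"]


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"phenotype file lacks columns {missing}")
    return df
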