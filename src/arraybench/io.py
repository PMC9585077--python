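"""Reading and writing the pipeline's file formats.

Panels travel as VCF 4.2 with phased GT (bgzipped, one file per
chromosome); pseudo-array data as unphased VCF; imputed results as VCF with
GT+DS FORMAT fields; manifests, summary statistics, population maps and
fold plans as tab-delimited text.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .hmm import DosageMatrix
from .masking import FoldPlan, PseudoArrayGenotypes
from .panel import ArrayManifest, HaplotypePanel

_VCF_HEADER = "##fileformat=VCFv4.2\n"


def _open_out(path: str):
    if str(path).endswith(".gz"):
        return pysam.BGZFile(str(path), "wb")
    return open(path, "wb")


def write_panel_vcf(panel: HaplotypePanel, path: str, chrom: str | None = None) -> str:
    """Write a (single-chromosome) panel as VCF with phased GT calls."""
    if chrom is None:
        chroms = pd.unique(panel.variants["chrom"])
        if len(chroms) != 1:
            raise ValueError("specify chrom, or use write_panel_vcfs for multi-chromosome panels")
        chrom = chroms[0]
    mask = (panel.variants["chrom"] == chrom).to_numpy()
    sub = panel.variants.loc[mask]
    haps = panel.haplotypes[:, mask]
    with _open_out(path) as fh:
        fh.write(_VCF_HEADER.encode())
        fh.write(f"##contig=<ID={chrom}>\n".encode())
        fh.write(b'##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(panel.samples) + "\n").encode()
        )
        for j, (_, row) in enumerate(sub.iterrows()):
            col = haps[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{chrom}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n".encode()
            )
    return str(path)


def write_panel_vcfs(panel: HaplotypePanel, directory: str, prefix: str = "panel") -> dict[str, str]:
    """One bgzipped VCF per chromosome; returns chrom -> path."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for chrom in pd.unique(panel.variants["chrom"]):
        path = os.path.join(directory, f"{prefix}.chr{chrom}.vcf.gz")
        write_panel_vcf(panel, path, chrom=chrom)
        paths[str(chrom)] = path
    return paths


def read_panel_vcf(
    paths: Iterable[str] | str,
    populations: Mapping[str, str] | str,
) -> HaplotypePanel:
    """Load phased VCF file(s) into a panel.

    Multiallelic records (multiple ALT alleles, or several records at one
    chrom+pos) are kept but flagged ``multiallelic`` so downstream filters
    can exclude and count them.  ``populations`` maps sample -> population
    (or is the path of a 2-column TSV).
    """
    if isinstance(paths, str):
        paths = [paths]
    if isinstance(populations, str):
        populations = read_popmap(populations)

    samples: list[str] | None = None
    blocks: list[np.ndarray] = []
    var_rows: list[tuple] = []
    for path in paths:
        vcf = VCF(str(path))
        if samples is None:
            samples = list(vcf.samples)
        elif list(vcf.samples) != samples:
            raise ValueError("all panel VCFs must share the same samples")
        for rec in vcf:
            multi = len(rec.ALT) != 1
            alt = rec.ALT[0] if rec.ALT else ""
            arr = rec.genotype.array()[:, :2]
            hap = np.clip(arr, 0, 1).astype(np.uint8).reshape(-1)
            blocks.append(hap)
            var_rows.append((rec.CHROM, rec.POS, rec.REF, alt, multi))
        vcf.close()
    if samples is None or not var_rows:
        raise ValueError("no variant records found")
    variants = pd.DataFrame(
        var_rows, columns=["chrom", "pos", "ref", "alt", "multiallelic"]
    )
    dup = variants.duplicated(subset=["chrom", "pos"], keep=False)
    variants.loc[dup, "multiallelic"] = True
    # keep the first record at a duplicated position so keys stay unique
    keep = ~variants.duplicated(subset=["chrom", "pos"], keep="first")
    variants = variants.loc[keep].reset_index(drop=True)
    haplotypes = np.stack([b for b, k in zip(blocks, keep) if k], axis=1)
    pops = np.array([populations[s] for s in samples], dtype=object)
    return HaplotypePanel(
        haplotypes=haplotypes, samples=samples, populations=pops, variants=variants
    )


def write_popmap(panel: HaplotypePanel, path: str) -> str:
    pd.DataFrame({"sample": panel.samples, "population": panel.populations}).to_csv(
        path, sep="\t", index=False, header=False
    )
    return str(path)


def read_popmap(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])
    return dict(zip(df["sample"], df["population"]))


def write_manifest(manifest: ArrayManifest, path: str) -> str:
    manifest.variants.to_csv(path, sep="\t", index=False)
    return str(path)


def read_manifest(path: str, name: str | None = None) -> ArrayManifest:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    return ArrayManifest(variants=df, name=name or os.path.basename(str(path)))


def write_summary_stats(stats: pd.DataFrame, path: str) -> str:
    stats.to_csv(path, sep="\t", index=False)
    return str(path)


def read_summary_stats(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_fold_plan(plan: FoldPlan, path: str) -> str:
    plan.to_frame().to_csv(path, sep="\t", index=False)
    return str(path)


def read_fold_plan(path: str) -> FoldPlan:
    df = pd.read_csv(path, sep="\t")
    return FoldPlan(
        k=int(df["fold"].max()) + 1,
        samples=df["sample"].tolist(),
        populations=df["population"].to_numpy(dtype=object),
        assignment=df["fold"].to_numpy(),
    )


def write_pseudo_vcf(pseudo: PseudoArrayGenotypes, path: str) -> str:
    """Write pseudo-array genotypes as unphased VCF (GT 0/1 style)."""
    gt_str = np.array(["0/0", "0/1", "1/1"])
    with _open_out(path) as fh:
        fh.write(_VCF_HEADER.encode())
        fh.write(b'##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(pseudo.samples) + "\n").encode()
        )
        for j, row in pseudo.variants.iterrows():
            col = pseudo.genotypes[:, j]
            gts = "\t".join("./." if g < 0 else gt_str[g] for g in col)
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n".encode()
            )
    return str(path)


def write_dosage_vcf(dm: DosageMatrix, path: str) -> str:
    """Write dosages as VCF with GT (hard call) + DS FORMAT fields."""
    with _open_out(path) as fh:
        fh.write(_VCF_HEADER.encode())
        fh.write(b'##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Genotyped on the array">\n')
        fh.write(b'##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (rounded dosage)">\n')
        fh.write(b'##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected ALT dosage">\n')
        fh.write(
            ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(dm.samples) + "\n").encode()
        )
        gt_str = ["0/0", "0/1", "1/1"]
        for j, row in dm.variants.iterrows():
            info = "TYPED" if dm.typed[j] else "."
            col = dm.dosages[:, j]
            cells = "\t".join(
                f"{gt_str[int(round(d))]}:{d:.4f}" for d in col
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t{info}\tGT:DS\t{cells}\n".encode()
            )
    return str(path)


def read_dosage_vcf(path: str) -> DosageMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, typed, dose_cols = [], [], []
    for rec in vcf:
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0] if rec.ALT else ""))
        typed.append(rec.INFO.get("TYPED") is not None)
        ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        dose_cols.append(ds)
    vcf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = np.clip(np.stack(dose_cols, axis=1), 0.0, 2.0)
    return DosageMatrix(
        samples=samples, variants=variants, dosages=dosages, typed=np.array(typed)
    )
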