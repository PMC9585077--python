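"""Imputation scoring: SNP-wise r², MAF bins, exclusions, coverage, aggregation.

Imputation accuracy at a site is the squared Pearson correlation between the
imputed dosage and the true genotype across samples; coverage is the
fraction of scored sites whose r² passes a cutoff (0.8 by default).  Sites
are stratified into left-open/right-closed MAF bins (0–0.01], (0.01–0.05],
(0.05–0.5] plus the union bin (0.01–0.5]; multiallelic records are dropped
everywhere and, within the rare bin, sites with minor-allele count below 2.
Per-chromosome bin means are aggregated as mean ± SD (n−1) across
chromosomes, stratified by population.

MAF and minor-allele count are computed from the truth genotypes of the full
evaluated population (all merged test folds).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .hmm import DosageMatrix
from .panel import HaplotypePanel

BIN_RARE = "(0,0.01]"
BIN_LOW = "(0.01,0.05]"
BIN_COMMON = "(0.05,0.5]"
BIN_UNION = "(0.01,0.5]"
BINS = (BIN_RARE, BIN_LOW, BIN_COMMON)
ALL_BINS = BINS + (BIN_UNION,)

STATUS_SCORED = "scored"


def site_r2(dosages: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation between dosage and truth at one site.

    Returns NaN (undefined) when either vector has zero variance.
    """
    dosages = np.asarray(dosages, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if dosages.shape != truth.shape:
        raise ValueError("dosage and truth vectors must have equal length")
    if dosages.size < 2:
        raise ValueError("need at least 2 samples")
    dx = dosages - dosages.mean()
    dy = truth - truth.mean()
    vx = dx @ dx
    vy = dy @ dy
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    r = (dx @ dy) / np.sqrt(vx * vy)
    return float(min(r * r, 1.0))


def assign_bin(maf: float) -> str | None:
    """MAF bin under left-open/right-closed edges; None when monomorphic."""
    if maf < 0 or maf > 0.5:
        raise ValueError(f"{maf} is not a minor-allele frequency")
    if maf == 0:
        return None
    if maf <= 0.01:
        return BIN_RARE
    if maf <= 0.05:
        return BIN_LOW
    return BIN_COMMON


def in_union_bin(maf: float) -> bool:
    return 0.01 < maf <= 0.5


def coverage(r2_values, cutoff: float = 0.8) -> float:
    """Fraction of r² values passing the cutoff; NaN on an empty set."""
    arr = np.asarray(list(r2_values), dtype=float)
    if arr.size == 0:
        return float("nan")
    return float(np.mean(arr >= cutoff))


def evaluate_imputation(
    dosage: DosageMatrix,
    truth: HaplotypePanel,
    include_typed: bool = False,
) -> pd.DataFrame:
    """Score imputed dosages against truth, per population and per site.

    Returns one row per (population, variant) with columns ``population,
    chrom, pos, ref, alt, maf, mac, bin, union_bin, r2, status``.  ``status``
    is ``scored`` or an exclusion reason (``multiallelic``, ``typed``,
    ``monomorphic``, ``ac_lt_2``, ``zero_variance``); every input site
    appears exactly once per population across the two.  Typed sites are
    excluded by default — the metric evaluates imputation — unless
    ``include_typed`` is set.
    """
    if dosage.variants[["chrom", "pos"]].to_numpy().tolist() != truth.variants[
        ["chrom", "pos"]
    ].to_numpy().tolist():
        raise ValueError("dosage and truth variant tables must align")
    sample_idx = truth.sample_indices(dosage.samples)

    multi = truth.variants["multiallelic"].to_numpy(dtype=bool)
    sample_pops = truth.populations[sample_idx]
    rows: list[pd.DataFrame] = []
    for pop in pd.unique(sample_pops):
        dos_rows = np.flatnonzero(sample_pops == pop)
        members = [dosage.samples[i] for i in dos_rows]
        gt = truth.genotypes(members)  # (n_pop, M)
        dm = dosage.dosages[dos_rows]
        n_hap = 2 * len(members)
        ac_alt = gt.sum(axis=0).astype(int)
        mac = np.minimum(ac_alt, n_hap - ac_alt)
        maf = mac / n_hap

        m = truth.n_variants
        status = np.full(m, STATUS_SCORED, dtype=object)
        r2 = np.full(m, np.nan)
        bins = np.full(m, "", dtype=object)
        union = np.zeros(m, dtype=bool)
        for j in range(m):
            if multi[j]:
                status[j] = "multiallelic"
                continue
            if dosage.typed[j] and not include_typed:
                status[j] = "typed"
                continue
            b = assign_bin(maf[j])
            if b is None:
                status[j] = "monomorphic"
                continue
            bins[j] = b
            union[j] = in_union_bin(maf[j])
            if b == BIN_RARE and mac[j] < 2:
                status[j] = "ac_lt_2"
                continue
            val = site_r2(dm[:, j], gt[:, j])
            if np.isnan(val):
                status[j] = "zero_variance"
                continue
            r2[j] = val
        rows.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "chrom": truth.variants["chrom"].to_numpy(),
                    "pos": truth.variants["pos"].to_numpy(),
                    "ref": truth.variants["ref"].to_numpy(),
                    "alt": truth.variants["alt"].to_numpy(),
                    "maf": maf,
                    "mac": mac,
                    "bin": bins,
                    "union_bin": union,
                    "r2": r2,
                    "status": status,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclasses.dataclass
class MetricsReport:
    """Per-chromosome and cross-chromosome imputation summaries.

    ``per_chromosome`` has one row per (population, bin, chrom) with the
    chromosome's mean r² and coverage over scored sites; ``summary``
    aggregates across chromosomes with mean and sample SD (ddof=1; reported
    as 0 with ``single_chromosome=True`` when only one chromosome exists).
    """

    per_chromosome: pd.DataFrame
    summary: pd.DataFrame
    cutoff: float = 0.8

    def mean_r2(self, population: str, bin_label: str) -> float:
        sel = self.summary[
            (self.summary["population"] == population) & (self.summary["bin"] == bin_label)
        ]
        return float(sel["mean_r2"].iloc[0]) if len(sel) else float("nan")

    def mean_coverage(self, population: str, bin_label: str) -> float:
        sel = self.summary[
            (self.summary["population"] == population) & (self.summary["bin"] == bin_label)
        ]
        return float(sel["mean_coverage"].iloc[0]) if len(sel) else float("nan")


def aggregate(site_metrics: pd.DataFrame, cutoff: float = 0.8) -> MetricsReport:
    """Aggregate per-site metrics into a per-chromosome, per-bin report."""
    scored = site_metrics[site_metrics["status"] == STATUS_SCORED]
    chrom_rows = []
    for (pop, chrom), grp in scored.groupby(["population", "chrom"], sort=False):
        for bin_label in ALL_BINS:
            sel = grp["union_bin"] if bin_label == BIN_UNION else (grp["bin"] == bin_label)
            vals = grp.loc[sel, "r2"].to_numpy()
            if vals.size == 0:
                continue
            chrom_rows.append(
                {
                    "population": pop,
                    "chrom": chrom,
                    "bin": bin_label,
                    "n_sites": int(vals.size),
                    "mean_r2": float(vals.mean()),
                    "coverage": coverage(vals, cutoff),
                }
            )
    per_chrom = pd.DataFrame(
        chrom_rows,
        columns=["population", "chrom", "bin", "n_sites", "mean_r2", "coverage"],
    )

    summary_rows = []
    if len(per_chrom):
        for (pop, bin_label), grp in per_chrom.groupby(["population", "bin"], sort=False):
            n_chrom = len(grp)
            single = n_chrom == 1
            summary_rows.append(
                {
                    "population": pop,
                    "bin": bin_label,
                    "n_chromosomes": n_chrom,
                    "n_sites": int(grp["n_sites"].sum()),
                    "mean_r2": float(grp["mean_r2"].mean()),
                    "sd_r2": 0.0 if single else float(grp["mean_r2"].std(ddof=1)),
                    "mean_coverage": float(grp["coverage"].mean()),
                    "sd_coverage": 0.0 if single else float(grp["coverage"].std(ddof=1)),
                    "single_chromosome": single,
                }
            )
    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "population", "bin", "n_chromosomes", "n_sites", "mean_r2", "sd_r2",
            "mean_coverage", "sd_coverage", "single_chromosome",
        ],
    )
    return MetricsReport(per_chromosome=per_chrom, summary=summary, cutoff=cutoff)
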