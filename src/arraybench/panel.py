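"""In-memory containers for phased haplotype panels and array manifests.

A :class:`HaplotypePanel` holds the phased, biallelic alleles of a diploid
cohort — the ground-truth stand-in for a whole-genome-sequenced reference
panel — as a ``(2N, M)`` matrix of 0/1 ALT-allele indicators together with a
variant table (``chrom, pos, ref, alt``) and a population label per sample.
An :class:`ArrayManifest` is simply the list of variant positions a
genotyping array assays (its "tag SNPs").
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric sort for '1'..'22', lexicographic fallback otherwise."""
    num = pd.to_numeric(chrom, errors="coerce")
    if num.notna().all():
        return num
    return chrom.astype(str)


def sort_variant_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Return ``df`` sorted by (chrom, pos), chromosomes numerically when possible."""
    key = _chrom_sort_key(df["chrom"])
    order = np.lexsort((df["pos"].to_numpy(), key.to_numpy()))
    return df.iloc[order].reset_index(drop=True)


@dataclasses.dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for N diploid samples over M variants.

    Parameters
    ----------
    haplotypes
        ``(2N, M)`` array of 0/1 ALT indicators; rows ``2i`` and ``2i+1`` are
        the two haplotypes of sample ``i``.
    samples
        N sample identifiers.
    populations
        N population labels aligned with ``samples``.
    variants
        Variant table with at least columns ``chrom, pos, ref, alt``;
        positions 1-based, strictly increasing within each chromosome.  An
        optional boolean ``multiallelic`` column flags records that were
        multiallelic in the source VCF (kept for exclusion accounting).
    """

    haplotypes: np.ndarray
    samples: list[str]
    populations: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.samples = list(self.samples)
        self.populations = np.asarray(self.populations, dtype=object)
        self.variants = self.variants.reset_index(drop=True)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D (2N, M) array")
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype rows must equal 2 x number of samples")
        if len(self.populations) != len(self.samples):
            raise ValueError("populations must align with samples")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("variant table must align with haplotype columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        if self.haplotypes.size and self.haplotypes.max(initial=0) > 1:
            raise ValueError("haplotype alleles must be 0/1")
        if "multiallelic" not in self.variants.columns:
            self.variants["multiallelic"] = False
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    # -- basic shape ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    def variant_keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.variants[["chrom", "pos"]])

    # -- genotype views ------------------------------------------------------

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def genotypes(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Unphased ALT-allele counts, ``(n, M)`` int8 in {0, 1, 2}."""
        idx = np.arange(self.n_samples) if names is None else self.sample_indices(names)
        return (
            self.haplotypes[2 * idx].astype(np.int8)
            + self.haplotypes[2 * idx + 1].astype(np.int8)
        )

    def allele_frequency(self) -> np.ndarray:
        """ALT-allele frequency per variant over all haplotypes."""
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        af = self.allele_frequency()
        return np.minimum(af, 1.0 - af)

    def population_samples(self, population: str) -> list[str]:
        return [s for s, p in zip(self.samples, self.populations) if p == population]

    # -- subsetting ----------------------------------------------------------

    def subset_samples(self, names: Sequence[str]) -> "HaplotypePanel":
        idx = self.sample_indices(names)
        hap_rows = np.empty(2 * len(idx), dtype=int)
        hap_rows[0::2] = 2 * idx
        hap_rows[1::2] = 2 * idx + 1
        return HaplotypePanel(
            haplotypes=self.haplotypes[hap_rows],
            samples=[self.samples[i] for i in idx],
            populations=self.populations[idx],
            variants=self.variants.copy(),
        )

    def subset_variants(self, mask_or_index: np.ndarray) -> "HaplotypePanel":
        arr = np.asarray(mask_or_index)
        if arr.dtype == bool:
            cols = np.flatnonzero(arr)
        else:
            cols = arr
        return HaplotypePanel(
            haplotypes=self.haplotypes[:, cols],
            samples=list(self.samples),
            populations=self.populations.copy(),
            variants=self.variants.iloc[cols].reset_index(drop=True),
        )

    @classmethod
    def concatenate(cls, panels: Iterable["HaplotypePanel"]) -> "HaplotypePanel":
        """Concatenate panels over variants (same samples, e.g. per-chromosome)."""
        panels = list(panels)
        first = panels[0]
        for p in panels[1:]:
            if p.samples != first.samples:
                raise ValueError("panels must share an identical sample list")
        return cls(
            haplotypes=np.concatenate([p.haplotypes for p in panels], axis=1),
            samples=list(first.samples),
            populations=first.populations.copy(),
            variants=pd.concat([p.variants for p in panels], ignore_index=True),
        )


@dataclasses.dataclass
class ArrayManifest:
    """Variant positions a genotyping array assays.

    ``variants`` has columns ``chrom, pos, ref, alt`` (alleles may be empty
    strings when the manifest does not state them).
    """

    variants: pd.DataFrame
    name: str = "array"

    def __post_init__(self) -> None:
        missing = [c for c in ("chrom", "pos") if c not in self.variants.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        for col in ("ref", "alt"):
            if col not in self.variants.columns:
                self.variants[col] = ""
        self.variants = sort_variant_frame(
            self.variants[list(VARIANT_COLUMNS)].astype({"pos": int})
        )

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> set[tuple]:
        return set(zip(self.variants["chrom"], self.variants["pos"]))
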