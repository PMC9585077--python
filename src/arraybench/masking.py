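"""Cross-validation folds and pseudo-array extraction.

Implements the mask-and-impute study design: samples are split into k
population-stratified, maximally balanced batches; in each turn one batch is
the test set whose genotypes are reduced to the array's manifest positions
with phase discarded ("pseudo-array" data), while the remaining batches form
the phased imputation reference.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .panel import ArrayManifest, HaplotypePanel, sort_variant_frame

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FoldPlan:
    """Assignment of every sample to one of ``k`` folds.

    Folds are disjoint, cover all samples, and are balanced to within one
    sample both overall and within every population.
    """

    k: int
    samples: list[str]
    populations: np.ndarray
    assignment: np.ndarray  # (N,) fold index per sample

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.populations = np.asarray(self.populations, dtype=object)
        if len(self.assignment) != len(self.samples):
            raise ValueError("assignment must cover every sample")
        if self.assignment.size and (
            self.assignment.min() < 0 or self.assignment.max() >= self.k
        ):
            raise ValueError("fold indices out of range")

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)

    def fold_samples(self, fold: int) -> list[str]:
        if not 0 <= fold < self.k:
            raise IndexError(f"fold {fold} out of range for k={self.k}")
        return [s for s, f in zip(self.samples, self.assignment) if f == fold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.samples, "population": self.populations, "fold": self.assignment}
        )


def stratified_folds(samples, labels, k: int, seed: int = 0) -> FoldPlan:
    """Split samples into ``k`` population-stratified balanced folds.

    Within each population the samples are shuffled (seeded) and dealt so
    per-population fold counts differ by at most one; each population's
    remainder samples go to the currently least-filled folds (seeded tie
    break), which keeps overall fold sizes maximally balanced as well.

    ``labels`` is either a mapping sample -> population or a sequence aligned
    with ``samples``.
    """
    samples = list(samples)
    n = len(samples)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if hasattr(labels, "__getitem__") and not isinstance(labels, (list, tuple, np.ndarray)):
        pops = np.array([labels[s] for s in samples], dtype=object)
    else:
        pops = np.asarray(list(labels), dtype=object)
        if len(pops) != n:
            raise ValueError("labels must align with samples")

    rng = np.random.default_rng(seed)
    totals = np.zeros(k, dtype=int)
    assignment = np.empty(n, dtype=int)
    seen: list = []
    for p in pops:  # preserve order of first appearance for determinism
        if p not in seen:
            seen.append(p)
    for pop in seen:
        members = np.flatnonzero(pops == pop)
        members = rng.permutation(members)
        base, rem = divmod(len(members), k)
        counts = np.full(k, base, dtype=int)
        if rem:
            # least-loaded folds first; random order among ties
            order = np.lexsort((rng.permutation(k), totals))
            counts[order[:rem]] += 1
        totals += counts
        slots = np.repeat(np.arange(k), counts)
        assignment[members] = slots
    return FoldPlan(k=k, samples=samples, populations=pops, assignment=assignment)


@dataclasses.dataclass
class PseudoArrayGenotypes:
    """Unphased genotypes at the manifest positions present in the panel.

    ``genotypes`` is ``(n_samples, n_typed)`` with ALT-allele counts in
    {0, 1, 2} (-1 = missing).  ``variants`` carries ``panel_index`` pointing
    back into the source panel's variant table.  ``skipped`` counts manifest
    entries that could not be matched, by reason.
    """

    samples: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray
    skipped: dict[str, int]

    @property
    def n_typed(self) -> int:
        return len(self.variants)


def make_pseudo_array(
    panel: HaplotypePanel, manifest: ArrayManifest, samples=None
) -> PseudoArrayGenotypes:
    """Extract manifest positions from the panel and discard phase.

    Matching is on chrom+pos.  Manifest positions absent from the panel are
    skipped (``skipped['absent']``); positions whose panel ref/alt disagree
    with stated manifest alleles are skipped and logged
    (``skipped['allele_mismatch']``) rather than strand-flipped; panel
    records flagged multiallelic are never matched
    (``skipped['multiallelic']``).  Output variants are sorted by
    (chrom, pos).
    """
    if samples is None:
        samples = list(panel.samples)
    else:
        samples = list(samples)

    pv = panel.variants
    usable = ~pv["multiallelic"].to_numpy(dtype=bool)
    # duplicated chrom+pos records are multiallelic split across lines
    dup = pv.duplicated(subset=["chrom", "pos"], keep=False).to_numpy()
    usable &= ~dup
    lookup: dict[tuple, int] = {
        (c, p): i
        for i, (c, p, ok) in enumerate(zip(pv["chrom"], pv["pos"], usable))
        if ok
    }
    blocked = {
        (c, p)
        for c, p, ok in zip(pv["chrom"], pv["pos"], usable)
        if not ok
    }

    skipped = {"absent": 0, "allele_mismatch": 0, "multiallelic": 0}
    taken: list[int] = []
    mv = sort_variant_frame(manifest.variants)
    for chrom, pos, ref, alt in mv[["chrom", "pos", "ref", "alt"]].itertuples(index=False):
        key = (chrom, pos)
        idx = lookup.get(key)
        if idx is None:
            if key in blocked:
                skipped["multiallelic"] += 1
            else:
                skipped["absent"] += 1
            continue
        if ref and alt and (pv.at[idx, "ref"] != ref or pv.at[idx, "alt"] != alt):
            skipped["allele_mismatch"] += 1
            logger.info(
                "skipping %s:%s — manifest alleles %s/%s disagree with panel %s/%s",
                chrom, pos, ref, alt, pv.at[idx, "ref"], pv.at[idx, "alt"],
            )
            continue
        taken.append(idx)

    taken_arr = np.array(sorted(set(taken)), dtype=int)
    variants = pv.iloc[taken_arr][["chrom", "pos", "ref", "alt"]].copy()
    variants["panel_index"] = taken_arr
    variants = variants.reset_index(drop=True)
    geno = panel.genotypes(samples)[:, taken_arr] if taken_arr.size else np.empty(
        (len(samples), 0), dtype=np.int8
    )
    if any(skipped.values()):
        logger.info("pseudo-array extraction skipped sites: %s", skipped)
    return PseudoArrayGenotypes(
        samples=samples, variants=variants, genotypes=geno, skipped=skipped
    )


def split_reference(
    panel: HaplotypePanel, plan: FoldPlan, test_fold: int
) -> tuple[list[str], HaplotypePanel]:
    """Return (test samples, reference panel of all remaining samples)."""
    test = plan.fold_samples(test_fold)
    test_set = set(test)
    reference = [s for s in panel.samples if s not in test_set]
    return test, panel.subset_samples(reference)
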