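"""P+T polygenic scores and concordance metrics.

A pruning-and-thresholding (P+T) score for individual *i* at p-value
threshold P_T is

    PGS_i(P_T) = sum_j 1{P_j < P_T} * x_ij * beta_j

over the SNPs retained by LD clumping (greedy index selection by ascending
p-value, removing neighbours within a window whose genotype r² with the
index passes a threshold; 250 kb and 0.1 by default).  x_ij is the ALT
allele count (truth genotypes) or the expected dosage (imputed data).

Array-vs-WGS concordance is measured two ways: Pearson correlation of the
two score vectors per threshold, and the absolute difference of percentile
ranking (ADPR) — per sample, |percentile under the array-imputed scores −
percentile under the WGS scores|, with percentile 100·(rank−0.5)/N and
mid-ranks for ties.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_THRESHOLDS = (
    5e-08, 1e-07, 1e-06, 1e-05, 0.0001, 0.001, 0.01, 0.1, 0.2, 0.3, 0.5, 1.0
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclasses.dataclass(frozen=True)
class ThresholdGrid:
    """Ordered p-value thresholds for the P+T grid."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be ascending")

    def __len__(self) -> int:
        return len(self.thresholds)

    def __iter__(self):
        return iter(self.thresholds)


@dataclasses.dataclass(frozen=True)
class ClumpSpec:
    """LD-clumping parameters: window in bp and the r² removal threshold."""

    window_bp: int = 250_000
    r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")


def _is_ambiguous(ref: str, alt: str) -> bool:
    return _COMPLEMENT.get(ref) == alt


def harmonize(stats: pd.DataFrame, variants: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Align summary-statistic effect alleles to panel ALT alleles.

    Exact effect/other vs alt/ref match keeps the row; a swapped match keeps
    it with the beta sign negated and the effect allele relabelled; A/T and
    C/G strand-ambiguous sites that would require a swap are dropped and
    counted, as are unmatched sites.  Returns the matched table (with column
    ``variant_index`` into ``variants``) and the drop counters.
    """
    for df, what in ((stats, "summary stats"), (variants, "variants")):
        if df.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError(f"duplicate chrom+pos keys in {what}")
    lookup = {
        (c, p): (i, r, a)
        for i, (c, p, r, a) in enumerate(
            zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"])
        )
    }
    counters = {"matched": 0, "swapped": 0, "ambiguous": 0, "unmatched": 0}
    out_rows = []
    for row in stats.itertuples(index=False):
        hit = lookup.get((row.chrom, row.pos))
        if hit is None:
            counters["unmatched"] += 1
            continue
        idx, ref, alt = hit
        if row.effect_allele == alt and row.other_allele == ref:
            counters["matched"] += 1
            out_rows.append((row.chrom, row.pos, alt, ref, row.beta, row.p, idx))
        elif row.effect_allele == ref and row.other_allele == alt:
            if _is_ambiguous(ref, alt):
                counters["ambiguous"] += 1
                continue
            counters["swapped"] += 1
            out_rows.append((row.chrom, row.pos, alt, ref, -row.beta, row.p, idx))
        else:
            counters["unmatched"] += 1
    matched = pd.DataFrame(
        out_rows,
        columns=["chrom", "pos", "effect_allele", "other_allele", "beta", "p", "variant_index"],
    )
    return matched, counters


def clump(
    table: pd.DataFrame,
    ld_genotypes: np.ndarray,
    spec: ClumpSpec = ClumpSpec(),
) -> np.ndarray:
    """Greedy LD clumping; returns retained row positions of ``table``.

    Repeatedly takes the unclumped variant with the smallest p-value (ties
    broken by ascending chrom, pos) as index, removes all unclumped variants
    on the same chromosome within ±window whose squared genotype correlation
    with the index reaches the threshold, and retains the index.
    ``ld_genotypes`` is (samples, variants) aligned with ``table`` rows.
    Deterministic and independent of input row order.
    """
    n = len(table)
    if ld_genotypes.shape[1] != n:
        raise ValueError("ld_genotypes columns must align with table rows")
    chrom = table["chrom"].to_numpy()
    pos = table["pos"].to_numpy()
    pval = table["p"].to_numpy(dtype=float)

    x = np.asarray(ld_genotypes, dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    ss = np.einsum("ij,ij->j", xc, xc)

    order = np.lexsort((pos, chrom, pval))
    state = np.zeros(n, dtype=np.int8)  # 0 free, 1 retained, 2 removed
    for idx in order:
        if state[idx] != 0:
            continue
        state[idx] = 1
        near = np.flatnonzero(
            (state == 0)
            & (chrom == chrom[idx])
            & (np.abs(pos - pos[idx]) <= spec.window_bp)
        )
        if near.size == 0:
            continue
        if ss[idx] == 0:
            continue  # monomorphic index: correlation undefined, removes nothing
        cov = xc[:, near].T @ xc[:, idx]
        denom = ss[near] * ss[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, cov * cov / denom, 0.0)
        state[near[r2 >= spec.r2_threshold]] = 2
    return np.flatnonzero(state == 1)


def score(
    x: np.ndarray,
    effects: pd.DataFrame,
    grid: ThresholdGrid = ThresholdGrid(),
) -> np.ndarray:
    """P+T scores, ``(n_samples, n_thresholds)``.

    ``x`` is (samples, SNPs) aligned with the clumped ``effects`` table
    (columns ``beta`` and ``p``); entries may be dosages or allele counts.
    The indicator uses the strict inequality P_j < P_T.
    """
    x = np.asarray(x, dtype=float)
    beta = effects["beta"].to_numpy(dtype=float)
    pval = effects["p"].to_numpy(dtype=float)
    if x.shape[1] != len(beta):
        raise ValueError("x columns must align with effects rows")
    thresholds = np.asarray(list(grid), dtype=float)
    passing = pval[:, None] < thresholds[None, :]  # (SNPs, T)
    return x @ (beta[:, None] * passing)


def pgs_correlation(
    array_scores: np.ndarray, wgs_scores: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Per-threshold Pearson correlation between the two score matrices.

    Returns (per-threshold r with NaN where either vector is constant,
    mean over defined thresholds, SD ddof=1 over defined thresholds).
    """
    a = np.asarray(array_scores, dtype=float)
    w = np.asarray(wgs_scores, dtype=float)
    if a.shape != w.shape:
        raise ValueError("score matrices must have identical shape")
    n_t = a.shape[1]
    r = np.full(n_t, np.nan)
    for t in range(n_t):
        da = a[:, t] - a[:, t].mean()
        dw = w[:, t] - w[:, t].mean()
        va, vw = da @ da, dw @ dw
        if va > 0 and vw > 0:
            r[t] = (da @ dw) / np.sqrt(va * vw)
    defined = r[~np.isnan(r)]
    mean = float(defined.mean()) if defined.size else float("nan")
    sd = float(defined.std(ddof=1)) if defined.size > 1 else float("nan")
    return r, mean, sd


def percentile_ranks(scores: np.ndarray) -> np.ndarray:
    """Percentile of each value in its vector: 100·(rank−0.5)/N, mid-ranks for ties."""
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(scores, method="average")
    return 100.0 * (ranks - 0.5) / scores.size

def adpr(array_scores: np.ndarray, wgs_scores: np.ndarray) -> tuple[np.ndarray, float]:
    """Absolute difference of percentile ranking, per sample, plus the mean."""
    a = np.asarray(array_scores, dtype=float)
    w = np.asarray(wgs_scores, dtype=float)
    if a.shape != w.shape or a.ndim != 1:
        raise ValueError("expected two aligned 1-D score vectors")
    if a.size < 2:
        raise ValueError("need at least 2 samples for percentile ranking")
    per_sample = np.abs(percentile_ranks(a) - percentile_ranks(w))
    return per_sample, float(per_sample.mean())


@dataclasses.dataclass
class PGSResult:
    """Scores and concordance for one (population, trait, array) cell."""

    thresholds: tuple[float, ...]
    array_scores: np.ndarray  # (n_samples, n_thresholds)
    wgs_scores: np.ndarray
    correlations: np.ndarray  # per threshold, NaN where undefined
    correlation_mean: float
    correlation_sd: float
    adpr_per_threshold: np.ndarray  # mean ADPR per threshold
    n_snps: int

    @classmethod
    def from_scores(cls, array_scores, wgs_scores, grid: ThresholdGrid, n_snps: int):
        r, mean, sd = pgs_correlation(array_scores, wgs_scores)
        adprs = np.array(
            [adpr(array_scores[:, t], wgs_scores[:, t])[1] for t in range(len(grid))]
        )
        return cls(
            thresholds=tuple(grid),
            array_scores=np.asarray(array_scores, dtype=float),
            wgs_scores=np.asarray(wgs_scores, dtype=float),
            correlations=r,
            correlation_mean=mean,
            correlation_sd=sd,
            adpr_per_threshold=adprs,
            n_snps=n_snps,
        )
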