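"""Diploid Li–Stephens haplotype-copying imputation.

The target's unphased genotypes at typed sites are modelled as noisy
observations of an ordered pair of reference haplotypes; the hidden pair
follows independent Li–Stephens chains, each switching between typed sites
with probability ``1 - exp(-switch_rate * gap)`` and landing uniformly on
one of the K reference haplotypes.  Emission at a typed site with genotype g
is the probability of reading g from the state's allele pair with per-allele
error ``error``.  A forward–backward recursion over the K^2 pair states
(linear scale, per-site rescaling) yields posterior state probabilities at
every typed site; dosages at untyped sites come from distance-weighted
linear interpolation of the per-haplotype posterior marginals of the two
flanking typed sites, contracted against the error-smoothed reference
alleles.  Complexity is O(T * K^2) per sample; ``max_ref_haplotypes`` caps K
by seeded subsampling of the reference.

Because the model works directly on unphased genotypes it needs no separate
phasing stage, replacing an external phase-then-impute tool chain with one
well-defined model.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .masking import PseudoArrayGenotypes
from .panel import HaplotypePanel


class DataLeakageError(ValueError):
    """Target samples overlap the imputation reference."""


@dataclasses.dataclass(frozen=True)
class HMMParams:
    """Li–Stephens copying parameters.

    ``switch_rate`` is the per-bp haplotype-switch intensity (default 1e-8,
    a human-scale recombination magnitude; tune to the data's LD scale).
    ``error`` is the per-allele mismatch emission probability.
    ``max_ref_haplotypes`` caps the number of reference haplotypes used
    (seeded subsample); ``None`` uses all.  ``numerical_floor`` guards the
    per-site rescaling against exact underflow.
    """

    switch_rate: float = 1e-8
    error: float = 1e-3
    max_ref_haplotypes: int | None = 32
    numerical_floor: float = 1e-300
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.error < 0.5:
            raise ValueError("error must be in (0, 0.5)")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")


@dataclasses.dataclass
class DosageMatrix:
    """Expected ALT-allele dosages, samples x variants, in [0, 2].

    ``typed`` flags variants observed on the pseudo-array (their dosages are
    the observed integer genotypes); the rest are imputed.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    typed: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.typed = np.asarray(self.typed, dtype=bool)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix shape mismatch")
        if self.typed.shape != (len(self.variants),):
            raise ValueError("typed flag shape mismatch")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")


def _emission_table(error: float) -> np.ndarray:
    """P(observed genotype g | state allele sum s), rows s=0..2, cols g=0..2."""
    e, q = error, 1.0 - error
    return np.array(
        [
            [q * q, 2 * e * q, e * e],
            [e * q, q * q + e * e, e * q],
            [e * e, 2 * e * q, q * q],
        ]
    )


def _pair_transition(mat: np.ndarray, rho: float, k: int) -> np.ndarray:
    """Apply the factorized pair transition to a K x K table."""
    out = (1.0 - rho) * mat + (rho / k) * mat.sum(axis=0, keepdims=True)
    out = (1.0 - rho) * out + (rho / k) * out.sum(axis=1, keepdims=True)
    return out


def impute_sample(
    target_gt: np.ndarray,
    ref_haps: np.ndarray,
    positions: np.ndarray,
    typed_idx: np.ndarray,
    params: HMMParams,
    return_diagnostics: bool = False,
):
    """Impute one sample's dosages at every site.

    Parameters
    ----------
    target_gt
        Genotypes at the typed sites, aligned with ``typed_idx``; values in
        {0, 1, 2}, -1 = missing (treated as untyped for this sample).
    ref_haps
        ``(K, M)`` phased reference alleles over all sites.
    positions
        ``(M,)`` base-pair positions, strictly increasing.
    typed_idx
        Indices into the M sites that are typed on the array.

    Returns the ``(M,)`` dosage vector; with ``return_diagnostics=True``
    also a dict carrying the posterior state tables and forward scaling
    factors at the observed sites.
    """
    params.validate()
    ref_haps = np.asarray(ref_haps, dtype=np.uint8)
    positions = np.asarray(positions, dtype=float)
    typed_idx = np.asarray(typed_idx, dtype=int)
    target_gt = np.asarray(target_gt, dtype=int)
    k, m = ref_haps.shape
    if k < 2:
        raise ValueError("need at least 2 reference haplotypes")

    eps = params.error
    smoothed = ref_haps * (1.0 - eps) + (1 - ref_haps) * eps  # P(ALT read | allele)

    observed_mask = target_gt >= 0
    obs = typed_idx[observed_mask]
    g = target_gt[observed_mask]
    if obs.size == 0:
        warnings.warn(
            "no typed genotypes for sample; returning allele-frequency dosages",
            stacklevel=2,
        )
        dosage = np.clip(2.0 * ref_haps.mean(axis=0), 0.0, 2.0)
        return (dosage, {}) if return_diagnostics else dosage

    order = np.argsort(obs)
    obs, g = obs[order], g[order]

    a = ref_haps[:, obs].astype(np.intp)
    pair_sum = a[:, None, :] + a[None, :, :]  # (K, K, T)
    etab = _emission_table(eps)
    emis = etab[pair_sum, g[None, None, :]]  # (K, K, T)

    t_obs = obs.size
    gaps = np.diff(positions[obs])
    rho = -np.expm1(-params.switch_rate * gaps)

    fwd = np.empty((t_obs, k, k))
    scale = np.empty(t_obs)
    cur = emis[:, :, 0] / (k * k)
    scale[0] = max(cur.sum(), params.numerical_floor)
    fwd[0] = cur / scale[0]
    for t in range(1, t_obs):
        cur = _pair_transition(fwd[t - 1], rho[t - 1], k) * emis[:, :, t]
        scale[t] = max(cur.sum(), params.numerical_floor)
        fwd[t] = cur / scale[t]

    bwd = np.empty((t_obs, k, k))
    bwd[-1] = 1.0 / (k * k)
    for t in range(t_obs - 2, -1, -1):
        cur = _pair_transition(bwd[t + 1] * emis[:, :, t + 1], rho[t], k)
        s = max(cur.sum(), params.numerical_floor)
        bwd[t] = cur / s

    post = fwd * bwd
    norm = post.sum(axis=(1, 2), keepdims=True)
    norm = np.maximum(norm, params.numerical_floor)
    post /= norm
    # per-haplotype marginals of the ordered pair; sums to 2 at every site
    marg = post.sum(axis=1) + post.sum(axis=2)  # (T, K)

    dosage = np.empty(m)
    dosage[obs] = g  # typed sites pass through as observed
    unobs = np.setdiff1d(np.arange(m), obs, assume_unique=False)
    if unobs.size:
        obs_pos = positions[obs]
        pos_u = positions[unobs]
        right = np.searchsorted(obs_pos, pos_u)
        left = np.clip(right - 1, 0, t_obs - 1)
        right = np.clip(right, 0, t_obs - 1)
        span = obs_pos[right] - obs_pos[left]
        with np.errstate(invalid="ignore", divide="ignore"):
            w_left = np.where(span > 0, (obs_pos[right] - pos_u) / np.where(span > 0, span, 1.0), 1.0)
        w_left = np.clip(w_left, 0.0, 1.0)
        interp = w_left[:, None] * marg[left] + (1.0 - w_left)[:, None] * marg[right]
        dosage[unobs] = np.einsum("uk,ku->u", interp, smoothed[:, unobs])
    np.clip(dosage, 0.0, 2.0, out=dosage)

    if return_diagnostics:
        return dosage, {"posterior": post, "scale": scale, "observed_sites": obs}
    return dosage


def impute_cohort(
    pseudo: PseudoArrayGenotypes,
    reference: HaplotypePanel,
    params: HMMParams,
) -> DosageMatrix:
    """Impute every target sample over all reference panel sites.

    The reference sample set must be disjoint from the target samples (data
    leakage otherwise).  Typed sites pass through as observed genotypes; all
    other reference sites receive imputed dosages.  The HMM runs per
    chromosome.
    """
    overlap = set(pseudo.samples) & set(reference.samples)
    if overlap:
        raise DataLeakageError(
            f"target samples present in reference: {sorted(overlap)[:5]}"
        )
    params.validate()

    rv = reference.variants
    ref_lookup = {
        (c, p): i for i, (c, p) in enumerate(zip(rv["chrom"], rv["pos"]))
    }
    typed_panel_idx = np.full(pseudo.n_typed, -1, dtype=int)
    for j, (c, p) in enumerate(zip(pseudo.variants["chrom"], pseudo.variants["pos"])):
        typed_panel_idx[j] = ref_lookup.get((c, p), -1)
    keep = typed_panel_idx >= 0

    haps = reference.haplotypes
    if params.max_ref_haplotypes is not None and haps.shape[0] > params.max_ref_haplotypes:
        rng = np.random.default_rng(params.seed)
        rows = np.sort(
            rng.choice(haps.shape[0], size=params.max_ref_haplotypes, replace=False)
        )
        haps = haps[rows]

    m = reference.n_variants
    n = len(pseudo.samples)
    dosages = np.empty((n, m))
    typed = np.zeros(m, dtype=bool)
    typed[typed_panel_idx[keep]] = True

    chroms = rv["chrom"].to_numpy()
    positions = rv["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        site_idx = np.flatnonzero(chroms == chrom)
        in_chrom = keep & np.isin(typed_panel_idx, site_idx)
        local = np.searchsorted(site_idx, typed_panel_idx[in_chrom])
        sub_haps = haps[:, site_idx]
        sub_pos = positions[site_idx]
        gts = pseudo.genotypes[:, in_chrom]
        for i in range(n):
            dosages[i, site_idx] = impute_sample(
                gts[i], sub_haps, sub_pos, local, params
            )
    return DosageMatrix(
        samples=list(pseudo.samples),
        variants=rv.copy(),
        dosages=dosages,
        typed=typed,
    )
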