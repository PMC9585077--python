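"""Synthetic data: LD-structured haplotype panels, manifests, summary statistics.

The panel generator uses founder-mosaic copying: a small set of founder
haplotypes is drawn from a site-wise allele-frequency spectrum, and each
cohort haplotype is a recombination mosaic of founders (per-interval switch
probability ``recomb_rate x gap``) with a per-site mutation flip.  This is
the simplest mechanism that yields tunable linkage disequilibrium — the
pipeline needs LD, not demographic realism.  Population structure comes from
independent per-population Dirichlet re-weighting of founder usage.

All randomness flows from the explicit ``seed`` of each config through a
single ``numpy.random.default_rng`` instance per operation, consumed in a
fixed documented order (positions, alleles, frequencies, founders, then
per-population mosaics), so identical configs give identical output.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .panel import ArrayManifest, HaplotypePanel

GWS_THRESHOLD = 5e-8  # genome-wide significance, assigned to causal variants

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the founder-mosaic panel simulator.

    ``n_samples`` is per population.  ``recomb_rate`` is the per-bp crossover
    probability of the copying mosaic; ``mutation_rate`` the per-site,
    per-haplotype allele flip probability.  ``maf_floor`` bounds the founder
    allele-frequency spectrum from below (frequencies are drawn log-uniformly
    on ``[maf_floor, 0.5]``, mimicking a rare-heavy site-frequency spectrum).
    ``differentiation`` controls the spread of per-population founder weights
    (0 = identical populations; larger = stronger drift).
    """

    n_samples: int = 200
    n_variants: int = 5000
    n_founders: int = 16
    chrom_length: int = 1_000_000
    recomb_rate: float = 1e-5
    mutation_rate: float = 1e-3
    populations: tuple[str, ...] = ("POP1", "POP2")
    maf_floor: float = 0.01
    differentiation: float = 0.3
    chrom: str = "1"
    seed: int = 0

    def validate(self) -> None:
        for name in ("recomb_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        if self.n_variants > self.chrom_length:
            raise ConfigurationError("n_variants must fit in chrom_length")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ConfigurationError("maf_floor must be in [0, 0.5)")
        if self.n_samples < 1 or not self.populations:
            raise ConfigurationError("need at least one sample in one population")


@dataclasses.dataclass(frozen=True)
class EffectModel:
    """Generator settings for GWAS-style summary statistics.

    ``causal_beta_variance`` is the variance of the zero-mean normal from
    which causal effect sizes are drawn (a heritability-like scale knob);
    ``null_beta_sd`` the standard deviation of the small zero-centred noise
    assigned to non-causal variants.  Causal variants receive p-values below
    genome-wide significance (5e-8) by construction; null variants receive
    uniform p-values (clipped below at 1e-7 so the causal count is exact).
    """

    n_causal: int = 50
    causal_beta_variance: float = 0.01
    null_beta_sd: float = 0.005
    seed: int = 0

    def validate(self, n_variants: int) -> None:
        if not 0 <= self.n_causal <= n_variants:
            raise ConfigurationError("n_causal must be in [0, n_variants]")
        if self.causal_beta_variance <= 0:
            raise ConfigurationError("causal_beta_variance must be > 0")


def simulate_panel(config: SimConfig) -> HaplotypePanel:
    """Simulate a phased, biallelic, multi-population haplotype panel.

    Returns a panel of ``2 x n_samples x len(populations)`` haplotypes over
    ``n_variants`` sites with strictly increasing 1-based positions on a
    single chromosome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    nf = config.n_founders

    pos = np.sort(rng.choice(config.chrom_length, size=m, replace=False)) + 1
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4

    lo = max(config.maf_floor, 5e-4)
    freq = np.exp(rng.uniform(math.log(lo), math.log(0.5), size=m))
    founders = (rng.random((nf, m)) < freq).astype(np.uint8)

    gaps = np.diff(pos)
    switch_prob = np.minimum(1.0, config.recomb_rate * gaps)

    hap_blocks = []
    samples: list[str] = []
    pop_labels: list[str] = []
    cols = np.arange(m)
    for pop in config.populations:
        if config.differentiation > 0:
            weights = rng.dirichlet(np.full(nf, 1.0 / config.differentiation))
        else:
            weights = np.full(nf, 1.0 / nf)
        h = 2 * config.n_samples
        draws = rng.choice(nf, size=(h, m), p=weights)
        if m > 1:
            switched = rng.random((h, m - 1)) < switch_prob
            marks = np.where(switched, cols[1:], 0)
            marks = np.concatenate([np.zeros((h, 1), dtype=int), marks], axis=1)
            last_switch = np.maximum.accumulate(marks, axis=1)
        else:
            last_switch = np.zeros((h, 1), dtype=int)
        founder_idx = draws[np.arange(h)[:, None], last_switch]
        alleles = founders[founder_idx, cols[None, :]]
        if config.mutation_rate > 0:
            alleles = alleles ^ (rng.random((h, m)) < config.mutation_rate)
        hap_blocks.append(alleles.astype(np.uint8))
        samples.extend(f"{pop}_{i:04d}" for i in range(config.n_samples))
        pop_labels.extend([pop] * config.n_samples)

    variants = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos.astype(int),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "multiallelic": False,
        }
    )
    return HaplotypePanel(
        haplotypes=np.concatenate(hap_blocks, axis=0),
        samples=samples,
        populations=np.array(pop_labels, dtype=object),
        variants=variants,
    )


def derive_manifest(
    panel: HaplotypePanel,
    density: float,
    strategy: str = "random",
    seed: int = 0,
    name: str | None = None,
) -> ArrayManifest:
    """Select ``round(density x M)`` panel variants as an array manifest.

    ``strategy='random'`` samples uniformly; ``'maf_weighted'`` samples
    proportionally to MAF, emulating the common-variant bias of tag-SNP
    selection on real arrays.
    """
    if not 0.0 < density <= 1.0:
        raise ConfigurationError(f"density must be in (0, 1], got {density}")
    m = panel.n_variants
    n_sel = int(round(density * m))
    rng = np.random.default_rng(seed)
    if strategy == "random":
        chosen = rng.choice(m, size=n_sel, replace=False)
    elif strategy == "maf_weighted":
        weights = panel.maf() + 1e-9  # keep monomorphic sites selectable
        chosen = rng.choice(m, size=n_sel, replace=False, p=weights / weights.sum())
    else:
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    rows = panel.variants.iloc[np.sort(chosen)][["chrom", "pos", "ref", "alt"]]
    return ArrayManifest(
        variants=rows.reset_index(drop=True),
        name=name or f"density{density:g}_{strategy}",
    )


def simulate_summary_stats(panel: HaplotypePanel, model: EffectModel) -> pd.DataFrame:
    """Assign GWAS-style (effect allele, beta, p) to every panel variant.

    The effect allele is always ALT.  ``model.n_causal`` variants (chosen
    uniformly) draw beta from N(0, causal_beta_variance) and a p-value
    log-uniform below 5e-8; the rest get small zero-centred noise betas and
    uniform p-values.  P-values are assigned, not computed from association
    tests: the pipeline consumes summary statistics, it does not run a GWAS.
    """
    model.validate(panel.n_variants)
    rng = np.random.default_rng(model.seed)
    m = panel.n_variants

    beta = rng.normal(0.0, model.null_beta_sd, size=m)
    pval = np.clip(rng.uniform(0.0, 1.0, size=m), 1e-7, 1.0)
    if model.n_causal > 0:
        causal = rng.choice(m, size=model.n_causal, replace=False)
        beta[causal] = rng.normal(
            0.0, math.sqrt(model.causal_beta_variance), size=model.n_causal
        )
        log_hi = math.log10(GWS_THRESHOLD) - 0.05  # strictly below 5e-8
        pval[causal] = 10.0 ** rng.uniform(log_hi - 8.0, log_hi, size=model.n_causal)

    return pd.DataFrame(
        {
            "chrom": panel.variants["chrom"].to_numpy(),
            "pos": panel.variants["pos"].to_numpy(),
            "effect_allele": panel.variants["alt"].to_numpy(),
            "other_allele": panel.variants["ref"].to_numpy(),
            "beta": beta,
            "p": pval,
        }
    )
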