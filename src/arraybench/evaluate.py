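"""Array evaluation as a fitted model: mask, impute, merge, benchmark.

:class:`ArrayEvaluation` is constructed from a truth panel, one manifest per
array and (optionally) one summary-statistics table per trait; ``fit()``
runs the stratified k-fold mask-and-impute loop for every array and returns
an :class:`EvaluationResults` holding per-site and aggregated imputation
metrics plus PGS concordance (correlation and ADPR) per
(array x population x trait), with a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from collections.abc import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .hmm import DosageMatrix, HMMParams, impute_cohort
from .masking import FoldPlan, make_pseudo_array, split_reference, stratified_folds
from .metrics import BIN_UNION, MetricsReport, aggregate, evaluate_imputation
from .panel import ArrayManifest, HaplotypePanel
from .pgs import ClumpSpec, PGSResult, ThresholdGrid, clump, harmonize, score


class ArrayEvaluation:
    """Mask-and-impute cross-validation benchmark of genotyping arrays.

    Parameters
    ----------
    panel
        Phased truth panel (the WGS gold standard).
    manifests
        Mapping array name -> :class:`ArrayManifest`.
    sumstats
        Optional mapping trait name -> summary-statistics DataFrame
        (columns chrom, pos, effect_allele, other_allele, beta, p).
    k
        Number of cross-validation folds (default 10).
    hmm_params, clump_spec, thresholds, r2_cutoff
        Method parameters; see the respective classes.
    score_dosage
        Score the imputed source on expected dosages (default) or on
        hard-called (rounded) genotypes.
    share_clump
        Clump once on the truth genotypes and reuse the retained set for
        both score sources (default; isolates imputation error).  When
        False, clumping is repeated on the imputed dosages for the
        array-derived scores.
    seed
        Master seed; fold assignment and per-(array, fold) reference
        subsampling seeds are derived from it via ``SeedSequence``.
    """

    def __init__(
        self,
        panel: HaplotypePanel,
        manifests: Mapping[str, ArrayManifest],
        sumstats: Mapping[str, pd.DataFrame] | None = None,
        *,
        k: int = 10,
        hmm_params: HMMParams | None = None,
        clump_spec: ClumpSpec | None = None,
        thresholds: ThresholdGrid | None = None,
        r2_cutoff: float = 0.8,
        score_dosage: bool = True,
        share_clump: bool = True,
        seed: int = 0,
    ) -> None:
        self.panel = panel
        self.manifests = dict(manifests)
        self.sumstats = dict(sumstats or {})
        self.k = k
        self.hmm_params = hmm_params or HMMParams()
        self.clump_spec = clump_spec or ClumpSpec()
        self.thresholds = thresholds or ThresholdGrid()
        self.r2_cutoff = r2_cutoff
        self.score_dosage = score_dosage
        self.share_clump = share_clump
        self.seed = seed

    @classmethod
    def from_files(
        cls,
        panel_vcfs,
        popmap,
        manifest_paths: Mapping[str, str],
        sumstat_paths: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "ArrayEvaluation":
        from . import io as abio

        panel = abio.read_panel_vcf(panel_vcfs, popmap)
        manifests = {
            name: abio.read_manifest(path, name=name)
            for name, path in manifest_paths.items()
        }
        sumstats = {
            trait: abio.read_summary_stats(path)
            for trait, path in (sumstat_paths or {}).items()
        }
        return cls(panel, manifests, sumstats, **kwargs)

    # -- fitting -------------------------------------------------------------

    def _fold_seeds(self) -> tuple[int, np.ndarray]:
        # one seed per fold (shared across arrays, so identical manifests give
        # identical results), all derived from the master seed
        ss = np.random.SeedSequence(self.seed)
        ints = ss.generate_state(1 + self.k) % (2**31)
        return int(ints[0]), ints[1:]

    def fit(self, verbose: bool = False) -> "EvaluationResults":
        fold_seed, hmm_seeds = self._fold_seeds()
        plan = stratified_folds(
            self.panel.samples, self.panel.populations, self.k, seed=fold_seed
        )
        merged: dict[str, DosageMatrix] = {}
        site_metrics: dict[str, pd.DataFrame] = {}
        reports: dict[str, MetricsReport] = {}
        n, m = self.panel.n_samples, self.panel.n_variants

        for name, manifest in self.manifests.items():
            dosages = np.empty((n, m))
            typed = np.zeros(m, dtype=bool)
            for fold in range(self.k):
                try:
                    test, reference = split_reference(self.panel, plan, fold)
                    assert not set(test) & set(reference.samples)
                    pseudo = make_pseudo_array(self.panel, manifest, test)
                    params = dataclasses.replace(
                        self.hmm_params, seed=int(hmm_seeds[fold])
                    )
                    dm = impute_cohort(pseudo, reference, params)
                except Exception as exc:
                    raise RuntimeError(
                        f"evaluation of array {name!r} failed in fold {fold}"
                    ) from exc
                rows = self.panel.sample_indices(test)
                dosages[rows] = dm.dosages
                typed |= dm.typed
                if verbose:
                    print(f"[{name}] fold {fold + 1}/{self.k} done")
            merged[name] = DosageMatrix(
                samples=list(self.panel.samples),
                variants=self.panel.variants.copy(),
                dosages=dosages,
                typed=typed,
            )
            site_metrics[name] = evaluate_imputation(merged[name], self.panel)
            reports[name] = aggregate(site_metrics[name], cutoff=self.r2_cutoff)

        pgs_rows, pgs_results = self._run_pgs(merged)
        return EvaluationResults(
            model=self,
            fold_plan=plan,
            dosages=merged,
            site_metrics=site_metrics,
            imputation=reports,
            pgs=pgs_rows,
            pgs_results=pgs_results,
        )

    def _run_pgs(self, merged: Mapping[str, DosageMatrix]):
        rows = []
        results: dict[tuple, PGSResult] = {}
        if not self.sumstats:
            return pd.DataFrame(), results
        grid = self.thresholds
        pops = pd.unique(self.panel.populations)
        truth_gt = self.panel.genotypes()
        for trait, stats in self.sumstats.items():
            matched, _ = harmonize(stats, self.panel.variants)
            vidx = matched["variant_index"].to_numpy()
            for pop in pops:
                members = self.panel.population_samples(pop)
                rows_idx = self.panel.sample_indices(members)
                x_truth = truth_gt[np.ix_(rows_idx, vidx)].astype(float)
                retained = clump(matched, x_truth, self.clump_spec)
                effects = matched.iloc[retained]
                x_truth_ret = x_truth[:, retained]
                wgs_scores = score(x_truth_ret, effects, grid)
                for name, dm in merged.items():
                    x_arr = dm.dosages[np.ix_(rows_idx, vidx)]
                    if not self.score_dosage:
                        x_arr = np.round(x_arr)
                    if self.share_clump:
                        eff_a, x_a = effects, x_arr[:, retained]
                    else:
                        ret_a = clump(matched, x_arr, self.clump_spec)
                        eff_a, x_a = matched.iloc[ret_a], x_arr[:, ret_a]
                    arr_scores = score(x_a, eff_a, grid)
                    res = PGSResult.from_scores(
                        arr_scores, wgs_scores, grid, n_snps=len(effects)
                    )
                    results[(name, pop, trait)] = res
                    for t, p_t in enumerate(grid):
                        rows.append(
                            {
                                "array": name,
                                "population": pop,
                                "trait": trait,
                                "threshold": p_t,
                                "pgs_correlation": res.correlations[t],
                                "adpr_mean": res.adpr_per_threshold[t],
                                "n_snps": res.n_snps,
                            }
                        )
        return pd.DataFrame(rows), results

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "k": self.k,
                "hmm": dataclasses.asdict(self.hmm_params),
                "clump": dataclasses.asdict(self.clump_spec),
                "thresholds": list(self.thresholds),
                "r2_cutoff": self.r2_cutoff,
                "seed": self.seed,
                "arrays": sorted(self.manifests),
                "traits": sorted(self.sumstats),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class EvaluationResults:
    """Fitted evaluation: metrics tables, PGS concordance, provenance."""

    model: ArrayEvaluation
    fold_plan: FoldPlan
    dosages: dict[str, DosageMatrix]
    site_metrics: dict[str, pd.DataFrame]
    imputation: dict[str, MetricsReport]
    pgs: pd.DataFrame
    pgs_results: dict

    # -- convenience accessors ----------------------------------------------

    def imputation_summary(self) -> pd.DataFrame:
        frames = []
        for name, report in self.imputation.items():
            if not len(report.summary):
                continue
            df = report.summary.copy()
            df.insert(0, "array", name)
            frames.append(df)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)

    def pgs_summary(self) -> pd.DataFrame:
        """Mean ± SD of PGS correlation over the threshold grid, plus mean ADPR."""
        if not len(self.pgs):
            return pd.DataFrame()
        rows = []
        for (name, pop, trait), res in self.pgs_results.items():
            rows.append(
                {
                    "array": name,
                    "population": pop,
                    "trait": trait,
                    "corr_mean": res.correlation_mean,
                    "corr_sd": res.correlation_sd,
                    "adpr_mean": float(np.mean(res.adpr_per_threshold)),
                    "n_snps": res.n_snps,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the union-bin metrics and PGS concordance."""
        lines = ["Array evaluation (mask-and-impute cross-validation)"]
        lines.append(f"  samples: {self.model.panel.n_samples}  "
                     f"variants: {self.model.panel.n_variants}  folds: {self.model.k}")
        imp = self.imputation_summary()
        if len(imp):
            union = imp[imp["bin"] == BIN_UNION]
            lines.append("")
            lines.append(f"  Imputation, MAF bin {BIN_UNION} "
                         f"(r2 cutoff {self.model.r2_cutoff}):")
            lines.append("  array                population   mean r2   coverage   sites")
            for _, r in union.iterrows():
                lines.append(
                    f"  {r['array']:<20} {r['population']:<12} "
                    f"{r['mean_r2']:>7.4f}   {r['mean_coverage']:>8.4f}   {r['n_sites']:>5d}"
                )
        pgs = self.pgs_summary()
        if len(pgs):
            lines.append("")
            lines.append("  PGS concordance to WGS (mean over p-value grid):")
            lines.append("  array                population   trait        corr      ADPR")
            for _, r in pgs.iterrows():
                lines.append(
                    f"  {r['array']:<20} {r['population']:<12} {r['trait']:<12} "
                    f"{r['corr_mean']:>7.4f}  {r['adpr_mean']:>7.3f}"
                )
        return "\n".join(lines)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        imp = self.imputation_summary()
        return {
            "version": __version__,
            "seed": self.model.seed,
            "config_hash": self.model.config_hash(),
            "imputation": imp.to_dict(orient="records"),
            "pgs": self.pgs.replace({np.nan: None}).to_dict(orient="records"),
        }

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.imputation_summary().to_csv(
            os.path.join(outdir, "imputation_summary.tsv"), sep="\t", index=False
        )
        for name, report in self.imputation.items():
            report.per_chromosome.to_csv(
                os.path.join(outdir, f"imputation_per_chrom.{name}.tsv"),
                sep="\t", index=False,
            )
            self.site_metrics[name].to_csv(
                os.path.join(outdir, f"site_metrics.{name}.tsv"), sep="\t", index=False
            )
        if len(self.pgs):
            self.pgs.to_csv(os.path.join(outdir, "pgs.tsv"), sep="\t", index=False)
            self.pgs_summary().to_csv(
                os.path.join(outdir, "pgs_summary.tsv"), sep="\t", index=False
            )
        self.fold_plan.to_frame().to_csv(
            os.path.join(outdir, "fold_plan.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, "results.json"), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
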