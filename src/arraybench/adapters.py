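"""Adapter contract for external phasing/imputation tools.

The built-in Li–Stephens imputer is the default engine, but the pipeline
exchanges data as VCF precisely so that an external phase+impute tool chain
can be slotted in: the adapter writes the pseudo-array and reference VCFs,
runs user-templated commands, and parses the dosage (DS) field back into a
:class:`~arraybench.hmm.DosageMatrix`.  Nothing in the test suite requires
external binaries.
"""

from __future__ import annotations

import dataclasses
import shlex
import shutil
import subprocess
import tempfile

from . import io as abio
from .hmm import DosageMatrix, HMMParams, impute_cohort
from .masking import PseudoArrayGenotypes
from .panel import HaplotypePanel


class FeatureUnavailableError(RuntimeError):
    """A configured external tool is not installed."""


@dataclasses.dataclass
class ExternalToolConfig:
    """Command templates for an external imputer.

    ``impute_cmd`` is formatted with ``{pseudo}``, ``{reference}`` and
    ``{out}`` placeholders and must produce a VCF with a DS FORMAT field at
    ``{out}``.  When ``fallback_to_builtin`` is set, a missing binary makes
    the pipeline fall back to the built-in imputer instead of failing.
    """

    impute_cmd: str
    fallback_to_builtin: bool = True
    workdir: str | None = None


def external_imputer_adapter(
    pseudo_vcf: str, reference_vcf: str, config: ExternalToolConfig
) -> DosageMatrix:
    """Run the configured external imputer on VCF inputs."""
    binary = shlex.split(config.impute_cmd)[0]
    if shutil.which(binary) is None:
        raise FeatureUnavailableError(
            f"external imputer {binary!r} not found on PATH; install it or "
            "set fallback_to_builtin to use the built-in model"
        )
    workdir = config.workdir or tempfile.mkdtemp(prefix="arraybench_ext_")
    out = f"{workdir}/imputed.vcf"
    cmd = config.impute_cmd.format(pseudo=pseudo_vcf, reference=reference_vcf, out=out)
    subprocess.run(shlex.split(cmd), check=True)
    return abio.read_dosage_vcf(out)


def impute_with_fallback(
    pseudo: PseudoArrayGenotypes,
    reference: HaplotypePanel,
    params: HMMParams,
    tool: ExternalToolConfig | None = None,
) -> DosageMatrix:
    """Use the external tool when available, else the built-in imputer."""
    if tool is not None:
        workdir = tool.workdir or tempfile.mkdtemp(prefix="arraybench_ext_")
        try:
            pseudo_vcf = abio.write_pseudo_vcf(pseudo, f"{workdir}/pseudo.vcf")
            ref_vcf = abio.write_panel_vcf(reference, f"{workdir}/reference.vcf")
            return external_imputer_adapter(pseudo_vcf, ref_vcf, tool)
        except FeatureUnavailableError:
            if not tool.fallback_to_builtin:
                raise
    return impute_cohort(pseudo, reference, params)
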