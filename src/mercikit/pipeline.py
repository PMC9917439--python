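"""End-to-end drivers composing the stage modules.

``run_merci`` is the full complex-identification pipeline: spike
normalization → replicate statistics → per-step Z-scores → stitching →
bait correlation ranking → trend-outlier partner detection.
``run_urcall`` is the copy-number pipeline: diploid normalization → UR
domain calling → per-mutant annotation → summary.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from . import copynumber as cnmod
from .correlation import RankedCorrelation, correlate_to_bait, detect_partners
from .normalize import replicate_stats, spike_normalize, zscore
from .profiles import stitch
from .quant_io import CopyNumberTrack, ReferenceSet, RunTable

__all__ = ["run_merci", "run_urcall"]


def run_merci(
    tables_by_step: Mapping[int, RunTable],
    refs: ReferenceSet,
    bait: str,
    *,
    steps: Sequence[int] | None = None,
    degree: int = 5,
    c: float = 3.0,
) -> RankedCorrelation:
    """Rank proteins by co-purification with the bait and flag partners.

    ``tables_by_step`` maps step id (purification order) to that step's
    protein×run table; every table must contain the spike-in references.
    Only proteins quantified in every step are ranked.
    """
    if steps is None:
        steps = sorted(tables_by_step)
    zprofiles = []
    for step in steps:
        table = spike_normalize(tables_by_step[step], refs)
        for prof in replicate_stats(table):
            if prof.protein in refs.ids:
                continue  # spike-ins are normalizers, not candidates
            zprofiles.append(zscore(prof))
    stitched, _dropped = stitch(zprofiles, steps, bait=bait)
    ranked = correlate_to_bait(stitched, bait)
    return detect_partners(ranked, degree=degree, c=c)


def run_urcall(
    sample: CopyNumberTrack,
    diploid: CopyNumberTrack,
    mutants: Mapping[str, CopyNumberTrack] | None = None,
    *,
    control_name: str = "control",
    bin_size: int = 5000,
    min_length: int = 100_000,
    gap_tol: int = 1,
    alpha: float = 0.01,
    mask: Sequence[tuple[str, int, int]] | None = None,
    mutant_pvalues: Mapping[int, Mapping] | None = None,
) -> tuple[list[cnmod.URDomain], dict]:
    """Call UR domains on a polytene sample and annotate per-mutant recovery.

    ``sample`` and each mutant track are normalized against the same
    ``diploid`` reference. Returns ``(domains, summary)``.
    """
    cn_control = cnmod.normalize_to_diploid(
        sample, diploid, bin_size=bin_size, mask=mask
    )
    domains = cnmod.call_ur_domains(
        cn_control,
        min_length=min_length,
        mask=mask,
        gap_tol=gap_tol,
        genotype=control_name,
    )
    if mutants:
        mutant_cn = {
            m: cnmod.normalize_to_diploid(
                t, diploid, bin_size=bin_size, mask=mask
            )
            for m, t in mutants.items()
        }
        cnmod.annotate_domains(
            domains,
            control=control_name,
            mutant_cn=mutant_cn,
            mutant_pvalues=mutant_pvalues,
            alpha=alpha,
        )
    summary = (
        cnmod.summarize_domains(domains, control=control_name)
        if domains
        else {"n_domains": 0, "mutants": {}}
    )
    return domains, summary
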