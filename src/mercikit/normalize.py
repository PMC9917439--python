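"""Spike-in normalization, replicate statistics and per-step Z-profiles.

This is the quantitative core of the co-fractionation procedure:

1. every run's peak areas are divided by the summed areas of the spike-in
   reference proteins in that same run (cancels injection-volume and
   ionization drift between acquisitions);
2. normalized values are averaged across technical replicates per
   (protein, step, fraction), with sample standard deviations;
3. each protein's per-step elution profile is converted to Z-scores across
   that step's fractions, so profile *shape* — not abundance — is compared
   downstream.

Missing-data convention: a protein entirely absent from a step's ion library
has no profile for that step (it cannot be quantified there); a protein
quantified in the step but undetected in some fractions is below detection,
and those fractions are set to 0 before Z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant_io import ReferenceSet, Role, RunTable

__all__ = [
    "NormalizedStepProfile",
    "ZProfile",
    "spike_normalize",
    "replicate_stats",
    "zscore",
]


@dataclass
class NormalizedStepProfile:
    """Per-fraction mean spike-normalized abundance of one protein in one step."""

    protein: str
    step_id: int
    fractions: np.ndarray       # fraction indices, ascending
    values: np.ndarray          # per-fraction replicate means
    sds: np.ndarray             # per-fraction sample SDs (ddof=1)
    n_replicates: np.ndarray    # replicates contributing per fraction

    def __post_init__(self):
        for name in ("fractions", "values", "sds", "n_replicates"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if not (
            len(self.fractions) == len(self.values) == len(self.sds)
            == len(self.n_replicates)
        ):
            raise ValueError("profile arrays must share length")


@dataclass
class ZProfile:
    """Z-scored elution profile of one protein across one step's fractions."""

    protein: str
    step_id: int
    z: np.ndarray
    constant: bool = False  # profile had (near-)zero spread; z forced to 0


def spike_normalize(table: RunTable, refs: ReferenceSet) -> RunTable:
    """Divide every peak area by the run's summed spike-in reference areas.

    Reference proteins are retained in the output (their normalized values
    sum to 1 per run by construction). A run in which every reference
    protein is missing or zero cannot be normalized and raises.
    """
    refs.validate_against(table)
    areas = table.areas
    ref_sums = areas.loc[list(refs.ids)].sum(axis=0, skipna=True)
    present = areas.loc[list(refs.ids)].notna().any(axis=0)
    bad = ref_sums.index[(~present) | (ref_sums <= 0)]
    if len(bad):
        raise ValueError(
            f"run {bad[0]!r} has no positive spike-in reference signal"
        )
    return RunTable(areas.div(ref_sums, axis=1), table.runs)


def replicate_stats(table: RunTable) -> list[NormalizedStepProfile]:
    """Average technical replicates per (protein, step, fraction).

    Only FRACTION runs contribute; SM/FT acquisitions are bookkeeping, not
    elution points. Mean and sample SD (n−1 denominator) are computed over
    the replicates in which the protein was quantified; a single replicate
    yields SD 0 with a warning. A (protein, step) pair with no quantified
    value in any fraction of the step yields no profile for that step.
    """
    frac_runs = table.fraction_runs()
    if not frac_runs:
        return []
    meta = pd.DataFrame(
        {
            "run_id": [r.run_id for r in frac_runs],
            "step": [r.step_id for r in frac_runs],
            "fraction": [r.fraction_index for r in frac_runs],
        }
    )
    single_rep = (
        meta.groupby(["step", "fraction"])["run_id"].count().le(1).any()
    )
    if single_rep:
        warnings.warn(
            "some (step, fraction) cells have a single replicate; SD=0",
            stacklevel=2,
        )

    long = (
        table.areas[meta["run_id"]]
        .T.join(meta.set_index("run_id"))
        .set_index(["step", "fraction"], append=False)
    )
    profiles: list[NormalizedStepProfile] = []
    grouped = long.groupby(level=["step", "fraction"])
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    counts = grouped.count()
    for step in sorted({r.step_id for r in frac_runs}):
        m_step = means.xs(step, level="step").sort_index()
        sd_step = sds.xs(step, level="step").reindex(m_step.index)
        n_step = counts.xs(step, level="step").reindex(m_step.index)
        fr = m_step.index.to_numpy()
        m_arr = m_step.to_numpy()
        sd_arr = np.nan_to_num(sd_step.to_numpy())
        n_arr = n_step.to_numpy()
        nan_cols = np.isnan(m_arr).all(axis=0)
        for j, protein in enumerate(m_step.columns):
            if nan_cols[j]:
                continue  # absent from this step's ion library
            profiles.append(
                NormalizedStepProfile(
                    protein=protein,
                    step_id=int(step),
                    fractions=fr,
                    values=m_arr[:, j],
                    sds=sd_arr[:, j],
                    n_replicates=n_arr[:, j],
                )
            )
    return profiles


def zscore(profile: NormalizedStepProfile, min_sd: float = 1e-12) -> ZProfile:
    """Z-score one step profile across its fractions (sample SD).

    Fractions where the protein was below detection (mean missing within a
    quantified step) count as 0. A profile with spread below ``min_sd`` is
    flagged constant and mapped to all-zero Z (no shape information).
    """
    x = np.nan_to_num(np.asarray(profile.values, dtype=float))
    if x.size < 2:
        raise ValueError(
            f"cannot Z-score a length-{x.size} profile "
            f"({profile.protein}, step {profile.step_id})"
        )
    sd = float(np.std(x, ddof=1))
    if sd < min_sd:
        return ZProfile(profile.protein, profile.step_id,
                        np.zeros_like(x), constant=True)
    return ZProfile(profile.protein, profile.step_id, (x - x.mean()) / sd)
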