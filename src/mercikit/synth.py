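"""Seeded synthetic-data generators with ground truth for every stage.

The generators emulate the study conditions end to end:

* **Fractionation** — five chromatographic steps of 14–20 fractions each
  (83 points total by default), ~140 proteins quantifiable in the final
  ion library, Gaussian elution peaks in fraction index, a planted
  co-eluting complex whose members share peak parameters, two spike-in
  references at constant amount, lognormal multiplicative replicate noise,
  per-run injection drift, and detection-limit censoring of proteins from
  a step's table (ion-library censoring).
* **Copy number** — chromosome arms as flat coverage with planted
  depth-reduced domains; a diploid reference is flat everywhere; each
  mutant restores a stated percentage of every domain's deficit
  (depth_mut = depth + recovery·(1 − depth)); per-bin Gaussian noise per
  replicate.
* **Titration** — a log–log linear dilution series with multiplicative
  signal noise.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant_io import CopyNumberTrack, ReferenceSet, Role, RunMeta, RunTable

__all__ = [
    "ComplexSpec",
    "GenomeSpec",
    "FractionationTruth",
    "simulate_fractionation",
    "simulate_copynumber",
    "simulate_titration",
    "DEFAULT_STEP_FRACTIONS",
    "SPIKE_IDS",
]

#: five steps totalling 83 fractions, within the 14–20 per-step range
DEFAULT_STEP_FRACTIONS: tuple[int, ...] = (20, 14, 17, 16, 16)
SPIKE_IDS: tuple[str, str] = ("SPIKE_TXNRD1", "SPIKE_TXNRD2")


@dataclass
class ComplexSpec:
    """A planted co-eluting complex: members share elution peaks."""

    members: tuple[str, ...]
    abundance: float = 50.0          # peak-height scale (arbitrary area units)
    center_jitter: float = 0.0       # SD of per-member peak-center offset
    stoichiometry: tuple[float, ...] | None = None  # per-member scale

    def __post_init__(self):
        if self.stoichiometry is None:
            self.stoichiometry = tuple(1.0 for _ in self.members)
        if len(self.stoichiometry) != len(self.members):
            raise ValueError("stoichiometry length must match members")


@dataclass
class FractionationTruth:
    """Ground truth of a simulated fractionation experiment."""

    bait: str
    complex_members: dict[str, tuple[str, ...]]
    peak_centers: dict[str, list[float]]   # protein -> per-step centers
    peak_widths: dict[str, list[float]]
    censored: dict[int, list[str]]         # step -> proteins below detection


def simulate_fractionation(
    n_background: int = 138,
    complexes: Sequence[ComplexSpec] = (),
    steps: Sequence[int] = DEFAULT_STEP_FRACTIONS,
    *,
    noise_sd: float = 0.2,
    detection_limit: float = 0.0,
    n_replicates: int = 3,
    spike_area: float = 1000.0,
    seed: int = 0,
) -> tuple[dict[int, RunTable], ReferenceSet, FractionationTruth]:
    """Simulate per-step protein×run peak-area tables with planted truth.

    Background proteins draw independent Gaussian elution peaks per step;
    complex members share their complex's peaks (± ``center_jitter``).
    ``noise_sd`` is the lognormal σ of the multiplicative measurement
    noise applied independently per replicate acquisition (σ 0.2 ≈ a 20%
    CV at the elution peak); each run additionally carries a lognormal
    injection-drift factor common to all its proteins, which spike
    normalization must cancel. A protein whose true peak height in a step
    falls below ``detection_limit`` is omitted from that step's table.

    Returns ``(tables_by_step, reference_set, truth)``; step ids are
    1-based in purification order.
    """
    rng = np.random.default_rng(seed)
    steps = [int(k) for k in steps]
    proteins = [f"BG{i:03d}" for i in range(n_background)]
    members: list[str] = []
    for cx in complexes:
        members.extend(cx.members)
    if set(members) & set(proteins):
        raise ValueError("complex member ids collide with background ids")
    all_proteins = members + proteins

    centers: dict[str, list[float]] = {p: [] for p in all_proteins}
    widths: dict[str, list[float]] = {p: [] for p in all_proteins}
    amps: dict[str, float] = {}
    for p in proteins:
        amps[p] = float(rng.lognormal(mean=np.log(20.0), sigma=1.0))
    for cx in complexes:
        for m, st in zip(cx.members, cx.stoichiometry):
            amps[m] = cx.abundance * st
    for s_idx, n_frac in enumerate(steps):
        for p in proteins:
            centers[p].append(float(rng.uniform(1, n_frac)))
            widths[p].append(float(rng.uniform(1.2, 3.0)))
        for cx in complexes:
            c = float(rng.uniform(2, n_frac - 1))
            w = float(rng.uniform(1.2, 2.5))
            for m in cx.members:
                jitter = (
                    float(rng.normal(0, cx.center_jitter))
                    if cx.center_jitter > 0
                    else 0.0
                )
                centers[m].append(c + jitter)
                widths[m].append(w)

    tables: dict[int, RunTable] = {}
    censored: dict[int, list[str]] = {}
    for s_idx, n_frac in enumerate(steps):
        step_id = s_idx + 1
        frac_idx = np.arange(1, n_frac + 1, dtype=float)
        mean_prof: dict[str, np.ndarray] = {}
        drop: list[str] = []
        for p in all_proteins:
            a = amps[p]
            prof = a * np.exp(
                -((frac_idx - centers[p][s_idx]) ** 2)
                / (2 * widths[p][s_idx] ** 2)
            )
            if prof.max() < detection_limit:
                drop.append(p)
                continue
            mean_prof[p] = prof
        censored[step_id] = drop

        runs: list[RunMeta] = []
        cols: dict[str, np.ndarray] = {}
        quantified = list(mean_prof)
        for f in range(1, n_frac + 1):
            for r in range(1, n_replicates + 1):
                run_id = f"s{step_id}f{f}r{r}"
                runs.append(RunMeta(run_id, step_id, f, r, Role.FRACTION))
                drift = float(rng.lognormal(0, 0.15))
                vals = np.array(
                    [mean_prof[p][f - 1] for p in quantified], dtype=float
                )
                rep_noise = rng.lognormal(0, noise_sd, size=vals.size)
                spikes = spike_area * rng.lognormal(0, noise_sd, size=2)
                col = np.concatenate([vals * rep_noise, spikes]) * drift
                cols[run_id] = col
        areas = pd.DataFrame(
            cols, index=pd.Index(quantified + list(SPIKE_IDS), name="protein")
        )
        tables[step_id] = RunTable(areas, runs)

    truth = FractionationTruth(
        bait=members[0] if members else "",
        complex_members={
            f"complex{i+1}": cx.members for i, cx in enumerate(complexes)
        },
        peak_centers=centers,
        peak_widths=widths,
        censored=censored,
    )
    return tables, ReferenceSet(SPIKE_IDS), truth


@dataclass
class GenomeSpec:
    """Arms, planted UR domains and noise for a copy-number simulation."""

    arm_lengths: Mapping[str, int]
    #: (chrom, start, end, control_depth, {mutant: recovery_pct})
    domains: Sequence[tuple[str, int, int, float, Mapping[str, float]]] = ()
    bin_size: int = 5000
    noise_sd: float = 0.05
    n_replicates: int = 3
    mask: Sequence[tuple[str, int, int]] = field(default_factory=tuple)

    def __post_init__(self):
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, depth, _rec in self.domains:
            if chrom not in self.arm_lengths:
                raise ValueError(f"domain on unknown arm {chrom!r}")
            if not (0 <= s < e <= self.arm_lengths[chrom]):
                raise ValueError("domain outside arm bounds")
            if not (0 <= depth < 1):
                raise ValueError("control depth must be in [0, 1)")
            for s2, e2 in seen.get(chrom, []):
                if s < e2 and e > s2:
                    raise ValueError("planted domains overlap")
            seen.setdefault(chrom, []).append((s, e))


def simulate_copynumber(
    spec: GenomeSpec,
    mutants: Sequence[str] = (),
    *,
    base_coverage: float = 100.0,
    seed: int = 0,
) -> tuple[dict[str, list[CopyNumberTrack]], dict]:
    """Simulate binned coverage tracks per genotype per replicate.

    Genotypes produced: ``"diploid"`` (flat reference), ``"control"``
    (polytene with planted dips) and every name in ``mutants``. Inside a
    planted domain, the mutant depth is
    ``depth + recovery/100 · (1 − depth)``; outside, all polytene
    genotypes sit at 1. Per-bin Gaussian noise (SD ``spec.noise_sd`` of
    the local depth) and a per-replicate lognormal library-size factor are
    applied; coverage is floored at a small positive value so ratios stay
    defined.

    Returns ``(tracks, truth)`` with ``tracks[genotype]`` a list of
    replicate tracks.
    """
    rng = np.random.default_rng(seed)
    genotypes = ["diploid", "control", *mutants]
    depth_fn: dict[str, dict[str, np.ndarray]] = {}

    bins: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, L in spec.arm_lengths.items():
        n = L // spec.bin_size
        starts = np.arange(n) * spec.bin_size
        bins[chrom] = (starts, starts + spec.bin_size)

    for g in genotypes:
        depth_fn[g] = {}
        for chrom, (starts, ends) in bins.items():
            d = np.ones(starts.size)
            if g != "diploid":
                for dc, ds, de, depth, rec in spec.domains:
                    if dc != chrom:
                        continue
                    inside = (starts >= ds) & (ends <= de)
                    if g == "control":
                        d[inside] = depth
                    else:
                        r = float(rec.get(g, 0.0)) / 100.0
                        d[inside] = depth + r * (1.0 - depth)
            depth_fn[g][chrom] = d

    tracks: dict[str, list[CopyNumberTrack]] = {g: [] for g in genotypes}
    for g in genotypes:
        for _rep in range(spec.n_replicates):
            lib = float(rng.lognormal(0, 0.1))
            pieces = []
            for chrom, (starts, ends) in bins.items():
                d = depth_fn[g][chrom]
                noise = rng.normal(0, spec.noise_sd, size=d.size)
                cov = base_coverage * lib * np.clip(d + noise, 1e-6, None)
                pieces.append(
                    pd.DataFrame(
                        {"chrom": chrom, "start": starts, "end": ends,
                         "value": cov}
                    )
                )
            tracks[g].append(
                CopyNumberTrack(
                    pd.concat(pieces, ignore_index=True), _validated=True
                )
            )
    truth = {
        "domains": [
            {
                "chrom": c, "start": int(s), "end": int(e),
                "control_depth": float(depth),
                "recovery_pct": dict(rec),
            }
            for c, s, e, depth, rec in spec.domains
        ],
        "bin_size": spec.bin_size,
        "noise_sd": spec.noise_sd,
    }
    return tracks, truth


def simulate_titration(
    slope: float = 1.0,
    intercept: float = -2.0,
    *,
    dilutions: Sequence[float] | None = None,
    noise: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[list[tuple[float, float]], dict]:
    """Simulate a dilution series on a log–log line.

    ``dilutions`` are masses in pg (default: tenfold series from 1 µg down
    to 10 fg, 9 points). ``noise`` is the relative SD of multiplicative
    signal noise. Returns replicate (mass_pg, signal) points and the
    generating truth.
    """
    rng = np.random.default_rng(seed)
    if dilutions is None:
        dilutions = [1e6 / 10**k for k in range(9)]  # 1 µg .. 10 fg, in pg
    pts: list[tuple[float, float]] = []
    for m in dilutions:
        base = 10 ** (slope * np.log10(m) + intercept)
        for _ in range(n_replicates):
            s = base * (float(rng.lognormal(0, noise)) if noise > 0 else 1.0)
            pts.append((float(m), float(s)))
    return pts, {"slope": slope, "intercept": intercept}
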