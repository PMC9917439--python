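"""Copy-number normalization, underreplication-domain calling and qPCR ΔΔCt.

In endoreplicating (polytene) tissue, intercalary and pericentric
heterochromatin fail to complete each endocycle, leaving domains of locally
reduced DNA copy number. The pipeline here:

* scales CPM coverage of a polytene sample to a diploid reference in fixed
  bins (default 5 kb) and rescales so the euchromatic genome averages 1;
* calls underreplicated (UR) domains as runs of bins strictly below the
  chromosome-arm mean, merged across small gaps, of span ≥ 100 kb, outside
  a pericentric/telomeric mask;
* quantifies per-mutant *recovery* — the fraction of the copy-number
  deficit restored, 100·(⟨CN⟩_mut − ⟨CN⟩_ctrl)/(1 − ⟨CN⟩_ctrl) — and calls
  a domain's UR *suppressed* by a mutant when the mean per-bin p-value is
  below α (default 0.01, strict) and the recovery is positive;
* summarizes a domain table with length-weighted means, as printed in the
  source-style report;
* converts qPCR Ct replicates to copy numbers via ΔΔCt = 2^−⟨ΔΔCt⟩ with
  the stated (non-standard) pooled-σ propagation and confidence interval.

The per-bin two-sample test provided here is a Welch t-test on
log-transformed bin values — a stand-in channel; differential-coverage
p-values from a dedicated count model can be supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant_io import CopyNumberTrack, CtTable

__all__ = [
    "URDomain",
    "DdCtResult",
    "cpm_normalize",
    "rebin",
    "normalize_to_diploid",
    "call_ur_domains",
    "recovery",
    "call_suppression",
    "perbin_test",
    "summarize_domains",
    "load_domain_table",
    "domains_to_frame",
    "ddct",
]

MaskT = Sequence[tuple[str, int, int]] | None


@dataclass
class URDomain:
    """One called underreplicated domain (internal coords 0-based half-open)."""

    chrom: str
    start: int
    end: int
    cn: dict[str, float] = field(default_factory=dict)      # genotype -> ⟨CN⟩
    recovery_pct: dict[str, float] = field(default_factory=dict)
    mean_p: dict[str, float] = field(default_factory=dict)
    suppressed: dict[str, bool | None] = field(default_factory=dict)
    cyto_band: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DdCtResult:
    amplicon: str
    group: str
    ddct: float
    sigma: float
    copy_number: float
    ci: tuple[float, float]


# ---------------------------------------------------------------------------
# track arithmetic


def cpm_normalize(track: CopyNumberTrack) -> CopyNumberTrack:
    """Scale to counts-per-million: value·10⁶ / Σ(value·width)."""
    w = track.widths()
    total = float((track.df["value"].to_numpy() * w).sum())
    if total <= 0:
        raise ValueError("track has no signal to CPM-normalize")
    df = track.df.copy()
    df["value"] = df["value"] * 1e6 / total
    return CopyNumberTrack(df, _validated=True)


def rebin(track: CopyNumberTrack, bin_size: int) -> CopyNumberTrack:
    """Re-bin to fixed-width bins by width-weighted mean of overlapping input."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    pieces = []
    for chrom in track.chroms:
        sub = track.chrom_view(chrom)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["value"].to_numpy()
        lo = int(starts.min()) // bin_size * bin_size
        hi = int(ends.max())
        n = -(-(hi - lo) // bin_size)
        acc = np.zeros(n)
        cov = np.zeros(n)
        for s, e, v in zip(starts, ends, vals):
            b0 = (s - lo) // bin_size
            b1 = (e - 1 - lo) // bin_size
            for b in range(b0, b1 + 1):
                o = min(e, lo + (b + 1) * bin_size) - max(s, lo + b * bin_size)
                acc[b] += v * o
                cov[b] += o
        keep = cov > 0
        idx = np.flatnonzero(keep)
        pieces.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": lo + idx * bin_size,
                    "end": lo + (idx + 1) * bin_size,
                    "value": acc[idx] / cov[idx],
                }
            )
        )
    return CopyNumberTrack(pd.concat(pieces, ignore_index=True),
                           _validated=True)


def _mask_bins(df: pd.DataFrame, mask: MaskT) -> np.ndarray:
    """Boolean array: bin overlaps any mask interval."""
    out = np.zeros(len(df), dtype=bool)
    if not mask:
        return out
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chroms = df["chrom"].to_numpy()
    for mc, ms, me in mask:
        out |= (chroms == mc) & (starts < me) & (ends > ms)
    return out


def normalize_to_diploid(
    sample: CopyNumberTrack,
    control: CopyNumberTrack,
    *,
    bin_size: int = 5000,
    mask: MaskT = None,
    cpm: bool = True,
) -> CopyNumberTrack:
    """Ratio of sample to diploid-control coverage, euchromatic mean scaled to 1.

    Both tracks are (optionally) CPM-normalized, re-binned to ``bin_size``
    by width-weighted mean, and divided bin-by-bin. Bins where the control
    has no signal are dropped (ratio undefined). The result is rescaled so
    the mean over unmasked bins equals 1.
    """
    if cpm:
        sample = cpm_normalize(sample)
        control = cpm_normalize(control)
    s = rebin(sample, bin_size).df.set_index(["chrom", "start", "end"])
    c = rebin(control, bin_size).df.set_index(["chrom", "start", "end"])
    joined = s.join(c, lsuffix="_s", rsuffix="_c", how="inner")
    ok = joined["value_c"] > 0
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} bin(s) with zero control coverage dropped", stacklevel=2
        )
    joined = joined[ok]
    df = joined.reset_index()
    df["value"] = df["value_s"] / df["value_c"]
    df = df[["chrom", "start", "end", "value"]]
    masked = _mask_bins(df, mask)
    mean_unmasked = df.loc[~masked, "value"].mean()
    if not np.isfinite(mean_unmasked) or mean_unmasked <= 0:
        raise ValueError("cannot rescale: unmasked mean is not positive")
    df = df.copy()
    df["value"] = df["value"] / mean_unmasked
    return CopyNumberTrack(df.reset_index(drop=True), _validated=True)


# ---------------------------------------------------------------------------
# domain calling


def call_ur_domains(
    cn: CopyNumberTrack,
    *,
    min_length: int = 100_000,
    mask: MaskT = None,
    gap_tol: int = 1,
    genotype: str = "control",
) -> list[URDomain]:
    """Call underreplicated domains on a normalized copy-number track.

    Per chromosome (arm), bins strictly below the arm mean (computed over
    unmasked bins) are marked; consecutive marked bins are merged, allowing
    up to ``gap_tol`` intervening above-mean bins; merged runs spanning at
    least ``min_length`` bp and not overlapping the mask are reported.
    The domain's ⟨CN⟩ under ``genotype`` is the width-weighted mean of its
    bins.
    """
    domains: list[URDomain] = []
    for chrom in cn.chroms:
        sub = cn.chrom_view(chrom).reset_index(drop=True)
        span = int(sub["end"].max() - sub["start"].min())
        if span < min_length:
            warnings.warn(
                f"{chrom}: arm span {span} bp < min_length; no calls",
                stacklevel=2,
            )
            continue
        masked = _mask_bins(sub, mask)
        if masked.all():
            continue
        arm_mean = float(sub.loc[~masked, "value"].mean())
        below = (sub["value"].to_numpy() < arm_mean) & ~masked
        idx = np.flatnonzero(below)
        if idx.size == 0:
            continue
        # merge runs allowing gaps of <= gap_tol bins
        runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
        for i in idx[1:]:
            if i - runs[-1][1] <= gap_tol + 1:
                runs[-1][1] = int(i)
            else:
                runs.append([int(i), int(i)])
        values = sub["value"].to_numpy()
        for a, b in runs:
            # Boundary refinement: gap-tolerant merging lets shallow
            # noise bins adjacent to a deep run chain onto it, so edge
            # bins above the midpoint between the arm mean and the run's
            # below-mean core are trimmed back.
            core = values[a : b + 1][below[a : b + 1]].mean()
            edge_thresh = 0.5 * (arm_mean + core)
            while a <= b and values[a] >= edge_thresh:
                a += 1
            while b >= a and values[b] >= edge_thresh:
                b -= 1
            if b < a:
                continue
            start = int(sub.loc[a, "start"])
            end = int(sub.loc[b, "end"])
            if end - start < min_length:
                continue
            rows = sub.iloc[a : b + 1]
            if _mask_bins(rows, mask).any():
                continue
            w = (rows["end"] - rows["start"]).to_numpy(dtype=float)
            mean_cn = float((rows["value"].to_numpy() * w).sum() / w.sum())
            domains.append(
                URDomain(chrom=chrom, start=start, end=end,
                         cn={genotype: mean_cn})
            )
    return domains


def domain_mean_cn(cn: CopyNumberTrack, domain: URDomain) -> float:
    """Width-weighted mean copy number of the track within a domain."""
    sub = cn.chrom_view(domain.chrom)
    s = np.maximum(sub["start"].to_numpy(), domain.start)
    e = np.minimum(sub["end"].to_numpy(), domain.end)
    w = np.clip(e - s, 0, None).astype(float)
    if w.sum() == 0:
        raise ValueError("domain has no overlapping bins")
    return float((sub["value"].to_numpy() * w).sum() / w.sum())


def recovery(cn_control: float, cn_mutant: float) -> float:
    """Percent of the UR copy-number deficit restored in a mutant.

    100·(⟨CN⟩_mut − ⟨CN⟩_ctrl)/(1 − ⟨CN⟩_ctrl); negative values mean the
    mutant deepened the deficit, values above 100 an overshoot past full
    replication. Undefined when the control shows no deficit (⟨CN⟩ ≥ 1).
    """
    if cn_control >= 1:
        raise ValueError(
            "recovery undefined: control copy number shows no deficit"
        )
    return 100.0 * (cn_mutant - cn_control) / (1.0 - cn_control)


def call_suppression(
    pvalues: Iterable[float], alpha: float = 0.01
) -> tuple[float, bool | None]:
    """Mean per-bin p-value over a domain and the strict p < α call.

    Returns ``(mean_p, flag)``; with no p-values the call is undefined
    (``(nan, None)``).
    """
    p = np.asarray([v for v in pvalues if np.isfinite(v)], dtype=float)
    if p.size == 0:
        return float("nan"), None
    mean_p = float(p.mean())
    return mean_p, bool(mean_p < alpha)


def perbin_test(
    sample: Sequence[float], control: Sequence[float]
) -> float:
    """Welch two-sample t-test on log-transformed bin values.

    A simple stand-in for a differential-coverage count model: it answers
    whether a bin's (log) coverage differs between genotypes across
    replicates. Requires ≥ 2 replicates per group. With zero variance in
    both groups, returns 1.0 for equal means and 0.0 otherwise.
    """
    a = np.log(np.asarray(sample, dtype=float))
    b = np.log(np.asarray(control, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def annotate_domains(
    domains: list[URDomain],
    *,
    control: str,
    mutant_cn: Mapping[str, CopyNumberTrack],
    mutant_pvalues: Mapping[str, Mapping[int, Sequence[float]]] | None = None,
    alpha: float = 0.01,
) -> list[URDomain]:
    """Fill per-mutant ⟨CN⟩, recovery, mean p and suppression flags in place.

    ``mutant_pvalues[mut][i]`` holds the per-bin p-values for domain ``i``.
    """
    for i, d in enumerate(domains):
        for mut, track in mutant_cn.items():
            d.cn[mut] = domain_mean_cn(track, d)
            d.recovery_pct[mut] = recovery(d.cn[control], d.cn[mut])
            if mutant_pvalues and mut in mutant_pvalues:
                mean_p, flag = call_suppression(
                    mutant_pvalues[mut].get(i, ()), alpha
                )
                d.mean_p[mut] = mean_p
                if flag is None:
                    d.suppressed[mut] = None
                else:
                    d.suppressed[mut] = flag and d.recovery_pct[mut] > 0
    return domains


# ---------------------------------------------------------------------------
# domain-table summaries


def load_domain_table(
    path: str | Path, *, control: str = "w1118", alpha: float = 0.01
) -> list[URDomain]:
    """Load a UR-domain report TSV into URDomain records.

    Expected columns: ``arm, start, end`` (1-based inclusive),
    ``cn_<control>`` and per mutant ``cn_<m>``, ``recovery_<m>``,
    ``p_<m>``. Suppression flags are (re)derived: mean p < α (strict) with
    positive recovery.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    mutants = [
        c[len("recovery_"):] for c in df.columns if c.startswith("recovery_")
    ]
    out: list[URDomain] = []
    for r in df.itertuples(index=False):
        d = URDomain(
            chrom=str(r.arm),
            start=int(r.start) - 1,     # report is 1-based inclusive
            end=int(r.end),
            cyto_band=str(getattr(r, "cyto_band", "")),
        )
        d.cn[control] = float(getattr(r, f"cn_{control}"))
        for m in mutants:
            d.cn[m] = float(getattr(r, f"cn_{m}"))
            d.recovery_pct[m] = float(getattr(r, f"recovery_{m}"))
            p = float(getattr(r, f"p_{m}"))
            d.mean_p[m] = p
            d.suppressed[m] = (p < alpha) and (d.recovery_pct[m] > 0)
        out.append(d)
    return out


def domains_to_frame(domains: list[URDomain], control: str) -> pd.DataFrame:
    """Tabular report with 1-based inclusive coordinates."""
    mutants = sorted({m for d in domains for m in d.recovery_pct})
    rows = []
    for d in domains:
        row = {
            "arm": d.chrom,
            "start": d.start + 1,
            "end": d.end,
            "length_bp": d.length,
            f"cn_{control}": d.cn.get(control),
        }
        for m in mutants:
            row[f"cn_{m}"] = d.cn.get(m)
            row[f"recovery_{m}"] = d.recovery_pct.get(m)
            row[f"p_{m}"] = d.mean_p.get(m)
            row[f"suppressed_{m}"] = d.suppressed.get(m)
        rows.append(row)
    return pd.DataFrame(rows)


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = float((w * x).sum() / w.sum())
    var = float((w * (x - m) ** 2).sum() / w.sum())
    return m, float(np.sqrt(var))


def summarize_domains(
    domains: list[URDomain], *, control: str
) -> dict:
    """Bottom-row style summary of a UR-domain table.

    Counts, unweighted mean length ± SD, length-weighted control ⟨CN⟩ ± SD,
    and per mutant: the number of suppressed domains and the
    length-weighted mean recovery ± SD over suppressed domains only.
    """
    if not domains:
        raise ValueError("no domains to summarize")
    L = np.array([d.length for d in domains], dtype=float)
    cn = np.array([d.cn[control] for d in domains], dtype=float)
    cn_mean, cn_sd = _weighted_mean_sd(cn, L)
    out = {
        "n_domains": len(domains),
        "mean_length_bp": float(L.mean()),
        "sd_length_bp": float(L.std(ddof=1)) if len(domains) > 1 else 0.0,
        "weighted_mean_cn": cn_mean,
        "weighted_sd_cn": cn_sd,
        "mutants": {},
    }
    mutants = sorted({m for d in domains for m in d.recovery_pct})
    for m in mutants:
        sup = [d for d in domains if d.suppressed.get(m)]
        entry: dict = {"n_suppressed": len(sup)}
        if sup:
            w = np.array([d.length for d in sup], dtype=float)
            r = np.array([d.recovery_pct[m] for d in sup], dtype=float)
            rm, rs = _weighted_mean_sd(r, w)
            entry.update(
                weighted_mean_recovery_pct=rm,
                weighted_sd_recovery_pct=rs,
                mean_length_bp=float(w.mean()),
            )
        out["mutants"][m] = entry
    return out


# ---------------------------------------------------------------------------
# qPCR ΔΔCt


def ddct(
    ct: CtTable,
    *,
    control_amplicon: str,
    control_group: str,
) -> list[DdCtResult]:
    """ΔΔCt copy-number estimates for every (amplicon, group) pair.

    For target amplicon t in sample group g:
    ⟨ΔΔCt⟩ = (⟨Ct_t⟩ − ⟨Ct_ctrl⟩)_g − (⟨Ct_t⟩ − ⟨Ct_ctrl⟩)_control_group,
    σ_ΔΔCt = sqrt((σ²_t + σ²_ctrl)/2) with the sample group's replicate
    SDs, copy number = 2^−⟨ΔΔCt⟩ and CI = [2^(−⟨ΔΔCt⟩−σ), 2^(−⟨ΔΔCt⟩+σ)].
    The σ propagation follows the stated protocol verbatim, averaging the
    two variances rather than summing them.
    """
    groups = ct.groups
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} absent")
    for g in groups:
        if (control_amplicon, g) not in ct.cts:
            raise ValueError(
                f"control amplicon {control_amplicon!r} missing in group {g!r}"
            )
    results: list[DdCtResult] = []
    for g in groups:
        if g == control_group:
            continue
        ctl_g = ct.replicates(control_amplicon, g)
        ctl_e = ct.replicates(control_amplicon, control_group)
        for amp in ct.amplicons:
            if amp == control_amplicon or (amp, g) not in ct.cts:
                continue
            if (amp, control_group) not in ct.cts:
                raise ValueError(
                    f"amplicon {amp!r} missing in control group"
                )
            tgt_g = ct.replicates(amp, g)
            tgt_e = ct.replicates(amp, control_group)
            d = (tgt_g.mean() - ctl_g.mean()) - (tgt_e.mean() - ctl_e.mean())
            sig_t = tgt_g.std(ddof=1) if tgt_g.size > 1 else 0.0
            sig_c = ctl_g.std(ddof=1) if ctl_g.size > 1 else 0.0
            sigma = float(np.sqrt((sig_t**2 + sig_c**2) / 2.0))
            cn = float(2.0 ** (-d))
            ci = (float(2.0 ** (-d - sigma)), float(2.0 ** (-d + sigma)))
            results.append(
                DdCtResult(
                    amplicon=amp, group=g, ddct=float(d),
                    sigma=sigma, copy_number=cn, ci=ci,
                )
            )
    return results
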