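"""Bait correlation ranking and trend-outlier partner detection.

Every stitched profile is Pearson-correlated with the bait's and proteins
are ranked from the highest coefficient down. Sorted this way, the bulk of
the proteome traces a smooth rank-vs-PCC curve; genuine complex partners
co-elute with the bait through every column and sit *above* the curve. The
decision stage fits a polynomial trend to the bottom of the ranking
(excluding the bait and the candidates under test), extrapolates it to the
top ranks, and flags candidates whose observed PCC both exceeds the
extrapolation by more than ``c`` fit-RMSEs and clears the stable-complex
co-elution floor (``min_pcc``), walking down the ranking until the first
non-outlier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import StitchedProfile

__all__ = [
    "RankedCorrelation",
    "correlate_to_bait",
    "fit_trend",
    "detect_partners",
]


@dataclass
class RankedCorrelation:
    """Proteins ranked by Pearson correlation to the bait profile."""

    bait: str
    #: columns: protein, pcc, rank (1-based); sorted by pcc descending,
    #: undefined (zero-variance) correlations last; ties broken by id.
    table: pd.DataFrame
    #: filled by fit_trend / detect_partners
    trend: np.ndarray | None = None
    trend_rmse: float | None = None
    partners: list[str] = field(default_factory=list)

    def pcc(self, protein: str) -> float:
        row = self.table.loc[self.table["protein"] == protein, "pcc"]
        if row.empty:
            raise KeyError(protein)
        return float(row.iloc[0])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        if self.trend is not None:
            out["trend_pred"] = self.trend
            out["residual"] = out["pcc"] - out["trend_pred"]
        out["partner"] = out["protein"].isin(self.partners)
        return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlate_to_bait(
    stitched: dict[str, StitchedProfile], bait: str
) -> RankedCorrelation:
    """Rank all stitched profiles by Pearson correlation to the bait's.

    The bait correlates with itself at exactly 1 and takes rank 1. A
    zero-variance profile has no defined correlation; it is recorded as
    missing and ranked last, with a warning.
    """
    if bait not in stitched:
        raise ValueError(f"bait {bait!r} not among stitched profiles")
    ref = stitched[bait].z_concat
    if ref.size < 3:
        raise ValueError("profiles must have length >= 3")
    if np.std(ref) == 0:
        raise ValueError("bait profile has zero variance")
    rows = []
    for pid, prof in stitched.items():
        z = prof.z_concat
        if z.size != ref.size:
            raise ValueError(f"profile length mismatch for {pid!r}")
        r = 1.0 if pid == bait else _pearson(z, ref)
        rows.append((pid, r))
    df = pd.DataFrame(rows, columns=["protein", "pcc"])
    if df["pcc"].isna().any():
        warnings.warn(
            "zero-variance profile(s) have undefined PCC; ranked last",
            stacklevel=2,
        )
    df = df.sort_values(
        ["pcc", "protein"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedCorrelation(bait=bait, table=df)


def fit_trend(
    ranked: RankedCorrelation,
    n_top_excluded: int = 2,
    degree: int = 5,
) -> tuple[np.ndarray, float]:
    """Fit a polynomial PCC-vs-rank trend to the bottom of the ranking.

    The top ``n_top_excluded`` ranks (bait plus candidates) are left out of
    the least-squares fit and the fitted polynomial is extrapolated over
    all ranks. Returns ``(predictions, rmse)`` where ``rmse`` is over the
    fitted (bottom) points only.
    """
    df = ranked.table
    finite = df["pcc"].notna().to_numpy()
    ranks = df["rank"].to_numpy(dtype=float)
    pcc = df["pcc"].to_numpy(dtype=float)
    fit_mask = finite & (ranks > n_top_excluded)
    n_fit = int(fit_mask.sum())
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if n_fit < degree + 2:
        raise ValueError(
            f"only {n_fit} points to fit a degree-{degree} polynomial; "
            "lower the degree or exclude fewer points"
        )
    # Domain-mapped Chebyshev-style scaling keeps the degree-5 Vandermonde
    # well conditioned on ranks 1..N.
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            poly = np.polynomial.Polynomial.fit(
                ranks[fit_mask], pcc[fit_mask], deg=degree
            )
        except np.exceptions.RankWarning:
            raise ValueError(
                "ill-conditioned trend fit; try a lower polynomial degree"
            ) from None
    pred = poly(ranks)
    resid = pcc[fit_mask] - pred[fit_mask]
    rmse = float(np.sqrt(np.mean(resid**2)))
    return pred, rmse


def detect_partners(
    ranked: RankedCorrelation,
    *,
    degree: int = 5,
    c: float = 3.0,
    min_pcc: float | None = 0.9,
    max_partners: int | None = None,
) -> RankedCorrelation:
    """Flag above-trend candidate partners by fixed-point iteration.

    The trend is fit on the bottom N − k ranks, k = bait + currently
    flagged candidates, and extrapolated over the excluded top. The
    flagged set is then re-derived as the contiguous run of ranks
    (starting at rank 2; rank 1 is the bait) whose residual over the
    extrapolated trend exceeds ``c`` × fit RMSE *and* whose PCC reaches
    ``min_pcc``, and the fit is repeated
    until the set stabilizes. The minimum-correlation condition is what
    controls false calls: residuals of a fitted *sorted* curve are tiny
    and autocorrelated, so the top order statistic of unrelated profiles
    routinely clears any pure residual band, whereas subunits of a stable
    stoichiometric complex co-elute at near-perfect correlation (the
    conventional co-elution cutoff of 0.9 is the default; set
    ``min_pcc=None`` for the pure residual rule). The first fit excludes
    the bait and the rank-2 candidate (the bottom N − 2 configuration),
    so the candidate is always tested against an extrapolation it did not
    influence. The bait itself is reported separately (``ranked.bait``),
    never as a partner.

    Lowering ``c`` can only grow the flagged set at each fit (the
    threshold test is monotone). The returned object carries the final
    trend/RMSE (fit with bait + flagged candidates excluded) and the
    partner list.
    """
    df = ranked.table
    n = len(df)
    pcc = df["pcc"].to_numpy(dtype=float)

    def flag_run(trend: np.ndarray, rmse: float) -> list[str]:
        out: list[str] = []
        for r in range(2, n + 1):
            if max_partners is not None and len(out) >= max_partners:
                break
            v = pcc[r - 1]
            if not np.isfinite(v) or v - trend[r - 1] <= c * rmse:
                break
            if min_pcc is not None and v < min_pcc:
                break
            out.append(str(df.iloc[r - 1]["protein"]))
        return out

    partners: list[str] = []
    trend, rmse = fit_trend(ranked, n_top_excluded=2, degree=degree)
    for _ in range(n):
        new = flag_run(trend, rmse)
        if new == partners:
            break
        partners = new
        trend, rmse = fit_trend(
            ranked, n_top_excluded=1 + len(partners), degree=degree
        )
    out = RankedCorrelation(bait=ranked.bait, table=df.copy())
    out.trend = trend
    out.trend_rmse = rmse
    out.partners = partners
    return out
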