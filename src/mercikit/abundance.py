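"""Titration-curve semi-quantification and purification metrics.

DIA peak areas are only relative; to put a mass on the bait, a calibration
("titration") curve is built from acquisitions of known amounts of the
purified recombinant protein — here a tenfold dilution series spanning up
to eight orders of magnitude — and unknowns are read off the curve by
inverse prediction. The curve is fit as a straight line in
log10(signal) vs log10(mass), the natural model for a series that spans
µg to fg. Saturated top points (signal no longer increasing with mass) are
trimmed before fitting.

Purification bookkeeping: with bait mass b and total protein T per stage,
mass fraction = b/T, purity % = 100·b/T, and fold enrichment is the stage's
mass fraction over the starting material's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TitrationCurve",
    "PurificationSummary",
    "fit_titration",
    "estimate_mass",
    "purification_metrics",
]

PG_PER_UG = 1e6


@dataclass
class TitrationCurve:
    """log10–log10 linear calibration: log10(signal) = slope·log10(mass) + b."""

    slope: float
    intercept: float
    r2: float
    residual_sd: float          # SD of log10-signal residuals
    mass_range_pg: tuple[float, float]
    signal_range: tuple[float, float]
    n_points: int

    def predict_signal(self, mass_pg: float) -> float:
        return 10 ** (self.slope * np.log10(mass_pg) + self.intercept)


@dataclass
class PurificationStage:
    label: str
    bait_mass_pg: float
    total_protein_ug: float
    mass_fraction: float
    purity_pct: float
    fold: float


@dataclass
class PurificationSummary:
    stages: list[PurificationStage]

    def stage(self, label: str) -> PurificationStage:
        for s in self.stages:
            if s.label == label:
                return s
        raise KeyError(label)


def fit_titration(
    points: Sequence[tuple[float, float]],
    *,
    trim_saturated: bool = True,
) -> TitrationCurve:
    """Fit the log–log calibration line to (mass_pg, signal) points.

    Non-positive masses or signals are excluded with a warning (below the
    limit of detection). If ``trim_saturated``, top-of-range points whose
    signal is not greater than the next-lower mass's signal are dropped —
    detector saturation breaks the power-law regime.
    """
    pts = [(float(m), float(s)) for m, s in points]
    usable = [(m, s) for m, s in pts if m > 0 and s > 0]
    if len(usable) < len(pts):
        warnings.warn(
            f"excluded {len(pts) - len(usable)} non-positive titration "
            "point(s) (below detection)",
            stacklevel=2,
        )
    # average replicate signals per calibrant mass before fitting
    by_mass: dict[float, list[float]] = {}
    for m, s in usable:
        by_mass.setdefault(m, []).append(s)
    usable = [(m, float(np.mean(s))) for m, s in by_mass.items()]
    usable.sort()
    if trim_saturated:
        while len(usable) > 2 and usable[-1][1] <= usable[-2][1]:
            warnings.warn(
                f"excluded saturated top point at {usable[-1][0]:g} pg",
                stacklevel=2,
            )
            usable.pop()
    if len(usable) < 3:
        raise ValueError("need at least 3 usable titration points")
    lm = np.log10([m for m, _ in usable])
    ls = np.log10([s for _, s in usable])
    res = stats.linregress(lm, ls)
    resid = ls - (res.slope * lm + res.intercept)
    return TitrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        residual_sd=float(np.std(resid, ddof=2)) if len(usable) > 2 else 0.0,
        mass_range_pg=(usable[0][0], usable[-1][0]),
        signal_range=(min(s for _, s in usable), max(s for _, s in usable)),
        n_points=len(usable),
    )


def estimate_mass(
    curve: TitrationCurve, signal: float
) -> tuple[float, tuple[float, float], bool]:
    """Invert the calibration: signal → mass in pg.

    Returns ``(mass_pg, (lo, hi), extrapolated)``. The interval maps the
    ±1 residual-SD band on log10 signal through the inverse prediction;
    ``extrapolated`` is set when the signal falls outside the calibrated
    range.
    """
    if signal <= 0:
        raise ValueError("signal must be positive")
    extrapolated = not (
        curve.signal_range[0] <= signal <= curve.signal_range[1]
    )
    if extrapolated:
        warnings.warn(
            "signal outside calibrated range; extrapolating", stacklevel=2
        )
    ls = np.log10(signal)

    def inv(lsig: float) -> float:
        return 10 ** ((lsig - curve.intercept) / curve.slope)

    mass = inv(ls)
    band = sorted((inv(ls - curve.residual_sd), inv(ls + curve.residual_sd)))
    return float(mass), (float(band[0]), float(band[1])), extrapolated


def purification_metrics(
    stages: Sequence[tuple[str, float, float]],
) -> PurificationSummary:
    """Mass fraction, purity % and fold enrichment per purification stage.

    ``stages`` are ``(label, bait_mass_pg, total_protein_ug)`` in
    purification order; the first is the starting material (fold ≡ 1).
    """
    if not stages:
        raise ValueError("no stages")
    out: list[PurificationStage] = []
    init_fraction = None
    for label, bait_pg, total_ug in stages:
        if total_ug <= 0:
            raise ValueError(f"stage {label!r}: total protein must be > 0")
        if bait_pg <= 0:
            raise ValueError(f"stage {label!r}: bait mass must be > 0")
        frac = bait_pg / (total_ug * PG_PER_UG)
        if init_fraction is None:
            init_fraction = frac
        out.append(
            PurificationStage(
                label=label,
                bait_mass_pg=bait_pg,
                total_protein_ug=total_ug,
                mass_fraction=frac,
                purity_pct=100.0 * frac,
                fold=frac / init_fraction,
            )
        )
    return PurificationSummary(out)
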