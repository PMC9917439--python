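"""Pixel-level colocalization of two immunofluorescence channels.

Each channel's pixel intensities are Z-normalized over the whole image and
compared by squared Pearson correlation. Because two chromatin factors can
each also occupy loci the other does not, the scatter of (Z_a, Z_b) has
channel-exclusive lobes; exclusion rules — conjunctions of threshold
inequalities on the two Z values — remove those lobes so the r² reflects
only the putatively co-occupied pixels. The defaults reproduce the rules
(Z_b > 1 and Z_a < 3) and (Z_b < 1 and Z_a > 3) with thresholds 1 and 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ExclusionRule", "default_exclusions", "coloc_r2", "read_grayscale"]


@dataclass(frozen=True)
class ExclusionRule:
    """Conjunction of Z-threshold inequalities; matching pixels are dropped.

    Each bound is ``None`` (unconstrained) or a threshold; ``a`` is the
    first channel, ``b`` the second. A pixel is excluded by the rule when
    *all* stated inequalities hold.
    """

    a_gt: float | None = None
    a_lt: float | None = None
    b_gt: float | None = None
    b_lt: float | None = None

    def matches(self, za: np.ndarray, zb: np.ndarray) -> np.ndarray:
        m = np.ones(za.shape, dtype=bool)
        if self.a_gt is not None:
            m &= za > self.a_gt
        if self.a_lt is not None:
            m &= za < self.a_lt
        if self.b_gt is not None:
            m &= zb > self.b_gt
        if self.b_lt is not None:
            m &= zb < self.b_lt
        return m


def default_exclusions(low: float = 1.0, high: float = 3.0) -> list[ExclusionRule]:
    """Channel-exclusive lobes: (Z_b > low, Z_a < high) and (Z_b < low, Z_a > high)."""
    return [
        ExclusionRule(b_gt=low, a_lt=high),
        ExclusionRule(b_lt=low, a_gt=high),
    ]


def _zscore_image(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("channel has zero intensity variance")
    return (x - x.mean()) / sd


def coloc_r2(
    a: np.ndarray,
    b: np.ndarray,
    exclusions: list[ExclusionRule] | None = None,
) -> tuple[float, float, int]:
    """Squared Pearson correlation of two channels, with and without masking.

    Returns ``(r2_all, r2_masked, n_used)`` where ``n_used`` counts pixels
    surviving the exclusion rules. Z-normalization makes the result
    invariant to affine rescaling of either channel (and r² of Z equals r²
    of raw intensities).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    za = _zscore_image(a).ravel()
    zb = _zscore_image(b).ravel()
    r_all = np.corrcoef(za, zb)[0, 1]
    if exclusions is None:
        exclusions = default_exclusions()
    excluded = np.zeros(za.shape, dtype=bool)
    for rule in exclusions:
        excluded |= rule.matches(za, zb)
    keep = ~excluded
    n_used = int(keep.sum())
    if n_used < 2:
        raise ValueError("all pixels excluded; masked r² undefined")
    r_masked = np.corrcoef(za[keep], zb[keep])[0, 1]
    return float(r_all**2), float(r_masked**2), n_used


def read_grayscale(path) -> np.ndarray:
    """Read an image file as a 2-D grayscale float array (imageio helper)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img
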