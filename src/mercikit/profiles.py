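"""Cross-step stitched profiles and peak-fraction selection.

After each purification step is Z-scored independently, the per-step
profiles of a protein are concatenated ("stitched") in purification order
into a single array — e.g. five steps of 20+14+17+16+16 fractions give an
83-point array. Only proteins quantified in *every* step are stitched;
anything else cannot be correlated over the full purification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .normalize import NormalizedStepProfile, ZProfile

__all__ = [
    "StitchedProfile",
    "stitch",
    "select_peak_fractions",
    "write_stitched_tsv",
]


@dataclass
class StitchedProfile:
    """Concatenated per-step Z-arrays of one protein, in step order."""

    protein: str
    z_concat: np.ndarray
    #: step_id -> (start, stop) slice into ``z_concat``
    step_offsets: dict[int, tuple[int, int]]

    def step_slice(self, step_id: int) -> np.ndarray:
        a, b = self.step_offsets[step_id]
        return self.z_concat[a:b]


def stitch(
    zprofiles: Iterable[ZProfile],
    steps: Sequence[int],
    *,
    bait: str | None = None,
) -> tuple[dict[str, StitchedProfile], list[str]]:
    """Stitch per-step Z-profiles into full-purification arrays.

    Parameters
    ----------
    zprofiles : iterable of ZProfile
        Per-(protein, step) Z-scored elution profiles.
    steps : ordered step ids
        Purification order; at least two steps, each with at least two
        fractions.
    bait : optional protein id
        If given, its absence from any step is an error (nothing can be
        ranked against a bait that was not followed through every column).

    Returns
    -------
    (stitched, dropped)
        ``stitched`` maps protein id to its StitchedProfile; ``dropped``
        lists proteins excluded for missing at least one step.
    """
    steps = [int(s) for s in steps]
    if len(steps) < 2:
        raise ValueError("stitching needs at least two steps")
    by_protein: dict[str, dict[int, np.ndarray]] = {}
    step_len: dict[int, int] = {}
    for zp in zprofiles:
        if zp.step_id not in steps:
            continue
        z = np.asarray(zp.z, dtype=float)
        if zp.step_id in step_len and step_len[zp.step_id] != z.size:
            raise ValueError(
                f"inconsistent fraction count in step {zp.step_id}"
            )
        step_len.setdefault(zp.step_id, z.size)
        by_protein.setdefault(zp.protein, {})[zp.step_id] = z
    missing_steps = [s for s in steps if s not in step_len]
    if missing_steps:
        raise ValueError(f"no profiles for step(s) {missing_steps}")
    if any(step_len[s] < 2 for s in steps):
        raise ValueError("every step must have at least two fractions")

    offsets: dict[int, tuple[int, int]] = {}
    pos = 0
    for s in steps:
        offsets[s] = (pos, pos + step_len[s])
        pos += step_len[s]

    stitched: dict[str, StitchedProfile] = {}
    dropped: list[str] = []
    for protein in sorted(by_protein):
        per_step = by_protein[protein]
        if any(s not in per_step for s in steps):
            dropped.append(protein)
            continue
        z_concat = np.concatenate([per_step[s] for s in steps])
        stitched[protein] = StitchedProfile(protein, z_concat, dict(offsets))
    if bait is not None and bait not in stitched:
        raise ValueError(
            f"bait {bait!r} is not quantified in every step; cannot rank"
        )
    return stitched, dropped


def write_stitched_tsv(stitched: dict[str, StitchedProfile], path) -> None:
    """Export stitched Z-profiles as a proteins × points TSV matrix.

    The header comment line records the step offsets so the per-step
    blocks can be recovered.
    """
    if not stitched:
        raise ValueError("nothing to write")
    first = next(iter(stitched.values()))
    offsets = ";".join(
        f"{s}:{a}-{b}" for s, (a, b) in sorted(first.step_offsets.items())
    )
    with open(path, "w") as fh:
        fh.write(f"# step_offsets {offsets}\n")
        n = len(first.z_concat)
        fh.write("protein\t" + "\t".join(f"z{i}" for i in range(n)) + "\n")
        for pid in sorted(stitched):
            z = stitched[pid].z_concat
            fh.write(pid + "\t" + "\t".join(f"{v:.6g}" for v in z) + "\n")


def select_peak_fractions(
    profile: NormalizedStepProfile, k: int
) -> tuple[int, int, bool]:
    """Contiguous window of ≤ k fractions maximizing summed mean abundance.

    Returns ``(first_fraction, last_fraction, tied)`` in the profile's own
    fraction numbering. Ties keep the earliest window and set ``tied``.
    The choice is advisory — pooling fractions for the next column is a
    bench decision.
    """
    if k < 1:
        raise ValueError("window size k must be >= 1")
    x = np.nan_to_num(np.asarray(profile.values, dtype=float))
    if x.size == 0:
        raise ValueError("empty profile")
    best = (-np.inf, 0, 0)
    sums = []
    for w in range(1, min(k, x.size) + 1):
        csum = np.convolve(x, np.ones(w), mode="valid")
        for i, s in enumerate(csum):
            sums.append(s)
            if s > best[0]:
                best = (s, i, i + w - 1)
    tied = sum(1 for s in sums if np.isclose(s, best[0])) > 1
    fr = np.asarray(profile.fractions)
    return int(fr[best[1]]), int(fr[best[2]]), tied
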