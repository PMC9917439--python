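"""Readers, writers and validated containers for quantification inputs.

The containers are thin wrappers over pandas objects:

* :class:`RunTable` — protein × acquisition-run peak-area matrix with per-run
  metadata (FPLC step, fraction, replicate, role). Missing cells stay missing
  (NaN); a protein absent from a run's ion library is *not* a zero.
* :class:`ReferenceSet` — spike-in protein identifiers added at constant mass.
* :class:`CtTable` — qPCR cycle-threshold replicates per (amplicon, group).
* :class:`CopyNumberTrack` — sorted, non-overlapping binned genome track
  (bedGraph carrier; internal coordinates 0-based half-open).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "RunMeta",
    "RunTable",
    "ReferenceSet",
    "CtTable",
    "CopyNumberTrack",
    "read_run_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_ct_table",
    "read_bed_mask",
]


class Role(str, Enum):
    """What a chromatographic acquisition represents."""

    SM = "SM"          # starting material loaded onto the column
    FT = "FT"          # column flow-through
    FRACTION = "FRACTION"  # eluted column fraction


@dataclass(frozen=True)
class RunMeta:
    """Metadata of one MS acquisition run.

    ``step_id`` is the ordinal FPLC step (1..S) in purification order,
    ``fraction_index`` the position within the step's elution, and
    ``replicate_index`` the technical DIA replicate (1..R).
    """

    run_id: str
    step_id: int
    fraction_index: int
    replicate_index: int
    role: Role = Role.FRACTION

    def key(self) -> tuple[int, int, int]:
        return (self.step_id, self.fraction_index, self.replicate_index)


class RunTable:
    """Protein × run peak-area matrix plus run metadata.

    Parameters
    ----------
    areas : DataFrame
        Index = protein ids (unique strings), columns = run ids. Values are
        non-negative peak areas; NaN marks a protein not quantified in that
        run.
    runs : sequence of RunMeta
        One entry per column of ``areas``.
    """

    def __init__(self, areas: pd.DataFrame, runs: Sequence[RunMeta]):
        areas = areas.copy()
        areas.index = areas.index.astype(str)
        if areas.index.duplicated().any():
            dupes = sorted(set(areas.index[areas.index.duplicated()]))
            raise ValueError(f"duplicate protein id(s): {', '.join(dupes)}")
        run_ids = [r.run_id for r in runs]
        if sorted(run_ids) != sorted(map(str, areas.columns)):
            raise ValueError("run metadata does not match area columns")
        if len({r.key() for r in runs if r.role is Role.FRACTION}) != sum(
            1 for r in runs if r.role is Role.FRACTION
        ):
            raise ValueError("duplicate (step, fraction, replicate) run key")
        vals = areas.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            bad = areas.columns[(vals < 0).any(axis=0)][0]
            raise ValueError(f"negative peak area in run {bad!r}")
        self.areas = areas[run_ids].astype(float)
        self.runs: list[RunMeta] = list(runs)
        self._by_id = {r.run_id: r for r in runs}

    @property
    def proteins(self) -> list[str]:
        return list(self.areas.index)

    @property
    def step_ids(self) -> list[int]:
        return sorted({r.step_id for r in self.runs})

    def run_meta(self, run_id: str) -> RunMeta:
        return self._by_id[run_id]

    def fraction_runs(self) -> list[RunMeta]:
        """Runs representing eluted fractions (SM/FT excluded)."""
        return [r for r in self.runs if r.role is Role.FRACTION]

    def subset_steps(self, steps: Iterable[int]) -> "RunTable":
        keep = {int(s) for s in steps}
        runs = [r for r in self.runs if r.step_id in keep]
        return RunTable(self.areas[[r.run_id for r in runs]], runs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RunTable({len(self.proteins)} proteins × {len(self.runs)} runs, "
            f"steps {self.step_ids})"
        )


@dataclass(frozen=True)
class ReferenceSet:
    """Spike-in reference proteins added at a constant mass per sample."""

    ids: tuple[str, ...]
    mass_per_run_ug: float = 1.5

    def __post_init__(self):
        if not self.ids:
            raise ValueError("reference set must be non-empty")

    def validate_against(self, table: RunTable) -> None:
        missing = [i for i in self.ids if i not in set(table.proteins)]
        if missing:
            raise ValueError(
                f"reference protein(s) absent from table: {', '.join(missing)}"
            )


@dataclass
class CtTable:
    """qPCR Ct replicates per (amplicon, sample group)."""

    #: mapping (amplicon, group) -> 1-D array of replicate Ct values
    cts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def amplicons(self) -> list[str]:
        return sorted({a for a, _ in self.cts})

    @property
    def groups(self) -> list[str]:
        return sorted({g for _, g in self.cts})

    def replicates(self, amplicon: str, group: str) -> np.ndarray:
        try:
            return self.cts[(amplicon, group)]
        except KeyError:
            raise KeyError(f"no Ct values for ({amplicon!r}, {group!r})") from None


class CopyNumberTrack:
    """Sorted, non-overlapping binned genome track (0-based half-open)."""

    def __init__(self, df: pd.DataFrame, *, _validated: bool = False):
        if not _validated:
            df = self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        required = ["chrom", "start", "end", "value"]
        if list(df.columns[:4]) != required:
            df = df.rename(
                columns=dict(zip(df.columns[:4], required))
            )[required]
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["value"] = df["value"].astype(float)
        if (df["end"] <= df["start"]).any():
            i = df.index[(df["end"] <= df["start"])][0]
            raise ValueError(f"interval with end <= start at record {i}")
        if not np.isfinite(df["value"]).all():
            raise ValueError("non-finite track value")
        if (df["value"] < 0).any():
            raise ValueError("negative track value")
        sorted_df = df.sort_values(["chrom", "start"], kind="mergesort")
        if not sorted_df.index.equals(df.index):
            warnings.warn("track records were unsorted; sorting", stacklevel=3)
        sorted_df = sorted_df.reset_index(drop=True)
        prev_end = sorted_df["end"].shift()
        same_chrom = sorted_df["chrom"].eq(sorted_df["chrom"].shift())
        overlap = same_chrom & (sorted_df["start"] < prev_end)
        if overlap.any():
            i = int(np.flatnonzero(overlap.to_numpy())[0])
            r = sorted_df.iloc[i]
            raise ValueError(
                f"overlapping bins on {r.chrom} near {int(r.start)}"
            )
        return sorted_df

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def chrom_view(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CopyNumberTrack) and self.df.equals(other.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CopyNumberTrack({len(self)} bins on {len(self.chroms)} chroms)"


# ---------------------------------------------------------------------------
# readers / writers


def read_run_table(
    path: str | Path,
    manifest: str | Path | Mapping[str, Mapping] | None = None,
    *,
    sep: str = "\t",
    protein_col: str | None = None,
) -> RunTable:
    """Read a delimited protein-quantification table plus a run manifest.

    The first column (or ``protein_col``) holds protein ids; every other
    column is one acquisition run. Run metadata comes from ``manifest`` —
    a YAML/JSON file or mapping ``{run_id: {step, fraction, replicate,
    role}}`` — or, if omitted, is parsed from headers shaped
    ``s<step>f<fraction>r<replicate>`` (e.g. ``s1f3r2``), with ``SM``/``FT``
    in place of ``f<n>`` for non-fraction runs (``s1SMr1``).

    Empty cells are recorded as missing (NaN), never as zero.
    """
    df = pd.read_csv(path, sep=sep, comment="#", dtype={0: str})
    pcol = protein_col or df.columns[0]
    if df[pcol].duplicated().any():
        dupes = sorted(set(df[pcol][df[pcol].duplicated()]))
        raise ValueError(f"duplicate protein id(s): {', '.join(dupes)}")
    areas = df.set_index(pcol)
    areas.index.name = "protein"

    meta: Mapping[str, Mapping]
    if manifest is None:
        meta = {c: _parse_run_header(c) for c in areas.columns}
    elif isinstance(manifest, (str, Path)):
        import yaml

        with open(manifest) as fh:
            meta = yaml.safe_load(fh)
    else:
        meta = manifest

    runs = []
    for col in areas.columns:
        if col not in meta:
            raise ValueError(f"run {col!r} lacks metadata in manifest")
        m = meta[col]
        runs.append(
            RunMeta(
                run_id=str(col),
                step_id=int(m["step"]),
                fraction_index=int(m.get("fraction", 0)),
                replicate_index=int(m.get("replicate", 1)),
                role=Role(str(m.get("role", "FRACTION")).upper()),
            )
        )
    return RunTable(areas, runs)


def _parse_run_header(header: str) -> dict:
    import re

    m = re.fullmatch(r"s(\d+)(f(\d+)|SM|FT)r(\d+)", header)
    if not m:
        raise ValueError(
            f"run {header!r} lacks metadata: header not parseable and no manifest"
        )
    role = "FRACTION" if m.group(3) else m.group(2)
    return {
        "step": int(m.group(1)),
        "fraction": int(m.group(3) or 0),
        "replicate": int(m.group(4)),
        "role": role,
    }


def read_bedgraph(path: str | Path) -> CopyNumberTrack:
    """Read a 4-column bedGraph (0-based half-open) into a track."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed bedGraph line {ln}")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed bedGraph line {ln}: {exc}"
                ) from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return CopyNumberTrack(df)


def write_bedgraph(track: CopyNumberTrack, path: str | Path) -> None:
    """Write a track as 4-column bedGraph text (round-trip stable)."""
    with open(path, "w") as fh:
        for r in track.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.value:g}\n")


def read_bed_mask(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3+-column BED of excluded intervals (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split()
            out.append((p[0], int(p[1]), int(p[2])))
    return out


def read_ct_table(path: str | Path, *, sep: str = "\t") -> CtTable:
    """Read a long-format Ct table with columns amplicon, group, ct.

    Extra columns (replicate labels etc.) are ignored; each row is one
    replicate measurement.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    need = {"amplicon", "group", "ct"}
    if not need.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(need)}")
    cts: dict[tuple[str, str], np.ndarray] = {}
    for (amp, grp), sub in df.groupby(["amplicon", "group"], sort=False):
        cts[(str(amp), str(grp))] = sub["ct"].to_numpy(dtype=float)
    return CtTable(cts)
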