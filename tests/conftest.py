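import numpy as np
import pandas as pd
import pytest

from mercikit.quant_io import (
    CopyNumberTrack,
    ReferenceSet,
    Role,
    RunMeta,
    RunTable,
)


def make_run_table(values, *, step=1, n_reps=1, roles=None):
    """Build a RunTable from {protein: per-run list}; runs are fractions
    of one step unless ``roles`` overrides."""
    n_runs = len(next(iter(values.values())))
    runs = []
    for i in range(n_runs):
        frac, rep = divmod(i, n_reps)
        role = roles[i] if roles else Role.FRACTION
        runs.append(
            RunMeta(f"s{step}f{frac+1}r{rep+1}", step, frac + 1, rep + 1, role)
        )
    areas = pd.DataFrame(
        {r.run_id: [values[p][i] for p in values] for i, r in enumerate(runs)},
        index=pd.Index(list(values), name="protein"),
    )
    return RunTable(areas, runs)


def make_track(chrom_values, bin_size=50):
    """Build a CopyNumberTrack from {chrom: [v0, v1, ...]} uniform bins."""
    pieces = []
    for chrom, vals in chrom_values.items():
        n = len(vals)
        pieces.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(n) * bin_size,
                    "end": (np.arange(n) + 1) * bin_size,
                    "value": np.asarray(vals, dtype=float),
                }
            )
        )
    return CopyNumberTrack(pd.concat(pieces, ignore_index=True))


@pytest.fixture
def spike_refs():
    return ReferenceSet(("REF1", "REF2"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
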