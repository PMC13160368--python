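"""Delimited-text readers and writers for functional data and results.

Functional data files are wide form: first column ``t`` (the grid), one
column per function.  Warpings use the same layout.  Bands are written
with columns ``t, lower, upper, length``; distance matrices carry the
metric name in a header comment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .conformal import PhasePredictionSet, PredictionBand
from .elastic import FunctionalSample, InvalidInputError, Warping, _check_grid
from .partial import DistanceMatrix


def read_functions(path, sep=",") -> list[FunctionalSample]:
    """Read wide-format functional data; validates the grid invariants."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise InvalidInputError("expected a grid column plus at least one function")
    t = _check_grid(df.iloc[:, 0].to_numpy(dtype=float))
    return [
        FunctionalSample(grid=t, values=df.iloc[:, j].to_numpy(dtype=float))
        for j in range(1, df.shape[1])
    ]


def write_functions(path, functions: list[FunctionalSample], sep=",", names=None) -> None:
    t = functions[0].grid
    cols = {"t": t}
    for i, f in enumerate(functions):
        cols[names[i] if names else f"f{i + 1}"] = f.values
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_warpings(path, sep=",") -> list[Warping]:
    df = pd.read_csv(path, sep=sep)
    t = _check_grid(df.iloc[:, 0].to_numpy(dtype=float))
    return [Warping(grid=t, values=df.iloc[:, j].to_numpy(dtype=float)) for j in range(1, df.shape[1])]


def write_band(path, band: PredictionBand, sep=",") -> None:
    pd.DataFrame(
        {"t": band.grid, "lower": band.lower, "upper": band.upper, "length": band.lengths}
    ).to_csv(path, sep=sep, index=False)


def write_phase_set(path, pred: PhasePredictionSet, sep=",") -> None:
    """Envelope plus point prediction on the coarse grid; the accepted
    vectors go to ``<path>.accepted`` one row each."""
    pd.DataFrame(
        {
            "t": pred.coarse_grid,
            "envelope_lower": pred.envelope_lower,
            "envelope_upper": pred.envelope_upper,
            "point_prediction": pred.point_prediction,
        }
    ).to_csv(path, sep=sep, index=False)
    np.savetxt(str(path) + ".accepted", pred.accepted, delimiter=sep)


def write_distance_matrix(path, D: DistanceMatrix, sep=",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# metric: {D.metric_name}\n")
        np.savetxt(fh, D.entries, delimiter=sep)


def read_distance_matrix(path, sep=",") -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        metric = header.split(":", 1)[1].strip() if ":" in header else "unknown"
        entries = np.loadtxt(fh, delimiter=sep)
    return DistanceMatrix(entries=entries, metric_name=metric)
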