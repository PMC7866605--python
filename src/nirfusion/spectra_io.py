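"""Labelled spectra container and delimited-text I/O.

The central in-memory object is :class:`SpectraSet`: an ``n x m`` matrix of
intensities on a common wavenumber grid, with per-sample class labels
(storage age in years, treated as opaque identifiers), unique sample ids and
a sensor tag (outer skin, inner capsule, or the combined pseudo-sensor
produced by low-level fusion).

The file dialect is plain CSV: the header row carries the wavenumber grid
(``sample_id,label,v1,...,vm`` where ``v`` are the wavenumbers), and each
subsequent row is one sample.  Grids are stored in acquisition order, i.e.
descending from 12,000 to 3,500 cm^-1; any strictly monotone grid is
accepted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SENSORS = ("outer_skin", "inner_capsule", "combined")

#: Minimum number of channels; window-based operators additionally validate
#: their own window against the channel count.
MIN_CHANNELS = 3


class SpectraError(ValueError):
    """Raised for malformed spectra files or inconsistent SpectraSet inputs."""


def _as_2d_float(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2:
        raise SpectraError(f"intensities must be 2-D, got shape {a.shape}")
    return a


def validate_grid(values: np.ndarray) -> np.ndarray:
    """Validate a wavenumber grid: 1-D, length >= 3, strictly monotone."""
    g = np.asarray(values, dtype=float).ravel()
    if g.size < MIN_CHANNELS:
        raise SpectraError(f"grid too short ({g.size} < {MIN_CHANNELS} channels)")
    d = np.diff(g)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise SpectraError("grid not monotone")
    return g


@dataclass(frozen=True)
class SpectraSet:
    """Labelled spectra on a common wavenumber grid.

    Parameters
    ----------
    grid
        Wavenumbers in cm^-1, strictly monotone (descending allowed).
    intensities
        ``n x m`` array of reflectance-derived absorbance-like values.
    labels
        Length-``n`` class identifiers (compared by equality only).
    sensor
        One of ``outer_skin``, ``inner_capsule``, ``combined``.
    sample_ids
        Length-``n`` unique identifiers.
    """

    grid: np.ndarray
    intensities: np.ndarray
    labels: tuple
    sensor: str
    sample_ids: tuple = field(default=())

    def __post_init__(self):
        g = validate_grid(self.grid)
        x = _as_2d_float(self.intensities)
        labels = tuple(self.labels)
        ids = tuple(self.sample_ids) if self.sample_ids else tuple(
            f"s{i:04d}" for i in range(x.shape[0])
        )
        if x.shape[1] != g.size:
            raise SpectraError(
                f"{x.shape[1]} intensity columns vs {g.size} grid points"
            )
        if not (x.shape[0] == len(labels) == len(ids)):
            raise SpectraError(
                f"row mismatch: {x.shape[0]} spectra, {len(labels)} labels, "
                f"{len(ids)} sample_ids"
            )
        if len(set(ids)) != len(ids):
            raise SpectraError("duplicate sample_id")
        if self.sensor not in SENSORS:
            raise SpectraError(f"unknown sensor {self.sensor!r}; expected one of {SENSORS}")
        if x.size and not np.isfinite(x).all():
            raise SpectraError("non-finite intensity values")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "intensities", x)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", ids)

    # -- basic introspection -------------------------------------------------
    @property
    def n(self) -> int:
        return self.intensities.shape[0]

    @property
    def m(self) -> int:
        return self.intensities.shape[1]

    @property
    def classes(self) -> tuple:
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(sorted(seen, key=lambda v: (str(type(v)), v)))

    def with_intensities(self, x: np.ndarray, sensor: str | None = None) -> "SpectraSet":
        """Return a copy with new intensities (same grid/labels/ids)."""
        return replace(
            self, intensities=np.asarray(x, dtype=float),
            sensor=self.sensor if sensor is None else sensor,
        )

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            grid=self.grid,
            intensities=self.intensities[idx],
            labels=tuple(self.labels[i] for i in idx),
            sensor=self.sensor,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
        )


def read_spectra(path: str | os.PathLike, sensor: str) -> SpectraSet:
    """Read a SpectraSet from the CSV dialect written by :func:`write_spectra`.

    The header row is ``sample_id,label,<wavenumbers...>``; each data row is
    ``sample_id,label,v1..vm``.  Ragged rows, non-numeric cells, duplicate
    sample ids and non-monotone grids are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, header=0, dtype=str)
    if df.shape[1] < 2 + MIN_CHANNELS:
        raise SpectraError("file has too few columns for a spectra matrix")
    try:
        grid = np.array([float(c) for c in df.columns[2:]])
    except ValueError as e:
        raise SpectraError(f"non-numeric wavenumber in header: {e}") from e
    grid = validate_grid(grid)
    if df.isna().any().any():
        raise SpectraError("ragged or missing cells in spectra file")
    ids = tuple(df.iloc[:, 0].astype(str))
    labels = tuple(_parse_label(v) for v in df.iloc[:, 1])
    try:
        x = df.iloc[:, 2:].to_numpy(dtype=float)
    except ValueError as e:
        raise SpectraError(f"non-numeric intensity cell: {e}") from e
    return SpectraSet(grid=grid, intensities=x, labels=labels,
                      sensor=sensor, sample_ids=ids)


def _parse_label(v: str):
    """Labels are opaque; ints round-trip as ints, everything else as str."""
    s = str(v)
    try:
        return int(s)
    except ValueError:
        return s


def write_spectra(s: SpectraSet, path: str | os.PathLike) -> str:
    """Write ``s`` in the dialect read by :func:`read_spectra`, full precision."""
    cols = ["sample_id", "label"] + [repr(float(w)) for w in s.grid]
    df = pd.DataFrame(s.intensities, columns=cols[2:])
    df.insert(0, "label", list(s.labels))
    df.insert(0, "sample_id", list(s.sample_ids))
    df.columns = cols
    df.to_csv(path, index=False, float_format="%.17g")
    return str(path)


def average_replicates(replicates: Iterable[SpectraSet]) -> SpectraSet:
    """Element-wise mean of replicate measurements of the same samples.

    All replicates must share grid, sample order, labels and sensor; this is
    the triplicate-averaging step applied at acquisition time.
    """
    reps = list(replicates)
    if not reps:
        raise SpectraError("no replicates given")
    first = reps[0]
    for r in reps[1:]:
        if not np.array_equal(r.grid, first.grid):
            raise SpectraError("replicate grids differ")
        if r.sample_ids != first.sample_ids or r.labels != first.labels:
            raise SpectraError("replicate sample order or labels differ")
        if r.sensor != first.sensor:
            raise SpectraError("replicate sensors differ")
    mean = np.mean([r.intensities for r in reps], axis=0)
    return first.with_intensities(mean)
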