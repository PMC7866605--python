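"""Kennard-Stone calibration/test partitioning.

Kennard-Stone is the deterministic max-min design: seed the calibration set
with the two most distant samples (Euclidean distance in intensity space),
then repeatedly add the sample whose minimum distance to the already
selected set is largest, until the requested calibration size is reached.
The remainder forms the test set.  At the conventional 2:1 proportion a
200-sample set splits into 133 calibration and 67 test samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import SpectraSet


@dataclass(frozen=True)
class Partition:
    """Disjoint calibration/test index sets covering 0..n-1.

    ``cal_indices`` are in selection order (the order Kennard-Stone picked
    them); ``test_indices`` are ascending.
    """

    cal_indices: tuple[int, ...]
    test_indices: tuple[int, ...]

    def __post_init__(self):
        cal, test = set(self.cal_indices), set(self.test_indices)
        n = len(self.cal_indices) + len(self.test_indices)
        if cal & test or (cal | test) != set(range(n)):
            raise ValueError("cal/test indices must disjointly cover 0..n-1")

    @property
    def n(self) -> int:
        return len(self.cal_indices) + len(self.test_indices)


def default_cal_size(n: int, cal_fraction: float = 2.0 / 3.0) -> int:
    """Calibration size at a given proportion, rounded down."""
    return int(np.floor(n * cal_fraction))


def kennard_stone(s: SpectraSet | np.ndarray, n_cal: int) -> Partition:
    """Kennard-Stone split of ``s`` into ``n_cal`` calibration samples.

    Deterministic; all ties are broken toward the lowest index, so identical
    input always yields an identical partition.  Accepts a SpectraSet or a
    plain ``n x m`` matrix (e.g. the two sensors' spectra concatenated so
    both share one partition).
    """
    x = s.intensities if isinstance(s, SpectraSet) else np.asarray(s, dtype=float)
    n = x.shape[0]
    if not (2 <= n_cal <= n):
        raise ValueError(f"n_cal must be in [2, {n}], got {n_cal}")

    # full pairwise squared distances; n is a few hundred in practice
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)

    # seed pair: maximal distance; np.argmax scans row-major, so the first
    # occurrence realises the lowest-(i, j) tie rule
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    selected = [min(i, j), max(i, j)]
    mask = np.zeros(n, dtype=bool)
    mask[selected] = True
    mind2 = np.minimum(d2[selected[0]], d2[selected[1]])

    while len(selected) < n_cal:
        cand = np.where(mask, -np.inf, mind2)
        nxt = int(np.argmax(cand))  # first occurrence -> lowest index on ties
        selected.append(nxt)
        mask[nxt] = True
        np.minimum(mind2, d2[nxt], out=mind2)

    test = tuple(int(k) for k in range(n) if not mask[k])
    return Partition(cal_indices=tuple(selected), test_indices=test)
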