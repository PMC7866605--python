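"""Spectral pretreatment operators and the named recipe battery.

Fourteen recipes are exposed (the ``original`` identity, eight single
operators and five compositions), matching the battery commonly screened in
NIR classification work: de-bias (per-spectrum mean removal), detrend
(per-spectrum linear fit removal), SNV, MinMax scaling, MSC,
Savitzky-Golay first and second derivatives, a single-scale Mexican-hat
CWT, and the compositions 1stDer+DT, 1stDer+SNV, 1stDer+MSC, CWT+SNV,
CWT+MSC (named first = applied first).

All operators are row-local except MSC, whose reference spectrum is fitted
on the calibration set only and then applied unchanged to test spectra.
Index-based operators (detrend, derivatives, CWT) work on the channel index
with unit spacing; on a uniform wavenumber grid this differs from
d/d(wavenumber) only by a global scale, which downstream classifiers absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import savgol_filter

from .spectra_io import SpectraSet, SpectraError

#: Default Savitzky-Golay window (channels) and polynomial order.
DEFAULT_WINDOW = 15
DEFAULT_POLY = 2
#: Default CWT scale in channels.
DEFAULT_CWT_SCALE = 20.0

#: The closed set of recipe names (the rows of the screening tables).
RECIPE_NAMES = (
    "original", "debias", "dt", "snv", "minmax", "msc",
    "der1", "der2", "der1_dt", "der1_snv", "der1_msc",
    "cwt", "cwt_snv", "cwt_msc",
)


@dataclass(frozen=True)
class PretreatmentSpec:
    """A named pretreatment recipe with operator parameters."""

    name: str
    params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in RECIPE_NAMES:
            raise ValueError(
                f"unknown pretreatment {self.name!r}; expected one of {RECIPE_NAMES}"
            )


@dataclass(frozen=True)
class FittedPretreatment:
    """A recipe bound to calibration statistics (the MSC reference, if any)."""

    spec: PretreatmentSpec
    reference: np.ndarray | None = None

    def __post_init__(self):
        needs_ref = self.spec.name.endswith("msc")
        if needs_ref != (self.reference is not None):
            raise ValueError("MSC reference present iff the recipe involves MSC")


# ---------------------------------------------------------------------------
# single operators
# ---------------------------------------------------------------------------

def debias(s: SpectraSet) -> SpectraSet:
    """Subtract each spectrum's own mean (simple per-spectrum bias removal)."""
    x = s.intensities
    return s.with_intensities(x - x.mean(axis=1, keepdims=True))


def detrend(s: SpectraSet) -> SpectraSet:
    """Remove each spectrum's least-squares straight line over channel index."""
    x = s.intensities
    m = s.m
    if m < 2:
        raise SpectraError("detrend needs at least 2 channels")
    t = np.arange(m, dtype=float)
    # design [1, t]; project out its column space, per row
    A = np.column_stack([np.ones(m), t])
    coef, *_ = np.linalg.lstsq(A, x.T, rcond=None)
    return s.with_intensities(x - (A @ coef).T)


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: per row, (x - mean) / sd with n-1 denominator."""
    x = s.intensities
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.nonzero(sd.ravel() <= 0)[0]
    if bad.size:
        raise SpectraError(
            f"degenerate (constant) spectrum, sample_id={s.sample_ids[bad[0]]}"
        )
    return s.with_intensities((x - mu) / sd)


def minmax(s: SpectraSet) -> SpectraSet:
    """Scale each row to the range [0, 1]."""
    x = s.intensities
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    bad = np.nonzero(span.ravel() <= 0)[0]
    if bad.size:
        raise SpectraError(
            f"degenerate (constant) spectrum, sample_id={s.sample_ids[bad[0]]}"
        )
    return s.with_intensities((x - lo) / span)


def msc_fit(cal: SpectraSet, spec: PretreatmentSpec | None = None) -> FittedPretreatment:
    """Fit MSC on calibration data: the reference is the column-wise mean."""
    if cal.n < 2:
        raise SpectraError("MSC needs at least 2 calibration spectra")
    return FittedPretreatment(
        spec=spec or PretreatmentSpec("msc"),
        reference=cal.intensities.mean(axis=0),
    )


def msc_apply(f: FittedPretreatment, s: SpectraSet) -> SpectraSet:
    """Correct each spectrum against the calibration reference.

    Per row ``x``: ordinary least squares ``x ~ a + b * reference``; the
    corrected spectrum is ``(x - a) / b``.  Test rows reuse the
    calibration-fitted reference (no refit).
    """
    ref = f.reference
    if ref is None:
        raise SpectraError("FittedPretreatment carries no MSC reference")
    if ref.size != s.m:
        raise SpectraError("MSC reference grid length mismatch")
    x = s.intensities
    rc = ref - ref.mean()
    denom = rc @ rc
    b = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
    a = x.mean(axis=1) - b * ref.mean()
    bad = np.nonzero(np.abs(b) < 1e-12)[0]
    if bad.size:
        raise SpectraError(
            f"non-correctable spectrum (slope ~ 0), sample_id={s.sample_ids[bad[0]]}"
        )
    return s.with_intensities((x - a[:, None]) / b[:, None])


def derivative(s: SpectraSet, order: int, window: int = DEFAULT_WINDOW,
               poly: int = DEFAULT_POLY) -> SpectraSet:
    """Savitzky-Golay derivative along the channel index with unit spacing.

    Output keeps length ``m``: edge values come from the polynomial fitted to
    the nearest full window (``mode='interp'``).
    """
    if order not in (1, 2):
        raise SpectraError("derivative order must be 1 or 2")
    if window % 2 == 0 or window > s.m:
        raise SpectraError(f"window must be odd and <= m, got {window}")
    if poly >= window or order > poly:
        raise SpectraError(f"need order <= poly < window, got order={order}, poly={poly}")
    d = savgol_filter(s.intensities, window_length=window, polyorder=poly,
                      deriv=order, delta=1.0, axis=1, mode="interp")
    return s.with_intensities(d)


def mexh_wavelet(scale: float, m: int) -> np.ndarray:
    """Sampled Mexican-hat (second derivative of Gaussian) at the given scale.

    Support is +-8 scale channels (clipped to the spectrum length).  The
    sample mean is subtracted so the discrete filter is exactly zero-mean,
    preserving the admissibility property under discretisation.
    """
    half = min(int(np.ceil(8 * scale)), m - 1)
    t = np.arange(-half, half + 1, dtype=float) / scale
    psi = (2.0 / (np.sqrt(3.0) * np.pi ** 0.25)) * (1.0 - t**2) * np.exp(-t**2 / 2.0)
    return psi - psi.mean()


def cwt_transform(s: SpectraSet, scale: float = DEFAULT_CWT_SCALE) -> SpectraSet:
    """Single-scale continuous wavelet transform with the Mexican-hat wavelet.

    Coefficients are the direct discretised convolution of each spectrum
    with the sampled wavelet, scaled by ``1/sqrt(scale)``, with mirrored
    edges.  Acts as a derivative-like background suppressor: the wavelet is
    zero-mean and symmetric, so constant rows map to zero everywhere and
    linear baselines to zero away from the edges.  Output length equals the
    input length.
    """
    if scale <= 0:
        raise SpectraError("CWT scale must be positive")
    psi = mexh_wavelet(scale, s.m)
    out = convolve1d(s.intensities, psi, axis=1, mode="mirror") / np.sqrt(scale)
    return s.with_intensities(out)


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

def _steps(name: str) -> tuple[str, ...]:
    return {
        "original": (),
        "debias": ("debias",),
        "dt": ("dt",),
        "snv": ("snv",),
        "minmax": ("minmax",),
        "msc": ("msc",),
        "der1": ("der1",),
        "der2": ("der2",),
        "der1_dt": ("der1", "dt"),
        "der1_snv": ("der1", "snv"),
        "der1_msc": ("der1", "msc"),
        "cwt": ("cwt",),
        "cwt_snv": ("cwt", "snv"),
        "cwt_msc": ("cwt", "msc"),
    }[name]


def apply_recipe(spec: PretreatmentSpec | str, cal: SpectraSet,
                 test: SpectraSet) -> tuple[SpectraSet, SpectraSet]:
    """Apply a named recipe to calibration and test sets.

    Composite names apply the operator named first, first (``cwt_msc`` = CWT
    then MSC).  Any MSC reference is fitted on the calibration set at the
    stage where MSC occurs — never on test rows.
    """
    if isinstance(spec, str):
        spec = PretreatmentSpec(spec)
    if not np.array_equal(cal.grid, test.grid):
        raise SpectraError("calibration and test grids differ")
    p = spec.params
    window = int(p.get("window", DEFAULT_WINDOW))
    poly = int(p.get("poly", DEFAULT_POLY))
    cwt_scale = float(p.get("cwt_scale", DEFAULT_CWT_SCALE))

    for step in _steps(spec.name):
        if step == "debias":
            cal, test = debias(cal), debias(test)
        elif step == "dt":
            cal, test = detrend(cal), detrend(test)
        elif step == "snv":
            cal, test = snv(cal), snv(test)
        elif step == "minmax":
            cal, test = minmax(cal), minmax(test)
        elif step == "msc":
            fitted = msc_fit(cal, PretreatmentSpec("msc"))
            cal, test = msc_apply(fitted, cal), msc_apply(fitted, test)
        elif step == "der1":
            cal, test = derivative(cal, 1, window, poly), derivative(test, 1, window, poly)
        elif step == "der2":
            cal, test = derivative(cal, 2, window, poly), derivative(test, 2, window, poly)
        elif step == "cwt":
            cal, test = cwt_transform(cal, cwt_scale), cwt_transform(test, cwt_scale)
    return cal, test
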