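"""Far-UV band extrema and the helicity indices R1 and R2.

Helical polypeptides show a positive π–π*⊥ band near 190 nm and negative
bands near 204–208 nm (π–π*∥) and 222 nm (n–π*).  Two dimensionless indices
summarize helical content and helix type:

    R1 = |[Θ]_max / [Θ]_min|      (190-ish maximum over 204-ish minimum)
    R2 = |[Θ]_222 / [Θ]_min|

Both are scale-invariant, so they compare samples independent of
concentration or chain length.  Extrema are located by exhaustive scan within
configurable wavelength windows; an extremum landing on a window edge is
flagged rather than silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import RangeError, ValidationError
from .spectra import Spectrum

#: Default search windows (nm): positive band near 190, negative near 204-208.
POSITIVE_WINDOW = (188.0, 196.0)
NEGATIVE_WINDOW = (200.0, 212.0)
REFERENCE_WAVELENGTH = 222.0


@dataclass(frozen=True)
class Extremum:
    wavelength: float
    value: float
    at_edge: bool = False


@dataclass(frozen=True)
class HelicityIndices:
    theta_max: Extremum
    theta_min: Extremum
    theta_222: float
    r1: float
    r2: float


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table-presentation rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _window_indices(s: Spectrum, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < s.wavelengths[0] or hi > s.wavelengths[-1]:
        raise RangeError(f"window [{lo}, {hi}] outside spectral support "
                         f"[{s.wavelengths[0]}, {s.wavelengths[-1]}]")
    idx = np.nonzero((s.wavelengths >= lo) & (s.wavelengths <= hi))[0]
    if idx.size == 0:
        raise RangeError(f"no grid points inside window [{lo}, {hi}]")
    return idx


def find_extrema(s: Spectrum,
                 pos_window: tuple[float, float] = POSITIVE_WINDOW,
                 neg_window: tuple[float, float] = NEGATIVE_WINDOW,
                 ) -> tuple[Extremum, Extremum]:
    """Locate the maximum in ``pos_window`` and the minimum in ``neg_window``.

    Returns (theta_max, theta_min); each carries its wavelength and an
    ``at_edge`` flag set when the extremum sits on the window boundary
    (monotonic segment — the window likely missed the true band).
    """
    if max(pos_window[0], neg_window[0]) <= min(pos_window[1], neg_window[1]):
        raise ValidationError("extremum windows must not overlap")
    out = []
    for window, pick in ((pos_window, np.argmax), (neg_window, np.argmin)):
        idx = _window_indices(s, window)
        j = idx[int(pick(s.values[idx]))]
        at_edge = j == idx[0] or j == idx[-1]
        out.append(Extremum(float(s.wavelengths[j]), float(s.values[j]), at_edge))
    return out[0], out[1]


def indices_from_values(theta_max: float, theta_min: float, theta_222: float,
                        wl_max: float = 192.0, wl_min: float = 204.0,
                        ) -> HelicityIndices:
    """Table-reproduction mode: R1/R2 straight from three ellipticity values."""
    if theta_min == 0:
        raise ValidationError("theta_min is zero; R1/R2 undefined")
    return HelicityIndices(
        theta_max=Extremum(wl_max, theta_max),
        theta_min=Extremum(wl_min, theta_min),
        theta_222=theta_222,
        r1=abs(theta_max / theta_min),
        r2=abs(theta_222 / theta_min),
    )


def helicity_indices(s: Spectrum,
                     pos_window: tuple[float, float] = POSITIVE_WINDOW,
                     neg_window: tuple[float, float] = NEGATIVE_WINDOW,
                     ref_wavelength: float = REFERENCE_WAVELENGTH,
                     ) -> HelicityIndices:
    """R1 and R2 of a far-UV mean-residue-ellipticity spectrum.

    The 222 nm reference is read from the nearest grid point (interpolated
    if off-grid).
    """
    theta_max, theta_min = find_extrema(s, pos_window, neg_window)
    theta_222 = s.value_at(ref_wavelength)
    if theta_min.value == 0:
        raise ValidationError("negative-band extremum is zero; R1/R2 undefined")
    return HelicityIndices(
        theta_max=theta_max,
        theta_min=theta_min,
        theta_222=theta_222,
        r1=abs(theta_max.value / theta_min.value),
        r2=abs(theta_222 / theta_min.value),
    )
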