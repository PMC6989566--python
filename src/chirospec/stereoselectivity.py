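"""Enantiomer assignment and the optical-purity / enantiomeric-excess calculus.

A tris-chelate Ru(II) polypyridyl chromophore bound to a protein shows a
bisignate exciton couplet in the near-UV ligand-centered band.  The couplet
sign encodes the propeller handedness: with the sign convention anchored to
the enantiopure Λ reference complex (Δε₂₉₅ = +114 M⁻¹cm⁻¹), a positive Δε at
295 nm means Λ is the bound major enantiomer and a negative one means Δ.

From the labeling-normalized difference spectrum (conjugate − parent mutant,
divided by the Ru:protein stoichiometry) the signed optical purity is

    op = Δε₂₉₅ / Δε_max   (= ee, numerically),

and the enantiomer mole fractions follow from the linear system
E_Λ − E_Δ = op, E_Λ + E_Δ = 1:

    E_Λ = (1 + op) / 2,   E_Δ = (1 − op) / 2,
    er  = E_major / E_minor,   Δ/Λ = E_Δ / E_Λ.

Signed op is the internal currency (positive = Λ-enriched); reports print
unsigned ee with the major-enantiomer label, matching chiroptical convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import RangeError, ValidationError
from .secondary_structure import round_half_away
from .spectra import DELTA_EPSILON, Spectrum, subtract

LAMBDA = "Λ"
DELTA = "Δ"
RACEMIC = "racemic"

#: |Δε| below this (M⁻¹cm⁻¹) is indistinguishable from instrument noise.
RACEMIC_THRESHOLD = 1.0

#: Allowed fractional overshoot of |op| beyond 1 before an error (noise slack).
OP_TOLERANCE = 0.02

REFERENCE_WAVELENGTH = 295.0


@dataclass(frozen=True)
class EnantiomerResult:
    """Full enantiomeric characterization of one conjugate.

    All numbers are unrounded; presentation rounding happens only in
    :func:`table_row`.  ``op`` is signed (positive = Λ-enriched); ``er`` is
    E_major/E_minor ≥ 1 (inf for an enantiopure sample).
    """

    delta_eps_295: float
    op: float
    ee_percent: float
    frac_lambda: float
    frac_delta: float
    er: float
    selection_ratio_dl: float      # E_Δ / E_Λ
    major: str
    clipped: bool = False


@dataclass(frozen=True)
class MassBalanceResult:
    residual: float
    opposite_majors: bool


def normalized_difference(conjugate: Spectrum, parent: Spectrum,
                          label_ratio: float) -> Spectrum:
    """(conjugate − parent) / label_ratio: per-bound-chromophore optical activity.

    The host protein contributes at full stoichiometry regardless of labeling,
    so the parent is subtracted first and only the chromophore residual is
    scaled by the Ru:protein ratio.
    """
    if not 0 < label_ratio <= 1.2:
        raise ValidationError("label_ratio must lie in (0, 1.2]")
    diff = subtract(conjugate, parent)
    out = diff.with_values(diff.values / label_ratio, label_ratio=label_ratio)
    return out


def assign_enantiomer(diff: Spectrum,
                      ref_wavelength: float = REFERENCE_WAVELENGTH,
                      racemic_threshold: float = RACEMIC_THRESHOLD,
                      ) -> tuple[str, bool]:
    """Major enantiomer from the couplet sign at the reference wavelength.

    Returns ``(assignment, couplet_consistent)``.  The couplet flag is True
    when a compensating lobe of opposite sign and comparable weight exists at
    shorter wavelength, as a genuine bisignate exciton couplet requires.
    """
    value = diff.value_at(ref_wavelength)
    if abs(value) < racemic_threshold:
        return RACEMIC, False
    assignment = LAMBDA if value > 0 else DELTA
    below = diff.wavelengths < ref_wavelength
    couplet = False
    if np.any(below):
        lobe = diff.values[below]
        opposite = -lobe if value > 0 else lobe
        couplet = bool(np.max(opposite) >= racemic_threshold)
    return assignment, couplet


def enantiomer_calculus(delta_eps_295: float, delta_eps_max: float = 114.0,
                        op_tolerance: float = OP_TOLERANCE) -> EnantiomerResult:
    """op, ee, mole fractions and ratios from the normalized Δε at 295 nm.

    ``delta_eps_max`` is the Δε of the enantiopure Λ reference at the same
    wavelength.  |op| marginally above 1 (noise) is clipped with a warning up
    to ``op_tolerance``; beyond that an error is raised since optical purity
    cannot exceed 1.
    """
    if not delta_eps_max > 0:
        raise ValidationError("delta_eps_max must be > 0")
    op = delta_eps_295 / delta_eps_max
    clipped = False
    if abs(op) > 1.0 + op_tolerance:
        raise ValidationError(
            f"|op| = {abs(op):.4f} exceeds 1 beyond the {op_tolerance:.0%} "
            "noise tolerance; optical purity cannot exceed 1")
    if abs(op) > 1.0:
        warnings.warn(f"|op| = {abs(op):.4f} > 1; clipping to ±1 (noise overshoot)")
        op = math.copysign(1.0, op)
        clipped = True
    frac_lambda = (1.0 + op) / 2.0
    frac_delta = 1.0 - frac_lambda
    hi, lo = max(frac_lambda, frac_delta), min(frac_lambda, frac_delta)
    er = hi / lo if lo > 0 else math.inf
    sel = frac_delta / frac_lambda if frac_lambda > 0 else math.inf
    major = RACEMIC if op == 0 else (LAMBDA if op > 0 else DELTA)
    return EnantiomerResult(
        delta_eps_295=delta_eps_295, op=op, ee_percent=abs(op) * 100.0,
        frac_lambda=frac_lambda, frac_delta=frac_delta, er=er,
        selection_ratio_dl=sel, major=major, clipped=clipped)


def analyze_conjugate(conjugate: Spectrum, parent: Spectrum, label_ratio: float,
                      delta_eps_max: float = 114.0,
                      ref_wavelength: float = REFERENCE_WAVELENGTH,
                      racemic_threshold: float = RACEMIC_THRESHOLD,
                      ) -> tuple[EnantiomerResult, str, bool]:
    """Full per-conjugate analysis: normalize, assign, run the calculus."""
    if conjugate.unit != DELTA_EPSILON or parent.unit != DELTA_EPSILON:
        raise ValidationError("conjugate and parent must be in delta_epsilon units")
    diff = normalized_difference(conjugate, parent, label_ratio)
    assignment, couplet = assign_enantiomer(diff, ref_wavelength, racemic_threshold)
    result = enantiomer_calculus(diff.value_at(ref_wavelength), delta_eps_max)
    return result, assignment, couplet


def estimate_op(diff: Spectrum, reference_couplet: Spectrum) -> float:
    """Signed optical purity by least-squares projection onto a reference couplet.

    The single-point Δε read at 295 nm carries the full per-point noise; when
    the couplet band shape is known (synthetic data, or a measured enantiopure
    reference spectrum), the amplitude is better estimated as the ordinary
    least-squares coefficient of the difference spectrum on the unit-purity Λ
    couplet evaluated on the same grid:

        op̂ = Σ d·u / Σ u·u,   u = pure-Λ reference couplet.

    Unbiased under additive zero-mean noise, with variance reduced by the
    effective number of informative grid points.
    """
    u = reference_couplet.values
    denom = float(np.dot(u, u))
    if denom == 0:
        raise ValidationError("reference couplet is identically zero")
    return float(np.dot(diff.values, u) / denom)


def unreacted_fraction_check(bound: EnantiomerResult, free: EnantiomerResult,
                             bound_moles: float, free_moles: float,
                             ) -> MassBalanceResult:
    """Mass balance between conjugate and recovered unreacted chromophore.

    Starting from a racemic labeling pool, chiral amounts must conserve:
    bound·op_bound + free·op_free = 0, so the free fraction is enriched in
    the enantiomer opposite to the bound one.  Returns the signed residual
    and whether the opposite-major check passes.
    """
    if bound_moles < 0 or free_moles < 0:
        raise ValidationError("amounts must be >= 0")
    if bound_moles == 0 and free_moles == 0:
        raise ValidationError("at least one amount must be positive")
    residual = bound_moles * bound.op + free_moles * free.op
    opposite = (bound.op * free.op < 0) or (bound.op == 0 and free.op == 0)
    return MassBalanceResult(residual=residual, opposite_majors=opposite)


def table_row(result: EnantiomerResult, name: str = "") -> dict:
    """Presentation-rounded report row (3 dp fractions/ratios, 1 dp ee%).

    The Δ/Λ selection ratio is recomputed from the rounded fractions, which
    is how such tables are conventionally typeset; the unrounded value stays
    available on :class:`EnantiomerResult`.
    """
    fl = round_half_away(result.frac_lambda, 3)
    fd = round_half_away(result.frac_delta, 3)
    return {
        "sample": name,
        "delta_eps_295": round_half_away(result.delta_eps_295, 2),
        "op": round_half_away(abs(result.op), 3),
        "ee_percent": round_half_away(result.ee_percent, 1),
        "frac_lambda": fl,
        "frac_delta": fd,
        "er": round_half_away(result.er, 3) if math.isfinite(result.er) else math.inf,
        "selection_ratio_dl": round_half_away(fd / fl, 3) if fl > 0 else math.inf,
        "major": result.major,
    }
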