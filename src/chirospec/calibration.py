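"""Unit calibration between observed ellipticity and molar CD quantities.

Conventions
-----------
Observed ellipticity θ comes off the spectropolarimeter in millidegrees.  The
molar ellipticity convention adopted throughout the package is the standard
spectroscopic one,

    [Θ]_M  (deg cm² dmol⁻¹) = 100 · θ(deg) / (c(mol/L) · l(cm))
                            = θ(mdeg) / (10 · c(mol/L) · l(cm)),

with the mean-residue flavor [Θ]_mrw = [Θ]_M / N for a chain of N peptide
bonds, and molar circular dichroism Δε = [Θ]/3298 (M⁻¹ cm⁻¹).  These are
linear, invertible maps; the scale factors live in
:class:`ExtinctionConstants` so they are visible configuration rather than
buried literals.

Concentrations are carried in mol/L everywhere inside the package.
Cytochrome concentration is quantified from the heme Soret band (ε = 332.9
mM⁻¹cm⁻¹ at 406 nm for the triheme protein), and labeling stoichiometry from
elemental Ru and Fe content assuming 3 Fe (hemes) per protein molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnitError, ValidationError
from .spectra import (DELTA_EPSILON, MEAN_RESIDUE_ELLIPTICITY, MILLIDEGREES,
                      MOLAR_ELLIPTICITY, SampleInfo, Spectrum)


@dataclass(frozen=True)
class ExtinctionConstants:
    """Calibration constants with their published defaults.

    soret_eps_mM : molar absorptivity of the triheme Soret band, mM⁻¹cm⁻¹ at 406 nm.
    ref_delta_eps_max : Δε at 295 nm of the enantiopure Λ reference complex, M⁻¹cm⁻¹.
    mre_to_de_factor : divisor converting molar ellipticity to Δε (treated as exact).
    """

    soret_eps_mM: float = 332.9
    ref_delta_eps_max: float = 114.0
    mre_to_de_factor: float = 3298.0


DEFAULT_CONSTANTS = ExtinctionConstants()


@dataclass(frozen=True)
class StoichiometryResult:
    """Labeling stoichiometry from elemental analysis."""

    ru_per_protein: float
    ru_conc: float                  # mol/L (any unit, consistent with fe_conc)
    fe_conc: float
    fe_per_protein_assumed: int = 3


def _require_unit(s: Spectrum, *units: str) -> None:
    if s.unit not in units:
        raise UnitError(f"expected unit in {units}, got {s.unit!r}")


def to_molar_ellipticity(s: Spectrum, info: SampleInfo) -> Spectrum:
    """millidegrees → molar ellipticity [Θ]_M (deg cm² dmol⁻¹)."""
    _require_unit(s, MILLIDEGREES)
    factor = 1.0 / (10.0 * info.protein_conc * info.pathlength)
    return s.with_values(s.values * factor, unit=MOLAR_ELLIPTICITY)


def to_mean_residue_ellipticity(s: Spectrum, info: SampleInfo) -> Spectrum:
    """millidegrees → mean residue ellipticity [Θ]_mrw = [Θ]_M / N."""
    if info.n_bonds is None:
        raise ValidationError("mean-residue conversion needs SampleInfo.n_bonds")
    molar = to_molar_ellipticity(s, info)
    return molar.with_values(molar.values / info.n_bonds,
                             unit=MEAN_RESIDUE_ELLIPTICITY)


def to_delta_epsilon(s: Spectrum,
                     constants: ExtinctionConstants = DEFAULT_CONSTANTS) -> Spectrum:
    """Molar ellipticity flavor → molar circular dichroism Δε = [Θ]/3298."""
    _require_unit(s, MOLAR_ELLIPTICITY, MEAN_RESIDUE_ELLIPTICITY)
    out = s.with_values(s.values / constants.mre_to_de_factor, unit=DELTA_EPSILON)
    out.meta["delta_eps_source"] = s.unit
    return out


def to_millidegrees(s: Spectrum, info: SampleInfo,
                    constants: ExtinctionConstants = DEFAULT_CONSTANTS) -> Spectrum:
    """Invert any calibrated unit back to observed millidegrees.

    A delta_epsilon spectrum inverts through the flavor recorded at
    conversion time (``meta['delta_eps_source']``, default molar).
    """
    if s.unit == MILLIDEGREES:
        return s
    if s.unit == DELTA_EPSILON:
        source = s.meta.get("delta_eps_source", MOLAR_ELLIPTICITY)
        s = s.with_values(s.values * constants.mre_to_de_factor, unit=source)
    if s.unit == MEAN_RESIDUE_ELLIPTICITY:
        if info.n_bonds is None:
            raise ValidationError("inverting mean-residue units needs n_bonds")
        s = s.with_values(s.values * info.n_bonds, unit=MOLAR_ELLIPTICITY)
    # molar ellipticity → millidegrees
    factor = 10.0 * info.protein_conc * info.pathlength
    return s.with_values(s.values * factor, unit=MILLIDEGREES)


def convert(s: Spectrum, to: str, info: SampleInfo | None = None,
            constants: ExtinctionConstants = DEFAULT_CONSTANTS) -> Spectrum:
    """Convert a millidegree spectrum to the requested calibrated unit.

    ``to`` ∈ {"molar", "mre", "deps", "deps_mre"}; "deps" goes through molar
    ellipticity (near-UV chromophore convention), "deps_mre" through the
    mean-residue flavor (far-UV protein convention).
    """
    if info is None:
        raise ValidationError("conversion needs SampleInfo")
    if to == "molar":
        return to_molar_ellipticity(s, info)
    if to == "mre":
        return to_mean_residue_ellipticity(s, info)
    if to == "deps":
        return to_delta_epsilon(to_molar_ellipticity(s, info), constants)
    if to == "deps_mre":
        return to_delta_epsilon(to_mean_residue_ellipticity(s, info), constants)
    raise ValidationError(f"unknown conversion target {to!r}")


def protein_conc_from_soret(a406: float, pathlength: float,
                            constants: ExtinctionConstants = DEFAULT_CONSTANTS) -> float:
    """Cytochrome concentration (mol/L) from Soret-band absorbance at 406 nm."""
    if a406 < 0:
        raise ValidationError("absorbance must be >= 0")
    if not pathlength > 0:
        raise ValidationError("pathlength must be > 0 (cm)")
    conc_mM = a406 / (constants.soret_eps_mM * pathlength)
    return conc_mM * 1e-3


def ru_per_protein(ru_conc: float, fe_conc: float,
                   fe_per_protein: int = 3) -> StoichiometryResult:
    """Labeling ratio Ru:protein from elemental Ru and Fe concentrations.

    The protein concentration is inferred from Fe assuming ``fe_per_protein``
    heme irons per molecule (3 for the triheme cytochrome).
    """
    if not fe_conc > 0:
        raise ValidationError("fe_conc must be > 0")
    if ru_conc < 0:
        raise ValidationError("ru_conc must be >= 0")
    ratio = ru_conc / (fe_conc / fe_per_protein)
    return StoichiometryResult(ru_per_protein=ratio, ru_conc=ru_conc,
                               fe_conc=fe_conc, fe_per_protein_assumed=fe_per_protein)
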